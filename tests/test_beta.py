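from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cervicomp import (
    DataError,
    DistanceMatrix,
    aitchison_distance,
    clr_transform,
    host_factor_screen,
    pairwise_permanova,
    pcoa,
    permanova,
    permdisp,
    replace_zeros,
    simulate_cohort,
    simulate_host_factors,
)
from cervicomp.io import SampleMetadata
from conftest import two_group_config


def dm_from_points(points):
    points = np.asarray(points, dtype=float)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    ids = [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))


def labels_for(dm, groups):
    return pd.Series(groups, index=dm.samples)


class TestPcoa:
    def test_collinear_points_single_axis_exact_embedding(self):
        dm = dm_from_points([[0.0], [1.0], [3.0], [7.0]])
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 1
        coords = res.coordinates.to_numpy()
        d = np.abs(coords - coords.T)
        np.testing.assert_allclose(d, dm.values, atol=1e-9)

    def test_aitchison_distances_fully_euclidean(self, cohort_distance):
        res = pcoa(cohort_distance)
        neg = res.eigenvalues[res.eigenvalues < 0]
        assert np.abs(neg).max(initial=0.0) < 1e-6 * res.eigenvalues[0]
        assert (np.diff(res.eigenvalues) <= 1e-9).all()  # descending

    def test_embedding_reproduces_distances(self, cohort_clr):
        small = clr_transform(
            replace_zeros(simulate_cohort(two_group_config(sizes=(5,), seed=2))[0]))
        dm = aitchison_distance(small)
        coords = pcoa(dm).coordinates.to_numpy()
        rebuilt = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(rebuilt, dm.values, atol=1e-9)

    def test_proportion_explained_sums_to_at_most_one(self, cohort_distance):
        res = pcoa(cohort_distance)
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-6)

    def test_too_few_samples(self):
        with pytest.raises(DataError, match="3 samples"):
            pcoa(dm_from_points([[0.0], [1.0]]))


class TestPermanova:
    def test_matches_exhaustive_enumeration(self, cohort_distance):
        """Permutation p agrees with the exact p over all 20 labelings (n=6)."""
        dm = cohort_distance.submatrix(cohort_distance.samples[:6])
        labels = labels_for(dm, ["A", "A", "A", "B", "B", "B"])
        res = permanova(dm, labels, permutations=9999, seed=0)
        d2 = dm.values ** 2

        def pseudo_f(assignment):
            sst = d2.sum() / (2 * 6)
            ssw = 0.0
            for g in ("A", "B"):
                idx = np.flatnonzero(np.asarray(assignment) == g)
                ssw += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
            return ((sst - ssw) / 1) / (ssw / 4)

        f_obs = pseudo_f(labels.to_numpy())
        assert res.pseudo_f == pytest.approx(f_obs, abs=1e-12)
        count = sum(
            pseudo_f(["A" if i in trio else "B" for i in range(6)]) >= f_obs - 1e-12
            for trio in combinations(range(6), 3))
        exact_p = count / 20
        assert abs(res.p_value - exact_p) < 0.02

    def test_agrees_with_independent_implementation(self, cohort_distance, cohort):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        _, meta = cohort
        mine = permanova(cohort_distance, meta.diagnosis, permutations=99, seed=0)
        theirs = sk_permanova(SkDM(cohort_distance.values, ids=cohort_distance.samples),
                              meta.data, column="diagnosis", permutations=99)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_equal_distances_give_p_one(self):
        d = np.ones((6, 6)) - np.eye(6)
        ids = [f"s{i}" for i in range(6)]
        dm = DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))
        res = permanova(dm, labels_for(dm, ["A"] * 3 + ["B"] * 3),
                        permutations=199, seed=1)
        assert res.p_value == pytest.approx(1.0)

    def test_maximal_separation_hits_p_floor(self):
        rng = np.random.default_rng(0)
        points = np.vstack([rng.normal(0, 0.1, size=(10, 2)),
                            rng.normal(50, 0.1, size=(10, 2))])
        dm = dm_from_points(points)
        res = permanova(dm, labels_for(dm, ["A"] * 10 + ["B"] * 10),
                        permutations=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_r_squared_partition_identity(self, cohort_distance, cohort):
        _, meta = cohort
        res = permanova(cohort_distance, meta.diagnosis, permutations=99, seed=0)
        d2 = cohort_distance.values ** 2
        n = d2.shape[0]
        sst = d2.sum() / (2 * n)
        ssw = 0.0
        for g in meta.diagnosis.unique():
            idx = np.flatnonzero((meta.diagnosis == g).to_numpy())
            ssw += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
        assert res.r_squared + ssw / sst == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_joint_reordering(self, cohort_distance, cohort):
        _, meta = cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort_distance.samples)
        dm2 = cohort_distance.submatrix(perm)
        r1 = permanova(cohort_distance, meta.diagnosis, permutations=99, seed=5)
        r2 = permanova(dm2, meta.diagnosis.loc[perm], permutations=99, seed=5)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, abs=1e-9)

    def test_singleton_group_rejected(self, cohort_distance, cohort):
        _, meta = cohort
        labels = meta.diagnosis.copy()
        labels.iloc[0] = "CCU"
        labels.iloc[1:] = "Normal"
        with pytest.raises(DataError, match="fewer than 2"):
            permanova(cohort_distance, labels, permutations=99)


class TestPairwisePermanova:
    def test_six_comparisons_consistent_with_submatrix_runs(
            self, cohort_distance, cohort):
        _, meta = cohort
        results = pairwise_permanova(cohort_distance, meta.diagnosis,
                                     permutations=99, seed=0)
        assert len(results) == 6
        for res in results:
            samples = [s for s in cohort_distance.samples
                       if meta.diagnosis[s] in (res.group1, res.group2)]
            direct = permanova(cohort_distance.submatrix(samples),
                               meta.diagnosis.loc[samples], permutations=99, seed=1)
            assert res.pseudo_f == pytest.approx(direct.pseudo_f, abs=1e-9)
        qs = [r.q_value for r in results]
        ps = [r.p_value for r in results]
        assert all(q >= p - 1e-12 for q, p in zip(qs, ps))

    def test_power_normal_vs_ccu(self, template):
        """Distinct community profiles separate reliably at cohort sizes."""
        from cervicomp import CohortConfig

        hits = 0
        reps = 500
        for rep in range(reps):
            config = CohortConfig(
                seed=3000 + rep,
                group_sizes={"Normal": 25, "CCU": 10},
                profiles={"Normal": template["Normal"], "CCU": template["CCU"]})
            table, meta = simulate_cohort(config)
            dm = aitchison_distance(clr_transform(replace_zeros(table)))
            res = pairwise_permanova(dm, meta.diagnosis, permutations=199,
                                     seed=rep)[0]
            hits += res.q_value < 0.05
        assert hits / reps >= 0.9


class TestPermdisp:
    def test_duplicated_points_degenerate(self):
        dm = dm_from_points([[0, 0], [0, 0], [5, 5], [5, 5]])
        res = permdisp(dm, labels_for(dm, ["A", "A", "B", "B"]),
                       permutations=99, seed=0)
        assert res.degenerate
        assert res.p_value == 1.0
        assert all(v == pytest.approx(0.0) for v in res.group_dispersions.values())

    def test_null_rejection_rate_calibrated(self):
        rejections = 0
        reps = 200
        for rep in range(reps):
            table, _ = simulate_cohort(two_group_config(sizes=(24,), seed=5000 + rep))
            dm = aitchison_distance(clr_transform(replace_zeros(table)))
            labels = labels_for(dm, ["A"] * 12 + ["B"] * 12)
            res = permdisp(dm, labels, permutations=99, seed=rep)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_low_concentration_group_more_dispersed(self):
        from cervicomp import CohortConfig
        from test_simulate import uniform_profile

        profiles = {
            "Normal": uniform_profile("Normal", 50.0),
            "LSIL": uniform_profile("LSIL", 5.0),
        }
        table, meta = simulate_cohort(CohortConfig(
            seed=8, group_sizes={"Normal": 20, "LSIL": 20}, profiles=profiles))
        dm = aitchison_distance(clr_transform(replace_zeros(table)))
        res = permdisp(dm, meta.diagnosis, permutations=99, seed=0)
        assert res.group_dispersions["LSIL"] > res.group_dispersions["Normal"]


class TestHostFactorScreen:
    def test_factor_identical_to_diagnosis_reproduces_global(
            self, cohort_distance, cohort):
        _, meta = cohort
        augmented = SampleMetadata(
            meta.data.assign(mirror=meta.diagnosis.to_numpy()))
        screen = host_factor_screen(cohort_distance, augmented,
                                    factors=["mirror"], permutations=99, seed=0)
        direct = permanova(cohort_distance, meta.diagnosis, permutations=99, seed=0)
        assert screen.loc[0, "pseudo_F"] == pytest.approx(direct.pseudo_f, abs=1e-9)
        assert screen.loc[0, "n_levels"] == 4

    def test_null_factors_rarely_significant(self, cohort_distance, cohort):
        _, meta = cohort
        nonsig = 0
        reps = 100
        for rep in range(reps):
            augmented = simulate_host_factors(meta, ["shuffled"], n_levels=3,
                                              seed=rep)
            screen = host_factor_screen(cohort_distance, augmented,
                                        factors=["shuffled"],
                                        permutations=99, seed=rep)
            nonsig += screen.loc[0, "p_value"] > 0.05
        assert nonsig / reps >= 0.90

    def test_wide_factor_list_shape_and_skips(self, cohort_distance, cohort):
        _, meta = cohort
        augmented = simulate_host_factors(meta, 27, n_levels=3, seed=1)
        # a constant factor must be skipped with a warning, not tested
        data = augmented.data.assign(constant="same")
        screen = host_factor_screen(cohort_distance, SampleMetadata(data),
                                    permutations=99, seed=0)
        assert len(screen) == 27
        assert "constant" not in set(screen["factor"])
        assert (screen["p_value"].diff().dropna() >= -1e-12).all()  # sorted
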