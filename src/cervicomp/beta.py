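"""Ordination and distance-based multivariate tests.

PCoA (classical metric scaling), PERMANOVA, pairwise PERMANOVA with FDR
correction, PERMDISP (homogeneity of multivariate dispersions), and the
single-factor host-variable screen. The permutation machinery is implemented
here directly: permutation p-values use the convention that includes the
observed statistic, p = (1 + #{stat_perm >= stat_obs}) / (1 + P), which
guarantees p >= 1/(P+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cervicomp.composition import DistanceMatrix
from cervicomp.io import DataError, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues, proportion explained."""

    samples: list[str]
    coordinates: pd.DataFrame  # samples x retained axes (PCo1, PCo2, ...)
    eigenvalues: np.ndarray    # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    permutations: int
    n_groups: int
    n_samples: int
    group1: str | None = None
    group2: str | None = None
    q_value: float | None = None

    def summary(self) -> pd.Series:
        return pd.Series({
            "pseudo_F": self.pseudo_f, "R2": self.r_squared,
            "p_value": self.p_value, "permutations": self.permutations,
            "n_groups": self.n_groups, "n_samples": self.n_samples,
        })


@dataclass
class PermdispResult:
    f_statistic: float
    p_value: float
    group_dispersions: dict[str, float]
    permutations: int
    degenerate: bool = False


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical scaling of the Gower-centred matrix −½ J D² J.

    Axes with eigenvalue > 1e-8 × the largest eigenvalue are retained; small
    negative eigenvalues (numerical noise — Aitchison distances are Euclidean
    by construction) are truncated.
    """
    d = dm.values
    n = d.shape[0]
    if n < 3:
        raise DataError("pcoa needs at least 3 samples")
    d2 = d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-8 * max(eigvals[0], 0.0)
    keep = eigvals > tol
    pos_sum = eigvals[eigvals > 0].sum()
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    axes = [f"PCo{i + 1}" for i in range(int(keep.sum()))]
    return OrdinationResult(
        samples=dm.samples,
        coordinates=pd.DataFrame(coords, index=dm.samples, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=eigvals[keep] / pos_sum if pos_sum > 0 else eigvals[keep],
    )


def _group_codes(labels: pd.Series, samples: list[str]) -> tuple[np.ndarray, list[str]]:
    lab = labels.loc[samples]
    groups = list(pd.unique(lab))
    codes = lab.map({g: i for i, g in enumerate(groups)}).to_numpy()
    return codes, groups


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for c in range(n_groups):
        idx = np.flatnonzero(codes == c)
        ss += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return ss


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = _ss_within(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(dm: DistanceMatrix, labels: pd.Series, permutations: int = 9999,
              seed: int | None = None) -> PermanovaResult:
    """Distance-based PERMANOVA of a single grouping factor.

    SS_total = Σ_{i<j} d²_ij / n, SS_within pools the analogous per-group
    terms, and pseudo-F = (SS_between/(g−1)) / (SS_within/(n−g)); the p-value
    comes from seeded permutations of the group labels.
    """
    labels = pd.Series(labels)
    codes, groups = _group_codes(labels, dm.samples)
    n, g = codes.size, len(groups)
    if g < 2:
        raise DataError("permanova needs at least 2 groups")
    sizes = np.bincount(codes, minlength=g)
    if (sizes < 2).any():
        raise DataError(
            f"group {groups[int(np.argmin(sizes))]!r} has fewer than 2 samples"
        )
    d2 = dm.values ** 2
    if _ss_within(d2, codes, g) <= 0:
        raise DataError("degenerate design: zero within-group sum of squares")
    f_obs, r2 = _pseudo_f(d2, codes, g)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        f_perm, _ = _pseudo_f(d2, rng.permutation(codes), g)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + permutations)
    return PermanovaResult(f_obs, r2, p, permutations, g, n)


def pairwise_permanova(dm: DistanceMatrix, labels: pd.Series,
                       permutations: int = 9999, seed: int | None = None,
                       group_order=None) -> list[PermanovaResult]:
    """One PERMANOVA per unordered group pair, BH-corrected across pairs."""
    labels = pd.Series(labels)
    from itertools import combinations

    from cervicomp.alpha import bh_fdr

    groups = [g for g in (group_order or pd.unique(labels.loc[dm.samples]))
              if (labels == g).any()]
    results = []
    rng = np.random.default_rng(seed)
    for g1, g2 in combinations(groups, 2):
        samples = [s for s in dm.samples if labels.loc[s] in (g1, g2)]
        res = permanova(dm.submatrix(samples), labels.loc[samples],
                        permutations, seed=int(rng.integers(2 ** 31)))
        res.group1, res.group2 = g1, g2
        results.append(res)
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def _dispersions(coords: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    disp = np.empty(codes.size)
    for c in range(n_groups):
        idx = np.flatnonzero(codes == c)
        centroid = coords[idx].mean(axis=0)
        disp[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    return disp


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = values.size
    grand = values.mean()
    ssb = ssw = 0.0
    for c in range(n_groups):
        sub = values[codes == c]
        ssb += sub.size * (sub.mean() - grand) ** 2
        ssw += ((sub - sub.mean()) ** 2).sum()
    if ssw == 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


def permdisp(dm: DistanceMatrix, labels: pd.Series, permutations: int = 9999,
             seed: int | None = None) -> PermdispResult:
    """Homogeneity of multivariate dispersions (centroid variant).

    Samples are embedded by PCoA; a sample's dispersion is its Euclidean
    distance to its group centroid in that space. The observed one-way ANOVA
    F on dispersions is compared against seeded label permutations with the
    dispersions recomputed under each permuted grouping.
    """
    labels = pd.Series(labels)
    codes, groups = _group_codes(labels, dm.samples)
    g = len(groups)
    if g < 2:
        raise DataError("permdisp needs at least 2 groups")
    sizes = np.bincount(codes, minlength=g)
    if (sizes < 2).any():
        raise DataError(
            f"group {groups[int(np.argmin(sizes))]!r} has fewer than 2 samples"
        )
    coords = pcoa(dm).coordinates.to_numpy()
    disp_obs = _dispersions(coords, codes, g)
    per_group = {groups[c]: float(disp_obs[codes == c].mean()) for c in range(g)}
    if np.allclose(disp_obs, 0.0):
        logger.warning("permdisp: all dispersions are zero (degenerate input)")
        return PermdispResult(0.0, 1.0, per_group, permutations, degenerate=True)
    f_obs = _anova_f(disp_obs, codes, g)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        if _anova_f(_dispersions(coords, perm, g), perm, g) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + permutations)
    return PermdispResult(float(f_obs), p, per_group, permutations)


def host_factor_screen(dm: DistanceMatrix, metadata: SampleMetadata,
                       factors: list[str] | None = None,
                       permutations: int = 9999,
                       seed: int | None = None) -> pd.DataFrame:
    """Single-factor PERMANOVA per host variable, sorted by p-value.

    Each factor is tested independently on its non-missing samples; factor
    levels with fewer than two samples are dropped (logged) and factors left
    with fewer than two usable levels are skipped with a warning.
    """
    factors = factors if factors is not None else metadata.factors
    rng = np.random.default_rng(seed)
    rows = []
    for factor in factors:
        sub_seed = int(rng.integers(2 ** 31))
        if factor not in metadata.data.columns:
            logger.warning("host_factor_screen: unknown factor %r skipped", factor)
            continue
        values = metadata.data[factor]
        values = values[values.notna() & (values.astype(str).str.strip() != "")]
        values = values[values.index.isin(dm.samples)]
        counts = values.value_counts()
        small = counts[counts < 2].index
        if len(small):
            logger.info("host_factor_screen: %r dropping levels with <2 samples: %s",
                        factor, list(small))
            values = values[~values.isin(small)]
        if values.nunique() < 2:
            logger.warning("host_factor_screen: factor %r has <2 usable levels; skipped",
                           factor)
            continue
        samples = [s for s in dm.samples if s in values.index]
        res = permanova(dm.submatrix(samples), values.loc[samples],
                        permutations, seed=sub_seed)
        rows.append({"factor": factor, "pseudo_F": res.pseudo_f,
                     "p_value": res.p_value, "n_samples": res.n_samples,
                     "n_levels": res.n_groups})
    out = pd.DataFrame(rows, columns=["factor", "pseudo_F", "p_value",
                                      "n_samples", "n_levels"])
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
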