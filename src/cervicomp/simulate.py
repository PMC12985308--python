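"""Seeded synthetic cohort generator.

Generates genus-level count tables plus metadata whose group-specific genus
means, prevalences and dispersion gradient emulate a published cervicovaginal
cohort spanning the four diagnostic groups (Normal, LSIL, HSIL, CCU): Normal
communities are near-monodominant in *Lactobacillus*, intermediate lesions are
transitional, and invasive carcinoma shows *Lactobacillus* depletion with
expansion of anaerobic genera and markedly higher within-group dispersion.

Generative model per sample of group g (zero-inflated Dirichlet-multinomial):

1. presence indicator per genus ~ Bernoulli(prevalence);
2. composition over the present genera ~ Dirichlet(c_g * mean, renormalised
   to the present set), with c_g a group concentration controlling
   within-group dispersion (lower c -> more heterogeneous communities);
3. library size ~ round(lognormal), floored at 100 reads;
4. counts ~ 1 per present genus + Multinomial(remaining reads, composition),
   so a genus is detected (count > 0) exactly when drawn present.

Everything is driven by ``numpy.random.default_rng`` (PCG64) from a single
integer seed; the generator name and seed are part of output provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cervicomp.io import AbundanceTable, DataError, DIAGNOSES, SampleMetadata

logger = logging.getLogger(__name__)

#: Mean floor (fraction) for genera drawn present but whose configured group
#: mean is 0 — half the print resolution of a two-decimal percentage.
MEAN_FLOOR = 2.5e-5

FILLER_GENUS = "Other"

# Per-genus (mean relative abundance %, prevalence %) by diagnostic group,
# from the published per-group genus summary of the motivating cohort.
_TEMPLATE = {
    #                      Normal          LSIL            HSIL            CCU
    "Lactobacillus":      ((90.58, 100.00), (83.48, 95.65), (66.88, 91.67), (19.52, 80.00)),
    "Streptococcus":      ((4.83, 44.00),   (2.44, 47.83),  (5.91, 45.83),  (17.44, 60.00)),
    "Limosilactobacillus": ((2.65, 60.00),  (2.87, 47.83),  (0.67, 33.33),  (0.68, 30.00)),
    "Dialister":          ((0.52, 48.00),   (2.24, 52.17),  (1.72, 41.67),  (0.69, 40.00)),
    "Prevotella":         ((0.28, 28.00),   (1.82, 47.83),  (0.56, 25.00),  (4.06, 70.00)),
    "Staphylococcus":     ((0.27, 28.00),   (1.17, 39.13),  (0.08, 33.33),  (1.32, 30.00)),
    "Hoylesella":         ((0.13, 20.00),   (0.57, 26.09),  (0.28, 8.33),   (0.20, 40.00)),
    "Anaerococcus":       ((0.10, 28.00),   (0.29, 60.87),  (1.81, 33.33),  (5.16, 70.00)),
    "Peptoniphilus":      ((0.10, 40.00),   (0.52, 43.48),  (1.66, 33.33),  (1.83, 70.00)),
    "Fenollaria":         ((0.08, 16.00),   (0.60, 17.39),  (0.38, 12.50),  (0.07, 20.00)),
    "Campylobacter":      ((0.08, 24.00),   (0.24, 39.13),  (0.73, 16.67),  (0.36, 50.00)),
    "Finegoldia":         ((0.07, 48.00),   (0.25, 56.52),  (3.33, 41.67),  (1.71, 60.00)),
    "Fusobacterium":      ((0.02, 20.00),   (0.58, 17.39),  (1.95, 16.67),  (4.19, 30.00)),
    "Enterococcus":       ((0.00, 4.00),    (0.13, 21.74),  (0.03, 4.17),   (6.13, 30.00)),
    "Peptostreptococcus": ((0.00, 8.00),    (0.59, 17.39),  (1.29, 20.83),  (7.93, 50.00)),
    "Fannyhessea":        ((0.00, 0.00),    (0.24, 21.74),  (3.93, 25.00),  (5.07, 10.00)),
    "Pasteurella":        ((0.00, 0.00),    (0.00, 0.00),   (0.56, 4.17),   (6.88, 10.00)),
}

#: Default Dirichlet concentrations per group; the decreasing gradient
#: reproduces the cohort's increasing within-group dispersion with severity.
DEFAULT_CONCENTRATIONS = {"Normal": 50.0, "LSIL": 20.0, "HSIL": 20.0, "CCU": 5.0}

#: Default group sizes implied by the cohort's per-group prevalence
#: denominators (e.g. a 95.65% prevalence is 22/23).
DEFAULT_GROUP_SIZES = {"Normal": 25, "LSIL": 23, "HSIL": 24, "CCU": 10}


@dataclass
class GroupProfile:
    """Genus-level generative profile for one diagnostic group.

    ``means`` and ``prevalence`` are fractions in [0, 1] indexed by genus
    (including the filler genus ``Other`` absorbing the unprofiled remainder);
    ``concentration`` is the unitless Dirichlet scale c_g > 0.
    """

    group: str
    means: pd.Series
    prevalence: pd.Series
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise DataError("concentration must be > 0")
        if not self.means.index.equals(self.prevalence.index):
            raise DataError("means and prevalence must share a genus index")
        if (self.means < 0).any():
            raise DataError("genus means must be non-negative")
        if self.means.sum() > 1 + 1e-9:
            raise DataError("genus means must sum to at most 1")
        if ((self.prevalence < 0) | (self.prevalence > 1)).any():
            raise DataError("prevalence must lie in [0, 1]")
        if ((self.means > 0) & (self.prevalence == 0)).any():
            bad = self.means.index[(self.means > 0) & (self.prevalence == 0)][0]
            raise DataError(f"genus {bad!r} has positive mean but zero prevalence")

    @property
    def genera(self) -> list[str]:
        return list(self.means.index)


@dataclass
class CohortConfig:
    """Cohort-level simulation settings; fully determined by ``seed``."""

    seed: int = 0
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    profiles: dict[str, GroupProfile] | None = None
    depth_log_mean: float = float(np.log(50_000.0))
    depth_log_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.profiles is None:
            self.profiles = default_template()
        if self.depth_log_sd < 0:
            raise DataError("depth_log_sd must be >= 0")
        for group, n in self.group_sizes.items():
            if n < 1:
                raise DataError(f"group size for {group!r} must be >= 1")
            if group not in self.profiles:
                raise DataError(f"no profile for group {group!r}")


def default_template(concentrations: dict[str, float] | None = None
                     ) -> dict[str, GroupProfile]:
    """Group profiles emulating the published cohort's genus summaries.

    Returns the 17 profiled genera plus the filler genus ``Other`` that
    absorbs each group's remaining mean abundance (always present), so every
    profile's means sum to exactly 1.
    """
    concentrations = {**DEFAULT_CONCENTRATIONS, **(concentrations or {})}
    genera = list(_TEMPLATE)
    profiles: dict[str, GroupProfile] = {}
    for gi, group in enumerate(DIAGNOSES):
        means = pd.Series({g: _TEMPLATE[g][gi][0] / 100.0 for g in genera})
        prev = pd.Series({g: _TEMPLATE[g][gi][1] / 100.0 for g in genera})
        means[FILLER_GENUS] = max(0.0, 1.0 - means.sum())
        prev[FILLER_GENUS] = 1.0
        profiles[group] = GroupProfile(group, means, prev, concentrations[group])
    return profiles


def _sample_counts(profile: GroupProfile, depth: int, rng: np.random.Generator,
                   sample_label: str) -> np.ndarray:
    prev = profile.prevalence.to_numpy(dtype=float)
    means = profile.means.to_numpy(dtype=float)
    present = rng.random(prev.size) < prev
    if not present.any():
        logger.warning("sample %s drew no present genera; forcing Lactobacillus",
                       sample_label)
        present = rng.random(prev.size) < prev
        if "Lactobacillus" in profile.means.index:
            present[profile.means.index.get_loc("Lactobacillus")] = True
        else:
            present[int(np.argmax(means))] = True
    m = np.where(present, np.maximum(means, MEAN_FLOOR), 0.0)
    m /= m.sum()
    alpha = profile.concentration * m[present]
    gamma = rng.standard_gamma(alpha)
    if gamma.sum() == 0:  # all-tiny alphas can underflow; keep the largest part
        gamma[int(np.argmax(alpha))] = 1.0
    composition = gamma / gamma.sum()
    counts = np.zeros(prev.size, dtype=np.int64)
    n_present = int(present.sum())
    counts[present] = 1
    if depth > n_present:
        counts[present] += rng.multinomial(depth - n_present, composition)
    return counts


def simulate_cohort(config: CohortConfig) -> tuple[AbundanceTable, SampleMetadata]:
    """Draw a seeded synthetic cohort (count table + metadata).

    Sample identifiers are ``<group>_<k>``; genus columns are the union of all
    profile genera in template order. Identical configs (including seed) give
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    genera: list[str] = []
    for profile in config.profiles.values():
        for g in profile.genera:
            if g not in genera:
                genera.append(g)
    rows, sample_ids, labels = [], [], []
    for group, n in config.group_sizes.items():
        profile = config.profiles[group]
        aligned = GroupProfile(
            group,
            profile.means.reindex(genera, fill_value=0.0),
            profile.prevalence.reindex(genera, fill_value=0.0),
            profile.concentration,
        )
        for k in range(n):
            sid = f"{group}_{k + 1:02d}"
            depth = max(100, int(round(rng.lognormal(config.depth_log_mean,
                                                     config.depth_log_sd))))
            rows.append(_sample_counts(aligned, depth, rng, sid))
            sample_ids.append(sid)
            labels.append(group)
    table = AbundanceTable(
        pd.DataFrame(np.asarray(rows), index=sample_ids, columns=genera),
        mode="counts",
    )
    meta = SampleMetadata(pd.DataFrame({"diagnosis": labels}, index=sample_ids))
    return table, meta


def simulate_host_factors(meta: SampleMetadata, factors, n_levels: int = 3,
                          seed: int = 0) -> SampleMetadata:
    """Attach uniformly random categorical host factors (null factors).

    ``factors`` is a list of column names or an integer count (names become
    ``factor_01`` ...). Useful for exercising the host-factor screen under the
    null of no association.
    """
    if isinstance(factors, int):
        factors = [f"factor_{i + 1:02d}" for i in range(factors)]
    rng = np.random.default_rng(seed)
    df = meta.data.copy()
    levels = [f"level_{i + 1}" for i in range(n_levels)]
    for name in factors:
        df[name] = rng.choice(levels, size=len(df))
    return SampleMetadata(df)
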