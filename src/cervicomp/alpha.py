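"""Alpha diversity and the nonparametric group-comparison stack.

Richness S is the number of genera detected (relative abundance > 0) in a
sample; Shannon diversity H' = −Σ p_k ln p_k (natural log, nats) over the
detected genera, so 0 ≤ H' ≤ ln S. Group comparisons follow the standard
microbiome recipe: Kruskal–Wallis across all groups, pairwise Mann–Whitney U,
Benjamini–Hochberg FDR within each family, and Cliff's delta effect sizes
with the conventional magnitude labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cervicomp.io import AbundanceTable, DataError, DIAGNOSES

#: |delta| thresholds for negligible / small / medium / large effect labels.
MAGNITUDE_THRESHOLDS = (0.147, 0.33, 0.474)


def alpha_metrics(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample richness and Shannon diversity.

    Returns a DataFrame indexed by sample id with columns ``richness`` and
    ``shannon``. Counts are closed to relative abundances first; an all-zero
    sample has no defined composition and is an error.
    """
    props = table.to_proportions().data.to_numpy(dtype=float)
    richness = (props > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(props > 0, -props * np.log(props), 0.0)
    shannon = terms.sum(axis=1)
    return pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon},
        index=table.data.index,
    )


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from chi-square (g−1 df).

    All-identical data is the degenerate no-information case: H = 0, p = 1.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise DataError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def mann_whitney(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of x, p).

    ``auto`` uses the exact null distribution when the smaller sample has at
    most 8 observations and there are no ties, otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("mann_whitney needs non-empty samples")
    if method == "auto":
        no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
        method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cliffs_delta(x, y) -> tuple[float, str]:
    """Cliff's delta: P(x > y) − P(x < y) over all pairs, with magnitude label."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("cliffs_delta needs non-empty samples")
    diff = np.sign(x[:, None] - y[None, :])
    delta = float(diff.sum() / (x.size * y.size))
    return delta, magnitude_label(delta)


def magnitude_label(delta: float) -> str:
    a = abs(delta)
    if a < MAGNITUDE_THRESHOLDS[0]:
        return "Negligible"
    if a < MAGNITUDE_THRESHOLDS[1]:
        return "Small"
    if a < MAGNITUDE_THRESHOLDS[2]:
        return "Medium"
    return "Large"


@dataclass
class GroupComparisonResult:
    """Kruskal–Wallis summary plus the pairwise comparison table."""

    kw_statistic: float
    kw_pvalue: float
    pairwise: pd.DataFrame  # group1, group2, statistic, p_value, q_value, delta, magnitude


def compare_groups(values: pd.Series, labels: pd.Series,
                   group_order=DIAGNOSES) -> GroupComparisonResult:
    """Full nonparametric comparison of one per-sample metric across groups.

    Pairwise Mann–Whitney p-values form a single BH family across all group
    pairs; Cliff's delta is oriented as group1 vs group2 (positive when group1
    tends to be larger).
    """
    values = values.loc[labels.index] if not values.index.equals(labels.index) else values
    present = [g for g in group_order if (labels == g).any()]
    present += [g for g in pd.unique(labels) if g not in present]
    data = {g: values[labels == g].to_numpy(dtype=float) for g in present}
    h, p_kw = kruskal_wallis(data)
    rows = []
    for g1, g2 in combinations(present, 2):
        u, p = mann_whitney(data[g1], data[g2])
        delta, mag = cliffs_delta(data[g1], data[g2])
        rows.append({"group1": g1, "group2": g2, "statistic": u,
                     "p_value": p, "delta": delta, "magnitude": mag})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise.insert(4, "q_value", bh_fdr(pairwise["p_value"].to_numpy()))
    return GroupComparisonResult(h, p_kw, pairwise)


def alpha_comparisons(table: AbundanceTable, labels: pd.Series) -> pd.DataFrame:
    """Pairwise comparison table for both alpha metrics (one BH family each)."""
    metrics = alpha_metrics(table)
    frames = []
    for metric in ("richness", "shannon"):
        res = compare_groups(metrics[metric], labels)
        frame = res.pairwise.copy()
        frame.insert(0, "metric", metric)
        frame["kw_statistic"] = res.kw_statistic
        frame["kw_p_value"] = res.kw_pvalue
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
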