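"""Compositional log-ratio dysbiosis indices and their diagnostic evaluation.

Two indices summarise the transition from *Lactobacillus*-dominated to
anaerobe-rich community states on the CLR scale:

* the predefined *Lactobacillus*-to-anaerobe log-ratio — CLR(*Lactobacillus*)
  minus the mean CLR over a curated panel of obligate anaerobes, equal to
  ln(*Lactobacillus* proportion / geometric mean of the panel proportions);
* a data-driven composite ratio contrasting the genera consistently
  increased versus decreased in invasive carcinoma relative to Normal.

Low values of either index indicate dysbiosis. Group differences reuse the
nonparametric stack (Kruskal–Wallis, Mann–Whitney, BH-FDR, Cliff's delta);
diagnostic performance is evaluated with rank-based ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cervicomp.alpha import GroupComparisonResult, compare_groups
from cervicomp.composition import CLRMatrix, clr_subset_mean, clr_transform, replace_zeros
from cervicomp.io import AbundanceTable, DataError, SampleMetadata

#: Curated obligate-anaerobe panel; intersected with table columns at use.
DEFAULT_ANAEROBE_PANEL = (
    "Gardnerella", "Prevotella", "Dialister", "Anaerococcus", "Peptoniphilus",
    "Finegoldia", "Fannyhessea", "Fusobacterium", "Peptostreptococcus",
    "Sneathia", "Megasphaera", "Hoylesella",
)


def la_logratio(clr: CLRMatrix, panel=DEFAULT_ANAEROBE_PANEL,
                target: str = "Lactobacillus") -> pd.Series:
    """Per-sample *Lactobacillus*-to-anaerobe log-ratio.

    CLR(target) − mean CLR over the panel genera found in the matrix.
    """
    if target not in clr.data.columns:
        raise DataError(f"{target!r} not present in CLR matrix")
    usable = [g for g in panel if g in clr.data.columns and g != target]
    if not usable:
        raise DataError("anaerobe panel has no genera in common with the matrix")
    values = clr.data[target] - clr_subset_mean(clr, usable)
    values.name = "la_logratio"
    return values


def composite_sets(table: AbundanceTable, metadata: SampleMetadata,
                   tau: float = 1.0, min_prevalence: float = 0.2,
                   case: str = "CCU", control: str = "Normal",
                   pseudocount: float = 0.5, delta: float = 1e-6,
                   ) -> tuple[list[str], list[str]]:
    """Data-driven genus sets consistently increased / decreased in case vs control.

    A genus joins the increased (decreased) set when its mean CLR difference
    case − control exceeds +tau (falls below −tau) in natural-log units AND
    its detection prevalence is at least ``min_prevalence`` in the group where
    it is higher. Either set coming out empty means no consistent signal at
    these thresholds — an error suggesting to relax them.
    """
    labels = metadata.diagnosis
    for group in (case, control):
        if not (labels == group).any():
            raise DataError(f"group {group!r} not present in metadata")
    clr = clr_transform(replace_zeros(table, pseudocount, delta))
    case_ids = labels.index[labels == case]
    ctrl_ids = labels.index[labels == control]
    diff = clr.data.loc[case_ids].mean() - clr.data.loc[ctrl_ids].mean()
    detected = table.data > 0
    prev_case = detected.loc[case_ids].mean()
    prev_ctrl = detected.loc[ctrl_ids].mean()
    increased = [g for g in table.genera
                 if diff[g] > tau and prev_case[g] >= min_prevalence]
    decreased = [g for g in table.genera
                 if diff[g] < -tau and prev_ctrl[g] >= min_prevalence]
    if not increased or not decreased:
        raise DataError(
            "no genera pass the composite-set thresholds "
            f"(tau={tau}, min_prevalence={min_prevalence}); relax them"
        )
    return increased, decreased


def composite_logratio(clr: CLRMatrix, increased, decreased) -> pd.Series:
    """Per-sample mean CLR over the increased set minus the decreased set."""
    increased, decreased = list(increased), list(decreased)
    overlap = set(increased) & set(decreased)
    if overlap:
        raise DataError(f"increased and decreased sets overlap: {sorted(overlap)}")
    values = clr_subset_mean(clr, increased) - clr_subset_mean(clr, decreased)
    values.name = "composite_logratio"
    return values


def compare_index_across_groups(values: pd.Series, labels: pd.Series
                                ) -> GroupComparisonResult:
    """Kruskal–Wallis plus pairwise Mann–Whitney/FDR/Cliff's delta on an index."""
    return compare_groups(values, labels)


@dataclass
class RocResult:
    """ROC summary: rank-based AUC and the operating-point curve."""

    auc: float
    points: pd.DataFrame       # threshold, sensitivity, specificity
    positive_label: str
    higher_is_positive: bool


def roc_auc(values: pd.Series, labels: pd.Series, positive: str = "CCU",
            higher_is_positive: bool = False) -> RocResult:
    """ROC evaluation of an index against a binary class definition.

    AUC uses the Mann–Whitney rank formula with half credit for ties, after
    orienting scores so that higher means more likely positive (for the
    dysbiosis indices, *lower* values indicate disease, hence the default
    ``higher_is_positive=False``). Operating points classify a sample
    positive when its oriented score is >= the threshold.
    """
    values = pd.Series(values)
    labels = pd.Series(labels).loc[values.index]
    is_pos = (labels == positive).to_numpy()
    if not is_pos.any() or is_pos.all():
        raise DataError("both classes must be non-empty")
    scores = values.to_numpy(dtype=float)
    if not higher_is_positive:
        scores = -scores
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    ranks = stats.rankdata(scores)  # average ranks: half credit for ties
    auc = (ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    for t in thresholds:
        called = scores >= t
        rows.append({
            "threshold": t,
            "sensitivity": called[is_pos].mean(),
            "specificity": (~called[~is_pos]).mean(),
        })
    return RocResult(float(auc), pd.DataFrame(rows), positive, higher_is_positive)
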