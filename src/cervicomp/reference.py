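"""Published per-group summary inputs from a cervicovaginal cohort study.

These constants record, for each diagnostic group, the printed co-occurrence
network summary (number of genera retained after filtering, and the edge list
that passed the group's |rho|/q thresholds) and the HR-HPV positivity
contingency counts of the same cohort. They are *inputs* for verification:
network densities, component counts and contingency percentages are always
recomputed from them by code, never stored.

Only genera appearing in an edge are named in the source; the remaining
isolated nodes are synthesized placeholder labels (``isolate_k``), which
cannot affect any graph metric.
"""

from __future__ import annotations

import pandas as pd

#: Per-group printed network summaries: retained-node count, |rho| and
#: prevalence thresholds used, and the significant edges (genus1, genus2,
#: Spearman rho, q).
REFERENCE_NETWORKS: dict[str, dict] = {
    "Normal": {
        "n_nodes": 7,
        "prevalence_threshold": 0.30,
        "rho_threshold": 0.60,
        "edges": [
            ("Dialister", "Peptoniphilus", 0.68615385, 0.003),
        ],
    },
    "LSIL": {
        "n_nodes": 15,
        "prevalence_threshold": 0.30,
        "rho_threshold": 0.60,
        "edges": [
            ("Escherichia", "Shigella", 0.77569170, 0.001),
            ("Dialister", "Anaerococcus", 0.70750988, 0.008),
            ("Dialister", "Prevotella", 0.68873518, 0.009),
        ],
    },
    "HSIL": {
        "n_nodes": 10,
        "prevalence_threshold": 0.30,
        "rho_threshold": 0.60,
        "edges": [
            ("Finegoldia", "Peptoniphilus", 0.74000000, 0.001),
            ("Dialister", "Peptoniphilus", 0.68695652, 0.004),
        ],
    },
    "CCU": {
        "n_nodes": 11,
        "prevalence_threshold": 0.40,
        "rho_threshold": 0.70,
        "edges": [
            ("Dialister", "Hoylesella", 0.98787879, 5.1e-06),
            ("Anaerococcus", "Peptoniphilus", 0.92727273, 0.0031),
            ("Anaerococcus", "Pseudomonas", -0.85454545, 0.0225),
            ("Peptoniphilus", "Campylobacter", 0.85454545, 0.0225),
        ],
    },
}

#: HR-HPV positivity contingency counts per diagnostic group:
#: (positive patients, group size).
HR_HPV_COUNTS: dict[str, tuple[int, int]] = {
    "Normal": (12, 26),
    "LSIL": (22, 25),
    "HSIL": (25, 25),
    "CCU": (10, 10),
}


def reference_network_inputs(group: str) -> tuple[list[str], pd.DataFrame]:
    """Node list (named + placeholder isolates) and edge table for a group."""
    spec = REFERENCE_NETWORKS[group]
    edges = pd.DataFrame(spec["edges"],
                         columns=["genus1", "genus2", "rho", "q_value"])
    named: list[str] = []
    for g in pd.concat([edges["genus1"], edges["genus2"]]):
        if g not in named:
            named.append(g)
    if len(named) > spec["n_nodes"]:
        raise ValueError(f"edge list names more genera than nodes for {group}")
    isolates = [f"isolate_{k + 1}" for k in range(spec["n_nodes"] - len(named))]
    return named + isolates, edges


def hr_hpv_positivity_percent(group: str) -> float:
    """HR-HPV positivity as a percentage, recomputed from the counts."""
    positive, total = HR_HPV_COUNTS[group]
    return 100.0 * positive / total
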