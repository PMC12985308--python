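"""Per-group genus co-occurrence networks.

Within each diagnostic group: genera are filtered by within-group prevalence
(>= 30%, or >= 40% for the small CCU group) and non-zero variance, capped at
the 20 most abundant; Spearman rank correlations are computed on the
CLR-transformed abundances with BH-FDR across all retained pairs; edges are
kept at |rho| >= 0.60 and q < 0.05 (|rho| >= 0.70 for CCU). Networks are
undirected and weighted by rho; nodes include edge-less retained genera, so
density = E / (N(N-1)/2) and component counts reflect the full filtered set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from cervicomp.alpha import bh_fdr
from cervicomp.composition import CLRMatrix, clr_transform, replace_zeros
from cervicomp.io import AbundanceTable, DataError, SampleMetadata

logger = logging.getLogger(__name__)

#: (prevalence threshold, |rho| threshold) per diagnostic group.
DEFAULT_GROUP_THRESHOLDS = {
    "Normal": (0.30, 0.60), "LSIL": (0.30, 0.60),
    "HSIL": (0.30, 0.60), "CCU": (0.40, 0.70),
}
DEFAULT_Q_THRESHOLD = 0.05
MAX_TAXA = 20


@dataclass
class GroupNetwork:
    """Filtered genus set plus significant weighted edges and graph metrics."""

    group: str
    nodes: list[str]
    edges: pd.DataFrame  # genus1, genus2, rho, p_value, q_value
    density: float
    n_components: int

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.genus1, row.genus2, weight=row.rho)
        return g


def filter_group_taxa(table: AbundanceTable, group_samples,
                      prevalence_threshold: float = 0.30,
                      max_taxa: int = MAX_TAXA) -> list[str]:
    """Genera retained for one group's network.

    Keep genera detected in at least ``prevalence_threshold`` of the group's
    samples (inclusive) with non-zero variance across them, then the
    ``max_taxa`` with highest within-group total abundance.
    """
    group_samples = list(group_samples)
    if not group_samples:
        raise DataError("group has no samples")
    sub = table.data.loc[group_samples]
    prevalence = (sub > 0).mean()
    variance = sub.var(ddof=0)
    keep = (prevalence >= prevalence_threshold) & (variance > 0)
    if not keep.any():
        raise DataError("no genus passes the prevalence/variance filters")
    totals = sub.loc[:, keep].sum().sort_values(ascending=False, kind="stable")
    return list(totals.index[:max_taxa])


def spearman_clr(clr: CLRMatrix, genera=None) -> pd.DataFrame:
    """Spearman correlations over all unordered genus pairs of a CLR matrix.

    Ties are handled by average ranks; p-values use the t approximation; pairs
    involving a constant vector are excluded (logged); q-values are BH across
    the retained pairs.
    """
    data = clr.data[list(genera)] if genera is not None else clr.data
    if len(data) < 3:
        raise DataError("spearman_clr needs at least 3 samples")
    rows = []
    values = data.to_numpy(dtype=float)
    constant = np.ptp(values, axis=0) == 0
    cols = list(data.columns)
    for i, j in combinations(range(len(cols)), 2):
        if constant[i] or constant[j]:
            logger.info("spearman_clr: skipping constant pair (%s, %s)",
                        cols[i], cols[j])
            continue
        rho, p = stats.spearmanr(values[:, i], values[:, j])
        if not np.isfinite(rho):
            logger.info("spearman_clr: undefined coefficient for (%s, %s)",
                        cols[i], cols[j])
            continue
        rows.append({"genus1": cols[i], "genus2": cols[j],
                     "rho": float(rho), "p_value": float(min(max(p, 1e-300), 1.0))})
    out = pd.DataFrame(rows, columns=["genus1", "genus2", "rho", "p_value"])
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def network_metrics(nodes, edges) -> tuple[int, int, float, int]:
    """(node count, edge count, density, connected components).

    ``edges`` is any iterable of (genus1, genus2) pairs (extra fields
    ignored); density follows the simple undirected convention
    E / (N(N−1)/2) and is 0 for fewer than 2 nodes; isolated nodes count as
    their own components.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for edge in edges:
        g.add_edge(edge[0], edge[1])
    n = g.number_of_nodes()
    e = g.number_of_edges()
    density = nx.density(g) if n >= 2 else 0.0
    components = nx.number_connected_components(g) if n else 0
    return n, e, density, components


def build_network(correlations: pd.DataFrame, rho_threshold: float,
                  q_threshold: float, nodes, group: str = "") -> GroupNetwork:
    """Threshold a correlation table into a weighted co-occurrence network."""
    if not 0 < rho_threshold <= 1 or not 0 < q_threshold <= 1:
        raise DataError("thresholds must lie in (0, 1]")
    nodes = list(nodes)
    keep = (correlations["rho"].abs() >= rho_threshold) & \
           (correlations["q_value"] < q_threshold)
    edges = correlations.loc[keep].reset_index(drop=True)
    n, e, density, components = network_metrics(
        nodes, edges[["genus1", "genus2"]].itertuples(index=False))
    return GroupNetwork(group, nodes, edges, density, components)


def group_networks(table: AbundanceTable, metadata: SampleMetadata,
                   thresholds: dict[str, tuple[float, float]] | None = None,
                   q_threshold: float = DEFAULT_Q_THRESHOLD,
                   max_taxa: int = MAX_TAXA,
                   pseudocount: float = 0.5, delta: float = 1e-6,
                   ) -> dict[str, GroupNetwork]:
    """End-to-end per-group networks from a counts table plus metadata."""
    thresholds = {**DEFAULT_GROUP_THRESHOLDS, **(thresholds or {})}
    clr = clr_transform(replace_zeros(table, pseudocount, delta))
    out: dict[str, GroupNetwork] = {}
    for group in pd.unique(metadata.diagnosis):
        prev_thr, rho_thr = thresholds.get(group, (0.30, 0.60))
        samples = metadata.diagnosis.index[metadata.diagnosis == group]
        samples = [s for s in samples if s in table.data.index]
        if len(samples) < 3:
            logger.warning("group %r has <3 samples; network skipped", group)
            continue
        genera = filter_group_taxa(table, samples, prev_thr, max_taxa)
        corr = spearman_clr(CLRMatrix(clr.data.loc[samples]), genera)
        out[group] = build_network(corr, rho_thr, q_threshold, genera, group)
    return out
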