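"""End-to-end orchestration of the analysis stages with provenance logging.

``run_all`` executes simulate (or load) → align → compositional transform →
alpha diversity → beta multivariate tests → differential abundance →
log-ratio indices → co-occurrence networks, writing each stage's tables as
TSV with a header comment recording the seed, package version and the
parameters that produced them. Re-running with the same configuration is
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import cervicomp
from cervicomp.alpha import alpha_comparisons, alpha_metrics
from cervicomp.beta import host_factor_screen, pairwise_permanova, pcoa, permanova, permdisp
from cervicomp.composition import aitchison_distance, clr_transform, replace_zeros
from cervicomp.da import BiasCorrectedDA
from cervicomp.indices import (DEFAULT_ANAEROBE_PANEL, compare_index_across_groups,
                               composite_logratio, composite_sets, la_logratio, roc_auc)
from cervicomp.io import (AbundanceTable, DataError, SampleMetadata, align,
                          read_abundance, read_metadata, write_abundance,
                          write_metadata, write_tsv)
from cervicomp.networks import DEFAULT_GROUP_THRESHOLDS, group_networks
from cervicomp.simulate import CohortConfig, simulate_cohort, simulate_host_factors

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline (YAML-compatible)."""

    seed: int = 0
    outdir: str = "cervicomp_out"
    abundance_path: str | None = None   # when None, a cohort is simulated
    metadata_path: str | None = None
    permutations: int = 9999
    pseudocount: float = 0.5            # counts zero replacement before CLR
    delta: float = 1e-6                 # proportions multiplicative replacement
    da_pseudocount: float = 1.0
    da_sig_q: float = 0.10
    da_reference: str = "Normal"
    anaerobe_panel: tuple[str, ...] = DEFAULT_ANAEROBE_PANEL
    composite_tau: float = 1.0
    composite_min_prevalence: float = 0.2
    network_q_threshold: float = 0.05
    group_sizes: dict[str, int] | None = None
    n_host_factors: int = 3             # null factors attached to simulated cohorts

    def __post_init__(self) -> None:
        if self.permutations < 99:
            raise DataError("permutations must be >= 99")
        for name in ("da_sig_q", "network_q_threshold"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise DataError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "anaerobe_panel" in raw and raw["anaerobe_panel"] is not None:
            raw["anaerobe_panel"] = tuple(raw["anaerobe_panel"])
        return cls(**raw)

    def provenance(self, **extra) -> dict:
        prov = {"package": "cervicomp", "version": cervicomp.__version__,
                "seed": self.seed, "rng": "numpy.random.default_rng (PCG64)",
                "permutations": self.permutations,
                "pseudocount": self.pseudocount, "delta": self.delta}
        prov.update(extra)
        return prov


def load_inputs(config: PipelineConfig) -> tuple[AbundanceTable, SampleMetadata]:
    """Read and align the configured inputs, or simulate a seeded cohort."""
    if config.abundance_path:
        if not config.metadata_path:
            raise DataError("metadata_path is required with abundance_path")
        table = read_abundance(config.abundance_path, mode="counts")
        meta = read_metadata(config.metadata_path)
        return align(table, meta)
    sim = CohortConfig(seed=config.seed,
                       **({"group_sizes": config.group_sizes}
                          if config.group_sizes else {}))
    table, meta = simulate_cohort(sim)
    if config.n_host_factors:
        meta = simulate_host_factors(meta, config.n_host_factors,
                                     seed=config.seed + 1)
    return table, meta


def _comparison_frame(result) -> pd.DataFrame:
    frame = result.pairwise.copy()
    frame["kw_statistic"] = result.kw_statistic
    frame["kw_p_value"] = result.kw_pvalue
    return frame


#: Stage names accepted by ``run_all``'s ``stages`` argument.
STAGES = ("simulate", "alpha", "beta", "host-screen", "da", "logratio", "network")


def run_all(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages (default: all) and write their tables.

    Returns the in-memory results plus the output-file manifest. Stages are
    always executed in pipeline order; compositional prerequisites (zero
    replacement, CLR, distances) are computed on demand.
    """
    want = set(STAGES if stages is None else stages)
    unknown = want - set(STAGES)
    if unknown:
        raise DataError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2 ** 16]))
    stage_seed = lambda: int(rng.integers(2 ** 31))  # noqa: E731
    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index_label=None, **extra) -> None:
        path = outdir / f"{name}.tsv"
        write_tsv(df, path, config.provenance(stage=name, **extra),
                  index_label=index_label)
        outputs[name] = path

    table, meta = load_inputs(config)
    write_abundance(table, outdir / "abundance.tsv", config.provenance(stage="abundance"))
    write_metadata(meta, outdir / "metadata.tsv", config.provenance(stage="metadata"))
    outputs["abundance"] = outdir / "abundance.tsv"
    outputs["metadata"] = outdir / "metadata.tsv"
    labels = meta.diagnosis
    results: dict = {"table": table, "metadata": meta, "outputs": outputs}

    clr = dm = None

    def substrate():
        nonlocal clr, dm
        if clr is None:
            clr = clr_transform(replace_zeros(table, config.pseudocount, config.delta))
            dm = aitchison_distance(clr)
        return clr, dm

    if "alpha" in want:
        per_sample = alpha_metrics(table)
        emit("alpha_per_sample", per_sample, index_label="sample_id")
        alpha_pairs = alpha_comparisons(table, labels)
        emit("alpha_comparisons", alpha_pairs)
        results["alpha"] = per_sample
        results["alpha_comparisons"] = alpha_pairs

    beta_seed = stage_seed()
    pairwise_seed = stage_seed()
    disp_seed = stage_seed()
    screen_seed = stage_seed()
    if "beta" in want:
        _, dmat = substrate()
        ordination = pcoa(dmat)
        emit("pcoa_coordinates", ordination.coordinates, index_label="sample_id")
        global_perm = permanova(dmat, labels, config.permutations, seed=beta_seed)
        emit("permanova_global", global_perm.summary().to_frame("value"),
             index_label="metric")
        pairwise = pairwise_permanova(dmat, labels, config.permutations,
                                      seed=pairwise_seed)
        emit("permanova_pairwise", pd.DataFrame([{
            "group1": r.group1, "group2": r.group2, "pseudo_F": r.pseudo_f,
            "R2": r.r_squared, "p_value": r.p_value, "q_value": r.q_value,
        } for r in pairwise]))
        disp = permdisp(dmat, labels, config.permutations, seed=disp_seed)
        emit("permdisp", pd.DataFrame(
            [{"diagnosis": g, "mean_dispersion": v}
             for g, v in disp.group_dispersions.items()]),
            F_statistic=f"{disp.f_statistic:.6g}", p_value=f"{disp.p_value:.6g}")
        results.update(ordination=ordination, permanova=global_perm,
                       pairwise_permanova=pairwise, permdisp=disp)
    if "host-screen" in want and meta.factors:
        _, dmat = substrate()
        screen = host_factor_screen(dmat, meta, permutations=config.permutations,
                                    seed=screen_seed)
        emit("host_factor_screen", screen)
        results["host_factor_screen"] = screen

    if "da" in want:
        da_results = BiasCorrectedDA(table, meta, reference=config.da_reference,
                                     pseudocount=config.da_pseudocount).fit(
            sig_q=config.da_sig_q)
        emit("differential_abundance", da_results.to_frame())
        results["da"] = da_results

    if "logratio" in want:
        cmat, _ = substrate()
        la = la_logratio(cmat, config.anaerobe_panel)
        index_frame = la.to_frame()
        composite = None
        try:
            inc, dec = composite_sets(
                table, meta, tau=config.composite_tau,
                min_prevalence=config.composite_min_prevalence,
                pseudocount=config.pseudocount, delta=config.delta)
            composite = composite_logratio(cmat, inc, dec)
            index_frame["composite_logratio"] = composite
        except DataError as exc:
            logger.warning("composite log-ratio skipped: %s", exc)
        emit("logratio_per_sample", index_frame, index_label="sample_id")
        la_compare = compare_index_across_groups(la, labels)
        emit("logratio_comparisons", _comparison_frame(la_compare))
        roc = roc_auc(la, labels, positive="CCU", higher_is_positive=False)
        emit("roc_points", roc.points, AUC=f"{roc.auc:.6g}",
             positive_class=roc.positive_label, orientation="lower-index-positive")
        results.update(la_logratio=la, composite_logratio=composite,
                       la_comparisons=la_compare, roc=roc)

    if "network" in want:
        networks = group_networks(table, meta,
                                  q_threshold=config.network_q_threshold,
                                  pseudocount=config.pseudocount, delta=config.delta)
        edge_rows, metric_rows = [], []
        for group, net in networks.items():
            for row in net.edges.itertuples(index=False):
                edge_rows.append({"group": group, **row._asdict()})
            metric_rows.append({"group": group, "n_nodes": len(net.nodes),
                                "n_edges": len(net.edges), "density": net.density,
                                "n_components": net.n_components})
        emit("network_edges", pd.DataFrame(
            edge_rows, columns=["group", "genus1", "genus2", "rho", "p_value",
                                "q_value"]))
        emit("network_metrics", pd.DataFrame(
            metric_rows, columns=["group", "n_nodes", "n_edges", "density",
                                  "n_components"]))
        results["networks"] = networks

    results["clr"], results["distance"] = clr, dm
    return results


def config_to_yaml(config: PipelineConfig, path) -> None:
    raw = asdict(config)
    raw["anaerobe_panel"] = list(raw["anaerobe_panel"])
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
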