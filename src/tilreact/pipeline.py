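"""End-to-end reproducible runs tying the stages together.

``run_pipeline`` simulates the requested modalities, runs the matching
analyses (gating → reactivity → combination profiles; paired LFC →
gene-set derivation → top-K validation; marker binarization → cluster
heatmaps → cross-tabs), writes tidy TSV/JSON outputs and emits a run
manifest (config echo, package version, output checksums, timings,
warnings) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, flow, genesets, insitu, io, synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Defaults follow the assay's reporting conventions: gating quantile
    0.999 on the unstimulated control, background-subtraction floor
    0.01% and cap 100%, DEG filters p < 0.01 with mean LFC > 2 (CD8) /
    > 1.4 (CD4), top-K validation window K = 300, and single-cell
    positivity as any detected expression (> 0).
    """

    out_dir: Path = Path("tilreact_run")
    stages: tuple[str, ...] = ("flow", "bulk", "sc")
    seed: int = 0
    gating_quantile: float = 0.999
    percent_floor: float = flow.PERCENT_FLOOR
    percent_cap: float = flow.PERCENT_CAP
    p_cutoff: float = 0.01
    lfc_cutoffs: dict[str, float] = field(default_factory=lambda: dict(genesets.LFC_CUTOFFS))
    top_k: int = 300
    sc_positivity_threshold: float = 0.0
    flow_config: synthetic.FlowSimConfig | None = None
    bulk_config: synthetic.BulkSimConfig | None = None
    sc_config: synthetic.SCSimConfig | None = None


@dataclass
class RunManifest:
    """Record of one pipeline run."""

    config: dict
    version: str
    stages_run: list[str]
    outputs: dict[str, str]  # relative path -> sha256
    timings: dict[str, float]
    warnings: list[str]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_flow(config: RunConfig, out: Path, outputs: dict[str, str]) -> None:
    sim = config.flow_config or synthetic.FlowSimConfig(seed=config.seed)
    tables, _truth = synthetic.generate_flow_events(sim)
    thresholds = flow.set_thresholds(tables[("alone", "none")], config.gating_quantile)

    rows, combo_rows = [], []
    control_subsets = flow.split_subsets(tables[("alone", "none")], thresholds)
    stim_subsets = flow.split_subsets(tables[("autologous", "none")], thresholds)
    for subset in ("CD8", "CD4"):
        pos = flow.call_positivity(stim_subsets[subset], thresholds)
        ctrl_pos = flow.call_positivity(control_subsets[subset], thresholds)
        res = flow.reactivity_metrics(pos, ctrl_pos, subset, sample_id=sim.sample_id)
        for metric, value in res.subtracted_unions.items():
            rows.append(
                {"sample": res.sample_id, "subset": subset, "metric": metric,
                 "raw_pct": res.unions[metric], "control_pct": res.control_unions[metric],
                 "subtracted_pct": value}
            )
        profile = flow.combination_profile(pos, ctrl_pos, subset=subset)
        for combo, frac in profile.fractions.items():
            combo_rows.append(
                {"sample": res.sample_id, "subset": subset, "combination": combo,
                 "fraction": frac}
            )
        for group, frac in profile.grouping.items():
            combo_rows.append(
                {"sample": res.sample_id, "subset": subset, "combination": group,
                 "fraction": frac}
            )
    for name, df in (("reactivity.tsv", pd.DataFrame(rows)),
                     ("combinations.tsv", pd.DataFrame(combo_rows))):
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = _checksum(path)
    io.write_json({"cutoffs": dict(thresholds.cutoffs),
                   "quantile": thresholds.quantile}, out / "thresholds.json")
    outputs["thresholds.json"] = _checksum(out / "thresholds.json")


def _stage_bulk(config: RunConfig, out: Path, outputs: dict[str, str]) -> None:
    sim = config.bulk_config or synthetic.BulkSimConfig(seed=config.seed)
    pair, _truth = synthetic.generate_bulk_pairs(sim)
    degs = genesets.compute_paired_lfc(pair)
    gene_set = genesets.derive_gene_set(
        degs, sim.subset, p_cutoff=config.p_cutoff,
        lfc_cutoff=config.lfc_cutoffs.get(sim.subset),
    )
    report = genesets.validate_top_k(
        gene_set, degs, k=min(config.top_k, len(degs.table)), reference_id="self"
    )
    degs.table.to_csv(out / "deg_table.tsv", sep="\t")
    (out / "gene_set.txt").write_text("\n".join(gene_set.genes) + "\n")
    io.write_json(report, out / "validation.json")
    for name in ("deg_table.tsv", "gene_set.txt", "validation.json"):
        outputs[name] = _checksum(out / name)


def _stage_sc(config: RunConfig, out: Path, outputs: dict[str, str]) -> None:
    sim = config.sc_config or synthetic.SCSimConfig(seed=config.seed)
    adata, _truth = synthetic.generate_sc_counts(sim)
    calls = insitu.binarize_markers(
        adata, sim.marker_genes, threshold=config.sc_positivity_threshold
    )
    clusters = insitu.assign_clusters(calls)
    heatmap = insitu.cluster_geneset_heatmap(
        adata, clusters, sim.activation_gene_names(), use_grouped=True
    )
    calls2 = insitu.binarize_markers(
        adata, sim.specificity_genes, threshold=config.sc_positivity_threshold
    )
    xtab = insitu.crosstab_specificity_markers(calls, calls2)

    clusters.labels.to_frame().assign(grouped=clusters.grouped).to_csv(
        out / "clusters.tsv", sep="\t"
    )
    heatmap.zscores.to_csv(out / "heatmap_zscores.tsv", sep="\t")
    xtab["counts"].to_csv(out / "crosstab.tsv", sep="\t")
    for name in ("clusters.tsv", "heatmap_zscores.tsv", "crosstab.tsv"):
        outputs[name] = _checksum(out / name)


_STAGES = {"flow": _stage_flow, "bulk": _stage_bulk, "sc": _stage_sc}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages and write outputs plus a manifest.

    Identical config and seed produce byte-identical outputs.  A stage
    failure aborts the run with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}
    warnings: list[str] = []

    handler = _ListHandler(warnings)
    logging.getLogger("tilreact").addHandler(handler)
    try:
        for stage in config.stages:
            if stage not in _STAGES:
                raise flow.ConfigurationError(f"unknown stage {stage!r}")
            t0 = time.perf_counter()
            try:
                _STAGES[stage](config, out, outputs)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            timings[stage] = time.perf_counter() - t0
    finally:
        logging.getLogger("tilreact").removeHandler(handler)

    manifest = RunManifest(
        config=io.jsonable(config),
        version=__version__,
        stages_run=list(config.stages),
        outputs=outputs,
        timings=timings,
        warnings=warnings,
    )
    io.write_json(manifest, out / "manifest.json")
    return manifest


class _ListHandler(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(self.format(record))
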