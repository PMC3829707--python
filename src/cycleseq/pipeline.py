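"""End-to-end orchestration: simulate -> quantify -> classify -> de ->
network -> phylo -> report, with one config, seed control and a provenance
manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import cycleseq
from cycleseq import coverage, de, network, phylo, structure, synthetic

log = logging.getLogger("cycleseq")

STAGES = ("simulate", "quantify", "classify", "de", "network", "phylo", "report")


@dataclass
class PipelineConfig:
    outdir: str = "cycleseq_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulate
    genome_length: int = 120_000
    n_genes: int = 200
    ccr_fraction: float = synthetic.DEFAULT_CCR_FRACTION
    gc_affected_fraction: float = 0.1
    gc_cv_target: float = 1.5
    n_species: int = 80
    n_broad_modules: int = 3
    n_clade_modules: int = 3
    module_size: int = 12
    loss_probability: float = 0.3
    # quantify
    cv_threshold: float = 1.0
    split_threshold: float = 1000.0
    window: int = 10_000
    # de
    de_threshold: float = 0.5
    de_q: int = 100
    # network
    beta: float = network.DEFAULT_BETA
    min_module_size: int = network.DEFAULT_MIN_SIZE
    cut_height: float = network.DEFAULT_CUT_HEIGHT
    # phylo
    randomizations: int = 999
    k_permutations: int = 999
    quadrant_threshold: float = phylo.QUADRANT_THRESHOLD

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the enabled stages in order; a stage failure halts the run with
    the failing stage named, keeping partial outputs.  Returns the run
    directory, which ends with a provenance manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": cycleseq.__version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages_run": [],
        "checksums": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s starting", stage)
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages_run"].append(stage)
        log.info("stage %s done", stage)
    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["checksums"][f.name] = _checksum(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> None:
    spec = synthetic.GenomeSpec(
        genome_length=cfg.genome_length, n_genes=cfg.n_genes
    )
    sim = synthetic.simulate_experiment(
        spec,
        seed=cfg.seed,
        gc_noise=synthetic.GcNoise(cfg.gc_affected_fraction, cfg.gc_cv_target),
        ccr_fraction=cfg.ccr_fraction,
    )
    state["sim"] = sim
    coverage.write_gff3(sim.experiment.annotation, out / "genes.gff3")
    for (t, r, s), trk in sim.experiment.tracks.items():
        name = f"coverage_t{t}_r{r}_{'plus' if s == '+' else 'minus'}.bedgraph"
        coverage.write_bedgraph(trk, out / name)
    synthetic.programs_to_frame(sim.programs).to_csv(
        out / "truth_programs.tsv", sep="\t"
    )

    module_truths = [
        {"module_id": f"broad{i}", "depth_class": "broad", "size": cfg.module_size}
        for i in range(cfg.n_broad_modules)
    ] + [
        {"module_id": f"clade{i}", "depth_class": "clade", "size": cfg.module_size}
        for i in range(cfg.n_clade_modules)
    ]
    tree, conservation, truth = synthetic.simulate_tree_and_conservation(
        cfg.n_species, module_truths, cfg.loss_probability, seed=cfg.seed
    )
    tree.write(path=str(out / "species.nwk"), schema="newick")
    conservation.to_csv(out / "conservation.tsv", sep="\t")
    truth.to_csv(out / "truth_conservation.tsv", sep="\t")
    state["tree"] = tree
    state["conservation"] = conservation


def _stage_quantify(cfg: PipelineConfig, out: Path, state: dict) -> None:
    exp = state["sim"].experiment
    matrix = coverage.quantify_experiment(
        exp,
        cv_threshold=cfg.cv_threshold,
        split_threshold=cfg.split_threshold,
        window=cfg.window,
    )
    state["matrix"] = matrix
    flat = matrix.values.copy()
    flat.columns = [f"t{t}_r{r}" for t, r in flat.columns]
    flat.to_csv(out / "expression.tsv", sep="\t")
    pd.DataFrame(
        {
            "retained_fraction": matrix.retained_fraction,
            "fallback": matrix.fallback_flag,
        }
    ).to_csv(out / "expression_qc.tsv", sep="\t")


def _stage_classify(cfg: PipelineConfig, out: Path, state: dict) -> None:
    matrix = state["matrix"]
    groups = structure.classify_groups(matrix)
    state["groups"] = groups
    groups.labels.to_frame().to_csv(out / "expression_groups.tsv", sep="\t")
    pooled = matrix.values.mean(axis=1)
    try:
        fit = structure.fit_power_law(pooled[pooled >= structure.LOW_CUT].values)
        fit_dict = asdict(fit) if hasattr(fit, "__dict__") else vars(fit)
    except ValueError as exc:
        fit_dict = {"error": str(exc)}
    summary = {
        "power_law": fit_dict,
        "group_sizes": groups.sizes.to_dict(),
        "group_mean_cv": groups.group_mean_cv.to_dict(),
        "cv_pooling": "per-timepoint replicate CV, averaged over timepoints",
    }
    (out / "classify_summary.json").write_text(json.dumps(summary, indent=2))


def _stage_de(cfg: PipelineConfig, out: Path, state: dict) -> None:
    matrix = state["matrix"]
    calls, result = de.run_de(
        matrix.values,
        threshold=cfg.de_threshold,
        q=cfg.de_q,
        seed=cfg.seed,
        split_threshold=cfg.split_threshold,
    )
    state["ccr_calls"] = calls
    calls.to_csv(out / "ccr_calls.tsv", sep="\t")


def _stage_network(cfg: PipelineConfig, out: Path, state: dict) -> None:
    matrix, calls = state["matrix"], state["ccr_calls"]
    ccr_genes = calls.index[calls["ccr_call"]]
    if len(ccr_genes) < cfg.min_module_size:
        state["modules"] = None
        log.warning("skipped: no CCR genes")
        return
    expr = matrix.values.loc[ccr_genes]
    expr = expr.loc[expr.var(axis=1) > 0]
    module_set = network.run_network(
        expr,
        beta=cfg.beta,
        min_size=cfg.min_module_size,
        cut_height=cfg.cut_height,
    )
    state["modules"] = module_set
    pd.DataFrame(
        {
            "module": module_set.labels,
            "contribution": module_set.contributions,
        }
    ).to_csv(out / "modules.tsv", sep="\t")
    flat = module_set.eigenvectors.copy()
    flat.index = [f"t{t}_r{r}" for t, r in flat.index]
    flat.to_csv(out / "module_eigenvectors.tsv", sep="\t")
    module_set.variance_explained.to_frame().to_csv(
        out / "module_variance_explained.tsv", sep="\t"
    )


def _stage_phylo(cfg: PipelineConfig, out: Path, state: dict) -> None:
    modules = state.get("modules")
    if modules is None:
        log.warning("skipped: no modules")
        return
    # the planted conservation matrix indexes its own gene universe; map the
    # detected CCR genes onto it by truth module membership where possible,
    # otherwise analyze the planted modules directly
    conservation = state["conservation"]
    tree = state["tree"]
    planted = {}
    truth = pd.read_csv(out / "truth_conservation.tsv", sep="\t", index_col=0)
    for mid, sub in truth.groupby("module_id"):
        planted[mid] = list(sub.index)
    table = phylo.analyze_modules(
        tree,
        conservation,
        planted,
        n_randomizations=cfg.randomizations,
        n_permutations=cfg.k_permutations,
        seed=cfg.seed,
    )
    table.to_csv(out / "module_phylo.tsv", sep="\t")
    state["phylo_table"] = table


def _stage_report(cfg: PipelineConfig, out: Path, state: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report: dict = {"sections": {}}
    matrix = state.get("matrix")
    if matrix is not None:
        report["sections"]["quantify"] = {
            "n_genes": int(matrix.values.shape[0]),
            "mean_retained_fraction": float(matrix.retained_fraction.mean()),
        }
    if "groups" in state:
        report["sections"]["classify"] = {
            "group_sizes": state["groups"].sizes.to_dict()
        }
    calls = state.get("ccr_calls")
    if calls is not None:
        report["sections"]["de"] = {"n_ccr": int(calls["ccr_call"].sum())}
    modules = state.get("modules")
    if modules is None:
        report["sections"]["network"] = {"skipped": "no CCR genes"}
        report["sections"]["phylo"] = {"skipped": "no CCR genes"}
    else:
        report["sections"]["network"] = {
            "n_modules": len(modules.modules),
            "median_variance_explained": float(
                modules.variance_explained.median()
            ),
        }
        table = state.get("phylo_table")
        if table is not None:
            tally = table["quadrant"].value_counts().to_dict()
            report["sections"]["phylo"] = {
                "quadrant_tally": {str(k): int(v) for k, v in tally.items()}
            }

    if matrix is not None:
        cv = structure.per_gene_cv(matrix)
        pooled = matrix.values.mean(axis=1)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(pooled, cv, s=6, alpha=0.5)
        ax.set_xscale("log")
        ax.set_xlabel("expression (x-fold)")
        ax.set_ylabel("replicate CV")
        fig.savefig(out / "cv_vs_expression.png", dpi=100)
        plt.close(fig)
    (out / "report.json").write_text(json.dumps(report, indent=2))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "classify": _stage_classify,
    "de": _stage_de,
    "network": _stage_network,
    "phylo": _stage_phylo,
    "report": _stage_report,
}
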