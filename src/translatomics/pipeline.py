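"""End-to-end orchestration: simulate/load -> translation-state calls ->
feature matrix -> one-vs-rest forests -> co-association and enrichment.

A run is fully specified by a :class:`PipelineConfig` (YAML-loadable) and
a seed; identical config + seed reproduces byte-identical TSV outputs.
Every TSV output starts with a ``# seed=N`` header line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .enrichment import coassociation_matrix, term_enrichment
from .expression import TranslationStateCaller, potentiation_correlation
from .features import SequenceFeaturizer, assemble_transcripts
from .forest import ForestConfig, ForestReport, make_binary_labels, tune_and_train
from .simulate import SimulationParams, export_truth, simulate_all

logger = logging.getLogger(__name__)


@dataclass
class InputPaths:
    fasta: str
    regions: str
    expression: str
    motif_panel: str | None = None
    target_sets: str | None = None
    term_sets: str | None = None


@dataclass
class PipelineConfig:
    """One config to drive the whole run (YAML-serialisable)."""

    inputs: InputPaths | None = None
    simulate: SimulationParams | None = None
    tau: float = 1.0
    alpha: float = 0.01
    moderation: bool = True
    prior_df: float = 4.0
    forest: ForestConfig = field(default_factory=ForestConfig)
    permutation_importance: bool = False
    outdir: str = "translatomics_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError(
                "config must provide exactly one of input paths or a "
                "simulate block"
            )
        if self.tau <= 0 or not 0 < self.alpha < 1:
            raise ValueError("invalid tau/alpha thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "inputs" in raw and raw["inputs"] is not None:
            raw["inputs"] = InputPaths(**raw["inputs"])
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationParams(**raw["simulate"])
        if "forest" in raw and raw["forest"] is not None:
            fc = dict(raw["forest"])
            for key in ("ntree_grid", "mtry_grid"):
                if key in fc and fc[key] is not None:
                    fc[key] = tuple(fc[key])
            raw["forest"] = ForestConfig(**fc)
        return cls(**raw)


@dataclass
class RunReport:
    """Per-stage counts and headline results of one pipeline run."""

    seed: int
    n_genes_in: int = 0
    n_assembled: int = 0
    n_assembly_dropped: int = 0
    n_tested: int = 0
    counts: dict = field(default_factory=dict)
    forest: dict = field(default_factory=dict)
    potentiation: dict = field(default_factory=dict)
    enrichment_summary: dict = field(default_factory=dict)
    incomplete: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order; any stage failure aborts with a
    stage-tagged error."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    report = RunReport(seed=config.seed)
    stage = "load"
    try:
        # ---------------- stage: simulate | load ----------------------
        if config.simulate is not None:
            stage = "simulate"
            params = dataclasses.replace(config.simulate, seed=config.seed)
            data = simulate_all(params)
            records, regions = data.records, data.regions
            expression = data.expression
            targets, terms = data.targets, data.terms
            export_truth(data.truth, outdir)
            panel = tio.default_motif_panel()
        else:
            stage = "load"
            paths = config.inputs
            records = tio.read_fasta(paths.fasta)
            regions = tio.read_region_table(paths.regions)
            expression = tio.read_expression_table(paths.expression)
            panel = (
                tio.read_motif_panel(paths.motif_panel)
                if paths.motif_panel else tio.default_motif_panel()
            )
            targets = (
                tio.read_gene_sets(paths.target_sets)
                if paths.target_sets else None
            )
            terms = (
                tio.read_gene_sets(paths.term_sets)
                if paths.term_sets else None
            )
        report.n_genes_in = len(records)
        fasta_ids = {r.id for r in records}
        expr_ids = set(expression.genes)
        if not fasta_ids & expr_ids:
            examples = sorted(fasta_ids - expr_ids)[:3]
            raise ValueError(
                f"no shared gene ids between sequences and expression "
                f"(sequence-only examples: {examples})"
            )

        # ---------------- stage: translation_state --------------------
        stage = "translation_state"
        caller = TranslationStateCaller(
            tau=config.tau, alpha=config.alpha,
            moderation=config.moderation, prior_df=config.prior_df,
        ).fit(expression)
        calls = caller.calls_
        report.n_tested = len(calls)
        report.counts = caller.counts_
        _write_tsv(calls, outdir / "translation_calls.tsv", config.seed)
        try:
            pot = potentiation_correlation(expression, calls)
            report.potentiation = {
                "r": pot.r, "p": pot.r_pvalue, "n": pot.n,
                "ranksum_up_p": pot.ranksum_up_p,
                "ranksum_down_p": pot.ranksum_down_p,
            }
        except ValueError as exc:
            logger.warning("potentiation stage skipped: %s", exc)

        # ---------------- stage: features ------------------------------
        stage = "features"
        transcripts, dropped = assemble_transcripts(records, regions)
        report.n_assembled = len(transcripts)
        report.n_assembly_dropped = dropped + (
            report.n_genes_in - len(transcripts) - dropped
        )
        featurizer = SequenceFeaturizer(panel=panel)
        X = featurizer.fit_transform(transcripts, expression=expression)
        _write_tsv(X, outdir / "feature_matrix.tsv", config.seed)
        with open(outdir / "schema.json", "w") as fh:
            json.dump(
                {
                    "version": featurizer.schema_.version,
                    "features": featurizer.feature_names_,
                },
                fh, indent=1,
            )

        # ---------------- stage: forest (per class) -------------------
        stage = "forest"
        shared = calls.index.intersection(X.index)
        calls_f = calls.loc[shared]
        X_f = X.loc[shared]
        for positive in ("up", "down"):
            if (calls_f["label"] == positive).sum() < max(
                5, config.forest.n_folds
            ):
                logger.warning(
                    "forest[%s] skipped: too few positive transcripts", positive
                )
                report.forest[positive] = {"skipped": True}
                continue
            y, _ = make_binary_labels(calls_f, positive)
            model, frep = tune_and_train(
                X_f, y, config.forest, positive=positive,
                permutation_importance=config.permutation_importance,
            )
            report.forest[positive] = frep.to_dict()
            _write_tsv(
                frep.roc, outdir / f"roc_points_{positive}.tsv", config.seed,
                index=False,
            )
            _write_tsv(
                frep.importance, outdir / f"importance_{positive}.tsv",
                config.seed, index=False,
            )
            with open(outdir / f"forest_report_{positive}.json", "w") as fh:
                json.dump(frep.to_dict(), fh, indent=1)

        # ---------------- stage: enrichment ---------------------------
        stage = "enrichment"
        if targets is not None:
            class_sets = tio.GeneSetCollection(
                {
                    lab: frozenset(calls_f.index[calls_f["label"] == lab])
                    for lab in ("up", "down")
                },
                frozenset(calls_f.index),
            )
            coassoc = coassociation_matrix(
                targets, class_sets, universe=frozenset(calls_f.index)
            )
            _write_tsv(coassoc, outdir / "enrichment.tsv", config.seed,
                       index=False)
            top = coassoc.sort_values("q").iloc[0]
            report.enrichment_summary["top_coassociation"] = {
                "set_a": top["set_a"], "set_b": top["set_b"],
                "q": float(top["q"]), "direction": top["direction"],
            }
            if terms is not None:
                down_genes = class_sets["down"]
                if down_genes:
                    te = term_enrichment(
                        down_genes, terms, universe=frozenset(calls_f.index)
                    )
                    _write_tsv(te, outdir / "term_enrichment_down.tsv",
                               config.seed, index=False)
                    report.enrichment_summary["top_term_down"] = {
                        "term": te.iloc[0]["set_a"], "q": float(te.iloc[0]["q"]),
                    }
        else:
            report.enrichment_summary["skipped"] = True
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_report(report, outdir / "run_report.json")
    _write_summary(report, outdir / "run_summary.txt")
    return report


def write_report(report: RunReport, path: str | Path) -> None:
    payload = report.to_dict()
    if report.incomplete:
        payload["incomplete"] = True
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _write_summary(report: RunReport, path: str | Path) -> None:
    """Human-readable summary with a confusion/AUC/top-features block per
    one-vs-rest task."""
    lines = [
        f"translatomics run (seed={report.seed})",
        f"genes in: {report.n_genes_in}; tested: {report.n_tested}; "
        f"assembled: {report.n_assembled}",
        "class counts: " + ", ".join(
            f"{k}={v}" for k, v in report.counts.items()
        ),
        "",
    ]
    for positive, rep in report.forest.items():
        if rep.get("skipped"):
            lines.append(f"[{positive}] skipped")
            continue
        conf = rep["confusion"]
        lines.append(
            f"[{positive}] TP={conf['TP']} FP={conf['FP']} "
            f"TN={conf['TN']} FN={conf['FN']} AUC={rep['auc']:.3f} "
            f"(ntree={rep['best_params']['ntree']}, "
            f"mtry={rep['best_params']['mtry']})"
        )
        for feat in rep["top_features"]:
            lines.append(
                f"    {feat['feature']:<28s} gini={feat['gini']:.4f} "
                f"effect={feat['sign']}"
            )
    if report.enrichment_summary and not report.enrichment_summary.get("skipped"):
        top = report.enrichment_summary.get("top_coassociation")
        if top:
            lines.append(
                f"top co-association: {top['set_a']} x {top['set_b']} "
                f"q={top['q']:.3g} ({top['direction']})"
            )
    else:
        lines.append("enrichment: skipped")
    Path(path).write_text("\n".join(lines) + "\n")
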