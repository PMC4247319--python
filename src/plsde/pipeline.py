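"""End-to-end orchestration: inputs -> normalization -> PLS/VIP selection
-> survival screen -> gene-level selection -> target network -> enrichment.

Each stage writes its output table under the run directory together with a
stage marker recording the configuration hash; re-running with an
unchanged configuration reuses completed stage outputs (idempotent
resume).  A run manifest collects the seed, configuration echo, per-stage
row counts and wall times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import enrich, read_annotations
from .errors import ParameterError
from .io import read_tsv, write_tsv
from .network import (build_network, filter_by_support, filter_de_targets,
                      read_predictions, write_network)
from .normalization import ExpressionMatrix, log2_transform, quantile_normalize
from .selection import run_selection, select_significant
from .survival import survival_screen
from .synthetic import SimulationConfig, generate_bundle, stage_rng, write_bundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, sizes and input locations for one pipeline run.

    In simulation mode (``simulate`` set) all inputs are generated; in
    file mode the four input paths must exist.  ``n_perm`` defaults to 500
    for the bundled synthetic study; raise it (the screen design value is
    10,000) for production-scale permutation resolution.
    """

    outdir: str | Path = "plsde_run"
    simulate: SimulationConfig | None = None
    expression_path: str | Path | None = None
    gene_expression_path: str | Path | None = None
    phenotype_path: str | Path | None = None
    predictions_path: str | Path | None = None
    annotations_path: str | Path | None = None
    already_logged: bool = True
    n_components: int = 2
    n_perm: int = 500
    fdr_threshold: float = 0.01
    survival_alpha: float = 0.05
    min_methods: int = 2
    enrichment_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "survival_alpha", "enrichment_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must be in (0, 1], got {v}")
        if self.simulate is None:
            required = {"expression_path": self.expression_path,
                        "phenotype_path": self.phenotype_path,
                        "predictions_path": self.predictions_path,
                        "annotations_path": self.annotations_path}
            for key, path in required.items():
                if path is None or not Path(path).exists():
                    raise ParameterError(f"non-simulation mode requires existing {key}")

    def config_hash(self) -> str:
        # outdir excluded: it locates outputs but does not affect their content
        payload = asdict(self)
        payload.pop("outdir")
        payload = {k: (str(v) if isinstance(v, Path) else v) for k, v in payload.items()}
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class _StageRunner:
    outdir: Path
    config_hash: str
    manifest: dict = field(default_factory=dict)

    def marker(self, stage: str) -> Path:
        return self.outdir / f".{stage}.done.json"

    def completed(self, stage: str, outputs: list[Path]) -> bool:
        m = self.marker(stage)
        if not m.exists() or not all(p.exists() for p in outputs):
            return False
        try:
            return json.loads(m.read_text()).get("config_hash") == self.config_hash
        except json.JSONDecodeError:
            return False

    def run(self, stage: str, outputs: list[Path], fn):
        t0 = time.perf_counter()
        resumed = self.completed(stage, outputs)
        if not resumed:
            try:
                fn()
            except Exception:
                logger.error("stage %r failed", stage)
                raise
            self.marker(stage).write_text(json.dumps({"config_hash": self.config_hash}))
        self.manifest[stage] = {
            "resumed": resumed,
            "seconds": round(time.perf_counter() - t0, 3),
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    runner = _StageRunner(outdir, chash)
    note = f"stage={{stage}} config_hash={chash}"
    planted_term = None

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.simulate.seed)
        indir = outdir / "inputs"

        def _simulate():
            write_bundle(generate_bundle(sim), indir)

        runner.run("simulate", [indir / "expression.tsv"], _simulate)
        expr_path = indir / "expression.tsv"
        gene_path = indir / "gene_expression.tsv"
        pheno_path = indir / "phenotype.tsv"
        pred_path = indir / "predictions.tsv"
        ann_path = indir / "annotations.tsv"
        planted_term = json.loads((indir / "bundle_meta.json").read_text())["planted_term"]
    else:
        expr_path = Path(config.expression_path)
        gene_path = (Path(config.gene_expression_path)
                     if config.gene_expression_path else None)
        pheno_path = Path(config.phenotype_path)
        pred_path = Path(config.predictions_path)
        ann_path = Path(config.annotations_path)

    # --- normalization ----------------------------------------------------
    norm_mirna = outdir / "normalized_expression.tsv"
    norm_gene = outdir / "normalized_gene_expression.tsv"

    def _normalize():
        for src, dst in ((expr_path, norm_mirna), (gene_path, norm_gene)):
            if src is None:
                continue
            mat = ExpressionMatrix.from_tsv(src, pheno_path)
            mat = quantile_normalize(log2_transform(mat, config.already_logged))
            out = mat.values.copy()
            out.insert(0, "feature_id", mat.values.index)
            write_tsv(out, dst, header_comment=note.format(stage="normalize"))

    runner.run("normalize", [norm_mirna], _normalize)

    # --- miRNA-level selection -------------------------------------------
    sel_path = outdir / "selection.tsv"

    def _select():
        mat = ExpressionMatrix.from_tsv(norm_mirna, pheno_path)
        table = run_selection(mat, n_components=config.n_components,
                              n_perm=config.n_perm,
                              seed=_stage_seed(config.seed, "select"),
                              fdr_threshold=config.fdr_threshold)
        write_tsv(table, sel_path, header_comment=note.format(stage="select"))

    runner.run("select", [sel_path], _select)
    selection = read_tsv(sel_path)
    significant = select_significant(selection, config.fdr_threshold)
    runner.manifest["select"]["rows"] = int(len(selection))
    runner.manifest["select"]["n_significant"] = int(len(significant))

    # --- survival screen --------------------------------------------------
    surv_path = outdir / "survival_screen.tsv"

    def _survival():
        mat = ExpressionMatrix.from_tsv(norm_mirna, pheno_path)
        pheno = read_tsv(pheno_path)
        table = survival_screen(mat, list(significant["feature"]), pheno,
                                alpha=config.survival_alpha)
        curves = table.attrs.get("km_curves", {})
        for feat, strata in curves.items():
            km = pd.concat([c.as_frame().assign(stratum=s) for s, c in strata.items()],
                           ignore_index=True)
            write_tsv(km, outdir / f"km_{feat}.tsv",
                      header_comment=note.format(stage="survival"))
        write_tsv(table.drop(columns=[], errors="ignore"), surv_path,
                  header_comment=note.format(stage="survival"))

    runner.run("survival", [surv_path], _survival)
    surv = read_tsv(surv_path)
    runner.manifest["survival"]["rows"] = int(len(surv))
    runner.manifest["survival"]["n_significant"] = (
        int(surv["significant"].sum()) if len(surv) else 0)

    # --- gene-level selection (same machinery, gene matrix) ---------------
    gene_sel_path = outdir / "gene_selection.tsv"
    if gene_path is not None:
        def _select_genes():
            mat = ExpressionMatrix.from_tsv(norm_gene, pheno_path)
            table = run_selection(mat, n_components=config.n_components,
                                  n_perm=config.n_perm,
                                  seed=_stage_seed(config.seed, "select_genes"),
                                  fdr_threshold=config.fdr_threshold)
            write_tsv(table, gene_sel_path,
                      header_comment=note.format(stage="select_genes"))

        runner.run("select_genes", [gene_sel_path], _select_genes)
        gene_selection = read_tsv(gene_sel_path)
        de_genes = set(gene_selection.loc[gene_selection["significant"], "feature"])
        runner.manifest["select_genes"]["rows"] = int(len(gene_selection))
        runner.manifest["select_genes"]["n_significant"] = len(de_genes)
    else:
        gene_selection = pd.DataFrame(columns=["feature", "fold_change", "significant"])
        de_genes = set()

    # --- network ----------------------------------------------------------
    net_nodes = outdir / "network_nodes.tsv"

    def _network():
        predictions = read_predictions(pred_path)
        keep_mirnas = set(significant["feature"])
        predictions = predictions[predictions["mirna"].isin(keep_mirnas)]
        supported = filter_by_support(predictions, config.min_methods)
        targets = filter_de_targets(supported, de_genes) if len(supported) else supported
        mirna_dir = _directions(selection)
        gene_dir = _directions(gene_selection)
        G = build_network(targets, mirna_dir, gene_dir)
        write_network(G, outdir)

    runner.run("network", [net_nodes], _network)
    nodes = read_tsv(net_nodes) if net_nodes.exists() else pd.DataFrame()
    edges = read_tsv(outdir / "network_edges.tsv")
    runner.manifest["network"]["n_nodes"] = int(len(nodes))
    runner.manifest["network"]["n_edges"] = int(len(edges))

    # --- enrichment -------------------------------------------------------
    enr_path = outdir / "enrichment.tsv"

    def _enrich():
        collection = read_annotations(ann_path)
        assayed = set(gene_selection["feature"]) if len(gene_selection) else None
        if assayed:
            universe = collection.universe & frozenset(assayed)
            collection = _restrict(collection, universe)
        query = (set(nodes.loc[nodes["kind"] == "gene", "node"])
                 if len(nodes) else set())
        table = enrich(query, collection, config.enrichment_threshold)
        write_tsv(table, enr_path, header_comment=note.format(stage="enrich"))

    runner.run("enrich", [enr_path], _enrich)
    enr = read_tsv(enr_path)
    runner.manifest["enrich"]["rows"] = int(len(enr))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "planted_term": planted_term,
        "stages": runner.manifest,
        "top_enriched_term": (str(enr["term"].iloc[0]) if len(enr) else None),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_seed(seed: int, stage: str) -> int:
    """Derive a stage-level integer seed below 2**31 from the master seed."""
    return int(stage_rng(seed, stage).integers(0, 2**31 - 1))


def _directions(selection: pd.DataFrame) -> dict[str, str]:
    if not len(selection):
        return {}
    return {str(f): ("up" if fc >= 0 else "down")
            for f, fc in zip(selection["feature"], selection["fold_change"])}


def _restrict(collection, universe):
    from .enrichment import AnnotationCollection, Term
    terms = []
    for t in collection.terms:
        members = t.members & universe
        if members:
            terms.append(Term(t.term_id, t.description, t.class_label, members))
    return AnnotationCollection(terms, frozenset(universe))
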