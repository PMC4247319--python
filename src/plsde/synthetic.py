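"""Synthetic cohort generator emulating a two-grade tumor expression study.

Every pipeline input is generated with the statistical structure the
analysis assumes, so each downstream stage is testable without external
data:

* a miRNA-like log2 expression matrix over two classes (default 24
  grade-III-like vs 50 grade-IV-like samples) in which ``n_spiked``
  features carry a true class-mean shift of ``effect_size`` within-class
  standard deviations, with alternating sign so both up- and
  down-regulation occur;
* exponential survival times whose hazard depends on the high/low stratum
  of a designated prognostic feature, plus independent exponential
  censoring;
* four-method miRNA->gene prediction lists with a controllable fraction of
  pairs shared by >= 2 methods;
* a gene-level expression matrix in which a fraction of the supported
  target genes is truly differential; and
* annotation terms over the gene universe with one planted enriched term.

A single master seed drives one RNG per stage (sub-streams split by stage
name), so any stage can be regenerated independently and a fixed
configuration yields byte-identical output files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationCollection, Term, write_annotations
from .errors import ParameterError
from .io import write_tsv
from .normalization import ExpressionMatrix

DEFAULT_METHODS = ("microt", "miranda", "mircode", "targetscan")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    The cohort shape mirrors the two-grade design the pipeline targets
    (24 + 50 samples); expression is Gaussian on the log2 scale around
    ``baseline_mean`` with within-class standard deviation ``noise_sd``,
    and spiked features shift the grade-IV-like class mean by
    ``effect_size * noise_sd`` (alternating sign).
    """

    n_features: int = 500
    n_class_a: int = 24
    n_class_b: int = 50
    n_spiked: int = 20
    effect_size: float = 1.5
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    # survival layer
    baseline_hazard: float = 0.05
    hazard_ratio: float = 4.0
    censor_rate: float = 0.01
    # target-prediction / annotation layer
    n_gene_features: int = 300
    targets_per_mirna: int = 5
    share_fraction: float = 0.5
    methods: tuple[str, ...] = DEFAULT_METHODS
    gene_de_fraction: float = 0.3
    n_terms: int = 20
    term_size_min: int = 5
    term_size_max: int = 30
    planted_term_size: int = 12
    planted_overlap: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_features, self.n_class_a, self.n_class_b) < 1:
            raise ParameterError("all counts must be >= 1")
        if not 0 <= self.n_spiked <= self.n_features:
            raise ParameterError("need 0 <= n_spiked <= n_features")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ParameterError("hazards must be > 0")
        if self.censor_rate < 0:
            raise ParameterError("censor_rate must be >= 0")
        if not 0 <= self.share_fraction <= 1:
            raise ParameterError("share_fraction must be in [0, 1]")
        if max(self.term_size_max, self.planted_term_size) > self.n_gene_features:
            raise ParameterError("gene universe smaller than the largest term")
        if self.planted_overlap > self.planted_term_size:
            raise ParameterError("planted_overlap cannot exceed planted_term_size")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG: the master seed plus a stage-name key."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode("utf-8"))]))


def _sample_frame(config: SimulationConfig) -> tuple[list[str], list[str]]:
    n = config.n_class_a + config.n_class_b
    ids = [f"S{i + 1:03d}" for i in range(n)]
    labels = ["gradeIII"] * config.n_class_a + ["gradeIV"] * config.n_class_b
    return ids, labels


def generate_expression(config: SimulationConfig,
                        prefix: str = "mir",
                        stage: str = "expression",
                        n_features: int | None = None,
                        spiked_ids: list[str] | None = None,
                        all_ids: list[str] | None = None,
                        ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw the two-class Gaussian matrix and the list of true effects.

    Returns the matrix and a truth table with columns ``feature_id`` and
    ``effect`` (the signed class-B minus class-A mean shift in log2 units,
    alternating +/- over the spiked features).  ``spiked_ids``/``all_ids``
    allow the gene layer to reuse this machinery with externally chosen
    spikes; by default ``n_spiked`` feature ids are drawn at random.
    """
    rng = stage_rng(config.seed, stage)
    p = n_features if n_features is not None else config.n_features
    ids = all_ids if all_ids is not None else [f"{prefix}-{i + 1:04d}" for i in range(p)]
    if len(ids) != p:
        raise ParameterError("all_ids length must equal n_features")
    sample_ids, labels = _sample_frame(config)
    n = len(sample_ids)

    if spiked_ids is None:
        if config.n_spiked > p:
            raise ParameterError("n_spiked exceeds n_features")
        idx = np.sort(rng.choice(p, size=config.n_spiked, replace=False))
        spiked_ids = [ids[i] for i in idx]
    missing = set(spiked_ids) - set(ids)
    if missing:
        raise ParameterError(f"spiked ids not in feature ids: {sorted(missing)[:5]}")

    values = config.baseline_mean + rng.normal(0.0, config.noise_sd, size=(p, n))
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(spiked_ids))])
    shift = config.effect_size * config.noise_sd
    is_b = np.array([lab == "gradeIV" for lab in labels])
    pos = {f: i for i, f in enumerate(ids)}
    for s, sign in zip(spiked_ids, signs):
        values[pos[s], is_b] += sign * shift

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=ids, columns=sample_ids),
        pd.Series(labels, index=sample_ids, name="class"))
    truth = pd.DataFrame({"feature_id": spiked_ids,
                          "effect": signs * shift if len(spiked_ids) else
                          np.empty(0, dtype=float)})
    return matrix, truth


def generate_survival(expression: ExpressionMatrix, truth: pd.DataFrame,
                      config: SimulationConfig) -> pd.DataFrame:
    """Exponential survival with stratum-dependent hazard, plus censoring.

    The first truth feature is the designated prognostic marker: samples
    above its median expression carry hazard ``baseline_hazard *
    hazard_ratio``, the rest ``baseline_hazard``.  Censoring times are
    independent exponentials at ``censor_rate`` (0 disables censoring).
    Returns the phenotype table (sample, class, time, event).
    """
    rng = stage_rng(config.seed, "survival")
    if truth.empty:
        if config.hazard_ratio != 1.0:
            raise ParameterError(
                "hazard_ratio != 1 requires a prognostic (spiked) feature")
        prognostic = expression.feature_ids[0]
    else:
        prognostic = truth["feature_id"].iloc[0]
    x = expression.values.loc[prognostic].to_numpy()
    high = x > np.median(x)
    hazard = np.where(high, config.baseline_hazard * config.hazard_ratio,
                      config.baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_time = rng.exponential(1.0 / config.censor_rate, size=len(x))
    else:
        censor_time = np.full(len(x), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({
        "sample": expression.sample_ids,
        "class": expression.class_labels.to_numpy(),
        "time": time,
        "event": event,
    })


def generate_predictions_and_annotations(
        de_features: list[str], config: SimulationConfig,
        universe: list[str] | None = None,
        de_target_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, AnnotationCollection, str]:
    """Multi-method target lists and annotation terms with one planted hit.

    Each miRNA in ``de_features`` receives ``targets_per_mirna`` genes from
    the universe; a pair is emitted by 2-3 methods with probability
    ``share_fraction`` and by a single method otherwise.  One planted term
    overlaps ``planted_overlap`` of the (differentially expressed, when
    given) target genes; the remaining terms draw members uniformly.
    Returns (predictions, annotations, planted_term_id).
    """
    rng = stage_rng(config.seed, "predictions")
    if universe is None:
        universe = [f"g{i + 1:04d}" for i in range(config.n_gene_features)]
    if max(config.term_size_max, config.planted_term_size) > len(universe):
        raise ParameterError("gene universe smaller than the largest term")

    records = []
    for m in de_features:
        genes = rng.choice(len(universe), size=min(config.targets_per_mirna, len(universe)),
                           replace=False)
        for gi in genes:
            g = universe[gi]
            if rng.random() < config.share_fraction:
                k = int(rng.integers(2, len(config.methods) + 1))
            else:
                k = 1
            for mi in sorted(rng.choice(len(config.methods), size=k, replace=False)):
                records.append({"mirna": m, "gene": g, "method": config.methods[mi]})
    predictions = pd.DataFrame(records, columns=["mirna", "gene", "method"])

    rng_ann = stage_rng(config.seed, "annotations")
    if de_target_genes is None:
        de_target_genes = sorted(set(predictions["gene"])) if len(predictions) else []
    hit_pool = [g for g in de_target_genes if g in set(universe)]
    n_hit = min(config.planted_overlap, len(hit_pool))
    planted = list(rng_ann.choice(hit_pool, size=n_hit, replace=False)) if n_hit else []
    outside = [g for g in universe if g not in set(planted)]
    n_fill = config.planted_term_size - len(planted)
    planted += list(rng_ann.choice(outside, size=n_fill, replace=False))

    classes = ("Nervous system", "Function", "Process", "Component")
    terms = [Term("T001", "planted enriched term", "Process", frozenset(planted))]
    for i in range(1, config.n_terms):
        size = int(rng_ann.integers(config.term_size_min, config.term_size_max + 1))
        members = frozenset(rng_ann.choice(universe, size=size, replace=False))
        terms.append(Term(f"T{i + 1:03d}", f"background term {i}",
                          classes[i % len(classes)], members))
    collection = AnnotationCollection(terms, frozenset(universe))
    return predictions, collection, "T001"


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus ground truth for testing."""

    expression: ExpressionMatrix          # miRNA-like layer
    gene_expression: ExpressionMatrix     # gene-like layer
    phenotype: pd.DataFrame
    truth: pd.DataFrame                   # spiked miRNA features with signed effect
    gene_truth: pd.DataFrame              # spiked gene features with signed effect
    predictions: pd.DataFrame
    annotations: AnnotationCollection
    planted_term: str
    config: SimulationConfig = field(repr=False, default=None)


def generate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate the full coherent input bundle.

    The spiked gene features are a ``gene_de_fraction`` subset of the
    genes targeted (with >= 2-method support) by the spiked miRNAs, so the
    downstream network is non-empty and the planted annotation term
    overlaps genuinely differential target genes.
    """
    from .network import filter_by_support

    expression, truth = generate_expression(config)
    phenotype = generate_survival(expression, truth, config)

    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_gene_features)]
    predictions, _, _ = generate_predictions_and_annotations(
        list(truth["feature_id"]), config, universe=gene_ids)

    supported = filter_by_support(predictions, 2) if len(predictions) else \
        pd.DataFrame(columns=["mirna", "gene", "support", "methods"])
    targeted = sorted(set(supported["gene"]))
    rng = stage_rng(config.seed, "gene_spikes")
    n_de = int(round(config.gene_de_fraction * len(targeted)))
    spiked_genes = sorted(rng.choice(targeted, size=n_de, replace=False)) if n_de else []

    gene_expression, gene_truth = generate_expression(
        config, stage="gene_expression", n_features=config.n_gene_features,
        all_ids=gene_ids, spiked_ids=list(spiked_genes))

    _, annotations, planted = generate_predictions_and_annotations(
        list(truth["feature_id"]), config, universe=gene_ids,
        de_target_genes=list(spiked_genes))

    return SyntheticBundle(expression, gene_expression, phenotype, truth,
                           gene_truth, predictions, annotations, planted, config)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component as the pipeline's TSV dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"

    def _expr(values: pd.DataFrame, path: Path) -> Path:
        out = values.round(10).copy()
        out.insert(0, "feature_id", values.index)
        out.to_csv(path, sep="\t", index=False, float_format=float_fmt)
        return path

    paths = {
        "expression": _expr(bundle.expression.values, outdir / "expression.tsv"),
        "gene_expression": _expr(bundle.gene_expression.values,
                                 outdir / "gene_expression.tsv"),
    }
    bundle.phenotype.to_csv(outdir / "phenotype.tsv", sep="\t", index=False,
                            float_format=float_fmt)
    paths["phenotype"] = outdir / "phenotype.tsv"
    paths["predictions"] = write_tsv(bundle.predictions, outdir / "predictions.tsv")
    paths["annotations"] = write_annotations(bundle.annotations, outdir / "annotations.tsv")
    truth = pd.concat([bundle.truth.assign(layer="mirna"),
                       bundle.gene_truth.assign(layer="gene")], ignore_index=True)
    paths["truth"] = write_tsv(truth, outdir / "truth.tsv")
    meta = {"planted_term": bundle.planted_term,
            "config": asdict(bundle.config) if bundle.config else None}
    (outdir / "bundle_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths["meta"] = outdir / "bundle_meta.json"
    return paths
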