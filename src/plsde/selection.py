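"""Permutation null of VIP scores, empirical FDR, and the selection table.

The null hypothesis is "no association between expression and grade".  It
is simulated by shuffling the class labels over samples (the feature matrix
untouched), refitting the PLS model, and pooling all p VIP scores from each
of B permutations into one empirical null distribution.  A feature's FDR at
its observed VIP v is the plug-in estimate

    FDR(v) = [ #{null >= v} / B ] / max(1, #{observed >= v}),

capped at 1 and then monotonized (step-up over the sorted VIPs) so that a
larger VIP never carries a larger FDR.  Features with FDR below the
threshold (default 0.01) are flagged significant.

Fold changes are class-mean differences on the log2 scale, comparison class
minus reference class (positive = overexpressed in the grade-IV-like
class).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, PlsdeError
from .normalization import ExpressionMatrix
from .pls import encode_response, fit_nipals, vip_scores

DEFAULT_N_PERM = 10_000
DEFAULT_FDR_THRESHOLD = 0.01


@dataclass
class PermutationNull:
    """Pooled empirical null of VIP scores from label permutations.

    ``null_scores`` holds B * p values (permutations that explain no
    response variance contribute a zero VIP for every feature and are
    counted in ``n_degenerate``).
    """

    null_scores: np.ndarray
    n_perm: int
    n_features: int
    seed: int | None = None
    n_degenerate: int = 0
    effective_components: np.ndarray | None = None


def _vip_or_zero(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[np.ndarray, int]:
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        fit = fit_nipals(X, y, n_components=n_components)
    try:
        return vip_scores(fit).vip, fit.n_components_effective
    except PlsdeError:
        return np.zeros(X.shape[1]), 0


def permute_null(X: np.ndarray, class_labels: Sequence[str], n_components: int = 2,
                 n_perm: int = DEFAULT_N_PERM, seed: int | None = None,
                 permutations: Sequence[np.ndarray] | None = None) -> PermutationNull:
    """Build the pooled VIP null by refitting PLS under label permutations.

    Parameters
    ----------
    X
        samples x features block (uncentered is fine; each refit centers).
    permutations
        Optional explicit list of index arrays, overriding random shuffles
        (used for exhaustive small-design enumeration); ``n_perm`` is then
        taken from its length.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(class_labels)
    if permutations is not None:
        perms: list[np.ndarray] = [np.asarray(p) for p in permutations]
        n_perm = len(perms)
    if n_perm < 1 or X.shape[1] < 1:
        raise ParameterError("need n_perm >= 1 and >= 1 feature")
    rng = np.random.default_rng(seed)

    pooled = np.empty((n_perm, X.shape[1]))
    eff = np.empty(n_perm, dtype=int)
    n_degenerate = 0
    for b in range(n_perm):
        idx = perms[b] if permutations is not None else rng.permutation(len(labels))
        y, _ = encode_response(labels[idx])
        vip, a_eff = _vip_or_zero(X, y, n_components)
        pooled[b] = vip
        eff[b] = a_eff
        if a_eff == 0:
            n_degenerate += 1
    return PermutationNull(
        null_scores=pooled.ravel(), n_perm=n_perm, n_features=X.shape[1],
        seed=seed, n_degenerate=n_degenerate, effective_components=eff)


def empirical_fdr(observed: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Empirical FDR of each observed VIP against the pooled null.

    Tail counts use >= (ties included); raw estimates are capped at 1 and
    monotonized so FDR is non-increasing in VIP.
    """
    v = np.asarray(observed, dtype=float)
    if null.null_scores.size == 0:
        raise ParameterError("empty permutation null")
    sorted_null = np.sort(null.null_scores)
    sorted_obs = np.sort(v)
    null_tail = sorted_null.size - np.searchsorted(sorted_null, v, side="left")
    obs_tail = sorted_obs.size - np.searchsorted(sorted_obs, v, side="left")
    raw = (null_tail / null.n_perm) / np.maximum(1, obs_tail)
    raw = np.minimum(raw, 1.0)
    # step-up: fdr_j = min raw over features with vip <= vip_j
    order = np.argsort(v, kind="stable")
    fdr = np.empty_like(raw)
    fdr[order] = np.minimum.accumulate(raw[order])
    return fdr


def fold_changes(matrix: ExpressionMatrix) -> pd.Series:
    """Per-feature log2 class-mean difference, comparison minus reference.

    The reference class is the lexicographically first label (grade-III-like),
    so a positive value means higher expression in the grade-IV-like class.
    """
    ref, cmp_ = matrix.classes
    labels = matrix.class_labels
    vals = matrix.values
    mean_cmp = vals.loc[:, (labels == cmp_).to_numpy()].mean(axis=1)
    mean_ref = vals.loc[:, (labels == ref).to_numpy()].mean(axis=1)
    out = mean_cmp - mean_ref
    out.name = "fold_change"
    return out


def build_selection_table(matrix: ExpressionMatrix, vip: np.ndarray, fdr: np.ndarray,
                          threshold: float = DEFAULT_FDR_THRESHOLD) -> pd.DataFrame:
    """Assemble the per-feature table: feature, vip, fold_change, fdr, significant."""
    fc = fold_changes(matrix)
    return pd.DataFrame({
        "feature": matrix.feature_ids,
        "vip": np.asarray(vip, dtype=float),
        "fold_change": fc.to_numpy(),
        "fdr": np.asarray(fdr, dtype=float),
        "significant": np.asarray(fdr, dtype=float) < threshold,
    })


def select_significant(table: pd.DataFrame,
                       threshold: float = DEFAULT_FDR_THRESHOLD) -> pd.DataFrame:
    """Rows with fdr < threshold, sorted by fdr then |fold change| descending."""
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must be in (0, 1]")
    kept = table[table["fdr"] < threshold].copy()
    kept["_absfc"] = kept["fold_change"].abs()
    kept = kept.sort_values(["fdr", "_absfc"], ascending=[True, False],
                            kind="stable").drop(columns="_absfc")
    return kept.reset_index(drop=True)


def run_selection(matrix: ExpressionMatrix, n_components: int = 2,
                  n_perm: int = DEFAULT_N_PERM, seed: int | None = None,
                  fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> pd.DataFrame:
    """Observed fit + permutation null + FDR, returning the selection table.

    Convenience wrapper used for both the miRNA and the gene matrix (the
    gene-level screen reuses the identical machinery).
    """
    y, _ = encode_response(matrix.class_labels.to_numpy())
    X = matrix.values.to_numpy().T
    fit = fit_nipals(X, y, n_components=n_components, feature_ids=matrix.feature_ids)
    vip = vip_scores(fit).vip
    null = permute_null(X, matrix.class_labels.to_numpy(), n_components=n_components,
                        n_perm=n_perm, seed=seed)
    fdr = empirical_fdr(vip, null)
    return build_selection_table(matrix, vip, fdr, threshold=fdr_threshold)
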