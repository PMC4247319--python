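"""Univariate-response partial least squares by NIPALS, and VIP scores.

PLS projects the (samples x features) predictor block X onto latent
components that maximize covariance with the response y — here a centered
0/1 coding of the two-level tumor-grade label.  For a univariate response
the NIPALS inner loop converges in a single pass per component: the weight
vector of component *a* is proportional to ``X_a' y_a``, followed by score,
loading and deflation updates.

Feature influence is summarized by the variable importance in the
projection (VIP),

    VIP_j = sqrt( p * sum_a ssy_a * w_aj^2 / sum_a ssy_a ),

where ``ssy_a = q_a^2 * t_a' t_a`` is the response variance captured by
component *a* and each weight column has unit norm.  The mean squared VIP
equals 1 by construction, so VIP > 1 flags features that are more
influential than average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, NoSignalWarning, ParameterError, PlsdeError


def encode_response(class_labels: Sequence[str]) -> tuple[np.ndarray, dict[str, float]]:
    """Code a two-level label vector as centered 0/1.

    The lexicographically first class maps to 0, the second to 1; the coded
    vector is then mean-centered.  Returns the centered vector and the
    label -> raw-code map.  Downstream VIP scores are invariant to any
    affine recoding of this choice.
    """
    labels = np.asarray(class_labels)
    levels = sorted(np.unique(labels).tolist())
    if len(levels) != 2:
        raise DataError(f"response must have exactly two classes, got {levels}")
    mapping = {levels[0]: 0.0, levels[1]: 1.0}
    y = np.array([mapping[l] for l in labels], dtype=float)
    return y - y.mean(), mapping


@dataclass
class PLSFit:
    """A fitted univariate-response PLS decomposition.

    Attributes
    ----------
    weights : (p, A) array, columns of unit norm
    scores : (n, A) array of mutually orthogonal score vectors
    x_loadings : (p, A) array
    y_loadings : (A,) array
    ssy : (A,) array, response sum of squares captured per component
    x_mean, y_mean : centering constants
    n_components_requested / n_components_effective : A before/after the
        early-termination tolerance rule
    """

    weights: np.ndarray
    scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    ssy: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    feature_ids: list[str] | None = None
    n_components_requested: int = 0
    n_components_effective: int = 0
    total_ssy: float = field(default=np.nan, compare=False)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def explained_response_fraction(self) -> np.ndarray:
        """Per-component fraction of the centered response sum of squares."""
        return self.ssy / self.total_ssy


def fit_nipals(X: np.ndarray, y: np.ndarray, n_components: int = 2,
               tol: float = 1e-12, max_iter: int = 500,
               scale: bool = False,
               feature_ids: Sequence[str] | None = None) -> PLSFit:
    """Fit PLS components by NIPALS on a samples x features block.

    ``X`` and ``y`` are centered internally (means recorded on the fit).
    With a univariate response the per-component iteration converges in one
    pass, so each component is computed directly as::

        w_a = X_a' y_a / ||X_a' y_a||      (unit-norm weights)
        t_a = X_a w_a
        p_a = X_a' t_a / (t_a' t_a)
        q_a = y_a' t_a / (t_a' t_a)
        X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - q_a t_a

    Components whose weight-defining covariance norm falls below
    ``tol * ||X_1' y_1||`` terminate fitting early; the effective number of
    components is recorded.  ``max_iter`` is kept in the signature for a
    multi-response generalization and is not consulted here.

    Raises
    ------
    ParameterError
        If ``n_components`` exceeds ``min(n - 1, p)`` or ``tol <= 0``.
    DataError
        If the response has zero variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ParameterError(f"X has {n} samples but y has {y.shape[0]}")
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    if not 1 <= n_components <= min(n - 1, p):
        raise ParameterError(
            f"n_components={n_components} outside [1, min(n-1, p)={min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise DataError("response has zero variance")

    x_mean = X.mean(axis=0)
    Xa = X - x_mean
    if scale:
        sd = Xa.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xa = Xa / sd
    y_mean = float(y.mean())
    ya = y - y_mean
    total_ssy = float(ya @ ya)

    W, T, P, Q, SSY = [], [], [], [], []
    init_norm = float(np.linalg.norm(Xa.T @ ya))
    if init_norm == 0.0:
        warnings.warn("X'y = 0: no feature covaries with the response; "
                      "0 effective components", NoSignalWarning, stacklevel=2)
    else:
        for _ in range(n_components):
            c = Xa.T @ ya
            cn = float(np.linalg.norm(c))
            if cn <= tol * init_norm:
                break
            w = c / cn
            t = Xa @ w
            tt = float(t @ t)
            if tt <= 0.0:
                break
            pa = Xa.T @ t / tt
            qa = float(ya @ t / tt)
            Xa = Xa - np.outer(t, pa)
            ya = ya - qa * t
            W.append(w)
            T.append(t)
            P.append(pa)
            Q.append(qa)
            SSY.append(qa * qa * tt)

    A = len(W)
    return PLSFit(
        weights=np.column_stack(W) if A else np.empty((p, 0)),
        scores=np.column_stack(T) if A else np.empty((n, 0)),
        x_loadings=np.column_stack(P) if A else np.empty((p, 0)),
        y_loadings=np.asarray(Q, dtype=float),
        ssy=np.asarray(SSY, dtype=float),
        x_mean=x_mean,
        y_mean=y_mean,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
        n_components_requested=n_components,
        n_components_effective=A,
        total_ssy=total_ssy,
    )


@dataclass
class VIPVector:
    """Per-feature VIP scores; ``sum(vip**2) == p`` up to rounding."""

    vip: np.ndarray
    feature_ids: list[str] | None = None


def vip_scores(fit: PLSFit) -> VIPVector:
    """Variable importance in the projection for a fitted model.

    Raises
    ------
    PlsdeError
        If the fit captured no response variance (0 effective components or
        all ``ssy`` zero), in which case VIP is undefined.
    """
    if fit.n_components_effective < 1 or not np.any(fit.ssy > 0):
        raise PlsdeError("VIP undefined: fit explains no response variance")
    p = fit.n_features
    num = (fit.weights ** 2) @ fit.ssy
    vip = np.sqrt(p * num / fit.ssy.sum())
    return VIPVector(vip=vip, feature_ids=fit.feature_ids)
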