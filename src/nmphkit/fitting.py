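"""Theory-constrained cubic (U-shape) fitting and cross-validation.

The nonmonotonic-plasticity prediction — no change at low coactivation,
differentiation (a dip) at moderate coactivation, integration at high —
is quantified by a cubic polynomial in similarity level whose leading
coefficient is constrained to be positive, guaranteeing a dip followed
by a positive inflection.  The model is evaluated by
leave-one-participant-out cross-validation: fit on the level-wise mean
curve of the remaining participants, predict the held-out curve, and
average the per-fold Pearson correlations (raw, not Fisher-transformed).

The constraint is a single lower bound on one coefficient, so the
constrained least-squares solution has a closed form: if the
unconstrained cubic already satisfies a >= a_min it is returned
unchanged; otherwise a is pinned at a_min and the remaining coefficients
re-fit on the residual y - a_min x^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .simulate import ChangeCurve

__all__ = [
    "CubicFit",
    "CVResult",
    "ConstrainedCubic",
    "fit_constrained_cubic",
    "loo_cv",
    "cv_fit_stat",
    "dip_contrasts",
]


@dataclass
class CubicFit:
    """Constrained cubic coefficients on the standardized level axis."""

    a: float
    b: float
    c: float
    d: float
    fitted: np.ndarray
    sse: float
    constraint_active: bool
    x_mean: float
    x_scale: float

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])

    @property
    def coef_raw(self) -> np.ndarray:
        """Coefficients on the raw (unstandardized) level axis."""
        m, s = self.x_mean, self.x_scale
        a, b, c, d = self.coef
        # substitute z = (x - m)/s into a z^3 + b z^2 + c z + d
        a3 = a / s**3
        b2 = b / s**2 - 3 * a * m / s**3
        c1 = c / s - 2 * b * m / s**2 + 3 * a * m**2 / s**3
        d0 = d - c * m / s + b * m**2 / s**2 - a * m**3 / s**3
        return np.array([a3, b2, c1, d0])


@dataclass
class CVResult:
    """Leave-one-participant-out fit statistic."""

    mean_r: float
    per_fold_r: np.ndarray
    n_folds: int
    n_skipped: int = 0


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    x = np.asarray(x, dtype=np.float64)
    m = float(x.mean())
    s = float(x.std())
    if s == 0:
        raise ValueError("x values are all identical")
    return (x - m) / s, m, s


def _design(z: np.ndarray) -> np.ndarray:
    return np.vander(z, 4)  # columns z^3, z^2, z, 1


def _solve_constrained(
    X: np.ndarray, y: np.ndarray, a_min: float
) -> tuple[np.ndarray, bool]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    if coef[0] >= a_min:
        return coef, False
    resid = y - a_min * X[:, 0]
    sub, *_ = np.linalg.lstsq(X[:, 1:], resid, rcond=None)
    return np.concatenate([[a_min], sub]), True


def fit_constrained_cubic(
    x: np.ndarray,
    y: np.ndarray | ChangeCurve,
    a_min: float = 1e-6,
) -> CubicFit:
    """Least-squares cubic in standardized x subject to a >= a_min.

    ``y`` may be a single curve or a stack of per-participant curves
    (participants x levels), in which case the fit targets all points
    pooled (equivalently the level-wise mean, since x repeats).
    """
    if isinstance(y, ChangeCurve):
        y = y.delta
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct x values for a cubic")
    if y.ndim == 2:
        if y.shape[1] != len(x):
            raise ValueError("curve length must match x")
        y_fit = y.mean(axis=0)
    else:
        y_fit = y
    z, m, s = _standardize(x)
    X = _design(z)
    coef, active = _solve_constrained(X, y_fit, a_min)
    fitted = X @ coef
    sse = float(np.sum((y_fit - fitted) ** 2))
    return CubicFit(*coef, fitted=fitted, sse=sse, constraint_active=active,
                    x_mean=m, x_scale=s)


class ConstrainedCubic(BaseEstimator, RegressorMixin):
    """Cubic regression with a positivity bound on the leading coefficient.

    scikit-learn-compatible estimator: ``fit(X, y)`` with X a single
    column of similarity levels, ``predict(X)`` returning the fitted
    curve.  Levels are standardized internally (the constraint applies
    to the standardized leading coefficient).

    Parameters
    ----------
    a_min:
        Lower bound for the leading coefficient; any positive value
        enforces the dip-then-rise shape, and the default keeps the
        unconstrained solution whenever that solution is already convex
        on the right.
    """

    def __init__(self, a_min: float = 1e-6):
        self.a_min = a_min

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("ConstrainedCubic expects a single feature")
            X = X[:, 0]
        result = fit_constrained_cubic(X, np.asarray(y, dtype=np.float64),
                                       self.a_min)
        self.coef_ = result.coef
        self.constraint_active_ = result.constraint_active
        self.x_mean_ = result.x_mean
        self.x_scale_ = result.x_scale
        self.sse_ = result.sse
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[:, 0]
        z = (X - self.x_mean_) / self.x_scale_
        return _design(z) @ self.coef_


def _loo_fold_fits(
    curves: np.ndarray, X: np.ndarray, a_min: float
) -> np.ndarray:
    """Vectorized per-fold constrained fits on leave-one-out means.

    curves: (n_subj, n_levels).  Returns (n_subj, n_levels) predictions,
    fold i fit on the mean of all curves but i.
    """
    n = curves.shape[0]
    fold_means = (curves.sum(axis=0)[None, :] - curves) / (n - 1)
    pinv_full = np.linalg.pinv(X)  # (4, L)
    coefs = fold_means @ pinv_full.T  # (n, 4)
    low = coefs[:, 0] < a_min
    if np.any(low):
        pinv_sub = np.linalg.pinv(X[:, 1:])  # (3, L)
        resid = fold_means[low] - a_min * X[:, 0][None, :]
        coefs_sub = resid @ pinv_sub.T
        coefs[low, 0] = a_min
        coefs[low, 1:] = coefs_sub
    return coefs @ X.T


def loo_cv(
    subject_curves: np.ndarray | list[ChangeCurve],
    a_min: float = 1e-6,
    levels: np.ndarray | None = None,
) -> CVResult:
    """Leave-one-participant-out cross-validated fit statistic.

    Each fold fits the constrained cubic to the level-wise mean of the
    training participants' change curves, predicts the held-out curve,
    and correlates prediction with observation; the per-fold Pearson
    correlations are averaged raw.  Folds whose held-out curve has zero
    variance are skipped (and counted).
    """
    if isinstance(subject_curves, list):
        subject_curves = np.stack(
            [c.delta if isinstance(c, ChangeCurve) else np.asarray(c)
             for c in subject_curves]
        )
    curves = np.asarray(subject_curves, dtype=np.float64)
    n, n_levels = curves.shape
    if n < 3:
        raise ValueError("need >= 3 participants for cross-validation")
    if levels is None:
        levels = np.arange(1, n_levels + 1, dtype=np.float64)
    z, _, _ = _standardize(np.asarray(levels, dtype=np.float64))
    X = _design(z)
    preds = _loo_fold_fits(curves, X, a_min)

    pc = preds - preds.mean(axis=1, keepdims=True)
    cc = curves - curves.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(pc, axis=1)
    cn = np.linalg.norm(cc, axis=1)
    valid = (pn > 0) & (cn > 0)
    rs = np.full(n, np.nan)
    rs[valid] = np.einsum("ij,ij->i", pc[valid], cc[valid]) / (pn[valid] * cn[valid])
    n_skipped = int((~valid).sum())
    return CVResult(
        mean_r=float(np.nanmean(rs)),
        per_fold_r=rs,
        n_folds=n,
        n_skipped=n_skipped,
    )


def cv_fit_stat(
    corr_matrices_pre: np.ndarray,
    corr_matrices_post: np.ndarray,
    pairing: np.ndarray,
    a_min: float = 1e-6,
) -> float:
    """LOO-CV mean r for an arbitrary A/B pairing (permutation-null helper).

    ``corr_matrices_*`` are (n_subj, n_pairs, n_pairs) cross-pair
    correlation stacks; the pairing assigns B image ``pairing[i]`` to A
    image i, and the re-paired pair inherits A's similarity level.
    """
    rows = np.arange(corr_matrices_pre.shape[-1])
    pre = corr_matrices_pre[:, rows, pairing]
    post = corr_matrices_post[:, rows, pairing]
    return loo_cv(post - pre, a_min).mean_r


def dip_contrasts(group_curve: ChangeCurve | np.ndarray) -> dict[str, float]:
    """Signed contrasts probing the differentiation dip of an 8-level curve.

    ``level5`` and ``level6`` are the trough levels' change scores
    themselves (negative = differentiation); the flank contrasts compare
    the neighboring peaks to the trough mean (positive = the trough is
    genuinely lower than its flanks).
    """
    delta = group_curve.delta if isinstance(group_curve, ChangeCurve) else np.asarray(group_curve)
    if len(delta) != 8:
        raise ValueError("dip contrasts are defined for 8-level curves")
    trough = 0.5 * (delta[4] + delta[5])
    return {
        "level5": float(delta[4]),
        "level6": float(delta[5]),
        "level4_minus_trough": float(delta[3] - trough),
        "level8_minus_trough": float(delta[7] - trough),
    }
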