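"""Binary logistic responder model: Newton/IRLS fit with diagnostics.

The two-class "multinomial" responder model is an ordinary binary logistic
regression.  Fitting is by Newton–Raphson on the log-likelihood (equivalent
to iteratively reweighted least squares) to a gradient max-norm below 1e-8.
Quasi-separation — likely under leave-one-out refits on small cohorts with
strong predictors — is detected (a coefficient walking past a threshold
while the likelihood still climbs) and handled by refitting with a small
ridge penalty, with a warning.

Diagnostics follow the conventional logistic summary: McFadden pseudo-R²
(1 − LL/LL₀), the likelihood-ratio chi-square 2(LL − LL₀) on df = number of
slope parameters, and its p-value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .features import FEATURE_COLUMNS, FeatureRow, feature_vector


class ModelError(ValueError):
    pass


class SeparationWarning(UserWarning):
    """Raised when (quasi-)separation is detected during fitting."""


@dataclass(frozen=True)
class ModelFit:
    """Coefficients and fit diagnostics of a logistic responder model."""

    coefficients: tuple[float, ...]  # intercept first, then slopes
    feature_names: tuple[str, ...]
    log_likelihood: float
    null_log_likelihood: float
    pseudo_r2: float
    lr_chi2: float
    df: int
    p_value: float
    n: int
    converged: bool
    separation_detected: bool
    ridge_lambda: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "coefficients": dict(
                        zip(("intercept", *self.feature_names), self.coefficients)
                    ),
                    "log_likelihood": self.log_likelihood,
                    "null_log_likelihood": self.null_log_likelihood,
                    "pseudo_r2": self.pseudo_r2,
                    "lr_chi2": self.lr_chi2,
                    "df": self.df,
                    "p_value": self.p_value,
                    "n": self.n,
                    "converged": self.converged,
                    "separation_detected": self.separation_detected,
                    "ridge_lambda": self.ridge_lambda,
                },
                indent=1,
            ),
            encoding="utf-8",
        )


def _design_matrix(rows: Sequence[FeatureRow] | np.ndarray) -> np.ndarray:
    if isinstance(rows, np.ndarray):
        x = np.asarray(rows, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    else:
        x = np.array([feature_vector(r) for r in rows], dtype=float)
    return np.column_stack([np.ones(len(x)), x])


def _log_likelihood(beta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    eta = x @ beta
    # log(1+e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _newton_fit(
    x: np.ndarray,
    y: np.ndarray,
    ridge: float,
    tol: float,
    max_iter: int,
    sep_threshold: float,
) -> tuple[np.ndarray, bool, bool]:
    """Newton iterations; returns (beta, converged, separation_suspected)."""
    n, p = x.shape
    beta = np.zeros(p)
    penalty = np.zeros(p)
    if ridge > 0:
        penalty = np.full(p, ridge)
        penalty[0] = 0.0  # intercept unpenalized
    prev_ll = -np.inf
    separation = False
    converged = False
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        grad = x.T @ (y - mu) - penalty * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        hess = (x * w[:, None]).T @ x + np.diag(penalty)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ModelError("singular information matrix") from exc
        # damped step if the likelihood clearly worsens (tolerance absorbs
        # float-level noise near the optimum, where the surface is flat)
        ll_floor = prev_ll - 1e-9 * max(1.0, abs(prev_ll))
        ll_new = _log_likelihood(beta + step, x, y) - 0.5 * (penalty * (beta + step) ** 2).sum()
        shrink = 0
        while ll_new < ll_floor and shrink < 30:
            step *= 0.5
            shrink += 1
            ll_new = _log_likelihood(beta + step, x, y) - 0.5 * (penalty * (beta + step) ** 2).sum()
        beta = beta + step
        if np.max(np.abs(beta[1:]), initial=0.0) > sep_threshold and ll_new >= prev_ll:
            separation = True
            break
        prev_ll = ll_new
    return beta, converged, separation


def fit_logistic(
    rows: Sequence[FeatureRow] | np.ndarray,
    labels: Sequence[bool] | Sequence[int],
    regularization: Optional[float] = None,
    feature_names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_threshold: float = 30.0,
    min_rows: int = 20,
) -> ModelFit:
    """Maximum-likelihood binary logistic fit with diagnostics.

    ``rows`` is either a sequence of :class:`~psilopred.features.FeatureRow`
    or a 2-D array of predictors (no intercept column).  ``regularization``
    of ``None`` means plain ML; a float λ applies a ridge penalty λ/2·Σβ²
    to the slopes.  On detected separation the fit falls back to a ridge fit
    (λ=1e-4) and emits :class:`SeparationWarning`.
    """
    x = _design_matrix(rows)
    y = np.asarray(labels, dtype=float)
    if len(y) != len(x):
        raise ModelError("rows and labels length mismatch")
    if len(y) < min_rows:
        raise ModelError(f"need at least {min_rows} rows, got {len(y)}")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))) or len(classes) < 2:
        raise ModelError("labels must contain both classes")
    if feature_names is None:
        feature_names = (
            tuple(FEATURE_COLUMNS)
            if not isinstance(rows, np.ndarray)
            else tuple(f"x{i + 1}" for i in range(x.shape[1] - 1))
        )

    ridge = float(regularization) if regularization else 0.0
    beta, converged, separation = _newton_fit(
        x, y, ridge, tol, max_iter, separation_threshold
    )
    if converged and not separation and ridge == 0.0:
        # saturated fit: every observation predicted with near-certainty in
        # its own class means the data are (quasi-)separated even though the
        # gradient vanished before any coefficient crossed the threshold
        mu = 1.0 / (1.0 + np.exp(-np.clip(x @ beta, -500, 500)))
        if np.all(np.abs(y - mu) < 1e-4):
            separation = True
    used_ridge = ridge
    if separation and ridge == 0.0:
        warnings.warn(
            "quasi-separation detected; refitting with ridge λ=1e-4",
            SeparationWarning,
            stacklevel=2,
        )
        used_ridge = 1e-4
        beta, converged, _ = _newton_fit(
            x, y, used_ridge, tol, max_iter, np.inf
        )
    if not converged:
        raise ModelError(
            "logistic fit did not converge after "
            f"{max_iter} iterations; consider regularization=1e-4 (ridge)"
        )

    ll = _log_likelihood(beta, x, y)
    p_mean = y.mean()
    ll_null = float(
        len(y) * (p_mean * np.log(p_mean) + (1 - p_mean) * np.log(1 - p_mean))
    )
    df = x.shape[1] - 1
    lr_chi2 = max(2.0 * (ll - ll_null), 0.0)
    pseudo_r2 = 1.0 - ll / ll_null if ll_null != 0 else 0.0
    p_value = float(stats.chi2.sf(lr_chi2, df)) if df > 0 else 1.0
    return ModelFit(
        coefficients=tuple(float(b) for b in beta),
        feature_names=tuple(feature_names),
        log_likelihood=ll,
        null_log_likelihood=ll_null,
        pseudo_r2=float(pseudo_r2),
        lr_chi2=float(lr_chi2),
        df=df,
        p_value=p_value,
        n=len(y),
        converged=converged,
        separation_detected=separation,
        ridge_lambda=used_ridge,
    )


def predict_proba(
    fit: ModelFit, rows: Sequence[FeatureRow] | np.ndarray
) -> np.ndarray:
    """Inverse-logit of the linear predictor for each row."""
    if not fit.converged:
        raise ModelError("cannot predict from an unconverged fit")
    x = _design_matrix(rows)
    if x.shape[1] != len(fit.coefficients):
        raise ModelError(
            f"row has {x.shape[1] - 1} predictors, fit expects "
            f"{len(fit.coefficients) - 1}"
        )
    eta = x @ np.asarray(fit.coefficients)
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class ClassProbabilityDensity:
    """Gaussian KDEs of predicted class probability, per outcome class."""

    grid: np.ndarray
    density_responder: np.ndarray
    density_non_responder: np.ndarray
    bandwidth_responder: float
    bandwidth_non_responder: float


def _gaussian_kde_reflected(
    points: np.ndarray, grid: np.ndarray, bandwidth: Optional[float]
) -> tuple[np.ndarray, float]:
    """Gaussian KDE on [0, 1] with boundary reflection.

    Reflection about 0 and 1 keeps the density mass inside the unit
    interval, so it integrates to 1 over the grid even when probabilities
    pile up near the boundaries.  Scott's rule bandwidth by default, with a
    small floor so degenerate (zero-variance) inputs still yield a density.
    """
    n = len(points)
    if bandwidth is None:
        sd = points.std(ddof=1) if n > 1 else 0.0
        bandwidth = sd * n ** (-1 / 5)
    bandwidth = max(float(bandwidth), 1e-2)
    x = grid[:, None]
    contrib = np.zeros_like(grid)
    for centers in (points, -points, 2.0 - points):
        z = (x - centers[None, :]) / bandwidth
        contrib += np.exp(-0.5 * z**2).sum(axis=1)
    density = contrib / (n * bandwidth * np.sqrt(2 * np.pi))
    return density, bandwidth


def class_probability_density(
    probabilities: Sequence[float],
    labels: Sequence[bool] | Sequence[int],
    bandwidth: Optional[float] = None,
    grid_size: int = 256,
) -> ClassProbabilityDensity:
    """Per-class Gaussian KDE of predicted probabilities on a [0, 1] grid."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ModelError("probabilities must lie in [0, 1]")
    grid = np.linspace(0.0, 1.0, grid_size)
    out = {}
    for cls in (1, 0):
        pts = p[y == cls]
        if len(pts) < 2:
            raise ModelError(f"class {cls} has fewer than 2 points")
        out[cls] = _gaussian_kde_reflected(pts, grid, bandwidth)
    return ClassProbabilityDensity(
        grid=grid,
        density_responder=out[1][0],
        density_non_responder=out[0][0],
        bandwidth_responder=out[1][1],
        bandwidth_non_responder=out[0][1],
    )
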