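"""Locally weighted polynomial regression (LOESS) with a local scale estimator.

The normative model in this package needs two ingredients from its control
sample: a smooth conditional mean of the outcome given the covariate, and a
smooth conditional standard deviation (the outcome noise may be
heteroscedastic, so a single global SD would mis-calibrate deviation scores
at the edges of the covariate range). Both are provided here by LOESS:
each fitted value is a weighted least-squares polynomial fit over the
``ceil(span * n)`` nearest training points, with tricube weights on the
normalized distance. The local SD is obtained by a second LOESS pass over
the squared residuals, followed by a square root and a floor.

Everything is fitted at the training abscissae and evaluated elsewhere by
linear interpolation; evaluation outside the training range clamps to the
boundary fit (extrapolating a local fit is unreliable) and warns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SmootherConfig",
    "FittedSmoother",
    "tricube_weight",
    "loess_fit",
    "local_scale",
]


@dataclass(frozen=True)
class SmootherConfig:
    """Configuration of the LOESS smoother.

    Parameters
    ----------
    span : float
        Fraction of the training points used in each local neighborhood,
        in ``(0, 1]``. Larger spans give smoother (more biased, less
        variable) fits. Default 0.75, the conventional LOESS default.
    degree : int
        Degree of the local polynomial: 0 (local constant), 1 (local
        linear, default) or 2 (local quadratic).
    robustness_iters : int
        Number of bisquare re-weighting passes applied after the initial
        fit to down-weight outlying residuals. 0 (default) disables
        robustification.
    scale_floor : float
        Minimum admissible local SD, in response units. Prevents division
        by (near-)zero when deviation scores are formed. Must be > 0.
    """

    span: float = 0.75
    degree: int = 1
    robustness_iters: int = 0
    scale_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.span <= 1.0):
            raise ValueError(f"span must be in (0, 1], got {self.span}")
        if self.degree not in (0, 1, 2):
            raise ValueError(f"degree must be 0, 1 or 2, got {self.degree}")
        if self.robustness_iters < 0:
            raise ValueError("robustness_iters must be >= 0")
        if not self.scale_floor > 0:
            raise ValueError("scale_floor must be > 0")


def tricube_weight(u):
    """Tricube kernel ``(1 - |u|^3)^3`` for ``|u| < 1``, else 0.

    ``u`` is the distance to the target point normalized by the
    neighborhood radius; the kernel is symmetric, equals 1 at ``u = 0``
    and vanishes at the neighborhood boundary.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("tricube_weight requires finite input")
    au = np.abs(u)
    w = np.where(au < 1.0, (1.0 - au**3) ** 3, 0.0)
    return w if w.ndim else float(w)


class _Interpolant:
    """Piecewise-linear evaluator over the training grid, clamped outside.

    Calling it outside ``[x[0], x[-1]]`` returns the boundary fitted value
    and emits a warning, since a local fit carries no information beyond
    its training range.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, warn_label: str):
        self._x = x
        self._y = y
        self._label = warn_label

    def __call__(self, x_new):
        x_new = np.asarray(x_new, dtype=float)
        scalar = x_new.ndim == 0
        xv = np.atleast_1d(x_new)
        outside = (xv < self._x[0]) | (xv > self._x[-1])
        if np.any(outside):
            warnings.warn(
                f"{int(outside.sum())} point(s) outside the training range "
                f"[{self._x[0]:.6g}, {self._x[-1]:.6g}] of {self._label}; "
                "clamped to the boundary fit",
                RuntimeWarning,
                stacklevel=2,
            )
        out = np.interp(xv, self._x, self._y)
        return float(out[0]) if scalar else out


@dataclass
class FittedSmoother:
    """A fitted LOESS mean with its accompanying local-SD function.

    Attributes
    ----------
    training_x : ndarray
        Sorted unique training abscissae.
    mean_at : callable
        Local mean, evaluable over the training range.
    scale_at : callable
        Local SD, evaluable over the training range; ``>= scale_floor``
        everywhere. Populated by :func:`local_scale`.
    config : SmootherConfig
    """

    training_x: np.ndarray
    mean_at: _Interpolant
    scale_at: _Interpolant | None
    config: SmootherConfig
    fitted_mean: np.ndarray = field(repr=False, default=None)

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.training_x[0]), float(self.training_x[-1])


def _neighborhood(x_sorted: np.ndarray, x0: float, k: int):
    """Indices of the k nearest points to x0 (ties at the boundary distance
    are all included), returned as a contiguous slice of the sorted grid."""
    d = np.abs(x_sorted - x0)
    if len(x_sorted) <= k:
        return np.arange(len(x_sorted)), d
    # kth smallest distance; include every point at that distance
    radius = np.partition(d, k - 1)[k - 1]
    idx = np.nonzero(d <= radius)[0]
    return idx, d[idx]


def _wls_poly(x: np.ndarray, y: np.ndarray, w: np.ndarray, degree: int, x0: float) -> float:
    """Weighted polynomial fit evaluated at x0; centers at x0 so the
    intercept is the fitted value."""
    wpos = w > 0
    n_eff = int(wpos.sum())
    if degree > 0 and n_eff >= degree + 1:
        xc = x - x0
        X = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        return float(beta[0])
    # degree 0, or too few distinct weighted points: weighted mean
    return float(np.sum(w * y) / np.sum(w))


def loess_fit(x, y, config: SmootherConfig | None = None) -> FittedSmoother:
    """Fit a LOESS smoother of ``y`` on ``x``.

    For each training point the local mean is the tricube-weighted
    least-squares polynomial fit over the ``ceil(span * n)`` nearest
    training points. Distances are normalized by the neighborhood's
    maximum distance; a neighborhood with zero distance spread falls back
    to a weighted mean. With ``robustness_iters > 0``, bisquare weights on
    the residuals are folded into the kernel weights between passes.

    Raises
    ------
    ValueError
        If inputs are non-finite, lengths differ, or there are fewer
        points than the local polynomial needs.
    """
    if config is None:
        config = SmootherConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    n = len(x)
    k = int(np.ceil(config.span * n))
    needed = max(config.degree + 2, k)
    if n < needed:
        raise ValueError(
            f"need at least {needed} points for span={config.span}, "
            f"degree={config.degree}; got {n}"
        )

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    robust = np.ones(n)
    fitted = np.empty(n)
    for iteration in range(config.robustness_iters + 1):
        for i in range(n):
            idx, d = _neighborhood(xs, xs[i], k)
            dmax = d.max()
            if dmax <= 0.0:
                # zero distance spread: weighted mean fallback
                w = robust[idx]
                fitted[i] = float(np.sum(w * ys[idx]) / np.sum(w))
                continue
            w = tricube_weight(d / dmax) * robust[idx]
            if not np.any(w > 0):
                w = robust[idx]
            fitted[i] = _wls_poly(xs[idx], ys[idx], w, config.degree, xs[i])
        if iteration < config.robustness_iters:
            resid = ys - fitted
            s = np.median(np.abs(resid))
            if s <= 0:
                robust = np.ones(n)
            else:
                u = resid / (6.0 * s)
                robust = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)

    # collapse duplicate abscissae to their mean fit for interpolation
    ux, inv = np.unique(xs, return_inverse=True)
    if len(ux) < n:
        uf = np.bincount(inv, weights=fitted) / np.bincount(inv)
    else:
        uf = fitted
    mean_at = _Interpolant(ux, uf, "the fitted mean")
    return FittedSmoother(
        training_x=ux, mean_at=mean_at, scale_at=None, config=config, fitted_mean=uf
    )


def local_scale(x, residuals, config: SmootherConfig | None = None) -> _Interpolant:
    """Local SD as the square root of a LOESS smooth of squared residuals.

    The variance pass uses a local *constant* (degree 0) fit: a local
    polynomial through squared residuals can dip negative near the
    boundaries, which after flooring would turn into wildly inflated
    deviation scores, whereas a kernel-weighted mean of squares is
    nonnegative by construction. The square root is clamped below at
    ``config.scale_floor``, so the returned function is strictly positive
    everywhere; all-zero residuals give the constant ``scale_floor``.
    """
    if config is None:
        config = SmootherConfig()
    x = np.asarray(x, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if x.shape != residuals.shape:
        raise ValueError("x and residuals must have equal length")
    var_config = replace(config, degree=0)
    sm = loess_fit(x, residuals**2, var_config)
    sd = np.sqrt(np.clip(sm.fitted_mean, 0.0, None))
    sd = np.maximum(sd, config.scale_floor)
    return _Interpolant(sm.training_x, sd, "the local scale")
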