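"""t-histogram evolution and asymptotic response-curve models.

Two descriptive summaries of how WM significance accrues with averaging:

1. Normalized histograms of the WM t-value distribution at each NSA, on
   the fixed range [-10, +50] (60 unit-width bins by default). Values
   outside the range are clipped into the end bins so each per-subject
   histogram keeps unit area; group curves average subjects bin-wise.
   With increasing NSA the distribution grows a right tail (responding
   voxels scale as sqrt(N)) while the left edge stays put — the adjusted
   Fisher-Pearson skewness quantifies this.

2. Competitive fits of percent-significant-voxels y against NSA x:

       exponential recovery   y = a (1 - exp(-b x))
       logarithmic            y = a ln(x)
       fractional recovery    y = a x / (b + x)      (Michaelis-Menten form)

   selected by residual error (sum of squared residuals), with 95%
   asymptotic parameter confidence intervals from the linearized
   covariance at the optimum. The fractional asymptote a is the model's
   estimate of the maximum reachable percentage: below 100 whenever some
   voxels never respond.

The mean WM t-value grows as sqrt(N) for a fixed per-pair effect-to-noise
ratio (t = u sqrt(N) / sd), so it is fitted through the origin as
y = K sqrt(NSA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import (EmptyMaskError, InsufficientDataError,
                         InvalidParameterError)
from .significance import TCurveSet

__all__ = ["THistogramSet", "FitResult", "SqrtFit", "t_histograms",
           "group_histograms", "skewness", "fit_response_curve",
           "fit_sqrt_law", "MODEL_FUNCS"]

T_RANGE = (-10.0, 50.0)
DEFAULT_BINS = 60


@dataclass
class THistogramSet:
    """Per-subject unit-area t-densities per NSA over a fixed t-range.

    ``densities`` has shape ``(n_subjects, n_nsa, n_bins)``; each
    ``densities[s, k]`` integrates to 1 over ``bin_edges``.
    """

    bin_edges: np.ndarray
    nsa_grid: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.atleast_3d(np.asarray(self.densities, float))
        widths = np.diff(self.bin_edges)
        areas = (self.densities * widths).sum(axis=-1)
        if not np.allclose(areas, 1.0, atol=1e-6):
            raise InvalidParameterError("each density must integrate to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def group_mean(self) -> np.ndarray:
        """Bin-wise mean density across subjects, shape (n_nsa, n_bins)."""
        return self.densities.mean(axis=0)


def t_histograms(curves: TCurveSet, mask=None, bins: int = DEFAULT_BINS,
                 t_range: tuple[float, float] = T_RANGE) -> THistogramSet:
    """Unit-area histogram of mask t-values at each grid NSA (one subject).

    t-values outside ``t_range`` (including infinite sentinels) are clipped
    into the extreme bins so normalization over the fixed range holds.
    """
    if mask is None:
        mask = np.ones(curves.voxel_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("t_histograms needs a nonempty mask")
    lo, hi = t_range
    edges = np.linspace(lo, hi, bins + 1)
    width = edges[1] - edges[0]
    tvals = curves.t[mask]                      # (m, n_nsa)
    # clip strictly inside so the top edge's right-closed bin catches hi
    clipped = np.clip(tvals, lo, hi - 1e-9 * (hi - lo))
    dens = np.empty((len(curves.nsa_grid), bins))
    for k in range(len(curves.nsa_grid)):
        counts, _ = np.histogram(clipped[:, k], bins=edges)
        dens[k] = counts / (counts.sum() * width)
    return THistogramSet(bin_edges=edges, nsa_grid=curves.nsa_grid.copy(),
                         densities=dens[None, ...])


def group_histograms(subjects: list[THistogramSet]) -> THistogramSet:
    """Stack per-subject histogram sets into one group set (same grid/edges)."""
    if not subjects:
        raise InvalidParameterError("no subjects supplied")
    first = subjects[0]
    for s in subjects[1:]:
        if (not np.array_equal(s.bin_edges, first.bin_edges)
                or not np.array_equal(s.nsa_grid, first.nsa_grid)):
            raise InvalidParameterError(
                "subjects must share bin edges and NSA grid")
    dens = np.concatenate([s.densities for s in subjects], axis=0)
    return THistogramSet(first.bin_edges.copy(), first.nsa_grid.copy(), dens)


def skewness(values) -> float:
    """Adjusted Fisher-Pearson sample skewness (bias-corrected)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 3:
        raise InsufficientDataError("skewness needs at least 3 values")
    if np.var(v) == 0:
        raise InvalidParameterError("skewness undefined for zero variance")
    return float(stats.skew(v, bias=False))


# --- response-curve fitting -------------------------------------------------

def _exp_recovery(x, a, b):
    return a * (1.0 - np.exp(-b * x))


def _fractional(x, a, b):
    return a * x / (b + x)


def _logarithmic(x, a):
    return a * np.log(x)


MODEL_FUNCS = {"exp_recovery": _exp_recovery,
               "logarithmic": _logarithmic,
               "fractional": _fractional}


@dataclass
class FitResult:
    """One fitted candidate model with SSR and 95% parameter CIs."""

    model: str
    params: dict[str, float]
    residual_error: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True

    def predict(self, x):
        return MODEL_FUNCS[self.model](np.asarray(x, float),
                                       **self.params)


@dataclass
class SqrtFit:
    """Through-origin fit of mean t against sqrt(NSA): y = K sqrt(x)."""

    k: float
    residual_error: float
    ci: tuple[float, float]

    def predict(self, x):
        return self.k * np.sqrt(np.asarray(x, float))


def _ci_from_cov(popt, pcov, dof) -> list[tuple[float, float]]:
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    q = stats.t.ppf(0.975, dof) if dof > 0 else 0.0
    return [(float(p - q * s), float(p + q * s)) for p, s in zip(popt, se)]


def _fit_nonlinear(name: str, x, y) -> FitResult:
    func = MODEL_FUNCS[name]
    ymax = float(np.max(y))
    xmed = float(np.median(x))
    p0 = ([ymax, 1.0 / xmed] if name == "exp_recovery" else [ymax, xmed])
    try:
        popt, pcov = optimize.curve_fit(
            func, x, y, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return FitResult(model=name, params=dict(zip("ab", p0)),
                         residual_error=np.inf, converged=False)
    resid = y - func(x, *popt)
    ssr = float(resid @ resid)
    dof = len(x) - 2
    los_his = _ci_from_cov(popt, pcov, dof)
    return FitResult(model=name,
                     params={"a": float(popt[0]), "b": float(popt[1])},
                     residual_error=ssr,
                     ci=dict(zip("ab", los_his)))


def _fit_log(x, y) -> FitResult:
    lx = np.log(x)
    denom = float(lx @ lx)
    if denom == 0:
        return FitResult(model="logarithmic", params={"a": 0.0},
                         residual_error=np.inf, converged=False)
    a = float(lx @ y) / denom
    resid = y - a * lx
    ssr = float(resid @ resid)
    dof = len(x) - 1
    s2 = ssr / dof if dof > 0 else 0.0
    se = np.sqrt(s2 / denom)
    q = stats.t.ppf(0.975, dof) if dof > 0 else 0.0
    return FitResult(model="logarithmic", params={"a": a},
                     residual_error=ssr,
                     ci={"a": (a - q * se, a + q * se)})


def fit_response_curve(nsa, percent_significant
                       ) -> tuple[FitResult, dict[str, FitResult]]:
    """Fit all three candidate response models; select by residual error.

    Parameters
    ----------
    nsa : array of positive counts (>= 4 points)
    percent_significant : array, same length

    Returns
    -------
    (best, candidates)
        ``best`` is the converged candidate with smallest SSR;
        ``candidates`` maps each model name to its :class:`FitResult`
        (non-converged fits carry ``converged=False`` and are excluded
        from selection).
    """
    x = np.asarray(nsa, dtype=np.float64)
    y = np.asarray(percent_significant, dtype=np.float64)
    if x.size < 4:
        raise InsufficientDataError("need at least 4 points to fit")
    if np.any(x <= 0):
        raise InvalidParameterError("nsa values must be positive")
    if x.shape != y.shape:
        raise InvalidParameterError("nsa and percent arrays differ in length")

    candidates = {
        "exp_recovery": _fit_nonlinear("exp_recovery", x, y),
        "logarithmic": _fit_log(x, y),
        "fractional": _fit_nonlinear("fractional", x, y),
    }
    converged = {k: v for k, v in candidates.items() if v.converged}
    if not converged:
        raise InvalidParameterError("no candidate model converged")
    best = min(converged.values(), key=lambda r: r.residual_error)
    return best, candidates


def fit_sqrt_law(nsa, mean_t) -> SqrtFit:
    """Least-squares slope of mean t on sqrt(NSA), through the origin."""
    x = np.asarray(nsa, dtype=np.float64)
    y = np.asarray(mean_t, dtype=np.float64)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 points")
    sx = np.sqrt(x)
    denom = float(sx @ sx)   # = sum(x)
    if denom == 0:
        raise InvalidParameterError("all-zero predictor")
    k = float(sx @ y) / denom
    resid = y - k * sx
    ssr = float(resid @ resid)
    dof = len(x) - 1
    s2 = ssr / dof if dof > 0 else 0.0
    se = np.sqrt(s2 / denom)
    q = stats.t.ppf(0.975, dof) if dof > 0 else 0.0
    return SqrtFit(k=k, residual_error=ssr, ci=(k - q * se, k + q * se))
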