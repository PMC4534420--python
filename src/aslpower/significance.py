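"""Cumulative-NSA paired t-testing: the core voxel-wise computation.

For each voxel the ordered control − label differences d_1..d_N are tested
one-tailed for a mean above zero. On a prefix of the first n differences,

    u  = mean(d_1..d_n)
    sd = sample standard deviation (n - 1 denominator)
    t  = u * sqrt(n) / sd,     p = upper tail of Student-t with n - 1 df.

The prefix engine evaluates t at every value of an increasing NSA grid
using running sums (cumulative sum and sum of squares), so the cost is
linear in the series length per voxel rather than quadratic.

Degenerate prefixes with sd = 0 take the limit values of t: +inf (p = 0)
when u > 0, 0 (p = 0.5) when u = 0, -inf (p = 1) when u < 0.

From the per-voxel t-curves the module derives the quantities of interest:
the fraction of mask voxels significant at each NSA under a chosen
threshold (uncorrected alpha or Bonferroni over the mask), the per-voxel
time-to-significance (first grid NSA at which p crosses the threshold),
and the non-responder set (t < 0 at every grid NSA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import DiffSeries
from .exceptions import (EmptyMaskError, InsufficientDataError,
                         InvalidParameterError)

__all__ = ["TStat", "TCurveSet", "SignificanceCurve", "paired_t", "t_curves",
           "one_sided_p", "significant_fraction", "time_to_significance",
           "find_nonresponders", "NEVER"]

#: Sentinel in time-to-significance maps for voxels that never cross.
NEVER = -1


@dataclass
class TStat:
    """Paired t-statistic: t = u * sqrt(n) / sd on n differences."""

    t: np.ndarray | float
    u: np.ndarray | float
    sd: np.ndarray | float
    n: int

    @property
    def p(self):
        """One-sided (upper tail) p-value, n - 1 degrees of freedom."""
        return one_sided_p(self.t, self.n)


@dataclass
class TCurveSet:
    """Per-voxel t, u, sd evaluated on cumulative prefixes over an NSA grid.

    ``t``, ``u``, ``sd`` have shape ``leading_shape + (len(nsa_grid),)``
    where the leading shape is the voxel layout of the input differences.
    """

    nsa_grid: np.ndarray
    t: np.ndarray
    u: np.ndarray
    sd: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.nsa_grid = np.asarray(self.nsa_grid, dtype=np.int64)
        if self.nsa_grid.ndim != 1 or len(self.nsa_grid) == 0:
            raise InvalidParameterError("nsa_grid must be a nonempty 1D array")
        if np.any(np.diff(self.nsa_grid) <= 0):
            raise InvalidParameterError("nsa_grid must be strictly increasing")
        if self.nsa_grid[-1] > self.n_pairs:
            raise InvalidParameterError("nsa_grid exceeds available pairs")

    @property
    def voxel_shape(self) -> tuple[int, ...]:
        return self.t.shape[:-1]

    @property
    def p(self) -> np.ndarray:
        """One-sided p-values, shape like ``t`` (df varies along the grid axis)."""
        return one_sided_p(self.t, self.nsa_grid)


@dataclass
class SignificanceCurve:
    """Fraction of mask voxels significant at each NSA under one threshold."""

    nsa_grid: np.ndarray
    fraction: np.ndarray
    alpha: float
    correction: str
    mask_size: int

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.fraction


def _t_from_moments(u: np.ndarray, sd: np.ndarray, n) -> np.ndarray:
    """t = u sqrt(n) / sd with sd = 0 mapped to limit sentinels."""
    u = np.asarray(u, dtype=np.float64)
    sd = np.asarray(sd, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = u * np.sqrt(n) / sd
    zero = sd == 0
    if np.any(zero):
        t = np.where(zero & (u > 0), np.inf, t)
        t = np.where(zero & (u == 0), 0.0, t)
        t = np.where(zero & (u < 0), -np.inf, t)
    return t


def one_sided_p(t, n):
    """Upper-tail p of Student-t with ``n - 1`` degrees of freedom.

    Infinite sentinels map to 0 (+inf) and 1 (-inf).
    """
    return stats.t.sf(t, np.asarray(n) - 1)


def paired_t(diffs, axis: int = -1) -> TStat:
    """One-tailed paired t-statistic on a full difference vector (or stack).

    Parameters
    ----------
    diffs : array-like
        Ordered differences; the test runs along ``axis``.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 differences are supplied.
    """
    d = np.asarray(diffs, dtype=np.float64)
    n = d.shape[axis]
    if n < 2:
        raise InsufficientDataError("paired t-test needs at least 2 pairs")
    u = d.mean(axis=axis)
    sd = d.std(axis=axis, ddof=1)
    t = _t_from_moments(u, sd, n)
    return TStat(t=t, u=u, sd=sd, n=n)


def _as_diff_array(diff) -> np.ndarray:
    if isinstance(diff, DiffSeries):
        return diff.data
    return np.asarray(diff, dtype=np.float64)


def t_curves(diff, nsa_grid=None) -> TCurveSet:
    """Evaluate the paired t-statistic on cumulative prefixes of each voxel.

    Parameters
    ----------
    diff : DiffSeries or array (..., n_pairs)
        Ordered differences per voxel.
    nsa_grid : increasing int array in [2, n_pairs], optional
        Prefix lengths at which to evaluate; default every pair 2..n_pairs.

    Returns
    -------
    TCurveSet

    Notes
    -----
    Uses running sums: for prefix length n, the centered sum of squares is
    ``css_n - cs_n**2 / n``, clipped at zero against cancellation, giving
    total cost linear in n_pairs per voxel.
    """
    d = _as_diff_array(diff)
    n_pairs = d.shape[-1]
    if nsa_grid is None:
        nsa_grid = np.arange(2, n_pairs + 1)
    grid = np.asarray(nsa_grid, dtype=np.int64)
    if grid.ndim != 1 or grid.size == 0:
        raise InvalidParameterError("nsa_grid must be a nonempty 1D array")
    if np.any(grid < 2) or np.any(grid > n_pairs):
        raise InvalidParameterError(
            f"nsa_grid values must lie in [2, {n_pairs}]")

    cs = np.cumsum(d, axis=-1)[..., grid - 1]
    css = np.cumsum(d * d, axis=-1)[..., grid - 1]
    nf = grid.astype(np.float64)
    u = cs / nf
    ss = np.maximum(css - cs * cs / nf, 0.0)
    sd = np.sqrt(ss / (nf - 1.0))
    t = _t_from_moments(u, sd, nf)
    return TCurveSet(nsa_grid=grid, t=t, u=u, sd=sd, n_pairs=n_pairs)


def _resolve_mask(curves: TCurveSet, mask) -> np.ndarray:
    if mask is None:
        mask = np.ones(curves.voxel_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != curves.voxel_shape:
        raise InvalidParameterError(
            f"mask shape {mask.shape} does not match voxels {curves.voxel_shape}")
    return mask


def adjusted_alpha(alpha: float, correction: str, mask_size: int) -> float:
    """Per-voxel threshold: alpha, or alpha / m under Bonferroni over m voxels."""
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    if correction == "none":
        return alpha
    if correction == "bonferroni":
        return alpha / mask_size
    raise InvalidParameterError("correction must be 'none' or 'bonferroni'")


def significant_fraction(curves: TCurveSet, mask=None, alpha: float = 0.05,
                         correction: str = "none") -> SignificanceCurve:
    """Fraction of mask voxels with one-sided p below the threshold, per NSA.

    Under Bonferroni the family is the mask itself: threshold alpha / m with
    m the mask voxel count.
    """
    mask = _resolve_mask(curves, mask)
    m = int(mask.sum())
    if m == 0:
        raise EmptyMaskError("significant_fraction needs a nonempty mask")
    thr = adjusted_alpha(alpha, correction, m)
    p = one_sided_p(curves.t[mask], curves.nsa_grid)
    frac = (p < thr).sum(axis=0) / m
    return SignificanceCurve(nsa_grid=curves.nsa_grid.copy(), fraction=frac,
                             alpha=alpha, correction=correction, mask_size=m)


def time_to_significance(curves: TCurveSet, alpha: float = 0.05,
                         correction: str = "none", mask=None) -> np.ndarray:
    """Smallest grid NSA at which each voxel first crosses the threshold.

    First crossing, not sustained significance. Returns an integer array of
    the voxel shape with :data:`NEVER` (= -1) where no grid value qualifies;
    voxels outside the mask are also :data:`NEVER`.
    """
    mask = _resolve_mask(curves, mask)
    m = int(mask.sum())
    if m == 0:
        raise EmptyMaskError("time_to_significance needs a nonempty mask")
    thr = adjusted_alpha(alpha, correction, m)
    sig = one_sided_p(curves.t[mask], curves.nsa_grid) < thr
    first = np.argmax(sig, axis=-1)
    ever = sig.any(axis=-1)
    nsa = np.where(ever, curves.nsa_grid[first], NEVER)
    out = np.full(curves.voxel_shape, NEVER, dtype=np.int64)
    out[mask] = nsa
    return out


def find_nonresponders(curves: TCurveSet, mask=None) -> np.ndarray:
    """Mask voxels with t strictly below zero at every grid NSA.

    These are the voxels showing no positive ASL effect at any averaging
    depth. Returns a boolean array of the voxel shape.
    """
    mask = _resolve_mask(curves, mask)
    out = np.zeros(curves.voxel_shape, dtype=bool)
    out[mask] = np.all(curves.t[mask] < 0, axis=-1)
    return out
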