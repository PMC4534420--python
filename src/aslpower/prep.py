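"""Label/control splitting, pairwise subtraction, and scan-time bookkeeping.

The ASL difference is defined as control − label so that a positive ASL
effect yields positive values (and positive t-statistics downstream).
Pairing is strictly adjacent: pair i is formed from volumes (2i, 2i+1),
with the declared acquisition order deciding which of the two is label.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np

from .containers import ASLSeries, DiffSeries
from .exceptions import InvalidParameterError, MalformedSeriesError
from .protocol import Protocol

__all__ = ["split_and_subtract", "scan_time_minutes", "scan_time_minutes_exact",
           "nsa_to_minutes", "total_scan_time_minutes"]


def split_and_subtract(series: ASLSeries, order: str | None = None) -> DiffSeries:
    """Split an interleaved series into label/control and subtract pairwise.

    Parameters
    ----------
    series : ASLSeries
        Interleaved 4D series with an even volume count.
    order : {"label-first", "control-first"}, optional
        Acquisition order; defaults to the order recorded on the series.

    Returns
    -------
    DiffSeries
        control − label per pair, shape ``(x, y, z, n_pairs)``.
    """
    order = order or series.order
    if order not in ("label-first", "control-first"):
        raise InvalidParameterError(
            "order must be 'label-first' or 'control-first'")
    data = series.data
    if data.shape[-1] % 2 != 0:
        raise MalformedSeriesError(
            f"cannot pair an odd number of volumes ({data.shape[-1]})")
    if order == "label-first":
        label, control = data[..., 0::2], data[..., 1::2]
    else:
        control, label = data[..., 0::2], data[..., 1::2]
    return DiffSeries(control - label, series.protocol, series.voxel_size)


def scan_time_minutes(protocol: Protocol) -> float:
    """Total scan time in minutes, truncated to one decimal place.

    ``n_pairs * 2 * TR`` converted to minutes. Truncation (not rounding)
    reproduces the convention of the tabulated protocol times: 400 pairs at
    TR 3500 ms is 46.67 min exact, printed 46.6.
    """
    exact = scan_time_minutes_exact(protocol.n_pairs, protocol)
    return math.floor(exact * 10 + 1e-9) / 10


def scan_time_minutes_exact(nsa: int, protocol: Protocol) -> float:
    """Unrounded scan time in minutes for ``nsa`` label/control pairs."""
    return nsa * 2 * protocol.repetition_time / 60000.0


def nsa_to_minutes(nsa, protocol: Protocol):
    """Map a prefix NSA (or array of them) to elapsed scan time in minutes.

    Unrounded; raises if any value is outside [1, n_pairs].
    """
    arr = np.asarray(nsa)
    if np.any(arr < 1) or np.any(arr > protocol.n_pairs):
        raise InvalidParameterError(
            f"nsa must be in [1, {protocol.n_pairs}]")
    out = arr * 2 * protocol.repetition_time / 60000.0
    return float(out) if out.ndim == 0 else out


def total_scan_time_minutes(protocols: Iterable[Protocol]) -> int:
    """Summed scan time over several protocols, in whole minutes.

    Each protocol's time is truncated to whole minutes before summing —
    the head-count arithmetic used when quoting a session total such as
    (2 x 46) + (2 x 53) = 198 min for four 400-pair runs.
    """
    return int(sum(math.floor(scan_time_minutes_exact(p.n_pairs, p) + 1e-9)
                   for p in protocols))
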