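"""WM segmentation from the SIR volume and the three-way sub-mask split.

A single-inversion-recovery (SIR) acquisition with the inversion timed to
null gray matter leaves WM bright, mixed-tissue voxels intermediate, and
CSF near-nulled, all in perfect register with the ASL series. Segmentation
is therefore intensity banding against a robust maximum (99th percentile of
positive voxels):

* WM:      intensity >= wm_threshold * robust_max
* mixed:   [mixed_exclusion, wm_threshold) * robust_max — excluded
* GM:      [background_threshold, mixed_exclusion) * robust_max, inside the brain
* ventricles: < ventricle_threshold * robust_max, inside the brain

The brain itself is the hole-filled support of the above-background voxels,
so enclosed dark ventricles count as inside.

The full WM mask is split into three disjoint sub-masks whose differential
filling the downstream analysis compares: periventricular (WM within a
one-voxel dilation of the ventricles), peripheral (WM directly bordering
GM), and deep (all remaining WM). A voxel qualifying as both
periventricular and peripheral is assigned periventricular.

"Bordering" and "one voxel outwards in all directions" default to 3D
26-connectivity (diagonals included); 6-connectivity and slice-wise 2D
8-connectivity are available, since 5 mm slices make through-plane
adjacency debatable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .containers import SIRVolume
from .exceptions import EmptyMaskWarning, InvalidParameterError

__all__ = ["MaskConfig", "WMMaskSet", "connectivity_structure", "segment_wm",
           "brain_mask", "ventricle_mask", "gm_mask_from_sir",
           "periventricular_mask", "peripheral_mask", "build_masks"]


def connectivity_structure(connectivity: str = "26") -> np.ndarray:
    """Binary structuring element for the named neighborhood.

    ``"26"``: full 3x3x3 cube; ``"6"``: faces only; ``"2d8"``: in-plane
    3x3 (no through-slice neighbors).
    """
    if connectivity == "26":
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == "6":
        return ndi.generate_binary_structure(3, 1)
    if connectivity == "2d8":
        return np.ones((3, 3, 1), dtype=bool)
    raise InvalidParameterError(
        "connectivity must be one of '26', '6', '2d8'")


@dataclass
class MaskConfig:
    """Thresholds (fractions of the robust maximum) and neighborhood choice."""

    wm_threshold: float = 0.8
    mixed_exclusion: float = 0.3
    ventricle_threshold: float = 0.05
    background_threshold: float = 0.05
    connectivity: str = "26"

    def __post_init__(self) -> None:
        for name in ("wm_threshold", "mixed_exclusion",
                     "ventricle_threshold", "background_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidParameterError(f"{name} must be in (0, 1)")
        if not self.wm_threshold > self.mixed_exclusion:
            raise InvalidParameterError(
                "wm_threshold must exceed mixed_exclusion")
        connectivity_structure(self.connectivity)  # validates


@dataclass
class WMMaskSet:
    """Full WM mask and its disjoint periventricular/peripheral/deep partition."""

    full_wm: np.ndarray
    periventricular: np.ndarray
    peripheral: np.ndarray
    deep: np.ndarray

    def __post_init__(self) -> None:
        pv, pe, dp = self.periventricular, self.peripheral, self.deep
        union = pv | pe | dp
        if not (np.array_equal(union, self.full_wm)
                and not np.any(pv & pe) and not np.any(pv & dp)
                and not np.any(pe & dp)):
            raise InvalidParameterError(
                "sub-masks must partition the full WM mask")

    def counts(self) -> dict[str, int]:
        return {"full": int(self.full_wm.sum()),
                "periventricular": int(self.periventricular.sum()),
                "peripheral": int(self.peripheral.sum()),
                "deep": int(self.deep.sum())}

    def items(self):
        """(name, mask) pairs in a fixed order, full WM first."""
        yield "full", self.full_wm
        yield "periventricular", self.periventricular
        yield "peripheral", self.peripheral
        yield "deep", self.deep


def _sir_data(sir) -> np.ndarray:
    return sir.data if isinstance(sir, SIRVolume) else np.asarray(sir, float)


def robust_max(sir) -> float:
    """99th percentile of the strictly positive voxels (0 if none)."""
    data = _sir_data(sir)
    pos = data[data > 0]
    return float(np.percentile(pos, 99)) if pos.size else 0.0


def segment_wm(sir, wm_threshold: float = 0.8,
               mixed_exclusion: float = 0.3) -> np.ndarray:
    """Threshold the SIR volume into a WM mask, excluding mixed-intensity voxels.

    Warns (:class:`EmptyMaskWarning`) rather than raising when nothing
    qualifies, e.g. on an all-zero volume.
    """
    if not (0 < mixed_exclusion < wm_threshold < 1):
        raise InvalidParameterError(
            "need 0 < mixed_exclusion < wm_threshold < 1")
    data = _sir_data(sir)
    rmax = robust_max(data)
    wm = data >= wm_threshold * rmax if rmax > 0 else np.zeros_like(data, bool)
    if not wm.any():
        warnings.warn("WM segmentation produced an empty mask",
                      EmptyMaskWarning, stacklevel=2)
    return wm


def brain_mask(sir, background_threshold: float = 0.05) -> np.ndarray:
    """Hole-filled support of above-background intensity (ventricles included)."""
    data = _sir_data(sir)
    rmax = robust_max(data)
    if rmax <= 0:
        return np.zeros(data.shape, dtype=bool)
    return ndi.binary_fill_holes(data > background_threshold * rmax)


def ventricle_mask(sir, ventricle_threshold: float = 0.05,
                   brain: np.ndarray | None = None) -> np.ndarray:
    """Low-intensity voxels inside the brain: the ventricle estimate."""
    data = _sir_data(sir)
    if brain is None:
        brain = brain_mask(data)
    rmax = robust_max(data)
    vent = brain & (data < ventricle_threshold * rmax)
    if not vent.any():
        warnings.warn("no ventricle voxels found", EmptyMaskWarning,
                      stacklevel=2)
    return vent


def gm_mask_from_sir(sir, config: MaskConfig | None = None) -> np.ndarray:
    """GM band: inside the brain, above ventricle level, below the mixed band."""
    config = config or MaskConfig()
    data = _sir_data(sir)
    rmax = robust_max(data)
    if rmax <= 0:
        return np.zeros(data.shape, dtype=bool)
    brain = brain_mask(data, config.background_threshold)
    return (brain & (data >= config.background_threshold * rmax)
            & (data < config.mixed_exclusion * rmax))


def periventricular_mask(sir, full_wm: np.ndarray,
                         ventricle_threshold: float = 0.05,
                         connectivity: str = "26",
                         ventricles: np.ndarray | None = None) -> np.ndarray:
    """WM within a one-voxel outward expansion of the ventricles.

    A precomputed (e.g. manual) ventricle mask may be supplied via
    ``ventricles``; otherwise ventricles are estimated from the SIR volume
    by low-intensity thresholding within the brain.
    """
    full_wm = np.asarray(full_wm, dtype=bool)
    if ventricles is None:
        ventricles = ventricle_mask(sir, ventricle_threshold)
    if ventricles.shape != full_wm.shape:
        raise InvalidParameterError("ventricle/WM grids differ")
    grown = ndi.binary_dilation(ventricles,
                                structure=connectivity_structure(connectivity))
    return grown & full_wm


def peripheral_mask(full_wm: np.ndarray, gm: np.ndarray,
                    connectivity: str = "26") -> np.ndarray:
    """WM voxels with at least one GM voxel in the chosen neighborhood."""
    full_wm = np.asarray(full_wm, dtype=bool)
    gm = np.asarray(gm, dtype=bool)
    if gm.shape != full_wm.shape:
        raise InvalidParameterError("GM/WM grids differ")
    near_gm = ndi.binary_dilation(gm,
                                  structure=connectivity_structure(connectivity))
    return full_wm & near_gm


def build_masks(sir, config: MaskConfig | None = None,
                gm: np.ndarray | None = None,
                ventricles: np.ndarray | None = None) -> WMMaskSet:
    """Segment WM and split it into periventricular, peripheral and deep.

    Precedence: periventricular wins over peripheral where both apply, so
    the three sub-masks partition the full WM mask exactly. External GM or
    ventricle masks may be passed in place of the SIR-derived estimates.
    """
    config = config or MaskConfig()
    full_wm = segment_wm(sir, config.wm_threshold, config.mixed_exclusion)
    if gm is None:
        gm = gm_mask_from_sir(sir, config)
    pv = periventricular_mask(sir, full_wm, config.ventricle_threshold,
                              config.connectivity, ventricles=ventricles)
    pe = peripheral_mask(full_wm, gm, config.connectivity) & ~pv
    deep = full_wm & ~pv & ~pe
    return WMMaskSet(full_wm=full_wm, periventricular=pv, peripheral=pe,
                     deep=deep)
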