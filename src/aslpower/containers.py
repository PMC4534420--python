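"""In-memory containers for volumes and time series, with NIfTI-1 I/O.

Arrays are indexed ``(x, y, z)`` with an optional trailing time axis; voxel
size is carried as a millimetre triple and becomes the diagonal of the NIfTI
affine. Ground-truth tissue maps additionally carry per-voxel CBF, arterial
transit time and a responder flag, and round-trip through a set of NIfTI
volumes plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import DimensionError, InvalidParameterError
from .protocol import Protocol

__all__ = [
    "ASLSeries", "SIRVolume", "DiffSeries", "TissueMap",
    "BACKGROUND", "GM", "WM", "CSF", "MIXED", "TISSUE_NAMES",
]

# tissue class codes used throughout the package
BACKGROUND, GM, WM, CSF, MIXED = 0, 1, 2, 3, 4
TISSUE_NAMES = {BACKGROUND: "background", GM: "GM", WM: "WM",
                CSF: "CSF", MIXED: "mixed"}

DEFAULT_VOXEL_SIZE = (3.75, 3.75, 5.0)  # mm, the study's EPI resolution


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def _check_finite(data: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(data)):
        raise InvalidParameterError(f"{what} contains non-finite values")


@dataclass
class ASLSeries:
    """4D interleaved label/control series, ``data.shape = (x, y, z, 2 * n_pairs)``.

    ``order`` records whether even time indices hold label ("label-first")
    or control ("control-first") volumes.
    """

    data: np.ndarray
    protocol: Protocol
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    order: str = "label-first"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise DimensionError("ASLSeries data must be 4D (x, y, z, t)")
        if self.data.shape[-1] != 2 * self.protocol.n_pairs:
            raise DimensionError(
                f"expected {2 * self.protocol.n_pairs} volumes "
                f"(2 x n_pairs), got {self.data.shape[-1]}")
        if self.order not in ("label-first", "control-first"):
            raise InvalidParameterError(
                "order must be 'label-first' or 'control-first'")
        _check_finite(self.data, "ASLSeries")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32),
                                 _affine(self.voxel_size)), str(path))

    @classmethod
    def load(cls, path: str | Path, protocol: Protocol,
             order: str = "label-first") -> "ASLSeries":
        img = nib.load(str(path))
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), protocol, vs, order)


@dataclass
class SIRVolume:
    """Single-inversion-recovery volume on the ASL grid (GM suppressed, WM bright)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionError("SIRVolume data must be 3D")
        _check_finite(self.data, "SIRVolume")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32),
                                 _affine(self.voxel_size)), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "SIRVolume":
        img = nib.load(str(path))
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), vs)


@dataclass
class DiffSeries:
    """Per-voxel ordered control − label differences, shape ``(x, y, z, n_pairs)``."""

    data: np.ndarray
    protocol: Protocol
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise DimensionError("DiffSeries data must be 4D (x, y, z, pairs)")
        if self.data.shape[-1] != self.protocol.n_pairs:
            raise DimensionError(
                f"expected {self.protocol.n_pairs} pairs, got {self.data.shape[-1]}")
        _check_finite(self.data, "DiffSeries")

    @property
    def n_pairs(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32),
                                 _affine(self.voxel_size)), str(path))

    @classmethod
    def load(cls, path: str | Path, protocol: Protocol) -> "DiffSeries":
        img = nib.load(str(path))
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), protocol, vs)


@dataclass
class TissueMap:
    """Per-voxel simulation ground truth.

    Attributes
    ----------
    tissue_class : int array (x, y, z)
        Codes ``BACKGROUND=0, GM=1, WM=2, CSF=3, MIXED=4``.
    cbf : float array (x, y, z)
        Perfusion in mL/100g/min, >= 0.
    transit_time : float array (x, y, z)
        Arterial transit time in ms, >= 0.
    responder : bool array (x, y, z)
        False for voxels whose expected ASL difference is <= 0 at any NSA.
    """

    tissue_class: np.ndarray
    cbf: np.ndarray
    transit_time: np.ndarray
    responder: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tissue_class = np.asarray(self.tissue_class, dtype=np.int16)
        self.cbf = np.asarray(self.cbf, dtype=np.float64)
        self.transit_time = np.asarray(self.transit_time, dtype=np.float64)
        self.responder = np.asarray(self.responder, dtype=bool)
        shape = self.tissue_class.shape
        if len(shape) != 3:
            raise DimensionError("TissueMap arrays must be 3D")
        for name in ("cbf", "transit_time", "responder"):
            if getattr(self, name).shape != shape:
                raise DimensionError(f"TissueMap field {name} has shape "
                                     f"{getattr(self, name).shape}, expected {shape}")
        if np.any(self.cbf < 0):
            raise InvalidParameterError("cbf must be >= 0 everywhere")
        if np.any(self.transit_time < 0):
            raise InvalidParameterError("transit_time must be >= 0 everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tissue_class.shape

    def class_mask(self, code: int) -> np.ndarray:
        return self.tissue_class == code

    @property
    def wm_mask(self) -> np.ndarray:
        return self.class_mask(WM)

    @property
    def gm_mask(self) -> np.ndarray:
        return self.class_mask(GM)

    @property
    def csf_mask(self) -> np.ndarray:
        return self.class_mask(CSF)

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>_class/cbf/att/responder.nii.gz`` and ``<prefix>_meta.json``."""
        prefix = str(prefix)
        aff = _affine(self.voxel_size)
        nib.save(nib.Nifti1Image(self.tissue_class.astype(np.int16), aff),
                 prefix + "_class.nii.gz")
        nib.save(nib.Nifti1Image(self.cbf.astype(np.float32), aff),
                 prefix + "_cbf.nii.gz")
        nib.save(nib.Nifti1Image(self.transit_time.astype(np.float32), aff),
                 prefix + "_att.nii.gz")
        nib.save(nib.Nifti1Image(self.responder.astype(np.uint8), aff),
                 prefix + "_responder.nii.gz")
        with open(prefix + "_meta.json", "w") as fh:
            json.dump({"voxel_size": list(self.voxel_size), **self.meta},
                      fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, prefix: str | Path) -> "TissueMap":
        prefix = str(prefix)
        imgs = {k: nib.load(prefix + f"_{k}.nii.gz")
                for k in ("class", "cbf", "att", "responder")}
        with open(prefix + "_meta.json") as fh:
            meta = json.load(fh)
        vs = tuple(meta.pop("voxel_size"))
        return cls(np.asanyarray(imgs["class"].dataobj),
                   np.asanyarray(imgs["cbf"].dataobj),
                   np.asanyarray(imgs["att"].dataobj),
                   np.asanyarray(imgs["responder"].dataobj).astype(bool),
                   vs, meta)


def save_mask(mask: np.ndarray, voxel_size: tuple[float, float, float],
              path: str | Path) -> None:
    """Write a boolean mask as a 0/1 NIfTI volume."""
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.uint8),
                             _affine(voxel_size)), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a 0/1 NIfTI volume back as a boolean array."""
    return np.asanyarray(nib.load(str(path)).dataobj) > 0
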