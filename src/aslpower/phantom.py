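"""Digital head phantom for background-suppressed PCASL simulation.

The phantom is a concentric-layer geometry on an 8-slice grid matching the
partial-brain acquisition: an elliptical head cross-section with a GM shell,
a WM core, a ventricle-like CSF block in the central slices, and a sparse
mixed-tissue layer at the GM/WM interface. It is deliberately not an
anatomical atlas — the point is analytic ground truth for every downstream
stage (segmentation, sub-masking, per-voxel testing), not realism.

Per-voxel CBF and arterial transit time are drawn from tissue-specific
normal distributions (truncated at zero). WM perfusion is 2-4x below GM
and WM transit times are prolonged, the two physiological facts that make
voxel-wise WM ASL hard. A configurable fraction of WM voxels is flagged as
non-responders: voxels with no positive ASL effect at any NSA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from .containers import (BACKGROUND, GM, WM, CSF, MIXED, TissueMap,
                         DEFAULT_VOXEL_SIZE)
from .exceptions import InvalidParameterError

__all__ = ["PhantomConfig", "sample_tissue_map", "null_tissue_map"]


@dataclass
class PhantomConfig:
    """Generator settings for :func:`sample_tissue_map`.

    CBF means/sds in mL/100g/min; transit times in ms. The WM CBF mean must
    lie between 1/4 and 1/2 of the GM mean (the physiological range the
    simulation is built to emulate).
    """

    shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    gm_cbf_mean: float = 60.0
    gm_cbf_sd: float = 6.0
    wm_cbf_mean: float = 20.0
    wm_cbf_sd: float = 4.0
    mixed_cbf_mean: float = 40.0
    mixed_cbf_sd: float = 6.0

    gm_att_mean: float = 900.0
    gm_att_sd: float = 100.0
    wm_att_mean: float = 1500.0
    wm_att_sd: float = 150.0
    mixed_att_mean: float = 1200.0
    mixed_att_sd: float = 150.0

    non_responder_fraction: float = 0.06
    #: fraction of GM/WM interface WM voxels relabeled as mixed tissue
    mixed_interface_fraction: float = 0.3

    # geometry, as fractions of the in-plane extent
    head_radius_frac: float = 0.45
    wm_radius_frac: float = 0.74       # of head radius
    ventricle_halfwidth: tuple[int, int] = (2, 3)   # voxels in x, y
    ventricle_slices: tuple[int, int] = (2, 6)      # z range [lo, hi)

    def __post_init__(self) -> None:
        if not 0 <= self.non_responder_fraction <= 1:
            raise InvalidParameterError(
                "non_responder_fraction must be in [0, 1]")
        if not 0 <= self.mixed_interface_fraction <= 1:
            raise InvalidParameterError(
                "mixed_interface_fraction must be in [0, 1]")
        if not (self.gm_cbf_mean / 4 <= self.wm_cbf_mean
                <= self.gm_cbf_mean / 2):
            raise InvalidParameterError(
                "wm_cbf_mean must lie in [gm_cbf_mean/4, gm_cbf_mean/2]")
        if any(s <= 0 for s in self.shape):
            raise InvalidParameterError("shape must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


def _layer_labels(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Tissue class volume: ellipse head, GM shell, WM core, CSF block, sparse mixed."""
    nx, ny, nz = cfg.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rx = cfg.head_radius_frac * nx
    ry = cfg.head_radius_frac * ny
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    r = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2)

    sl = np.full((nx, ny), BACKGROUND, dtype=np.int16)
    sl[r <= 1.0] = GM
    sl[r <= cfg.wm_radius_frac] = WM
    labels = np.repeat(sl[:, :, None], nz, axis=2)

    # ventricle-like CSF block in the central slices, inside WM
    hx, hy = cfg.ventricle_halfwidth
    zlo, zhi = cfg.ventricle_slices
    zhi = min(zhi, nz)
    xlo, xhi = int(round(cx)) - hx, int(round(cx)) + hx + 1
    ylo, yhi = int(round(cy)) - hy, int(round(cy)) + hy + 1
    if zlo < zhi:
        block = labels[xlo:xhi, ylo:yhi, zlo:zhi]
        block[block == WM] = CSF

    # sparse mixed-tissue voxels at the GM/WM interface; the rest of the
    # interface keeps direct WM-GM contact so a peripheral sub-mask exists
    gm_mask = labels == GM
    interface = (labels == WM) & ndi.binary_dilation(
        gm_mask, structure=np.ones((3, 3, 3), bool))
    idx = np.flatnonzero(interface.ravel())
    n_mixed = int(round(cfg.mixed_interface_fraction * idx.size))
    if n_mixed:
        chosen = rng.choice(idx, size=n_mixed, replace=False)
        labels.ravel()[chosen] = MIXED
    return labels


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size), 0.0, None)


def sample_tissue_map(shape: tuple[int, int, int] | None = None,
                      config: PhantomConfig | None = None,
                      seed: int = 0) -> TissueMap:
    """Draw a layered phantom with per-voxel CBF, transit time and responder flags.

    Deterministic given ``seed``: a single :class:`numpy.random.Generator`
    stream is consumed in a fixed order (interface relabeling, CBF per
    tissue class, transit time per class, non-responder selection).

    Exactly ``round(non_responder_fraction * n_wm)`` WM voxels are flagged
    ``responder = False``.
    """
    config = config or PhantomConfig()
    if shape is not None and tuple(shape) != tuple(config.shape):
        config = PhantomConfig(**{**config.as_dict(), "shape": tuple(shape)})

    rng = np.random.default_rng(seed)
    labels = _layer_labels(config, rng)

    cbf = np.zeros(config.shape, dtype=np.float64)
    att = np.zeros(config.shape, dtype=np.float64)
    for code, (cm, cs, am, asd) in {
            GM: (config.gm_cbf_mean, config.gm_cbf_sd,
                 config.gm_att_mean, config.gm_att_sd),
            WM: (config.wm_cbf_mean, config.wm_cbf_sd,
                 config.wm_att_mean, config.wm_att_sd),
            MIXED: (config.mixed_cbf_mean, config.mixed_cbf_sd,
                    config.mixed_att_mean, config.mixed_att_sd),
    }.items():
        m = labels == code
        n = int(m.sum())
        cbf[m] = _truncated_normal(rng, cm, cs, n)
        att[m] = _truncated_normal(rng, am, asd, n)

    responder = np.ones(config.shape, dtype=bool)
    wm_idx = np.flatnonzero((labels == WM).ravel())
    n_nr = int(round(config.non_responder_fraction * wm_idx.size))
    if n_nr:
        chosen = rng.choice(wm_idx, size=n_nr, replace=False)
        responder.ravel()[chosen] = False

    return TissueMap(labels, cbf, att, responder, config.voxel_size,
                     meta={"seed": seed, "generator": config.as_dict()})


def null_tissue_map(shape: tuple[int, int, int] = (36, 36, 8),
                    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
                    ) -> TissueMap:
    """All-WM phantom with zero CBF everywhere: the null condition.

    Every voxel has zero true ASL effect, so the simulated difference series
    is pure noise — the input for calibrating the false-positive rate of the
    one-tailed paired t-test.
    """
    labels = np.full(shape, WM, dtype=np.int16)
    zeros = np.zeros(shape, dtype=np.float64)
    return TissueMap(labels, zeros, zeros.copy(),
                     np.ones(shape, dtype=bool), voxel_size,
                     meta={"null": True})
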