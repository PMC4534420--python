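"""Forward simulation of background-suppressed PCASL label/control series.

The expected ASL difference signal per voxel comes from the standard
single-compartment continuous-labeling kinetic model: a bolus of labeled
blood water of duration tau (the labeling duration) arrives after the
arterial transit time delta and decays with the T1 of blood throughout.
With readout at t = LD + PLD measured from the start of labeling, effective
labeling efficiency eps (labeling x background-suppression efficiency),
partition coefficient lambda and equilibrium magnetization M0:

    dM(t) = 0                                                    t <= delta
    dM(t) = A * exp(-delta/T1b) * (1 - exp(-(t - delta)/T1b))    delta < t <= delta + tau
    dM(t) = A * exp(-delta/T1b) * (1 - exp(-tau/T1b))
              * exp(-(t - delta - tau)/T1b)                      t > delta + tau

with A = 2 * eps * M0 * (f / lambda) * (T1b / 60000) and f the perfusion in
mL/100g/min (the 60000 converts per-minute flow to the millisecond clock).
The model is continuous in t and nonnegative.

Control volumes carry a residual static signal that grows with slice index,
mimicking progressively incomplete background suppression in an ascending
2D readout; label volumes carry the same static signal minus dM. Both get
independent Gaussian noise. Non-responder voxels replace dM by a draw that
is <= 0 (half-normal reflected to the nonpositive axis), so they show no
positive ASL effect at any averaging depth.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .containers import (ASLSeries, SIRVolume, TissueMap,
                         BACKGROUND, GM, WM, CSF, MIXED)
from .exceptions import InvalidParameterError
from .protocol import KineticParams, Protocol

__all__ = ["NoiseConfig", "kinetic_delta_m", "simulate_series"]


@dataclass
class NoiseConfig:
    """Noise and static-signal settings for :func:`simulate_series`.

    ``noise_sd`` is the per-volume Gaussian noise sd in signal units (the
    difference series then has sd ``noise_sd * sqrt(2)``). The static
    residual in slice z is ``static_base + static_slice_gain * z``.
    ``nonresponder_scale`` is the half-normal scale of the (nonpositive)
    expected difference assigned to non-responder voxels; 0 means exactly
    no effect. SIR intensities are per tissue class, WM brightest.
    """

    noise_sd: float = 40.0
    static_base: float = 20.0
    static_slice_gain: float = 2.0
    nonresponder_scale: float = 0.0
    sir_levels: dict[int, float] | None = None
    sir_noise_sd: float = 10.0
    sir_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.sir_noise_sd < 0:
            raise InvalidParameterError("noise sds must be >= 0")
        if self.nonresponder_scale < 0:
            raise InvalidParameterError("nonresponder_scale must be >= 0")
        if self.sir_levels is None:
            # fractions of sir_scale: GM strongly suppressed, WM bright,
            # mixed intermediate, CSF near-nulled at this inversion time
            self.sir_levels = {BACKGROUND: 0.0, GM: 0.10, WM: 1.0,
                               CSF: 0.02, MIXED: 0.5}

    def as_dict(self) -> dict:
        d = asdict(self)
        d["sir_levels"] = {int(k): v for k, v in self.sir_levels.items()}
        return d


def kinetic_delta_m(cbf, transit_time, protocol: Protocol,
                    kp: KineticParams | None = None):
    """Expected ASL difference signal for given perfusion and transit time.

    Parameters
    ----------
    cbf : float or array
        Perfusion f in mL/100g/min, >= 0.
    transit_time : float or array
        Arterial transit time delta in ms, >= 0.
    protocol : Protocol
        Supplies labeling duration tau and readout time t = LD + PLD.
    kp : KineticParams, optional
        Kinetic constants; defaults are the standard 3T values.

    Returns
    -------
    float or ndarray — dM in the (arbitrary) units of ``kp.equilibrium_magnetization``.
    """
    kp = kp or KineticParams()
    cbf = np.asarray(cbf, dtype=np.float64)
    delta = np.asarray(transit_time, dtype=np.float64)
    if np.any(cbf < 0):
        raise InvalidParameterError("cbf must be >= 0")
    if np.any(delta < 0):
        raise InvalidParameterError("transit_time must be >= 0")

    t = protocol.readout_time
    tau = protocol.label_duration
    t1b = kp.t1_blood
    eps = kp.labeling_efficiency * kp.bs_efficiency
    amp = (2.0 * eps * kp.equilibrium_magnetization
           * (cbf / kp.blood_brain_partition) * (t1b / 60000.0))

    decay = np.exp(-delta / t1b)
    during = 1.0 - np.exp(-np.maximum(t - delta, 0.0) / t1b)
    after = ((1.0 - np.exp(-tau / t1b))
             * np.exp(-np.maximum(t - delta - tau, 0.0) / t1b))

    dm = np.where(t <= delta, 0.0,
                  np.where(t <= delta + tau, amp * decay * during,
                           amp * decay * after))
    return dm if dm.ndim else float(dm)


def simulate_series(tmap: TissueMap, protocol: Protocol,
                    kp: KineticParams | None = None,
                    noise: NoiseConfig | None = None,
                    seed: int = 0) -> tuple[ASLSeries, SIRVolume]:
    """Simulate an interleaved label/control series and a co-registered SIR volume.

    Deterministic given ``seed``; a single generator stream is consumed in
    the order: non-responder effect draws, control noise, label noise, SIR
    noise. Noise arrays are always drawn (and scaled, possibly by zero) so
    the stream position is independent of the noise settings.

    Returns
    -------
    (ASLSeries, SIRVolume)
        Series ordered label-first, ``2 * protocol.n_pairs`` volumes.
    """
    kp = kp or KineticParams()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    shape = tmap.shape
    n = protocol.n_pairs

    dm = np.asarray(kinetic_delta_m(tmap.cbf, tmap.transit_time, protocol, kp))
    nonresp = ~tmap.responder
    if np.any(nonresp):
        draws = -np.abs(rng.normal(0.0, 1.0, int(nonresp.sum())))
        dm[nonresp] = (noise.nonresponder_scale * draws
                       if noise.nonresponder_scale > 0 else 0.0)

    z = np.arange(shape[2], dtype=np.float64)
    static = np.zeros(shape)
    static += noise.static_base + noise.static_slice_gain * z[None, None, :]
    static[tmap.tissue_class == BACKGROUND] = 0.0

    noise_c = rng.standard_normal(shape + (n,))
    noise_l = rng.standard_normal(shape + (n,))
    control = static[..., None] + noise.noise_sd * noise_c
    label = (static - dm)[..., None] + noise.noise_sd * noise_l

    data = np.empty(shape + (2 * n,), dtype=np.float64)
    data[..., 0::2] = label
    data[..., 1::2] = control
    series = ASLSeries(data, protocol, tmap.voxel_size, order="label-first")

    sir = np.zeros(shape)
    for code, level in noise.sir_levels.items():
        sir[tmap.tissue_class == code] = level * noise.sir_scale
    sir = sir + noise.sir_noise_sd * rng.standard_normal(shape)
    return series, SIRVolume(sir, tmap.voxel_size)
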