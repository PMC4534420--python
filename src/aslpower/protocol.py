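"""PCASL acquisition protocols.

A :class:`Protocol` bundles the labeling timing of one background-suppressed
PCASL acquisition scheme: labeling duration (LD), post-labeling delay (PLD),
repetition time (TR), the two background-suppression (BS) inversion pulse
times, and the number of label/control pairs acquired (NSA).

Four named presets (``exp1`` .. ``exp4``) cover the labeling schemes of the
underlying study design: LD/PLD of 1650/1500, 1650/2000, 2150/1500 and
2150/1000 ms, with TR 3500 or 4000 ms and 400 pairs each.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .exceptions import InvalidParameterError

__all__ = ["Protocol", "KineticParams", "PROTOCOLS", "get_protocol"]


@dataclass(frozen=True)
class Protocol:
    """One PCASL acquisition scheme. All times in milliseconds.

    Parameters
    ----------
    label_duration : float
        Labeling duration LD (ms), the length of the RF labeling train.
    post_label_delay : float
        Post-labeling delay PLD (ms) between end of labeling and readout.
    repetition_time : float
        TR (ms) of a single (label or control) volume.
    bs1_time, bs2_time : float
        Background-suppression inversion pulse times (ms after start of the
        labeling module); must satisfy bs1 < bs2 < LD + PLD.
    n_pairs : int
        Number of label/control pairs (NSA).
    """

    label_duration: float
    post_label_delay: float
    repetition_time: float
    bs1_time: float
    bs2_time: float
    n_pairs: int = 400

    def __post_init__(self) -> None:
        for name in ("label_duration", "post_label_delay", "repetition_time",
                     "bs1_time", "bs2_time"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not (self.bs1_time < self.bs2_time
                < self.label_duration + self.post_label_delay):
            raise InvalidParameterError(
                "BS pulse times must satisfy bs1 < bs2 < LD + PLD "
                f"(got {self.bs1_time}, {self.bs2_time}, "
                f"{self.label_duration + self.post_label_delay})")
        if not (isinstance(self.n_pairs, (int,)) and self.n_pairs >= 1):
            raise InvalidParameterError("n_pairs must be an integer >= 1")

    @property
    def readout_time(self) -> float:
        """Time of readout measured from the start of labeling: LD + PLD (ms)."""
        return self.label_duration + self.post_label_delay

    def with_pairs(self, n_pairs: int) -> "Protocol":
        """Copy of this protocol with a different NSA."""
        return replace(self, n_pairs=n_pairs)


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the single-compartment PCASL signal model.

    Defaults are the community-standard 3T values: blood T1 1650 ms,
    labeling efficiency 0.85, combined background-suppression efficiency
    0.75, blood-brain partition coefficient 0.9 mL/g. The equilibrium
    magnetization sets the (arbitrary) signal scale.
    """

    t1_blood: float = 1650.0            # ms
    labeling_efficiency: float = 0.85   # fraction
    bs_efficiency: float = 0.75         # fraction
    blood_brain_partition: float = 0.9  # mL/g
    equilibrium_magnetization: float = 100.0  # arbitrary signal units

    def __post_init__(self) -> None:
        if not self.t1_blood > 0:
            raise InvalidParameterError("t1_blood must be > 0")
        for name in ("labeling_efficiency", "bs_efficiency"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidParameterError(f"{name} must be in (0, 1]")
        if not self.blood_brain_partition > 0:
            raise InvalidParameterError("blood_brain_partition must be > 0")


#: The four acquisition schemes evaluated by the study design, keyed by name.
PROTOCOLS: dict[str, Protocol] = {
    "exp1": Protocol(1650, 1500, 3500, 1672, 2803, 400),
    "exp2": Protocol(1650, 2000, 4000, 1671, 3164, 400),
    "exp3": Protocol(2150, 1500, 4000, 2390, 3366, 400),
    "exp4": Protocol(2150, 1000, 3500, 2261, 2989, 400),
}


def get_protocol(name: str) -> Protocol:
    """Look up a preset protocol by name (``exp1`` .. ``exp4``)."""
    try:
        return PROTOCOLS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOLS)}") from None
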