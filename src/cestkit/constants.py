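"""Physical constants and saturation-scheme bookkeeping.

Everything downstream works in ppm relative to the water resonance; this
module owns the ppm <-> Hz conversion for a given static field, the
continuous-wave power-equivalent (CWPE) B1 summary of a pulsed saturation
train, and construction of the saturation offset schedule used by the
prostate protocol (0.25-ppm spacing across +/-5 ppm plus sparse outer
samples out to +/-300 ppm for characterising the semisolid MT pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "FieldConstants",
    "PulseTrain",
    "OffsetSchedule",
    "ppm_to_hz",
    "hz_to_ppm",
    "b1_cwpe",
    "total_saturation_time",
    "build_protocol_offset_schedule",
]

#: gyromagnetic ratio of 1H divided by 2*pi, MHz/T
GAMMA_BAR_MHZ_PER_T = 42.577


@dataclass(frozen=True)
class FieldConstants:
    """Static-field constants tying ppm offsets to absolute frequencies.

    Attributes
    ----------
    gamma_bar : float
        Reduced gyromagnetic ratio of 1H (gamma / 2 pi), MHz/T.
    field_strength : float
        Static field B0, tesla.
    """

    gamma_bar: float = GAMMA_BAR_MHZ_PER_T
    field_strength: float = 3.0

    def __post_init__(self) -> None:
        if not (self.gamma_bar > 0 and np.isfinite(self.gamma_bar)):
            raise ValueError(f"gamma_bar must be positive and finite, got {self.gamma_bar}")
        if not (self.field_strength > 0 and np.isfinite(self.field_strength)):
            raise ValueError(
                f"field_strength must be positive and finite, got {self.field_strength}"
            )

    @property
    def larmor_mhz(self) -> float:
        """Proton Larmor frequency in MHz (equals Hz per ppm)."""
        return self.gamma_bar * self.field_strength


@dataclass(frozen=True)
class PulseTrain:
    """Pulsed saturation train: N pulses of duration tp separated by delay td.

    flip_deg is the per-pulse rotation in degrees; shape_label is free text
    (the CWPE summary below does not depend on the pulse waveform).
    """

    shape_label: str = "sinc-Gaussian"
    flip_deg: float = 1133.0
    tp_ms: float = 40.0
    td_ms: float = 40.0
    n_pulses: int = 60

    def __post_init__(self) -> None:
        if not self.flip_deg > 0:
            raise ValueError(f"flip_deg must be > 0, got {self.flip_deg}")
        if not self.tp_ms > 0:
            raise ValueError(f"tp_ms must be > 0, got {self.tp_ms}")
        if self.td_ms < 0:
            raise ValueError(f"td_ms must be >= 0, got {self.td_ms}")
        if self.n_pulses < 1:
            raise ValueError(f"n_pulses must be >= 1, got {self.n_pulses}")

    @property
    def duty_cycle(self) -> float:
        return self.tp_ms / (self.tp_ms + self.td_ms)


@dataclass(frozen=True)
class OffsetSchedule:
    """Ordered list of saturation offsets (ppm) plus a reference-image flag."""

    offsets_ppm: tuple[float, ...]
    has_reference: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets_ppm, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("all offsets must be finite")
        if len(np.unique(arr)) != arr.size:
            raise ValueError("offsets must be unique")
        object.__setattr__(self, "offsets_ppm", tuple(float(x) for x in arr))

    def __len__(self) -> int:
        return len(self.offsets_ppm)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.offsets_ppm, dtype=float)

    def sorted(self) -> "OffsetSchedule":
        """Schedule with offsets in ascending ppm order."""
        return OffsetSchedule(tuple(sorted(self.offsets_ppm)), self.has_reference)


def ppm_to_hz(offset_ppm, constants: FieldConstants = FieldConstants()):
    """Convert a chemical-shift offset in ppm to Hz at the given field.

    One ppm corresponds to one millionth of the Larmor frequency, so the
    Hz-per-ppm factor numerically equals the Larmor frequency in MHz
    (127.731 Hz/ppm at 3.0 T).
    """
    arr = np.asarray(offset_ppm, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"offset_ppm must be finite, got {offset_ppm}")
    out = arr * constants.larmor_mhz
    return float(out) if np.isscalar(offset_ppm) or out.ndim == 0 else out


def hz_to_ppm(offset_hz, constants: FieldConstants = FieldConstants()):
    """Inverse of :func:`ppm_to_hz`."""
    arr = np.asarray(offset_hz, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"offset_hz must be finite, got {offset_hz}")
    out = arr / constants.larmor_mhz
    return float(out) if np.isscalar(offset_hz) or out.ndim == 0 else out


def b1_cwpe(train: PulseTrain, constants: FieldConstants = FieldConstants()) -> float:
    """Continuous-wave power-equivalent B1 of a saturation train, in uT.

    Uses the time-averaged-rotation definition: the constant field that
    accumulates the same total rotation over the same total time,

        B1_CWPE = (flip in cycles) / (gamma_bar * per-pulse period),

    where the per-pulse period is tp + td for a train and just tp for a
    single continuous pulse (td = 0 counts the full rotation against the
    pulse duration only when there is no delay to average over).
    """
    period_s = (train.tp_ms + train.td_ms) * 1e-3
    cycles = train.flip_deg / 360.0
    gamma_bar_hz_per_t = constants.gamma_bar * 1e6
    b1_tesla = cycles / (gamma_bar_hz_per_t * period_s)
    return b1_tesla * 1e6


def total_saturation_time(train: PulseTrain) -> float:
    """Total duration of the saturation train in seconds: N * (tp + td)."""
    return train.n_pulses * (train.tp_ms + train.td_ms) * 1e-3


# outer offsets sampled beyond the dense +/-5 ppm grid (ppm, positive side)
_OUTER_PPM = (5.5, 6.0, 6.5, 7.0, 7.5, 10.0, 15.0, 20.0, 25.0, 30.0, 100.0, 300.0)


def build_protocol_offset_schedule() -> OffsetSchedule:
    """Saturation schedule of the optimized prostate protocol.

    0.25-ppm steps across [-5, +5] ppm (41 points) plus symmetric outer
    samples at +/-{5.5, 6, 6.5, 7, 7.5, 10, 15, 20, 25, 30, 100, 300} ppm
    (24 points) -> 65 saturated offsets, with an unsaturated reference image.
    Offsets are stored in descending absolute-value order (outermost first);
    downstream code never depends on acquisition order.
    """
    inner = np.round(np.arange(-20, 21) * 0.25, 10)
    outer = [s * o for o in _OUTER_PPM for s in (+1.0, -1.0)]
    allofs = sorted(set(outer) | set(inner.tolist()), key=lambda x: (-abs(x), -x))
    return OffsetSchedule(tuple(allofs), has_reference=True)


def schedule_to_csv(schedule: OffsetSchedule, path) -> None:
    """Write a schedule as a one-column CSV of ppm values (optional 'ref' row)."""
    with open(path, "w") as fh:
        fh.write("offset_ppm\n")
        if schedule.has_reference:
            fh.write("ref\n")
        for o in schedule.offsets_ppm:
            fh.write(f"{o:.6g}\n")


def schedule_from_csv(path) -> OffsetSchedule:
    """Read a schedule written by :func:`schedule_to_csv`."""
    offsets: list[float] = []
    has_ref = False
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if not tok or tok.lower() == "offset_ppm":
                continue
            if tok.lower() == "ref":
                has_ref = True
                continue
            offsets.append(float(tok))
    return OffsetSchedule(tuple(offsets), has_reference=has_ref)
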