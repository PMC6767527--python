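"""WASABI B0 mapping and voxelwise B0 correction of z-spectra.

WASABI (water shift and B1) acquires a short off-resonant block pulse at
~20 offsets within +/-3 ppm; the resulting signal shows a Rabi oscillation
pattern whose phase encodes the water frequency shift (delta B0) and whose
period encodes B1.  The signal model is

    S(f) = | c - d * sin^2(arctan(gb1 / (f - fd))) *
                   sin^2(pi * tp * sqrt(gb1^2 + (f - fd)^2)) |

with all frequencies in Hz: f the saturation offset, fd the water shift,
gb1 = gamma_bar * B1 the Rabi frequency, tp the pulse duration in seconds,
and c, d dimensionless baseline/depth parameters.  Only the fitted shift
feeds the pipeline; B1, c, d are retained for quality control.

B0 correction interpolates each voxel's z-spectrum onto a 1-Hz grid over
the densely sampled inner region, shifts it by the negative fitted water
shift, and resamples at the nominal offsets.  Sparse outer offsets
(|w| >= 5.5 ppm) are left in place: the shift is far below their spacing,
so nearest-sample assignment is the identity there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .constants import FieldConstants
from .volume import ZSpectrumVolume

__all__ = [
    "WasabiFitResult",
    "B0Map",
    "wasabi_model",
    "fit_wasabi_voxel",
    "fit_b0_map",
    "correct_b0",
]


@dataclass(frozen=True)
class WasabiFitResult:
    """Per-voxel WASABI fit: water shift (ppm), B1 (uT), baseline c, depth d, RSS."""

    delta_b0_ppm: float
    b1_ut: float
    c: float
    d: float
    rss: float


@dataclass
class B0Map:
    """Per-voxel water frequency shift (ppm) with a validity mask."""

    delta_b0_ppm: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.delta_b0_ppm = np.asarray(self.delta_b0_ppm, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.delta_b0_ppm.shape != self.mask.shape:
            raise ValueError("delta map and mask shapes differ")
        if not np.all(np.isfinite(self.delta_b0_ppm[self.mask])):
            raise ValueError("non-finite B0 values inside mask")


def wasabi_model(
    offset_ppm,
    delta_b0_ppm: float,
    b1_ut: float,
    c: float,
    d: float,
    tp_s: float,
    constants: FieldConstants = FieldConstants(),
):
    """Evaluate the WASABI Rabi-oscillation signal model at offset(s) in ppm.

    The on-resonance limit is handled exactly: sin^2(arctan(x)) is computed
    as x^2/(1+x^2) = gb1^2/(gb1^2 + (f-fd)^2), which tends to 1 as f -> fd.
    """
    if not tp_s > 0:
        raise ValueError(f"tp_s must be > 0, got {tp_s}")
    f = np.asarray(offset_ppm, dtype=float) * constants.larmor_mhz  # Hz
    fd = delta_b0_ppm * constants.larmor_mhz
    gb1 = constants.gamma_bar * b1_ut  # Hz (MHz/T * uT = Hz)
    df2 = (f - fd) ** 2
    envelope = gb1**2 / (gb1**2 + df2)
    rabi = np.sin(np.pi * tp_s * np.sqrt(gb1**2 + df2)) ** 2
    out = np.abs(c - d * envelope * rabi)
    return float(out) if out.ndim == 0 else out


def fit_wasabi_voxel(
    signal,
    offsets_ppm,
    tp_s: float = 0.005,
    nominal_b1_ut: float = 3.7,
    constants: FieldConstants = FieldConstants(),
    delta_bounds_ppm: tuple[float, float] = (-1.0, 1.0),
    b1_fraction: float = 0.5,
    delta_starts_ppm: tuple[float, ...] = (-0.8, -0.4, 0.0, 0.4, 0.8),
) -> WasabiFitResult:
    """Bounded least-squares WASABI fit of (delta, B1, c, d) for one voxel.

    The oscillatory model has aliasing-prone local minima in delta, so the
    fit multistarts over a small delta grid and keeps the lowest-RSS
    solution.  Raises ValueError for unusable voxels (fewer than 8 finite
    samples, or an all-constant signal).
    """
    sig = np.asarray(signal, dtype=float)
    offs = np.asarray(offsets_ppm, dtype=float)
    finite = np.isfinite(sig)
    if finite.sum() < 8:
        raise ValueError(f"need >= 8 finite samples, got {int(finite.sum())}")
    sig, offs = sig[finite], offs[finite]
    if np.ptp(sig) < 1e-12:
        raise ValueError("all-constant signal")

    lb = np.array([delta_bounds_ppm[0], nominal_b1_ut * (1 - b1_fraction), 0.0, 0.0])
    ub = np.array([delta_bounds_ppm[1], nominal_b1_ut * (1 + b1_fraction), 2.0, 2.0])
    c0 = float(np.percentile(sig, 90))

    def resid(x):
        return sig - wasabi_model(offs, x[0], x[1], x[2], x[3], tp_s, constants)

    best = None
    for d0 in delta_starts_ppm:
        if not (lb[0] <= d0 <= ub[0]):
            continue
        x0 = np.array([d0, nominal_b1_ut, min(c0, 2.0), 1.0])
        res = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                            ftol=1e-12, xtol=1e-12, max_nfev=400)
        if best is None or res.cost < best.cost:
            best = res
    x = best.x
    return WasabiFitResult(float(x[0]), float(x[1]), float(x[2]), float(x[3]),
                           float(np.sum(best.fun**2)))


def fit_b0_map(
    wasabi_volume: ZSpectrumVolume,
    tp_s: float = 0.005,
    nominal_b1_ut: float = 3.7,
    constants: FieldConstants = FieldConstants(),
) -> tuple[B0Map, list[dict]]:
    """Voxelwise WASABI fits over a volume.

    Returns the B0 map (voxels whose fit is unusable are dropped from the
    map mask) and a per-voxel QC table (list of dict rows: iy, ix, delta,
    B1, c, d, rss) suitable for a DataFrame.
    """
    offs = wasabi_volume.offsets_ppm
    ny, nx = wasabi_volume.shape
    delta = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    qc: list[dict] = []
    for iy, ix in zip(*np.nonzero(wasabi_volume.mask)):
        try:
            res = fit_wasabi_voxel(
                wasabi_volume.signal[iy, ix], offs, tp_s, nominal_b1_ut, constants
            )
        except ValueError:
            continue
        delta[iy, ix] = res.delta_b0_ppm
        valid[iy, ix] = True
        qc.append(
            {"iy": int(iy), "ix": int(ix), "delta_b0_ppm": res.delta_b0_ppm,
             "b1_ut": res.b1_ut, "c": res.c, "d": res.d, "rss": res.rss}
        )
    return B0Map(delta, valid), qc


def correct_b0(
    volume: ZSpectrumVolume,
    b0map: B0Map,
    constants: FieldConstants = FieldConstants(),
    inner_ppm: float = 5.0,
    support_ppm: float = 7.5,
    grid_step_hz: float = 1.0,
    return_flags: bool = False,
):
    """Voxelwise B0 correction by 1-Hz interpolation and shifting.

    For each voxel inside the B0-map mask, the spectrum over the spline
    support region (|w| <= support_ppm) is cubic-spline interpolated onto a
    1-Hz grid, shifted by the negative fitted water shift, and resampled at
    the nominal offsets of the dense inner region (|w| <= inner_ppm).
    Offsets beyond the dense region keep their measured values
    (nearest-sample assignment under a sub-0.5-ppm shift is the identity).
    Voxels outside the B0-map mask pass through uncorrected and are flagged.

    The unsaturated reference image is never modified.
    """
    if b0map.delta_b0_ppm.shape != volume.shape:
        raise ValueError(
            f"B0 map shape {b0map.delta_b0_ppm.shape} != volume grid {volume.shape}"
        )
    offsets = volume.offsets_ppm
    hz_per_ppm = constants.larmor_mhz
    inner = np.abs(offsets) <= inner_ppm
    support = np.abs(offsets) <= support_ppm
    order = np.argsort(offsets[support])
    sup_hz = offsets[support][order] * hz_per_ppm
    # 1-Hz grid over the inner region, padded so shifted inner offsets
    # (|delta| <= ~0.5 ppm) stay inside the spline support
    pad_hz = (support_ppm - inner_ppm) * hz_per_ppm / 2.0
    grid = np.arange(np.floor(-inner_ppm * hz_per_ppm - pad_hz),
                     np.ceil(inner_ppm * hz_per_ppm + pad_hz) + grid_step_hz,
                     grid_step_hz)
    inner_hz = offsets[inner] * hz_per_ppm

    out = volume.copy()
    uncorrected = np.zeros(volume.shape, dtype=bool)
    for iy, ix in zip(*np.nonzero(volume.mask)):
        if not b0map.mask[iy, ix]:
            uncorrected[iy, ix] = True
            continue
        delta_hz = b0map.delta_b0_ppm[iy, ix] * hz_per_ppm
        cs = CubicSpline(sup_hz, volume.signal[iy, ix][support][order])
        dense = cs(grid)
        # corrected(w) = measured(w + delta), read off the 1-Hz grid with a
        # cubic resample (nearest- or linear-sample read-off aliases by up
        # to half a grid step at the steep water slope)
        sig = out.signal[iy, ix]
        sig[inner] = CubicSpline(grid, dense)(inner_hz + delta_hz)
    if return_flags:
        return out, uncorrected
    return out
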