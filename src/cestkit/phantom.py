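"""Synthetic single-slice prostate CEST studies.

Generates phantom ground truth (region label map, per-region four-pool
parameters, a smooth B0 field), forward-simulates saturated z-spectrum
volumes and matching WASABI series with additive Gaussian noise, and
replicates the two-session / two-scans-per-session design used for
test-retest repeatability.  Everything is deterministic under fixed seeds.

Default region peak heights follow published prostate values (transition
zone: amide 0.113, NOE 0.109, MT 0.222) with the tumor region carrying the
published MT contrast of +0.038; peripheral-zone and muscle values are
plausible synthetic choices, not measured ones.  Geometry defaults to a
64 x 63 single slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import FieldConstants, OffsetSchedule
from .lineshapes import (
    DEFAULT_SPLINE,
    LorentzianPool,
    SplineConfig,
    SuperLorentzianPool,
    ZModelParams,
    forward_zspectrum,
)
from .volume import ZSpectrumVolume
from .wasabi import wasabi_model

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "SyntheticStudy",
    "lorentzian_amplitude_for_height",
    "default_region_params",
    "make_phantom",
    "simulate_scan",
    "simulate_study",
    "region_masks",
]

REGION_LABELS = {"background": 0, "pz": 1, "tz": 2, "muscle": 3, "tumor": 4}


def lorentzian_amplitude_for_height(height: float, gamma_ppm: float) -> float:
    """Invert peak height = 2A/(pi*Gamma) for the amplitude A."""
    return height * np.pi * gamma_ppm / 2.0


def _region(
    amide_h: float, noe_h: float, mt_h: float,
    water_amp: float = 0.75, water_gamma: float = 1.4,
    amide_gamma: float = 2.2, noe_gamma: float = 2.5, t2b_us: float = 9.0,
    v: float = 0.0,
) -> ZModelParams:
    return ZModelParams(
        water=LorentzianPool(0.0, water_gamma, water_amp),
        amide=LorentzianPool(3.5, amide_gamma, lorentzian_amplitude_for_height(amide_h, amide_gamma)),
        noe=LorentzianPool(-3.5, noe_gamma, lorentzian_amplitude_for_height(noe_h, noe_gamma)),
        # peak-normalized super-Lorentzian: amplitude IS the peak height
        mt=SuperLorentzianPool(-1.27, t2b_us, mt_h),
        h_ppm=0.0,
        v=v,
    )


def default_region_params() -> dict[str, ZModelParams]:
    """Per-region four-pool truths.

    TZ and TZ-tumor peak heights follow published medians (amide 0.113 /
    0.102, NOE 0.109 / 0.096, MT 0.222 / 0.260, i.e. MT contrast +0.038);
    PZ and muscle are realistic synthetic settings (muscle with the largest
    semisolid MT fraction).
    """
    return {
        "tz": _region(0.113, 0.109, 0.222, water_amp=0.75, t2b_us=9.0),
        "tumor": _region(0.102, 0.096, 0.260, water_amp=0.76, t2b_us=9.0),
        "pz": _region(0.100, 0.100, 0.190, water_amp=0.78, water_gamma=1.5, t2b_us=10.0),
        # muscle T2 is shorter than prostate, so its direct-saturation line is broader
        "muscle": _region(0.090, 0.120, 0.300, water_amp=0.70, water_gamma=2.0, t2b_us=8.0),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, noise, B0 field and per-region overrides for a phantom."""

    shape: tuple[int, int] = (64, 63)
    include_tumor: bool = False
    b0_amplitude_ppm: float = 0.3
    noise_sigma: float = 0.005
    region_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.region_overrides) - set(REGION_LABELS)
        if unknown:
            raise ValueError(f"unknown region label(s): {sorted(unknown)}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth of one synthetic subject."""

    label_map: np.ndarray
    region_params: dict[str, ZModelParams]
    b0_map_ppm: np.ndarray
    noise_sigma: float
    seed: int

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0


def _ellipse(shape, cy, cx, ry, rx):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _build_label_map(shape: tuple[int, int], include_tumor: bool) -> np.ndarray:
    ny, nx = shape
    labels = np.zeros(shape, dtype=np.int16)
    cy, cx = ny * 0.5, nx * 0.5
    prostate = _ellipse(shape, cy, cx, ny * 0.28, nx * 0.30)
    tz = _ellipse(shape, cy - ny * 0.06, cx, ny * 0.16, nx * 0.20)
    labels[prostate] = REGION_LABELS["pz"]
    labels[prostate & tz] = REGION_LABELS["tz"]
    for side in (-1, +1):
        musc = _ellipse(shape, cy + ny * 0.05, cx + side * nx * 0.40, ny * 0.12, nx * 0.07)
        labels[musc & ~prostate] = REGION_LABELS["muscle"]
    if include_tumor:
        tum = _ellipse(shape, cy - ny * 0.08, cx + nx * 0.08, ny * 0.06, nx * 0.07)
        labels[tum & (labels == REGION_LABELS["tz"])] = REGION_LABELS["tumor"]
    return labels


def _smooth_b0(shape: tuple[int, int], amplitude_ppm: float, rng: np.random.Generator) -> np.ndarray:
    """Low-order 2D polynomial field scaled to the requested peak amplitude."""
    if amplitude_ppm == 0:
        return np.zeros(shape)
    ny, nx = shape
    y = np.linspace(-1, 1, ny)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    c = rng.normal(0, 1, 6)
    fieldmap = c[0] + c[1] * x + c[2] * y + c[3] * x * y + c[4] * x**2 + c[5] * y**2
    return amplitude_ppm * fieldmap / np.max(np.abs(fieldmap))


def make_phantom(config: PhantomConfig | None = None, seed: int = 0) -> PhantomTruth:
    """Build a deterministic phantom truth for the given config and seed."""
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    labels = _build_label_map(config.shape, config.include_tumor)
    params = default_region_params()
    params.update(config.region_overrides)
    if not config.include_tumor:
        params.pop("tumor", None)
    b0 = _smooth_b0(config.shape, config.b0_amplitude_ppm, rng)
    return PhantomTruth(labels, params, b0, config.noise_sigma, seed)


# WASABI acquisition defaults: 20 offsets evenly spaced over +/-3 ppm,
# 5-ms block pulse, nominal B1 3.7 uT
WASABI_OFFSETS_PPM = tuple(np.linspace(-3.0, 3.0, 20))
WASABI_TP_S = 0.005
WASABI_B1_UT = 3.7
# baseline and oscillation depth of the simulated WASABI signal
WASABI_C = 1.0
WASABI_D = 1.2


def simulate_scan(
    truth: PhantomTruth,
    schedule: OffsetSchedule,
    scan_seed: int = 0,
    constants: FieldConstants = FieldConstants(),
    spline: SplineConfig = DEFAULT_SPLINE,
) -> tuple[ZSpectrumVolume, ZSpectrumVolume]:
    """Forward-simulate one CEST scan and its WASABI companion.

    Per voxel, the region's four-pool model is evaluated with the voxel's
    true B0 offset added to the whole-fit frequency shift h, and zero-mean
    Gaussian noise (sigma = truth.noise_sigma) is added to the normalized
    saturated signals.  The WASABI volume is generated from the Rabi
    oscillation signal model at the same true B0 with nominal B1.  The
    unsaturated reference is exactly 1 in the normalized representation.
    """
    rng = np.random.default_rng(scan_seed)
    offsets = schedule.as_array()
    ny, nx = truth.label_map.shape
    signal = np.zeros((ny, nx, offsets.size))
    wofs = np.asarray(WASABI_OFFSETS_PPM)
    wsig = np.zeros((ny, nx, wofs.size))
    name_of = {v: k for k, v in REGION_LABELS.items()}

    # clean spectra are identical within a region except for the B0 shift;
    # cache per (region, b0) would still be per-voxel, so evaluate per voxel
    for iy, ix in zip(*np.nonzero(truth.mask)):
        region = name_of[int(truth.label_map[iy, ix])]
        p = truth.region_params[region]
        b0 = float(truth.b0_map_ppm[iy, ix])
        shifted = replace(p, h_ppm=p.h_ppm + b0)
        signal[iy, ix] = forward_zspectrum(shifted, offsets, constants, spline)
        wsig[iy, ix] = wasabi_model(
            wofs, b0, WASABI_B1_UT, WASABI_C, WASABI_D, WASABI_TP_S, constants
        )
    if truth.noise_sigma > 0:
        signal[truth.mask] += rng.normal(0, truth.noise_sigma, (int(truth.mask.sum()), offsets.size))
        wsig[truth.mask] += rng.normal(0, truth.noise_sigma, (int(truth.mask.sum()), wofs.size))

    ref = np.ones((ny, nx))
    zvol = ZSpectrumVolume(signal, schedule, mask=truth.mask.copy(), reference=ref)
    wvol = ZSpectrumVolume(
        wsig,
        OffsetSchedule(tuple(wofs), has_reference=False),
        mask=truth.mask.copy(),
    )
    return zvol, wvol


@dataclass
class SyntheticStudy:
    """Two-session, two-scans-per-session replication of one subject.

    ``scans[(session, scan)]`` maps to (CEST volume, WASABI volume) with
    session and scan indexed from 1.  Session 2 uses region parameters
    perturbed multiplicatively by the between-session coefficient of
    variation; scans within a session differ only by noise realization.
    """

    truth: PhantomTruth
    truth_session2: PhantomTruth
    scans: dict[tuple[int, int], tuple[ZSpectrumVolume, ZSpectrumVolume]]
    between_session_cv: float
    scan_seeds: tuple[int, int, int, int]


def _perturb_amplitudes(
    params: ZModelParams, rng: np.random.Generator, cv: float
) -> ZModelParams:
    def f() -> float:
        return max(0.0, 1.0 + rng.normal(0.0, cv))

    return ZModelParams(
        water=replace(params.water, amplitude=params.water.amplitude * f()),
        amide=replace(params.amide, amplitude=params.amide.amplitude * f()),
        noe=replace(params.noe, amplitude=params.noe.amplitude * f()),
        mt=replace(params.mt, amplitude=params.mt.amplitude * f()),
        h_ppm=params.h_ppm,
        v=params.v,
    )


def simulate_study(
    truth: PhantomTruth,
    schedule: OffsetSchedule,
    between_session_cv: float = 0.1,
    scan_seeds: tuple[int, int, int, int] = (1, 2, 3, 4),
    param_seed: int | None = None,
    constants: FieldConstants = FieldConstants(),
) -> SyntheticStudy:
    """Simulate the two-session / two-scan repeatability design.

    Session-2 region pool amplitudes are session-1 values multiplied by
    independent draws of (1 + Normal(0, between_session_cv)); the four scan
    volumes use the four scan seeds in (session, scan) order.
    """
    if len(scan_seeds) != 4:
        raise ValueError("need exactly 4 scan seeds")
    if param_seed is None:
        param_seed = int(np.random.SeedSequence(scan_seeds).generate_state(1)[0] % (2**31))
    prng = np.random.default_rng(param_seed)
    if between_session_cv > 0:
        params2 = {
            name: _perturb_amplitudes(p, prng, between_session_cv)
            for name, p in truth.region_params.items()
        }
    else:
        params2 = dict(truth.region_params)
    truth2 = PhantomTruth(
        truth.label_map.copy(), params2, truth.b0_map_ppm.copy(), truth.noise_sigma, param_seed
    )
    scans = {}
    for i, (session, scan) in enumerate([(1, 1), (1, 2), (2, 1), (2, 2)]):
        t = truth if session == 1 else truth2
        scans[(session, scan)] = simulate_scan(t, schedule, scan_seeds[i], constants)
    return SyntheticStudy(truth, truth2, scans, between_session_cv, tuple(scan_seeds))


def region_masks(truth: PhantomTruth) -> dict[str, np.ndarray]:
    """Boolean ROI mask per non-background region present in the phantom."""
    return {
        name: truth.label_map == lbl
        for name, lbl in REGION_LABELS.items()
        if lbl > 0 and np.any(truth.label_map == lbl)
    }
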