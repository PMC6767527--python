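"""In-memory containers for z-spectra and single-slice spectral volumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import OffsetSchedule

__all__ = ["ZSpectrum", "ZSpectrumVolume"]


@dataclass
class ZSpectrum:
    """A single normalized z-spectrum: signal Mz/M0 versus offset (ppm).

    Normalization by the unsaturated reference is assumed to have been
    applied already.  ``weight`` is a per-point fit weight (all ones by
    default); ``n_averaged`` records how many voxel spectra were averaged
    to produce this one.
    """

    offsets_ppm: np.ndarray
    signal: np.ndarray
    weight: np.ndarray | None = None
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.weight is None:
            self.weight = np.ones_like(self.signal)
        else:
            self.weight = np.asarray(self.weight, dtype=float)
        if not (self.offsets_ppm.shape == self.signal.shape == self.weight.shape):
            raise ValueError(
                f"length mismatch: offsets {self.offsets_ppm.shape}, "
                f"signal {self.signal.shape}, weight {self.weight.shape}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    def __len__(self) -> int:
        return self.signal.size

    def sorted(self) -> "ZSpectrum":
        order = np.argsort(self.offsets_ppm)
        return ZSpectrum(
            self.offsets_ppm[order], self.signal[order], self.weight[order], self.n_averaged
        )


@dataclass
class ZSpectrumVolume:
    """Single-slice grid of normalized z-spectra sharing one offset schedule.

    ``signal`` has shape (ny, nx, n_offsets) ordered like
    ``schedule.offsets_ppm``; ``mask`` marks voxels with valid data.  The
    affine is carried through so parameter maps can be written back in
    acquisition geometry.
    """

    signal: np.ndarray
    schedule: OffsetSchedule
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 3:
            raise ValueError(f"signal must be (ny, nx, n_offsets), got shape {self.signal.shape}")
        if self.signal.shape[-1] != len(self.schedule):
            raise ValueError(
                f"signal has {self.signal.shape[-1]} frames but schedule lists "
                f"{len(self.schedule)} offsets"
            )
        if self.mask is None:
            self.mask = np.ones(self.signal.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.signal.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} != grid shape {self.signal.shape[:2]}"
                )
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def shape(self) -> tuple[int, int]:
        return self.signal.shape[:2]

    @property
    def offsets_ppm(self) -> np.ndarray:
        return self.schedule.as_array()

    def voxel(self, iy: int, ix: int) -> ZSpectrum:
        return ZSpectrum(self.offsets_ppm.copy(), self.signal[iy, ix].copy())

    def copy(self) -> "ZSpectrumVolume":
        return ZSpectrumVolume(
            self.signal.copy(),
            self.schedule,
            self.mask.copy(),
            None if self.affine is None else self.affine.copy(),
            None if self.reference is None else self.reference.copy(),
        )
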