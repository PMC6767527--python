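"""Readers and writers: NIfTI volumes, offset CSVs, masks, YAML config.

Image interchange uses NIfTI (de facto standard for MRI post-processing):
a z-spectrum acquisition is a 4D stack (ny, nx, 1, n_frames) whose frame
order matches a sidecar one-column CSV of ppm values, with an optional
``ref`` row marking the unsaturated reference frame.  Offsets always
travel in the sidecar, never inferred from headers.  Maps and statistics
are written as NIfTI and CSV respectively for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
import yaml

from .constants import FieldConstants, OffsetSchedule, PulseTrain, build_protocol_offset_schedule
from .volume import ZSpectrumVolume

__all__ = [
    "read_offsets_csv",
    "write_offsets_csv",
    "write_zspectrum_volume",
    "read_zspectrum_volume",
    "write_map",
    "read_map",
    "read_mask",
    "write_mask",
    "PipelineConfig",
]


def write_offsets_csv(path, offsets_ppm, reference_index: int | None = None) -> None:
    """One ppm value per line; a 'ref' row marks the reference frame position."""
    offsets = list(offsets_ppm)
    lines = [f"{o:.10g}" for o in offsets]
    if reference_index is not None:
        lines.insert(reference_index, "ref")
    Path(path).write_text("offset_ppm\n" + "\n".join(lines) + "\n")


def read_offsets_csv(path) -> tuple[np.ndarray, int | None]:
    """Returns (offsets_ppm, reference_index or None); index counts frames."""
    offsets: list[float] = []
    ref_index: int | None = None
    i = 0
    for line in Path(path).read_text().splitlines():
        tok = line.strip()
        if not tok or tok.lower() == "offset_ppm":
            continue
        if tok.lower() == "ref":
            if ref_index is not None:
                raise ValueError(f"{path}: multiple 'ref' rows")
            ref_index = i
        else:
            offsets.append(float(tok))
        i += 1
    return np.asarray(offsets), ref_index


def write_zspectrum_volume(volume: ZSpectrumVolume, image_path, offsets_path) -> None:
    """Write a volume as a 4D NIfTI plus its sidecar offsets CSV.

    If the volume carries a reference image it is written as the first
    frame and the sidecar gains a leading 'ref' row; the saturated frames
    are stored as (normalized signal x reference), so reading back with
    :func:`read_zspectrum_volume` round-trips the normalized signal.
    """
    frames = [volume.signal[..., k] for k in range(volume.signal.shape[-1])]
    ref_index = None
    if volume.reference is not None:
        frames = [volume.reference] + [f * volume.reference for f in frames]
        ref_index = 0
    stack = np.stack(frames, axis=-1)[:, :, None, :]
    nib.save(nib.Nifti1Image(stack.astype(np.float64), volume.affine), str(image_path))
    write_offsets_csv(offsets_path, volume.offsets_ppm, ref_index)


def read_zspectrum_volume(
    image_path, offsets_path, mask_path=None, reference_index: int | None = None
) -> ZSpectrumVolume:
    """Read a 4D NIfTI z-stack and normalize it by the reference frame.

    The sidecar CSV fixes the frame order; ``reference_index`` overrides
    the sidecar's 'ref' row.  Voxels with a zero (or non-finite) reference
    are masked out.  Raises if the frame count does not match the sidecar.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        if data.shape[2] != 1:
            raise ValueError(f"expected a single slice, got shape {data.shape}")
        data = data[:, :, 0, :]
    elif data.ndim != 3:
        raise ValueError(f"expected 3D/4D NIfTI, got shape {data.shape}")
    offsets, sidecar_ref = read_offsets_csv(offsets_path)
    if reference_index is None:
        reference_index = sidecar_ref
    n_expected = offsets.size + (1 if reference_index is not None else 0)
    if data.shape[-1] != n_expected:
        raise ValueError(
            f"image has {data.shape[-1]} frames but sidecar implies {n_expected} "
            f"({offsets.size} offsets"
            + (", +1 reference)" if reference_index is not None else ", no reference)")
        )
    if reference_index is not None:
        reference = data[..., reference_index]
        sat = np.delete(data, reference_index, axis=-1)
        good = np.isfinite(reference) & (reference != 0)
        n_bad = int((~good).sum())
        if n_bad:
            import logging

            logging.getLogger(__name__).info("masked %d voxels with zero/invalid reference", n_bad)
        signal = np.zeros_like(sat)
        signal[good] = sat[good] / reference[good][:, None]
        mask = good
    else:
        signal = sat = data
        reference = None
        mask = np.ones(data.shape[:2], dtype=bool)
    if mask_path is not None:
        mask = mask & read_mask(mask_path)
    schedule = OffsetSchedule(tuple(offsets), has_reference=reference is not None)
    return ZSpectrumVolume(signal, schedule, mask=mask, affine=img.affine, reference=reference)


def write_map(map2d, affine, path) -> None:
    """Write a 2D parameter map as a single-slice NIfTI."""
    arr = np.asarray(map2d, dtype=np.float64)[:, :, None]
    nib.save(nib.Nifti1Image(arr, affine if affine is not None else np.eye(4)), str(path))


def read_map(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return arr[:, :, 0] if arr.ndim == 3 else arr


def write_mask(mask, affine, path) -> None:
    p = str(path)
    if p.endswith(".csv"):
        np.savetxt(p, np.asarray(mask, dtype=int), fmt="%d", delimiter=",")
    else:
        nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16)[:, :, None],
                                 affine if affine is not None else np.eye(4)), p)


def read_mask(path) -> np.ndarray:
    """Read a NIfTI or CSV label map as a boolean mask (label > 0)."""
    p = str(path)
    if p.endswith(".csv"):
        return np.loadtxt(p, delimiter=",") > 0
    arr = np.asarray(nib.load(p).dataobj)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 0


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-serializable).

    Paths may be None when a stage is skipped; ``offsets`` is either the
    string ``"protocol_default"`` (the 65-offset protocol schedule) or a
    path to a sidecar CSV.
    """

    out_dir: str = "cest_out"
    cest_image: str | None = None
    offsets: str = "protocol_default"
    wasabi_image: str | None = None
    wasabi_offsets: str | None = None
    mask: str | None = None
    reference_index: int | None = None
    field_strength_t: float = 3.0
    gamma_bar_mhz_per_t: float = 42.577
    pulse: dict = field(default_factory=lambda: {
        "shape": "sinc-Gaussian", "flip_deg": 1133.0, "tp_ms": 40.0,
        "td_ms": 40.0, "n_pulses": 60,
    })
    wasabi_tp_s: float = 0.005
    wasabi_nominal_b1_ut: float = 3.7
    b0_correction: bool = True
    estimate_mt_offset: bool = False
    fix_mt_offset_ppm: float = -1.27
    fit_overrides: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def constants(self) -> FieldConstants:
        return FieldConstants(self.gamma_bar_mhz_per_t, self.field_strength_t)

    @property
    def pulse_train(self) -> PulseTrain:
        p = self.pulse
        return PulseTrain(p.get("shape", "sinc-Gaussian"), p["flip_deg"],
                          p["tp_ms"], p["td_ms"], p["n_pulses"])

    def schedule(self) -> OffsetSchedule:
        if self.offsets == "protocol_default":
            return build_protocol_offset_schedule()
        offsets, ref = read_offsets_csv(self.offsets)
        return OffsetSchedule(tuple(offsets), has_reference=ref is not None)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
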