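"""End-to-end orchestration: WASABI -> B0 correction -> fitting -> maps/tables.

Each stage is runnable in isolation through the library (or the CLI); this
module chains them for a single configured run, writing NIfTI maps, CSV
tables, and a machine-readable JSON run log (config hash, seeds, package
versions, stage timings).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry import mtr_asym_map
from .fitting import FitConfig, SuperLorentzianTable, estimate_mt_offset, fit_maps
from .io import PipelineConfig, read_zspectrum_volume, write_map
from .wasabi import correct_b0, fit_b0_map

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps({k: getattr(config, k) for k in config.__dataclass_fields__},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; returns a dict of output paths/values.

    Stages: read inputs -> WASABI B0 fit -> voxelwise B0 correction ->
    (optional) MT-offset estimation -> voxelwise four-pool fitting ->
    MTRasym -> maps and run log.  Stage failures raise
    :class:`PipelineError` naming the stage.
    """
    if config.cest_image is None:
        raise PipelineError("config: cest_image is required")
    if config.b0_correction and config.wasabi_image is None:
        raise PipelineError("config: B0 correction enabled but no wasabi_image given")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    outputs: dict = {"log": str(out_dir / "run_log.json")}
    constants = config.constants

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                log["stages"][name] = {"seconds": round(time.time() - self.t0, 3),
                                       "ok": exc_type is None}
                if exc_type is not None:
                    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _T()

    if config.offsets == "protocol_default":
        raise PipelineError(
            "config: reading an image requires a sidecar offsets CSV path "
            "(the named default schedule is only for simulation)"
        )
    with stage("read"):
        volume = read_zspectrum_volume(
            config.cest_image, config.offsets, config.mask, config.reference_index
        )

    if config.b0_correction:
        with stage("wasabi"):
            wvol = read_zspectrum_volume(config.wasabi_image, config.wasabi_offsets,
                                         config.mask)
            b0map, qc = fit_b0_map(wvol, config.wasabi_tp_s,
                                   config.wasabi_nominal_b1_ut, constants)
            write_map(b0map.delta_b0_ppm, volume.affine, out_dir / "b0_map_ppm.nii.gz")
            pd.DataFrame(qc).to_csv(out_dir / "wasabi_qc.csv", index=False)
            outputs["b0_map"] = str(out_dir / "b0_map_ppm.nii.gz")
        with stage("correct"):
            volume = correct_b0(volume, b0map, constants)

    fit_config = FitConfig()
    if config.estimate_mt_offset:
        with stage("mt_offset"):
            est = estimate_mt_offset(volume, constants)
            log["mt_offset_median_ppm"] = est.median_ppm
            np.savetxt(out_dir / "mt_offset_per_voxel_ppm.csv", est.per_voxel_ppm,
                       delimiter=",", header="mt_offset_ppm", comments="")
    # downstream fits keep the configured constant unless overridden
    fit_config = fit_config.with_mt_offset(config.fix_mt_offset_ppm)

    with stage("fit"):
        table = SuperLorentzianTable(constants=constants)
        maps = fit_maps(volume, fit_config, constants, sl_table=table)
        for name in ("amide", "noe", "mt", "water", "h", "v", "rss"):
            write_map(maps[name], volume.affine, out_dir / f"{name}_map.nii.gz")
            outputs[name] = str(out_dir / f"{name}_map.nii.gz")
        write_map(maps["converged"].astype(float), volume.affine,
                  out_dir / "converged_map.nii.gz")

    with stage("asym"):
        asym = mtr_asym_map(volume)
        write_map(asym, volume.affine, out_dir / "mtr_asym_map.nii.gz")
        outputs["mtr_asym"] = str(out_dir / "mtr_asym_map.nii.gz")

    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return outputs
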