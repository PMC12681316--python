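"""File I/O: NIfTI patch images, CSV tables, JSON results, YAML config.

Images are written one NIfTI per da-hdrAFI signal (s_a1, s_a2, s_b1,
s_b2), shape (n, n, 1), with the voxel size in the affine and a JSON
sidecar carrying geometry and provenance. Patches are extracted on the
acquisition grid without resampling.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .forward import PatchGeometry, SignalPatch
from .heating import HeatingObservation, ImplantCalibration, ThermoTimeSeries
from .sequence import SequenceParams

__all__ = [
    "SIGNAL_NAMES",
    "write_patch_images",
    "read_patch_images",
    "read_thermometry_csv",
    "write_thermometry_csv",
    "read_observations_csv",
    "write_observations_csv",
    "write_calibration",
    "read_calibration",
    "load_config",
    "sequence_from_config",
    "geometry_from_config",
]

SIGNAL_NAMES = ("s_a1", "s_a2", "s_b1", "s_b2")


def _affine(geom: PatchGeometry) -> np.ndarray:
    return np.diag([geom.voxel_size, geom.voxel_size, geom.slice_thickness, 1.0])


def write_patch_images(patch: SignalPatch, out_dir, prefix: str = "patch"):
    """Write the 4 signal images plus a JSON sidecar; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, name in enumerate(SIGNAL_NAMES):
        img = nib.Nifti1Image(
            patch.signals[:, :, j][:, :, None].astype(np.float64),
            _affine(patch.geometry),
        )
        p = out_dir / f"{prefix}_{name}.nii"
        nib.save(img, str(p))
        paths.append(p)
    sidecar = out_dir / f"{prefix}.json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "geometry": {
                    "n_voxels": patch.geometry.n_voxels,
                    "voxel_size_mm": patch.geometry.voxel_size,
                    "slice_thickness_mm": patch.geometry.slice_thickness,
                    "subdivision": patch.geometry.subdivision,
                    "exclusion_radius_mm": patch.geometry.exclusion_radius,
                },
                "provenance": patch.provenance,
                "normalized": True,
            },
            fh,
            indent=2,
        )
    return paths, sidecar


def read_patch_images(
    paths,
    center_hint=None,
    geom: PatchGeometry | None = None,
    normalized: bool = False,
) -> SignalPatch:
    """Assemble a SignalPatch from 4 co-registered magnitude images.

    ``paths`` are the (s_a1, s_a2, s_b1, s_b2) images on a common grid.
    ``center_hint`` is the approximate wire location in voxel indices
    (row, col) about which the patch is extracted; by default the image
    must already be patch-sized. Raw scanner magnitudes are normalized per
    voxel unless ``normalized`` is set; all-zero voxels are flagged
    degenerate.
    """
    if len(paths) != 4:
        raise ValueError("expected 4 image paths (s_a1, s_a2, s_b1, s_b2)")
    imgs = [nib.load(str(p)) for p in paths]
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"images are on mismatched grids: {shapes}")
    for im in imgs[1:]:
        if not np.allclose(im.affine, imgs[0].affine):
            raise ValueError("images have mismatched affines")
    vols = [np.asarray(im.dataobj, dtype=float) for im in imgs]
    planes = [v[:, :, 0] if v.ndim == 3 else v for v in vols]

    aff = imgs[0].affine
    geom = geom or PatchGeometry(
        voxel_size=float(abs(aff[0, 0])),
        slice_thickness=float(abs(aff[2, 2])) or 2.0,
    )
    n = geom.n_voxels
    if center_hint is None:
        if planes[0].shape != (n, n):
            raise ValueError(
                f"image shape {planes[0].shape} is not patch-sized ({n}, {n}); "
                "supply center_hint"
            )
        r0 = c0 = 0
    else:
        r, c = (int(round(v)) for v in center_hint)
        r0, c0 = r - n // 2, c - n // 2
        nr, nc = planes[0].shape
        if r0 < 0 or c0 < 0 or r0 + n > nr or c0 + n > nc:
            raise ValueError("patch around center_hint exceeds image bounds")
    stack = np.stack([p[r0 : r0 + n, c0 : c0 + n] for p in planes], axis=-1)

    finite = np.isfinite(stack).all(axis=-1)
    norm = np.sqrt((np.where(finite[..., None], stack, 0.0) ** 2).sum(axis=-1))
    degenerate = ~finite | (norm == 0)
    if degenerate.all():
        raise ValueError("patch contains no usable voxels")
    if normalized:
        signals = np.where(degenerate[..., None], np.nan, stack)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            signals = stack / norm[..., None]
        signals = np.where(degenerate[..., None], np.nan, signals)
    return SignalPatch(
        signals=signals,
        geometry=geom,
        degenerate=degenerate,
        provenance={"kind": "acquired", "paths": [str(p) for p in paths]},
    )


# -- tabular ------------------------------------------------------------


def write_thermometry_csv(series: ThermoTimeSeries, path) -> None:
    pd.DataFrame({"time_s": series.time, "temp_K": series.temperature}).to_csv(
        path, index=False
    )


def read_thermometry_csv(
    path, baseline_window: float = 300.0, exposure_start: float | None = None
) -> ThermoTimeSeries:
    df = pd.read_csv(path)
    for col in ("time_s", "temp_K"):
        if col not in df.columns:
            raise ValueError(f"thermometry CSV must have a {col!r} column")
    return ThermoTimeSeries(
        time=df["time_s"].to_numpy(),
        temperature=df["temp_K"].to_numpy(),
        baseline_window=baseline_window,
        exposure_start=baseline_window if exposure_start is None else exposure_start,
    )


def write_observations_csv(observations, path) -> None:
    pd.DataFrame(
        {
            "config_label": [o.config_label for o in observations],
            "i_mri_A": [o.i_mri for o in observations],
            "dT_thermo_K": [o.dt_thermo for o in observations],
        }
    ).to_csv(path, index=False)


def read_observations_csv(path) -> list[HeatingObservation]:
    df = pd.read_csv(path)
    for col in ("i_mri_A", "dT_thermo_K"):
        if col not in df.columns:
            raise ValueError(f"observations CSV must have a {col!r} column")
    labels = df.get("config_label", pd.Series([""] * len(df)))
    return [
        HeatingObservation(i_mri=float(i), dt_thermo=float(dt), config_label=str(lab))
        for i, dt, lab in zip(df["i_mri_A"], df["dT_thermo_K"], labels)
    ]


def write_calibration(cal: ImplantCalibration, path) -> None:
    with open(path, "w") as fh:
        json.dump(cal.to_dict(), fh, indent=2)


def read_calibration(path) -> ImplantCalibration:
    with open(path) as fh:
        return ImplantCalibration.from_dict(json.load(fh))


# -- config -------------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def sequence_from_config(cfg: dict) -> SequenceParams:
    return SequenceParams(**cfg.get("sequence", {}))


def geometry_from_config(cfg: dict) -> PatchGeometry:
    return PatchGeometry(**cfg.get("geometry", {}))
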