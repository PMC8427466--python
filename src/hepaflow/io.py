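"""NIfTI and tabular persistence for simulated series, maps and results.

Image stacks are written as NIfTI-1 with the in-plane pixel size and slice
thickness in the affine; acquisition metadata that NIfTI cannot carry
(inversion times, inversion mode, venc, frame times) goes to a JSON
sidecar next to the image file.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import FairProtocol, InversionRecoverySeries


def _affine(pixel_mm: float, slice_mm: float) -> np.ndarray:
    return np.diag([pixel_mm, pixel_mm, slice_mm, 1.0])


def save_series(series: InversionRecoverySeries, path) -> Path:
    """Write an inversion-recovery series as NIfTI + JSON sidecar."""
    path = Path(path)
    data = np.moveaxis(series.images, 0, -1)[:, :, None, :]  # x, y, z, TI
    img = nib.Nifti1Image(data.astype(np.float32),
                          _affine(series.protocol.pixel_mm,
                                  series.protocol.slice_mm))
    nib.save(img, path)
    sidecar = {
        "tis_ms": list(map(float, series.tis_ms)),
        "inversion_mode": series.inversion_mode,
        "protocol": series.protocol.__dict__,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def load_series(path) -> InversionRecoverySeries:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    images = np.moveaxis(np.asarray(img.dataobj)[:, :, 0, :], -1, 0).astype(float)
    protocol = FairProtocol(**meta["protocol"])
    series = InversionRecoverySeries(images=images,
                                     tis_ms=np.asarray(meta["tis_ms"]),
                                     inversion_mode=meta["inversion_mode"],
                                     protocol=protocol)
    series.validate()
    return series


def save_map(array: np.ndarray, pixel_mm: float, path, units: str = "",
             slice_mm: float = 2.0) -> Path:
    """Write a 2D parameter map as NIfTI; units recorded in the header."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(array, np.float32)[:, :, None],
                          _affine(pixel_mm, slice_mm))
    if units:
        img.header["descrip"] = units.encode()[:79]
    nib.save(img, path)
    return path


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj)[:, :, 0].astype(float)


def save_cine(cine, path) -> Path:
    """Write a velocity cine (wrapped phase frames) as NIfTI + JSON sidecar."""
    path = Path(path)
    px = float(np.sqrt(cine.voxel_area_mm2))
    data = np.moveaxis(cine.frames, 0, -1)[:, :, None, :]
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(px, 2.0)), path)
    sidecar = {
        "venc_cm_s": cine.venc_cm_s,
        "frame_times_ms": list(map(float, cine.frame_times_ms)),
        "voxel_area_mm2": cine.voxel_area_mm2,
        "vessel_label": cine.vessel_label,
        "heart_rate_bpm": cine.heart_rate_bpm,
        "vessel_centre_px": list(cine.vessel_centre_px),
        "vessel_radius_px": cine.vessel_radius_px,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def load_cine(path):
    from .phantom import VelocityCine

    path = Path(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    frames = np.moveaxis(np.asarray(nib.load(path).dataobj)[:, :, 0, :],
                         -1, 0).astype(float)
    cine = VelocityCine(frames=frames, venc_cm_s=meta["venc_cm_s"],
                        frame_times_ms=np.asarray(meta["frame_times_ms"]),
                        voxel_area_mm2=meta["voxel_area_mm2"],
                        vessel_label=meta["vessel_label"],
                        heart_rate_bpm=meta["heart_rate_bpm"],
                        vessel_centre_px=tuple(meta["vessel_centre_px"]),
                        vessel_radius_px=meta["vessel_radius_px"])
    cine.validate()
    return cine
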