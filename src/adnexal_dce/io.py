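"""Reading and writing of images, maps and curve tables.

NIfTI-1 is used for 4-D dynamic series, binary masks and parameter maps
(via nibabel); curves and result tables are plain CSV.  A colour-coded
Ktrans PNG per slice mirrors the maps radiologists read.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from adnexal_dce.aif import ConcentrationCurve
from adnexal_dce.pk_model import FIT_OK, ParameterMap
from adnexal_dce.semiquant import EnhancementCurve

__all__ = [
    "load_series",
    "save_series",
    "load_mask",
    "save_parameter_maps",
    "save_ktrans_png_slices",
    "read_curves_csv",
    "write_curves_csv",
    "read_arterial_csv",
]

_STATUS_CODES = {"ok": 1, "zero-signal": 2, "failed": 3, "absent": 0}


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def load_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D dynamic series; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series, got {data.ndim}-D")
    return data, img.affine


def save_series(path: str | Path, data: np.ndarray,
                voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                             _affine(voxel_size_mm)), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def save_parameter_maps(pmap: ParameterMap, outdir: str | Path,
                        prefix: str = "pk") -> dict[str, Path]:
    """Write one NIfTI volume per kinetic parameter plus a status volume.

    Failed/absent voxels keep NaN in the parameter volumes; the integer
    status volume (0 absent, 1 ok, 2 zero-signal, 3 failed) tells them
    apart.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(pmap.voxel_size_mm)
    written = {}
    for name in ("ktrans", "kep", "ve", "vp", "delta", "r2"):
        path = outdir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(
            np.asarray(getattr(pmap, name), dtype=np.float32), aff),
            str(path))
        written[name] = path
    status = np.vectorize(_STATUS_CODES.get)(pmap.status).astype(np.int16)
    path = outdir / f"{prefix}_status.nii.gz"
    nib.save(nib.Nifti1Image(status, aff), str(path))
    written["status"] = path
    return written


def save_ktrans_png_slices(pmap: ParameterMap, outdir: str | Path,
                           prefix: str = "ktrans") -> list[Path]:
    """Colour-coded Ktrans image per axial slice (jet colormap, NaN grey)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = np.where(pmap.ok, pmap.ktrans, np.nan)
    finite = data[np.isfinite(data)]
    vmax = float(finite.max()) if finite.size else 1.0
    paths = []
    for k in range(pmap.shape[2]):
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(data[:, :, k].T, origin="lower", cmap="jet",
                       vmin=0.0, vmax=vmax or 1.0)
        ax.set_title(f"Ktrans (1/min), slice {k}")
        ax.axis("off")
        fig.colorbar(im, ax=ax, shrink=0.8)
        path = outdir / f"{prefix}_slice{k:02d}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


def read_curves_csv(path: str | Path, injection_time: float,
                    frame_interval: float) -> dict[str, EnhancementCurve]:
    """Read long-format lesion curves (columns lesion_id, time_s, signal)."""
    df = pd.read_csv(path)
    out = {}
    for lesion_id, grp in df.groupby("lesion_id", sort=False):
        out[str(lesion_id)] = EnhancementCurve(
            times=grp["time_s"].to_numpy(),
            signal=grp["signal"].to_numpy(),
            injection_time=injection_time,
            frame_interval=frame_interval,
        )
    return out


def write_curves_csv(path: str | Path,
                     curves: dict[str, EnhancementCurve]) -> None:
    frames = [
        pd.DataFrame({"lesion_id": lesion_id, "time_s": c.times,
                      "signal": c.signal})
        for lesion_id, c in curves.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_arterial_csv(path: str | Path) -> list[ConcentrationCurve]:
    """Read measured arterial curves (columns curve_id, time_s, value)."""
    df = pd.read_csv(path)
    return [
        ConcentrationCurve(times=g["time_s"].to_numpy(),
                           values=g["value"].to_numpy(), compartment="blood")
        for _, g in df.groupby("curve_id", sort=False)
    ]
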