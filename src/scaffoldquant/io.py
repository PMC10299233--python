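"""Readers and writers for the pipeline's on-disk formats.

Conventions: CSV is comma-separated UTF-8 with a header row and '.'
decimals; images are 8-bit grayscale TIFF or PNG (16-bit inputs are
accepted and kept at native depth in memory); orientation fields dump as
32-bit float TIFF.  Every writer's output round-trips through its paired
reader with lossless field recovery.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .orientation import OrientationField, OrientationHistogram
from .pores import GrayImage
from .synthetic import StressStrainCurve

__all__ = [
    "read_image", "write_image", "read_traction_csv", "write_traction_csv",
    "read_ramp_csv", "write_ramp_csv", "write_pore_table", "read_pore_table",
    "write_histogram_csv", "read_histogram_csv", "write_curve_csv",
    "read_curve_csv", "write_orientation_field", "write_json", "read_json",
]


def read_image(path: str | Path, pixel_scale: float = 1.0,
               provenance: str = "") -> GrayImage:
    """Load a grayscale TIFF/PNG; RGB inputs are rejected, not converted."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.ptp(arr[..., :3], axis=2).max() == 0:
            arr = arr[..., 0]  # gray stored as RGB
        else:
            raise ValueError(f"{path}: color image; expected grayscale")
    return GrayImage(pixels=arr, pixel_scale=pixel_scale,
                     provenance=provenance or str(path))


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(pixels)
    if arr.dtype not in (np.uint8, np.uint16):
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_orientation_field(prefix: str | Path, fld: OrientationField) -> None:
    """Dump angle and coherency rasters as 32-bit float TIFFs."""
    prefix = Path(prefix)
    tifffile.imwrite(prefix.with_suffix(".angle.tif"),
                     fld.angle_deg.astype(np.float32))
    tifffile.imwrite(prefix.with_suffix(".coherency.tif"),
                     fld.coherency.astype(np.float32))


def _write_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def write_traction_csv(path: str | Path, df: pd.DataFrame) -> None:
    _write_csv(path, df[["time_s", "displacement_mm", "force_N"]])


def read_traction_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"time_s", "displacement_mm", "force_N"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: traction log needs columns {sorted(need)}")
    return df


def write_ramp_csv(path: str | Path, df: pd.DataFrame) -> None:
    _write_csv(path, df[["time_s", "temp_C"]])


def read_ramp_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time_s", "temp_C"} <= set(df.columns):
        raise ValueError(f"{path}: ramp log needs time_s and temp_C columns")
    return df


def write_pore_table(path: str | Path, table: pd.DataFrame) -> None:
    _write_csv(path, table)


def read_pore_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_histogram_csv(path: str | Path, hist: OrientationHistogram) -> None:
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    _write_csv(path, pd.DataFrame({"bin_center_deg": centers,
                                   "density": hist.density}))


def read_histogram_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_curve_csv(path: str | Path, curve: StressStrainCurve) -> None:
    df = curve.to_frame()
    if curve.regions:
        bounds = [curve.regions.get(k, np.inf) for k in
                  ("toe_end", "linear_end", "yield_end", "failure")]
        names = np.array(["toe", "linear", "yield", "post_yield", "failed"])
        df["region"] = names[np.searchsorted(bounds, df["strain_pct"],
                                             side="left")]
    _write_csv(path, df)


def read_curve_csv(path: str | Path) -> StressStrainCurve:
    df = pd.read_csv(path)
    return StressStrainCurve(strain_pct=df["strain_pct"].to_numpy(),
                             stress_kPa=df["stress_kPa"].to_numpy())


def write_json(path: str | Path, obj: dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
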