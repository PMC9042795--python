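"""Format readers and writers shared by all stages.

TIFF is the image interchange format: stacks are written with x/y
resolution tags plus a structured metadata block carrying the voxel size
(nm), channel names and axis order, and are read back losslessly.
ImageJ-dialect TIFFs (resolution tags + ``spacing``) are accepted on
read. A TIFF without resolvable voxel size and without a user override is
an explicit error, never a silent default.

Tabular data (granule records, FRAP traces) travels as CSV with a
versioned ``# granulekit:`` header comment; ground truth as sidecar JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frap import FrapTrace
from .image import ImageStack
from .segmentation import GranuleRecord

__all__ = [
    "MetadataError",
    "read_image",
    "write_image",
    "records_to_dataframe",
    "write_records_csv",
    "read_records_csv",
    "write_frap_csv",
    "read_frap_csv",
]

_CSV_SCHEMA = "granulekit-records-v1"
_FRAP_SCHEMA = "granulekit-frap-v1"


class MetadataError(RuntimeError):
    """Required image metadata (voxel size) missing and not overridden."""


def write_image(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as TIFF with voxel-size metadata.

    Voxel size goes into the x/y resolution tags (pixels per cm) and into
    a structured metadata block together with channel names and z spacing.
    """
    vy, vx = stack.voxel_size_nm[-2], stack.voxel_size_nm[-1]
    axes = "C" + ("ZYX" if stack.ndim_spatial == 3 else "YX")
    tifffile.imwrite(
        str(path),
        stack.data,
        resolution=(1e7 / vx, 1e7 / vy),
        resolutionunit="CENTIMETER",
        metadata={
            "axes_order": axes,
            "voxel_size_nm": list(stack.voxel_size_nm),
            "channels": list(stack.channels),
        },
    )


def read_image(
    path: str | Path, voxel_size_nm: tuple[float, ...] | None = None
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Voxel size resolution order: granulekit metadata block; ImageJ
    ``spacing`` + resolution tags; plain resolution tags (2D); the
    ``voxel_size_nm`` override. With none of these, raises
    :class:`MetadataError`.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.series[0].asarray()
        meta = None
        if tif.shaped_metadata:
            meta = tif.shaped_metadata[0]
        channels = None
        vox = None
        if meta and "voxel_size_nm" in meta:
            vox = tuple(float(v) for v in meta["voxel_size_nm"])
            channels = list(meta.get("channels", []))
        else:
            # ImageJ dialect / bare resolution tags
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            unit_nm = None
            if xres is not None and yres is not None:
                runit = page.tags.get("ResolutionUnit")
                unit = getattr(runit, "value", None)
                scale = {2: 2.54e7, 3: 1e7}.get(getattr(unit, "value", unit))
                if scale is None and tif.imagej_metadata:
                    scale = {"um": 1e3, "micron": 1e3, "nm": 1.0}.get(
                        tif.imagej_metadata.get("unit", ""), None
                    )
                if scale is not None:
                    fx = xres.value[0] / xres.value[1]
                    fy = yres.value[0] / yres.value[1]
                    vx = scale / fx
                    vy = scale / fy
                    if data.ndim == 2:
                        vox = (vy, vx)
                    elif tif.imagej_metadata and "spacing" in tif.imagej_metadata:
                        vz = float(tif.imagej_metadata["spacing"]) * 1e3  # µm -> nm
                        vox = (vz, vy, vx)
        if vox is None:
            vox = voxel_size_nm
        if vox is None:
            raise MetadataError(
                f"{path}: no resolvable voxel size in TIFF metadata; pass "
                "voxel_size_nm explicitly"
            )
    if data.ndim == len(vox):  # single-channel plane(s)
        data = data[np.newaxis]
    if not channels:
        channels = [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(data, channels, tuple(vox))


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------


def records_to_dataframe(records: list[GranuleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "volume": r.volume,
            "equivalent_diameter_nm": r.equivalent_diameter_nm,
            "major_axis_nm": r.major_axis_nm,
            "minor_axis_nm": r.minor_axis_nm,
            "aspect_ratio": r.aspect_ratio,
            "n_voxels": r.n_voxels,
        }
        for ax, c in zip("zyx"[-len(r.centroid_nm) :], r.centroid_nm):
            row[f"centroid_{ax}_nm"] = c
        for ch, v in r.mean_intensity.items():
            row[f"mean_intensity_{ch}"] = v
        for ch, v in r.integrated_intensity.items():
            row[f"integrated_intensity_{ch}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_records_csv(records: list[GranuleRecord], path: str | Path) -> None:
    """One row per segmented object, with a schema-version header line."""
    df = records_to_dataframe(records)
    with open(path, "w") as fh:
        fh.write(f"# {_CSV_SCHEMA}\n")
        df.to_csv(fh, index=False)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_frap_csv(trace: FrapTrace, path: str | Path) -> None:
    cols = {"time_s": trace.time_s, "roi": trace.roi}
    if trace.reference is not None:
        cols["reference"] = trace.reference
    if trace.background is not None:
        cols["background"] = trace.background
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# {_FRAP_SCHEMA} bleach_index={trace.bleach_index}\n")
        df.to_csv(fh, index=False)


def read_frap_csv(path: str | Path, bleach_index: int | None = None) -> FrapTrace:
    with open(path) as fh:
        first = fh.readline()
    if bleach_index is None:
        if "bleach_index=" not in first:
            raise ValueError("bleach_index not in header and not supplied")
        bleach_index = int(first.split("bleach_index=")[1].split()[0])
    df = pd.read_csv(path, comment="#")
    return FrapTrace(
        time_s=df["time_s"].to_numpy(),
        roi=df["roi"].to_numpy(),
        reference=df["reference"].to_numpy() if "reference" in df else None,
        background=df["background"].to_numpy() if "background" in df else None,
        bleach_index=bleach_index,
    )


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
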