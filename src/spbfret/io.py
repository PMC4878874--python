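"""File I/O: multi-page TIFF image sets, trace CSVs and result JSON.

Image sets are written one multi-page TIFF per cell, page order
acceptor-pre, donor-pre, acceptor-post, donor-post (the acquisition order of
one bleach cycle), with a CSV manifest of per-cell metadata and a YAML echo
of the generating configuration.  Intensities are kept as floating point
throughout the pipeline; integerization to 16-bit happens only at TIFF
write, with the global scale factor recorded in the config echo.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import SimConfig
from .frap import FrapTrace
from .simulate import PAGE_ORDER, SAMPLE_CLASSES, FretImageSet, SimulatedCell
from .stats import SpindleTrace

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


# ---------------------------------------------------------------- image sets

def write_image_set(image_set: FretImageSet, outdir) -> Path:
    """Write a FRET image set as per-cell TIFFs + manifest.csv + config.yaml.

    Returns the output directory.  Pixel values are scaled by a single
    global factor to span the 16-bit range; the factor is stored in the
    config echo under ``tiff_counts_per_unit``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    global_max = max(float(img.max()) for c in image_set.cells
                     for img in c.images.values())
    scale = 60000.0 / global_max if global_max > 0 else 1.0
    rows = []
    for cell in image_set.cells:
        fname = f"{cell.cell_id}.tif"
        pages = [np.clip(cell.images[p] * scale, 0, 65535).astype(np.uint16)
                 for p in PAGE_ORDER]
        tifffile.imwrite(outdir / fname, np.stack(pages),
                         photometric="minisblack")
        r, c = cell.true_center if cell.true_center else (np.nan, np.nan)
        rows.append({
            "cell_id": cell.cell_id, "class": cell.sample_class,
            "file": fname, "true_center_row": r, "true_center_col": c,
            "true_efficiency_pct": cell.true_efficiency_pct,
        })
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    echo = dataclasses.asdict(image_set.config)
    echo["image_shape_px"] = list(echo["image_shape_px"])
    echo["tiff_counts_per_unit"] = scale
    echo["page_order"] = list(PAGE_ORDER)
    echo["schema_version"] = SCHEMA_VERSION
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    return outdir


def read_image_set(indir) -> FretImageSet:
    """Read an image set written by :func:`write_image_set`.

    Raises with the file name and page on truncated TIFFs and lists the
    allowed values on unknown class labels.
    """
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    with open(indir / "config.yaml") as fh:
        echo = yaml.safe_load(fh)
    scale = float(echo.pop("tiff_counts_per_unit", 1.0))
    echo.pop("page_order", None)
    echo.pop("schema_version", None)
    echo["image_shape_px"] = tuple(echo["image_shape_px"])
    config = SimConfig(**echo)
    cells = []
    for _, row in manifest.iterrows():
        klass = str(row["class"])
        if klass not in SAMPLE_CLASSES:
            raise ValueError(
                f"manifest row {row['cell_id']!r} has unknown class "
                f"{klass!r}; allowed values: {list(SAMPLE_CLASSES)}")
        path = indir / str(row["file"])
        try:
            stack = tifffile.imread(path)
        except Exception as exc:
            raise IOError(f"failed to read TIFF {path.name}: {exc}") from exc
        if stack.ndim != 3 or stack.shape[0] != len(PAGE_ORDER):
            got = stack.shape[0] if stack.ndim == 3 else 1
            raise IOError(
                f"TIFF {path.name} is truncated or malformed: expected "
                f"{len(PAGE_ORDER)} pages ({', '.join(PAGE_ORDER)}), "
                f"got {got}")
        images = {p: stack[i].astype(float) / scale
                  for i, p in enumerate(PAGE_ORDER)}
        center = (None if np.isnan(row["true_center_row"])
                  else (float(row["true_center_row"]),
                        float(row["true_center_col"])))
        cells.append(SimulatedCell(
            cell_id=str(row["cell_id"]), sample_class=klass, images=images,
            true_center=center,
            true_efficiency_pct=float(row["true_efficiency_pct"])))
    return FretImageSet(cells=cells, config=config)


# -------------------------------------------------------------- trace tables

def write_frap_traces(traces: list[FrapTrace], path) -> Path:
    """Write FRAP traces as long-format CSV.

    Columns: trace_id, time_s, intensity, post_bleach (0/1) and, when a
    reference trace is attached, reference.
    """
    path = Path(path)
    frames = []
    for i, tr in enumerate(traces):
        df = pd.DataFrame({
            "trace_id": f"trace_{i:03d}",
            "time_s": tr.time_s,
            "intensity": tr.intensity,
            "post_bleach": (np.arange(tr.time_s.size) >= tr.bleach_index
                            ).astype(int),
        })
        if tr.reference_intensity is not None:
            df["reference"] = tr.reference_intensity
        frames.append(df)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_frap_traces(path) -> list[FrapTrace]:
    """Read FRAP traces written by :func:`write_frap_traces`."""
    df = pd.read_csv(path)
    required = {"trace_id", "time_s", "intensity", "post_bleach"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FRAP trace CSV {path} is missing columns "
                         f"{sorted(missing)}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("time_s")
        post = grp["post_bleach"].to_numpy()
        if post.max() == 0:
            raise ValueError(f"trace {tid!r} has no post-bleach frames")
        bleach_index = int(np.argmax(post == 1))
        ref = (grp["reference"].to_numpy(dtype=float)
               if "reference" in grp.columns else None)
        traces.append(FrapTrace(
            time_s=grp["time_s"].to_numpy(dtype=float),
            intensity=grp["intensity"].to_numpy(dtype=float),
            bleach_index=bleach_index, reference_intensity=ref))
    return traces


def write_spindle_traces(traces: list[SpindleTrace], path) -> Path:
    """Write spindle traces as long-format CSV (trace_id, time_min, length_um)."""
    path = Path(path)
    frames = [pd.DataFrame({"trace_id": f"trace_{i:03d}",
                            "time_min": tr.time_min,
                            "length_um": tr.length_um})
              for i, tr in enumerate(traces)]
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_spindle_traces(path) -> list[SpindleTrace]:
    df = pd.read_csv(path)
    required = {"trace_id", "time_min", "length_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spindle trace CSV {path} is missing columns "
                         f"{sorted(missing)}")
    traces = []
    for _, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("time_min")
        traces.append(SpindleTrace(
            time_min=grp["time_min"].to_numpy(dtype=float),
            length_um=grp["length_um"].to_numpy(dtype=float)))
    return traces


# ------------------------------------------------------------------- results

def write_result_json(result: dict, path) -> Path:
    """Write a result dictionary as schema-versioned JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(result)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
    return path


def write_measurements_csv(measurements, path) -> Path:
    """Write per-cell FRET measurements (including exclusions) as CSV."""
    path = Path(path)
    rows = [{
        "cell_id": m.cell_id, "class": m.sample_class,
        "FL_pre": m.FL_pre, "FL_post": m.FL_post,
        "FL_bg_pre": m.FL_bg_pre, "FL_bg_post": m.FL_bg_post,
        "FL_cor_pre": m.FL_cor_pre, "FL_cor_post": m.FL_cor_post,
        "E_pct": m.E_pct, "excluded_reason": m.excluded_reason,
    } for m in measurements]
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
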