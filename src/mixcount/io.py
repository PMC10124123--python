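"""File I/O: TIFF frames, ground-truth CSV, sample manifests, results CSV.

All outputs are plain standard formats readable without this package:
16-bit single-channel TIFF per field, CSV for truth annotations, manifests
and results, and a JSON provenance record per run.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .counts import CountResult
from .detect import ImageFrame
from .simulate import SimulatedSample

__all__ = [
    "write_samples",
    "read_manifest",
    "read_frames",
    "write_results",
    "read_results",
    "write_provenance",
]


def write_samples(samples: Sequence[SimulatedSample], outdir: str | Path) -> Path:
    """Write a simulated sample set: TIFFs, truth CSV, and a manifest CSV.

    Returns the manifest path.  The manifest has one row per written frame
    with the sample descriptor columns inlined, so a counting run can be
    reconstructed from the manifest alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for sample in samples:
        for role, frames in sample.frames.items():
            for i, frame in enumerate(frames):
                fname = f"{sample.sample_id}_f{i}_{role}.tif"
                tifffile.imwrite(outdir / fname, frame.pixels)
                row = {
                    "sample_id": sample.sample_id,
                    "field": i,
                    "channel_role": role,
                    "file": fname,
                    "pixel_area_um2": frame.pixel_area,
                    "bit_depth": frame.bit_depth,
                }
                row.update(sample.descriptor)
                manifest_rows.append(row)
        for i, truth in enumerate(sample.truths):
            for j, obj in enumerate(truth.objects):
                truth_rows.append(
                    {
                        "sample_id": sample.sample_id,
                        "field": i,
                        "object_id": j,
                        "class": obj.cls,
                        "viability": obj.viability,
                        "centroid_x_um": obj.x_um,
                        "centroid_y_um": obj.y_um,
                        "diameter_um": obj.diameter_um,
                        "length_um": obj.length_um,
                        "width_um": obj.width_um,
                        "orientation_rad": obj.orientation_rad,
                        "peak_intensity": obj.peak_intensity,
                    }
                )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
    return manifest


def read_manifest(manifest: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(manifest))


def read_frames(
    manifest: str | Path, sample_id: str, channel_role: str | None = None
) -> list[ImageFrame]:
    """Load the frames of one sample listed in a manifest."""
    manifest = Path(manifest)
    df = read_manifest(manifest)
    rows = df[df["sample_id"] == sample_id]
    if channel_role is not None:
        rows = rows[rows["channel_role"] == channel_role]
    if rows.empty:
        raise FileNotFoundError(
            f"no frames for sample {sample_id!r}"
            + (f" role {channel_role!r}" if channel_role else "")
        )
    frames = []
    missing = []
    for _, row in rows.sort_values("field").iterrows():
        path = manifest.parent / row["file"]
        if not path.exists():
            missing.append(str(path))
            continue
        frames.append(
            ImageFrame(
                pixels=tifffile.imread(path),
                pixel_area=float(row["pixel_area_um2"]),
                channel_role=str(row["channel_role"]),
                frame_id=f"{sample_id}_f{row['field']}",
                bit_depth=int(row.get("bit_depth", 16)),
            )
        )
    if missing:
        raise FileNotFoundError(f"missing frame files: {missing}")
    return frames


def write_results(
    results: Sequence[tuple[str, CountResult]], path: str | Path
) -> Path:
    """Write (sample_id, CountResult) pairs as a results CSV."""
    rows = [
        {
            "sample_id": sid,
            "population": r.population,
            "raw_count": r.raw_count,
            "fields": r.fields_used,
            "concentration_cells_per_ml": r.concentration,
            "chamber_concentration_cells_per_ml": r.chamber_concentration,
            "viability": r.viability,
            "spillover_count": r.spillover_count,
        }
        for sid, r in results
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_provenance(outdir: str | Path, config: dict) -> Path:
    """Write the machine-readable provenance record for a run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "mixcount_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "config": config,
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
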