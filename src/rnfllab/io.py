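"""Serialization: TIFF thickness/percentile grids with JSON sidecars.

Thickness maps are stored as single-page 32-bit float TIFFs next to a JSON
sidecar holding pixel size, landmarks, laterality, age, view/frame tags,
layer and optional ground-truth labels.  Normative models are stored as a
directory with a two-page TIFF (slope, intercept), a residual-stack TIFF and
a JSON manifest.  Cohorts get a CSV manifest with one row per eye.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .normative import NormativeModel, ProbabilityMap, categorize
from .simulate import EyeAnatomy, SimulatedEye, ThicknessMap


def save_thickness_map(tmap: ThicknessMap, path: str | Path, labels: dict | None = None) -> Path:
    """Write ``<path>.tif`` and ``<path>.json``; returns the TIFF path."""
    base = Path(path)
    tif = base.with_suffix(".tif")
    tifffile.imwrite(tif, np.asarray(tmap.values, dtype=np.float32))
    sidecar = {
        "pixel_size_mm": list(tmap.pixel_size),
        "view": tmap.view,
        "frame": tmap.frame,
        "layer": tmap.layer,
        "anatomy": tmap.anatomy.to_dict(),
        "labels": labels or {},
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return tif


def load_thickness_map(path: str | Path) -> ThicknessMap:
    base = Path(path)
    values = tifffile.imread(base.with_suffix(".tif"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return ThicknessMap(
        values=np.asarray(values, dtype=np.float32),
        pixel_size=tuple(meta["pixel_size_mm"]),
        view=meta["view"],
        anatomy=EyeAnatomy.from_dict(meta["anatomy"]),
        layer=meta["layer"],
        frame=meta.get("frame", "native"),
    )


def save_pmap(pmap: ProbabilityMap, path: str | Path) -> Path:
    base = Path(path)
    tif = base.with_suffix(".tif")
    tifffile.imwrite(tif, np.asarray(pmap.percentile, dtype=np.float32))
    sidecar = {
        "pixel_size_mm": list(pmap.pixel_size),
        "view": pmap.view,
        "frame": pmap.frame,
        "layer": pmap.layer,
        "red_threshold": pmap.red_threshold,
        "yellow_threshold": pmap.yellow_threshold,
        "anatomy": pmap.anatomy.to_dict(),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return tif


def load_pmap(path: str | Path) -> ProbabilityMap:
    base = Path(path)
    pct = np.asarray(tifffile.imread(base.with_suffix(".tif")), dtype=np.float64)
    meta = json.loads(base.with_suffix(".json").read_text())
    return ProbabilityMap(
        percentile=pct,
        category=categorize(pct, meta["red_threshold"], meta["yellow_threshold"]),
        anatomy=EyeAnatomy.from_dict(meta["anatomy"]),
        layer=meta["layer"],
        pixel_size=tuple(meta["pixel_size_mm"]),
        view=meta["view"],
        frame=meta["frame"],
        red_threshold=meta["red_threshold"],
        yellow_threshold=meta["yellow_threshold"],
    )


def save_normative_model(model: NormativeModel, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "regression.tif", np.stack([model.slope, model.intercept]))
    tifffile.imwrite(d / "residuals.tif", model.residuals_sorted)
    (d / "manifest.json").write_text(
        json.dumps(
            {
                "n_reference": model.n_reference,
                "age_range": list(model.age_range),
                "layer": model.layer,
                "pixel_size_mm": list(model.pixel_size),
            },
            indent=2,
        )
    )
    return d


def load_normative_model(directory: str | Path) -> NormativeModel:
    d = Path(directory)
    reg = tifffile.imread(d / "regression.tif")
    residuals = np.asarray(tifffile.imread(d / "residuals.tif"), dtype=np.float32)
    meta = json.loads((d / "manifest.json").read_text())
    return NormativeModel(
        slope=np.asarray(reg[0], dtype=np.float32),
        intercept=np.asarray(reg[1], dtype=np.float32),
        residuals_sorted=residuals,
        n_reference=int(meta["n_reference"]),
        age_range=tuple(meta["age_range"]),
        layer=meta["layer"],
        pixel_size=tuple(meta["pixel_size_mm"]),
    )


def cohort_manifest(eyes: Sequence[SimulatedEye]) -> pd.DataFrame:
    rows = []
    for e in eyes:
        rows.append(
            {
                "eye_id": e.eye_id,
                "group": e.group,
                "laterality": e.thickness.anatomy.laterality,
                "age": e.thickness.anatomy.age,
                "mechanism": e.mechanism,
                "displaced": e.displaced,
                "defect_kind": e.defect.kind,
                "defect_depth": e.defect.depth_fraction,
                "md_242": e.md_242,
                "abnormal_hemifield": e.abnormal_hemifield,
            }
        )
    return pd.DataFrame(rows)


def save_cohort(eyes: Sequence[SimulatedEye], directory: str | Path) -> Path:
    """Write per-eye TIFF/JSON pairs plus a cohort CSV manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for e in eyes:
        save_thickness_map(
            e.thickness, d / f"{e.eye_id}_RNFL",
            labels={"group": e.group, "mechanism": e.mechanism, "md_242": e.md_242},
        )
        if e.gcl is not None:
            save_thickness_map(e.gcl, d / f"{e.eye_id}_GCLplus", labels={"group": e.group})
    cohort_manifest(eyes).to_csv(d / "manifest.csv", index=False)
    return d
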