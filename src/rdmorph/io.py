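"""Readers and writers for the pipeline's on-disk formats.

Images travel as TIFF (16-bit phantom tiles, 8-bit label masks with 0
background / 1 RPE / 2 ONL / 3 INL), ground truth and ROIs as JSON,
profiles and cohorts as CSV, parameters as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import ThicknessProfile
from .phantom import CohortDesign, GroundTruth, PhantomSpec
from .regions import RegionOfInterest


def write_tile(out_dir, image: np.ndarray, labels: np.ndarray, gt: GroundTruth) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "tile.tif", image.astype(np.uint16))
    tifffile.imwrite(out / "labels.tif", labels.astype(np.uint8))
    (out / "ground_truth.json").write_text(json.dumps(_jsonable(gt), indent=1))


def read_tile(in_dir):
    p = Path(in_dir)
    image = tifffile.imread(p / "tile.tif")
    labels = tifffile.imread(p / "labels.tif")
    gt = None
    gt_path = p / "ground_truth.json"
    if gt_path.exists():
        d = json.loads(gt_path.read_text())
        fields = {f.name for f in dataclasses.fields(GroundTruth)}
        d = {k: v for k, v in d.items() if k in fields}
        for k in ("centroids_rc", "centroid_arc_um", "centroid_radius_um",
                  "rpe_curve", "onl_outer_curve", "onl_arc_um"):
            d[k] = np.asarray(d[k], dtype=float)
        d["region_intervals_um"] = {
            k: tuple(v) for k, v in d["region_intervals_um"].items()
        }
        for k in ("attached_onl_interval_um", "detached_onl_interval_um"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        gt = GroundTruth(**d)
    return image, labels, gt


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_profile_csv(path, profiles: list[ThicknessProfile]) -> None:
    frames = []
    for p in profiles:
        df = pd.DataFrame({
            "layer": p.layer,
            "arc_um": p.arc_um,
            "thickness_um": p.thickness_um,
        })
        if p.station_xy is not None:
            df["station_row"] = p.station_xy[:, 0]
            df["station_col"] = p.station_xy[:, 1]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profile_csv(path) -> dict[str, ThicknessProfile]:
    df = pd.read_csv(path)
    out = {}
    for layer, grp in df.groupby("layer"):
        xy = None
        if {"station_row", "station_col"} <= set(grp.columns):
            xy = grp[["station_row", "station_col"]].to_numpy()
        out[layer] = ThicknessProfile(
            layer=str(layer),
            arc_um=grp.arc_um.to_numpy(),
            thickness_um=grp.thickness_um.to_numpy(),
            calliper_interval_px=1.0,
            station_xy=xy,
        )
    return out


def write_rois_json(path, rois: dict[str, RegionOfInterest]) -> None:
    payload = {
        name: {
            "name": r.name,
            "arc_start_um": r.arc_start_um,
            "arc_end_um": r.arc_end_um,
            "polygon": None if r.polygon is None else r.polygon.tolist(),
        }
        for name, r in rois.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois_json(path) -> dict[str, RegionOfInterest]:
    payload = json.loads(Path(path).read_text())
    return {
        name: RegionOfInterest(
            d["name"], d["arc_start_um"], d["arc_end_um"],
            None if d["polygon"] is None else np.asarray(d["polygon"], dtype=float),
        )
        for name, d in payload.items()
    }


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal_id", "day", "region", "onl_count", "onl_inl_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def read_phantom_spec_yaml(path) -> PhantomSpec:
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if "image_shape" in data:
        data["image_shape"] = tuple(data["image_shape"])
    return PhantomSpec(**data)


def read_design_yaml(path) -> CohortDesign:
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    return CohortDesign(pd.DataFrame(data["cells"]))
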