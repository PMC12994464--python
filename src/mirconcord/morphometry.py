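"""Nuclear morphometry from detection-centroid tables.

Works from the tables exported by image-analysis software (one row per
detected nucleus: centroid x/y and area, in calibrated micrometres) plus a
polygonal region of interest.  Produces the summary used to compare groups:
nucleus count, ROI area, nuclear density per 1000 um^2, mean nearest-
neighbour inter-nuclear distance and mean nuclear area.

Nearest-neighbour distances are raw (no edge correction): a nucleus near
the ROI boundary may have its true nearest neighbour outside the imaged
region, which biases the mean slightly upward.  ``nn_distances`` exposes the
per-nucleus values so callers can apply minus-sampling if they need an
unbiased spatial statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

DEFAULT_COLUMNS = {"x": "Centroid X µm", "y": "Centroid Y µm", "area": "Nucleus: Area"}


@dataclass
class MorphometrySummary:
    n_nuclei: int
    roi_area_um2: float
    density_per_1000um2: float
    mean_nn_distance_um: float | None
    mean_nuclear_area_um2: float | None


def pixel_calibration(n_pixels: int, field_um: float) -> float:
    """Micrometres per pixel for a field of ``n_pixels`` spanning ``field_um``."""
    if n_pixels <= 0 or field_um <= 0:
        raise ValueError("pixel count and field size must be positive")
    return field_um / n_pixels


def make_polygon(vertices) -> Polygon:
    """Validated ROI polygon from an (n, 2) vertex ring."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("ROI needs at least 3 (x, y) vertices")
    if not np.isfinite(verts).all():
        raise ValueError("non-finite ROI vertex")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ValueError("self-intersecting ROI polygon")
    if poly.area <= 0:
        raise ValueError("ROI polygon has zero area")
    return poly


def polygon_area(roi) -> float:
    """Absolute (shoelace) area of the ROI, orientation-independent."""
    poly = roi if isinstance(roi, Polygon) else make_polygon(roi)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("invalid ROI polygon")
    return float(poly.area)


def load_detections(path: str | Path, columns: dict | None = None) -> pd.DataFrame:
    """Read a nucleus-detection CSV into columns x_um, y_um, area_um2."""
    raw = pd.read_csv(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if set(("x_um", "y_um", "area_um2")) <= set(raw.columns):
        df = raw[["x_um", "y_um", "area_um2"]].copy()
    else:
        missing = [c for c in cols.values() if c not in raw.columns]
        if missing:
            raise ValueError(f"{path}: missing detection columns {missing}")
        df = pd.DataFrame(
            {"x_um": raw[cols["x"]], "y_um": raw[cols["y"]], "area_um2": raw[cols["area"]]}
        )
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
        raise ValueError("non-finite centroid coordinates")
    if (df["area_um2"] <= 0).any():
        raise ValueError("nuclear areas must be positive")
    return df


def load_roi(path: str | Path) -> Polygon:
    """ROI from a vertex CSV (columns x_um, y_um or x, y) or GeoJSON polygon."""
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        import json

        with open(path) as fh:
            obj = json.load(fh)
        geom = obj.get("geometry", obj)
        if geom.get("type") != "Polygon":
            raise ValueError("ROI GeoJSON must be a Polygon")
        return make_polygon(geom["coordinates"][0][:-1])
    df = pd.read_csv(path)
    cols = ["x_um", "y_um"] if "x_um" in df.columns else list(df.columns[:2])
    return make_polygon(df[cols].to_numpy())


def points_in_roi(nuclei: pd.DataFrame, roi: Polygon) -> np.ndarray:
    """Boolean mask of nuclei inside the ROI (boundary counts as inside)."""
    return np.array(
        [roi.covers(Point(x, y)) for x, y in zip(nuclei["x_um"], nuclei["y_um"])]
    )


def nuclear_density(nuclei: pd.DataFrame, roi: Polygon) -> tuple[int, float]:
    """Nucleus count inside the ROI and density per 1000 um^2."""
    area = polygon_area(roi)
    count = int(points_in_roi(nuclei, roi).sum())
    return count, 1000.0 * count / area


def nn_distances(nuclei: pd.DataFrame) -> np.ndarray:
    """Per-nucleus Euclidean distance to its nearest other centroid."""
    pts = nuclei[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(pts) < 2:
        raise ValueError("nearest-neighbour distances need at least 2 nuclei")
    d, _ = cKDTree(pts).query(pts, k=2)
    return d[:, 1]


def mean_nn_distance(nuclei: pd.DataFrame) -> float:
    """Mean nearest-neighbour inter-nuclear distance (um), uncorrected."""
    return float(nn_distances(nuclei).mean())


def mean_pairwise_distance(nuclei: pd.DataFrame) -> float:
    """Mean over all distinct centroid pairs (scales with ROI extent)."""
    pts = nuclei[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(pts) < 2:
        raise ValueError("pairwise distances need at least 2 nuclei")
    from scipy.spatial.distance import pdist

    return float(pdist(pts).mean())


def summarize(nuclei: pd.DataFrame, roi: Polygon) -> MorphometrySummary:
    """Full morphometry summary for one ROI (nuclei filtered to the ROI)."""
    inside = nuclei[points_in_roi(nuclei, roi)]
    area = polygon_area(roi)
    n = len(inside)
    return MorphometrySummary(
        n_nuclei=n,
        roi_area_um2=area,
        density_per_1000um2=1000.0 * n / area,
        mean_nn_distance_um=mean_nn_distance(inside) if n >= 2 else None,
        mean_nuclear_area_um2=float(inside["area_um2"].mean()) if n else None,
    )
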