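"""Reading QuPath-style detection exports and cohort manifests.

Two detection dialects are supported, both of which occur in the wild:

* **GeoJSON** — an RFC 7946 ``FeatureCollection`` whose features are nucleus
  detections (``Point`` geometry, or a ``Polygon`` nucleus boundary that is
  reduced to its centroid) with the class stored under
  ``properties.classification.name``.
* **TSV** — a measurement table with columns ``Centroid X µm``,
  ``Centroid Y µm`` and ``Class``.

Windows travel as GeoJSON ``Polygon`` features: the exterior ring is the
square region annotation, interior rings are the cleaved holes.

Class labels are normalized through a configurable map; by default
``Tumor`` (any case) maps to ``tumor`` and every other known label to
``non_tumor``.  The cohort manifest is a CSV with one row per patient:
``patient_id, grade, metastatic, roi1..roi3, win1..win3``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import shape

from .geometry import PointPattern, Window

__all__ = [
    "PatientRecord",
    "read_detections",
    "read_window",
    "write_window",
    "write_detections",
    "build_roi_pattern",
    "load_cohort",
]

#: default normalization of QuPath free-text classes
DEFAULT_CLASS_MAP = {
    "tumor": "tumor",
    "stroma": "non_tumor",
    "non-tumor": "non_tumor",
    "non_tumor": "non_tumor",
    "nontumor": "non_tumor",
    "immune cells": "non_tumor",
    "other": "non_tumor",
}


class FormatError(ValueError):
    """Raised when a detection or window file does not parse."""


@dataclass
class PatientRecord:
    """One patient: id, grade, metastasis flag, and three ROI patterns."""

    patient_id: str
    grade: int
    metastatic: bool
    roi_patterns: list[PointPattern]
    mean_pcf: object | None = None  # PCFCurve, filled by the pipeline
    spatial_group: int | None = None
    regime: str | None = None  # ground truth for synthetic cohorts

    def __post_init__(self):
        if self.grade not in (2, 3):
            raise ValueError(f"grade must be 2 or 3, got {self.grade}")
        if len(self.roi_patterns) != 3:
            raise ValueError(
                f"patient {self.patient_id}: expected exactly 3 ROI patterns, "
                f"got {len(self.roi_patterns)}"
            )


def _normalize_class(name: str, class_map: dict[str, str]) -> str:
    key = name.strip().lower()
    if key in class_map:
        return class_map[key]
    raise FormatError(
        f"unknown detection class {name!r}; extend the class map to handle it"
    )


def read_detections(
    path, dialect: str | None = None, class_map: dict[str, str] | None = None
) -> list[tuple[float, float, str]]:
    """Read nucleus detections as (x µm, y µm, normalized class) records.

    The dialect (``geojson`` or ``tsv``) is inferred from the file extension
    unless given.  Polygon nuclei are reduced to their centroid.
    """
    path = Path(path)
    class_map = {**DEFAULT_CLASS_MAP, **{k.lower(): v for k, v in (class_map or {}).items()}}
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".txt", ".csv") else "geojson"
    if dialect == "geojson":
        return _read_detections_geojson(path, class_map)
    if dialect == "tsv":
        return _read_detections_tsv(path, class_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_detections_geojson(path: Path, class_map) -> list[tuple[float, float, str]]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid JSON ({e})") from e
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        if gtype == "Point":
            x, y = geom["coordinates"][:2]
        elif gtype == "Polygon":
            c = shape(geom).centroid
            x, y = c.x, c.y
        else:
            raise FormatError(f"{path}: unsupported geometry type {gtype!r}")
        props = feat.get("properties") or {}
        cls = props.get("classification") or {}
        name = cls.get("name") if isinstance(cls, dict) else cls
        if name is None:
            name = props.get("class", "")
        out.append((float(x), float(y), _normalize_class(str(name), class_map)))
    return out


def _read_detections_tsv(path: Path, class_map) -> list[tuple[float, float, str]]:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as e:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"{path}: cannot parse TSV ({e})") from e
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        xcol = next(cols[k] for k in cols if k.startswith("centroid x"))
        ycol = next(cols[k] for k in cols if k.startswith("centroid y"))
        ccol = cols["class"]
    except (StopIteration, KeyError) as e:
        raise FormatError(
            f"{path}: need 'Centroid X µm', 'Centroid Y µm' and 'Class' columns"
        ) from e
    return [
        (float(x), float(y), _normalize_class(str(c), class_map))
        for x, y, c in zip(df[xcol], df[ycol], df[ccol])
    ]


def _is_square(ring: np.ndarray, rtol: float = 1e-6) -> bool:
    if len(ring) != 4:
        return False
    xs = np.unique(np.round(ring[:, 0], 6))
    ys = np.unique(np.round(ring[:, 1], 6))
    if len(xs) != 2 or len(ys) != 2:
        return False
    return bool(np.isclose(xs[1] - xs[0], ys[1] - ys[0], rtol=rtol))


def read_window(path, allow_bbox_fallback: bool = False) -> Window:
    """Read a window (square region annotation + hole rings) from GeoJSON."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid JSON ({e})") from e
    if doc.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in doc["features"]]
    elif doc.get("type") == "Feature":
        geoms = [doc["geometry"]]
    else:
        geoms = [doc]
    polys = [g for g in geoms if g.get("type") == "Polygon"]
    if not polys:
        raise FormatError(f"{path}: no Polygon geometry found")
    rings = polys[0]["coordinates"]
    outer = np.asarray(rings[0], dtype=float)
    if np.allclose(outer[0], outer[-1]):
        outer = outer[:-1]
    holes = []
    for ring in rings[1:]:
        h = np.asarray(ring, dtype=float)
        if np.allclose(h[0], h[-1]):
            h = h[:-1]
        holes.append(h)
    if not _is_square(outer):
        if not allow_bbox_fallback:
            raise FormatError(f"{path}: outer ring is not an axis-aligned square")
        import warnings

        warnings.warn(f"{path}: non-square outer ring, falling back to bounding box")
    x0, y0 = outer[:, 0].min(), outer[:, 1].min()
    side_x = outer[:, 0].max() - x0
    side_y = outer[:, 1].max() - y0
    return Window(origin=(x0, y0), side=float(max(side_x, side_y)), holes=tuple(holes))


def write_window(w: Window, path) -> None:
    """Write a window as a GeoJSON Polygon (exterior square + hole rings)."""
    x0, y0 = w.origin
    s = w.side
    ext = [[x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s], [x0, y0]]
    rings = [ext] + [[list(map(float, v)) for v in h] + [list(map(float, h[0]))] for h in w.holes]
    doc = {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": rings},
        "properties": {"object_type": "annotation"},
    }
    Path(path).write_text(json.dumps(doc))


def write_detections(p: PointPattern, path, class_names: dict[str, str] | None = None) -> None:
    """Write a pattern's points as a GeoJSON FeatureCollection of detections."""
    class_names = class_names or {"tumor": "Tumor", "non_tumor": "Stroma", "random_cell": "Random"}
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"classification": {"name": class_names.get(m, m)}},
        }
        for (x, y), m in zip(p.points, p.marks)
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def build_roi_pattern(
    detections: list[tuple[float, float, str]],
    w: Window,
    keep: str | None = "tumor",
) -> PointPattern:
    """Assemble an ROI point pattern from detections inside a window.

    Detections outside the window (or inside holes) are dropped with a
    logged count; only the `keep` mark is retained (None keeps all marks).
    An empty result is returned with a warning rather than an error.
    """
    if detections:
        pts = np.array([(d[0], d[1]) for d in detections], dtype=float)
        marks = np.array([d[2] for d in detections], dtype=object)
    else:
        pts = np.empty((0, 2))
        marks = np.empty(0, dtype=object)
    if keep is not None:
        sel = marks == keep
        pts, marks = pts[sel], marks[sel]
    if len(pts):
        inside = w.contains(pts)
        n_dropped = int((~inside).sum())
        if n_dropped:
            import logging

            logging.getLogger(__name__).info(
                "dropped %d detection(s) outside the window", n_dropped
            )
        pts, marks = pts[inside], marks[inside]
    if len(pts) == 0:
        import warnings

        warnings.warn("ROI pattern is empty after filtering")
    return PointPattern(w, pts, marks)


def load_cohort(manifest_path, keep: str | None = "tumor") -> list[PatientRecord]:
    """Load a cohort manifest CSV into PatientRecords; fail fast with a
    complete report of all invalid rows."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    records, errors = [], []
    with open(manifest_path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                grade = int(row["grade"])
                met = str(row["metastatic"]).strip().lower() in ("1", "true", "yes")
                rois = [row.get(f"roi{k}", "").strip() for k in (1, 2, 3)]
                wins = [row.get(f"win{k}", "").strip() for k in (1, 2, 3)]
                if any(not r for r in rois) or any(not w for w in wins):
                    raise ValueError("need roi1..roi3 and win1..win3 paths")
                patterns = []
                for rp, wp in zip(rois, wins):
                    win = read_window(base / wp)
                    det = read_detections(base / rp)
                    patterns.append(build_roi_pattern(det, win, keep=keep))
                records.append(
                    PatientRecord(
                        patient_id=row["patient_id"],
                        grade=grade,
                        metastatic=met,
                        roi_patterns=patterns,
                        regime=row.get("regime") or None,
                    )
                )
            except Exception as e:  # noqa: BLE001 - collected into the report
                errors.append(f"row {i} ({row.get('patient_id', '?')}): {e}")
    if errors:
        raise ValueError("invalid manifest rows:\n  " + "\n  ".join(errors))
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id in manifest")
    return records
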