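"""Reading and writing slide annotations and cohort tables.

Slide annotations hold the outputs of upstream segmentation models: nuclear
centroids classified as ``epithelial`` or ``iel`` (intra-epithelial
lymphocyte), and dysplasia regions as closed polygons, all in pixel
coordinates at a stated resolution (microns per pixel, mpp). The interchange
format is a GeoJSON FeatureCollection in the de-facto viewer dialect: point
geometry = nucleus centroid, polygon geometry = dysplasia region, with the
class carried in ``properties.classification.name``. Binary masks (PNG/TIFF)
plus a points CSV are accepted as an alternative region source.

Cohort tables are plain CSV with one row per slide: demographics, intraoral
site, scanner, WHO and binary dysplasia grades, transformation outcome and
follow-up months, and optionally 12 binary histological features, each rated
by three pathologists (columns ``<feature>__r1..r3``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

__all__ = [
    "NUCLEUS_CLASSES",
    "DEFAULT_CLASS_MAP",
    "HISTOLOGICAL_FEATURES",
    "NucleusRecord",
    "SlideAnnotation",
    "CohortRecord",
    "read_annotation",
    "write_annotation",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "rescale_annotation",
    "mask_to_polygons",
]

NUCLEUS_CLASSES = ("epithelial", "iel")

#: Default mapping from upstream label vocabularies to our two classes.
#: Upstream nuclear classifiers emit "epithelial" vs "other" within the
#: epithelium; the "other" intra-epithelial nuclei are treated as IELs.
DEFAULT_CLASS_MAP: dict[str, str] = {
    "epithelial": "epithelial",
    "other": "iel",
    "lymphocyte": "iel",
    "iel": "iel",
}

#: The 12 pathologist-rated binary histological features of oral epithelial
#: dysplasia used by the point-based prognostic models.
HISTOLOGICAL_FEATURES = (
    "basal_cell_hyperplasia",
    "bulbous_rete_pegs",
    "dyskeratosis",
    "hyperchromatism",
    "irregular_surface_keratin",
    "loss_of_epithelial_cohesion",
    "loss_of_stratification",
    "suprabasal_mitoses",
    "nuclear_pleomorphism",
    "abrupt_orthokeratosis",
    "lymphocytic_band",
    "verrucous_surface",
)

SEXES = ("female", "male")
SITES = ("buccal_mucosa", "tongue", "floor_of_mouth", "other")
SCANNERS = ("aperio_cs2", "nanozoomer_s360", "p1000")
WHO_GRADES = ("mild", "moderate", "severe")
BINARY_GRADES = ("low", "high")


@dataclass(frozen=True)
class NucleusRecord:
    """One detected nucleus: centroid in pixels at base resolution."""

    x: float
    y: float
    cls: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite nucleus centroid ({self.x}, {self.y})")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"negative nucleus centroid ({self.x}, {self.y})")
        if self.cls not in NUCLEUS_CLASSES:
            raise ValueError(f"unknown nucleus class {self.cls!r}")


@dataclass
class SlideAnnotation:
    """Nuclear detections + dysplasia polygons for one slide.

    Coordinates are 0-based pixel coordinates at ``base_mpp`` microns per
    pixel, x rightward and y downward (image convention). Polygons are closed
    vertex lists (the closing vertex may be omitted).
    """

    slide_id: str
    nuclei: list[NucleusRecord]
    regions: list[np.ndarray]
    base_mpp: float
    scanner: str | None = None

    def __post_init__(self) -> None:
        if not self.base_mpp > 0:
            raise ValueError(f"base_mpp must be > 0, got {self.base_mpp}")
        clean = []
        for verts in self.regions:
            arr = np.asarray(verts, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("region must be an (n, 2) vertex array")
            # drop an explicit closing vertex
            if len(arr) > 1 and np.allclose(arr[0], arr[-1]):
                arr = arr[:-1]
            if len(arr) < 3:
                warnings.warn(
                    f"slide {self.slide_id}: dropping region with "
                    f"{len(arr)} vertices (< 3)",
                    stacklevel=2,
                )
                continue
            if Polygon(arr).area == 0:
                warnings.warn(
                    f"slide {self.slide_id}: dropping degenerate zero-area region",
                    stacklevel=2,
                )
                continue
            clean.append(arr)
        self.regions = clean

    # -- convenience accessors ------------------------------------------------

    def nucleus_coords(self, cls: str | None = None) -> np.ndarray:
        """Centroids as an (n, 2) array, optionally restricted to one class."""
        recs = self.nuclei if cls is None else [n for n in self.nuclei if n.cls == cls]
        if not recs:
            return np.empty((0, 2))
        return np.array([(n.x, n.y) for n in recs], dtype=float)

    def region_union(self) -> shapely.Geometry:
        """Union of all dysplasia polygons (overlaps merged)."""
        return unary_union([Polygon(r) for r in self.regions])

    def region_area_px2(self) -> float:
        """Total dysplasia area in px² at base resolution (union of polygons)."""
        if not self.regions:
            return 0.0
        return float(self.region_union().area)

    def region_area_mm2(self) -> float:
        """Total dysplasia area in mm² (1 px² at m mpp = m² × 1e-6 mm²)."""
        return self.region_area_px2() * self.base_mpp**2 * 1e-6


@dataclass
class CohortRecord:
    """Clinical covariates and outcome for one slide."""

    slide_id: str
    patient_id: str
    age: float
    sex: str
    site: str
    scanner: str
    who_grade: str
    binary_grade: str
    transformed: bool
    months: float
    features: dict[str, tuple[int, int, int]] | None = None

    def __post_init__(self) -> None:
        for value, levels, name in (
            (self.sex, SEXES, "sex"),
            (self.site, SITES, "site"),
            (self.scanner, SCANNERS, "scanner"),
            (self.who_grade, WHO_GRADES, "who_grade"),
            (self.binary_grade, BINARY_GRADES, "binary_grade"),
        ):
            if value not in levels:
                raise ValueError(f"unknown {name} level {value!r}; expected one of {levels}")
        if not self.months >= 0:
            raise ValueError(f"months must be >= 0, got {self.months}")
        if self.features is not None:
            for name, votes in self.features.items():
                if name not in HISTOLOGICAL_FEATURES:
                    raise ValueError(f"unknown histological feature {name!r}")
                if len(votes) != 3 or any(v not in (0, 1) for v in votes):
                    raise ValueError(f"feature {name!r} needs exactly 3 binary votes")


# -- GeoJSON ------------------------------------------------------------------


def _feature_class(props: Mapping, class_map: Mapping[str, str]) -> str:
    raw = props.get("classification")
    if isinstance(raw, Mapping):
        raw = raw.get("name")
    if raw is None:
        raw = props.get("class")
    if raw is None:
        raise ValueError("point feature has no classification")
    key = str(raw).strip().lower()
    if key not in class_map:
        raise ValueError(
            f"unknown nucleus class label {raw!r}; supply a class mapping for it"
        )
    return class_map[key]


def _read_geojson(path: Path, class_map: Mapping[str, str], mpp: float | None,
                  slide_id: str | None) -> SlideAnnotation:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    meta = doc.get("properties", {})
    base_mpp = mpp if mpp is not None else meta.get("mpp")
    if base_mpp is None:
        raise ValueError(f"{path}: no mpp in file metadata and none supplied")
    nuclei: list[NucleusRecord] = []
    regions: list[np.ndarray] = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        if gtype == "Point":
            x, y = geom["coordinates"][:2]
            cls = _feature_class(feat.get("properties", {}), class_map)
            nuclei.append(NucleusRecord(float(x), float(y), cls))
        elif gtype == "Polygon":
            regions.append(np.asarray(geom["coordinates"][0], dtype=float))
        elif gtype == "MultiPolygon":
            for poly in geom["coordinates"]:
                regions.append(np.asarray(poly[0], dtype=float))
        else:
            warnings.warn(f"{path}: skipping unsupported geometry {gtype!r}", stacklevel=2)
    return SlideAnnotation(
        slide_id=slide_id or meta.get("slide_id") or path.stem,
        nuclei=nuclei,
        regions=regions,
        base_mpp=float(base_mpp),
        scanner=meta.get("scanner"),
    )


def mask_to_polygons(mask: np.ndarray) -> list[np.ndarray]:
    """Convert a binary mask to region polygons by boundary tracing.

    Each 4-connected foreground component becomes one polygon whose interior
    is exactly the union of its pixel squares (pixel (i, j) covers
    [j, j+1) x [i, i+1)), so polygon area equals the filled-pixel count.
    """
    from skimage.measure import label

    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    labeled = label(mask > 0, connectivity=1)
    polygons: list[np.ndarray] = []
    for lab in range(1, labeled.max() + 1):
        rows, cols = np.nonzero(labeled == lab)
        # one box per horizontal run to keep the union cheap
        boxes = []
        for r in np.unique(rows):
            cs = np.sort(cols[rows == r])
            splits = np.split(cs, np.nonzero(np.diff(cs) > 1)[0] + 1)
            for run in splits:
                boxes.append(box(run[0], r, run[-1] + 1, r + 1))
        geom = unary_union(boxes)
        polys = getattr(geom, "geoms", [geom])
        for p in polys:
            polygons.append(np.asarray(p.exterior.coords)[:-1])
    return polygons


def _read_points_csv(path: Path, class_map: Mapping[str, str]) -> list[NucleusRecord]:
    df = pd.read_csv(path)
    for col in ("x", "y", "class"):
        if col not in df.columns:
            raise ValueError(f"{path}: points CSV missing column {col!r}")
    nuclei = []
    for x, y, raw in zip(df["x"], df["y"], df["class"]):
        nuclei.append(NucleusRecord(float(x), float(y),
                                    _feature_class({"class": raw}, class_map)))
    return nuclei


def read_annotation(
    path: str | Path,
    format: str = "geojson",
    *,
    mpp: float | None = None,
    mask_path: str | Path | None = None,
    class_map: Mapping[str, str] | None = None,
    slide_id: str | None = None,
    scanner: str | None = None,
) -> SlideAnnotation:
    """Read a :class:`SlideAnnotation` from disk.

    Parameters
    ----------
    path
        GeoJSON file (``format="geojson"``) or points CSV with columns
        x, y, class (``format="csv_points_plus_mask"``).
    format
        ``"geojson"`` or ``"csv_points_plus_mask"``.
    mpp
        Microns per pixel at which the coordinates are expressed. Mandatory
        for mask input (unless a ``<path stem>.json`` sidecar provides it);
        overrides file metadata for GeoJSON.
    mask_path
        Binary region mask (PNG/TIFF) for ``csv_points_plus_mask``; defaults
        to ``<path stem>.mask.png``.
    class_map
        Extra label -> class mappings, merged over the defaults
        (``other``/``lymphocyte`` -> ``iel``). Keys are lower-cased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_CLASS_MAP)
    if class_map:
        cmap.update({str(k).strip().lower(): v for k, v in class_map.items()})

    if format == "geojson":
        ann = _read_geojson(path, cmap, mpp, slide_id)
    elif format == "csv_points_plus_mask":
        sidecar = path.with_suffix(".json")
        if mpp is None and sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
            mpp = meta.get("mpp")
            slide_id = slide_id or meta.get("slide_id")
            scanner = scanner or meta.get("scanner")
        if mpp is None:
            raise ValueError("mask input requires an mpp value (argument or JSON sidecar)")
        if mask_path is None:
            mask_path = path.with_suffix(".mask.png")
        import imageio.v3 as iio

        mask = iio.imread(mask_path)
        if mask.ndim == 3:
            mask = mask[..., 0]
        ann = SlideAnnotation(
            slide_id=slide_id or path.stem,
            nuclei=_read_points_csv(path, cmap),
            regions=mask_to_polygons(mask),
            base_mpp=float(mpp),
            scanner=scanner,
        )
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if scanner is not None:
        ann.scanner = scanner
    return ann


def write_annotation(ann: SlideAnnotation, path: str | Path) -> None:
    """Write a :class:`SlideAnnotation` as a GeoJSON FeatureCollection."""
    features = []
    for n in ann.nuclei:
        label = "epithelial" if n.cls == "epithelial" else "other"
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [n.x, n.y]},
                "properties": {"classification": {"name": label}},
            }
        )
    for verts in ann.regions:
        ring = np.vstack([verts, verts[:1]]).tolist()
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"classification": {"name": "dysplasia"}},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "slide_id": ann.slide_id,
            "mpp": ann.base_mpp,
            "scanner": ann.scanner,
        },
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def rescale_annotation(ann: SlideAnnotation, target_mpp: float) -> SlideAnnotation:
    """Return a copy of ``ann`` with coordinates expressed at ``target_mpp``.

    Coordinates are multiplied by ``base_mpp / target_mpp``; nucleus and
    region counts are unchanged. Count-based scores are unaffected by this
    operation; areas in mm² are likewise preserved because the px -> mm
    conversion uses the (new) mpp.
    """
    if not target_mpp > 0:
        raise ValueError(f"target_mpp must be > 0, got {target_mpp}")
    f = ann.base_mpp / target_mpp
    nuclei = [NucleusRecord(n.x * f, n.y * f, n.cls) for n in ann.nuclei]
    regions = [r * f for r in ann.regions]
    return SlideAnnotation(
        slide_id=ann.slide_id,
        nuclei=nuclei,
        regions=regions,
        base_mpp=target_mpp,
        scanner=ann.scanner,
    )


# -- cohort CSV ---------------------------------------------------------------

_MANDATORY_COLUMNS = (
    "slide_id",
    "patient_id",
    "age",
    "sex",
    "site",
    "scanner",
    "who_grade",
    "binary_grade",
    "transformed",
    "months",
)

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def read_cohort(
    path: str | Path,
    *,
    level_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> list[CohortRecord]:
    """Read a cohort CSV into validated :class:`CohortRecord` objects.

    ``level_maps`` optionally maps raw categorical values to canonical levels,
    keyed by column, e.g. ``{"sex": {"M": "male", "F": "female"}}``. Feature
    vote columns ``<feature>__r1..r3`` are optional; a record either has all
    three votes for a feature or none.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing mandatory column(s): {missing}")
    level_maps = level_maps or {}

    def canon(col: str, value) -> str:
        value = str(value).strip()
        mapped = level_maps.get(col, {}).get(value, value)
        return str(mapped).strip().lower()

    records: list[CohortRecord] = []
    for _, row in df.iterrows():
        features: dict[str, tuple[int, int, int]] = {}
        for feat in HISTOLOGICAL_FEATURES:
            cols = [f"{feat}__r{i}" for i in (1, 2, 3)]
            if all(c in df.columns for c in cols) and not any(
                pd.isna(row[c]) for c in cols
            ):
                features[feat] = tuple(int(row[c]) for c in cols)
        raw_t = str(row["transformed"]).strip().lower()
        if raw_t not in _BOOL_MAP:
            raise ValueError(f"cannot parse transformed value {row['transformed']!r}")
        records.append(
            CohortRecord(
                slide_id=str(row["slide_id"]),
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                sex=canon("sex", row["sex"]),
                site=canon("site", row["site"]),
                scanner=canon("scanner", row["scanner"]),
                who_grade=canon("who_grade", row["who_grade"]),
                binary_grade=canon("binary_grade", row["binary_grade"]),
                transformed=_BOOL_MAP[raw_t],
                months=float(row["months"]),
                features=features or None,
            )
        )
    return records


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (feature votes as ``<feat>__r<i>``)."""
    rows = []
    for r in records:
        d = {
            "slide_id": r.slide_id,
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex,
            "site": r.site,
            "scanner": r.scanner,
            "who_grade": r.who_grade,
            "binary_grade": r.binary_grade,
            "transformed": r.transformed,
            "months": r.months,
        }
        if r.features:
            for feat, votes in r.features.items():
                for i, v in enumerate(votes, 1):
                    d[f"{feat}__r{i}"] = v
        rows.append(d)
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[CohortRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)
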