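"""IEL scores from nuclear detections restricted to dysplastic regions.

Four scores are computed per slide, all from nuclei whose centroids fall
inside the annotated dysplasia:

* ``iel_c``  — IEL Count: IELs per 100 dysplastic epithelial cells, over the
  entire dysplastic region (the per-100 convention mirrors duodenal IEL
  counts used in coeliac-disease histology).
* ``iel_pc`` — IEL Peak Count: the maximum of the same ratio over square
  sliding windows (default 512x512 px at 1.0 microns per pixel).
* ``iel_i``  — IEL Index: IELs per mm² of dysplasia.
* ``iel_pi`` — IEL Peak Index: the windowed maximum of IELs per mm² of the
  dysplasia area falling inside the window.

Windowing conventions: windows are axis-aligned squares on a regular grid
anchored to the bounding box of the dysplastic nuclei (expanded by one
window on the top-left), with membership on the half-open interval
[x, x+w) x [y, y+w). Windows with too few epithelial cells (``iel_pc``) or
too little dysplasia area (``iel_pi``) are ineligible: a denominator floor
suppresses spuriously high ratios from near-empty windows. Peak ties are
broken by scan order (row-major, top-left first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from ielscore.io_annotations import SlideAnnotation, rescale_annotation

__all__ = [
    "UndefinedScoreError",
    "ScoreParams",
    "IELScores",
    "nuclei_in_dysplasia",
    "compute_iel_c",
    "compute_iel_i",
    "compute_iel_pc",
    "compute_iel_pi",
    "score_slide",
    "window_grid",
    "window_counts",
]


class UndefinedScoreError(ValueError):
    """A score's denominator is empty (no epithelial cells / zero area)."""


@dataclass(frozen=True)
class ScoreParams:
    """Tunable parameters of the windowed peak search.

    ``window_px`` and ``stride_px`` are in pixels at ``target_mpp``. The
    default half-window stride bounds the peak underestimate of a coarse
    grid at ~4x the work of non-overlapping tiling. ``min_epi`` is the
    epithelial-cell floor for an IEL-PC window; ``min_area_mm2`` the
    dysplasia-area floor for an IEL-PI window (default: a quarter of the
    window area).
    """

    window_px: int = 512
    stride_px: int = 256
    min_epi: int = 20
    min_area_mm2: float | None = None
    target_mpp: float = 1.0

    def __post_init__(self) -> None:
        if self.window_px <= 0 or self.stride_px <= 0:
            raise ValueError("window_px and stride_px must be positive")
        if self.min_epi < 1:
            raise ValueError("min_epi must be >= 1")

    @property
    def resolved_min_area_mm2(self) -> float:
        if self.min_area_mm2 is not None:
            return self.min_area_mm2
        return 0.25 * (self.window_px * self.target_mpp) ** 2 * 1e-6


@dataclass
class IELScores:
    """The four slide-level scores plus their ingredients.

    ``hotspot_pc`` / ``hotspot_pi`` are the winning window origins (x, y) at
    ``target_mpp`` (first window in scan order attaining the peak), or None
    when no window was eligible. Scores are unrounded; round only for
    display.
    """

    slide_id: str
    n_epi: int
    n_iel: int
    dysplasia_area_mm2: float
    iel_c: float | None
    iel_pc: float | None
    iel_i: float | None
    iel_pi: float | None
    hotspot_pc: tuple[float, float] | None = None
    hotspot_pi: tuple[float, float] | None = None

    def to_row(self) -> dict:
        hx_pc, hy_pc = self.hotspot_pc if self.hotspot_pc else (None, None)
        hx_pi, hy_pi = self.hotspot_pi if self.hotspot_pi else (None, None)
        return {
            "slide_id": self.slide_id,
            "n_epi": self.n_epi,
            "n_iel": self.n_iel,
            "area_mm2": self.dysplasia_area_mm2,
            "iel_c": self.iel_c,
            "iel_pc": self.iel_pc,
            "iel_i": self.iel_i,
            "iel_pi": self.iel_pi,
            "hotspot_x": hx_pc,
            "hotspot_y": hy_pc,
            "hotspot_pi_x": hx_pi,
            "hotspot_pi_y": hy_pi,
        }


# -- restriction to dysplasia -------------------------------------------------


def nuclei_in_dysplasia(ann: SlideAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """Split nuclei into (epithelial, IEL) centroid arrays inside dysplasia.

    A nucleus is retained when its centroid lies inside or on the boundary of
    any region; overlapping regions never double-count a nucleus.

    Returns
    -------
    (epi, iel)
        Two (n, 2) float arrays of centroids, at the annotation's resolution.
    """
    if not ann.regions:
        raise ValueError(f"slide {ann.slide_id}: no dysplasia annotated")
    union = ann.region_union()
    shapely.prepare(union)
    out = []
    for cls in ("epithelial", "iel"):
        coords = ann.nucleus_coords(cls)
        if len(coords) == 0:
            out.append(coords)
            continue
        pts = shapely.points(coords)
        keep = shapely.intersects(union, pts)  # boundary-inclusive
        out.append(coords[keep])
    return out[0], out[1]


# -- global scores ------------------------------------------------------------


def compute_iel_c(n_iel: int, n_epi: int) -> float:
    """IELs per 100 dysplastic epithelial cells (global, unrounded)."""
    if n_epi <= 0:
        raise UndefinedScoreError("IEL-C undefined: no dysplastic epithelial cells")
    return 100.0 * n_iel / n_epi


def compute_iel_i(n_iel: int, dysplasia_area_mm2: float) -> float:
    """IELs per mm² of dysplasia (global, unrounded)."""
    if not dysplasia_area_mm2 > 0:
        raise UndefinedScoreError("IEL-I undefined: zero dysplasia area")
    return n_iel / dysplasia_area_mm2


# -- sliding-window machinery -------------------------------------------------


def window_grid(
    coords: np.ndarray, window_px: int, stride_px: int
) -> tuple[np.ndarray, np.ndarray]:
    """Window origins spanning the nuclei bounding box, expanded by one window.

    The grid is anchored at the bounding-box minimum, which makes every score
    translation-invariant. With ``stride_px <= window_px`` every nucleus is
    covered by at least one window.
    """
    if len(coords) == 0:
        return np.array([]), np.array([])
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    xs = np.arange(xmin - window_px, xmax + stride_px, stride_px)
    ys = np.arange(ymin - window_px, ymax + stride_px, stride_px)
    return xs, ys


def window_counts(
    points: np.ndarray, xs: np.ndarray, ys: np.ndarray, window_px: int
) -> np.ndarray:
    """Counts of ``points`` in each half-open window [x, x+w) x [y, y+w).

    Returns an array of shape (len(ys), len(xs)) — rows scan y, columns x.
    """
    counts = np.zeros((len(ys), len(xs)), dtype=np.int64)
    if len(points) == 0 or len(xs) == 0 or len(ys) == 0:
        return counts
    order = np.argsort(points[:, 0], kind="stable")
    px = points[order, 0]
    py = points[order, 1]
    for j, ox in enumerate(xs):
        lo = np.searchsorted(px, ox, side="left")
        hi = np.searchsorted(px, ox + window_px, side="left")
        if hi == lo:
            continue
        ysub = np.sort(py[lo:hi])
        counts[:, j] = np.searchsorted(ysub, ys + window_px, side="left") - np.searchsorted(
            ysub, ys, side="left"
        )
    return counts


def _first_argmax(values: np.ndarray, eligible: np.ndarray) -> tuple[int, int] | None:
    """Row-major first (i, j) maximizing ``values`` among ``eligible`` cells."""
    if not eligible.any():
        return None
    masked = np.where(eligible, values, -np.inf)
    flat = int(np.argmax(masked))  # np.argmax returns the first maximum
    return np.unravel_index(flat, values.shape)  # type: ignore[return-value]


def _check_scoring_resolution(ann: SlideAnnotation, target_mpp: float = 1.0) -> None:
    if abs(ann.base_mpp - target_mpp) > 1e-9:
        raise ValueError(
            f"annotation is at {ann.base_mpp} mpp; rescale to {target_mpp} mpp "
            "before windowed scoring"
        )


def compute_iel_pc(
    ann: SlideAnnotation,
    window_px: int = 512,
    stride_px: int = 256,
    min_epi: int = 20,
) -> tuple[float | None, tuple[float, float] | None]:
    """Peak IELs per 100 epithelial cells over sliding windows (IEL-PC).

    ``ann`` must be at 1.0 mpp with nuclei already restricted to dysplasia
    (see :func:`score_slide` for the orchestrated path). Windows with fewer
    than ``min_epi`` epithelial cells are ineligible. Returns
    ``(score, (x, y))`` of the first-in-scan-order peak window, or
    ``(None, None)`` with a warning when no window is eligible.
    """
    if window_px <= 0 or stride_px <= 0:
        raise ValueError("window_px and stride_px must be positive")
    _check_scoring_resolution(ann)
    epi = ann.nucleus_coords("epithelial")
    iel = ann.nucleus_coords("iel")
    allc = ann.nucleus_coords()
    xs, ys = window_grid(allc, window_px, stride_px)
    n_epi_w = window_counts(epi, xs, ys, window_px)
    n_iel_w = window_counts(iel, xs, ys, window_px)
    eligible = n_epi_w >= min_epi
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = 100.0 * n_iel_w / n_epi_w
    peak = _first_argmax(scores, eligible)
    if peak is None:
        warnings.warn(
            f"slide {ann.slide_id}: no window with >= {min_epi} epithelial cells; "
            "IEL-PC undefined",
            stacklevel=2,
        )
        return None, None
    i, j = peak
    return float(scores[i, j]), (float(xs[j]), float(ys[i]))


def compute_iel_pi(
    ann: SlideAnnotation,
    window_px: int = 512,
    stride_px: int = 256,
    min_area_mm2: float = 0.065536,
) -> tuple[float | None, tuple[float, float] | None]:
    """Peak IELs per mm² of within-window dysplasia (IEL-PI).

    The per-window denominator is the area of the dysplasia polygons clipped
    to the window, in mm² at 1.0 mpp. Windows whose dysplasia intersection is
    below ``min_area_mm2`` are ineligible.
    """
    if window_px <= 0 or stride_px <= 0:
        raise ValueError("window_px and stride_px must be positive")
    _check_scoring_resolution(ann)
    if not ann.regions:
        raise ValueError(f"slide {ann.slide_id}: no dysplasia annotated")
    iel = ann.nucleus_coords("iel")
    allc = ann.nucleus_coords()
    xs, ys = window_grid(allc, window_px, stride_px)
    if len(xs) == 0:
        warnings.warn(f"slide {ann.slide_id}: no nuclei, IEL-PI undefined", stacklevel=2)
        return None, None
    n_iel_w = window_counts(iel, xs, ys, window_px)
    union = ann.region_union()
    gx, gy = np.meshgrid(xs, ys)
    boxes = shapely.box(gx.ravel(), gy.ravel(), gx.ravel() + window_px, gy.ravel() + window_px)
    inter_px2 = shapely.area(shapely.intersection(union, boxes)).reshape(gy.shape)
    inter_mm2 = inter_px2 * 1e-6  # at 1.0 mpp, 1 px² = 1e-6 mm²
    eligible = inter_mm2 >= min_area_mm2
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = n_iel_w / inter_mm2
    peak = _first_argmax(scores, eligible)
    if peak is None:
        warnings.warn(
            f"slide {ann.slide_id}: no window with >= {min_area_mm2} mm² of "
            "dysplasia; IEL-PI undefined",
            stacklevel=2,
        )
        return None, None
    i, j = peak
    return float(scores[i, j]), (float(xs[j]), float(ys[i]))


# -- orchestration ------------------------------------------------------------


def score_slide(ann: SlideAnnotation, params: ScoreParams | None = None) -> IELScores:
    """Compute all four IEL scores for one slide.

    Rescales to ``params.target_mpp``, restricts nuclei to the dysplasia
    union (boundary-inclusive, de-duplicated across overlapping regions) and
    evaluates the global and windowed scores. Undefined denominators null
    only the affected scores; a slide without regions is a hard error.
    Deterministic for fixed input and parameters.
    """
    from ielscore.io_annotations import NucleusRecord

    params = params or ScoreParams()
    scaled = rescale_annotation(ann, params.target_mpp)
    epi, iel = nuclei_in_dysplasia(scaled)
    area_mm2 = scaled.region_area_mm2()
    n_epi, n_iel = len(epi), len(iel)

    try:
        iel_c = compute_iel_c(n_iel, n_epi)
    except UndefinedScoreError as err:
        warnings.warn(f"slide {ann.slide_id}: {err}", stacklevel=2)
        iel_c = None
    try:
        iel_i = compute_iel_i(n_iel, area_mm2)
    except UndefinedScoreError as err:
        warnings.warn(f"slide {ann.slide_id}: {err}", stacklevel=2)
        iel_i = None

    restricted = SlideAnnotation(
        slide_id=scaled.slide_id,
        nuclei=[NucleusRecord(x, y, "epithelial") for x, y in epi]
        + [NucleusRecord(x, y, "iel") for x, y in iel],
        regions=scaled.regions,
        base_mpp=scaled.base_mpp,
        scanner=scaled.scanner,
    )
    iel_pc, hotspot_pc = compute_iel_pc(
        restricted, params.window_px, params.stride_px, params.min_epi
    )
    iel_pi, hotspot_pi = compute_iel_pi(
        restricted, params.window_px, params.stride_px, params.resolved_min_area_mm2
    )
    return IELScores(
        slide_id=ann.slide_id,
        n_epi=n_epi,
        n_iel=n_iel,
        dysplasia_area_mm2=area_mm2,
        iel_c=iel_c,
        iel_pc=iel_pc,
        iel_i=iel_i,
        iel_pi=iel_pi,
        hotspot_pc=hotspot_pc,
        hotspot_pi=hotspot_pi,
    )
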