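"""Laminar puncta quantification and structure-function regression.

Immunofluorescent puncta (GLAST, synaptophysin, GFAP) are segmented from
calibrated 2-D images, filtered by area and circularity (4*pi*A/P**2, the
Fiji convention), and summarized per cortical layer as mean puncta size,
fractional coverage (%) and density per 1000 um^2.  Layer I is subdivided
into three equal-depth sublayers (I-1 superficial to I-3 deep).  Histology
metrics are then regressed against seizure-burden metrics per layer with
ordinary least squares, reporting slope, intercept and R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely.geometry import Point, Polygon, box
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import ParameterError

__all__ = [
    "ParticleFilter",
    "GLAST_FILTER",
    "SYNAPTOPHYSIN_FILTER",
    "GFAP_FILTER",
    "LayerMetrics",
    "RegressionResult",
    "segment_particles",
    "apply_filter",
    "layer_metrics",
    "subdivide_layer1",
    "linfit",
    "flag_outliers",
    "r2_matrix",
]


@dataclass(frozen=True)
class ParticleFilter:
    """Area (um^2) and circularity retention window, inclusive bounds."""

    min_area: float
    max_area: float | None = None  # None = no upper bound
    min_circularity: float = 0.3
    max_circularity: float = 1.0

    def __post_init__(self) -> None:
        if self.max_area is not None and self.min_area >= self.max_area:
            raise ParameterError("min_area must be below max_area")
        if not 0 <= self.min_circularity <= self.max_circularity <= 1:
            raise ParameterError("circularity bounds must lie in [0, 1]")


#: GLAST- and synaptophysin-positive particles: 0.05-3 um^2, contours 0.3-1.
GLAST_FILTER = ParticleFilter(min_area=0.05, max_area=3.0)
SYNAPTOPHYSIN_FILTER = GLAST_FILTER
#: GFAP-positive particles: minimum 1 um^2, contours 0.3-1, no upper bound.
GFAP_FILTER = ParticleFilter(min_area=1.0, max_area=None)


@dataclass
class LayerMetrics:
    """Per-layer puncta summary."""

    layer: str
    n_puncta: int
    mean_puncta_area_um2: float | None  # absent when no puncta
    coverage_pct: float
    density_per_1000um2: float
    roi_area_um2: float


@dataclass
class RegressionResult:
    """Simple linear regression summary (OLS)."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    predictor: str = "x"
    response: str = "y"
    layer: str | None = None


def segment_particles(
    image: np.ndarray,
    pixel_size_um: float,
    threshold_method: str = "otsu",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold and label puncta; return the label image and a particle table.

    The table carries area (um^2), perimeter (um, Crofton estimate),
    circularity 4*pi*A/P**2 clipped to [0, 1], and centroid coordinates in
    um.  A blank (constant) image yields an empty table.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ParameterError("a positive pixel size calibration is required")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("expected a 2-D grayscale image")
    cols = ["particle_id", "area_um2", "perimeter_um", "circularity",
            "cx_um", "cy_um"]
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=int), pd.DataFrame(columns=cols)
    if threshold_method == "otsu":
        thresh = threshold_otsu(image)
    else:
        raise ParameterError(f"unknown threshold method {threshold_method!r}")
    mask = image > thresh
    labels = sk_label(mask, connectivity=2)
    rows = []
    for prop in regionprops(labels):
        area = prop.area * pixel_size_um ** 2
        perim = prop.perimeter_crofton * pixel_size_um
        circ = 4 * np.pi * area / perim ** 2 if perim > 0 else 0.0
        cy, cx = prop.centroid  # row, col
        rows.append({
            "particle_id": prop.label,
            "area_um2": area,
            "perimeter_um": perim,
            "circularity": min(circ, 1.0),
            "cx_um": cx * pixel_size_um,
            "cy_um": cy * pixel_size_um,
        })
    return labels, pd.DataFrame(rows, columns=cols)


def apply_filter(table: pd.DataFrame, filt: ParticleFilter) -> pd.DataFrame:
    """Retain particles inside the area and circularity windows (inclusive)."""
    if len(table) == 0:
        return table.copy()
    keep = (table["area_um2"] >= filt.min_area)
    if filt.max_area is not None:
        keep &= table["area_um2"] <= filt.max_area
    keep &= table["circularity"].between(filt.min_circularity,
                                         filt.max_circularity)
    return table[keep].reset_index(drop=True)


def _as_polygon(roi) -> Polygon:
    if isinstance(roi, Polygon):
        return roi
    try:
        return Polygon(roi)
    except Exception as exc:
        raise ParameterError(f"invalid ROI polygon: {exc}") from exc


def layer_metrics(table: pd.DataFrame, roi, layer: str = "") -> LayerMetrics:
    """Mean puncta area, % coverage and density per 1000 um^2 inside an ROI.

    Particles are assigned to the ROI by centroid membership (boundary
    inclusive).  Zero particles yields coverage 0, density 0, absent mean.
    """
    poly = _as_polygon(roi)
    roi_area = poly.area
    if roi_area <= 0:
        raise ParameterError("ROI area must be positive")
    if len(table):
        inside = table.apply(
            lambda r: poly.covers(Point(r["cx_um"], r["cy_um"])), axis=1)
        sub = table[inside]
    else:
        sub = table
    n = len(sub)
    total_area = float(sub["area_um2"].sum()) if n else 0.0
    return LayerMetrics(
        layer=layer,
        n_puncta=n,
        mean_puncta_area_um2=float(sub["area_um2"].mean()) if n else None,
        coverage_pct=100.0 * total_area / roi_area,
        density_per_1000um2=1000.0 * n / roi_area,
        roi_area_um2=roi_area,
    )


def subdivide_layer1(roi, depth_axis: str = "y") -> list[tuple[str, Polygon]]:
    """Split a layer-I ROI into three equal-depth sublayer bands I-1..I-3.

    The depth axis runs along y (image rows) by default; I-1 is the
    superficial (smallest-depth) band.  Bands partition the ROI: their
    areas sum to the ROI area.
    """
    poly = _as_polygon(roi)
    if poly.area <= 0:
        raise ParameterError("degenerate layer-I ROI")
    minx, miny, maxx, maxy = poly.bounds
    lo, hi = (miny, maxy) if depth_axis == "y" else (minx, maxx)
    if hi - lo <= 0:
        raise ParameterError("ROI has zero extent along the depth axis")
    edges = np.linspace(lo, hi, 4)
    out = []
    for i, name in enumerate(["I-1", "I-2", "I-3"]):
        if depth_axis == "y":
            band = box(minx - 1, edges[i], maxx + 1, edges[i + 1])
        else:
            band = box(edges[i], miny - 1, edges[i + 1], maxy + 1)
        out.append((name, poly.intersection(band)))
    return out


def linfit(x, y, predictor: str = "x", response: str = "y",
           layer: str | None = None) -> RegressionResult:
    """Ordinary least squares y = slope * x + intercept with R^2.

    Constant x is a degenerate fit (error); constant y is reported with
    R^2 = 0 and a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have the same length")
    if x.size < 3:
        raise ParameterError("simple linear regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ParameterError("constant predictor: degenerate fit")
    if np.ptp(y) == 0:
        warnings.warn("constant response: R^2 reported as 0", stacklevel=2)
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                n=int(x.size), predictor=predictor,
                                response=response, layer=layer)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(x.size),
        predictor=predictor,
        response=response,
        layer=layer,
    )


def flag_outliers(x, y, threshold: float = 3.0) -> np.ndarray:
    """Flag points with |studentized residual| above ``threshold``.

    A simple documented robust-residual flag; flagged points are reported,
    never silently removed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        return np.zeros(x.size, dtype=bool)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = model.get_influence().resid_studentized_internal
    return np.abs(resid) > threshold


def r2_matrix(
    cohort: pd.DataFrame,
    predictors: list[str],
    responses: list[str],
    layer_col: str = "layer",
    layers: list[str] | None = None,
) -> pd.DataFrame:
    """Layer x (predictor, response) grid of R^2 values with per-cell n.

    Returns a long-format table with columns layer, predictor, response,
    r_squared, slope, intercept, n.  A layer with fewer than 3 usable
    points contributes no row (absent, not zero).
    """
    for col in predictors + responses + [layer_col]:
        if col not in cohort.columns:
            raise ParameterError(f"column {col!r} missing from cohort table")
    if layers is None:
        layers = list(pd.unique(cohort[layer_col]))
    rows = []
    for layer in layers:
        sub = cohort[cohort[layer_col] == layer]
        for pred in predictors:
            for resp in responses:
                pair = sub[[pred, resp]].dropna()
                if len(pair) < 3 or np.ptp(pair[pred].to_numpy()) == 0:
                    continue
                fit = linfit(pair[pred], pair[resp], predictor=pred,
                             response=resp, layer=str(layer))
                rows.append({
                    "layer": layer, "predictor": pred, "response": resp,
                    "r_squared": fit.r_squared, "slope": fit.slope,
                    "intercept": fit.intercept, "n": fit.n,
                })
    return pd.DataFrame(rows, columns=["layer", "predictor", "response",
                                       "r_squared", "slope", "intercept", "n"])
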