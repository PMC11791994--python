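"""Per-root trait extraction: length, diameter, area, curvature.

Traits are measured on a single-object mask and its skeleton polyline at a
known scanner scale (``mm_per_px = 25.4 / dpi``).  Curvature follows the
plane-curve formula for a fitted quadratic ``y = a x^2 + b x + c``::

    K(x) = |y''| / (1 + y'^2)^(3/2),   y' = 2 a x + b,  y'' = 2 a
    rho  = 1 / K                        (radius of curvature)

A single summary value of K per root is reported (domain midpoint by
default; the parabola vertex and the domain-mean of |K| are selectable) and
optionally transformed as ``-log K`` for cross-day trend plots.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from rootgrain.instance_postprocess import InstanceMask, largest_component
from rootgrain.skeletonize import Polyline, Skeleton, prune_spurs, thin, to_polyline

__all__ = [
    "CurvatureResult",
    "PhenotypeConfig",
    "QuadraticFit",
    "RootPhenotype",
    "ScaleModel",
    "TRAIT_COLUMNS",
    "curvature",
    "fit_quadratic",
    "phenotype_batch",
    "phenotype_instance",
    "root_areas",
    "root_diameters",
    "root_length",
    "trim_tip_overshoot",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaleModel:
    """Scanner scale; 1200 dpi gives 25.4/1200 = 0.021167 mm per pixel."""

    dpi: float = 1200.0

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")

    @property
    def mm_per_px(self) -> float:
        return 25.4 / self.dpi

    @property
    def px_per_mm(self) -> float:
        return self.dpi / 25.4


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic fitted to a (possibly rotated) polyline.

    ``rotation`` is the angle (radians) by which the points were rotated
    about ``center`` before fitting, so the fit is traceable back to image
    coordinates.  ``domain`` is the fitted x-range in the rotated frame.
    """

    a: float
    b: float
    c: float
    rotation: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    domain: tuple[float, float] = (0.0, 0.0)
    rms: float = 0.0
    #: fitted-frame x of the input's middle point (the arc-length midpoint
    #: for polylines sampled uniformly along the curve)
    x_arc_mid: float | None = None


@dataclass(frozen=True)
class CurvatureResult:
    """Curvature summary of one root; units 1/mm (or 1/px when unscaled)."""

    K: float
    rho: float
    K_mean_abs: float
    neg_log_K: float
    straight: bool
    where: str = "midpoint"
    units: str = "1/mm"


@dataclass
class RootPhenotype:
    """Trait record of one root instance."""

    instance_id: int
    label: str
    length_mm: float
    avg_diameter_mm: float
    max_diameter_mm: float
    min_diameter_mm: float
    projected_area_mm2: float
    cylindrical_surface_mm2: float
    curvature: CurvatureResult | None = None
    timestamp: int | None = None
    status: str = "ok"
    error: str = ""


TRAIT_COLUMNS = [
    "instance_id",
    "label",
    "timestamp",
    "length_mm",
    "avg_diameter_mm",
    "max_diameter_mm",
    "min_diameter_mm",
    "projected_area_mm2",
    "cylindrical_surface_mm2",
    "curvature_per_mm",
    "radius_of_curvature_mm",
    "curvature_mean_abs_per_mm",
    "neg_log_curvature",
    "straight",
    "status",
    "error",
]


@dataclass(frozen=True)
class PhenotypeConfig:
    """Tunable knobs of the per-instance trait pipeline (defaults documented
    in the methods note)."""

    min_score: float = 0.4
    connectivity: int = 8
    criterion: str = "area"
    thin_method: str = "k3m"
    min_branch_px: int = 10
    curvature_at: str = "midpoint"
    log_base: float = math.e
    #: chord-resampling interval for length measurement; 1 = raw chain code
    length_resample_px: float = 7.0


def root_length(
    poly: Polyline, scale: ScaleModel, resample_px: float = 1.0
) -> float:
    """Polyline length in millimetres.

    With ``resample_px <= 1`` (default) the classic chain-code convention is
    used: each axial step counts 1 px and each diagonal step sqrt(2) px.
    That estimator is exact on axis-aligned and diagonal lines but biased
    upward for other orientations, so the pipeline resamples the polyline
    at ``resample_px`` intervals and sums chord lengths instead.
    """
    pts = poly.as_array()
    if len(pts) < 2:
        warnings.warn("polyline has fewer than 2 points; length is 0")
        return 0.0
    steps = np.diff(pts, axis=0)
    chain = np.where((steps[:, 0] != 0) & (steps[:, 1] != 0), math.sqrt(2.0), 1.0)
    if resample_px <= 1.0:
        return float(chain.sum()) * scale.mm_per_px
    cum = np.concatenate([[0.0], np.cumsum(chain)])
    total = cum[-1]
    targets = np.arange(0.0, total, resample_px)
    idx = np.unique(np.searchsorted(cum, targets, side="left"))
    if idx[-1] != len(pts) - 1:
        idx = np.append(idx, len(pts) - 1)
    sampled = pts[idx]
    return float(np.linalg.norm(np.diff(sampled, axis=0), axis=1).sum()) * scale.mm_per_px


def trim_tip_overshoot(
    poly: Polyline, mask: InstanceMask | np.ndarray, slope: float = 0.2
) -> Polyline:
    """Trim skeleton tips that overshoot into the rounded root ends.

    Thinning a round-capped ribbon leaves a short ridge running from the
    true curve endpoint (the centre of the end cap, where the inscribed
    disk is locally largest) toward the cap boundary.  Along that ridge the
    distance transform climbs steeply (about one pixel per step), whereas
    along the root body it is nearly constant, so each end is trimmed back
    while the EDT still rises faster than ``slope`` px/px over a short
    window.  At most a quarter of the polyline is trimmed per end and at
    least three points are kept.
    """
    pixels = mask.pixels if isinstance(mask, InstanceMask) else np.asarray(mask, bool)
    pts = poly.points
    n = len(pts)
    if n < 8:
        return Polyline(list(pts))
    edt = ndimage.distance_transform_edt(np.pad(pixels, 1))[1:-1, 1:-1]
    vals = np.array([edt[y, x] for x, y in pts])
    window = 3
    lo, hi = 0, n - 1
    limit = n // 4
    while lo < limit and vals[lo + window] - vals[lo] > slope * window:
        lo += 1
    while (n - 1 - hi) < limit and vals[hi - window] - vals[hi] > slope * window:
        hi -= 1
    if hi - lo + 1 < 3:
        return Polyline(list(pts))
    return Polyline(list(pts[lo : hi + 1]))


def root_diameters(
    mask: InstanceMask | np.ndarray,
    skel: Skeleton | Polyline,
    scale: ScaleModel,
) -> tuple[float, float, float]:
    """(average, maximum, minimum) local diameter along the skeleton, in mm.

    The local diameter at a skeleton pixel is ``2*EDT - 1`` px, where EDT is
    the Euclidean distance from the pixel centre to the nearest background
    pixel centre (a width-1 line therefore measures exactly 1 px).  Passing
    a (tip-trimmed) :class:`Polyline` restricts the statistics to the root
    body, excluding the declining cap regions at the tips.
    """
    pixels = mask.pixels if isinstance(mask, InstanceMask) else np.asarray(mask, bool)
    edt = ndimage.distance_transform_edt(np.pad(pixels, 1))[1:-1, 1:-1]
    if isinstance(skel, Polyline):
        if len(skel.points) == 0:
            raise ValueError("empty polyline: no pixels to measure diameter at")
        vals = np.array([edt[y, x] for x, y in skel.points])
    else:
        if skel.n_pixels == 0:
            raise ValueError("empty skeleton: no pixels to measure diameter at")
        vals = edt[skel.mask]
    d_px = 2.0 * vals - 1.0
    return (
        float(d_px.mean()) * scale.mm_per_px,
        float(d_px.max()) * scale.mm_per_px,
        float(d_px.min()) * scale.mm_per_px,
    )


def root_areas(
    mask: InstanceMask | np.ndarray,
    length_mm: float,
    avg_diameter_mm: float,
    scale: ScaleModel,
) -> tuple[float, float]:
    """(projected area, cylindrical surface area) in mm^2.

    Projected area is the foreground pixel count scaled by ``mm_per_px^2``;
    the cylindrical surface models the root as a cylinder of the average
    diameter: ``pi * d_avg * L``.
    """
    pixels = mask.pixels if isinstance(mask, InstanceMask) else np.asarray(mask, bool)
    projected = float(pixels.sum()) * scale.mm_per_px**2
    cylindrical = math.pi * avg_diameter_mm * length_mm
    return projected, cylindrical


def _pca_angle(pts: np.ndarray) -> float:
    """Orientation of the principal axis of a 2-D point cloud, in radians."""
    centered = pts - pts.mean(axis=0)
    sxx, sxy = centered[:, 0] @ centered[:, 0], centered[:, 0] @ centered[:, 1]
    syy = centered[:, 1] @ centered[:, 1]
    return 0.5 * math.atan2(2.0 * sxy, sxx - syy)


def fit_quadratic(poly: Polyline | np.ndarray, rotation: str = "pca") -> QuadraticFit:
    """Fit ``y = a x^2 + b x + c`` to a polyline by least squares.

    ``rotation="pca"`` (pipeline default) rotates the points about their
    centroid so the principal axis is horizontal before fitting, which keeps
    y(x) single-valued for near-vertical roots; ``rotation="none"`` fits the
    raw coordinates (exact coefficient recovery for already axis-aligned
    data).  The applied angle is recorded in the result.
    """
    pts = poly.as_array() if isinstance(poly, Polyline) else np.asarray(poly, float)
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points to fit a quadratic, got {len(pts)}")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate polyline: all points identical")
    if rotation == "pca":
        angle = _pca_angle(pts)
        center = tuple(pts.mean(axis=0))
        c, s = math.cos(angle), math.sin(angle)
        centered = pts - center
        # rotate by -angle so the principal axis lands on the x-axis
        rotated = centered @ np.array([[c, -s], [s, c]])
        x, y = rotated[:, 0], rotated[:, 1]
    elif rotation == "none":
        angle = 0.0
        center = (0.0, 0.0)
        x, y = pts[:, 0], pts[:, 1]
    else:
        raise ValueError(f"rotation must be 'pca' or 'none', got '{rotation}'")
    if np.ptp(x) == 0.0:
        raise ValueError("points are vertically collinear after rotation")
    coeffs = np.polyfit(x, y, 2)
    resid = np.polyval(coeffs, x) - y
    return QuadraticFit(
        a=float(coeffs[0]),
        b=float(coeffs[1]),
        c=float(coeffs[2]),
        rotation=angle,
        center=(float(center[0]), float(center[1])),
        domain=(float(x.min()), float(x.max())),
        rms=float(np.sqrt(np.mean(resid**2))),
        x_arc_mid=float(x[len(x) // 2]),
    )


def _k_of_x(a: float, b: float, x: float) -> float:
    yp = 2.0 * a * x + b
    return abs(2.0 * a) / (1.0 + yp * yp) ** 1.5


def curvature(
    fit: QuadraticFit,
    where: str = "midpoint",
    scale: ScaleModel | None = None,
    log_base: float = math.e,
) -> CurvatureResult:
    """Summarize the curvature of a fitted quadratic.

    ``where`` selects the summary point: ``"vertex"`` (K = |2a| exactly),
    ``"midpoint"`` of the fitted domain, or ``"mean_abs"`` (the analytic
    domain-mean of |K|).  With a :class:`ScaleModel` the result is in 1/mm
    (and rho in mm); otherwise pixel units are reported.  A straight root
    (a = 0) yields K = 0 and an infinite radius, flagged ``straight``.
    """
    a, b = fit.a, fit.b
    x0, x1 = fit.domain
    # analytic domain-mean of |K|: d/dx [ t / sqrt(1+t^2) ] = 2a K with t = y'
    if x1 > x0 and a != 0.0:
        t0, t1 = 2 * a * x0 + b, 2 * a * x1 + b
        mean_abs = abs(
            t1 / math.sqrt(1 + t1 * t1) - t0 / math.sqrt(1 + t0 * t0)
        ) / (x1 - x0)
    else:
        mean_abs = abs(2.0 * a)
    if where == "vertex":
        k = abs(2.0 * a)
    elif where == "midpoint":
        xm = fit.x_arc_mid if fit.x_arc_mid is not None else 0.5 * (x0 + x1)
        k = _k_of_x(a, b, xm)
    elif where == "mean_abs":
        k = mean_abs
    else:
        raise ValueError(f"unknown curvature summary '{where}'")
    units = "1/px"
    if scale is not None:  # curvature scales inversely with length
        k /= scale.mm_per_px
        mean_abs /= scale.mm_per_px
        units = "1/mm"
    straight = a == 0.0 or k == 0.0
    rho = math.inf if straight else 1.0 / k
    neg_log = math.inf if straight else -math.log(k) / math.log(log_base)
    return CurvatureResult(
        K=0.0 if straight else k,
        rho=rho,
        K_mean_abs=mean_abs,
        neg_log_K=neg_log,
        straight=straight,
        where=where,
        units=units,
    )


def phenotype_instance(
    mask: InstanceMask,
    scale: ScaleModel | None = None,
    config: PhenotypeConfig | None = None,
) -> RootPhenotype:
    """Full trait pipeline for one instance mask.

    Runs largest-component selection, thinning, spur pruning, polyline
    ordering and every trait measurement.  Raises on degenerate inputs
    (empty mask, skeleton too short to fit); :func:`phenotype_batch` catches
    these and records a failed row instead.
    """
    scale = scale or ScaleModel()
    config = config or PhenotypeConfig()
    clean = largest_component(mask, config.connectivity, config.criterion)
    skel = prune_spurs(
        thin(clean, method=config.thin_method), config.min_branch_px
    )
    raw = to_polyline(skel)
    poly = trim_tip_overshoot(raw, clean)
    # tip-to-tip length: the raw polyline plus the distance transform at its
    # two tips.  On the ridge the skeleton leaves inside a rounded end, the
    # EDT equals the remaining distance to the root tip, so this extends the
    # measurement to the full visible root regardless of how far thinning
    # retracted or overshot the tip.
    length_mm = root_length(raw, scale, resample_px=config.length_resample_px)
    edt = ndimage.distance_transform_edt(np.pad(clean.pixels, 1))[1:-1, 1:-1]
    x0, y0 = raw.points[0]
    x1, y1 = raw.points[-1]
    length_mm += (float(edt[y0, x0]) + float(edt[y1, x1]) - 1.0) * scale.mm_per_px
    d_avg, d_max, d_min = root_diameters(clean, poly, scale)
    projected, cylindrical = root_areas(clean, length_mm, d_avg, scale)
    fit = fit_quadratic(poly, rotation="pca")
    curv = curvature(
        fit, where=config.curvature_at, scale=scale, log_base=config.log_base
    )
    return RootPhenotype(
        instance_id=mask.instance_id,
        label=mask.label,
        length_mm=length_mm,
        avg_diameter_mm=d_avg,
        max_diameter_mm=d_max,
        min_diameter_mm=d_min,
        projected_area_mm2=projected,
        cylindrical_surface_mm2=cylindrical,
        curvature=curv,
        timestamp=mask.timestamp,
    )


def _phenotype_row(p: RootPhenotype) -> dict:
    c = p.curvature
    return {
        "instance_id": p.instance_id,
        "label": p.label,
        "timestamp": p.timestamp,
        "length_mm": p.length_mm,
        "avg_diameter_mm": p.avg_diameter_mm,
        "max_diameter_mm": p.max_diameter_mm,
        "min_diameter_mm": p.min_diameter_mm,
        "projected_area_mm2": p.projected_area_mm2,
        "cylindrical_surface_mm2": p.cylindrical_surface_mm2,
        "curvature_per_mm": c.K if c else np.nan,
        "radius_of_curvature_mm": c.rho if c else np.nan,
        "curvature_mean_abs_per_mm": c.K_mean_abs if c else np.nan,
        "neg_log_curvature": c.neg_log_K if c else np.nan,
        "straight": c.straight if c else True,
        "status": p.status,
        "error": p.error,
    }


def phenotype_batch(
    masks,
    scale: ScaleModel | None = None,
    config: PhenotypeConfig | None = None,
) -> pd.DataFrame:
    """Trait table over a batch of instance masks (one row per instance).

    ``masks`` is a list of :class:`InstanceMask` or a directory of
    single-object mask PNGs (with optional JSON sidecars).  Per-instance
    failures are logged and recorded as ``status="failed"`` rows; the batch
    never aborts.  Columns are fixed (:data:`TRAIT_COLUMNS`) and the table
    is sorted by (timestamp, instance_id) so time-series of the same scene
    group naturally.
    """
    scale = scale or ScaleModel()
    config = config or PhenotypeConfig()
    if isinstance(masks, (str, Path)):
        from rootgrain.io_utils import read_masks_dir

        masks = read_masks_dir(masks)
    rows = []
    for mask in masks:
        if mask.score < config.min_score:
            continue
        try:
            rows.append(_phenotype_row(phenotype_instance(mask, scale, config)))
        except Exception as exc:  # degenerate instance: record and continue
            log.warning("instance %s failed: %s", mask.instance_id, exc)
            failed = RootPhenotype(
                instance_id=mask.instance_id,
                label=mask.label,
                length_mm=np.nan,
                avg_diameter_mm=np.nan,
                max_diameter_mm=np.nan,
                min_diameter_mm=np.nan,
                projected_area_mm2=np.nan,
                cylindrical_surface_mm2=np.nan,
                curvature=None,
                timestamp=mask.timestamp,
                status="failed",
                error=str(exc),
            )
            rows.append(_phenotype_row(failed))
    df = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["timestamp", "instance_id"], na_position="first"
        ).reset_index(drop=True)
    return df
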