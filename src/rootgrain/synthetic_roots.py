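"""Seeded synthetic root scenes with analytic ground truth.

The generator emulates scanner-style images of elongated, curved, possibly
overlapping roots on a soil-like speckle background at a stated dpi, with
exact per-instance ground truth (arc length, diameter, curvature), so the
whole tiling / post-processing / skeletonization / phenotyping pipeline is
testable offline.  It makes no attempt at photorealism: its purpose is
geometric ground truth, not scanner optics or root hairs.

Roots are parametric medial curves — straight segments, circular arcs
(curvature exactly 1/R) or quadratics — dilated to a constant or linearly
tapering diameter.  All randomness is driven by a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.draw import disk as _draw_disk

from rootgrain.annotation_tiler import AnnotationDoc, LabeledPolygon
from rootgrain.instance_postprocess import InstanceMask
from rootgrain.phenotypes import ScaleModel

__all__ = [
    "RootGroundTruth",
    "RootParams",
    "SceneGroundTruth",
    "gen_root",
    "gen_scene",
    "gen_timeseries",
]

_CURVE_KINDS = ("straight", "arc", "quadratic")


@dataclass(frozen=True)
class RootParams:
    """Parametric description of one synthetic root.

    ``curve`` is ``("straight",)``, ``("arc", radius_mm)`` or
    ``("quadratic", a, b, c)`` (coefficients in mm units, y = a x^2 + b x + c).
    ``diameter_mm`` is a constant or a ``(d_start, d_end)`` linear taper.
    """

    curve: tuple
    length_mm: float
    diameter_mm: float | tuple[float, float] = 0.6
    pattern: str = "curved"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.curve[0] not in _CURVE_KINDS:
            raise ValueError(f"unknown curve kind '{self.curve[0]}'")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        d = self.diameter_mm
        dmin = min(d) if isinstance(d, tuple) else d
        if dmin <= 0:
            raise ValueError("diameter_mm must be positive")


@dataclass
class RootGroundTruth:
    """Analytic truth for one generated root.

    ``length_mm`` is the tip-to-tip length of the rasterized root (medial
    curve plus the two rounded end caps); ``medial_px`` holds the cap-centre
    to cap-centre curve samples.
    """

    length_mm: float
    diameter_mm: float  # mean of the taper profile
    curvature_per_mm: float  # at the arc-length midpoint of the medial curve
    pattern: str
    medial_px: np.ndarray  # (N, 2) sub-pixel (x, y) samples of the true curve
    params: RootParams | None = None


@dataclass
class SceneGroundTruth:
    """One composed scene: image, per-instance masks and truths, annotations."""

    image: np.ndarray  # uint8 grayscale composite
    masks: list[InstanceMask]
    truths: list[RootGroundTruth]
    annotation: AnnotationDoc
    dpi: float
    day: int | None = None


def _inner_length_mm(params: RootParams) -> float:
    """Arc length of the medial curve between the two end-cap centres.

    ``length_mm`` is the tip-to-tip root length; the rounded caps extend
    half a diameter beyond each end of the medial curve.
    """
    d = params.diameter_mm
    d_mean = float(np.mean(d)) if isinstance(d, tuple) else float(d)
    return max(params.length_mm - d_mean, 0.5 * params.length_mm)


def _medial_curve_mm(params: RootParams, ds_mm: float) -> np.ndarray:
    """Sample the medial curve at ~ds_mm arc-length steps, local mm frame."""
    L = _inner_length_mm(params)
    n = max(int(math.ceil(L / ds_mm)), 2)
    s = np.linspace(0.0, L, n + 1)
    kind = params.curve[0]
    if kind == "straight":
        return np.stack([s, np.zeros_like(s)], axis=1)
    if kind == "arc":
        R = float(params.curve[1])
        theta = s / R
        return np.stack([R * np.sin(theta), R * (1 - np.cos(theta))], axis=1)
    # quadratic: march x so that arc length is uniform in s
    a, b, _c = (float(v) for v in params.curve[1:])
    xs = [0.0]
    step = ds_mm / 4.0
    acc = [0.0]
    x = 0.0
    while acc[-1] < L:
        slope = 2 * a * x + b
        x += step / math.sqrt(1.0 + slope * slope)
        xs.append(x)
        acc.append(acc[-1] + step)
    xs = np.interp(s, np.asarray(acc), np.asarray(xs))
    ys = a * xs**2 + b * xs  # constant offset folded into placement
    return np.stack([xs, ys], axis=1)


def _true_curvature(params: RootParams) -> float:
    kind = params.curve[0]
    if kind == "straight":
        return 0.0
    if kind == "arc":
        return 1.0 / float(params.curve[1])
    a, b, _c = (float(v) for v in params.curve[1:])
    # curvature at the arc-length midpoint of the sampled curve
    pts = _medial_curve_mm(params, ds_mm=0.05)
    xm = float(pts[len(pts) // 2, 0])
    yp = 2 * a * xm + b
    return abs(2 * a) / (1 + yp * yp) ** 1.5


def _diameter_profile(params: RootParams, n: int) -> np.ndarray:
    d = params.diameter_mm
    if isinstance(d, tuple):
        return np.linspace(d[0], d[1], n)
    return np.full(n, float(d))


def gen_root(
    params: RootParams,
    scale: ScaleModel | None = None,
    canvas_hw: tuple[int, int] | None = None,
    origin_px: tuple[float, float] | None = None,
    angle: float = 0.0,
) -> tuple[InstanceMask, RootGroundTruth]:
    """Rasterize one root; returns its mask and analytic ground truth.

    The medial curve is sampled at quarter-pixel arc-length steps, rotated
    by ``angle`` and shifted to ``origin_px``, then dilated by stamping
    disks of the local radius.  The resulting mask is a single connected
    component.  With an explicit ``canvas_hw``, a root that does not fit
    raises a ValueError.
    """
    scale = scale or ScaleModel()
    ds_mm = 0.25 / scale.px_per_mm
    curve_mm = _medial_curve_mm(params, ds_mm)
    pts = curve_mm * scale.px_per_mm  # to pixels
    if angle:
        c, s = math.cos(angle), math.sin(angle)
        pts = pts @ np.array([[c, s], [-s, c]])
    d_px = _diameter_profile(params, len(pts)) * scale.px_per_mm
    # true geometric dilation: pixel centres within d/2 of the curve
    # (+0.5 compensates the strict-inequality disk rasterization)
    radii = np.maximum(d_px / 2.0 + 0.5, 1.0)
    rmax = float(radii.max())
    if canvas_hw is None:
        margin = rmax + 3.0
        shift = margin - pts.min(axis=0)
        pts = pts + shift
        w = int(math.ceil(pts[:, 0].max() + margin))
        h = int(math.ceil(pts[:, 1].max() + margin))
        canvas_hw = (h, w)
    else:
        if origin_px is not None:
            pts = pts + np.asarray(origin_px, float)
        h, w = canvas_hw
        lo = pts.min(axis=0) - rmax
        hi = pts.max(axis=0) + rmax
        if lo[0] < 0 or lo[1] < 0 or hi[0] >= w or hi[1] >= h:
            raise ValueError(
                f"root (extent {lo} .. {hi}) does not fit canvas {canvas_hw}"
            )
    mask = np.zeros(canvas_hw, dtype=bool)
    for (x, y), r in zip(pts, radii):
        rr, cc = _draw_disk((y, x), r, shape=canvas_hw)
        mask[rr, cc] = True
    d = params.diameter_mm
    d_mean = float(np.mean(d)) if isinstance(d, tuple) else float(d)
    truth = RootGroundTruth(
        length_mm=params.length_mm,
        diameter_mm=d_mean,
        curvature_per_mm=_true_curvature(params),
        pattern=params.pattern,
        medial_px=pts,
        params=params,
    )
    return InstanceMask(pixels=mask, label="lateral root"), truth


def _mask_polygon(mask: np.ndarray, step: int = 4) -> list[tuple[float, float]]:
    """Longest outline of a mask as an (x, y) polygon, subsampled."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return []
    contour = max(contours, key=len)
    contour = contour[::step]
    return [(float(c), float(r)) for r, c in contour]


def _random_root_params(rng: np.random.Generator, pattern: str) -> RootParams:
    """Field-plausible cotton-root presets (lengths mm, diameters mm)."""
    if pattern == "curved":
        length = float(rng.uniform(8.0, 16.0))
        diameter = float(rng.uniform(0.5, 1.0))
        if rng.random() < 0.5:
            radius = float(rng.uniform(8.0, 25.0))
            curve = ("arc", radius)
        else:
            a = float(rng.uniform(0.02, 0.08) * rng.choice([-1.0, 1.0]))
            curve = ("quadratic", a, float(rng.uniform(-0.3, 0.3)), 0.0)
    else:
        length = float(rng.uniform(5.0, 10.0))
        diameter = float(rng.uniform(0.4, 0.8))
        if rng.random() < 0.5:
            curve = ("straight",)
        else:
            curve = ("arc", float(rng.uniform(150.0, 400.0)))  # nearly straight
    return RootParams(
        curve=curve, length_mm=length, diameter_mm=diameter, pattern=pattern
    )


def gen_scene(
    n_roots: int = 12,
    pattern_mix: float = 0.5,
    overlap_prob: float = 0.15,
    noise: float = 0.05,
    seed: int = 0,
    scale: ScaleModel | None = None,
    canvas_mm: float = 28.0,
    day: int | None = None,
) -> SceneGroundTruth:
    """Compose a scene of ``n_roots`` roots with known per-instance truth.

    ``pattern_mix`` is the fraction of curved-pattern roots; ``overlap_prob``
    is the chance a root is anchored on top of an already placed one;
    ``noise`` is the speckle fraction of the soil background.  Output masks
    are full-canvas per-instance masks (overlaps resolved in the composite
    image only, in favour of the later-drawn root); the annotation document
    holds one polygon per instance.
    """
    if n_roots < 0:
        raise ValueError("n_roots must be non-negative")
    scale = scale or ScaleModel()
    rng = np.random.default_rng(seed)
    side = int(round(canvas_mm * scale.px_per_mm))
    canvas_hw = (side, side)
    image = np.full(canvas_hw, 52, dtype=np.uint8)
    speckle = rng.random(canvas_hw) < noise
    image[speckle] = rng.integers(20, 110, int(speckle.sum()), dtype=np.uint8)
    masks: list[InstanceMask] = []
    truths: list[RootGroundTruth] = []
    shapes: list[LabeledPolygon] = []
    for i in range(n_roots):
        pattern = "curved" if rng.random() < pattern_mix else "straight"
        for _attempt in range(60):
            params = _random_root_params(rng, pattern)
            angle = float(rng.uniform(0.0, 2 * math.pi))
            extent = params.length_mm * scale.px_per_mm
            if extent + 40 >= side:
                continue
            if masks and rng.random() < overlap_prob:
                donor = masks[rng.integers(len(masks))]
                ys, xs = np.nonzero(donor.pixels)
                j = rng.integers(len(xs))
                origin = (float(xs[j]), float(ys[j]))
            else:
                margin = 30.0
                origin = (
                    float(rng.uniform(margin, side - margin)),
                    float(rng.uniform(margin, side - margin)),
                )
            try:
                mask, truth = gen_root(
                    params, scale, canvas_hw=canvas_hw,
                    origin_px=origin, angle=angle,
                )
            except ValueError:
                continue
            break
        else:
            raise RuntimeError("could not place a root; enlarge the canvas")
        mask.instance_id = i
        mask.label = "lateral root"
        mask.source_image = f"scene_{seed}.png"
        mask.timestamp = day
        mask.score = 1.0
        masks.append(mask)
        truths.append(truth)
        shade = int(rng.integers(170, 230))
        image[mask.pixels] = shade
        poly = _mask_polygon(mask.pixels)
        if len(poly) >= 3:
            shapes.append(LabeledPolygon(label=mask.label, points=poly))
    annotation = AnnotationDoc(
        shapes=shapes,
        image_path=f"scene_{seed}.png",
        image_data=None,
        image_height=side,
        image_width=side,
    )
    return SceneGroundTruth(
        image=image,
        masks=masks,
        truths=truths,
        annotation=annotation,
        dpi=scale.dpi,
        day=day,
    )


# Growth presets for the two observed growth patterns.  Curved roots
# elongate fast along an arc whose radius relaxes with age, so total bend
# (L/R) keeps rising while the fitted curvature K = 1/R drops and -ln K
# trends upward; straight roots elongate slowly at a near-zero, almost
# constant curvature.
_CURVED_L0, _CURVED_RATE = 3.0, 2.5  # mm, mm/day
_CURVED_R0, _CURVED_R_RATE = 10.0, 2.0  # mm, mm/day
_STRAIGHT_L0, _STRAIGHT_RATE = 3.0, 0.8
_STRAIGHT_RADIUS = 220.0  # mm; effectively straight


def gen_timeseries(
    pattern: str,
    n_days: int,
    seed: int = 0,
    n_roots: int = 6,
    scale: ScaleModel | None = None,
) -> list[SceneGroundTruth]:
    """Grow ``n_roots`` roots of one pattern over ``n_days`` daily scenes.

    Root identities persist across days (same instance ids and anchors);
    lengths increase strictly monotonically.  Per-root growth-rate
    multipliers are wider for the curved pattern, giving it the larger
    cross-instance length dispersion.
    """
    if pattern not in ("curved", "straight"):
        raise ValueError("pattern must be 'curved' or 'straight'")
    scale = scale or ScaleModel()
    rng = np.random.default_rng(seed)
    if pattern == "curved":
        rates = rng.uniform(0.75, 1.25, n_roots) * _CURVED_RATE
        l0 = _CURVED_L0
    else:
        rates = rng.uniform(0.9, 1.1, n_roots) * _STRAIGHT_RATE
        l0 = _STRAIGHT_L0
    diameters = rng.uniform(0.5, 0.9, n_roots)
    angles = rng.uniform(0.0, 2 * math.pi, n_roots)
    max_len_mm = l0 + float(rates.max()) * (n_days - 1)
    side = int(round((max_len_mm + 6.0) * scale.px_per_mm))
    canvas_hw = (side, side)
    anchors = rng.uniform(40.0, side - 40.0, size=(n_roots, 2))
    scenes: list[SceneGroundTruth] = []
    for day in range(n_days):
        image = np.full(canvas_hw, 52, dtype=np.uint8)
        masks, truths, shapes = [], [], []
        for i in range(n_roots):
            length = l0 + rates[i] * day
            if pattern == "curved":
                radius = _CURVED_R0 + _CURVED_R_RATE * day
                curve = ("arc", radius)
            else:
                curve = ("arc", _STRAIGHT_RADIUS)
            params = RootParams(
                curve=curve,
                length_mm=float(length),
                diameter_mm=float(diameters[i]),
                pattern=pattern,
                seed=seed,
            )
            # anchor at the canvas centre side: clip origin so the root fits
            mask, truth = gen_root(params, scale)
            full = np.zeros(canvas_hw, dtype=bool)
            mh, mw = mask.pixels.shape
            oy = int(min(anchors[i, 1], side - mh))
            ox = int(min(anchors[i, 0], side - mw))
            oy, ox = max(oy, 0), max(ox, 0)
            full[oy : oy + mh, ox : ox + mw] = mask.pixels
            inst = InstanceMask(
                pixels=full,
                label="lateral root",
                instance_id=i,
                source_image=f"{pattern}_day{day:02d}.png",
                timestamp=day,
            )
            truth.medial_px = truth.medial_px + np.array([ox, oy], float)
            masks.append(inst)
            truths.append(truth)
            image[full] = 200
            poly = _mask_polygon(full)
            if len(poly) >= 3:
                shapes.append(LabeledPolygon(label=inst.label, points=poly))
        annotation = AnnotationDoc(
            shapes=shapes,
            image_path=f"{pattern}_day{day:02d}.png",
            image_data=None,
            image_height=side,
            image_width=side,
        )
        scenes.append(
            SceneGroundTruth(
                image=image,
                masks=masks,
                truths=truths,
                annotation=annotation,
                dpi=scale.dpi,
                day=day,
            )
        )
    return scenes
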