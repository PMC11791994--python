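"""Tiling of oversized annotated root scans into fixed-size training tiles.

Flatbed-scanned in situ root images are far larger (up to ~10 200 x 14 039 px
at 1200 dpi) than what fits into GPU memory, so both the image and its
polygon annotation document are split into s x s tiles (2048 px by default).

Two polygon-splitting modes are provided:

``faithful``
    Vertex-deletion semantics: every point is shifted by the tile origin and
    points falling strictly outside ``[0, s]`` in either coordinate are
    deleted; shapes left with two or fewer vertices are dropped.  Boundary
    coordinates (0 and s exactly) are kept.  This distorts polygons that
    cross tile borders but reproduces the historical splitting behaviour
    used to build the original training set.

``clip``
    Geometric intersection of each polygon with the tile square; polygons
    crossing the border are cut cleanly and may split into several parts.
    Recommended for new datasets.
"""

from __future__ import annotations

import base64
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from shapely.geometry import GeometryCollection, MultiPolygon, Polygon, box

__all__ = [
    "AnnotationDoc",
    "AnnotationParseError",
    "LabeledPolygon",
    "TileSpec",
    "decode_image_data",
    "reencode_tile_image",
    "tile_annotation",
    "tile_grid",
]

#: canonical key order of the annotation dialect (Labelme)
_DOC_KEYS = ("shapes", "imagePath", "imageData", "imageHeight", "imageWidth")
_SHAPE_KEYS = ("label", "points")


class AnnotationParseError(ValueError):
    """A required annotation field is missing or malformed."""


@dataclass
class LabeledPolygon:
    """One labelled polygon outline (e.g. ``primary root``, ``lateral root``)."""

    label: str
    points: list[tuple[float, float]]
    #: unknown per-shape fields (shape_type, group_id, flags, ...) passed through
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict, index: int = 0) -> "LabeledPolygon":
        for key in _SHAPE_KEYS:
            if key not in d:
                raise AnnotationParseError(
                    f"shape {index}: missing required field '{key}'"
                )
        points = [(float(x), float(y)) for x, y in d["points"]]
        extra = {k: v for k, v in d.items() if k not in _SHAPE_KEYS}
        return cls(label=str(d["label"]), points=points, extra=extra)

    def to_dict(self) -> dict:
        d = {"label": self.label, "points": [[x, y] for x, y in self.points]}
        d.update(self.extra)
        return d


@dataclass
class AnnotationDoc:
    """Polygon annotation document for one scan (Labelme JSON dialect).

    Unknown fields are preserved verbatim in :attr:`extra`; :attr:`key_order`
    records the original top-level key order so a read-write round trip
    reproduces the document apart from float formatting.
    """

    shapes: list[LabeledPolygon]
    image_path: str
    image_height: int
    image_width: int
    image_data: str | None = None
    extra: dict = field(default_factory=dict)
    key_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise AnnotationParseError(
                "imageHeight and imageWidth must be positive, got "
                f"{self.image_height} x {self.image_width}"
            )
        if not self.key_order:
            self.key_order = tuple(self.extra) + _DOC_KEYS

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationDoc":
        for key in _DOC_KEYS:
            if key not in d:
                raise AnnotationParseError(f"missing required field '{key}'")
        shapes = [
            LabeledPolygon.from_dict(s, i) for i, s in enumerate(d["shapes"])
        ]
        extra = {k: v for k, v in d.items() if k not in _DOC_KEYS}
        return cls(
            shapes=shapes,
            image_path=str(d["imagePath"]),
            image_data=d["imageData"],
            image_height=int(d["imageHeight"]),
            image_width=int(d["imageWidth"]),
            extra=extra,
            key_order=tuple(d.keys()),
        )

    def to_dict(self) -> dict:
        known = {
            "shapes": [s.to_dict() for s in self.shapes],
            "imagePath": self.image_path,
            "imageData": self.image_data,
            "imageHeight": self.image_height,
            "imageWidth": self.image_width,
        }
        out: dict = {}
        for key in self.key_order:
            if key in known:
                out[key] = known.pop(key)
            elif key in self.extra:
                out[key] = self.extra[key]
        # fields never seen in key_order still have to be emitted
        out.update(known)
        for key, value in self.extra.items():
            out.setdefault(key, value)
        return out


@dataclass(frozen=True)
class TileSpec:
    """One tile of the splitting grid; origin is ``(col*s, row*s)``."""

    s: int
    row: int = 0
    col: int = 0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"tile size must be positive, got {self.s}")
        if self.row < 0 or self.col < 0:
            raise ValueError("tile grid indices must be non-negative")

    @property
    def origin(self) -> tuple[int, int]:
        return (self.col * self.s, self.row * self.s)


def _clip_polygon(
    points: Sequence[tuple[float, float]], s: int
) -> list[list[tuple[float, float]]]:
    """Intersect a polygon (tile-local coordinates) with the tile square."""
    if len(points) < 3:
        return []
    poly = Polygon(points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    clipped = poly.intersection(box(0.0, 0.0, float(s), float(s)))
    parts: list[list[tuple[float, float]]] = []
    geoms: Iterable
    if isinstance(clipped, Polygon):
        geoms = [clipped]
    elif isinstance(clipped, (MultiPolygon, GeometryCollection)):
        geoms = [g for g in clipped.geoms if isinstance(g, Polygon)]
    else:  # point/line touch only
        geoms = []
    for g in geoms:
        if g.is_empty or g.area == 0.0:
            continue
        coords = list(g.exterior.coords)[:-1]  # drop closing vertex
        if len(coords) >= 3:
            parts.append([(float(x), float(y)) for x, y in coords])
    return parts


def tile_annotation(
    doc: AnnotationDoc,
    tile: TileSpec,
    mode: str = "clip",
    image_data: str | None = None,
) -> AnnotationDoc:
    """Shift an annotation document into one tile's frame and crop its shapes.

    Parameters
    ----------
    doc : source annotation document.
    tile : the tile to extract; all points are shifted by ``-tile.origin``.
    mode : ``"faithful"`` (vertex deletion, strict inequality at the border)
        or ``"clip"`` (polygon-rectangle intersection).
    image_data : optional base64 payload (from :func:`reencode_tile_image`)
        to embed; by default ``imageData`` is null in the output.

    Returns
    -------
    AnnotationDoc with ``imageHeight == imageWidth == tile.s``.
    """
    if mode not in ("faithful", "clip"):
        raise ValueError(f"unknown mode '{mode}', expected faithful|clip")
    ox, oy = tile.origin
    s = tile.s
    out_shapes: list[LabeledPolygon] = []
    for shape in doc.shapes:
        shifted = [(x - ox, y - oy) for x, y in shape.points]
        if mode == "faithful":
            # strict test: boundary coordinates 0 and s are kept
            kept = [
                (x, y)
                for x, y in shifted
                if not (x > s or x < 0 or y > s or y < 0)
            ]
            if len(kept) <= 2:
                continue
            out_shapes.append(
                LabeledPolygon(shape.label, kept, dict(shape.extra))
            )
        else:
            for part in _clip_polygon(shifted, s):
                out_shapes.append(
                    LabeledPolygon(shape.label, part, dict(shape.extra))
                )
    return AnnotationDoc(
        shapes=out_shapes,
        image_path=doc.image_path,
        image_data=image_data,
        image_height=s,
        image_width=s,
        extra=dict(doc.extra),
        key_order=doc.key_order,
    )


def tile_grid(
    doc: AnnotationDoc,
    image: np.ndarray,
    s: int,
    mode: str = "clip",
    reencode: bool = False,
    pad_value: int = 0,
) -> list[tuple[TileSpec, AnnotationDoc, np.ndarray]]:
    """Split an image and its annotation document into a full tile grid.

    ``ceil(H/s) * ceil(W/s)`` tiles are produced; right/bottom edge tiles are
    padded to ``s x s`` with ``pad_value``.  Tile documents carry the shifted
    (and cropped) shapes of the source document; a polygon spanning several
    tiles appears in each of them.
    """
    if s <= 0:
        raise ValueError(f"tile size must be positive, got {s}")
    h, w = image.shape[:2]
    if (h, w) != (doc.image_height, doc.image_width):
        raise ValueError(
            f"image is {h} x {w} but annotation document declares "
            f"{doc.image_height} x {doc.image_width}"
        )
    n_rows = math.ceil(h / s)
    n_cols = math.ceil(w / s)
    tiles = []
    for row in range(n_rows):
        for col in range(n_cols):
            spec = TileSpec(s=s, row=row, col=col)
            ox, oy = spec.origin
            crop = image[oy : oy + s, ox : ox + s]
            if crop.shape[:2] != (s, s):
                padded_shape = (s, s) + crop.shape[2:]
                padded = np.full(padded_shape, pad_value, dtype=image.dtype)
                padded[: crop.shape[0], : crop.shape[1]] = crop
                crop = padded
            payload = reencode_tile_image(crop) if reencode else None
            tile_doc = tile_annotation(doc, spec, mode=mode, image_data=payload)
            tiles.append((spec, tile_doc, crop))
    return tiles


def reencode_tile_image(image: np.ndarray) -> str:
    """Encode a tile image to the base64 PNG payload of the ``imageData`` field.

    The encoding is lossless: decoding the returned string yields a
    pixel-identical array, so the tile document opens in the original
    annotation tool with the image displayed.
    """
    buf = io.BytesIO()
    Image.fromarray(np.asarray(image)).save(buf, format="PNG")
    return base64.b64encode(buf.getvalue()).decode("ascii")


def decode_image_data(payload: str) -> np.ndarray:
    """Inverse of :func:`reencode_tile_image`."""
    return np.array(Image.open(io.BytesIO(base64.b64decode(payload))))
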