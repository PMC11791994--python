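"""Readers/writers for annotation JSON, mask PNGs, trait CSVs and run config."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from rootgrain.annotation_tiler import AnnotationDoc, AnnotationParseError
from rootgrain.instance_postprocess import InstanceMask
from rootgrain.phenotypes import TRAIT_COLUMNS
from rootgrain.skeletonize import Polyline, Skeleton

__all__ = [
    "RunConfig",
    "read_annotation",
    "read_config",
    "read_image",
    "read_mask",
    "read_masks_dir",
    "write_annotation",
    "write_config",
    "write_mask",
    "write_skeleton_csv",
    "write_skeleton_png",
    "write_traits",
]


@dataclass
class RunConfig:
    """All pipeline defaults in one serializable record."""

    dpi: float = 1200.0
    tile_size: int = 2048
    tile_mode: str = "clip"
    min_score: float = 0.4
    connectivity: int = 8
    criterion: str = "area"
    thin_method: str = "k3m"
    min_branch_px: int = 10
    curvature_at: str = "midpoint"
    log_base: float = 2.718281828459045
    length_resample_px: float = 7.0
    log_level: str = "INFO"
    seed: int = 0


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def read_annotation(path: str | Path) -> AnnotationDoc:
    """Parse an annotation JSON document; errors name the offending field
    or (for truncated/invalid JSON) the byte offset."""
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(
            f"{path}: invalid JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc
    try:
        return AnnotationDoc.from_dict(data)
    except AnnotationParseError as exc:
        raise AnnotationParseError(f"{path}: {exc}") from exc


def write_annotation(doc: AnnotationDoc, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc.to_dict(), fh, indent=2)


def read_image(path: str | Path) -> np.ndarray:
    return np.array(Image.open(path))


def read_mask(path: str | Path) -> InstanceMask:
    """Read a single-object binary mask PNG (0 = background, 255 = object).

    A JSON sidecar ``<stem>.json`` holding label/score/bbox/instance_id/
    timestamp is applied when present.  Non-binary images are rejected with
    a hint to threshold them first.
    """
    path = Path(path)
    arr = np.array(Image.open(path).convert("L"))
    values = np.unique(arr)
    if not set(values.tolist()) <= {0, 1, 255}:
        raise ValueError(
            f"{path}: mask is not binary (values {values[:8].tolist()}...); "
            "threshold it to 0/255 first"
        )
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return InstanceMask(
        pixels=arr > 0,
        label=meta.get("label", "root"),
        score=float(meta.get("score", 1.0)),
        bbox=tuple(meta["bbox"]) if "bbox" in meta else None,
        source_image=meta.get("source_image", path.name),
        instance_id=int(meta.get("instance_id", 0)),
        timestamp=meta.get("timestamp"),
    )


def write_mask(mask: InstanceMask, path: str | Path, sidecar: bool = True) -> None:
    path = Path(path)
    Image.fromarray(mask.pixels.astype(np.uint8) * 255).save(path)
    if sidecar:
        meta = {
            "label": mask.label,
            "score": mask.score,
            "bbox": list(mask.bbox) if mask.bbox else None,
            "source_image": mask.source_image,
            "instance_id": mask.instance_id,
            "timestamp": mask.timestamp,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_masks_dir(directory: str | Path) -> list[InstanceMask]:
    return [read_mask(p) for p in sorted(Path(directory).glob("*.png"))]


def write_traits(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trait table with the stable documented header."""
    missing = [c for c in TRAIT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table is missing columns: {missing}")
    table.to_csv(path, index=False, columns=TRAIT_COLUMNS)


def write_skeleton_png(skel: Skeleton, path: str | Path) -> None:
    Image.fromarray(skel.mask.astype(np.uint8) * 255).save(path)


def write_skeleton_csv(poly: Polyline, path: str | Path) -> None:
    """Ordered skeleton coordinates, one ``x,y`` row per pixel."""
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for x, y in poly.points:
            fh.write(f"{x},{y}\n")
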