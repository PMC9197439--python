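"""Slide tiling, patch classification and TIL-map construction.

The prediction workflow: a slide (any raster image with known
microns-per-pixel) is partitioned into non-overlapping patches of fixed
*physical* size — 50 x 50 square microns by default, so 200 px at
0.25 mpp (40x) or 100 px at 0.5 mpp (20x).  Each patch is resized to the
classifier's input side and scored; scores thresholded into
TIL-positive/negative labels form a grid map over the slide, rendered as
red dots on a blue tissue background.

The grid therefore depends only on the slide's physical extent: two scans
of the same tissue at different magnifications produce identical map
shapes, and the number of patches a model must process is independent of
the model's input resolution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import SpecError

#: physical patch side in microns
PATCH_MICRONS = 50.0

_POSITIVE_COLOR = (220, 40, 40)   # red
_NEGATIVE_COLOR = (40, 60, 200)   # blue


@dataclass(frozen=True)
class SlideMeta:
    """Slide dimensions in pixels plus physical pixel size in microns."""

    width: int
    height: int
    mpp: float

    def __post_init__(self):
        if self.mpp <= 0:
            raise SpecError(f"mpp must be positive, got {self.mpp}")
        if self.width < 1 or self.height < 1:
            raise SpecError("slide dimensions must be positive")


@dataclass(frozen=True)
class PatchRef:
    """One grid cell: 0-based row/col plus its half-open pixel box."""

    row: int
    col: int
    x: int
    y: int
    side_px: int


def patch_grid(meta: SlideMeta, patch_microns: float = PATCH_MICRONS) -> list[PatchRef]:
    """Row-major grid of non-overlapping fixed-physical-size patches.

    ``side_px = round(patch_microns / mpp)``; trailing partial patches are
    dropped so every patch covers exactly the requested tissue area.  A
    slide smaller than one patch yields an empty list.
    """
    side_px = int(round(patch_microns / meta.mpp))
    if side_px < 1:
        raise SpecError(f"patch side rounds to zero at mpp={meta.mpp}")
    rows = meta.height // side_px
    cols = meta.width // side_px
    return [
        PatchRef(row=r, col=c, x=c * side_px, y=r * side_px, side_px=side_px)
        for r in range(rows) for c in range(cols)
    ]


def _extract(image: np.ndarray, p: PatchRef) -> np.ndarray:
    if (p.y + p.side_px > image.shape[0]) or (p.x + p.side_px > image.shape[1]):
        raise SpecError(f"patch (row={p.row}, col={p.col}) exceeds image bounds")
    return image[p.y:p.y + p.side_px, p.x:p.x + p.side_px]


def classify_patches(model, image: np.ndarray, patches: list[PatchRef],
                     input_side: int, batch_size: int = 64) -> np.ndarray:
    """Score every patch with ``model``; order follows ``patches``.

    Each patch is resized bilinearly from its native pixel size to the
    model's input side and normalized to ``[-1, 1]``.  ``model`` is
    anything exposing ``predict_proba(x) -> (n, 2)`` (positive class is
    column 1) or a plain callable returning per-patch scores.
    """
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    batch = []
    for p in patches:
        tile = _extract(image, p)
        im = Image.fromarray(np.ascontiguousarray(tile.astype(np.uint8)))
        im = im.resize((input_side, input_side), Image.Resampling.BILINEAR)
        batch.append(np.asarray(im, dtype=np.float32) / 127.5 - 1.0)
    if not batch:
        return np.zeros(0)
    x = np.stack(batch)
    if hasattr(model, "predict_proba"):
        scores = []
        for i in range(0, len(x), batch_size):
            scores.append(np.asarray(model.predict_proba(x[i:i + batch_size]))[:, 1])
        return np.concatenate(scores)
    return np.asarray(model(x), dtype=float)


@dataclass
class TILMap:
    """Grid of per-patch scores and labels over a slide."""

    scores: np.ndarray           # (rows, cols) float in [0, 1]
    labels: np.ndarray           # (rows, cols) bool, score >= threshold
    slide: SlideMeta
    threshold: float

    @property
    def positive_fraction(self) -> float:
        return float(self.labels.mean()) if self.labels.size else 0.0


def build_til_map(scores, patches: list[PatchRef], meta: SlideMeta,
                  threshold: float = 0.5) -> TILMap:
    """Assemble patch scores into a grid map; positive means score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(patches):
        raise SpecError(f"{len(scores)} scores for {len(patches)} patches")
    rows = max((p.row for p in patches), default=-1) + 1
    cols = max((p.col for p in patches), default=-1) + 1
    grid = np.zeros((rows, cols), dtype=float)
    for s, p in zip(scores, patches):
        grid[p.row, p.col] = s
    return TILMap(scores=grid, labels=grid >= threshold, slide=meta,
                  threshold=threshold)


def write_map_csv(tmap: TILMap, path) -> None:
    """Write ``row, col, score, label`` records, one per grid cell."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "score", "label"])
        rows, cols = tmap.scores.shape
        for r in range(rows):
            for c in range(cols):
                writer.writerow([r, c, repr(float(tmap.scores[r, c])),
                                 int(tmap.labels[r, c])])


def read_map_csv(path, meta: SlideMeta, threshold: float = 0.5) -> TILMap:
    """Inverse of :func:`write_map_csv`."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append((int(rec["row"]), int(rec["col"]),
                         float(rec["score"]), int(rec["label"])))
    if not rows:
        return TILMap(np.zeros((0, 0)), np.zeros((0, 0), dtype=bool),
                      meta, threshold)
    nr = max(r for r, _, _, _ in rows) + 1
    nc = max(c for _, c, _, _ in rows) + 1
    scores = np.zeros((nr, nc))
    labels = np.zeros((nr, nc), dtype=bool)
    for r, c, s, l in rows:
        scores[r, c] = s
        labels[r, c] = bool(l)
    return TILMap(scores=scores, labels=labels, slide=meta, threshold=threshold)


def render_png(tmap: TILMap, path, cell_px: int = 8) -> None:
    """Render the map: red dots (positive) on a blue background."""
    rows, cols = tmap.labels.shape
    img = np.zeros((max(rows, 1) * cell_px, max(cols, 1) * cell_px, 3),
                   dtype=np.uint8)
    img[:, :] = _NEGATIVE_COLOR
    yy, xx = np.mgrid[0:cell_px, 0:cell_px] - (cell_px - 1) / 2.0
    dot = (yy ** 2 + xx ** 2) <= (cell_px / 2.4) ** 2
    for r in range(rows):
        for c in range(cols):
            if tmap.labels[r, c]:
                cell = img[r * cell_px:(r + 1) * cell_px,
                           c * cell_px:(c + 1) * cell_px]
                cell[dot] = _POSITIVE_COLOR
    Image.fromarray(img).save(path)


def read_png_labels(path) -> np.ndarray:
    """Recover the boolean label grid from a rendered map (exact round-trip)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    cell = _infer_cell(arr)
    rows, cols = arr.shape[0] // cell, arr.shape[1] // cell
    labels = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            center = arr[r * cell + cell // 2, c * cell + cell // 2]
            labels[r, c] = tuple(center) == _POSITIVE_COLOR
    return labels


def _infer_cell(arr: np.ndarray, default: int = 8) -> int:
    return default
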