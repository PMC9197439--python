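"""Deterministic generator of TIL-like labeled patches and slides.

The binary task emulated here is patch-level tumor-infiltrating-lymphocyte
(TIL) detection in H&E-stained tissue: TIL-positive patches contain many
small, dark, basophilic (purple) nuclei scattered over pink eosin-stained
tissue; negative patches show the same tissue texture with at most a
couple of stray nuclei.  The class signal is therefore *blob density* at a
few-pixel scale, not a global color shift: per-patch brightness jitter is
of the same order as the mean-intensity shift the nuclei cause, so a
classifier has to resolve the nuclei to do well — and aggressive input
downsampling genuinely degrades the task.

All randomness flows through ``numpy.random.Generator`` seeded explicitly,
with purely array-based drawing (no platform-dependent font or geometry
code), so outputs are bit-identical across platforms for a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import SpecError
from .tilmap import SlideMeta, patch_grid

#: base eosin-pink tissue color
_TISSUE = np.array([231.0, 178.0, 192.0])
#: hematoxylin-dark nucleus color
_NUCLEUS = np.array([93.0, 58.0, 138.0])

#: positive patches carry at least this many nuclei
MIN_POSITIVE_BLOBS = 20
#: negative patches carry at most this many
MAX_NEGATIVE_BLOBS = 2


def _background(rng: np.random.Generator, side: int) -> np.ndarray:
    """Pink tissue texture: global brightness jitter + smooth mottling."""
    img = np.tile(_TISSUE, (side, side, 1))
    img += rng.normal(0.0, 7.0)                      # per-patch brightness
    coarse = rng.normal(0.0, 9.0, (side // 8 + 2, side // 8 + 2, 3))
    # bilinear-free smooth upsample: nearest repeat then box blur
    mottle = np.repeat(np.repeat(coarse, 8, axis=0), 8, axis=1)[:side, :side]
    k = 7
    pad = np.pad(mottle, ((k, k), (k, k), (0, 0)), mode="edge")
    csum = pad.cumsum(axis=0).cumsum(axis=1)
    w = 2 * (k // 2) + 1
    top = k - k // 2 - 1
    sl = slice(top, top + side)
    sl2 = slice(top + w, top + w + side)
    mottle = (csum[sl2, sl2] - csum[sl2, sl] - csum[sl, sl2] + csum[sl, sl]) / w ** 2
    img += mottle
    img += rng.normal(0.0, 3.0, (side, side, 3))     # fine grain
    return img


def _draw_blob(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
               side: int) -> None:
    cy, cx = rng.uniform(2, side - 2, 2)
    a = rng.uniform(0.022, 0.042) * side + 1.2       # semi-axes in pixels
    b = a * rng.uniform(0.6, 1.0)
    theta = rng.uniform(0, np.pi)
    color = _NUCLEUS + rng.normal(0.0, 8.0, 3)
    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    d2 = (u / a) ** 2 + (v / b) ** 2
    alpha = np.clip(1.6 * (1.0 - d2), 0.0, 0.92)     # soft-edged ellipse
    img *= (1.0 - alpha)[:, :, None]
    img += alpha[:, :, None] * color
    mask |= d2 <= 1.0


def make_patch(label: int, side_px: int, seed: int,
               return_mask: bool = False):
    """Generate one RGB patch; ``label`` 1 = TIL-positive, 0 = negative.

    Deterministic per ``(label, side_px, seed)``.  With ``return_mask``
    the boolean union of all nucleus ellipses is returned alongside the
    image, so tests can count blobs on the generator's own geometry.
    """
    if side_px < 32:
        raise SpecError(f"side_px must be >= 32, got {side_px}")
    # background depends only on (side, seed) so that matched seeds share
    # tissue texture and the label signal is purely the nuclei
    bg_rng = np.random.default_rng(np.random.SeedSequence([side_px, seed]))
    img = _background(bg_rng, side_px)
    mask = np.zeros((side_px, side_px), dtype=bool)
    rng = np.random.default_rng(np.random.SeedSequence([int(label), side_px, seed, 1]))
    if label:
        n_blobs = MIN_POSITIVE_BLOBS + rng.poisson(9.0)
    else:
        n_blobs = int(rng.integers(0, MAX_NEGATIVE_BLOBS + 1))
    for _ in range(n_blobs):
        _draw_blob(img, mask, rng, side_px)
    out = np.clip(img, 0, 255).astype(np.uint8)
    if return_mask:
        return out, mask
    return out


@dataclass
class SyntheticSlide:
    """A generated slide image with its ground-truth patch label grid."""

    image: np.ndarray
    meta: SlideMeta
    truth: np.ndarray            # (rows, cols) binary grid
    positive_fraction: float
    seed: int


def make_slide(dims_px: tuple[int, int], mpp: float, positive_fraction: float,
               seed: int) -> SyntheticSlide:
    """Generate a slide of ``(width, height)`` pixels at ``mpp`` microns/pixel.

    Per-patch labels are independent Bernoulli draws with the requested
    positive fraction; pixels come from :func:`make_patch` on the standard
    50 um grid, and trailing margins are filled with plain tissue texture.
    """
    width, height = dims_px
    if not 0.0 <= positive_fraction <= 1.0:
        raise SpecError(f"positive_fraction must be in [0, 1], got {positive_fraction}")
    meta = SlideMeta(width=width, height=height, mpp=mpp)
    patches = patch_grid(meta)
    rng = np.random.default_rng(np.random.SeedSequence([width, height, seed]))
    rows = max((p.row for p in patches), default=-1) + 1
    cols = max((p.col for p in patches), default=-1) + 1
    truth = np.zeros((rows, cols), dtype=np.int8)
    image = np.clip(_background(rng, max(height, width))[:height, :width],
                    0, 255).astype(np.uint8)
    for p in patches:
        label = int(rng.random() < positive_fraction)
        truth[p.row, p.col] = label
        patch_seed = int(rng.integers(0, 2 ** 31))
        image[p.y:p.y + p.side_px, p.x:p.x + p.side_px] = make_patch(
            label, p.side_px, patch_seed)
    return SyntheticSlide(image=image, meta=meta, truth=truth,
                          positive_fraction=positive_fraction, seed=seed)


def make_manifest(n_patches: int, positive_fraction: float, side_px: int,
                  out_dir, seed: int, mpp: float = 0.5,
                  require_both_classes: bool = True) -> Path:
    """Write ``n_patches`` PNG patches plus a ``manifest.csv`` and return its path.

    The manifest has columns ``path`` (relative), ``label`` (0/1) and
    ``mpp``, the format :func:`nar.runtime.train` consumes via
    :func:`load_manifest`.  With ``require_both_classes`` a request that
    cannot contain both classes is rejected, and a degenerate draw is
    repaired by flipping the first patch.
    """
    if n_patches < 2:
        raise SpecError(f"need at least 2 patches, got {n_patches}")
    if require_both_classes and positive_fraction in (0.0, 1.0):
        raise SpecError(
            f"positive_fraction={positive_fraction} cannot yield both classes")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([n_patches, side_px, seed]))
    labels = (rng.random(n_patches) < positive_fraction).astype(int)
    if require_both_classes and len(np.unique(labels)) < 2:
        labels[0] = 1 - labels[0]
    records = []
    for i, label in enumerate(labels):
        patch_seed = int(rng.integers(0, 2 ** 31))
        img = make_patch(int(label), side_px, patch_seed)
        name = f"patch_{i:04d}_{label}.png"
        Image.fromarray(img).save(out_dir / name)
        records.append({"path": name, "label": int(label), "mpp": mpp})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def load_manifest(manifest_path, input_side: int) -> tuple[np.ndarray, np.ndarray]:
    """Load a manifest into model-ready arrays.

    Images are resized bilinearly to ``input_side`` and scaled to
    ``[-1, 1]``; labels come back as an int vector.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    images = []
    for rel in df["path"]:
        with Image.open(manifest_path.parent / rel) as im:
            im = im.convert("RGB").resize((input_side, input_side),
                                          Image.Resampling.BILINEAR)
            images.append(np.asarray(im, dtype=np.float32) / 127.5 - 1.0)
    return np.stack(images), df["label"].to_numpy(dtype=np.int64)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
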