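"""Preprocessing and overlapped sliding-window tiling.

Inference preprocessing is CLAHE (contrast-limited adaptive histogram
equalization, removing field-level illumination nonuniformity) followed by
per-image zero-mean / unit-variance normalization.  The image is then cut
into overlapped ``patch_size`` x ``patch_size`` windows: each window carries
a disposable ``overlap_margin``-pixel rim per side (stride =
``patch_size - 2 * overlap_margin``), and only the margin-free core of each
per-window prediction is stitched back, so every output pixel comes from
exactly one window and never from a window edge where context is truncated.
Borders and remainders are reflect-padded to avoid artificial dark rims.

The stitching is hard core-cropping (no blending): output is independent of
window visitation order and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from distseg.io_formats import Image


@dataclass(frozen=True)
class PreprocessConfig:
    """CLAHE and tiling parameters.

    clahe_clip_limit
        Histogram clip factor; per-tile 256-bin histograms are clipped at
        ``clip_limit * tile_pixels / 256`` with the excess redistributed
        uniformly (the de-facto default semantics of mainstream CLAHE
        implementations).
    clahe_grid
        Tiles per axis (rows, cols).
    patch_size, overlap_margin
        Sliding-window geometry; stride is ``patch_size - 2*overlap_margin``.
    """

    clahe_clip_limit: float = 2.0
    clahe_grid: tuple[int, int] = (8, 8)
    patch_size: int = 256
    overlap_margin: int = 32

    def __post_init__(self) -> None:
        if self.patch_size <= 2 * self.overlap_margin:
            raise ValueError("patch_size must exceed 2*overlap_margin")
        if min(self.clahe_grid) < 1:
            raise ValueError("clahe_grid must be >= 1 per axis")

    @property
    def stride(self) -> int:
        return self.patch_size - 2 * self.overlap_margin


@dataclass(frozen=True)
class PatchGrid:
    """Tiling layout of overlapped windows over a (padded) image.

    ``windows`` are (row0, col0) anchors into the padded image; adjacent
    anchors differ by the stride, except the last along each axis which is
    clamped so its window ends exactly at the padded edge.  ``core_regions``
    are half-open (r0, r1, c0, c1) rectangles that partition the padded
    image; each lies inside its window at least ``overlap_margin`` from the
    window edge except where the window touches the padded-image border.
    """

    image_height: int
    image_width: int
    patch_size: int
    overlap_margin: int
    padded_height: int
    padded_width: int
    pad_spec: tuple[int, int, int, int]  # top, bottom, left, right
    windows: tuple[tuple[int, int], ...]
    core_regions: tuple[tuple[int, int, int, int], ...]


def _axis_plan(n: int, patch: int, margin: int) -> tuple[int, list[int], list[tuple[int, int]]]:
    """Anchors and core intervals along one axis of length ``n``.

    Returns (padded length, anchors, core (start, stop) pairs).
    """
    stride = patch - 2 * margin
    padded = max(n + 2 * margin, patch)
    if padded == patch:
        anchors = [0]
    else:
        k = int(np.ceil((padded - patch) / stride)) + 1
        anchors = [min(i * stride, padded - patch) for i in range(k)]
    bounds = [0]
    for a in anchors[1:]:
        bounds.append(a + margin)
    bounds.append(padded)
    cores = list(zip(bounds[:-1], bounds[1:]))
    return padded, anchors, cores


def plan_tiles(height: int, width: int, config: PreprocessConfig | None = None) -> PatchGrid:
    """Plan the overlapped sliding-window layout for an image shape."""
    config = config or PreprocessConfig()
    patch, margin = config.patch_size, config.overlap_margin
    ph, row_anchors, row_cores = _axis_plan(height, patch, margin)
    pw, col_anchors, col_cores = _axis_plan(width, patch, margin)
    pad_top, pad_left = margin, margin
    pad_bottom, pad_right = ph - height - margin, pw - width - margin
    windows = tuple((r, c) for r in row_anchors for c in col_anchors)
    cores = tuple(
        (r0, r1, c0, c1) for (r0, r1) in row_cores for (c0, c1) in col_cores
    )
    return PatchGrid(
        image_height=height,
        image_width=width,
        patch_size=patch,
        overlap_margin=margin,
        padded_height=ph,
        padded_width=pw,
        pad_spec=(pad_top, pad_bottom, pad_left, pad_right),
        windows=windows,
        core_regions=cores,
    )


def reflect_pad(arr: np.ndarray, pads: tuple[int, int, int, int]) -> np.ndarray:
    """Reflect-pad (mirror without edge duplication), tolerating pads
    larger than the array by applying the reflection repeatedly."""
    top, bottom, left, right = pads
    out = arr
    while top or bottom or left or right:
        t = min(top, max(out.shape[0] - 1, 1))
        b = min(bottom, max(out.shape[0] - 1, 1))
        l = min(left, max(out.shape[1] - 1, 1))
        r = min(right, max(out.shape[1] - 1, 1))
        mode = "reflect" if min(out.shape) > 1 else "edge"
        out = np.pad(out, ((t, b), (l, r)), mode=mode)
        top, bottom, left, right = top - t, bottom - b, left - l, right - r
    return out


def padded_image(img: np.ndarray, grid: PatchGrid) -> np.ndarray:
    if img.shape != (grid.image_height, grid.image_width):
        raise ValueError(
            f"grid planned for {(grid.image_height, grid.image_width)}, "
            f"image is {img.shape}"
        )
    return reflect_pad(img, grid.pad_spec)


def extract_patches(img: Image | np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    """Cut the reflect-padded image into windows, row-major anchor order."""
    arr = img.pixels if isinstance(img, Image) else np.asarray(img)
    padded = padded_image(arr, grid)
    p = grid.patch_size
    return [padded[r : r + p, c : c + p] for (r, c) in grid.windows]


def stitch(patch_outputs: Sequence[np.ndarray], grid: PatchGrid) -> np.ndarray:
    """Assemble per-window outputs into a full-size map via core cropping."""
    if len(patch_outputs) != len(grid.windows):
        raise ValueError(
            f"expected {len(grid.windows)} patch outputs, got {len(patch_outputs)}"
        )
    p = grid.patch_size
    canvas = np.zeros((grid.padded_height, grid.padded_width), dtype=np.float64)
    for out, (wr, wc), (r0, r1, c0, c1) in zip(
        patch_outputs, grid.windows, grid.core_regions
    ):
        out = np.asarray(out)
        if out.shape != (p, p):
            raise ValueError(f"patch output shape {out.shape}, expected {(p, p)}")
        canvas[r0:r1, c0:c1] = out[r0 - wr : r1 - wr, c0 - wc : c1 - wc]
    top, _, left, _ = grid.pad_spec
    return canvas[top : top + grid.image_height, left : left + grid.image_width]


def clahe(
    img: Image | np.ndarray,
    clip_limit: float = 2.0,
    grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is min-max scaled to [0, 255] and partitioned into ``grid``
    tiles.  Each tile's 256-bin histogram is clipped at
    ``clip_limit * tile_pixels / 256`` with the excess redistributed
    uniformly over all bins; the per-tile CDF transfer functions are then
    applied with bilinear interpolation between tile centers.  Output is
    float in [0, 255].  A constant image is returned spatially constant.
    """
    arr = (img.pixels if isinstance(img, Image) else np.asarray(img)).astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.full(arr.shape, 127.5)
    scaled = (arr - lo) / (hi - lo) * 255.0
    quant = np.clip(scaled, 0, 255).astype(np.uint8)

    gr, gc = grid
    h, w = quant.shape
    gr, gc = min(gr, h), min(gc, w)
    # pad to a multiple of the tile grid so tiles are equal-sized
    th, tw = int(np.ceil(h / gr)), int(np.ceil(w / gc))
    padded = reflect_pad(quant, (0, th * gr - h, 0, tw * gc - w))
    tiles = padded.reshape(gr, th, gc, tw).transpose(0, 2, 1, 3).reshape(gr, gc, th * tw)

    nbins = 256
    hist = np.zeros((gr, gc, nbins), dtype=np.float64)
    for i in range(gr):
        for j in range(gc):
            hist[i, j] = np.bincount(tiles[i, j], minlength=nbins)
    clip = max(clip_limit * (th * tw) / nbins, 1.0)
    excess = np.clip(hist - clip, 0, None).sum(axis=2, keepdims=True)
    hist = np.minimum(hist, clip) + excess / nbins
    cdf = np.cumsum(hist, axis=2)
    # transfer function per tile, mapping bin -> [0, 255]
    luts = (cdf - cdf[:, :, :1]) / np.maximum(cdf[:, :, -1:] - cdf[:, :, :1], 1e-12) * 255.0

    # bilinear blend between the 4 surrounding tile transfer functions
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    fr = np.clip((rows + 0.5) / th - 0.5, 0, gr - 1)
    fc = np.clip((cols + 0.5) / tw - 0.5, 0, gc - 1)
    r0 = np.floor(fr).astype(int)
    c0 = np.floor(fc).astype(int)
    r1 = np.minimum(r0 + 1, gr - 1)
    c1 = np.minimum(c0 + 1, gc - 1)
    wr = fr - r0
    wc = fc - c0

    v = quant[:h, :w].astype(int)
    rr0 = np.broadcast_to(r0, (h, w))
    rr1 = np.broadcast_to(r1, (h, w))
    cc0 = np.broadcast_to(c0, (h, w))
    cc1 = np.broadcast_to(c1, (h, w))
    t00 = luts[rr0, cc0, v]
    t01 = luts[rr0, cc1, v]
    t10 = luts[rr1, cc0, v]
    t11 = luts[rr1, cc1, v]
    wr = np.broadcast_to(wr, (h, w))
    wc = np.broadcast_to(wc, (h, w))
    out = (
        (1 - wr) * ((1 - wc) * t00 + wc * t01)
        + wr * ((1 - wc) * t10 + wc * t11)
    )
    return out


def znorm(img: Image | np.ndarray) -> np.ndarray:
    """Per-image zero-mean / unit-variance normalization.

    A constant image (zero variance) maps to all zeros.
    """
    arr = (img.pixels if isinstance(img, Image) else np.asarray(img)).astype(np.float64)
    mu = arr.mean()
    sd = arr.std()
    if sd == 0:
        return np.zeros_like(arr)
    return (arr - mu) / sd


def preprocess_image(img: Image | np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """CLAHE then z-normalization — the full inference-time preprocessing."""
    config = config or PreprocessConfig()
    return znorm(clahe(img, config.clahe_clip_limit, config.clahe_grid))


def bilinear_resize(arr: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resample with the corner-aligned-off convention
    (output pixel i samples input coordinate (i + 0.5) * n_in / n_out - 0.5,
    clamped at the edges)."""
    h_in, w_in = arr.shape
    h_out, w_out = out_shape
    rows = np.clip((np.arange(h_out) + 0.5) * h_in / h_out - 0.5, 0, h_in - 1)
    cols = np.clip((np.arange(w_out) + 0.5) * w_in / w_out - 0.5, 0, w_in - 1)
    coords = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(
        arr.astype(np.float64), coords, order=1, mode="nearest"
    )


def upsample_patch(patch: np.ndarray, factor: int) -> np.ndarray:
    """Bilinearly upsample a patch by an integer factor (factor 1 = identity).

    Used by backbone adapters whose native input exceeds the patch size
    (e.g. 1024 for a SAM-style encoder fed 256-pixel windows).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return np.asarray(patch, dtype=np.float64).copy()
    h, w = patch.shape
    return bilinear_resize(np.asarray(patch), (h * factor, w * factor))


def downsample_pred(pred: np.ndarray, out_size: int = 256) -> np.ndarray:
    """Bilinearly resample a prediction back to the patch resolution."""
    return bilinear_resize(np.asarray(pred), (out_size, out_size))


def tiled_inference(
    img: Image | np.ndarray,
    predict: Callable[[np.ndarray], np.ndarray],
    config: PreprocessConfig | None = None,
    preprocess: bool = True,
) -> np.ndarray:
    """Full-image distance-map inference: preprocess, tile, predict, stitch."""
    config = config or PreprocessConfig()
    arr = img.pixels if isinstance(img, Image) else np.asarray(img)
    prepped = preprocess_image(arr, config) if preprocess else arr
    grid = plan_tiles(arr.shape[0], arr.shape[1], config)
    patches = extract_patches(prepped, grid)
    outputs = [np.asarray(predict(p), dtype=np.float64) for p in patches]
    return stitch(outputs, grid)
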