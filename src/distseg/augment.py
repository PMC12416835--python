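"""Training-time augmentation.

Five transforms: horizontal mirroring (p = 0.5), rotation uniform in
[-180, 180] degrees, rescaling uniform in [80%, 120%], brightness
multiplication uniform in [95%, 105%], and intensity inversion (p = 0.5).
Inversion makes the model agnostic to imaging polarity (bright cells on a
dark field vs. dark cells on a bright field).

Only the geometric transforms (mirror, rotation, rescale) are applied to
the distance-map target; brightness and inversion are photometric and
never touch it.  Per-cell normalization makes the target scale-invariant
up to interpolation error, so rescaling does not renormalize it.  Each
epoch draws exactly one augmented 256x256 patch from every training image.

Order of training-time operations: geometric -> brightness -> inversion
(on the raw intensity scale, x -> max - x) -> CLAHE -> z-normalization.
Keeping CLAHE's nonlinearity downstream of the photometric jitter means
the jitter is not undone by normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage


PATCH = 256


@dataclass(frozen=True)
class AugmentationSpec:
    """A fully-determined draw of the augmentation parameters."""

    mirror: bool
    rotation_deg: float  # in [-180, 180]
    scale: float  # in [0.8, 1.2]
    brightness: float  # in [0.95, 1.05]
    invert: bool
    crop_anchor: tuple[int, int]  # top-left of the 256x256 crop, post-scale
    seed: int


def _scaled_shape(shape: tuple[int, int], scale: float) -> tuple[int, int]:
    return (int(round(shape[0] * scale)), int(round(shape[1] * scale)))


def sample_spec(rng_seed: int, image_shape: tuple[int, int]) -> AugmentationSpec:
    """Draw an AugmentationSpec; the same seed yields the identical spec."""
    rng = np.random.default_rng(rng_seed)
    mirror = bool(rng.random() < 0.5)
    rotation = float(rng.uniform(-180.0, 180.0))
    scale = float(rng.uniform(0.8, 1.2))
    brightness = float(rng.uniform(0.95, 1.05))
    invert = bool(rng.random() < 0.5)
    sh, sw = _scaled_shape(image_shape, scale)
    if sh < PATCH or sw < PATCH:
        raise ValueError(
            f"image of shape {image_shape} too small for a {PATCH} crop at "
            f"scale {scale:.3f}; pad first"
        )
    anchor = (int(rng.integers(0, sh - PATCH + 1)), int(rng.integers(0, sw - PATCH + 1)))
    return AugmentationSpec(
        mirror=mirror,
        rotation_deg=rotation,
        scale=scale,
        brightness=brightness,
        invert=invert,
        crop_anchor=anchor,
        seed=int(rng_seed),
    )


def _geometric(arr: np.ndarray, spec: AugmentationSpec, fill_reflect: bool) -> np.ndarray:
    """mirror -> rotation -> rescale, bilinear; reflect fill for images,
    zero fill for distance maps (0 is the defined background value)."""
    out = arr.astype(np.float64)
    if spec.mirror:
        out = out[:, ::-1]
    mode = "reflect" if fill_reflect else "constant"
    if spec.rotation_deg != 0.0:
        out = ndimage.rotate(
            out, spec.rotation_deg, reshape=False, order=1, mode=mode, cval=0.0
        )
    if spec.scale != 1.0:
        target = _scaled_shape(arr.shape, spec.scale)
        zoom = (target[0] / out.shape[0], target[1] / out.shape[1])
        zmode = "grid-mirror" if fill_reflect else "grid-constant"
        out = ndimage.zoom(out, zoom, order=1, mode=zmode, cval=0.0, grid_mode=True)
    return out


def apply(
    img: np.ndarray, dmap: np.ndarray, spec: AugmentationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Apply an AugmentationSpec to an image and its distance-map target.

    Returns the augmented 256x256 image patch (photometric transforms
    applied) and the augmented 256x256 distance-map patch (geometric only,
    clipped back to [0, 1]).
    """
    if img.shape != dmap.shape:
        raise ValueError("image and distance map must share a shape")
    gi = _geometric(np.asarray(img), spec, fill_reflect=True)
    gd = np.clip(_geometric(np.asarray(dmap), spec, fill_reflect=False), 0.0, 1.0)
    r, c = spec.crop_anchor
    if r < 0 or c < 0 or r + PATCH > gi.shape[0] or c + PATCH > gi.shape[1]:
        raise ValueError(
            f"crop anchor {spec.crop_anchor} outside bounds {gi.shape}; pad first"
        )
    pi = gi[r : r + PATCH, c : c + PATCH]
    pd = gd[r : r + PATCH, c : c + PATCH].copy()
    pi = pi * spec.brightness
    if spec.invert:
        pi = pi.max() - pi
    return pi, pd


def epoch_sampler(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    epoch_seed: int,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield one augmented (patch, target) pair per image, shuffled.

    The stream is fully reproducible from ``epoch_seed``.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    root = np.random.SeedSequence(epoch_seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    order = order_rng.permutation(len(dataset))
    child_seeds = root.generate_state(len(dataset)) % (2**31)
    for idx in order:
        img, dmap = dataset[idx]
        spec = sample_spec(int(child_seeds[idx]), img.shape)
        yield apply(img, dmap, spec)
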