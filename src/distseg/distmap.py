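"""Per-cell normalized Euclidean distance maps — the regression target.

For every cell pixel p in cell c the raw value is the Euclidean distance
from p to the nearest pixel center NOT belonging to c (background or a
different cell), so touching cells produce a valley between them.  Each
cell is then normalized by its own maximum, putting every cell's interior
peak at exactly 1 regardless of cell size; background stays exactly 0.
A boundary-adjacent cell pixel therefore has raw distance 1 (standard
discrete EDT convention, pixel-center metric).  Pixel centers beyond the
image frame count as background, so a cell touching the frame border still
has a well-defined boundary there.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

from distseg.io_formats import LabelMask


def compute_distance_map(mask: LabelMask | np.ndarray) -> np.ndarray:
    """Per-cell normalized Euclidean distance map of an instance mask.

    Parameters
    ----------
    mask
        Instance label mask (0 = background).

    Returns
    -------
    2D float64 array in [0, 1]; background exactly 0, each cell's maximum
    exactly 1.
    """
    lab = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    out = np.zeros(lab.shape, dtype=np.float64)
    if lab.size == 0 or lab.max() <= 0:
        return out
    # Per-label EDT on a padded bounding box: everything that is not this
    # label (other cells, background, the outside of the frame treated as
    # in-frame background via zero padding of the binary box) is distance 0.
    objects = ndimage.find_objects(lab)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rs = slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, lab.shape[0]))
        cs = slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, lab.shape[1]))
        box = lab[rs, cs] == idx
        # pad with False so cells on the frame border still see "outside"
        padded = np.pad(box, 1, mode="constant", constant_values=False)
        dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        peak = dist.max()
        if peak > 0:
            np.maximum(out[rs, cs], np.where(box, dist / peak, 0.0), out=out[rs, cs])
    return out


def mask_content_hash(lab: np.ndarray) -> str:
    """Content hash of a label mask (shape + exact pixel values)."""
    h = hashlib.sha256()
    h.update(str(lab.shape).encode())
    h.update(np.ascontiguousarray(lab.astype(np.int64)).tobytes())
    return h.hexdigest()[:24]


def precompute_targets(
    masks: Sequence[LabelMask | np.ndarray],
    cache_dir: str | Path,
) -> list[np.ndarray]:
    """Compute (or load cached) distance-map targets for a set of masks.

    Targets are cached as 32-bit float TIFFs keyed by mask content hash,
    beside a JSON manifest.  A corrupt cache entry is recomputed and
    overwritten.  Returns float32 maps (the training precision).
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = cache_dir / "targets.json"
    manifest: dict[str, str] = {}
    if manifest_path.exists():
        try:
            manifest = json.loads(manifest_path.read_text())
        except (json.JSONDecodeError, OSError):
            manifest = {}

    out: list[np.ndarray] = []
    dirty = False
    for mask in masks:
        lab = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
        key = mask_content_hash(lab)
        fname = manifest.get(key)
        dmap = None
        if fname is not None and (cache_dir / fname).exists():
            try:
                dmap = tifffile.imread(cache_dir / fname)
                if dmap.shape != lab.shape:
                    dmap = None
            except Exception:  # noqa: BLE001 - corrupt entry: recompute
                dmap = None
        if dmap is None:
            dmap = compute_distance_map(lab).astype(np.float32)
            fname = f"target_{key}.tif"
            tifffile.imwrite(cache_dir / fname, dmap)
            manifest[key] = fname
            dirty = True
        out.append(np.asarray(dmap, dtype=np.float32))
    if dirty:
        manifest_path.write_text(json.dumps(manifest, indent=0, sort_keys=True))
    return out


def brute_force_distance_map(lab: np.ndarray) -> np.ndarray:
    """O(N^2) oracle: nearest pixel of a different label, by full search.

    Independent of the EDT route; intended for tests on small masks.
    """
    lab = np.asarray(lab)
    h, w = lab.shape
    rows, cols = np.mgrid[0:h, 0:w]
    out = np.zeros((h, w), dtype=np.float64)
    raw = np.zeros((h, w), dtype=np.float64)
    for lbl in np.unique(lab):
        if lbl <= 0:
            continue
        inside = lab == lbl
        # "outside" includes pixels beyond the frame: the nearest such pixel
        # center is at distance = 1 + distance to the nearest border
        other_r, other_c = np.nonzero(~inside)
        for r, c in zip(*np.nonzero(inside)):
            d_frame = min(r + 1, c + 1, h - r, w - c)
            if other_r.size:
                d2 = (other_r - r) ** 2 + (other_c - c) ** 2
                d = min(float(np.sqrt(d2.min())), float(d_frame))
            else:
                d = float(d_frame)
            raw[r, c] = d
        peak = raw[inside].max()
        out[inside] = raw[inside] / peak
    return out
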