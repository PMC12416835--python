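"""Cell Tracking Challenge SEG / DET measures, OP_CSB, and culture metrics.

SEG: each reference cell R is matched to the predicted cell S covering a
strict majority of it (|R ∩ S| > 0.5·|R|; the match is unique because the
intersections of distinct predictions with R are disjoint), scored by the
Jaccard index |R ∩ S| / |R ∪ S| (0 when unmatched) and averaged over all
reference cells.

DET: the detection graphs (one node per cell, no edges in the single-frame
case) are compared through the Acyclic Oriented Graph Matching measure for
detection, AOGM-D — the weighted minimum number of node operations needed
to turn the predicted graph into the reference graph.  With the canonical
Cell Tracking Challenge weights (false negative 10, false positive 1,
split 5):

    AOGM-D = 10·FN + 1·FP + 5·NS
    DET    = 1 − min(AOGM-D, AOGM-D0) / AOGM-D0,   AOGM-D0 = 10·n_ref

where a predicted cell *claims* every reference cell it majority-covers,
FN counts unclaimed reference cells, FP counts predictions claiming
nothing, and a prediction claiming k ≥ 2 references needs k−1 splits.

OP_CSB = 0.5·(SEG + DET).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from distseg.io_formats import LabelMask


def _as_labels(mask: LabelMask | np.ndarray) -> np.ndarray:
    return mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)


@dataclass(frozen=True)
class DetCosts:
    """Node-operation weights of the detection graph-edit measure."""

    weight_split: float = 5.0
    weight_false_negative: float = 10.0
    weight_false_positive: float = 1.0


@dataclass
class MatchTable:
    """Majority-overlap matching between reference and predicted cells."""

    #: reference label -> (predicted label or None, intersection pixels)
    matches: dict[int, tuple[int | None, int]] = field(default_factory=dict)
    ref_sizes: dict[int, int] = field(default_factory=dict)
    pred_sizes: dict[int, int] = field(default_factory=dict)


def _joint_histogram(ref: np.ndarray, pred: np.ndarray):
    """Pixel-count contingency between the two label maps."""
    if ref.shape != pred.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {pred.shape}")
    ref_ids, ref_inv = np.unique(ref, return_inverse=True)
    pred_ids, pred_inv = np.unique(pred, return_inverse=True)
    joint = np.zeros((ref_ids.size, pred_ids.size), dtype=np.int64)
    np.add.at(joint, (ref_inv.ravel(), pred_inv.ravel()), 1)
    return ref_ids, pred_ids, joint


def match_cells(reference: LabelMask | np.ndarray, predicted: LabelMask | np.ndarray) -> MatchTable:
    """Match each reference cell to the prediction covering >50% of it."""
    ref = _as_labels(reference)
    pred = _as_labels(predicted)
    ref_ids, pred_ids, joint = _joint_histogram(ref, pred)
    table = MatchTable()
    ref_tot = joint.sum(axis=1)
    pred_tot = joint.sum(axis=0)
    for j, p in enumerate(pred_ids):
        if p > 0:
            table.pred_sizes[int(p)] = int(pred_tot[j])
    for i, r in enumerate(ref_ids):
        if r <= 0:
            continue
        table.ref_sizes[int(r)] = int(ref_tot[i])
        best = None
        best_inter = 0
        for j, p in enumerate(pred_ids):
            if p <= 0:
                continue
            inter = int(joint[i, j])
            if inter * 2 > ref_tot[i]:  # strict majority
                best, best_inter = int(p), inter
                break
        table.matches[int(r)] = (best, best_inter)
    return table


def seg_score(reference: LabelMask | np.ndarray, predicted: LabelMask | np.ndarray) -> float:
    """Mean Jaccard index over reference cells under majority matching."""
    ref = _as_labels(reference)
    pred = _as_labels(predicted)
    table = match_cells(ref, pred)
    if not table.ref_sizes:
        return 1.0 if not table.pred_sizes else 0.0
    scores = []
    for r, (p, inter) in table.matches.items():
        if p is None:
            scores.append(0.0)
        else:
            union = table.ref_sizes[r] + table.pred_sizes[p] - inter
            scores.append(inter / union)
    return float(np.mean(scores))


def det_assignment(
    reference: LabelMask | np.ndarray, predicted: LabelMask | np.ndarray
) -> tuple[int, int, int, int]:
    """(n_ref, FN, FP, NS) of the detection assignment.

    Applied from the predicted side: each predicted cell claims every
    reference cell it majority-covers; a prediction claiming k >= 2
    references requires k-1 split operations.
    """
    ref = _as_labels(reference)
    pred = _as_labels(predicted)
    ref_ids, pred_ids, joint = _joint_histogram(ref, pred)
    ref_pos = ref_ids > 0
    pred_pos = pred_ids > 0
    ref_tot = joint.sum(axis=1)
    claimed = (joint * 2 > ref_tot[:, None]) & ref_pos[:, None] & pred_pos[None, :]
    n_ref = int(ref_pos.sum())
    fn = int((~claimed.any(axis=1) & ref_pos).sum())
    fp = int((~claimed.any(axis=0) & pred_pos).sum())
    claims_per_pred = claimed.sum(axis=0)
    ns = int(np.clip(claims_per_pred - 1, 0, None).sum())
    return n_ref, fn, fp, ns


def det_score(
    reference: LabelMask | np.ndarray,
    predicted: LabelMask | np.ndarray,
    costs: DetCosts | None = None,
) -> float:
    """Detection measure DET = 1 - min(AOGM-D, AOGM-D0)/AOGM-D0."""
    costs = costs or DetCosts()
    n_ref, fn, fp, ns = det_assignment(reference, predicted)
    if n_ref == 0:
        pred = _as_labels(predicted)
        return 1.0 if not (pred > 0).any() else 0.0
    aogm_d = (
        costs.weight_false_negative * fn
        + costs.weight_false_positive * fp
        + costs.weight_split * ns
    )
    aogm_d0 = costs.weight_false_negative * n_ref
    return float(1.0 - min(aogm_d, aogm_d0) / aogm_d0)


def op_csb(seg: float, det: float) -> float:
    """Overall performance: the exact arithmetic mean of SEG and DET."""
    if not (0 <= seg <= 1 and 0 <= det <= 1):
        raise ValueError("SEG and DET must lie in [0, 1]")
    return 0.5 * (seg + det)


def culture_metrics(mask: LabelMask | np.ndarray, dilation_px: int = 2) -> dict:
    """Cell-culture summary of a label mask.

    cell_count, mean_cell_area (px^2; 0 for an empty mask), confluency
    (cell pixels / total pixels), and per-cell neighbor counts, where the
    neighbors of a cell are the distinct other labels its ``dilation_px``
    disk dilation touches.
    """
    lab = _as_labels(mask)
    ids = np.unique(lab)
    ids = ids[ids > 0]
    total = lab.size
    if ids.size == 0:
        return {
            "cell_count": 0,
            "mean_cell_area": 0.0,
            "confluency": 0.0,
            "neighbor_counts": {},
        }
    sizes = np.bincount(lab.ravel())
    footprint = disk(dilation_px)
    pad = dilation_px
    neighbor_counts: dict[int, int] = {}
    objects = ndimage.find_objects(lab)
    for lbl in ids:
        sl = objects[int(lbl) - 1]
        rs = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, lab.shape[0]))
        cs = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, lab.shape[1]))
        box = lab[rs, cs]
        dil = ndimage.binary_dilation(box == lbl, structure=footprint)
        touched = np.unique(box[dil])
        neighbor_counts[int(lbl)] = int(((touched != lbl) & (touched > 0)).sum())
    cell_px = int((lab > 0).sum())
    return {
        "cell_count": int(ids.size),
        "mean_cell_area": float(np.mean([sizes[i] for i in ids])),
        "confluency": cell_px / total,
        "neighbor_counts": neighbor_counts,
    }


def metrics_report(
    reference: LabelMask | np.ndarray, predicted: LabelMask | np.ndarray
) -> dict:
    """SEG/DET/OP_CSB plus culture metrics of the prediction."""
    seg = seg_score(reference, predicted)
    det = det_score(reference, predicted)
    report = {"seg": seg, "det": det, "op_csb": op_csb(seg, det)}
    report.update(culture_metrics(predicted))
    return report
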