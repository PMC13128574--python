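"""Instance-segmentation metrics: VOI, adapted Rand error, AP-75.

All three are computed from the joint label-count (contingency) table of a
candidate segmentation against ground truth:

* VOI — the two conditional entropies of the voxel-label joint
  distribution.  ``voi_split`` = H(seg | gt) grows with over-segmentation,
  ``voi_merge`` = H(gt | seg) with over-merging; lower is better.  (The
  component names follow the conventional split = H(seg|gt) mapping; the
  explicit conditional entropies are also reported so either naming can be
  read off.)
* ARAND — 1 minus the F-score of pairwise Rand precision and recall over
  unordered voxel pairs, ignoring ground-truth background voxels.
* AP-75 — each ground-truth instance is matched to the predicted instance of
  maximal IoU; a match counts as a true positive only at IoU >= 0.75.
  Predictions are ranked by voxel count (watershed output carries no
  confidence scores) and the average precision is the area under the
  resulting precision-recall curve.  Instances are stratified by voxel
  count: small < 5k, large > 30k, medium in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix

from .exceptions import DimensionError, UndefinedMetricError

__all__ = ["ContingencyTable", "MetricReport", "contingency", "voi", "arand",
           "ap75", "evaluate_labels", "SIZE_STRATA"]

#: instance-size strata bounds in voxels: small < 5k, large > 30k
SIZE_STRATA = (5000, 30000)


@dataclass
class ContingencyTable:
    """Sparse joint counts n[i, j] of voxels with gt id i and seg id j."""

    counts: "coo_matrix"
    gt_ids: np.ndarray
    seg_ids: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict:
        c = self.counts.tocoo()
        return {(int(self.gt_ids[i]), int(self.seg_ids[j])): int(v)
                for i, j, v in zip(c.row, c.col, c.data)}

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class MetricReport:
    """Bundle of VOI components, ARAND and size-stratified AP-75."""

    voi_split: float = 0.0
    voi_merge: float = 0.0
    voi_total: float = 0.0
    arand: float = 0.0
    ap75: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"voi_split": self.voi_split, "voi_merge": self.voi_merge,
                "voi_total": self.voi_total, "arand": self.arand,
                "ap75": dict(self.ap75), "counts": dict(self.counts)}


def _lab(x) -> np.ndarray:
    from .targets import LabelVolume
    if isinstance(x, LabelVolume):
        return x.labels
    return np.asarray(x)


def contingency(seg, gt, ignore_background: bool = False) -> ContingencyTable:
    """Joint count table; optionally drop voxels with gt background."""
    seg, gt = _lab(seg), _lab(gt)
    if seg.shape != gt.shape:
        raise DimensionError(f"segmentation shape {seg.shape} != gt shape {gt.shape}")
    s, g = seg.ravel(), gt.ravel()
    if ignore_background:
        keep = g > 0
        s, g = s[keep], g[keep]
    gt_ids, gi = np.unique(g, return_inverse=True)
    seg_ids, si = np.unique(s, return_inverse=True)
    counts = coo_matrix((np.ones(g.size), (gi, si)),
                        shape=(gt_ids.size, seg_ids.size)).tocsr().tocoo()
    return ContingencyTable(counts=counts, gt_ids=gt_ids, seg_ids=seg_ids)


def voi(seg, gt, log_base: float = 2.0,
        ignore_background: bool = False) -> tuple[float, float, float]:
    """Variation of information: (voi_split, voi_merge, voi_total).

    voi_split = H(seg | gt), voi_merge = H(gt | seg), in units of the
    configured log base (bits by default).
    """
    table = contingency(seg, gt, ignore_background=ignore_background)
    if table.total == 0:
        raise UndefinedMetricError("VOI is undefined on an empty volume")
    c = table.counts.tocoo()
    n = c.data / table.total
    p_gt = np.asarray(table.counts.sum(axis=1)).ravel() / table.total
    p_seg = np.asarray(table.counts.sum(axis=0)).ravel() / table.total
    lb = np.log(log_base)
    h_joint = -np.sum(n * np.log(n)) / lb
    h_gt = -np.sum(p_gt * np.log(p_gt)) / lb
    h_seg = -np.sum(p_seg * np.log(p_seg)) / lb
    split = max(h_joint - h_gt, 0.0)     # H(seg | gt)
    merge = max(h_joint - h_seg, 0.0)    # H(gt | seg)
    return float(split), float(merge), float(split + merge)


def _pairs(x: np.ndarray) -> np.ndarray:
    return x * (x - 1.0) / 2.0


def arand(seg, gt, ignore_background: bool = True) -> float:
    """Adapted Rand error: 1 - F-score of pairwise precision and recall."""
    table = contingency(seg, gt, ignore_background=ignore_background)
    gt_fg = table.gt_ids[table.gt_ids > 0] if not ignore_background else table.gt_ids
    if table.total == 0 or gt_fg.size == 0:
        raise UndefinedMetricError("ARAND is undefined without ground-truth foreground")
    c = table.counts.tocoo()
    joint = float(np.sum(_pairs(c.data)))
    a = float(np.sum(_pairs(np.asarray(table.counts.sum(axis=1)).ravel())))
    b = float(np.sum(_pairs(np.asarray(table.counts.sum(axis=0)).ravel())))
    if a == 0.0 and b == 0.0:
        return 0.0
    precision = joint / b if b > 0 else (1.0 if joint == 0 else 0.0)
    recall = joint / a if a > 0 else (1.0 if joint == 0 else 0.0)
    if precision + recall == 0.0:
        return 1.0
    return float(1.0 - 2.0 * precision * recall / (precision + recall))


def _stratum_of(size: int) -> str:
    if size < SIZE_STRATA[0]:
        return "small"
    if size > SIZE_STRATA[1]:
        return "large"
    return "medium"


def ap75(pred, gt, iou_threshold: float = 0.75) -> tuple[dict, dict]:
    """Size-stratified average precision at the given IoU threshold.

    Returns (ap, counts): ``ap`` maps {small, medium, large, all} to the AP
    value (strata with no ground-truth instance are absent); ``counts`` maps
    each stratum to its TP/FP/FN tallies.
    """
    pred, gt = _lab(pred), _lab(gt)
    if pred.shape != gt.shape:
        raise DimensionError(f"prediction shape {pred.shape} != gt shape {gt.shape}")
    gt_ids, gt_sizes = np.unique(gt[gt > 0], return_counts=True)
    pr_ids, pr_sizes = np.unique(pred[pred > 0], return_counts=True)
    gt_size = dict(zip(gt_ids.tolist(), gt_sizes.tolist()))
    pr_size = dict(zip(pr_ids.tolist(), pr_sizes.tolist()))

    both = (gt > 0) & (pred > 0)
    table = contingency(pred[both], gt[both]) if both.any() else None

    # candidate matches with IoU, greedy one-to-one assignment by IoU desc
    matches: dict[int, tuple[int, float]] = {}       # gt id -> (pred id, IoU)
    if table is not None:
        c = table.counts.tocoo()
        cand = []
        for i, j, n in zip(c.row, c.col, c.data):
            gid, pid = int(table.gt_ids[i]), int(table.seg_ids[j])
            iou = n / (gt_size[gid] + pr_size[pid] - n)
            cand.append((-iou, gid, pid))
        cand.sort()
        used_gt: set[int] = set()
        used_pr: set[int] = set()
        for neg_iou, gid, pid in cand:
            iou = -neg_iou
            if iou < iou_threshold:
                break
            if gid in used_gt or pid in used_pr:
                continue
            used_gt.add(gid)
            used_pr.add(pid)
            matches[gid] = (pid, iou)

    matched_pred = {pid: gid for gid, (pid, _) in matches.items()}
    # ranked predictions: confidence = voxel count, descending; ties by id
    ranked = sorted(pr_ids.tolist(), key=lambda p: (-pr_size[p], p))

    ap: dict[str, float] = {}
    counts: dict[str, dict] = {}
    strata = {"small": lambda s: s < SIZE_STRATA[0],
              "medium": lambda s: SIZE_STRATA[0] <= s <= SIZE_STRATA[1],
              "large": lambda s: s > SIZE_STRATA[1],
              "all": lambda s: True}
    for name, member in strata.items():
        gt_in = [g for g in gt_ids.tolist() if member(gt_size[g])]
        n_gt = len(gt_in)
        if n_gt == 0:
            continue
        gt_in_set = set(gt_in)
        entries = []                     # (is_tp) in confidence order
        for pid in ranked:
            gid = matched_pred.get(pid)
            if gid is not None:
                if gid in gt_in_set:
                    entries.append(True)
                # matched to a gt outside the stratum: not counted here
            elif member(pr_size[pid]):
                entries.append(False)
        tp = fp = 0
        area = 0.0
        prev_recall = 0.0
        for is_tp in entries:
            if is_tp:
                tp += 1
                recall = tp / n_gt
                area += (recall - prev_recall) * (tp / (tp + fp))
                prev_recall = recall
            else:
                fp += 1
        ap[name] = float(area)
        counts[name] = {"tp": tp, "fp": fp, "fn": n_gt - tp}
    return ap, counts


def evaluate_labels(pred, gt, log_base: float = 2.0,
                    voi_ignore_background: bool = False,
                    arand_ignore_background: bool = True,
                    iou_threshold: float = 0.75) -> MetricReport:
    """All metrics in one report."""
    vs, vm, vt = voi(pred, gt, log_base=log_base,
                     ignore_background=voi_ignore_background)
    ar = arand(pred, gt, ignore_background=arand_ignore_background)
    ap, counts = ap75(pred, gt, iou_threshold=iou_threshold)
    return MetricReport(voi_split=vs, voi_merge=vm, voi_total=vt, arand=ar,
                        ap75=ap, counts=counts)
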