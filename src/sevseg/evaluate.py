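"""Detection, segmentation and distribution-level scoring of masks.

Detection follows the Cell Tracking Challenge protocol: a ground-truth
object ``g`` is detected by a predicted object ``s`` iff ``s`` covers
more than half of ``g`` (majority rule); the detection score is the
normalised acyclic-oriented-graph-matching cost

    DET = 1 - min(AOGM_D, AOGM_0) / AOGM_0,

where ``AOGM_D = w_NS * NS + w_FN * FN + w_FP * FP`` is the cost of
editing the predicted node set into the ground-truth one and
``AOGM_0 = w_FN * |GT|`` the cost of creating the ground truth from
scratch.  The standard detection weights are w_NS = 5, w_FN = 10,
w_FP = 1; NS counts the splits required for predicted nodes covering
several ground-truth objects (k objects -> k - 1 splits).

Segmentation quality is the mean Jaccard coefficient over ground-truth
objects: SEG averages over *all* of them (an undetected object scores
0), SEG* only over the correctly detected ones.

Distributions of per-vesicle diameter and roundness are compared with a
Monte-Carlo subsampled two-sided Wilcoxon rank-sum test: each fold draws
``fold_size`` values (30, or 2/3 of the sample when it is smaller) from
both sets without replacement and the mean p-value over
``floor(10 * sample_size / fold_size)`` folds is reported, which makes
the test size-stable across the very different vesicle counts of
typical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .postprocess import LabeledMask

__all__ = ["Matching", "DetectionReport", "SegmentationReport",
           "MCWilcoxonResult", "match", "det_score", "seg_score",
           "mc_wilcoxon", "evaluate_masks", "EvaluationReport",
           "AOGM_WEIGHTS"]

#: Cell Tracking Challenge detection weights (node split / add / delete).
AOGM_WEIGHTS = {"NS": 5.0, "FN": 10.0, "FP": 1.0}


@dataclass
class Matching:
    """Majority-overlap assignment between GT and predicted labels."""

    pairs: dict                 # gt_label -> pred_label or None
    fp_labels: list             # predicted labels covering no GT majority
    ns_groups: dict             # pred_label -> [gt labels] when >= 2
    jaccard: dict               # gt_label -> IoU with its matched partner
    n_gt: int
    n_pred: int


@dataclass
class DetectionReport:
    AOGM_D: float
    AOGM_0: float
    DET: float
    TP: int
    FN: int
    FP: int
    NS: int
    fp_ratio: float


@dataclass
class SegmentationReport:
    SEG: float
    SEG_star: float


@dataclass
class MCWilcoxonResult:
    mean_p: float
    folds: int
    fold_size: int
    seed: int | None = None


def _overlap_table(gt: np.ndarray, pred: np.ndarray):
    n_gt, n_pred = int(gt.max()), int(pred.max())
    pair = gt.astype(np.int64).ravel() * (n_pred + 1) + pred.astype(np.int64).ravel()
    counts = np.bincount(pair, minlength=(n_gt + 1) * (n_pred + 1))
    return counts.reshape(n_gt + 1, n_pred + 1), n_gt, n_pred


def match(gt: LabeledMask, pred: LabeledMask) -> Matching:
    """Assign predicted objects to GT objects by the majority rule.

    GT object g is detected by predicted object s iff |g & s| > 0.5 |g|;
    at most one s can satisfy this per g.  A predicted object claiming
    >= 2 GT objects forms an NS (wrong-merge) group; predicted objects
    claiming none are false positives.
    """
    g = np.asarray(gt.labels)
    p = np.asarray(pred.labels)
    if g.shape != p.shape:
        raise ValueError("ground-truth and predicted masks differ in shape")
    ov, n_gt, n_pred = _overlap_table(g, p)
    gt_sizes = ov.sum(axis=1)
    pairs, jaccard = {}, {}
    claimed = {}
    for gl in range(1, n_gt + 1):
        row = ov[gl, 1:]
        partner = None
        if row.size:
            best = int(np.argmax(row)) + 1
            if row[best - 1] * 2 > gt_sizes[gl]:
                partner = best
        pairs[gl] = partner
        if partner is not None:
            inter = ov[gl, partner]
            union = gt_sizes[gl] + ov[:, partner].sum() - inter
            jaccard[gl] = float(inter) / float(union)
            claimed.setdefault(partner, []).append(gl)
        else:
            jaccard[gl] = 0.0
    fp_labels = [pl for pl in range(1, n_pred + 1) if pl not in claimed]
    ns_groups = {pl: gls for pl, gls in claimed.items() if len(gls) >= 2}
    return Matching(pairs=pairs, fp_labels=fp_labels, ns_groups=ns_groups,
                    jaccard=jaccard, n_gt=n_gt, n_pred=n_pred)


def det_score(matching: Matching, weights: dict | None = None) -> DetectionReport:
    """Detection accuracy (normalised AOGM) and false-positive ratio."""
    w = weights or AOGM_WEIGHTS
    tp = sum(1 for v in matching.pairs.values() if v is not None)
    fn = matching.n_gt - tp
    fp = len(matching.fp_labels)
    ns = sum(len(gls) - 1 for gls in matching.ns_groups.values())
    aogm_d = w["NS"] * ns + w["FN"] * fn + w["FP"] * fp
    aogm_0 = w["FN"] * matching.n_gt
    if aogm_0 == 0:
        det = 1.0 if aogm_d == 0 else 0.0   # empty GT: only edits can hurt
    else:
        det = 1.0 - min(aogm_d, aogm_0) / aogm_0
    fp_ratio = fp / (fp + tp) if (fp + tp) else 0.0
    return DetectionReport(AOGM_D=aogm_d, AOGM_0=aogm_0, DET=det, TP=tp,
                           FN=fn, FP=fp, NS=ns, fp_ratio=fp_ratio)


def seg_score(matching: Matching) -> SegmentationReport:
    """Mean Jaccard over all GT objects (SEG) and detected ones (SEG*)."""
    if matching.n_gt == 0:
        raise ValueError("no ground-truth objects to score")
    scores = [matching.jaccard[gl] for gl in range(1, matching.n_gt + 1)]
    detected = [matching.jaccard[gl] for gl, pl in matching.pairs.items()
                if pl is not None]
    seg = float(np.mean(scores))
    seg_star = float(np.mean(detected)) if detected else 0.0
    return SegmentationReport(SEG=seg, SEG_star=seg_star)


def mc_wilcoxon(sample_gt, sample_pred, fold_size_cap: int = 30,
                seed=None) -> MCWilcoxonResult:
    """Monte-Carlo subsampled two-sided Wilcoxon rank-sum comparison.

    fold_size = cap (30) when both samples have at least that many
    values, else floor(2/3 * min(n)); the number of folds is
    floor(10 * min(n) / fold_size).  Each fold draws fold_size values
    without replacement from each sample; the mean p over folds is
    returned.
    """
    a = np.asarray(sample_gt, dtype=float)
    b = np.asarray(sample_pred, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n = min(a.size, b.size)
    fold_size = fold_size_cap if n >= fold_size_cap else int(np.floor(2 * n / 3))
    if fold_size < 2:
        raise ValueError(f"fold size {fold_size} too small for a rank test")
    folds = int(np.floor(10 * n / fold_size))
    rng = np.random.default_rng(seed)
    method = "exact" if fold_size < 10 else "asymptotic"
    ps = np.empty(folds)
    for k in range(folds):
        xa = rng.choice(a, size=fold_size, replace=False)
        xb = rng.choice(b, size=fold_size, replace=False)
        ps[k] = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                   method=method).pvalue
    return MCWilcoxonResult(mean_p=float(ps.mean()), folds=folds,
                            fold_size=fold_size,
                            seed=seed if isinstance(seed, int) else None)


@dataclass
class EvaluationReport:
    """Full scoring of one (ground truth, prediction) mask pair."""

    detection: DetectionReport
    segmentation: SegmentationReport
    delta_d: float | None = None
    delta_r: float | None = None
    p_d_all: float | None = None
    p_r_all: float | None = None
    p_d_detected: float | None = None
    p_r_detected: float | None = None
    per_object: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "DET": self.detection.DET, "SEG": self.segmentation.SEG,
            "SEG_star": self.segmentation.SEG_star,
            "TP": self.detection.TP, "FN": self.detection.FN,
            "FP": self.detection.FP, "NS": self.detection.NS,
            "fp_ratio": self.detection.fp_ratio,
            "delta_d": self.delta_d, "delta_r": self.delta_r,
            "p_d_all": self.p_d_all, "p_r_all": self.p_r_all,
            "p_d_detected": self.p_d_detected,
            "p_r_detected": self.p_r_detected,
        }


def evaluate_masks(gt: LabeledMask, pred: LabeledMask,
                   seed=None) -> EvaluationReport:
    """Score a predicted mask against ground truth on every axis.

    Computes DET / SEG / SEG*, the mean relative diameter and roundness
    errors over correctly detected objects, and the Monte-Carlo rank-sum
    p-values of the diameter and roundness distributions (over all
    segmented objects and over correctly detected objects only).
    """
    from .morphometry import measure, shape_errors

    m = match(gt, pred)
    det = det_score(m)
    seg = seg_score(m)
    report = EvaluationReport(detection=det, segmentation=seg)

    gt_meas = {v.label: v for v in measure(gt)}
    pred_meas = {v.label: v for v in measure(pred)}
    dds, drs = [], []
    det_d_gt, det_r_gt, det_d_s, det_r_s = [], [], [], []
    for gl, pl in m.pairs.items():
        if pl is None or gl not in gt_meas or pl not in pred_meas:
            continue
        dd, dr = shape_errors(gt_meas[gl], pred_meas[pl])
        dds.append(dd)
        drs.append(dr)
        det_d_gt.append(gt_meas[gl].diameter_nm)
        det_r_gt.append(gt_meas[gl].roundness)
        det_d_s.append(pred_meas[pl].diameter_nm)
        det_r_s.append(pred_meas[pl].roundness)
    if dds:
        report.delta_d = float(np.mean(dds))
        report.delta_r = float(np.mean(drs))
    all_d_gt = [v.diameter_nm for v in gt_meas.values()]
    all_r_gt = [v.roundness for v in gt_meas.values()]
    all_d_s = [v.diameter_nm for v in pred_meas.values()]
    all_r_s = [v.roundness for v in pred_meas.values()]

    def _p(x, y, salt):
        try:
            sub_seed = None if seed is None else int(seed) + salt
            return mc_wilcoxon(x, y, seed=sub_seed).mean_p
        except ValueError:
            return None

    report.p_d_all = _p(all_d_gt, all_d_s, 1)
    report.p_r_all = _p(all_r_gt, all_r_s, 2)
    report.p_d_detected = _p(det_d_gt, det_d_s, 3)
    report.p_r_detected = _p(det_r_gt, det_r_s, 4)
    report.per_object = {"gt": gt_meas, "pred": pred_meas}
    return report
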