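"""ROI-level detection and classification evaluation protocol.

Predicted ROIs (mask + 4-class label + prediction score) are compared with
ground-truth ROIs (mask + benign/malignant label) per patient and view:

* predictions with score <= 0.1 are discarded;
* predictions and ground truths are matched one-to-one among pairs with
  IoU > 0.1, maximizing total IoU;
* a matched prediction is a *correct detection* iff its benign/malignant
  probability for the true class exceeds 0.5;
* sensitivity = correct detections / all true ROIs; precision = correct
  detections / all surviving predicted ROIs (correct + non-overlapping +
  wrongly classified);
* for classification ROC analysis every surviving prediction contributes a
  malignancy score; the reference label is the matched ground truth's class,
  or *benign* for unmatched predictions (predicting a spurious malignant ROI
  is the worse error);
* DL scores are mapped to a benign/malignant binomial
  (p(predicted class) = 0.5 * pred_score + 0.5) so they can be averaged with
  a radiomics classifier's probabilities in an ensemble;
* confidence intervals come from a patient-level bootstrap (2000 resamples,
  percentile 95% interval).
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata

from .raster_io import View

IOU_THRESHOLD = 0.1
SCORE_THRESHOLD = 0.1
CLASS_PROB_THRESHOLD = 0.5

#: Sentinel for metrics that are undefined on the data at hand
UNDEFINED = float("nan")


class Label2(str, enum.Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class Label4(str, enum.Enum):
    BENIGN_MASS = "benign_mass"
    MALIGNANT_MASS = "malignant_mass"
    BENIGN_CLUSTER = "benign_cluster"
    MALIGNANT_CLUSTER = "malignant_cluster"


class LesionType(str, enum.Enum):
    MASS = "mass"
    CLUSTER = "cluster"


@dataclasses.dataclass
class GroundTruthROI:
    patient_id: str
    view: View
    mask: np.ndarray
    label2: Label2
    lesion_type: LesionType = LesionType.CLUSTER

    def __post_init__(self) -> None:
        self.view = View(self.view)
        self.label2 = Label2(self.label2)
        self.lesion_type = LesionType(self.lesion_type)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ground-truth mask must be nonempty")


@dataclasses.dataclass
class PredictionROI:
    patient_id: str
    view: View
    mask: np.ndarray
    label4: Label4
    pred_score: float

    def __post_init__(self) -> None:
        self.view = View(self.view)
        self.label4 = Label4(self.label4)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0.0 <= self.pred_score <= 1.0:
            raise ValueError("pred_score must lie in [0, 1]")


@dataclasses.dataclass
class BinomialProbs:
    """Benign/malignant probability pair summing to 1."""

    p_ben: float
    p_mal: float

    def __post_init__(self) -> None:
        if abs(self.p_ben + self.p_mal - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    @property
    def predicted_class(self) -> Label2:
        # ties at exactly 0.5 resolve to malignant, mirroring the strict
        # > 0.5 correctness threshold for the true class
        return Label2.BENIGN if self.p_ben > 0.5 else Label2.MALIGNANT


@dataclasses.dataclass
class MatchedPair:
    pred: PredictionROI
    gt: GroundTruthROI
    iou: float
    probs: BinomialProbs
    correct: bool


@dataclasses.dataclass
class MatchResult:
    pairs: List[MatchedPair]
    unmatched_preds: List[Tuple[PredictionROI, BinomialProbs]]
    unmatched_gts: List[GroundTruthROI]

    @property
    def n_correct(self) -> int:
        return sum(p.correct for p in self.pairs)

    @property
    def n_preds(self) -> int:
        return len(self.pairs) + len(self.unmatched_preds)

    @property
    def n_gts(self) -> int:
        return len(self.pairs) + len(self.unmatched_gts)


@dataclasses.dataclass
class MetricsReport:
    sensitivity: float
    precision: float
    auc: float
    sensitivity_ci: Tuple[float, float] = (UNDEFINED, UNDEFINED)
    precision_ci: Tuple[float, float] = (UNDEFINED, UNDEFINED)
    auc_ci: Tuple[float, float] = (UNDEFINED, UNDEFINED)
    n_bootstrap: int = 0


# ---------------------------------------------------------------------------
# Label and probability mappings
# ---------------------------------------------------------------------------

def binarize_label(label4) -> Label2:
    """Map the 4-class scheme to benign/malignant."""
    label4 = Label4(label4)
    return (Label2.BENIGN
            if label4 in (Label4.BENIGN_MASS, Label4.BENIGN_CLUSTER)
            else Label2.MALIGNANT)


def lesion_type_of(label4) -> LesionType:
    label4 = Label4(label4)
    return (LesionType.MASS
            if label4 in (Label4.BENIGN_MASS, Label4.MALIGNANT_MASS)
            else LesionType.CLUSTER)


def dl_score_to_binomial(label4, pred_score: float) -> BinomialProbs:
    """Map a DL class label + prediction score to a benign/malignant binomial.

    The predicted class receives 0.5 * pred_score + 0.5 (always >= 0.5), the
    other class the complement, aligning the DL output with the binomial
    probabilities of a radiomics classifier.
    """
    if not 0.0 <= pred_score <= 1.0:
        raise ValueError("pred_score must lie in [0, 1]")
    p = 0.5 * pred_score + 0.5
    if binarize_label(label4) is Label2.BENIGN:
        return BinomialProbs(p_ben=p, p_mal=1.0 - p)
    return BinomialProbs(p_ben=1.0 - p, p_mal=p)


def ensemble_probs(dl: BinomialProbs, hr: BinomialProbs) -> BinomialProbs:
    """Average DL and handcrafted-radiomics probabilities elementwise."""
    return BinomialProbs(p_ben=0.5 * (dl.p_ben + hr.p_ben),
                         p_mal=0.5 * (dl.p_mal + hr.p_mal))


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def compute_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two aligned binary masks (0 if both empty)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _probs_for(pred: PredictionROI,
               probs_map: Optional[Dict[int, BinomialProbs]]) -> BinomialProbs:
    if probs_map is not None and id(pred) in probs_map:
        return probs_map[id(pred)]
    return dl_score_to_binomial(pred.label4, pred.pred_score)


def match_rois(preds: Sequence[PredictionROI], gts: Sequence[GroundTruthROI],
               iou_thr: float = IOU_THRESHOLD,
               score_thr: float = SCORE_THRESHOLD,
               class_prob_thr: float = CLASS_PROB_THRESHOLD,
               probs_map: Optional[Dict[int, BinomialProbs]] = None) -> MatchResult:
    """Match predictions to ground truths within each (patient, view) scope.

    Predictions with score <= ``score_thr`` are discarded. Among remaining
    pairs with IoU > ``iou_thr``, a one-to-one assignment maximizing total IoU
    is computed. A matched pair is a correct detection iff the prediction's
    probability for the true class exceeds ``class_prob_thr``. Unmatched
    surviving predictions are the falsely detected ROIs.

    ``probs_map`` optionally overrides per-prediction probabilities (keyed by
    ``id(pred)``), e.g. with ensembled DL + radiomics values; by default the
    DL binomialization of each prediction's own label and score is used.
    """
    surviving = [p for p in preds if p.pred_score > score_thr]
    scopes = sorted({(p.patient_id, p.view.value) for p in surviving}
                    | {(g.patient_id, g.view.value) for g in gts})
    pairs: List[MatchedPair] = []
    unmatched_preds: List[Tuple[PredictionROI, BinomialProbs]] = []
    unmatched_gts: List[GroundTruthROI] = []
    for scope in scopes:
        sp = [p for p in surviving if (p.patient_id, p.view.value) == scope]
        sg = [g for g in gts if (g.patient_id, g.view.value) == scope]
        matched_p = set()
        matched_g = set()
        if sp and sg:
            iou = np.array([[compute_iou(p.mask, g.mask) for g in sg] for p in sp])
            weight = np.where(iou > iou_thr, iou, 0.0)
            rows, cols = linear_sum_assignment(weight, maximize=True)
            for i, j in zip(rows, cols):
                if iou[i, j] > iou_thr:
                    probs = _probs_for(sp[i], probs_map)
                    correct = (getattr(probs, f"p_{sg[j].label2.value[:3]}")
                               > class_prob_thr)
                    pairs.append(MatchedPair(pred=sp[i], gt=sg[j],
                                             iou=float(iou[i, j]), probs=probs,
                                             correct=bool(correct)))
                    matched_p.add(i)
                    matched_g.add(j)
        unmatched_preds.extend((p, _probs_for(p, probs_map))
                               for i, p in enumerate(sp) if i not in matched_p)
        unmatched_gts.extend(g for j, g in enumerate(sg) if j not in matched_g)
    return MatchResult(pairs=pairs, unmatched_preds=unmatched_preds,
                       unmatched_gts=unmatched_gts)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _gt_in_class(gt: GroundTruthROI, restrict_class, restrict_type) -> bool:
    if restrict_class is not None and gt.label2 is not Label2(restrict_class):
        return False
    if restrict_type is not None and gt.lesion_type is not LesionType(restrict_type):
        return False
    return True


def detection_metrics(match: MatchResult, restrict_class=None,
                      restrict_type=None) -> Tuple[float, float]:
    """(sensitivity, precision), optionally restricted to one GT class/type.

    Sensitivity counts correct detections over all true ROIs of the selected
    class; precision counts them over all surviving predicted ROIs of that
    predicted class (correct detections + non-overlapping + wrongly
    classified). With no predictions, precision is undefined (NaN) while
    sensitivity is still reported.
    """
    def pred_in_class(probs: BinomialProbs) -> bool:
        return (restrict_class is None
                or probs.predicted_class is Label2(restrict_class))

    correct = sum(1 for p in match.pairs
                  if p.correct and _gt_in_class(p.gt, restrict_class, restrict_type))
    n_true = (sum(1 for p in match.pairs
                  if _gt_in_class(p.gt, restrict_class, restrict_type))
              + sum(1 for g in match.unmatched_gts
                    if _gt_in_class(g, restrict_class, restrict_type)))
    n_pred = (sum(1 for p in match.pairs if pred_in_class(p.probs))
              + sum(1 for _, pr in match.unmatched_preds if pred_in_class(pr)))
    sensitivity = correct / n_true if n_true else UNDEFINED
    precision = correct / n_pred if n_pred else UNDEFINED
    return sensitivity, precision


def classification_auc(match: MatchResult) -> float:
    """ROC AUC of benign-vs-malignant classification over all predicted ROIs.

    Matched predictions take the overlapped ground truth's class as
    reference; unmatched predictions are referenced as benign. The score is
    the prediction's malignancy probability; AUC is the midrank
    (Mann-Whitney) statistic. Undefined (NaN) if only one reference class is
    present.
    """
    scores: List[float] = []
    labels: List[int] = []
    for p in match.pairs:
        scores.append(p.probs.p_mal)
        labels.append(1 if p.gt.label2 is Label2.MALIGNANT else 0)
    for _, probs in match.unmatched_preds:
        scores.append(probs.p_mal)
        labels.append(0)   # falsely detected ROIs are referenced as benign
    labels_arr = np.asarray(labels)
    n_pos = int(labels_arr.sum())
    n_neg = labels_arr.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return UNDEFINED
    ranks = rankdata(scores, method="average")
    return float((ranks[labels_arr == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Patient-level bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(metric_fn: Callable, patient_records: Dict,
                 n_boot: int = 2000, level: float = 0.95,
                 seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None,
                 max_redraws: int = 100000) -> Tuple[float, float]:
    """Percentile bootstrap CI of a metric over patient resamples.

    ``patient_records`` maps patient id -> that patient's records (any
    object ``metric_fn`` understands as a list). Each resample draws patients
    with replacement, the same number as observed; resamples on which the
    metric is undefined (NaN) are redrawn so all ``n_boot`` draws count.
    """
    if not patient_records:
        raise ValueError("need at least one patient")
    if rng is None:
        rng = np.random.default_rng(seed)
    ids = sorted(patient_records)
    n = len(ids)
    stats = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            picks = rng.integers(0, n, size=n)
            records = [r for i in picks for r in patient_records[ids[i]]]
            value = metric_fn(records)
            if not np.isnan(value):
                stats[b] = value
                break
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("metric undefined on too many resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def metric_difference_ci(metric_fn: Callable, records_a: Dict, records_b: Dict,
                         n_boot: int = 2000, level: float = 0.95,
                         seed: Optional[int] = None) -> Tuple[float, float, float]:
    """Paired patient-level bootstrap of metric(A) - metric(B).

    Both setups must be evaluated on the same patient set; each resample
    draws one patient list applied to both. Returns (mean_diff, lo, hi).
    """
    if sorted(records_a) != sorted(records_b):
        raise ValueError("setups must cover the same patient set")
    rng = np.random.default_rng(seed)
    ids = sorted(records_a)
    n = len(ids)
    diffs = np.empty(n_boot)
    b = 0
    guard = 0
    while b < n_boot:
        picks = rng.integers(0, n, size=n)
        va = metric_fn([r for i in picks for r in records_a[ids[i]]])
        vb = metric_fn([r for i in picks for r in records_b[ids[i]]])
        if np.isnan(va) or np.isnan(vb):
            guard += 1
            if guard > 100000:
                raise RuntimeError("metric undefined on too many resamples")
            continue
        diffs[b] = va - vb
        b += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(diffs, [100 * alpha, 100 * (1 - alpha)])
    return float(diffs.mean()), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def _patient_summaries(preds, gts, restrict_class) -> Dict:
    """Match each patient once; summarize counts and ROC points per patient.

    Resampling a patient twice in the bootstrap then simply counts their
    summary twice — ROIs of duplicated patients are never re-matched against
    each other.
    """
    patient_ids = sorted({p.patient_id for p in preds}
                         | {g.patient_id for g in gts})
    summaries = {}
    for pid in patient_ids:
        m = match_rois([p for p in preds if p.patient_id == pid],
                       [g for g in gts if g.patient_id == pid])
        correct = sum(1 for p in m.pairs
                      if p.correct and _gt_in_class(p.gt, restrict_class, None))
        n_true = (sum(1 for p in m.pairs
                      if _gt_in_class(p.gt, restrict_class, None))
                  + sum(1 for g in m.unmatched_gts
                        if _gt_in_class(g, restrict_class, None)))
        def in_class(probs):
            return (restrict_class is None
                    or probs.predicted_class is Label2(restrict_class))
        n_pred = (sum(1 for p in m.pairs if in_class(p.probs))
                  + sum(1 for _, pr in m.unmatched_preds if in_class(pr)))
        roc = ([(p.probs.p_mal, 1 if p.gt.label2 is Label2.MALIGNANT else 0)
                for p in m.pairs]
               + [(pr.p_mal, 0) for _, pr in m.unmatched_preds])
        summaries[pid] = [(correct, n_true, n_pred, roc)]
    return summaries


def _aggregate_metric(stat: str):
    def fn(records):
        correct = sum(r[0] for r in records)
        n_true = sum(r[1] for r in records)
        n_pred = sum(r[2] for r in records)
        if stat == "sens":
            return correct / n_true if n_true else UNDEFINED
        if stat == "prec":
            return correct / n_pred if n_pred else UNDEFINED
        scores, labels = [], []
        for r in records:
            for s, y in r[3]:
                scores.append(s)
                labels.append(y)
        labels_arr = np.asarray(labels)
        n_pos = int(labels_arr.sum()) if labels_arr.size else 0
        n_neg = labels_arr.size - n_pos
        if n_pos == 0 or n_neg == 0:
            return UNDEFINED
        ranks = rankdata(scores, method="average")
        return float((ranks[labels_arr == 1].sum() - n_pos * (n_pos + 1) / 2)
                     / (n_pos * n_neg))
    return fn


def evaluate(preds: Sequence[PredictionROI], gts: Sequence[GroundTruthROI],
             n_boot: int = 2000, seed: Optional[int] = None,
             restrict_class=None) -> MetricsReport:
    """Full protocol: match, point metrics, and patient-bootstrap 95% CIs."""
    match = match_rois(preds, gts)
    sens, prec = detection_metrics(match, restrict_class=restrict_class)
    auc = classification_auc(match)

    by_patient = _patient_summaries(preds, gts, restrict_class)
    rng = np.random.default_rng(seed)
    cis = {}
    for stat in ("sens", "prec", "auc"):
        try:
            cis[stat] = bootstrap_ci(_aggregate_metric(stat), by_patient,
                                     n_boot=n_boot, rng=rng)
        except RuntimeError:
            cis[stat] = (UNDEFINED, UNDEFINED)
    return MetricsReport(sensitivity=sens, precision=prec, auc=auc,
                         sensitivity_ci=cis["sens"], precision_ci=cis["prec"],
                         auc_ci=cis["auc"], n_bootstrap=n_boot)
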