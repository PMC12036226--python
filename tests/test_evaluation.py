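import itertools

import numpy as np
import pytest

from cemsim import evaluation as ev
from cemsim import fixtures as fx


def toy_mask(shape, r0, c0, size=6):
    m = np.zeros(shape, bool)
    m[r0:r0 + size, c0:c0 + size] = True
    return m


class TestLabelMappings:
    @pytest.mark.parametrize("label4,expected", [
        ("benign_mass", "benign"), ("benign_cluster", "benign"),
        ("malignant_mass", "malignant"), ("malignant_cluster", "malignant")])
    def test_binarize(self, label4, expected):
        assert ev.binarize_label(label4).value == expected

    def test_exhaustive_coverage(self):
        outputs = [ev.binarize_label(l).value for l in ev.Label4]
        assert sorted(outputs) == ["benign", "benign", "malignant", "malignant"]


class TestDlScoreToBinomial:
    @pytest.mark.parametrize("label,score,p_ben,p_mal", [
        ("benign_mass", 0.0, 0.5, 0.5),
        ("malignant_mass", 1.0, 0.0, 1.0),
        ("benign_cluster", 0.6, 0.8, 0.2),
        ("malignant_cluster", 0.2, 0.4, 0.6)])
    def test_formula(self, label, score, p_ben, p_mal):
        probs = ev.dl_score_to_binomial(label, score)
        assert probs.p_ben == pytest.approx(p_ben)
        assert probs.p_mal == pytest.approx(p_mal)

    def test_grid_complement_and_predicted_class_floor(self):
        for score in np.linspace(0, 1, 101):
            for label in ev.Label4:
                probs = ev.dl_score_to_binomial(label, float(score))
                assert probs.p_ben + probs.p_mal == pytest.approx(1.0, abs=1e-12)
                predicted = (probs.p_ben if ev.binarize_label(label).value
                             == "benign" else probs.p_mal)
                assert predicted >= 0.5
                assert predicted == pytest.approx(0.5 * score + 0.5)


class TestEnsembleProbs:
    def test_arithmetic_mean(self):
        out = ev.ensemble_probs(ev.BinomialProbs(0.8, 0.2),
                                ev.BinomialProbs(0.4, 0.6))
        assert out.p_ben == pytest.approx(0.6)
        assert out.p_mal == pytest.approx(0.4)

    def test_idempotent_on_identical_inputs(self):
        p = ev.BinomialProbs(0.3, 0.7)
        out = ev.ensemble_probs(p, p)
        assert (out.p_ben, out.p_mal) == (0.3, 0.7)

    def test_confident_radiomics_overrules_dl(self):
        out = ev.ensemble_probs(ev.BinomialProbs(0.55, 0.45),
                                ev.BinomialProbs(0.1, 0.9))
        assert out.p_mal == pytest.approx(0.675)
        assert out.predicted_class is ev.Label2.MALIGNANT


class TestComputeIou:
    def test_identical(self):
        m = toy_mask((20, 20), 5, 5)
        assert ev.compute_iou(m, m) == 1.0

    def test_disjoint(self):
        assert ev.compute_iou(toy_mask((20, 20), 0, 0),
                              toy_mask((20, 20), 10, 10)) == 0.0

    def test_half_overlap_thirds(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True          # 100 px
        b[0:10, 5:15] = True          # 100 px, overlap 50
        assert ev.compute_iou(a, b) == pytest.approx(1 / 3)


def brute_force_assignment(iou, thr):
    """Enumerate all one-to-one assignments; maximize total IoU above thr."""
    n_p, n_g = iou.shape
    best, best_pairs = -1.0, []
    gts = list(range(n_g))
    for k in range(0, min(n_p, n_g) + 1):
        for preds in itertools.permutations(range(n_p), k):
            for chosen_gts in itertools.permutations(gts, k):
                pairs = [(p, g) for p, g in zip(preds, chosen_gts)
                         if iou[p, g] > thr]
                total = sum(iou[p, g] for p, g in pairs)
                if total > best:
                    best, best_pairs = total, pairs
    return best, set(best_pairs)


def random_instance(rng, shape=(48, 48)):
    def rois(n, cls):
        out = []
        for _ in range(n):
            r0, c0 = rng.integers(0, shape[0] - 12, 2)
            size = int(rng.integers(5, 12))
            mask = toy_mask(shape, int(r0), int(c0), size)
            if cls == "pred":
                out.append(ev.PredictionROI(
                    "p0", "CC", mask,
                    list(ev.Label4)[rng.integers(0, 4)],
                    float(rng.uniform(0.2, 1.0))))
            else:
                out.append(ev.GroundTruthROI(
                    "p0", "CC", mask,
                    ["benign", "malignant"][rng.integers(0, 2)]))
        return out
    return rois(int(rng.integers(0, 6)), "pred"), rois(int(rng.integers(0, 6)), "gt")


class TestMatchRois:
    def test_low_score_prediction_excluded(self):
        gt = ev.GroundTruthROI("p0", "CC", toy_mask((30, 30), 5, 5), "benign")
        pred = ev.PredictionROI("p0", "CC", toy_mask((30, 30), 5, 5),
                                "benign_mass", 0.05)
        match = ev.match_rois([pred], [gt])
        assert match.pairs == []
        assert match.unmatched_preds == []     # discarded, not false positive
        assert len(match.unmatched_gts) == 1

    def test_low_iou_is_false_positive(self):
        gt = ev.GroundTruthROI("p0", "CC", toy_mask((40, 40), 0, 0, 10), "benign")
        pred = ev.PredictionROI("p0", "CC", toy_mask((40, 40), 9, 9, 10),
                                "benign_mass", 0.9)
        assert ev.compute_iou(gt.mask, pred.mask) <= 0.1
        match = ev.match_rois([pred], [gt])
        assert match.pairs == []
        assert len(match.unmatched_preds) == 1

    def test_correctness_requires_true_class_probability(self):
        gt = ev.GroundTruthROI("p0", "CC", toy_mask((30, 30), 5, 5), "malignant")
        right = ev.PredictionROI("p0", "CC", toy_mask((30, 30), 5, 5),
                                 "malignant_mass", 0.8)
        wrong = ev.PredictionROI("p0", "CC", toy_mask((30, 30), 5, 5),
                                 "benign_mass", 0.8)
        assert ev.match_rois([right], [gt]).pairs[0].correct
        assert not ev.match_rois([wrong], [gt]).pairs[0].correct

    def test_scoping_prevents_cross_patient_matches(self):
        gt = ev.GroundTruthROI("pA", "CC", toy_mask((30, 30), 5, 5), "benign")
        pred = ev.PredictionROI("pB", "CC", toy_mask((30, 30), 5, 5),
                                "benign_mass", 0.9)
        match = ev.match_rois([pred], [gt])
        assert match.pairs == []
        assert len(match.unmatched_preds) == 1
        assert len(match.unmatched_gts) == 1

    @pytest.mark.parametrize("seed", range(60))
    def test_equals_exhaustive_assignment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        preds, gts = random_instance(rng)
        surviving = [p for p in preds if p.pred_score > 0.1]
        match = ev.match_rois(preds, gts)
        if not surviving or not gts:
            assert match.pairs == []
            return
        iou = np.array([[ev.compute_iou(p.mask, g.mask) for g in gts]
                        for p in surviving])
        best_total, best_pairs = brute_force_assignment(iou, 0.1)
        pred_idx = {id(p): i for i, p in enumerate(surviving)}
        gt_idx = {id(g): j for j, g in enumerate(gts)}
        got_pairs = {(pred_idx[id(p.pred)], gt_idx[id(p.gt)])
                     for p in match.pairs}
        got_total = sum(p.iou for p in match.pairs)
        assert got_total == pytest.approx(max(best_total, 0.0))
        assert got_pairs == best_pairs


class TestDetectionMetrics:
    def test_planted_counts(self):
        shape = (200, 200)
        gts, preds = [], []
        # 30 GTs; predictions for 20 of them (correct), 10 missed; 10 spurious
        for i in range(30):
            r0 = (i % 15) * 13
            c0 = (i // 15) * 60
            gts.append(ev.GroundTruthROI(f"p{i}", "CC",
                                         toy_mask(shape, r0, c0), "malignant"))
            if i < 20:
                preds.append(ev.PredictionROI(f"p{i}", "CC",
                                              toy_mask(shape, r0, c0),
                                              "malignant_mass", 0.9))
        for i in range(10):
            preds.append(ev.PredictionROI(f"p{i}", "CC",
                                          toy_mask(shape, 150, 150),
                                          "benign_mass", 0.8))
        match = ev.match_rois(preds, gts)
        sens, prec = ev.detection_metrics(match)
        assert sens == pytest.approx(20 / 30)
        assert prec == pytest.approx(20 / 30)

    def test_perfect_toy_set(self):
        toy = fx.generate_toy_annotations(20, fx.ErrorRates(), seed=1)
        match = ev.match_rois(toy.predictions, toy.ground_truths)
        sens, prec = ev.detection_metrics(match)
        assert (sens, prec) == (1.0, 1.0)

    def test_no_predictions_precision_undefined(self):
        gt = ev.GroundTruthROI("p0", "CC", toy_mask((30, 30), 5, 5), "benign")
        match = ev.match_rois([], [gt])
        sens, prec = ev.detection_metrics(match)
        assert sens == 0.0
        assert np.isnan(prec)


def auc_concordance_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        return float("nan")
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestClassificationAuc:
    def _match_from(self, scores, labels):
        shape = (300, 12)
        pairs, unmatched = [], []
        for i, (s, l) in enumerate(zip(scores, labels)):
            mask = toy_mask(shape, i * 12, 0, 6)
            probs = ev.BinomialProbs(1 - s, s)
            pred = ev.PredictionROI("p0", "CC", mask, "malignant_mass", 0.9)
            if l is None:
                unmatched.append((pred, probs))
            else:
                gt = ev.GroundTruthROI(
                    "p0", "CC", mask,
                    "malignant" if l == 1 else "benign")
                pairs.append(ev.MatchedPair(pred, gt, 1.0, probs, True))
        return ev.MatchResult(pairs=pairs, unmatched_preds=unmatched,
                              unmatched_gts=[])

    def test_perfect_separation(self):
        m = self._match_from([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ev.classification_auc(m) == 1.0

    def test_all_ties_half(self):
        m = self._match_from([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert ev.classification_auc(m) == 0.5

    def test_unmatched_referenced_benign(self):
        # one unmatched ROI with p_mal 0.9 enters as a benign reference
        m = self._match_from([0.8, 0.3, 0.9], [1, 0, None])
        scores, labels = [0.8, 0.3, 0.9], [1, 0, 0]
        assert ev.classification_auc(m) == pytest.approx(
            auc_concordance_oracle(scores, labels))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        scores = np.round(rng.uniform(0, 1, n), 1).tolist()
        labels = [int(x) for x in rng.integers(0, 2, n)]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        m = self._match_from(scores, labels)
        assert ev.classification_auc(m) == pytest.approx(
            auc_concordance_oracle(scores, labels))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(0.01, 0.99, 12).tolist()
        labels = [int(x) for x in rng.integers(0, 2, 12)]
        labels[0], labels[1] = 0, 1
        a1 = ev.classification_auc(self._match_from(scores, labels))
        squeezed = [s ** 3 for s in scores]   # strictly monotone
        a2 = ev.classification_auc(self._match_from(squeezed, labels))
        assert a1 == pytest.approx(a2)

    def test_single_class_undefined(self):
        m = self._match_from([0.7, 0.2], [1, 1])
        assert np.isnan(ev.classification_auc(m))


class TestBootstrap:
    def test_zero_variance_degenerate_interval(self):
        records = {f"p{i}": [0.7] for i in range(30)}
        lo, hi = ev.bootstrap_ci(lambda r: float(np.mean(r)), records,
                                 n_boot=200, seed=0)
        assert lo == hi == pytest.approx(0.7)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        records = {f"p{i}": [float(v)] for i, v in
                   enumerate(rng.uniform(0, 1, 50))}
        ci1 = ev.bootstrap_ci(lambda r: float(np.mean(r)), records,
                              n_boot=2000, seed=42)
        ci2 = ev.bootstrap_ci(lambda r: float(np.mean(r)), records,
                              n_boot=2000, seed=42)
        assert ci1 == ci2

    def test_nominal_coverage_on_bernoulli_means(self):
        # nested Monte Carlo: 95% interval should cover p=0.7 in 92-98%
        outer = 200
        n_patients = 200
        hits = 0
        rng = np.random.default_rng(7)
        for rep in range(outer):
            data = (rng.random(n_patients) < 0.7).astype(float)
            records = {f"p{i}": [float(v)] for i, v in enumerate(data)}
            lo, hi = ev.bootstrap_ci(lambda r: float(np.mean(r)), records,
                                     n_boot=2000,
                                     rng=np.random.default_rng(1000 + rep))
            if lo <= 0.7 <= hi:
                hits += 1
        assert 0.92 <= hits / outer <= 0.98

    def test_empty_patient_set_rejected(self):
        with pytest.raises(ValueError):
            ev.bootstrap_ci(lambda r: 0.0, {}, n_boot=10, seed=0)


class TestMetricDifference:
    def _records(self, rng, n=60, shift=0.0):
        return {f"p{i}": [float(rng.uniform(0, 1)) + shift] for i in range(n)}

    def test_identical_setups_zero_difference(self):
        rng = np.random.default_rng(0)
        a = self._records(rng)
        mean, lo, hi = ev.metric_difference_ci(
            lambda r: float(np.mean(r)), a, a, n_boot=300, seed=1)
        assert mean == 0.0
        assert lo <= 0.0 <= hi

    def test_planted_improvement_detected(self):
        rng = np.random.default_rng(2)
        base = {f"p{i}": [float(rng.uniform(0, 1))] for i in range(200)}
        better = {k: [v[0] + 0.1] for k, v in base.items()}
        mean, lo, hi = ev.metric_difference_ci(
            lambda r: float(np.mean(r)), better, base, n_boot=500, seed=3)
        assert mean == pytest.approx(0.1, abs=1e-9)
        assert lo > 0.0

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(4)
        a = self._records(rng, 40)
        b = {k: [v[0] * 0.8] for k, v in a.items()}
        m1, _, _ = ev.metric_difference_ci(lambda r: float(np.mean(r)), a, b,
                                           n_boot=200, seed=5)
        m2, _, _ = ev.metric_difference_ci(lambda r: float(np.mean(r)), b, a,
                                           n_boot=200, seed=5)
        assert m1 == pytest.approx(-m2)
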