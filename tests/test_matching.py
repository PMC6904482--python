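"""IoU arithmetic and greedy one-to-one hit assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from cadrepro import Box, Detection, Lesion, MatchConfig, counts_at_threshold, iou, match_exam
from cadrepro.matching import MixedExamError


def L(i, box):
    return Lesion(f"L{i}", "E", Box(*box))


def D(box, conf):
    return Detection("E", Box(*box), conf)


class TestIou:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 0, 10, 10), (0, 0, 10, 10), 1.0),
        ((0, 0, 1, 1), (5, 5, 6, 6), 0.0),
        ((0, 0, 10, 10), (5, 0, 15, 10), 50 / 150),
        ((0, 0, 10, 10), (10, 0, 20, 10), 0.0),  # edge-touching interiors disjoint
    ])
    def test_values(self, a, b, expected):
        assert iou(Box(*a), Box(*b)) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=8, max_size=8))
    def test_symmetric_and_bounded(self, vals):
        def mk(v):
            x0, y0, dx, dy = v
            return Box(x0, y0, x0 + dx + 0.5, y0 + dy + 0.5)
        a, b = mk(vals[:4]), mk(vals[4:])
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0


class TestMatchExam:
    def test_higher_confidence_claims_the_lesion(self):
        lesions = [L(0, (0, 0, 10, 10))]
        dets = [D((1, 1, 11, 11), 0.9), D((0, 0, 10, 10), 0.8)]
        res = match_exam(lesions, dets)
        assert len(res.hits) == 1
        hit = res.hits[0]
        assert hit.detection.confidence == 0.9
        assert hit.iou == pytest.approx(81 / 119)
        assert res.false_positives[0].confidence == 0.8
        assert res.missed == ()

    def test_zero_detections_all_missed(self):
        res = match_exam([L(0, (0, 0, 10, 10)), L(1, (20, 20, 30, 30))], [])
        assert res.hits == () and res.false_positives == ()
        assert set(res.missed) == {"L0", "L1"}

    def test_iou_exactly_at_threshold_is_fp_when_strict(self):
        lesions = [L(0, (0, 0, 10, 10))]
        dets = [D((0, 0, 10, 5), 0.9)]  # IoU = 50/100 = 0.5 exactly
        assert iou(lesions[0].box, dets[0].box) == 0.5
        strict = match_exam(lesions, dets, MatchConfig(strict=True))
        assert strict.hits == () and len(strict.false_positives) == 1
        lax = match_exam(lesions, dets, MatchConfig(strict=False))
        assert len(lax.hits) == 1

    def test_mixed_exam_ids_raise(self):
        with pytest.raises(MixedExamError):
            match_exam([L(0, (0, 0, 10, 10))],
                       [Detection("OTHER", Box(0, 0, 10, 10), 0.5)])

    def test_one_to_one_each_lesion_claimed_once(self):
        lesions = [L(0, (0, 0, 10, 10))]
        dets = [D((0, 0, 10, 10), 0.9), D((1, 1, 10, 10), 0.8)]
        res = match_exam(lesions, dets)
        assert len(res.hits) == 1 and len(res.false_positives) == 1


class TestCountsAtThreshold:
    def setup_method(self):
        self.lesions = [L(0, (0, 0, 10, 10))]
        self.dets = [D((1, 1, 11, 11), 0.9), D((0, 0, 10, 10), 0.8)]
        self.match = match_exam(self.lesions, self.dets)

    @pytest.mark.parametrize("tau,expected", [
        (0.0, (1, 1, 0)),    # below all confidences: full match counts
        (0.85, (1, 0, 0)),   # keeps only the hit
        (0.95, (0, 0, 1)),   # above all: everything gone, lesion missed
    ])
    def test_enumerated(self, tau, expected):
        assert counts_at_threshold(self.match, self.dets, tau) == expected

    def test_tp_monotone_in_tau(self):
        taus = np.linspace(0, 1, 21)
        tps = [counts_at_threshold(self.match, self.dets, t)[0] for t in taus]
        fns = [counts_at_threshold(self.match, self.dets, t)[2] for t in taus]
        assert all(a >= b for a, b in zip(tps, tps[1:]))
        assert all(a <= b for a, b in zip(fns, fns[1:]))


def random_disjoint_instance(rng, max_lesions=5, max_dets=5):
    """Random exam with disjoint lesions (as in real nodule annotation)."""
    n_l = rng.integers(0, max_lesions + 1)
    n_d = rng.integers(0, max_dets + 1)
    lesions = []
    grid = rng.permutation(16)[:n_l]  # disjoint cells of a 4x4 grid
    for i, cell in enumerate(grid):
        gx, gy = (cell % 4) * 100, (cell // 4) * 100
        w, h = rng.uniform(30, 80, size=2)
        x0, y0 = gx + rng.uniform(0, 90 - w), gy + rng.uniform(0, 90 - h)
        lesions.append(L(i, (x0, y0, x0 + w, y0 + h)))
    dets = []
    for _ in range(n_d):
        if lesions and rng.random() < 0.6:
            base = lesions[rng.integers(0, len(lesions))].box
            dx, dy = rng.normal(0, 10, size=2)
            dets.append(D((base.x_min + dx, base.y_min + dy,
                           base.x_max + dx, base.y_max + dy),
                          float(rng.random())))
        else:
            x0, y0 = rng.uniform(0, 350, size=2)
            w, h = rng.uniform(20, 60, size=2)
            dets.append(D((x0, y0, x0 + w, y0 + h), float(rng.random())))
    return lesions, dets


def max_cardinality_hits(lesions, dets, config=MatchConfig()):
    """Exhaustive maximum-cardinality assignment via linear_sum_assignment."""
    if not lesions or not dets:
        return 0
    gain = np.zeros((len(dets), len(lesions)))
    for i, d in enumerate(dets):
        for j, l in enumerate(lesions):
            gain[i, j] = 1.0 if config.passes(iou(d.box, l.box)) else 0.0
    rows, cols = linear_sum_assignment(-gain)
    return int(gain[rows, cols].sum())


def test_greedy_equals_exhaustive_assignment_on_disjoint_lesions():
    rng = np.random.default_rng(42)
    for _ in range(300):
        lesions, dets = random_disjoint_instance(rng)
        res = match_exam(lesions, dets)
        assert len(res.hits) == max_cardinality_hits(lesions, dets)
        # partition invariants
        assert len(res.hits) + len(res.false_positives) == len(dets)
        assert len(res.hits) + len(res.missed) == len(lesions)
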