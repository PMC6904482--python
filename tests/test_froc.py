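"""FROC construction, operating-point selection and the figure of merit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cadrepro import (
    Box,
    Detection,
    FrocCurve,
    FrocPoint,
    SimConfig,
    fom_ci,
    froc_curve,
    jafroc_fom,
    simulate_paired_detections,
    threshold_at_fp,
)
from cadrepro.matching import Hit, MatchResult


def make_match(hit_confs, fp_confs, n_lesions):
    """Assemble a MatchResult directly from confidence lists."""
    hits = tuple(
        Hit(f"L{i}", Detection("E", Box(0, 0, 1, 1), c), 0.9)
        for i, c in enumerate(hit_confs)
    )
    fps = tuple(Detection("E", Box(2, 2, 3, 3), c) for c in fp_confs)
    missed = tuple(f"M{i}" for i in range(n_lesions - len(hits)))
    return MatchResult(hits=hits, false_positives=fps, missed=missed,
                       n_lesions=n_lesions)


WORKED_CURVE = froc_curve([
    make_match([0.9], [0.6], 1),   # exam 1: hit at 0.9, FP at 0.6
    make_match([0.4], [], 1),      # exam 2: hit at 0.4
])


class TestFrocCurve:
    def test_worked_sweep(self):
        assert WORKED_CURVE.points == (
            FrocPoint(0.9, 0.0, 0.5),
            FrocPoint(0.6, 0.5, 0.5),
            FrocPoint(0.4, 0.5, 1.0),
        )

    def test_perfect_detector_single_point(self):
        curve = froc_curve([make_match([1.0], [], 1), make_match([1.0], [], 1)])
        assert curve.points == (FrocPoint(1.0, 0.0, 1.0),)

    def test_all_false_positives_zero_sensitivity(self):
        curve = froc_curve([make_match([], [0.7, 0.2], 1)])
        assert all(p.sensitivity == 0.0 for p in curve.points)

    def test_zero_lesions_raises(self):
        with pytest.raises(ValueError):
            froc_curve([make_match([], [0.5], 0)])


class TestThresholdAtFp:
    @pytest.mark.parametrize("fp_target,expected_tau", [
        (0.5, 0.4),
        (0.0, 0.9),
        (10.0, 0.4),   # budget never binds -> smallest tau
    ])
    def test_selection(self, fp_target, expected_tau):
        assert threshold_at_fp(WORKED_CURVE, fp_target) == expected_tau

    def test_infeasible_budget_silences_detector(self):
        curve = froc_curve([make_match([0.5], [0.8], 1)])  # avg_fp 1 even at top
        tau = threshold_at_fp(curve, 0.1)
        assert tau > 0.8

    def test_negative_target_raises(self):
        with pytest.raises(ValueError):
            threshold_at_fp(WORKED_CURVE, -0.1)


class TestJafrocFom:
    def test_perfect_detector_is_one(self):
        assert jafroc_fom([make_match([0.9], [], 1), make_match([0.8], [], 1)]) == 1.0

    def test_worked_psi_table(self):
        # lesions rated {0.9, 0.4}; image 1 has an FP at 0.6, image 2 none
        matches = [make_match([0.9], [0.6], 1), make_match([0.4], [], 1)]
        assert jafroc_fom(matches) == 0.75

    def test_no_detections_is_chance(self):
        assert jafroc_fom([make_match([], [], 1), make_match([], [], 2)]) == 0.5

    def test_zero_lesions_raises(self):
        with pytest.raises(ValueError):
            jafroc_fom([make_match([], [0.3], 0)])

    def brute_force(self, matches):
        ratings, max_fps = [], []
        for m in matches:
            rs = [h.detection.confidence for h in m.hits]
            rs += [-np.inf] * len(m.missed)
            ratings.extend(rs)
            fps = [d.confidence for d in m.false_positives]
            max_fps.append(max(fps) if fps else -np.inf)
        total = 0.0
        for mf in max_fps:
            for r in ratings:
                if r > mf:
                    total += 1.0
                elif r == mf and (np.isfinite(r) or (np.isneginf(r) and np.isneginf(mf))):
                    total += 0.5
        return total / (len(max_fps) * len(ratings))

    def test_matches_exhaustive_double_loop(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_img = rng.integers(1, 5)
            matches, n_lesions = [], 0
            for _ in range(n_img):
                n_l = int(rng.integers(0, 4))
                n_hit = int(rng.integers(0, n_l + 1))
                confs = np.round(rng.random(n_hit + rng.integers(0, 4)), 1)
                matches.append(make_match(list(confs[:n_hit]), list(confs[n_hit:]), n_l))
                n_lesions += n_l
            if n_lesions == 0:
                continue
            assert jafroc_fom(matches) == pytest.approx(self.brute_force(matches))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        matches = [
            make_match(list(rng.random(2)), list(rng.random(3)), 3)
            for _ in range(5)
        ]
        def transform(m):
            return make_match(
                [np.expm1(h.detection.confidence * 3) for h in m.hits],
                [np.expm1(d.confidence * 3) for d in m.false_positives],
                m.n_lesions,
            )
        assert jafroc_fom(matches) == pytest.approx(
            jafroc_fom([transform(m) for m in matches])
        )


@st.composite
def random_matches(draw):
    n_img = draw(st.integers(1, 6))
    matches = []
    total = 0
    for _ in range(n_img):
        n_l = draw(st.integers(0, 3))
        n_hit = draw(st.integers(0, n_l))
        confs = draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n_hit + 0,
            max_size=n_hit + 3))
        hit_confs = confs[:n_hit]
        fp_confs = confs[n_hit:]
        matches.append(make_match(hit_confs, fp_confs, n_l))
        total += n_l
    return matches, total


@settings(max_examples=300, deadline=None)
@given(random_matches())
def test_froc_monotone_and_fom_bounded(case):
    matches, total = case
    if total == 0:
        return
    fom = jafroc_fom(matches)
    assert 0.0 <= fom <= 1.0
    curve = froc_curve(matches)
    pts = curve.points
    for p0, p1 in zip(pts, pts[1:]):  # decreasing tau
        assert p1.avg_fp >= p0.avg_fp
        assert p1.sensitivity >= p0.sensitivity


class TestFomCi:
    def test_perfect_detector_degenerate_interval(self):
        matches_ds, _ = simulate_paired_detections(
            SimConfig(n_pairs=5, sensitivity=1.0, correlation=1.0, fp_rate=0.0, seed=2)
        )
        res = fom_ci(matches_ds, n_boot=200, seed=1)
        assert (res.fom, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)

    def test_deterministic_given_seed(self):
        ds, _ = simulate_paired_detections(SimConfig(n_pairs=20, seed=8))
        r1 = fom_ci(ds, n_boot=200, seed=5)
        r2 = fom_ci(ds, n_boot=200, seed=5)
        assert r1 == r2

    def test_interval_contains_full_data_fom(self):
        ds, _ = simulate_paired_detections(SimConfig(n_pairs=200, seed=4))
        res = fom_ci(ds, n_boot=1000, seed=3)
        assert res.ci_low <= res.fom <= res.ci_high
        assert res.ci_high - res.ci_low < 0.2

    def test_jackknife_option(self):
        ds, _ = simulate_paired_detections(SimConfig(n_pairs=30, seed=9))
        res = fom_ci(ds, n_boot=200, seed=1, method="jackknife")
        assert res.ci_low <= res.fom <= res.ci_high

    def test_too_few_patients_raises(self):
        ds, _ = simulate_paired_detections(SimConfig(n_pairs=1, seed=0))
        with pytest.raises(ValueError):
            fom_ci(ds, n_boot=200, seed=0)
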