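"""Synthetic paired-exam detection datasets with known reproducibility.

The simulator emulates a test–retest cohort: each patient is imaged twice
within a short interval with no disease change, so the two exams share the
same lesions. Detection is modelled per lesion as a pair of Bernoulli events
with marginal rate ``sensitivity`` and a shared-draw correlation mechanism:
with probability ``correlation`` a single draw is used for both exams,
otherwise the two exams draw independently. This yields the closed form

    E[PPA]  = 100 * (rho + (1 - rho) * s)
    E[CPPA] = 100 * E[PPA] / (200 - E[PPA])

for sensitivity s and correlation rho, evaluated at a threshold every true
detection survives. Each exam additionally receives a Poisson number of
false positives at locations disjoint from every lesion, with confidences
drawn low; true-positive confidences are drawn high. Detected-lesion boxes
are jittered versions of the ground-truth box, small enough that the
IoU > 0.5 hit criterion always recognises them.

Defaults mirror a 121-patient validation cohort in which 108 patients have
one lesion and 13 have more, detector sensitivity is around 0.8 at the usual
operating band, and the per-image false-positive rate is of order one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .annotations import Box, Dataset, Detection, Exam, ExamPair, Lesion

__all__ = [
    "SimConfig",
    "LesionEvents",
    "SimTruth",
    "simulate_paired_detections",
    "expected_ppa",
    "expected_cppa",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the paired-detection simulator.

    n_pairs : patients (each contributes an initial and a follow-up exam).
    extra_lesion_prob : probability a patient carries a second lesion
        (lesion count is 1 + Bernoulli).
    image_size : square image side in pixels.
    sensitivity : per-exam marginal probability that a lesion is detected.
    correlation : probability the two exams share one detection draw.
    fp_rate : Poisson mean number of false positives per image.
    tp_score, fp_score : Beta(alpha, beta) parameters of true-positive and
        false-positive confidence distributions on [0, 1].
    box_jitter : pixel scale of follow-up ground-truth displacement and of
        detection-box jitter (capped relative to box size so hits survive
        the IoU criterion).
    lesion_size_range : (min, max) box side length in pixels.
    seed : RNG seed; everything downstream is deterministic given it.
    """

    n_pairs: int = 121
    extra_lesion_prob: float = 13 / 121
    image_size: int = 1024
    sensitivity: float = 0.8
    correlation: float = 0.8
    fp_rate: float = 1.0
    tp_score: tuple[float, float] = (6.0, 2.0)
    fp_score: tuple[float, float] = (2.0, 6.0)
    box_jitter: float = 8.0
    lesion_size_range: tuple[float, float] = (32.0, 160.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        if not 0.0 <= self.extra_lesion_prob <= 1.0:
            raise ValueError("extra_lesion_prob must be in [0, 1]")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in [0, 1]")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be non-negative")
        if self.box_jitter < 0:
            raise ValueError("box_jitter must be non-negative")
        lo, hi = self.lesion_size_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_size_range must satisfy 0 < min <= max")
        if hi > self.image_size / 2:
            raise ValueError("largest lesion must fit in half the image")


class LesionEvents(NamedTuple):
    """Latent per-lesion detection events for one lesion across the pair."""

    patient_id: str
    lesion_id: str
    detected_initial: bool
    detected_followup: bool


@dataclass(frozen=True)
class SimTruth:
    """The configuration used plus the latent detection events."""

    config: SimConfig
    events: tuple[LesionEvents, ...]


class _Placer:
    """Rejection-samples boxes that do not intersect already placed ones."""

    def __init__(self, image_size: int, rng: np.random.Generator):
        self.image_size = image_size
        self.rng = rng
        self.placed: list[tuple[float, float, float, float]] = []

    def place(self, w: float, h: float, max_tries: int = 200) -> Box:
        for _ in range(max_tries):
            x0 = self.rng.uniform(0, self.image_size - w)
            y0 = self.rng.uniform(0, self.image_size - h)
            cand = (x0, y0, x0 + w, y0 + h)
            if all(
                cand[2] <= p[0] or p[2] <= cand[0] or cand[3] <= p[1] or p[3] <= cand[1]
                for p in self.placed
            ):
                self.placed.append(cand)
                return Box(*cand)
        raise ValueError(
            f"could not place a {w:.0f}x{h:.0f} box in a {self.image_size}px image "
            "without overlap; geometry infeasible"
        )


def _jitter_box(box: Box, scale: float, image_size: int, rng: np.random.Generator) -> Box:
    """Translate/scale a box by a bounded amount: IoU with the original stays > 0.5.

    Per-axis shift is capped at 12% of the side and the size factor lies in
    [0.95, 1.05], giving worst-case IoU around 0.6.
    """
    w = box.x_max - box.x_min
    h = box.y_max - box.y_min
    dx = float(np.clip(rng.normal(0.0, scale), -0.12 * w, 0.12 * w))
    dy = float(np.clip(rng.normal(0.0, scale), -0.12 * h, 0.12 * h))
    f = float(rng.uniform(0.95, 1.05))
    cx = (box.x_min + box.x_max) / 2 + dx
    cy = (box.y_min + box.y_max) / 2 + dy
    hw, hh = f * w / 2, f * h / 2
    cx = float(np.clip(cx, hw, image_size - hw))
    cy = float(np.clip(cy, hh, image_size - hh))
    return Box(cx - hw, cy - hh, cx + hw, cy + hh)


def simulate_paired_detections(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Draw a full paired dataset (ground truth + detections) from the model."""
    rng = np.random.default_rng(config.seed)
    s, rho = config.sensitivity, config.correlation
    lo, hi = config.lesion_size_range

    pairs: list[ExamPair] = []
    detections: dict[str, list[Detection]] = {}
    events: list[LesionEvents] = []

    for p in range(config.n_pairs):
        patient_id = f"P{p:04d}"
        exam_init = Exam(f"{patient_id}_I", patient_id, "initial",
                         config.image_size, config.image_size)
        exam_fu = Exam(f"{patient_id}_F", patient_id, "followup",
                       config.image_size, config.image_size)
        n_lesions = 1 + int(rng.random() < config.extra_lesion_prob)

        placer_init = _Placer(config.image_size, rng)
        placer_fu = _Placer(config.image_size, rng)
        init_lesions: list[Lesion] = []
        fu_lesions: list[Lesion] = []
        det_init: list[Detection] = []
        det_fu: list[Detection] = []

        for li in range(n_lesions):
            lesion_id = f"{patient_id}_L{li}"
            w = float(rng.uniform(lo, hi))
            h = float(w * rng.uniform(0.8, 1.25))
            h = min(h, hi)
            box_init = placer_init.place(w, h)
            # patient repositioning between exams shifts the box slightly
            box_fu = _jitter_box(box_init, config.box_jitter, config.image_size, rng)
            placer_fu.placed.append((box_fu.x_min, box_fu.y_min,
                                     box_fu.x_max, box_fu.y_max))
            size_mm = float((w + h) / 2 * 0.35)  # ~0.35 mm/px CXR scale
            init_lesions.append(Lesion(lesion_id, exam_init.exam_id, box_init, size_mm))
            fu_lesions.append(Lesion(lesion_id, exam_fu.exam_id, box_fu, size_mm))

            if rng.random() < rho:
                z = rng.random() < s
                hit_init = hit_fu = z
            else:
                hit_init = rng.random() < s
                hit_fu = rng.random() < s
            events.append(LesionEvents(patient_id, lesion_id, hit_init, hit_fu))

            for hit, exam, gt_box, sink in (
                (hit_init, exam_init, box_init, det_init),
                (hit_fu, exam_fu, box_fu, det_fu),
            ):
                if hit:
                    dbox = _jitter_box(gt_box, config.box_jitter / 2,
                                       config.image_size, rng)
                    conf = float(rng.beta(*config.tp_score))
                    sink.append(Detection(exam.exam_id, dbox, conf))

        for exam, placer, sink in (
            (exam_init, placer_init, det_init),
            (exam_fu, placer_fu, det_fu),
        ):
            n_fp = int(rng.poisson(config.fp_rate))
            for _ in range(n_fp):
                w = float(rng.uniform(lo, hi))
                h = float(rng.uniform(lo, hi))
                fp_box = placer.place(w, h)
                conf = float(rng.beta(*config.fp_score))
                sink.append(Detection(exam.exam_id, fp_box, conf))

        pairs.append(ExamPair(patient_id, exam_init, exam_fu,
                              tuple(init_lesions), tuple(fu_lesions)))
        detections[exam_init.exam_id] = det_init
        detections[exam_fu.exam_id] = det_fu

    dataset = Dataset(pairs=pairs, detections=detections)
    return dataset, SimTruth(config=config, events=tuple(events))


def expected_ppa(s: float, rho: float) -> float:
    """Analytic PPA of the shared-draw model: 100 * (rho + (1 - rho) * s).

    Per lesion, P(both) = rho*s + (1-rho)*s^2 and P(exactly one) =
    2*(1-rho)*s*(1-s); substituting into PPA = 100*2a/(2a+b+c) cancels to
    the stated form.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError(f"sensitivity must be in (0, 1], got {s}")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"correlation must be in [0, 1], got {rho}")
    return 100.0 * (rho + (1.0 - rho) * s)


def expected_cppa(s: float, rho: float) -> float:
    """Analytic CPPA via the identity CPPA = 100*PPA/(200-PPA)."""
    p = expected_ppa(s, rho)
    return 100.0 * p / (200.0 - p)
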