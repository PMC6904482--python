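"""IoU computation and assignment of detections to ground-truth lesions.

The hit criterion declares a detection a true positive when its
intersection-over-union with a labeled lesion box exceeds a threshold
(default 0.5, strictly). Assignment is greedy and one-to-one: detections are
visited in descending confidence and each claims the still-unclaimed lesion
of highest IoU among those above threshold. Ties in confidence are broken by
higher best-available IoU, then by input order, so reruns are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .annotations import Box, Detection, Lesion

__all__ = [
    "MatchConfig",
    "Hit",
    "MatchResult",
    "MixedExamError",
    "iou",
    "match_exam",
    "counts_at_threshold",
]


class MixedExamError(ValueError):
    """Lesions and detections passed to match_exam span multiple exams."""


@dataclass(frozen=True)
class MatchConfig:
    """Hit-criterion configuration.

    iou_threshold : float in (0, 1)
        Minimum overlap for a detection to count as a hit.
    strict : bool
        If True (default) the IoU must strictly exceed the threshold
        ("over 0.5"); if False, equality also counts.
    """

    iou_threshold: float = 0.5
    strict: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError(f"iou_threshold must be in (0,1), got {self.iou_threshold}")

    def passes(self, value: float) -> bool:
        return value > self.iou_threshold if self.strict else value >= self.iou_threshold


class Hit(NamedTuple):
    lesion_id: str
    detection: Detection
    iou: float


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one exam: hits, unmatched detections, missed lesions."""

    hits: tuple[Hit, ...]
    false_positives: tuple[Detection, ...]
    missed: tuple[str, ...]
    n_lesions: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.hits) + len(self.missed) != self.n_lesions:
            raise ValueError("hits + missed must cover all lesions")

    @property
    def hit_confidences(self) -> np.ndarray:
        return np.array([h.detection.confidence for h in self.hits], dtype=float)

    @property
    def fp_confidences(self) -> np.ndarray:
        return np.array([d.confidence for d in self.false_positives], dtype=float)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def match_exam(
    lesions: Sequence[Lesion],
    detections: Sequence[Detection],
    config: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Greedy one-to-one assignment of detections to lesions under the hit criterion."""
    exam_ids = {l.exam_id for l in lesions} | {d.exam_id for d in detections}
    if len(exam_ids) > 1:
        raise MixedExamError(f"items span multiple exams: {sorted(exam_ids)}")

    n_l, n_d = len(lesions), len(detections)
    iou_mat = np.zeros((n_d, n_l))
    for i, det in enumerate(detections):
        for j, lesion in enumerate(lesions):
            iou_mat[i, j] = iou(det.box, lesion.box)

    best_iou = iou_mat.max(axis=1) if n_l else np.zeros(n_d)
    order = sorted(
        range(n_d),
        key=lambda i: (-detections[i].confidence, -best_iou[i], i),
    )

    claimed: set[int] = set()
    hits: list[Hit] = []
    false_positives: list[Detection] = []
    for i in order:
        best_j, best_v = -1, -1.0
        for j in range(n_l):
            if j in claimed:
                continue
            v = iou_mat[i, j]
            if config.passes(v) and v > best_v:
                best_j, best_v = j, v
        if best_j >= 0:
            claimed.add(best_j)
            hits.append(Hit(lesions[best_j].lesion_id, detections[i], best_v))
        else:
            false_positives.append(detections[i])

    missed = tuple(l.lesion_id for j, l in enumerate(lesions) if j not in claimed)
    return MatchResult(
        hits=tuple(hits),
        false_positives=tuple(false_positives),
        missed=missed,
        n_lesions=n_l,
    )


def counts_at_threshold(
    match: MatchResult,
    detections: Sequence[Detection],
    tau: float,
) -> tuple[int, int, int]:
    """(tp, fp, fn) when only detections with confidence >= tau are kept.

    Matching is performed once on the full detection list; thresholding then
    simply discards hits and false positives whose detection falls below tau.
    """
    tp = int(sum(h.detection.confidence >= tau for h in match.hits))
    fp = int(sum(d.confidence >= tau for d in match.false_positives))
    fn = match.n_lesions - tp
    return tp, fp, fn
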