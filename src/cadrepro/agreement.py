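"""Paired-exam agreement: the a/b/c/d confusion and PPA / CPPA statistics.

For each ground-truth lesion of a patient imaged twice, four outcomes are
possible at a given operating threshold: detected in both exams (a),
detected only in the initial exam (b), only in the follow-up exam (c), or in
neither (d). Agreement between the two readings is summarised by

    PPA  = 100 * 2a / (2a + b + c)        (percent positive agreement)
    CPPA = 100 *  a / ( a + b + c)        (Chamberlain's PPA)

d is deliberately excluded: the statistics measure how consistently lesions
known to be present are re-detected, not how often absence is agreed on.
For any single confusion the two are algebraically linked by
CPPA = 100*PPA/(200-PPA); means across several operating points do not obey
the identity because averaging does not commute with it.

Operating thresholds are taken from the FROC curve at target average-FP
rates (default 0.1–0.5 per image). The selection FROC pools both exams of
every pair by default, so the chosen threshold reflects the scores it will
be applied to; an initial-exams-only selection is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .annotations import Dataset, ExamPair
from .froc import froc_curve, match_dataset, threshold_at_fp
from .matching import MatchConfig, MatchResult

__all__ = [
    "PairedConfusion",
    "ThresholdAgreement",
    "AgreementResult",
    "UndefinedAgreementError",
    "compute_ppa",
    "compute_cppa",
    "cppa_from_ppa",
    "ppa_from_cppa",
    "paired_confusion",
    "agreement_over_thresholds",
    "DEFAULT_FP_TARGETS",
]

DEFAULT_FP_TARGETS = (0.1, 0.2, 0.3, 0.4, 0.5)


class UndefinedAgreementError(ValueError):
    """PPA/CPPA are undefined when a = b = c = 0 (no positive reading at all)."""


@dataclass(frozen=True)
class PairedConfusion:
    """Per-lesion paired detection outcomes: both / initial only / follow-up only / neither."""

    a: int
    b: int
    c: int
    d: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def ppa(self) -> float:
        return compute_ppa(self.a, self.b, self.c)

    @property
    def cppa(self) -> float:
        return compute_cppa(self.a, self.b, self.c)


def _check_counts(a: int, b: int, c: int) -> None:
    for name, v in (("a", a), ("b", b), ("c", c)):
        if v < 0:
            raise ValueError(f"count {name} must be non-negative, got {v}")
    if a == 0 and b == 0 and c == 0:
        raise UndefinedAgreementError("agreement undefined: a = b = c = 0")


def compute_ppa(a: int, b: int, c: int) -> float:
    """Percent positive agreement, 100 * 2a / (2a + b + c)."""
    _check_counts(a, b, c)
    return 100.0 * 2 * a / (2 * a + b + c)


def compute_cppa(a: int, b: int, c: int) -> float:
    """Chamberlain's percent positive agreement, 100 * a / (a + b + c)."""
    _check_counts(a, b, c)
    return 100.0 * a / (a + b + c)


def cppa_from_ppa(ppa: float) -> float:
    """Map PPA to CPPA via the single-confusion identity CPPA = 100*PPA/(200-PPA)."""
    if not 0.0 <= ppa <= 100.0:
        raise ValueError(f"PPA must be in [0, 100], got {ppa}")
    return 100.0 * ppa / (200.0 - ppa)


def ppa_from_cppa(cppa: float) -> float:
    """Inverse identity: PPA = 200*CPPA/(100+CPPA)."""
    if not 0.0 <= cppa <= 100.0:
        raise ValueError(f"CPPA must be in [0, 100], got {cppa}")
    return 200.0 * cppa / (100.0 + cppa)


def _detected_ids(match: MatchResult, tau: float) -> set[str]:
    return {h.lesion_id for h in match.hits if h.detection.confidence >= tau}


def paired_confusion(
    pairs: Sequence[ExamPair],
    matches_initial: Sequence[MatchResult],
    matches_followup: Sequence[MatchResult],
    tau: float,
) -> PairedConfusion:
    """Tally a/b/c/d per lesion across all pairs at threshold tau.

    A lesion counts as detected in an exam iff its hit detection survives tau.
    """
    if not math.isfinite(tau):
        raise ValueError(f"tau must be finite, got {tau}")
    if not (len(pairs) == len(matches_initial) == len(matches_followup)):
        raise ValueError("pairs and match sequences must be aligned")
    a = b = c = d = 0
    for pair, m_init, m_fu in zip(pairs, matches_initial, matches_followup):
        det_init = _detected_ids(m_init, tau)
        det_fu = _detected_ids(m_fu, tau)
        for lesion_id in pair.lesion_ids:
            in_init = lesion_id in det_init
            in_fu = lesion_id in det_fu
            if in_init and in_fu:
                a += 1
            elif in_init:
                b += 1
            elif in_fu:
                c += 1
            else:
                d += 1
    return PairedConfusion(a, b, c, d)


class ThresholdAgreement(NamedTuple):
    fp_target: float
    tau: float
    confusion: PairedConfusion
    ppa: float
    cppa: float


@dataclass(frozen=True)
class AgreementResult:
    """Agreement at each FP operating point plus mean +/- spread across points.

    Standard deviations are population (divide by n) — a descriptive spread
    over the handful of operating points, not an inferential estimate.
    """

    per_threshold: tuple[ThresholdAgreement, ...]
    ppa_mean: float
    ppa_std: float
    cppa_mean: float
    cppa_std: float


def agreement_over_thresholds(
    dataset: Dataset,
    fp_targets: Sequence[float] = DEFAULT_FP_TARGETS,
    config: MatchConfig = MatchConfig(),
    froc_roles: str = "both",
) -> AgreementResult:
    """PPA/CPPA at each FP-budget operating point, then mean +/- std.

    The FROC used for threshold selection is built over the exams named by
    froc_roles ("both" by default; "initial"/"followup" restrict it).
    """
    if len(fp_targets) == 0:
        raise ValueError("fp_targets must be non-empty")
    if any(t < 0 for t in fp_targets):
        raise ValueError("fp_targets must be non-negative")
    matches = match_dataset(dataset, config, roles="both")
    m_init = [matches[p.initial.exam_id] for p in dataset.pairs]
    m_fu = [matches[p.followup.exam_id] for p in dataset.pairs]
    froc_matches = {
        "initial": m_init,
        "followup": m_fu,
        "both": m_init + m_fu,
    }[froc_roles]
    curve = froc_curve(froc_matches)

    rows = []
    for fp_target in sorted(fp_targets):
        tau = threshold_at_fp(curve, fp_target)
        confusion = paired_confusion(dataset.pairs, m_init, m_fu, tau)
        rows.append(
            ThresholdAgreement(fp_target, tau, confusion, confusion.ppa, confusion.cppa)
        )
    ppas = np.array([r.ppa for r in rows])
    cppas = np.array([r.cppa for r in rows])
    return AgreementResult(
        per_threshold=tuple(rows),
        ppa_mean=float(ppas.mean()),
        ppa_std=float(ppas.std(ddof=0)),
        cppa_mean=float(cppas.mean()),
        cppa_std=float(cppas.std(ddof=0)),
    )
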