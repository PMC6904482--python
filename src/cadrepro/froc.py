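"""FROC curve, operating-point selection and JAFROC figure of merit.

The free-response ROC (FROC) plots lesion sensitivity against the average
number of false positives per image as the confidence threshold sweeps over
the detector's scores. Operating points are picked as the most permissive
threshold whose average false-positive rate stays within a budget (e.g. 0.1
to 0.5 FPs per image).

The figure of merit (FOM) is the JAFROC1-style statistic: the probability
that a randomly chosen lesion's hit rating exceeds the highest
false-positive rating of a randomly chosen image, counting unhit lesions and
FP-free images as rating minus infinity and scoring exact (finite) ties and
doubly-absent comparisons 1/2. It is invariant under any strictly increasing
transform of the confidences. Because every image in the intended setting
contains at least one lesion, the highest FP rating is taken from all
images (no normal-image subset exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotations import Dataset
from .matching import MatchConfig, MatchResult, match_exam

__all__ = [
    "FrocPoint",
    "FrocCurve",
    "FomResult",
    "froc_curve",
    "threshold_at_fp",
    "jafroc_fom",
    "fom_ci",
    "match_dataset",
]


class FrocPoint(NamedTuple):
    tau: float
    avg_fp: float
    sensitivity: float


@dataclass(frozen=True)
class FrocCurve:
    """FROC points ordered by decreasing threshold.

    As tau decreases both avg_fp and sensitivity are non-decreasing.
    """

    points: tuple[FrocPoint, ...]

    def __post_init__(self) -> None:
        taus = [p.tau for p in self.points]
        if any(t0 <= t1 for t0, t1 in zip(taus, taus[1:])):
            raise ValueError("FROC points must be ordered by strictly decreasing tau")
        for p in self.points:
            if not (0.0 <= p.sensitivity <= 1.0) or p.avg_fp < 0:
                raise ValueError(f"invalid FROC point {p}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["tau", "avg_fp", "sensitivity"])


@dataclass(frozen=True)
class FomResult:
    fom: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    method: str = "bootstrap"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.fom <= self.ci_high):
            raise ValueError("FOM must lie inside its confidence interval")


def _pool(matches: Sequence[MatchResult]) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Pooled hit confidences, FP confidences, lesion and image counts."""
    hit_conf = np.concatenate([m.hit_confidences for m in matches]) if matches else np.array([])
    fp_conf = np.concatenate([m.fp_confidences for m in matches]) if matches else np.array([])
    n_lesions = sum(m.n_lesions for m in matches)
    return hit_conf, fp_conf, n_lesions, len(matches)


def froc_curve(matches: Sequence[MatchResult]) -> FrocCurve:
    """Build the FROC curve from per-exam match results (one per image)."""
    hit_conf, fp_conf, n_lesions, n_images = _pool(matches)
    if n_lesions == 0:
        raise ValueError("FROC undefined: no lesions in any exam")
    all_conf = np.concatenate([hit_conf, fp_conf])
    if all_conf.size == 0:
        return FrocCurve(points=())
    taus = np.unique(all_conf)[::-1]
    # counts of scores >= tau via sorted cumulative sums
    hit_sorted = np.sort(hit_conf)
    fp_sorted = np.sort(fp_conf)
    points = []
    for tau in taus:
        tp = hit_sorted.size - np.searchsorted(hit_sorted, tau, side="left")
        fp = fp_sorted.size - np.searchsorted(fp_sorted, tau, side="left")
        points.append(FrocPoint(float(tau), fp / n_images, tp / n_lesions))
    return FrocCurve(points=tuple(points))


def threshold_at_fp(curve: FrocCurve, fp_target: float) -> float:
    """Most permissive threshold whose average FP rate stays within budget.

    Returns the smallest tau on the curve with avg_fp <= fp_target (this
    maximises sensitivity subject to the FP budget). If even the strictest
    point exceeds the budget, a threshold just above the highest confidence
    is returned, silencing the detector.
    """
    if fp_target < 0:
        raise ValueError(f"fp_target must be non-negative, got {fp_target}")
    if not curve.points:
        raise ValueError("empty FROC curve")
    chosen = None
    for p in curve.points:  # decreasing tau, non-decreasing avg_fp
        if p.avg_fp <= fp_target:
            chosen = p.tau
        else:
            break
    if chosen is None:
        return float(np.nextafter(curve.points[0].tau, np.inf))
    return float(chosen)


def jafroc_fom(matches: Sequence[MatchResult]) -> float:
    """JAFROC1-style figure of merit from per-exam match results.

    Every lesion rating (hit confidence, or -inf if missed) is compared with
    every image's highest false-positive rating (-inf if the image has none):
    score 1 if the lesion rating is higher, 1/2 on a finite tie or when both
    are absent, 0 otherwise; the FOM is the average over all
    (image, lesion) comparisons.
    """
    n_lesions = sum(m.n_lesions for m in matches)
    if n_lesions == 0:
        raise ValueError("FOM undefined: no lesions")
    ratings = np.full(n_lesions, -np.inf)
    k = 0
    for m in matches:
        nh = len(m.hits)
        ratings[k:k + nh] = m.hit_confidences
        k += m.n_lesions  # missed lesions stay at -inf
    max_fp = np.array([
        m.fp_confidences.max() if len(m.false_positives) else -np.inf
        for m in matches
    ])
    les = ratings[None, :]            # (1, n_lesions)
    fps = max_fp[:, None]             # (n_images, 1)
    wins = les > fps
    both_absent = np.isneginf(les) & np.isneginf(fps)
    finite_tie = (les == fps) & np.isfinite(les)
    psi = wins + 0.5 * (both_absent | finite_tie)
    return float(psi.mean())


def match_dataset(
    dataset: Dataset,
    config: MatchConfig = MatchConfig(),
    roles: str = "both",
) -> dict[str, MatchResult]:
    """Match every exam of the dataset; keys are exam ids.

    roles: "initial", "followup" or "both" — which exam of each pair to match.
    """
    if roles not in ("initial", "followup", "both"):
        raise ValueError(f"roles must be initial/followup/both, got {roles!r}")
    out: dict[str, MatchResult] = {}
    for pair in dataset.pairs:
        slots = []
        if roles in ("initial", "both"):
            slots.append((pair.initial, pair.initial_lesions))
        if roles in ("followup", "both"):
            slots.append((pair.followup, pair.followup_lesions))
        for exam, lesions in slots:
            out[exam.exam_id] = match_exam(
                lesions, dataset.detections_for(exam.exam_id), config
            )
    return out


def fom_ci(
    dataset: Dataset,
    n_boot: int = 2000,
    seed: int | None = None,
    config: MatchConfig = MatchConfig(),
    roles: str = "both",
    method: str = "bootstrap",
) -> FomResult:
    """FOM with a 95% interval by patient-level resampling.

    method="bootstrap" (default): percentile bootstrap over patients.
    method="jackknife": leave-one-patient-out t interval centred on the
    full-sample FOM.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if len(dataset.pairs) < 2:
        raise ValueError("confidence interval requires at least 2 patients")
    matches = match_dataset(dataset, config, roles)

    def exam_matches(pair) -> list[MatchResult]:
        out = []
        if roles in ("initial", "both"):
            out.append(matches[pair.initial.exam_id])
        if roles in ("followup", "both"):
            out.append(matches[pair.followup.exam_id])
        return out

    per_patient = [exam_matches(p) for p in dataset.pairs]
    full = jafroc_fom([m for ms in per_patient for m in ms])
    n = len(per_patient)

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            pooled = [m for i in idx for m in per_patient[i]]
            if sum(m.n_lesions for m in pooled) == 0:
                continue
            stats.append(jafroc_fom(pooled))
        lo, hi = np.percentile(stats, [2.5, 97.5])
        lo, hi = min(float(lo), full), max(float(hi), full)
        return FomResult(full, lo, hi, n_boot, seed, "bootstrap")
    if method == "jackknife":
        from scipy import stats as sps

        loo = []
        for i in range(n):
            pooled = [m for j, ms in enumerate(per_patient) if j != i for m in ms]
            loo.append(jafroc_fom(pooled))
        pseudo = n * full - (n - 1) * np.asarray(loo)
        se = float(pseudo.std(ddof=1) / np.sqrt(n))
        tcrit = float(sps.t.ppf(0.975, n - 1))
        lo = min(full - tcrit * se, full)
        hi = max(full + tcrit * se, full)
        return FomResult(full, lo, hi, 0, seed, "jackknife")
    raise ValueError(f"unknown method {method!r}")
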