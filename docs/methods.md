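# Methods

`cadrepro` evaluates how reproducibly a lesion-detection system (a CAD model
or a human reader) marks the same lesions on two chest exams of the same
patient taken within a short interval with no disease change. This note
records the statistical model, the estimators, the numerical conventions,
and the design choices made where the method left room.

## Data model

Every patient contributes an *initial* and a *follow-up* exam. Ground truth
is a set of axis-aligned lesion boxes per exam; the same `lesion_id` appears
in both exams of a pair, making lesion correspondence explicit input rather
than something inferred by the scorer. Detector output is a set of boxes
with confidence scores; only the score ordering is ever used, so scores need
not be calibrated. Coordinates are continuous pixels, origin top-left,
boxes half-open `[x_min, x_max) × [y_min, y_max)`.

## Hit criterion and matching

A detection is a candidate hit for a lesion when their intersection-over-
union strictly exceeds 0.5 (`MatchConfig(strict=False)` admits equality).
Assignment is one-to-one and greedy: detections are visited in descending
confidence and each claims the unclaimed lesion of highest IoU above
threshold. Confidence ties break by higher best IoU, then input order, so
reruns are deterministic. With disjoint ground-truth lesions — the realistic
regime, and the one the simulator produces — a detection can exceed IoU 0.5
with at most one lesion, and greedy assignment provably attains the
maximum-cardinality matching; with heavily overlapping lesions greedy can in
principle drop a hit relative to the optimum, which is why the oracle
equivalence test constrains lesions to disjoint placements.

## FROC and operating points

The FROC curve sweeps the confidence threshold over every distinct observed
score and plots lesion sensitivity against the average number of false
positives per image. An operating point for an average-FP budget `f` is the
smallest threshold whose avg-FP stays ≤ `f` (maximal sensitivity within the
budget); an infeasible budget returns a threshold above the top score,
silencing the detector. Reproducibility is assessed at five budgets,
0.1–0.5 FPs per image.

Threshold selection uses the FROC pooled over both exams of every pair by
default (`froc_roles="initial"` restricts it). The pooled choice is made
because the threshold is subsequently applied to both exams: selecting on
initial exams alone places the lowest operating point exactly at the lowest
initial hit score, and with continuous scores roughly half of all runs then
cut the lowest follow-up hit, so even a detector that finds every lesion
fails to show perfect agreement — an artifact of the selection set, not of
the detector.

## Figure of merit

The localization summary is the JAFROC1-style figure of merit

    FOM = (1 / (N_I · N_L)) Σ_i Σ_l ψ(maxFP_i, r_l)

where `r_l` is lesion `l`'s hit confidence (−∞ if missed), `maxFP_i` is
image `i`'s highest false-positive confidence (−∞ if none), and ψ scores 1
when the lesion outranks the FP, ½ on a finite tie or when both are absent,
0 otherwise. The variant that takes the highest FP from *every* image is
used because the intended datasets contain no normal images to restrict to.
FOM lies in [0, 1], equals ½ for a silent detector, 1 for a perfect one, and
is invariant under strictly increasing transforms of the scores.

The 95% interval is a percentile bootstrap over patients (default 2000
resamples, seeded); resamples with zero lesions are discarded. A
leave-one-patient-out jackknife is available (`method="jackknife"`), giving
a t interval centred on the full-sample FOM. The percentile bootstrap is the
default because it respects the [0, 1] range without truncation.

## Paired agreement

At each operating threshold, every lesion falls in one of four cells:
detected in both exams (a), initial only (b), follow-up only (c), neither
(d). Agreement is

    PPA  = 100·2a/(2a+b+c)      CPPA = 100·a/(a+b+c)

d never enters either statistic: the cohort is all-diseased by design, so
agreement on absence is not the quantity of interest. Counting is per
lesion (a patient with two lesions contributes two outcomes); a per-exam
reading would discard the multiplicity recorded in the data. For any single
confusion the identity `CPPA = 100·PPA/(200−PPA)` holds exactly, and
`PPA − CPPA = 100·a(b+c)/((2a+b+c)(a+b+c)) ≥ 0`; the identity does *not*
survive averaging across thresholds, so mean PPA and mean CPPA are reported
separately. The ± spread over the five operating points is the population
standard deviation (divide by n) — a descriptive spread over exactly five
numbers, recorded as `std_convention` in report metadata.

## Synthetic cohort

The simulator emulates a paired validation cohort: 121 patients, lesion
count 1 + Bernoulli(13/121) (so about one patient in nine carries a second
lesion), square 1024 px images, lesion box sides 32–160 px placed without
overlap. Per lesion, detection in the two exams follows a shared-draw
mixture: with probability ρ one Bernoulli(s) draw decides both exams,
otherwise the exams draw independently at rate s. This mechanism was chosen
over a Gaussian copula because it gives closed forms,

    E[PPA] = 100(ρ + (1−ρ)s),    E[CPPA] = 100·E[PPA]/(200−E[PPA]),

against which the whole pipeline is checked (parameter recovery within
3 Monte-Carlo standard errors on a 3×3 grid of s and ρ at 5000 pairs, the
delta-method SE computed from the multinomial cell probabilities).

Defaults: s = 0.8 (detector sensitivities cluster near 0.8 at the usual
operating band), ρ = 0.8 (E[PPA] = 96, the middle of the plausible range
for a competent detector), Poisson false positives at rate λ = 1 per image
(so the FROC spans the 0.1–0.5 budget band with room to spare),
true-positive confidences Beta(6, 2), false-positive confidences Beta(2, 6).
Detected-lesion boxes are jittered copies of the ground truth with per-axis
shift capped at 12% of the side and scale within ±5%, which keeps IoU ≥ ~0.6
— every emitted true detection is re-identified by the matcher, so measured
a/b/c equal the latent events exactly (tested). False-positive boxes are
placed disjoint from all lesions, so they can never be mistaken for hits.

What the simulator does not model: anatomy or lesion texture, confidence
correlation between exams given detection, registration error beyond small
box jitter, reader-style satisfaction-of-search effects. Passing tests
therefore demonstrate that the *evaluation machinery* is correct and
unbiased under a controlled detection process, not that any particular
detector is reproducible on real radiographs.

## Toy image pipeline

For an end-to-end exercise from pixels, lesions are rendered as Gaussian
blobs (σ = side/4, amplitude 0.55 over a 0.25 background) with additive
Gaussian noise (σ = 0.04 initial, 0.06 follow-up — the follow-up is the
degraded acquisition). The toy detector is scale-normalised
Laplacian-of-Gaussian blob detection (`skimage.feature.blob_log`, σ from 4
to 48 over 12 scales, response floor 0.08); boxes are recovered by inverting
the σ↔side convention and confidences are the mean image excess over the
median inside the box, clipped to [0, 1]. The smoke study uses 20 pairs of
256 px images with 28–64 px lesions — sizes chosen so the whole run,
repeated twice to verify byte-identical reports, completes in seconds.

## Numerical conventions and degenerate inputs

- PPA/CPPA with a = b = c = 0 raise `UndefinedAgreementError` rather than
  return a convention value.
- A FROC over zero lesions is an error (sensitivity undefined); a FROC over
  zero detections is an empty curve.
- An operating threshold is always one of the observed scores (or just above
  the maximum when the budget is infeasible); between observed scores the
  operating point is constant, so nothing is interpolated.
- All randomness flows through `numpy.random.default_rng(seed)`; a dataset,
  a report and the rendered images are bit-reproducible from the seed.
- Reports serialise with sorted keys and full float precision; the printed
  table rounds to two decimals.

## Known limitations

- Greedy matching is the contract even where an optimal assignment would
  differ (overlapping lesions with shared candidate detections).
- The bootstrap FOM interval ignores the five-threshold selection step; it
  quantifies patient sampling only.
- Per-lesion counting treats lesions within a patient as independent in the
  Monte-Carlo SE; the mild clustering from multi-lesion patients makes the
  3 SE band slightly conservative in the recovery tests.
- The simulator's follow-up degradation (jitter, extra rendering noise) is a
  placeholder severity, not an estimate from real repeat acquisitions.
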