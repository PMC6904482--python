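"""Toy image rendering and blob detection for end-to-end exercises.

Renders paired grayscale images with Gaussian-profile bright blobs at the
ground-truth lesion boxes over a noisy background; the follow-up image is
re-rendered with jittered positions and a different noise realisation,
mimicking a repeat acquisition under worse conditions. A multiscale
Laplacian-of-Gaussian blob detector turns such images back into scored
boxes, standing in for a full detection model so that the matching, FROC and
agreement machinery can be driven end to end from pixels.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from skimage.feature import blob_log

from .annotations import Box, Dataset, Detection, ExamPair
from .simulate import SimConfig, simulate_paired_detections

__all__ = [
    "render_exam_image",
    "render_pair_images",
    "toy_blob_detector",
    "simulate_image_dataset",
]

# rendered blob sigma as a fraction of the box side; the detector inverts this
_SIGMA_PER_SIDE = 0.25
_BLOB_AMPLITUDE = 0.55
_BACKGROUND = 0.25
_NOISE_SIGMA = 0.04


def render_exam_image(
    shape: tuple[int, int],
    boxes: list[Box],
    rng: np.random.Generator,
    noise_sigma: float = _NOISE_SIGMA,
    amplitude: float = _BLOB_AMPLITUDE,
) -> np.ndarray:
    """Noisy background plus one Gaussian-profile bright blob per box."""
    h, w = shape
    img = _BACKGROUND + rng.normal(0.0, noise_sigma, size=(h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for box in boxes:
        cx = (box.x_min + box.x_max) / 2
        cy = (box.y_min + box.y_max) / 2
        sx = _SIGMA_PER_SIDE * (box.x_max - box.x_min)
        sy = _SIGMA_PER_SIDE * (box.y_max - box.y_min)
        img += amplitude * np.exp(
            -((xx - cx) ** 2 / (2 * sx**2) + (yy - cy) ** 2 / (2 * sy**2))
        )
    return np.clip(img, 0.0, 1.0)


def render_pair_images(
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray, ExamPair]:
    """Render the initial/follow-up images of one simulated patient.

    Uses the simulator's geometry for a single pair; the follow-up image gets
    a fresh noise realisation and slightly stronger noise, emulating a repeat
    exam under degraded conditions.
    """
    one = replace(config, n_pairs=1)
    dataset, _ = simulate_paired_detections(one)
    pair = dataset.pairs[0]
    rng = np.random.default_rng(config.seed + 1_000_003)
    shape = (config.image_size, config.image_size)
    img_init = render_exam_image(
        shape, [l.box for l in pair.initial_lesions], rng
    )
    img_fu = render_exam_image(
        shape, [l.box for l in pair.followup_lesions], rng,
        noise_sigma=1.5 * _NOISE_SIGMA,
    )
    return img_init, img_fu, pair


def toy_blob_detector(
    image: np.ndarray,
    exam_id: str = "",
    min_sigma: float = 4.0,
    max_sigma: float = 48.0,
    num_sigma: int = 12,
    threshold: float = 0.08,
) -> list[Detection]:
    """Multiscale Laplacian-of-Gaussian blob detection with scored boxes.

    Local maxima of the scale-normalised LoG response above ``threshold``
    become detections; the box side is the blob scale divided by the
    rendering sigma-per-side factor, and the confidence is the mean image
    excess over the median inside the box, clipped to [0, 1]. Deterministic.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        return []
    h, w = image.shape
    blobs = blob_log(
        image,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=num_sigma,
        threshold=threshold,
    )
    background = float(np.median(image))
    detections: list[Detection] = []
    for cy, cx, sigma in blobs:
        half = sigma / (2 * _SIGMA_PER_SIDE)
        x0, x1 = max(cx - half, 0.0), min(cx + half, float(w))
        y0, y1 = max(cy - half, 0.0), min(cy + half, float(h))
        if x1 - x0 <= 1.0 or y1 - y0 <= 1.0:
            continue
        patch = image[int(y0):max(int(y1), int(y0) + 1),
                      int(x0):max(int(x1), int(x0) + 1)]
        conf = float(np.clip((patch.mean() - background) / _BLOB_AMPLITUDE, 0.0, 1.0))
        detections.append(Detection(exam_id, Box(x0, y0, x1, y1), conf))
    detections.sort(key=lambda d: (-d.confidence, d.box.x_min, d.box.y_min))
    return detections


def simulate_image_dataset(config: SimConfig) -> Dataset:
    """End-to-end synthetic study: render every pair, detect blobs, assemble.

    Ground truth comes from the simulator's geometry; detections come from
    the toy detector run on the rendered images, so detection events are no
    longer under direct statistical control — this exercises the full
    pixels-to-agreement path.
    """
    base, _ = simulate_paired_detections(config)
    shape = (config.image_size, config.image_size)
    detections: dict[str, list[Detection]] = {}
    for i, pair in enumerate(base.pairs):
        rng = np.random.default_rng(config.seed + 7_919 * (i + 1))
        img_init = render_exam_image(shape, [l.box for l in pair.initial_lesions], rng)
        img_fu = render_exam_image(
            shape, [l.box for l in pair.followup_lesions], rng,
            noise_sigma=1.5 * _NOISE_SIGMA,
        )
        detections[pair.initial.exam_id] = toy_blob_detector(
            img_init, pair.initial.exam_id
        )
        detections[pair.followup.exam_id] = toy_blob_detector(
            img_fu, pair.followup.exam_id
        )
    return Dataset(pairs=base.pairs, detections=detections)
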