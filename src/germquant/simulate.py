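"""Synthetic micrographs and embryo score tables with known ground truth.

Real inputs to this pipeline are confocal projections of oocytes/embryos
plus hand-traced masks, and manually scored per-embryo phenotype tables.
Neither is distributable at useful scale, so this module generates
controllable stand-ins:

* an elliptical "specimen" whose anchor channel carries an anteriorly
  peaked signal, ``baseline + A * exp(-x_hat / lambda)`` with ``x_hat`` the
  normalized AP coordinate (0 = anterior), plus additive Gaussian noise
  clipped at zero;
* a second channel linearly mixed against the noise-free anchor signal, so
  the true colocalization strength is set by a single mixing parameter
  ``alpha`` (alpha = 1 with zero noise makes the channels identical);
* cohorts of embryo scores with a chosen penetrance (probability of the
  anterior-pole-cell phenotype), attempt rate, and Poisson pole-cell
  counts (anterior counts truncated at >= 1 for positive embryos, so the
  category and the count are mutually consistent).

Every generator is a pure function of its parameter record, including the
seed; identical parameters give bit-identical outputs.  The geometry is a
deliberately plain axis-aligned ellipse: enough to exercise masking, column
aggregation and the anterior selection, with no optics or 3-D modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import OrientedSample

__all__ = [
    "ImageSimParams",
    "ScoreSimParams",
    "LabeledMicrograph",
    "generate_sample_image",
    "generate_score_table",
    "write_micrograph",
    "CATEGORIES",
]

CATEGORIES = ("negative", "attempt", "anterior_pole_cells")


@dataclass(frozen=True)
class ImageSimParams:
    """Parameters of one synthetic two-channel micrograph.

    ``amplitude`` (A) and ``baseline`` are in the same arbitrary intensity
    units as the noise; ``decay_length`` (lambda) is a fraction of the AP
    extent; ``mixing`` (alpha, in [0, 1]) sets how much of the noise-free
    anchor signal appears in channel 2.  Defaults emulate a mid-sized
    specimen occupying most of a small projected frame with signal-to-noise
    typical of antibody stains.
    """

    height: int = 96
    width: int = 160
    ellipse_axes: tuple[float, float] = (70.0, 40.0)  # semi-axes (a along x, b along y)
    amplitude: float = 2.0
    decay_length: float = 0.15
    baseline: float = 100.0
    noise_sd: float = 5.0
    mixing: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.ellipse_axes
        cx, cy = self.width / 2, self.height / 2
        if cx - a < 0 or cx + a > self.width or cy - b < 0 or cy + b > self.height:
            raise ValueError(
                f"ellipse with semi-axes {self.ellipse_axes} exceeds the "
                f"{self.height}x{self.width} frame"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if not 0 <= self.mixing <= 1:
            raise ValueError("mixing must be in [0, 1]")


@dataclass(frozen=True)
class ScoreSimParams:
    """Parameters of one synthetic embryo-score cohort.

    ``penetrance`` is the probability of the anterior-pole-cell phenotype,
    ``attempt_rate`` the probability of an incomplete "attempt"; the
    remainder are negative.  Anterior counts for positive embryos are
    Poisson(``count_mean_anterior``) truncated at >= 1; posterior counts
    are Poisson(``count_mean_posterior``) for every embryo.
    """

    n_embryos: int = 100
    penetrance: float = 0.15
    attempt_rate: float = 0.05
    count_mean_anterior: float = 20.5
    count_mean_posterior: float = 24.3
    genotype: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.penetrance <= 1 or not 0 <= self.attempt_rate <= 1:
            raise ValueError("penetrance and attempt_rate must be probabilities")
        if self.penetrance + self.attempt_rate > 1:
            raise ValueError("penetrance + attempt_rate must be <= 1")
        if self.count_mean_anterior < 0 or self.count_mean_posterior < 0:
            raise ValueError("count means must be >= 0")
        if self.n_embryos < 0:
            raise ValueError("n_embryos must be >= 0")


@dataclass
class LabeledMicrograph:
    """A synthetic sample plus the ground truth that produced it."""

    sample: OrientedSample
    ground_truth: dict = field(default_factory=dict)


def _ellipse_mask(params: ImageSimParams) -> np.ndarray:
    a, b = params.ellipse_axes
    cy, cx = params.height / 2, params.width / 2
    yy, xx = np.mgrid[0 : params.height, 0 : params.width]
    return ((xx + 0.5 - cx) / a) ** 2 + ((yy + 0.5 - cy) / b) ** 2 <= 1.0


def generate_sample_image(
    params: ImageSimParams, sample_id: str = "sim"
) -> LabeledMicrograph:
    """Generate one two-channel elliptical specimen with anterior signal.

    Channel 0 ("HA", the anchor): ``baseline + A*exp(-x_hat/lambda)`` plus
    N(0, noise_sd^2) inside the mask.  Channel 1 ("target"):
    ``baseline + alpha * signal + (1-alpha) * independent noise``.  Pixels
    outside the mask are 0.  Anterior is at the left; negative intensities
    are clipped to 0.
    """
    rng = np.random.default_rng(params.seed)
    mask = _ellipse_mask(params)
    ys, xs = np.nonzero(mask)
    x_min, x_max = xs.min(), xs.max()
    x_hat = (xs - x_min) / (x_max - x_min)
    signal = params.amplitude * np.exp(-x_hat / params.decay_length)

    noise1 = rng.normal(0.0, params.noise_sd, size=len(xs)) if params.noise_sd > 0 else 0.0
    noise2 = rng.normal(0.0, params.noise_sd, size=len(xs)) if params.noise_sd > 0 else 0.0
    ch1_vals = params.baseline + signal + noise1
    ch2_vals = params.baseline + params.mixing * signal + (1 - params.mixing) * noise2

    image = np.zeros((2, params.height, params.width))
    image[0][ys, xs] = np.clip(ch1_vals, 0, None)
    image[1][ys, xs] = np.clip(ch2_vals, 0, None)

    sample = OrientedSample(
        image=image,
        mask=mask,
        channel_names=("HA", "target"),
        sample_id=sample_id,
        orientation_applied=True,  # generated directly in the AP frame
    )
    truth = {
        "amplitude": params.amplitude,
        "decay_length": params.decay_length,
        "mixing": params.mixing,
        "baseline": params.baseline,
        "noise_sd": params.noise_sd,
        "seed": params.seed,
        "anterior": "left",
    }
    return LabeledMicrograph(sample=sample, ground_truth=truth)


def _truncated_poisson_ge1(rng: np.random.Generator, mean: float, n: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1, by inverse CDF on U(P(0), 1)."""
    from scipy import stats

    if n == 0:
        return np.zeros(0, dtype=int)
    if mean == 0:
        return np.ones(n, dtype=int)  # degenerate: smallest admissible count
    p0 = float(np.exp(-mean))
    u = rng.uniform(p0, 1.0, size=n)
    return stats.poisson.ppf(u, mean).astype(int)


def generate_score_table(params: ScoreSimParams) -> pd.DataFrame:
    """Generate a per-embryo phenotype score table.

    Columns: ``embryo_id, genotype, category, n_anterior, n_posterior``.
    Each embryo draws exactly one category; ``n_embryos = 0`` yields an
    empty (but well-formed) table.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_embryos
    probs = np.array(
        [1 - params.penetrance - params.attempt_rate, params.attempt_rate, params.penetrance]
    )
    cat_idx = rng.choice(3, size=n, p=probs)
    categories = np.array(CATEGORIES)[cat_idx]
    n_anterior = np.zeros(n, dtype=int)
    pos = cat_idx == 2
    n_anterior[pos] = _truncated_poisson_ge1(rng, params.count_mean_anterior, int(pos.sum()))
    n_posterior = rng.poisson(params.count_mean_posterior, size=n)
    return pd.DataFrame(
        {
            "embryo_id": [f"{params.genotype}_{i:04d}" for i in range(n)],
            "genotype": params.genotype,
            "category": categories,
            "n_anterior": n_anterior,
            "n_posterior": n_posterior,
        }
    )


def write_micrograph(mic: LabeledMicrograph, directory: str | Path, stem: str) -> dict:
    """Write a synthetic sample as TIFF + mask TIFF + ground-truth JSON.

    Returns the manifest row (paths, identity, orientation) for the sample.
    """
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{stem}.tif"
    mask_path = directory / f"{stem}_mask.tif"
    truth_path = directory / f"{stem}_truth.json"
    tifffile.imwrite(img_path, mic.sample.image.astype(np.float32))
    tifffile.imwrite(mask_path, (mic.sample.mask.astype(np.uint8) * 255))
    truth_path.write_text(json.dumps(mic.ground_truth, indent=2, sort_keys=True))
    return {
        "sample_id": mic.sample.sample_id,
        "image_path": str(img_path),
        "mask_path": str(mask_path),
        "rotation_deg": 0.0,
        "flip_lr": False,
    }
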