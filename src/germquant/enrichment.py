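"""Per-pixel z-scores, anterior integrated enrichment, and AP-axis profiles.

The central statistic standardizes every pixel inside the specimen mask
against the whole-mask mean and standard deviation,

    z_i = (I_i - mu) / sigma,

with mu and sigma computed over all mask pixels (population convention,
divide by N).  "Anterior integrated enrichment" is the sum of z over the
anterior-most fraction of the mask (default 15%): positive when anterior
signal exceeds the specimen average, zero in expectation under a flat
signal, and exactly zero when summed over the whole mask.

Profiles reduce the 2-D z-field to one value per mask column (mean over the
mask pixels of that column), map column positions linearly onto the
normalized AP axis [0, 1] (0 = anterior), and resample to a standard
300-point grid so specimens of different sizes can be averaged pointwise.
Group aggregation reports the pointwise mean with a 95% confidence band
(mean +/- 1.96 * SEM, sample SD with n-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prep import OrientedSample, PixelSet

__all__ = [
    "ZScoreField",
    "EnrichmentResult",
    "APProfile",
    "ProfileEnsemble",
    "zscore_field",
    "anterior_integrated_enrichment",
    "ap_profile",
    "aggregate_profiles",
]

DEFAULT_N_POINTS = 300
CI_FACTOR = 1.96  # 95% normal interval on the mean


@dataclass
class ZScoreField:
    """Standardized intensities for one channel over a specimen mask.

    ``z`` is a full-frame float array, NaN outside the mask.  ``mask_mean``
    and ``mask_sd`` are the whole-mask statistics (population SD).  By
    construction the z-values over the mask sum to zero.
    """

    z: np.ndarray
    mask: np.ndarray
    mask_mean: float
    mask_sd: float
    channel: str = ""

    def values(self) -> np.ndarray:
        """Z-scores of mask pixels, in row-major mask order."""
        return self.z[self.mask]

    def at(self, pixels: PixelSet) -> np.ndarray:
        ys, xs = pixels.index_arrays()
        return self.z[ys, xs]


@dataclass(frozen=True)
class EnrichmentResult:
    """Sum of z-scores over an anterior pixel set."""

    value: float
    n_pixels: int
    fraction: float
    mode: str
    sample_id: str = ""
    channel: str = ""


@dataclass
class APProfile:
    """Z-score profile on the normalized AP axis (0 = anterior)."""

    positions: np.ndarray
    values: np.ndarray
    sample_id: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values length mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.positions)


@dataclass
class ProfileEnsemble:
    """Pointwise mean profile across samples with a 95% confidence band."""

    positions: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_samples: int
    channel: str = ""


def zscore_field(sample: OrientedSample, channel: str | int) -> ZScoreField:
    """Standardize one channel against its whole-mask mean and SD.

    Raises ``ValueError`` for masks of fewer than 2 pixels or a constant
    channel (sigma = 0), for which the statistic is undefined.
    """
    img = sample.channel(channel)
    vals = img[sample.mask]
    if vals.size < 2:
        raise ValueError("mask must contain at least 2 pixels")
    mu = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd == 0:
        raise ValueError("channel is constant over the mask; z-score undefined")
    z = np.full(img.shape, np.nan)
    z[sample.mask] = (vals - mu) / sd
    name = channel if isinstance(channel, str) else sample.channel_names[channel]
    return ZScoreField(z=z, mask=sample.mask, mask_mean=mu, mask_sd=sd, channel=name)


def anterior_integrated_enrichment(
    zfield: ZScoreField,
    region: PixelSet,
    fraction: float = 0.15,
    mode: str = "pixels",
    sample_id: str = "",
) -> EnrichmentResult:
    """Sum the z-scores over an anterior pixel set.

    ``fraction`` and ``mode`` are carried through for bookkeeping; the
    region itself determines the value.  Raises on an empty region or a
    region reaching outside the mask.
    """
    if len(region) == 0:
        raise ValueError("region is empty")
    ys, xs = region.index_arrays()
    if not zfield.mask[ys, xs].all():
        raise ValueError("region contains pixels outside the mask")
    return EnrichmentResult(
        value=float(zfield.z[ys, xs].sum()),
        n_pixels=len(region),
        fraction=fraction,
        mode=mode,
        sample_id=sample_id,
        channel=zfield.channel,
    )


def ap_profile(
    zfield: ZScoreField,
    sample: OrientedSample,
    n_points: int = DEFAULT_N_POINTS,
) -> APProfile:
    """Column-wise z-score profile resampled to a standard AP grid.

    Each mask column contributes the mean z over its mask pixels; columns
    between the anterior and posterior boundaries that contain no mask
    pixels are bridged linearly from their populated neighbours.  Column
    centres map linearly from ``[x_min, x_max]`` to ``[0, 1]`` and values
    are linearly interpolated at ``n_points`` equally spaced positions
    (interpolation only — the standard positions never leave the data span).
    """
    x_min, x_max = sample.ap_bounds
    if x_max == x_min:
        raise ValueError("mask spans a single column; AP profile undefined")
    counts = sample.mask[:, x_min : x_max + 1].sum(axis=0)
    sums = np.nansum(
        np.where(sample.mask, zfield.z, 0.0)[:, x_min : x_max + 1], axis=0
    )
    populated = counts > 0
    col_pos = (np.arange(x_min, x_max + 1) - x_min) / (x_max - x_min)
    col_vals = np.empty_like(col_pos)
    col_vals[populated] = sums[populated] / counts[populated]
    if not populated.all():
        # bridge empty interior columns from populated neighbours
        col_vals[~populated] = np.interp(
            col_pos[~populated], col_pos[populated], col_vals[populated]
        )
    std_pos = np.linspace(0.0, 1.0, n_points)
    return APProfile(
        positions=std_pos,
        values=np.interp(std_pos, col_pos, col_vals),
        sample_id=sample.sample_id,
        channel=zfield.channel,
    )


def aggregate_profiles(profiles: list[APProfile]) -> ProfileEnsemble:
    """Pointwise mean and 95% CI (mean +/- 1.96*SEM) across profiles.

    SEM uses the sample SD (n-1); a single profile yields a zero-width
    band.  All profiles must share the same number of points.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    n_points = profiles[0].n_points
    if any(p.n_points != n_points for p in profiles):
        raise ValueError("profiles have mixed n_points")
    mat = np.vstack([p.values for p in profiles])
    mean = mat.mean(axis=0)
    n = len(profiles)
    if n > 1:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros(n_points)
    channels = {p.channel for p in profiles}
    return ProfileEnsemble(
        positions=profiles[0].positions.copy(),
        mean=mean,
        ci_low=mean - CI_FACTOR * sem,
        ci_high=mean + CI_FACTOR * sem,
        n_samples=n,
        channel=channels.pop() if len(channels) == 1 else "mixed",
    )
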