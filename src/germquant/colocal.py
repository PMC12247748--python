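"""Anchor-thresholded colocalization within the anterior region.

The question this answers: where the anchor channel (the HA-tagged protein)
is brightest at the anterior, does a target channel (Vasa protein, *nanos*
or *pgc* mRNA) co-vary with it?  The procedure:

1. within the anterior region, select high-anchor pixels — either those
   strictly above mean + 2 SD of the anchor intensity over the region
   (default), or the top 17.5% by rank;
2. Gaussian-filter the channels (the selection mask is built on the raw
   anchor first);
3. compute the Pearson correlation of the two filtered channels over the
   selected pixels, provided at least ``min_pixels`` (default 2) were
   selected and neither vector is constant.  Otherwise the result is
   *undefined* — flagged, not an error — and group summaries exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .prep import OrientedSample, PixelSet, _round_half_up

__all__ = [
    "ColocSettings",
    "ColocResult",
    "ha_high_mask",
    "gaussian_filter_channel",
    "colocalization",
]


@dataclass(frozen=True)
class ColocSettings:
    """Selection and filtering knobs for the colocalization measure.

    ``threshold_mode`` is ``"mean_plus_2sd"`` (intensity threshold over the
    region) or ``"top_fraction"`` (rank selection, ``top_fraction`` of the
    region's pixels, default 17.5%).  ``gaussian_sigma`` is in pixels;
    sigma = 0 disables filtering.
    """

    threshold_mode: str = "mean_plus_2sd"
    top_fraction: float = 0.175
    gaussian_sigma: float = 1.0
    min_pixels: int = 2

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("mean_plus_2sd", "top_fraction"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.min_pixels < 2:
            raise ValueError("min_pixels must be >= 2")


@dataclass(frozen=True)
class ColocResult:
    """Pearson r over the selected high-anchor pixels, or undefined.

    ``defined`` is False when fewer than ``min_pixels`` pixels were
    selected or either channel was constant on the set; ``r`` is then NaN.
    """

    r: float
    n_pixels: int
    defined: bool
    channel_pair: tuple[str, str]
    sample_id: str = ""


def ha_high_mask(
    sample: OrientedSample,
    region: PixelSet,
    settings: ColocSettings = ColocSettings(),
    anchor_channel: str | int = 0,
) -> PixelSet:
    """Select the high-anchor pixels of a region.

    ``mean_plus_2sd``: threshold = mean + 2 SD of the anchor intensity over
    the region (population SD); pixels strictly above are kept — an
    all-equal region therefore yields an empty set.  ``top_fraction``: the
    ``round(f * |region|)`` brightest pixels, ties broken by descending
    value then ascending (y, x).  May return an empty set; downstream
    treats that as an undefined result.
    """
    if len(region) == 0:
        raise ValueError("region is empty")
    anchor = sample.channel(anchor_channel)
    ys, xs = region.index_arrays()
    vals = anchor[ys, xs]
    if settings.threshold_mode == "mean_plus_2sd":
        threshold = vals.mean() + 2 * vals.std(ddof=0)
        keep = vals > threshold
        coords = np.column_stack([ys[keep], xs[keep]])
    else:
        k = _round_half_up(settings.top_fraction * len(region))
        order = np.lexsort((xs, ys, -vals))  # value desc, then (y, x) asc
        sel = order[:k]
        coords = np.column_stack([ys[sel], xs[sel]])
    return PixelSet(coordinates=coords, provenance=f"anchor-high-{settings.threshold_mode}")


def gaussian_filter_channel(
    sample: OrientedSample, channel: str | int, sigma: float
) -> np.ndarray:
    """Mask-aware 2-D Gaussian filter of one channel; sigma=0 is identity.

    Smoothing is by normalized convolution, ``G(I * M) / G(M)`` inside the
    mask (reflect boundary), so the zero-filled exterior of the specimen
    never bleeds into boundary pixels — a plain convolution would darken
    every pixel near the outline and impose a strong spurious correlation
    between any two channels there.  On a full-frame mask this reduces
    exactly to the ordinary Gaussian convolution.  Pixels outside the mask
    are returned as 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = sample.channel(channel)
    if sigma == 0:
        return img.copy()
    m = sample.mask.astype(np.float64)
    num = ndimage.gaussian_filter(img * m, sigma=sigma, mode="reflect")
    den = ndimage.gaussian_filter(m, sigma=sigma, mode="reflect")
    out = np.zeros_like(img, dtype=np.float64)
    inside = sample.mask
    out[inside] = num[inside] / den[inside]
    return out


def colocalization(
    sample: OrientedSample,
    anchor_channel: str | int,
    target_channel: str | int,
    region: PixelSet,
    settings: ColocSettings = ColocSettings(),
) -> ColocResult:
    """Pearson correlation of anchor vs target on high-anchor anterior pixels.

    The selection mask is built on the unfiltered anchor channel; both
    channels are then Gaussian-filtered before the paired values are
    gathered.  Undersized or constant selections give ``defined=False``
    with ``r = NaN`` rather than raising.
    """
    sample.channel(anchor_channel), sample.channel(target_channel)  # validate labels
    selected = ha_high_mask(sample, region, settings, anchor_channel=anchor_channel)
    name = lambda c: c if isinstance(c, str) else sample.channel_names[int(c)]
    pair = (name(anchor_channel), name(target_channel))
    if len(selected) < settings.min_pixels:
        return ColocResult(
            r=float("nan"), n_pixels=len(selected), defined=False,
            channel_pair=pair, sample_id=sample.sample_id,
        )
    fa = gaussian_filter_channel(sample, anchor_channel, settings.gaussian_sigma)
    ft = gaussian_filter_channel(sample, target_channel, settings.gaussian_sigma)
    ys, xs = selected.index_arrays()
    a, t = fa[ys, xs], ft[ys, xs]
    if a.std() == 0 or t.std() == 0:
        return ColocResult(
            r=float("nan"), n_pixels=len(selected), defined=False,
            channel_pair=pair, sample_id=sample.sample_id,
        )
    if np.array_equal(a, t):
        r = 1.0  # identical vectors: avoid 1-ulp rounding in corrcoef
    else:
        r = float(np.corrcoef(a, t)[0, 1])
    return ColocResult(
        r=r, n_pixels=len(selected), defined=True,
        channel_pair=pair, sample_id=sample.sample_id,
    )
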