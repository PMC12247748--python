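"""Image preprocessing: projection, AP orientation, and anterior-region selection.

The quantification unit is an :class:`OrientedSample` — a 2-D multichannel
projection with a binary specimen mask, rotated so the anteroposterior (AP)
axis is horizontal with the posterior at the right (larger ``x``).  Specimen
outlines are traced upstream and supplied as mask files; this module never
segments.

Coordinate convention: 0-based ``(row y, column x)``.  ``x`` increases toward
the posterior once a sample is oriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MicrographStack",
    "OrientedSample",
    "PixelSet",
    "sum_project",
    "orient_sample",
    "anterior_region",
]


def _round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (never banker's)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class MicrographStack:
    """A confocal z-stack: intensities indexed ``(z, channel, y, x)``.

    Intensities must be non-negative with at least one z-plane and one
    channel; ``channel_names`` labels axis 1 (e.g. ``["HA", "Vasa"]``).
    """

    voxels: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 4:
            raise ValueError(f"voxels must be 4-D (z, channel, y, x), got ndim={v.ndim}")
        if v.shape[0] < 1:
            raise ValueError("stack needs at least one z-plane")
        if v.shape[1] < 1:
            raise ValueError("stack needs at least one channel")
        if len(self.channel_names) != v.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {v.shape[1]} channels"
            )
        if np.any(v < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))


@dataclass
class OrientedSample:
    """A masked, AP-oriented 2-D multichannel image.

    ``image`` is ``(channel, y, x)``; ``mask`` is boolean ``(y, x)`` and must
    be nonempty.  ``ap_bounds`` is the inclusive ``(x_min, x_max)`` column
    span of the mask, i.e. the anterior and posterior specimen boundaries.
    """

    image: np.ndarray
    mask: np.ndarray
    channel_names: tuple[str, ...]
    sample_id: str = ""
    orientation_applied: bool = False
    ap_bounds: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.ndim != 3:
            raise ValueError("image must be (channel, y, x)")
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError(
                f"image spatial shape {self.image.shape[1:]} != mask shape {self.mask.shape}"
            )
        if len(self.channel_names) != self.image.shape[0]:
            raise ValueError("one channel name per image channel required")
        self.channel_names = tuple(self.channel_names)
        if not self.mask.any():
            raise ValueError("mask is empty")
        xs = np.where(self.mask.any(axis=0))[0]
        self.ap_bounds = (int(xs[0]), int(xs[-1]))

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a 2-D array, by name or index."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"unknown channel {name_or_index!r}; have {self.channel_names}"
                ) from None
        else:
            idx = int(name_or_index)
            if not 0 <= idx < self.image.shape[0]:
                raise KeyError(f"channel index {idx} out of range")
        return self.image[idx]

    @property
    def n_mask_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PixelSet:
    """An ordered, duplicate-free set of ``(y, x)`` mask coordinates.

    ``provenance`` records how the set was built (``"anterior-15%"``,
    ``"HA-high"``, ...).  Coordinates are stored as an ``(n, 2)`` int array.
    """

    coordinates: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=np.intp).reshape(-1, 2)
        if len(c) and len(np.unique(c, axis=0)) != len(c):
            raise ValueError("duplicate coordinates in PixelSet")
        object.__setattr__(self, "coordinates", c)

    def __len__(self) -> int:
        return len(self.coordinates)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """``(ys, xs)`` suitable for fancy indexing into a 2-D image."""
        return self.coordinates[:, 0], self.coordinates[:, 1]


def sum_project(stack: MicrographStack) -> np.ndarray:
    """Sum-intensity projection over z, per channel.

    Returns a ``(channel, y, x)`` array.  The accumulator dtype is widened
    (int64 for integer stacks, float64 otherwise) so deep stacks of 16-bit
    planes cannot overflow.
    """
    v = stack.voxels
    acc_dtype = np.int64 if np.issubdtype(v.dtype, np.integer) else np.float64
    return v.sum(axis=0, dtype=acc_dtype)


def orient_sample(
    image: np.ndarray,
    mask: np.ndarray,
    rotation_deg: float = 0.0,
    flip_lr: bool = False,
    channel_names: tuple[str, ...] | None = None,
    sample_id: str = "",
) -> OrientedSample:
    """Rotate and optionally mirror a projected image + mask onto the AP frame.

    ``rotation_deg`` is applied counter-clockwise in array coordinates with
    the frame enlarged to hold the rotated footprint; the image is
    interpolated bilinearly, the mask nearest-neighbour so it stays binary.
    ``flip_lr`` mirrors left-right afterwards (used when the posterior ended
    up on the left).  Raises ``ValueError`` if the mask is empty after the
    transform.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[None]
    mask = np.asarray(mask, dtype=bool)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(image.shape[0]))

    if rotation_deg % 360 != 0:
        rot_img = ndimage.rotate(
            image, rotation_deg, axes=(2, 1), order=1, reshape=True, mode="constant"
        )
        rot_mask = ndimage.rotate(
            mask.astype(np.uint8), rotation_deg, axes=(1, 0), order=0,
            reshape=True, mode="constant",
        ).astype(bool)
    else:
        rot_img, rot_mask = image.copy(), mask.copy()

    if flip_lr:
        rot_img = rot_img[:, :, ::-1]
        rot_mask = rot_mask[:, ::-1]

    if not rot_mask.any():
        raise ValueError("mask is empty after orientation transform")
    return OrientedSample(
        image=rot_img,
        mask=rot_mask,
        channel_names=channel_names,
        sample_id=sample_id,
        orientation_applied=True,
    )


def anterior_region(
    sample: OrientedSample, fraction: float = 0.15, mode: str = "pixels"
) -> PixelSet:
    """Select the anterior-most portion of the specimen mask.

    mode="pixels"
        The ``round(fraction * N)`` mask pixels of smallest ``x`` (round
        half-up), ties at equal ``x`` broken by ascending ``y`` — a rank
        selection on pixel count.
    mode="length"
        Every mask pixel with ``x < x_min + fraction * (x_max - x_min)`` — a
        fraction of the AP length.  ``fraction = 1`` returns the whole mask
        in both modes.

    Both readings of "anterior-most 15%" occur in practice; pixels is the
    default.  Raises ``ValueError`` if the selection is empty.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    ys, xs = np.nonzero(sample.mask)
    if mode == "pixels":
        n_take = _round_half_up(fraction * len(ys))
        order = np.lexsort((ys, xs))  # primary x asc, secondary y asc
        sel = order[:n_take]
        coords = np.column_stack([ys[sel], xs[sel]])
        label = f"anterior-{fraction:g}-pixels"
    elif mode == "length":
        x_min, x_max = sample.ap_bounds
        if fraction >= 1:
            keep = np.ones_like(xs, dtype=bool)
        else:
            keep = xs < x_min + fraction * (x_max - x_min)
        coords = np.column_stack([ys[keep], xs[keep]])
        label = f"anterior-{fraction:g}-length"
    else:
        raise ValueError(f"mode must be 'pixels' or 'length', got {mode!r}")
    if len(coords) == 0:
        raise ValueError("anterior selection is empty")
    return PixelSet(coordinates=coords, provenance=label)
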