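"""Intensity discretization of in-VOI SUV values to integer gray levels.

Two schemes are compared throughout the analysis:

* **absolute** resampling ("fixed bin size" in IBSI terms): a single global
  map from SUV to levels 1..G over fixed bounds, by default 64 bins over
  [0, 60] SUV (bin width 60/64 = 0.9375 SUV).  Two VOIs with the same SUV
  values always receive identical levels, whatever their own min/max.
* **relative** resampling ("fixed bin number"): the same binning formula with
  the bounds taken as the in-VOI min and max, so the bin width varies from
  lesion to lesion and the levels always span the full 1..G range.

Bins are half-open ``[edge, edge + w)`` with the top bin closed, so every
value maps to exactly one level and the maximum maps to level G.  Values
outside the absolute bounds clamp to the boundary levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EmptyVOIError, SUVImage, VOIMask, check_aligned

ABSOLUTE = "absolute"
RELATIVE = "relative"


@dataclass(frozen=True)
class DiscretizationSetting:
    """How SUV values are mapped to gray levels.

    The default is the absolute scheme with 64 levels over 0-60 SUV (AR60);
    ``DiscretizationSetting(mode="relative")`` gives the per-VOI min-max
    scheme (RR).
    """

    mode: str = ABSOLUTE
    n_bins: int = 64
    bounds: tuple[float, float] = (0.0, 60.0)

    def __post_init__(self):
        if self.mode not in (ABSOLUTE, RELATIVE):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.mode == ABSOLUTE and not self.bounds[1] > self.bounds[0]:
            raise ValueError("absolute bounds must satisfy high > low")

    @property
    def name(self) -> str:
        if self.mode == ABSOLUTE:
            return f"AR{self.bounds[1]:g}"
        return "RR"


@dataclass
class DiscretizedVOI:
    """Gray levels 1..n_bins for the in-mask voxels of one VOI.

    ``levels`` is a dense integer array over the mask's grid with 0 outside
    the mask; ``coords`` are the in-mask voxel indices.  ``bin_width`` is in
    SUV units; for a constant VOI under relative resampling it is 0 and all
    voxels sit at level 1 (flagged by :attr:`single_level`).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    setting: DiscretizationSetting
    bin_width: float
    spacing: tuple[float, float, float]

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def coords(self) -> np.ndarray:
        return np.argwhere(self.mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def n_levels_occupied(self) -> int:
        return int(np.unique(self.in_mask_levels).size)

    @property
    def single_level(self) -> bool:
        return self.n_levels_occupied <= 1


def discretize(
    image: SUVImage, mask: VOIMask, setting: DiscretizationSetting
) -> DiscretizedVOI:
    """Assign integer gray levels 1..n_bins to the in-mask voxels.

    ``level = floor((SUV - low) / w) + 1`` with ``w = (high - low)/n_bins``,
    values clamped to ``[low, high)`` and the top edge mapped to ``n_bins``.
    """
    check_aligned(image, mask)
    if mask.voxel_count() == 0:
        raise EmptyVOIError("cannot discretize an empty VOI")
    vals = image.values[mask.values]
    if setting.mode == ABSOLUTE:
        low, high = setting.bounds
    else:
        low, high = float(vals.min()), float(vals.max())
    if high > low:
        w = (high - low) / setting.n_bins
        lev = np.floor((vals - low) / w).astype(np.int64) + 1
        lev = np.clip(lev, 1, setting.n_bins)
    else:  # constant VOI under relative resampling
        w = 0.0
        lev = np.ones(vals.shape, dtype=np.int64)
    levels = np.zeros(mask.shape, dtype=np.int64)
    levels[mask.values] = lev
    return DiscretizedVOI(
        levels=levels,
        mask=mask.values.copy(),
        n_bins=setting.n_bins,
        setting=setting,
        bin_width=float(w),
        spacing=mask.spacing,
    )
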