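"""ADC map quantification: the ADC-R(x) voxel-fraction statistic.

The marker quantified here is the percentage of analysable brain voxels
whose apparent diffusion coefficient (ADC) falls at or below a threshold
``x``.  Voxels outside the analysable band [200, 2000] (units of
1e-6 mm^2/s) are excluded as artefact/fluid before the fraction is taken:

    ADC-R(x) [%] = 100 * #{v : 200 <= v <= x} / #{v : 200 <= v <= 2000}

Both intervals are closed.  Counts are integer voxel counts; no
interpolation is performed, so ADC-R depends only on the multiset of
in-mask voxel values, never on their spatial arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelFilter",
    "ThresholdGrid",
    "ADCVolume",
    "ADCRProfile",
    "load_adc_volume",
    "extract_brain_values",
    "adc_r",
    "adc_r_profile",
]


@dataclass(frozen=True)
class VoxelFilter:
    """Analysable-voxel band in 1e-6 mm^2/s; both ends inclusive.

    Values below ``lower`` or above ``upper`` (and non-finite values) are
    excluded from both numerator and denominator of ADC-R.
    """

    lower: float = 200.0
    upper: float = 2000.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"filter lower bound must be < upper bound, got [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered thresholds x at which ADC-R(x) is evaluated.

    The default grid covers 250 to 1150 in steps of 50 (19 thresholds),
    the interior points of the analysable band divided every 50 units.
    """

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.thresholds)
        if len(t) == 0:
            raise ValueError("threshold grid is empty")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", t)

    @classmethod
    def default(cls) -> "ThresholdGrid":
        return cls.from_range(250.0, 1150.0, 50.0)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "ThresholdGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(tuple(start + i * step for i in range(n)))

    def validate_against(self, filt: VoxelFilter) -> None:
        t = self.thresholds
        if t[0] <= filt.lower or t[-1] > filt.upper:
            raise ValueError(
                f"grid [{t[0]}, {t[-1]}] must lie within ({filt.lower}, {filt.upper}]"
            )

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass
class ADCVolume:
    """A 3-D ADC map in 1e-6 mm^2/s with spatial metadata and optional brain mask."""

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"ADC volume must be 3-D, got shape {self.voxels.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.voxels.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match volume shape "
                    f"{self.voxels.shape}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass(frozen=True)
class ADCRProfile:
    """Per-subject mapping x -> ADC-R(x) in percent, plus exclusion bookkeeping.

    ``denominator_count`` is the number of in-mask voxels inside the
    analysable band; it is shared by every threshold.  ``excluded_low``
    counts voxels below the band; ``excluded_high`` counts voxels above
    it, including any non-finite voxels.
    """

    values: Mapping[float, float]
    denominator_count: int
    excluded_low: int = 0
    excluded_high: int = 0

    def __post_init__(self) -> None:
        if self.denominator_count < 1:
            raise ValueError("profile requires denominator_count >= 1")
        vals = list(self.values.values())
        if any(v < 0 or v > 100 for v in vals):
            raise ValueError("ADC-R values must lie in [0, 100]")
        if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValueError("ADC-R profile must be non-decreasing in x")

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(self.values.keys())

    def __getitem__(self, x: float) -> float:
        return self.values[float(x)]

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def load_adc_volume(
    path: str | Path,
    scale_factor: float = 1.0,
    mask_path: str | Path | None = None,
) -> ADCVolume:
    """Read a NIfTI ADC map (and optional binary mask) into an :class:`ADCVolume`.

    ``scale_factor`` rescales stored voxel values into 1e-6 mm^2/s; maps
    stored in mm^2/s need ``scale_factor=1e6``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    data = data * float(scale_factor)
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mdata = np.asanyarray(mimg.dataobj)
        if mdata.ndim == 4 and mdata.shape[-1] == 1:
            mdata = mdata[..., 0]
        if mdata.shape != data.shape:
            raise ValueError(
                f"mask shape {mdata.shape} does not match volume shape {data.shape} "
                f"({mask_path} vs {path})"
            )
        mask = mdata > 0.5
    return ADCVolume(voxels=data, affine=img.affine, mask=mask)


# Crude positivity-threshold brain proxy used when no mask is supplied.
# NOT equivalent to skull-stripping: it keeps every strictly positive
# voxel up to this ceiling, so residual extra-cranial tissue survives.
_FALLBACK_UPPER = 3500.0


def extract_brain_values(vol: ADCVolume, fallback_segmentation: bool = False) -> np.ndarray:
    """Return the multiset (1-D array) of brain voxel values.

    With a mask, returns exactly the in-mask voxels.  Without one,
    ``fallback_segmentation=True`` enables a threshold-based proxy that
    keeps voxels in (0, 3500]; this is a coarse stand-in for a proper
    eroded brain mask and is documented as such.
    """
    if vol.mask is not None:
        if not vol.mask.any():
            raise ValueError("empty brain mask")
        return vol.voxels[vol.mask]
    if not fallback_segmentation:
        raise ValueError(
            "volume has no brain mask; pass fallback_segmentation=True to use the "
            "positivity-threshold proxy"
        )
    v = vol.voxels
    sel = (v > 0) & (v <= _FALLBACK_UPPER)
    return v[sel]


def adc_r(
    values: Sequence[float] | np.ndarray,
    x: float,
    filt: VoxelFilter = VoxelFilter(),
) -> float:
    """ADC-R(x) in percent for a voxel-value multiset.

    Integer counts over closed intervals: numerator #{lower <= v <= x},
    denominator #{lower <= v <= upper}.
    """
    v = np.asarray(values, dtype=float)
    if not filt.lower <= x <= filt.upper:
        raise ValueError(f"threshold x={x} outside analysable band [{filt.lower}, {filt.upper}]")
    in_band = (v >= filt.lower) & (v <= filt.upper)  # NaN compares False
    denom = int(np.count_nonzero(in_band))
    if denom == 0:
        raise ValueError("no analysable voxels")
    num = int(np.count_nonzero(in_band & (v <= x)))
    return 100.0 * num / denom


def adc_r_profile(
    values: Sequence[float] | np.ndarray,
    grid: ThresholdGrid = ThresholdGrid.default(),
    filt: VoxelFilter = VoxelFilter(),
) -> ADCRProfile:
    """ADC-R over all grid thresholds, with one shared denominator count."""
    grid.validate_against(filt)
    v = np.sort(np.asarray(values, dtype=float))  # NaNs sort to the end
    n = v.size
    lo = int(np.searchsorted(v, filt.lower, side="left"))
    hi = int(np.searchsorted(v, filt.upper, side="right"))
    denom = hi - lo
    if denom == 0:
        raise ValueError("no analysable voxels")
    xs = np.asarray(grid.thresholds, dtype=float)
    nums = np.searchsorted(v, xs, side="right") - lo
    vals = {float(x): 100.0 * int(c) / denom for x, c in zip(xs, nums)}
    return ADCRProfile(
        values=vals,
        denominator_count=denom,
        excluded_low=lo,
        excluded_high=n - hi,
    )
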