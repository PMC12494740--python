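"""Hypercube data model and wavelength arithmetic.

A hyperspectral scan is a 3-D array ``values[y, x, l]`` of non-negative
intensities: two spatial axes and one spectral axis. The spectral axis is a
uniform grid described by :class:`WavelengthAxis` (start wavelength, per-channel
step in nm, channel count). Channel indexing is 0-based and spectral windows are
half-open intervals ``[s, e)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError

__all__ = [
    "WavelengthAxis",
    "Hypercube",
    "LabeledDataset",
    "nm_width_to_channels",
    "reduction_fraction",
    "slice_bands",
    "pseudo_rgb",
]


@dataclass(frozen=True)
class WavelengthAxis:
    """Uniform spectral grid: channel ``i`` sits at ``start_nm + i * step_nm``.

    The reference instrument records 1004 channels at 0.728 nm per channel
    starting at 325 nm, for a total span that rounds to 731 nm.
    """

    start_nm: float
    step_nm: float
    n_channels: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValidationError(f"step_nm must be positive, got {self.step_nm}")
        if self.n_channels < 1:
            raise ValidationError(f"n_channels must be >= 1, got {self.n_channels}")

    def wavelength(self, i: int | np.ndarray) -> float | np.ndarray:
        """Wavelength (nm) of channel ``i``."""
        return self.start_nm + np.asarray(i) * self.step_nm if isinstance(i, np.ndarray) \
            else self.start_nm + i * self.step_nm

    @property
    def wavelengths(self) -> np.ndarray:
        """All channel wavelengths as a 1-D array."""
        return self.start_nm + self.step_nm * np.arange(self.n_channels)

    @property
    def span_nm(self) -> float:
        """Total spectral span covered: ``n_channels * step_nm``."""
        return self.n_channels * self.step_nm

    def channel_of(self, nm: float) -> int:
        """Nearest channel index for a wavelength inside the axis range."""
        lo = self.start_nm
        hi = self.start_nm + (self.n_channels - 1) * self.step_nm
        if not (lo <= nm <= hi):
            raise ValueError(f"wavelength {nm} nm outside axis range [{lo}, {hi}] nm")
        return int(round((nm - self.start_nm) / self.step_nm))

    def interval_channels(self, start_nm: float, end_nm: float) -> tuple[int, int]:
        """Channel interval [s, e) covering the wavelength interval [start_nm, end_nm]."""
        if end_nm <= start_nm:
            raise ValueError("end_nm must exceed start_nm")
        eps = 1e-9  # absorb float error when an endpoint sits on the grid
        s = max(0, math.floor((start_nm - self.start_nm) / self.step_nm + eps))
        e = min(self.n_channels,
                math.floor((end_nm - self.start_nm) / self.step_nm + eps) + 1)
        if e <= s:
            raise ValueError(
                f"interval [{start_nm}, {end_nm}] nm does not overlap the axis"
            )
        return s, e


@dataclass
class Hypercube:
    """One scan: ``values[y, x, l]`` intensities plus its wavelength axis.

    Values must be finite and non-negative; the spectral extent must match the
    axis. ``label`` is an optional class identifier, ``meta`` free annotations.
    """

    values: np.ndarray
    axis: WavelengthAxis
    label: int | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be 3-D (y, x, lambda), got {self.values.ndim}-D")
        if min(self.values.shape[:2]) < 1:
            raise ValidationError("spatial extents must be >= 1")
        if self.values.shape[2] != self.axis.n_channels:
            raise ValidationError(
                f"spectral extent {self.values.shape[2]} != axis n_channels {self.axis.n_channels}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("hypercube contains non-finite values (NaN/Inf)")
        if np.any(self.values < 0):
            raise ValidationError("hypercube contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_channels(self) -> int:
        return self.axis.n_channels


@dataclass
class LabeledDataset:
    """An ordered collection of hypercubes with integer class labels.

    All cubes share one wavelength axis and one spatial extent; labels index
    into ``class_names``.
    """

    cubes: list[Hypercube]
    labels: list[int]
    class_names: list[str]

    def __post_init__(self) -> None:
        if len(self.cubes) != len(self.labels):
            raise ValidationError("cubes and labels differ in length")
        if len(self.cubes) == 0:
            raise ValidationError("dataset is empty")
        for lab in self.labels:
            if not (0 <= lab < len(self.class_names)):
                raise ValidationError(f"label {lab} outside [0, {len(self.class_names)})")
        ax0 = self.cubes[0].axis
        sp0 = self.cubes[0].shape[:2]
        for c in self.cubes:
            if c.axis != ax0:
                raise ValidationError("cubes do not share one wavelength axis")
            if c.shape[:2] != sp0:
                raise ValidationError("cubes do not share one spatial extent")

    def __len__(self) -> int:
        return len(self.cubes)

    @property
    def axis(self) -> WavelengthAxis:
        return self.cubes[0].axis

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset(
            cubes=[self.cubes[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            class_names=list(self.class_names),
        )


def nm_width_to_channels(width_nm: float, step_nm: float) -> int:
    """Convert a window width in nm to a channel count.

    Round-to-nearest, halves away from zero, floored at one channel. With the
    0.728 nm instrument step, a 20 nm window spans 27 channels.
    """
    if width_nm <= 0 or step_nm <= 0:
        raise ValueError("width_nm and step_nm must be positive")
    return max(1, math.floor(width_nm / step_nm + 0.5))


def reduction_fraction(w_channels: int, total_channels: int) -> float:
    """Fraction of spectral channels discarded by keeping a w-channel window.

    Spatial extents are unchanged by band selection, so this is the data-size
    reduction: keeping 27 of 1004 channels discards 97.3 %.
    """
    if not (1 <= w_channels <= total_channels):
        raise ValueError(
            f"w_channels must satisfy 1 <= w <= total_channels, got {w_channels}/{total_channels}"
        )
    return 1.0 - w_channels / total_channels


def slice_bands(cube: Hypercube, window) -> Hypercube:
    """Restrict a cube to the spectral window ``[s, e)``.

    The axis start shifts to the wavelength of channel ``s``; values are copied.
    ``window`` is anything with ``s`` and ``e`` attributes, or an ``(s, e)`` pair.
    """
    s, e = (window.s, window.e) if hasattr(window, "s") else (int(window[0]), int(window[1]))
    n = cube.n_channels
    if not (0 <= s < e <= n):
        raise IndexError(f"window [{s}, {e}) invalid for {n} channels")
    new_axis = WavelengthAxis(
        start_nm=cube.axis.start_nm + s * cube.axis.step_nm,
        step_nm=cube.axis.step_nm,
        n_channels=e - s,
    )
    return Hypercube(
        values=cube.values[:, :, s:e].copy(),
        axis=new_axis,
        label=cube.label,
        meta=dict(cube.meta),
    )


def pseudo_rgb(cube: Hypercube, r_nm: float, g_nm: float, b_nm: float) -> np.ndarray:
    """Render a false-colour image from three wavelengths.

    Each plane is the nearest spectral channel, min-max normalised to [0, 1];
    a spatially constant plane maps to mid-gray 0.5.
    """
    img = np.empty(cube.shape[:2] + (3,), dtype=np.float64)
    for k, nm in enumerate((r_nm, g_nm, b_nm)):
        plane = cube.values[:, :, cube.axis.channel_of(nm)]
        lo, hi = plane.min(), plane.max()
        img[:, :, k] = 0.5 if hi == lo else (plane - lo) / (hi - lo)
    return img
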