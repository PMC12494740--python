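"""Synthetic H&E-like hyperspectral datasets with a planted informative window.

The generator emulates a stained-tissue microscopy regime: several classes
whose spectra are highly similar everywhere except inside one informative
wavelength window, plus one baseline-only background class. Each pixel's
spectrum is the class signature scaled by a spatially correlated amplitude
field (mimicking stain-density variation) plus wavelength-dependent Gaussian
noise that inflates near the spectral edges (mimicking instrument roll-off):

    pixel(i, j, l) = A(i, j) * signature(l) + eps(i, j, l),   clipped at 0
    A = 1 + texture_amp * G,  G a unit-variance smoothed Gaussian field

Because the texture is multiplicative, the noiseless per-band standard
deviation has the closed form sigma_l = std(A) * signature(l), which makes
the standard-deviation band selector analytically checkable.

Two ready-made profiles are provided: ``paper_profile()`` reproduces the
reference study's geometry (11 classes x 100 cubes, 64 x 64 x 1004 channels,
325-1056 nm) and ``test_profile()`` is a desk-scale variant (5 classes x 10
cubes, 32 x 32 x 200 channels) used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .hypercube import Hypercube, LabeledDataset, WavelengthAxis
from .selection import SpectralWindow

__all__ = [
    "ClassSignature",
    "NoiseModel",
    "SimulationConfig",
    "paper_profile",
    "test_profile",
    "make_default_signatures",
    "simulate_cube",
    "simulate_dataset",
    "planted_window",
]


@dataclass(frozen=True)
class ClassSignature:
    """A class's mean spectrum: shared smooth baseline + Gaussian peaks.

    ``baseline`` holds polynomial coefficients in a normalised axis coordinate
    t in [0, 1] (lowest order first); ``peaks`` is a list of
    (center_nm, width_nm, amplitude) Gaussian features. The signature must be
    non-negative over the whole axis.
    """

    baseline: tuple[float, ...]
    peaks: tuple[tuple[float, float, float], ...] = ()

    def __call__(self, axis: WavelengthAxis) -> np.ndarray:
        wl = axis.wavelengths
        t = (wl - axis.start_nm) / max(axis.span_nm, 1e-12)
        sig = np.zeros_like(wl)
        for k, c in enumerate(self.baseline):
            sig += c * t**k
        for center, width, amp in self.peaks:
            sig += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return sig


@dataclass(frozen=True)
class NoiseModel:
    """Per-voxel Gaussian noise with edge-inflated scale.

    The per-channel scale is ``base_sigma * (1 + (edge_factor - 1) * ramp)``
    where the ramp rises linearly from 0 to 1 inside ``edge_width_nm`` of
    either spectral end, emulating detector roll-off near the band edges.
    """

    base_sigma: float = 0.02
    edge_factor: float = 3.0
    edge_width_nm: float = 30.0

    def __post_init__(self) -> None:
        if self.base_sigma < 0:
            raise ValueError("base_sigma must be >= 0")
        if self.edge_factor < 1:
            raise ValueError("edge_factor must be >= 1")
        if self.edge_width_nm < 0:
            raise ValueError("edge_width_nm must be >= 0")

    def channel_scales(self, axis: WavelengthAxis) -> np.ndarray:
        """Noise standard deviation per channel."""
        wl = axis.wavelengths
        lo, hi = wl[0], wl[-1]
        if self.edge_width_nm == 0:
            ramp = np.zeros_like(wl)
        else:
            d_edge = np.minimum(wl - lo, hi - wl)
            ramp = np.clip(1.0 - d_edge / self.edge_width_nm, 0.0, 1.0)
        return self.base_sigma * (1.0 + (self.edge_factor - 1.0) * ramp)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic dataset."""

    n_classes: int = 11
    cubes_per_class: int = 100
    spatial: tuple[int, int] = (64, 64)
    axis: WavelengthAxis = field(
        default_factory=lambda: WavelengthAxis(325.0, 0.728, 1004)
    )
    informative_window: tuple[float, float] = (470.0, 570.0)
    peak_amplitude: float = 0.5
    peak_width_nm: float = 6.0
    texture_scale: float = 4.0
    texture_amp: float = 0.15
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.cubes_per_class < 1:
            raise ValueError("cubes_per_class must be >= 1")
        lo, hi = self.informative_window
        wl = self.axis.wavelengths
        if not (wl[0] <= lo < hi <= wl[-1]):
            raise ValueError(
                f"informative_window {self.informative_window} outside axis range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )


def paper_profile(**overrides) -> SimulationConfig:
    """The reference study's geometry: 11 x 100 cubes of 64 x 64 x 1004."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def test_profile(**overrides) -> SimulationConfig:
    """Desk-scale profile: 5 classes x 10 cubes of 32 x 32 x 200 channels.

    The 200-channel axis spans 325-470 nm, so the planted window moves to
    390-420 nm (same relative position as the full-scale default).
    """
    cfg = SimulationConfig(
        n_classes=5,
        cubes_per_class=10,
        spatial=(32, 32),
        axis=WavelengthAxis(325.0, 0.728, 200),
        informative_window=(390.0, 420.0),
        peak_width_nm=3.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


def make_default_signatures(config: SimulationConfig) -> list[ClassSignature]:
    """One signature per class, distinguishable mainly inside the planted window.

    All classes share a gentle quadratic baseline. The last class is the
    background: baseline only, no peaks. Every other class gets two Gaussian
    peaks whose centers lie strictly inside the informative window, laid out
    on a per-class offset grid (with a small seeded jitter) so that pairwise
    spectral differences concentrate inside the window; outside it only the
    Gaussian tails remain, well under 10 % of the in-window contrast.
    """
    lo, hi = config.informative_window
    width = config.peak_width_nm
    margin = 3.0 * width  # keeps tails inside the window
    if hi - lo <= 2 * margin:
        raise ValueError(
            f"informative window [{lo}, {hi}] nm too narrow for peaks of "
            f"width {width} nm (needs > {2 * margin:.1f} nm)"
        )
    baseline = (0.9, 0.2, -0.2)  # smooth, non-negative, nearly flat (+-5 %)
    n_signal = config.n_classes - 1
    rng = np.random.default_rng(config.seed)
    usable_lo, usable_hi = lo + margin, hi - margin
    # Interleave two center grids so every class's peak pair is unique.
    grid = np.linspace(usable_lo, usable_hi, 2 * n_signal) if n_signal > 1 else \
        np.array([usable_lo, usable_hi])
    jitter_span = 0.2 * (grid[1] - grid[0]) if grid.size > 1 else 0.0
    signatures: list[ClassSignature] = []
    for c in range(n_signal):
        c1 = grid[c] + rng.uniform(-jitter_span, jitter_span)
        c2 = grid[2 * n_signal - 1 - c] + rng.uniform(-jitter_span, jitter_span)
        c1 = float(np.clip(c1, usable_lo, usable_hi))
        c2 = float(np.clip(c2, usable_lo, usable_hi))
        signatures.append(ClassSignature(
            baseline=baseline,
            peaks=((c1, width, config.peak_amplitude),
                   (c2, width, 0.6 * config.peak_amplitude)),
        ))
    signatures.append(ClassSignature(baseline=baseline, peaks=()))  # background
    return signatures


def _texture_field(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    g = rng.standard_normal(shape)
    if scale > 0:
        g = ndimage.gaussian_filter(g, sigma=scale, mode="wrap")
    sd = g.std()
    if sd > 0:
        g = (g - g.mean()) / sd
    return g


def simulate_cube(
    signature: ClassSignature,
    config: SimulationConfig,
    rng: np.random.Generator,
    label: int | None = None,
) -> Hypercube:
    """Draw one cube: multiplicative texture x signature + edge-weighted noise.

    Advances ``rng``; negative values (rare, noise-driven) are clipped at 0.
    """
    y, x = config.spatial
    sig = signature(config.axis)
    amp = 1.0 + config.texture_amp * _texture_field((y, x), config.texture_scale, rng)
    values = amp[:, :, None] * sig[None, None, :]
    if config.noise.base_sigma > 0:
        scales = config.noise.channel_scales(config.axis)
        values = values + rng.standard_normal(values.shape) * scales[None, None, :]
    np.clip(values, 0.0, None, out=values)
    return Hypercube(values=values, axis=config.axis, label=label)


def simulate_dataset(config: SimulationConfig) -> LabeledDataset:
    """Full labeled dataset: n_classes x cubes_per_class cubes, seed-determined."""
    signatures = make_default_signatures(config)
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from signatures
    cubes: list[Hypercube] = []
    labels: list[int] = []
    for c, sig in enumerate(signatures):
        for _ in range(config.cubes_per_class):
            cubes.append(simulate_cube(sig, config, rng, label=c))
            labels.append(c)
    names = [f"class_{c}" for c in range(config.n_classes - 1)] + ["background"]
    return LabeledDataset(cubes=cubes, labels=labels, class_names=names)


def planted_window(config: SimulationConfig) -> SpectralWindow:
    """Channel interval covering the informative wavelength window."""
    s, e = config.axis.interval_channels(*config.informative_window)
    return SpectralWindow(s=s, e=e, method="std")
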