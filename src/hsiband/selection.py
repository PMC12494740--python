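"""Ranking-based spectral band selection.

Each criterion produces one non-negative score per spectral channel:

* **std** — the population standard deviation of the band's pixel intensities
  over the spatial plane,

  .. math:: \\sigma_\\lambda = \\sqrt{\\tfrac{1}{yx}\\sum_{ij}(X_{ij\\lambda}-\\mu_\\lambda)^2}

  High spatial dispersion marks a band where the scene actually varies.
* **mi** — the mutual information, in bits, between the discretised band and
  the discretised per-pixel mean intensity across all bands (equal-width
  histogram binning on each variable's own range).
* **entropy** — the Shannon entropy, in bits, of the band's pixel-intensity
  histogram over ``n_bins`` equal-width bins.

A window of fixed channel width ``w`` then slides along the spectral axis with
stride 1; the window maximising the cumulative (summed) score is selected.
Ties resolve to the smallest start channel. The random baseline draws the
window start uniformly instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypercube import Hypercube, LabeledDataset, nm_width_to_channels
from .errors import ValidationError

__all__ = [
    "BandScores",
    "SpectralWindow",
    "SelectionConfig",
    "spatial_mean",
    "band_std_scores",
    "mi_scores",
    "entropy_scores",
    "mutual_information",
    "shannon_entropy",
    "cumulative_window_scores",
    "select_window",
    "random_window",
    "select_for_dataset",
]

DEFAULT_N_BINS = 64  # equal-width histogram bins for MI / entropy

METHODS = ("std", "mi", "entropy", "random")


@dataclass(frozen=True)
class BandScores:
    """Per-channel score vector from one criterion."""

    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=np.float64))
        if self.scores.ndim != 1:
            raise ValidationError("scores must be a 1-D vector")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValidationError("scores must be finite and non-negative")

    @property
    def n_channels(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class SpectralWindow:
    """Half-open channel interval [s, e) with its cumulative score."""

    s: int
    e: int
    score: float = 0.0
    method: str = "std"

    def __post_init__(self) -> None:
        if not (0 <= self.s < self.e):
            raise ValidationError(f"invalid window [{self.s}, {self.e})")

    @property
    def width(self) -> int:
        return self.e - self.s


@dataclass
class SelectionConfig:
    """How one selection run is configured.

    ``window_nm`` is converted to a channel width on the dataset's axis.
    Window widths below 20 nm are admitted but discouraged for raw instrument
    data, where narrow edge-noise regions can masquerade as features.
    """

    method: str = "std"
    window_nm: float = 20.0
    n_bins: int = DEFAULT_N_BINS
    aggregation: str = "per_cube_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.window_nm <= 0:
            raise ValueError("window_nm must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.aggregation != "per_cube_mean":
            raise ValueError("only 'per_cube_mean' aggregation is supported")


# ---------------------------------------------------------------------------
# per-band scoring


def spatial_mean(cube: Hypercube, l: int) -> float:
    """Mean intensity of spectral band ``l`` over all spatial pixels."""
    if not (0 <= l < cube.n_channels):
        raise IndexError(f"channel {l} out of range [0, {cube.n_channels})")
    return float(cube.values[:, :, l].mean())


def band_std_scores(cube: Hypercube) -> BandScores:
    """Population standard deviation of each band over the spatial plane.

    Divides by the pixel count y*x (not y*x - 1): the band's pixels are the
    whole population of interest, not a sample.
    """
    flat = cube.values.reshape(-1, cube.n_channels)
    return BandScores(scores=flat.std(axis=0, ddof=0), method="std")


def _discretize(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning over the variable's own [min, max]; max lands in the
    last bin; a constant variable occupies a single bin."""
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(v.shape, dtype=np.intp)
    idx = np.floor((v - lo) / (hi - lo) * n_bins).astype(np.intp)
    return np.minimum(idx, n_bins - 1)


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Mutual information I(X; Y) in bits between two discretised variables.

    Each variable is binned independently into ``n_bins`` equal-width bins on
    its own range; probabilities are plug-in pixel frequencies; zero joint
    cells contribute nothing. A constant variable carries zero information.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same number of samples")
    xi = _discretize(x, n_bins)
    yi = _discretize(y, n_bins)
    joint = np.zeros((n_bins, n_bins), dtype=np.float64)
    np.add.at(joint, (xi, yi), 1.0)
    joint /= x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))
    return max(mi, 0.0)  # clamp tiny negative round-off


def shannon_entropy(v: np.ndarray, n_bins: int) -> float:
    """Shannon entropy in bits of the equal-width histogram of ``v``."""
    counts = np.bincount(_discretize(np.asarray(v, dtype=np.float64).ravel(), n_bins),
                         minlength=n_bins).astype(np.float64)
    p = counts / counts.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def mi_scores(cube: Hypercube, n_bins: int = DEFAULT_N_BINS) -> BandScores:
    """Mutual information of each band with the per-pixel spectral mean.

    The cube is reshaped to (y*x) x lambda; the reference variable is each
    pixel's mean intensity across all channels.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    flat = cube.values.reshape(-1, cube.n_channels)
    if flat.shape[0] < 2:
        raise ValueError("mutual information needs at least 2 pixels")
    mu = flat.mean(axis=1)
    scores = np.array([mutual_information(flat[:, l], mu, n_bins)
                       for l in range(cube.n_channels)])
    return BandScores(scores=scores, method="mi")


def entropy_scores(cube: Hypercube, n_bins: int = DEFAULT_N_BINS) -> BandScores:
    """Shannon entropy of each band's pixel-intensity histogram."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    flat = cube.values.reshape(-1, cube.n_channels)
    scores = np.array([shannon_entropy(flat[:, l], n_bins)
                       for l in range(cube.n_channels)])
    return BandScores(scores=scores, method="entropy")


_SCORERS = {
    "std": lambda cube, n_bins: band_std_scores(cube),
    "mi": lambda cube, n_bins: mi_scores(cube, n_bins),
    "entropy": lambda cube, n_bins: entropy_scores(cube, n_bins),
}


# ---------------------------------------------------------------------------
# window scoring and selection


def cumulative_window_scores(scores: BandScores, w: int) -> np.ndarray:
    """Sum of per-band scores in every width-``w`` window (stride 1).

    Returns ``n_channels - w + 1`` values; entry ``k`` covers channels
    ``[k, k+w)``. Shared by all criteria.
    """
    n = scores.n_channels
    if not (1 <= w <= n):
        raise ValueError(f"window width {w} out of range [1, {n}]")
    csum = np.concatenate(([0.0], np.cumsum(scores.scores)))
    return csum[w:] - csum[:-w]


def select_window(scores: BandScores, w: int) -> SpectralWindow:
    """Window of width ``w`` maximising the cumulative score (ties: smallest s)."""
    window_scores = cumulative_window_scores(scores, w)
    s = int(np.argmax(window_scores))  # argmax returns the first maximum
    return SpectralWindow(s=s, e=s + w, score=float(window_scores[s]),
                          method=scores.method)


def random_window(
    n_channels: int,
    w: int,
    seed: int,
    scores: BandScores | None = None,
) -> SpectralWindow:
    """Window start drawn uniformly from {0, ..., n_channels - w}.

    Deterministic given ``seed``. If per-band ``scores`` are supplied the
    window's cumulative score is filled in; otherwise it is 0.
    """
    if not (1 <= w <= n_channels):
        raise ValueError(f"window width {w} out of range [1, {n_channels}]")
    rng = np.random.default_rng(seed)
    s = int(rng.integers(0, n_channels - w + 1))
    score = float(scores.scores[s:s + w].sum()) if scores is not None else 0.0
    return SpectralWindow(s=s, e=s + w, score=score, method="random")


def mean_band_scores(dataset: LabeledDataset, method: str,
                     n_bins: int = DEFAULT_N_BINS) -> BandScores:
    """Unweighted mean of per-cube score vectors across a dataset."""
    if method not in _SCORERS:
        raise ValueError(f"no scorer for method {method!r}")
    acc = np.zeros(dataset.axis.n_channels)
    for cube in dataset.cubes:
        acc += _SCORERS[method](cube, n_bins).scores
    return BandScores(scores=acc / len(dataset), method=method)


def select_for_dataset(dataset: LabeledDataset, config: SelectionConfig) -> SpectralWindow:
    """One global window for a whole dataset.

    Scores are computed per cube, averaged (unweighted) across cubes, and the
    argmax window of the mean score vector is returned. The random method
    skips scoring and draws the start uniformly with ``config.seed``.
    """
    axis = dataset.axis
    w = nm_width_to_channels(config.window_nm, axis.step_nm)
    if w > axis.n_channels:
        raise ValueError(
            f"window of {config.window_nm} nm spans {w} channels, "
            f"more than the axis's {axis.n_channels}"
        )
    if config.method == "random":
        return random_window(axis.n_channels, w, config.seed)
    return select_window(mean_band_scores(dataset, config.method, config.n_bins), w)
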