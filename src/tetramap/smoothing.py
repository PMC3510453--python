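"""Gaussian / moving-average convolution smoothing of coverage tracks.

The smoother is a symmetrical convolution sum

    y[i] = sum_{j=-m}^{+m} h[j] * x[i-j],      m = floor(M/2)

with a Gaussian kernel h[j] proportional to exp(-j^2 / (2 sigma^2)) where
sigma = M/6: the length-M window spans 6 sigma, which holds ~99.73% of the
continuous Gaussian mass, so truncation loses essentially nothing.  The
sampled kernel is renormalized to sum exactly 1 so a constant track is a
fixed point and total mass is conserved on circular replicons.

Edge handling: ``wrap`` indexes modulo the track length (circular
replicons); ``renormalize`` divides by the in-bounds kernel mass at linear
ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import SmoothedTrack

__all__ = [
    "GaussianKernel",
    "CorrelationResult",
    "gaussian_kernel",
    "sma_kernel",
    "convolve",
    "two_pass_sma",
    "pearson",
    "select_window",
    "gaussian_interval_mass",
]


@dataclass(frozen=True)
class GaussianKernel:
    M: int
    sigma: float
    weights: np.ndarray  # length 2*floor(M/2)+1, symmetric, sums to 1

    def describe(self) -> str:
        return f"gaussian(M={self.M},sigma={self.sigma:g})"


@dataclass(frozen=True)
class SMAKernel:
    window: int
    weights: np.ndarray

    def describe(self) -> str:
        return f"sma(w={self.window})"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int


def gaussian_kernel(M: int) -> GaussianKernel:
    """Discrete Gaussian kernel of bandwidth ``M`` bp with sigma = M/6."""
    if M < 2:
        raise ValueError("kernel bandwidth M must be >= 2")
    sigma = M / 6.0
    half = M // 2
    j = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-(j**2) / (2.0 * sigma**2))
    w /= w.sum()
    return GaussianKernel(M, sigma, w)


def sma_kernel(window: int) -> SMAKernel:
    """Uniform-weight (simple moving average) kernel of ``window`` bp."""
    if window < 2:
        raise ValueError("SMA window must be >= 2")
    half = window // 2
    n = 2 * half + 1
    return SMAKernel(window, np.full(n, 1.0 / n))


def _convolve_values(x: np.ndarray, weights: np.ndarray, edge: str) -> np.ndarray:
    if len(weights) > len(x):
        raise ValueError("kernel longer than track")
    if edge == "wrap":
        # symmetric kernel: correlation == convolution
        return ndimage.convolve1d(x, weights, mode="wrap")
    if edge == "renormalize":
        y = np.convolve(x, weights, mode="same")
        mass = np.convolve(np.ones_like(x), weights, mode="same")
        return y / mass
    raise ValueError(f"unknown edge mode {edge!r}")


def convolve(track, kernel, edge: str | None = None) -> SmoothedTrack:
    """Apply the symmetrical convolution sum to a track.

    ``edge`` defaults to wrap for circular replicons and renormalize for
    linear ones.
    """
    if edge is None:
        edge = "wrap" if track.replicon.circular else "renormalize"
    x = np.asarray(track.values, dtype=float)
    y = _convolve_values(x, kernel.weights, edge)
    return SmoothedTrack(track.replicon, y, kernel.describe())


def two_pass_sma(track, w1: int = 40, w2: int = 15, edge: str | None = None) -> SmoothedTrack:
    """Two-pass simple moving average (first pass ``w1`` bp, second ``w2`` bp)."""
    first = convolve(track, sma_kernel(w1), edge)
    second = convolve(first, sma_kernel(w2), edge)
    return SmoothedTrack(track.replicon, second.values, f"sma2(w1={w1},w2={w2})")


def pearson(a, b) -> CorrelationResult:
    """Pearson product-moment correlation between two equal-length tracks."""
    x = np.asarray(a.values, dtype=float)
    y = np.asarray(b.values, dtype=float)
    if len(x) != len(y):
        raise ValueError("tracks differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 positions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant track")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r, len(x))


def select_window(track, candidates, r_min: float = 0.85, edge: str | None = None):
    """Choose the Gaussian bandwidth M by correlation with the raw data.

    Correlation with the raw track decreases as M grows, so "optimal" is
    taken as the largest candidate whose smoothed track still correlates at
    least ``r_min`` with the raw signal — the strongest smoothing that still
    tracks the data.  Returns (chosen M, table of (M, r)).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate bandwidths")
    table = []
    for M in sorted(candidates):
        sm = convolve(track, gaussian_kernel(M), edge)
        table.append((M, pearson(track, sm).r))
    eligible = [M for M, r in table if r >= r_min]
    if not eligible:
        raise ValueError(f"no candidate reaches r >= {r_min}; table: {table}")
    return max(eligible), table


def gaussian_interval_mass(n_sigma: float = 6.0) -> float:
    """Probability mass of a Gaussian inside an interval of length n_sigma*sigma
    centered on the mean (0.9973 for the default 6-sigma window)."""
    half = n_sigma / 2.0
    return float(stats.norm.cdf(half) - stats.norm.cdf(-half))
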