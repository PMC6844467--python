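"""Deming (orthogonal) regression on above-threshold colocalisation intensities.

Both fluorescence channels are measured with error, so the line of best fit
through the joint intensities is estimated with an errors-in-variables model
rather than ordinary least squares: Deming regression with error-variance
ratio ``lam`` (``lam = 1`` is orthogonal regression, the default — both
channels are assumed to be acquired under comparable conditions).

Only voxels whose intensities are strictly above the per-channel background
thresholds enter the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantoms import ChannelPair

__all__ = [
    "ColocThresholds",
    "SampleStats",
    "DemingFit",
    "ColocalisationError",
    "InsufficientVoxelsError",
    "DegenerateCorrelationError",
    "coloc_mask",
    "sample_stats",
    "fit_deming",
    "pcc",
]


class ColocalisationError(ValueError):
    """Base class for data-dependent failures of the colocalisation model."""


class InsufficientVoxelsError(ColocalisationError):
    """Fewer than three voxels have both channels above threshold."""


class DegenerateCorrelationError(ColocalisationError):
    """No discernible linear relation between the channels (zero variance or
    vanishing covariance); a regression-based colour mapping is not
    meaningful for such data."""


@dataclass(frozen=True)
class ColocThresholds:
    """Per-channel background cutoffs; voxels must be strictly above both."""

    t_ch1: float
    t_ch2: float

    def validate(self, i_max: float) -> None:
        for t in (self.t_ch1, self.t_ch2):
            if not 0 <= t < i_max:
                raise ValueError(f"threshold {t} outside [0, i_max={i_max})")


@dataclass(frozen=True)
class SampleStats:
    """First and second sample moments of the masked joint intensities."""

    n: int
    mean_x: float
    mean_y: float
    s_xx: float
    s_yy: float
    s_xy: float


@dataclass(frozen=True)
class DemingFit:
    """Fitted regression line ``y = beta0 + beta1 * x`` (beta1 > 0)."""

    beta0: float
    beta1: float
    lam: float
    stats: SampleStats


def coloc_mask(pair: ChannelPair, thr: ColocThresholds) -> np.ndarray:
    """Boolean grid: True exactly where both channels are strictly above
    their respective thresholds."""
    thr.validate(pair.i_max)
    return (pair.ch1 > thr.t_ch1) & (pair.ch2 > thr.t_ch2)


def sample_stats(pair: ChannelPair, mask: np.ndarray) -> SampleStats:
    """Means and unbiased (n-1) covariances over the masked voxels only."""
    if mask.shape != pair.shape:
        raise ValueError("mask shape does not match the channel grids")
    x = pair.ch1[mask].astype(np.float64)
    y = pair.ch2[mask].astype(np.float64)
    n = x.size
    if n < 3:
        raise InsufficientVoxelsError(
            f"only {n} colocalised voxels above thresholds; need at least 3"
        )
    mean_x = float(x.mean())
    mean_y = float(y.mean())
    dx = x - mean_x
    dy = y - mean_y
    denom = n - 1
    return SampleStats(
        n=int(n),
        mean_x=mean_x,
        mean_y=mean_y,
        s_xx=float(dx @ dx) / denom,
        s_yy=float(dy @ dy) / denom,
        s_xy=float(dx @ dy) / denom,
    )


def fit_deming(stats: SampleStats, lam: float = 1.0) -> DemingFit:
    """Closed-form Deming slope and intercept from sample moments.

    The slope solves ``lam*s_xy*b^2 + (s_xx - lam*s_yy)*b - s_xy = 0``; the
    two roots have opposite signs and the positive one is always selected, so
    that high joint intensities map to high colourmap values even when the
    sample covariance happens to be negative (a warning is emitted in that
    case, since it signals essentially uncorrelated channels).
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if stats.s_xx == 0.0 or stats.s_yy == 0.0:
        raise DegenerateCorrelationError(
            "zero variance in a channel: no regression line exists; "
            "a regression-adjusted colour mapping is not meaningful here"
        )
    eps = 1e-12 * stats.s_xx
    if abs(stats.s_xy) < eps:
        raise DegenerateCorrelationError(
            "covariance is (numerically) zero: the channels show no linear "
            "relation, so a regression-adjusted colour mapping is not "
            "meaningful here"
        )
    if stats.s_xy < 0:
        warnings.warn(
            "channel intensities are negatively correlated; the positive "
            "regression slope is used regardless",
            stacklevel=2,
        )
    diff = lam * stats.s_yy - stats.s_xx
    root = np.sqrt(diff * diff + 4.0 * lam * stats.s_xy**2)
    # sign(s_xy) picks the positive root: the root product is -1/lam < 0.
    beta1 = (diff + np.sign(stats.s_xy) * root) / (2.0 * lam * stats.s_xy)
    beta0 = stats.mean_y - beta1 * stats.mean_x
    return DemingFit(beta0=float(beta0), beta1=float(beta1), lam=float(lam), stats=stats)


def pcc(stats: SampleStats) -> float:
    """Pearson correlation coefficient from the sample moments."""
    if stats.s_xx <= 0.0 or stats.s_yy <= 0.0:
        raise DegenerateCorrelationError(
            "zero variance in a channel: PCC is undefined"
        )
    return float(stats.s_xy / np.sqrt(stats.s_xx * stats.s_yy))
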