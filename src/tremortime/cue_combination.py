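"""Bayesian cue combination of duration estimates.

Two independent duration estimates -- one sensory (auditory or visual), one
motor (the timing signal carried by ongoing movement) -- are fused by
inverse-variance weighting.  Writing the two channels as Gaussians with
means ``mu_S``, ``mu_M`` and standard deviations ``sigma_S``, ``sigma_M``,
the combined sensorimotor estimate is

    mu_SM    = w_S * mu_S + w_M * mu_M,
    w_M      = sigma_S**2 / (sigma_S**2 + sigma_M**2)          (and vice versa),
    sigma_SM = sqrt(sigma_S**2 * sigma_M**2 / (sigma_S**2 + sigma_M**2)).

The combined width is always below either input width (precision adds:
1/sigma_SM**2 = 1/sigma_S**2 + 1/sigma_M**2), and the combined mean is
pulled toward the more reliable channel.  A consequence exercised by
:func:`noise_response_curve` is that the damage done by adding noise to one
channel grows with the width of the *other* (base) channel: a precise base
modality shields the combined estimate, an imprecise one does not.

All widths here are standard deviations on a single common duration scale
(seconds or log-seconds); the module never converts between scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SensoryEstimate",
    "CombinedEstimate",
    "weight",
    "combine",
    "noise_response_curve",
    "optimality_ratio",
]


@dataclass(frozen=True)
class SensoryEstimate:
    """One channel's duration estimate: a Gaussian with mean and width.

    Parameters
    ----------
    mu : float
        Mean of the estimate distribution (> 0, common duration scale).
    sigma : float
        Standard deviation of the estimate (> 0, same scale).
    label : str
        Modality tag, e.g. ``"auditory"``, ``"visual"``, ``"movement"``.
    """

    mu: float
    sigma: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class CombinedEstimate:
    """Inverse-variance weighted fusion of two estimates."""

    mu: float
    sigma: float
    w_first: float
    w_second: float

    def __post_init__(self) -> None:
        if abs(self.w_first + self.w_second - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if not self.sigma > 0:
            raise ValueError("combined sigma must be > 0")


def weight(sigma_self: float, sigma_other: float) -> float:
    """Reliability weight on the "self" channel.

    ``w_self = sigma_other**2 / (sigma_self**2 + sigma_other**2)``: the
    weight on an estimate is the *other* channel's variance over the sum of
    variances, so the more reliable (narrower) channel gets the larger
    weight.  Result is strictly inside (0, 1) for finite positive widths.
    """
    if not (sigma_self > 0 and sigma_other > 0):
        raise ValueError("widths must be > 0")
    vs, vo = sigma_self**2, sigma_other**2
    return vo / (vs + vo)


def combine(est_a: SensoryEstimate, est_b: SensoryEstimate) -> CombinedEstimate:
    """Fuse two estimates by inverse-variance weighting.

    Returns the combined mean ``w_a*mu_a + w_b*mu_b`` and width
    ``sqrt(sa**2*sb**2/(sa**2+sb**2))``, which is strictly smaller than
    either input width.
    """
    w_a = weight(est_a.sigma, est_b.sigma)
    w_b = weight(est_b.sigma, est_a.sigma)
    va, vb = est_a.sigma**2, est_b.sigma**2
    sigma = float(np.sqrt(va * vb / (va + vb)))
    mu = w_a * est_a.mu + w_b * est_b.mu
    return CombinedEstimate(mu=mu, sigma=sigma, w_first=w_a, w_second=w_b)


def combined_sigma(sigma_a: float, sigma_b: float) -> float:
    """Width of the fused estimate (convenience wrapper around the variance rule)."""
    if not (sigma_a > 0 and sigma_b > 0):
        raise ValueError("widths must be > 0")
    va, vb = sigma_a**2, sigma_b**2
    return float(np.sqrt(va * vb / (va + vb)))


def noise_response_curve(
    sigma_base: float, noise_grid: Sequence[float]
) -> np.ndarray:
    """Combined width as the second channel's noise sweeps over a grid.

    The base channel is held at ``sigma_base`` while the other channel's
    width takes each value of ``noise_grid`` (strictly increasing, > 0).
    The returned curve is non-decreasing and bounded above by
    ``sigma_base``; its total rise over a fixed grid grows with
    ``sigma_base`` -- an imprecise base modality is hurt more by added
    noise in its partner.
    """
    grid = np.asarray(noise_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("noise_grid must be non-empty")
    if np.any(grid <= 0) or not sigma_base > 0:
        raise ValueError("widths must be > 0")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("noise_grid must be strictly increasing")
    vb = sigma_base**2
    vg = grid**2
    return np.sqrt(vb * vg / (vb + vg))


def optimality_ratio(sigma_observed: float, sigma_predicted: float) -> float:
    """Observed / optimal combined width; 1 means optimal fusion, > 1 suboptimal."""
    if not (sigma_observed > 0 and sigma_predicted > 0):
        raise ValueError("widths must be > 0")
    return sigma_observed / sigma_predicted


def curve_table(sigma_bases: Sequence[float], noise_grid: Sequence[float]):
    """Long-format table of noise-response curves (one row per grid point).

    Columns ``base_sigma, noise_sigma, combined_sigma``; serialisable to CSV.
    """
    import pandas as pd

    rows = []
    for b in sigma_bases:
        curve = noise_response_curve(b, noise_grid)
        for g, c in zip(noise_grid, curve):
            rows.append({"base_sigma": b, "noise_sigma": g, "combined_sigma": c})
    return pd.DataFrame(rows)
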