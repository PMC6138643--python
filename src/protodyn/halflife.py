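"""Correction of measured protein half-lives.

Decay-rate experiments report half-lives that can be arbitrarily large
or even negative when the underlying degradation-rate estimate is noisy
and close to zero.  The correction treats the observed degradation rate
k_obs = ln(2)/observed_halflife as a Gaussian measurement of the true
rate, with standard deviation sigma_k = ln(2)/max_reliable (the rate of
the longest reliably measurable half-life, 300 min by default), and a
prior that the true rate is positive.  The corrected rate is the mean
of N(k_obs, sigma_k^2) truncated to (0, inf):

    k_corr = k_obs + sigma_k * phi(alpha)/(1 - Phi(alpha)),
    alpha = -k_obs / sigma_k,

evaluated through scaled complementary error functions so that it stays
accurate for strongly negative observations.  The corrected half-life
is ln(2)/k_corr; it is always positive and finite, and the correction
is negligible for half-lives much shorter than max_reliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "HalfLifeRecord",
    "degradation_rate",
    "halflife_from_rate",
    "correct_halflife",
    "correct_halflife_table",
]

LN2 = float(np.log(2.0))

#: Longest reliably measurable half-life [min]; sets the error scale.
DEFAULT_MAX_RELIABLE = 300.0


@dataclass(frozen=True)
class HalfLifeRecord:
    gene_id: str
    observed_halflife: float  # minutes; may be negative or huge
    corrected_halflife: float  # minutes; > 0
    k_d: float  # per minute; ln(2)/corrected_halflife

    def __post_init__(self) -> None:
        if not self.corrected_halflife > 0:
            raise ValueError(f"{self.gene_id}: corrected half-life must be positive")
        if abs(self.k_d - LN2 / self.corrected_halflife) > 1e-12 * self.k_d:
            raise ValueError(f"{self.gene_id}: k_d inconsistent with corrected half-life")


def degradation_rate(halflife: float) -> float:
    """First-order degradation rate k_d = ln(2)/half-life [1/min]."""
    if not halflife > 0:
        raise ValueError(
            f"half-life must be positive, got {halflife}; correct observed values first"
        )
    return LN2 / halflife


def halflife_from_rate(k_d: float) -> float:
    """Inverse of :func:`degradation_rate`."""
    if not k_d > 0:
        raise ValueError(f"degradation rate must be positive, got {k_d}")
    return LN2 / k_d


def _inverse_mills(alpha):
    """phi(alpha) / (1 - Phi(alpha)), stable for large |alpha| via erfcx."""
    return np.sqrt(2.0 / np.pi) / special.erfcx(np.asarray(alpha) / np.sqrt(2.0))


def correct_halflife(
    observed_halflife, max_reliable: float = DEFAULT_MAX_RELIABLE
) -> float | np.ndarray:
    """Map an observed half-life [min] to a corrected positive one.

    Accepts a scalar or an array.  ``observed_halflife`` may be negative
    (rate measured below zero) but not exactly zero, which corresponds
    to an infinite rate.  Infinite observed half-life (k_obs = 0) is
    allowed and yields the half-normal mean rate sigma_k*sqrt(2/pi).
    """
    obs = np.asarray(observed_halflife, dtype=float)
    if np.any(obs == 0):
        raise ValueError("observed half-life of exactly 0 min is undefined as a rate")
    if not max_reliable > 0:
        raise ValueError("max_reliable must be positive")
    sigma_k = LN2 / max_reliable
    with np.errstate(divide="ignore"):
        k_obs = np.where(np.isinf(obs), 0.0, LN2 / obs)
    alpha = -k_obs / sigma_k
    k_corr = k_obs + sigma_k * _inverse_mills(alpha)
    out = LN2 / k_corr
    return float(out) if np.isscalar(observed_halflife) else out


def correct_halflife_table(
    df: pd.DataFrame, max_reliable: float = DEFAULT_MAX_RELIABLE
) -> pd.DataFrame:
    """Add corrected_halflife_min and k_d_per_min columns to a half-life table.

    Expects columns ``gene`` and ``observed_halflife_min``.
    """
    for col in ("gene", "observed_halflife_min"):
        if col not in df.columns:
            raise ValueError(f"half-life table is missing column {col!r}")
    out = df.copy()
    corrected = correct_halflife(out["observed_halflife_min"].to_numpy(float), max_reliable)
    out["corrected_halflife_min"] = corrected
    out["k_d_per_min"] = LN2 / corrected
    return out
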