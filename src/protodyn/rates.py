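"""Steady-state vs time-course translation rates and their comparison.

The steady-state translation rate assumes dP/dt = 0, so synthesis
balances degradation:

    TR_ss = k_d * <P> / <M>.

The time-course rate TR_tc is the k_trans returned by the periodic
solver (<P>/<R>); this module only packages it.  Their relative
divergence

    TR_diff = |TR_ss - TR_tc| / min(TR_ss, TR_tc)

is zero when the two approaches agree and grows without bound as they
separate; genes with TR_diff above a threshold (0.1 by default) are
flagged as divergent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TranslationRates",
    "DIVERGENT_THRESHOLD",
    "tr_ss",
    "tr_diff",
    "translational_activity",
    "rate_correlation_report",
    "rates_table",
]

#: TR_diff above which a gene is reported as divergent.
DIVERGENT_THRESHOLD = 0.1


@dataclass(frozen=True)
class TranslationRates:
    gene_id: str
    tr_ss: float  # proteins/mRNA/min
    tr_tc: float  # proteins/mRNA/min
    tr_diff: float  # dimensionless >= 0

    def __post_init__(self) -> None:
        if not (self.tr_ss > 0 and self.tr_tc > 0):
            raise ValueError(f"{self.gene_id}: translation rates must be positive")

    @property
    def divergent(self) -> bool:
        return self.tr_diff > DIVERGENT_THRESHOLD


def tr_ss(k_d: float, mean_protein: float, mean_mrna: float) -> float:
    """Steady-state translation rate k_d * <P> / <M> [proteins/mRNA/min]."""
    if not (k_d > 0 and mean_protein > 0 and mean_mrna > 0):
        raise ValueError("k_d, mean_protein and mean_mrna must all be positive")
    return k_d * mean_protein / mean_mrna


def tr_diff(rate_a: float, rate_b: float) -> float:
    """Relative divergence |a - b| / min(a, b); symmetric, 0 iff equal."""
    if not (rate_a > 0 and rate_b > 0):
        raise ValueError("translation rates must be positive")
    return abs(rate_a - rate_b) / min(rate_a, rate_b)


def translational_activity(
    density: float,
    occupancy: float,
    mrna: float,
    cai: float | None = None,
    variant: Literal["TA1", "TA2"] = "TA1",
) -> float:
    """Translational-activity descriptor.

    TA1 = density * occupancy * mRNA; TA2 additionally multiplies by the
    codon adaptation index.  Density is ribosomes per 100 nt, occupancy
    the fraction of transcripts engaged in translation.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError(f"occupancy must lie in [0, 1], got {occupancy}")
    if density < 0 or mrna < 0:
        raise ValueError("density and mrna must be non-negative")
    ta = density * occupancy * mrna
    if variant == "TA1":
        return ta
    if variant == "TA2":
        if cai is None or cai < 0:
            raise ValueError("TA2 requires a non-negative CAI")
        return ta * cai
    raise ValueError(f"unknown variant {variant!r}")


def _spearman_exact_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p-value for Spearman's rho (n <= 10)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            count += 1
    return count / total


def rate_correlation_report(
    pairs: pd.DataFrame,
    x: str,
    y: str,
    exact_spearman_max_n: int = 10,
) -> dict:
    """Pearson and Spearman correlation between two columns of a table.

    Rows with a missing value in either column are dropped (their count
    is reported).  Spearman p-values come from the large-n approximation
    except at very small n, where all rank permutations are enumerated.
    """
    sub = pairs[[x, y]].dropna()
    n_dropped = len(pairs) - len(sub)
    if len(sub) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(sub)}")
    xv = sub[x].to_numpy(float)
    yv = sub[y].to_numpy(float)
    pearson = stats.pearsonr(xv, yv)
    spearman = stats.spearmanr(xv, yv)
    sp_p = float(spearman.pvalue)
    if len(sub) <= exact_spearman_max_n:
        sp_p = _spearman_exact_pvalue(xv, yv)
    return {
        "n": len(sub),
        "n_dropped": n_dropped,
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": sp_p,
    }


def rates_table(
    records: list[TranslationRates], threshold: float = DIVERGENT_THRESHOLD
) -> pd.DataFrame:
    """Tabulate rates with a boolean divergence flag at ``threshold``."""
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in records],
            "tr_ss": [r.tr_ss for r in records],
            "tr_tc": [r.tr_tc for r in records],
            "tr_diff": [r.tr_diff for r in records],
            "divergent": [r.tr_diff > threshold for r in records],
        }
    )
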