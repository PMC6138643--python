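"""Synthetic data with known ground truth for every stage of the pipeline.

The generator embodies the kinetic model's own assumptions: sinusoidal
transcription

    M(t) = m0 + A sin(2 pi t / T + phi),   m0 > A >= 0,

first-order degradation, and constant (or step-function) translation
and degradation rates.  Because the forcing is sinusoidal, the periodic
solution of the kinetic equation is available in closed form and serves
as an independent oracle for the numeric solver:

    P(t) = k_trans [ m0/k_d + A/sqrt(k_d^2 + w^2) sin(w t + phi - atan(w/k_d)) ].

Measurement noise mirrors the two data modalities: expression noise is
additive in log2 space (microarray-like), protein noise is bounded
multiplicative with factor up to 2 (western-blot-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .halflife import LN2
from .io_preprocess import ExpressionSeries, GeneAverages, MinuteGrid
from .posttranslational import StepHalfLife

__all__ = [
    "SyntheticGene",
    "simulate_expression",
    "sinusoid_mrna",
    "square_wave_mrna",
    "analytic_periodic_protein",
    "simulate_measured_protein",
    "random_gene_set",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticGene:
    """Ground-truth parameters for one simulated gene."""

    gene_id: str
    true_k_trans: float  # proteins/mRNA/min
    true_halflife: float | StepHalfLife  # minutes, or a step function
    m0: float  # baseline mRNA [molecules/cell]
    amplitude: float  # mRNA oscillation amplitude
    period_T: float  # minutes
    phase: float  # radians
    log2_noise_sd: float = 0.0
    protein_noise_factor: float = 1.0  # multiplicative, >= 1

    def __post_init__(self) -> None:
        if not self.m0 > self.amplitude >= 0:
            raise ValueError(
                f"{self.gene_id}: need m0 > A >= 0 to keep mRNA positive "
                f"(m0={self.m0}, A={self.amplitude})"
            )
        if self.protein_noise_factor < 1:
            raise ValueError(f"{self.gene_id}: protein noise factor must be >= 1")
        if self.log2_noise_sd < 0:
            raise ValueError(f"{self.gene_id}: negative noise sd")

    @property
    def true_k_d(self) -> float:
        if isinstance(self.true_halflife, StepHalfLife):
            raise ValueError("constant k_d undefined for a step-function half-life")
        return LN2 / self.true_halflife

    def mrna(self, t) -> np.ndarray:
        """Noise-free mRNA concentration at time(s) t."""
        t = np.asarray(t, float)
        return self.m0 + self.amplitude * np.sin(2 * np.pi * t / self.period_T + self.phase)


def sinusoid_mrna(gene: SyntheticGene, dt: float = 1.0) -> MinuteGrid:
    """Noise-free mRNA grid for a synthetic gene over one period."""
    n = round(gene.period_T / dt)
    times = np.arange(n + 1) * dt
    return MinuteGrid(gene.gene_id, gene.period_T, dt, gene.mrna(times))


def square_wave_mrna(
    gene_id: str,
    low: float,
    high: float,
    t_on: float,
    t_off: float,
    period_T: float,
    dt: float = 1.0,
) -> MinuteGrid:
    """Piecewise-constant mRNA grid (high on [t_on, t_off), low elsewhere).

    Piecewise-constant forcing admits a piecewise-exponential analytic
    solution, which makes it the natural companion for testing the
    step-function half-life machinery.
    """
    if not (0 <= t_on < t_off <= period_T):
        raise ValueError("need 0 <= t_on < t_off <= T")
    n = round(period_T / dt)
    times = np.arange(n + 1) * dt
    values = np.where((times >= t_on) & (times < t_off), high, low)
    return MinuteGrid(gene_id, period_T, dt, values.astype(float))


def analytic_periodic_protein(
    m0: float, A: float, omega: float, phi: float, k_trans: float, k_d: float
):
    """Closed-form periodic solution of the kinetic model for sinusoidal mRNA.

    Returns a callable P(t).  The oscillatory response is attenuated by
    1/sqrt(k_d^2 + omega^2) and lagged by atan(omega/k_d): fast-decaying
    proteins track their mRNA, stable proteins average it out.
    """
    if not k_d > 0:
        raise ValueError("k_d must be positive")
    gain = A / np.hypot(k_d, omega)
    lag = np.arctan2(omega, k_d)

    def P(t):
        t = np.asarray(t, float)
        out = k_trans * (m0 / k_d + gain * np.sin(omega * t + phi - lag))
        return float(out) if out.ndim == 0 else out

    return P


def simulate_expression(
    genes: list[SyntheticGene],
    sample_times,
    seed: int,
) -> tuple[list[ExpressionSeries], dict[str, GeneAverages]]:
    """Simulate measured log2-ratio series plus a gene-averages table.

    The log2 ratio is taken relative to the gene's true average mRNA,
    with additive Gaussian noise of the gene's ``log2_noise_sd``; the
    averages table carries the true means (the average protein level is
    the analytic period mean k_trans * m0 / k_d).  Fully reproducible
    for a fixed seed.
    """
    sample_times = np.asarray(sample_times, float)
    rng = np.random.default_rng(seed)
    series = []
    averages = {}
    for g in genes:
        if np.any(sample_times < 0) or np.any(sample_times > g.period_T):
            raise ValueError(f"{g.gene_id}: sample times must lie within [0, T]")
        m = g.mrna(sample_times)
        log2 = np.log2(m / g.m0) + rng.normal(0.0, g.log2_noise_sd, len(sample_times))
        series.append(ExpressionSeries(g.gene_id, sample_times, log2))
        if isinstance(g.true_halflife, StepHalfLife):
            mean_protein = g.true_k_trans * g.m0 * g.true_halflife.theta2 / LN2
        else:
            mean_protein = g.true_k_trans * g.m0 / g.true_k_d
        averages[g.gene_id] = GeneAverages(g.gene_id, g.m0, mean_protein)
    return series, averages


def simulate_measured_protein(
    values: np.ndarray,
    sample_times,
    grid_dt: float = 1.0,
    factor: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Western-blot-like measurement of a protein trajectory.

    Samples the trajectory at ``sample_times`` (grid-aligned), applies
    independent multiplicative errors drawn log-uniformly from
    [1/factor, factor] — the stated accuracy of band quantification —
    and rescales the result to unit mean (band intensities are relative
    units).
    """
    if factor < 1:
        raise ValueError("noise factor must be >= 1")
    sample_times = np.asarray(sample_times, float)
    idx = np.rint(sample_times / grid_dt).astype(int)
    if np.any(np.abs(idx * grid_dt - sample_times) > 1e-9):
        raise ValueError("sample times must lie on the trajectory grid")
    sampled = np.asarray(values, float)[idx]
    rng = np.random.default_rng(seed)
    u = np.exp(rng.uniform(-np.log(factor), np.log(factor), len(sampled)))
    noisy = sampled * u
    return noisy / noisy.mean()


def random_gene_set(
    n_genes: int,
    period_T: float = 60.0,
    seed: int = 0,
    log2_noise_sd: float = 0.0,
    halflife_range: tuple[float, float] = (5.0, 300.0),
) -> list[SyntheticGene]:
    """A reproducible cohort of sinusoidal genes with varied kinetics.

    Baselines, amplitudes, phases, half-lives (log-uniform over
    ``halflife_range``) and translation rates are drawn once from the
    seeded generator; the defaults span the kinetic regimes seen in
    yeast (half-lives from minutes to hours, mRNA levels of a few
    molecules per cell).
    """
    rng = np.random.default_rng(seed)
    genes = []
    lo, hi = halflife_range
    for i in range(n_genes):
        m0 = rng.uniform(2.0, 50.0)
        amp = rng.uniform(0.2, 0.8) * m0
        genes.append(
            SyntheticGene(
                gene_id=f"SYN{i:04d}",
                true_k_trans=rng.uniform(0.05, 5.0),
                true_halflife=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                m0=m0,
                amplitude=amp,
                period_T=period_T,
                phase=rng.uniform(0.0, 2.0 * np.pi),
                log2_noise_sd=log2_noise_sd,
            )
        )
    return genes


def write_dataset(genes, sample_times, seed: int, outdir) -> dict:
    """Emit expression/averages/half-life TSVs plus a ground-truth JSON dict."""
    from pathlib import Path
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, averages = simulate_expression(genes, sample_times, seed)

    expr = pd.DataFrame(
        [s.values for s in series],
        index=pd.Index([s.gene_id for s in series], name="gene"),
        columns=[f"{t:g}" for t in np.asarray(sample_times, float)],
    )
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    pd.DataFrame(
        {
            "gene": [g.gene_id for g in genes],
            "mean_mrna": [averages[g.gene_id].mean_mrna for g in genes],
            "mean_protein": [averages[g.gene_id].mean_protein for g in genes],
        }
    ).to_csv(outdir / "averages.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene": [g.gene_id for g in genes],
            "observed_halflife_min": [
                g.true_halflife if not isinstance(g.true_halflife, StepHalfLife) else g.true_halflife.theta2
                for g in genes
            ],
        }
    ).to_csv(outdir / "halflives.tsv", sep="\t", index=False)

    truth = {
        g.gene_id: {
            "k_trans": g.true_k_trans,
            "halflife": g.true_halflife
            if not isinstance(g.true_halflife, StepHalfLife)
            else list(g.true_halflife.as_tuple()),
            "m0": g.m0,
            "amplitude": g.amplitude,
            "phase": g.phase,
            "period_T": g.period_T,
        }
        for g in genes
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
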