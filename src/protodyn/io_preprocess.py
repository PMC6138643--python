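"""Reading expression tables and converting log2 ratios to concentration grids.

Gene-expression time-courses are typically reported as log2 ratios
``L_i(t)`` relative to an asynchronous reference.  To feed the kinetic
model they must be converted to absolute mRNA concentrations
[molecules/cell] using a literature value for the cell-cycle average
concentration, and then resampled by linear interpolation onto a uniform
minute grid spanning one period ``T``.

The conversion is

    ``M_i(t) = 2^{L_i(t)} * <M_i> / <2^{L_i}>``

where ``<.>`` denotes the arithmetic mean over the gene's measured time
points, so that the mean of the transformed values equals the literature
average exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionSeries",
    "MinuteGrid",
    "GeneAverages",
    "read_expression_table",
    "read_averages_table",
    "log2_to_concentration",
    "interpolate_to_minute_grid",
]


@dataclass(frozen=True)
class ExpressionSeries:
    """A per-gene measured time series.

    ``values`` holds log2 ratios when freshly read, or concentrations
    [molecules/cell] after :func:`log2_to_concentration`.
    """

    gene_id: str
    times: np.ndarray  # minutes, strictly increasing
    values: np.ndarray  # same length as times

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(times) != len(values):
            raise ValueError(
                f"{self.gene_id}: {len(times)} times but {len(values)} values"
            )
        if len(times) < 2:
            raise ValueError(f"{self.gene_id}: need at least 2 measured points")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{self.gene_id}: times must be strictly increasing")
        if np.any(times < 0):
            raise ValueError(f"{self.gene_id}: negative time point")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MinuteGrid:
    """Concentrations on the closed uniform grid 0, dt, ..., T.

    The grid has ``N = T/dt`` intervals and ``N+1`` points; the point at
    ``T`` duplicates the period start under the periodic boundary
    condition, so period averages use points ``0..N-1`` only.
    """

    gene_id: str
    period_T: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.dt <= 0 or self.period_T <= 0:
            raise ValueError("period_T and dt must be positive")
        n = self.period_T / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"dt={self.dt} does not divide T={self.period_T}")
        if len(values) != round(n) + 1:
            raise ValueError(
                f"{self.gene_id}: expected {round(n) + 1} grid values, got {len(values)}"
            )
        if np.any(values < 0):
            raise ValueError(f"{self.gene_id}: negative concentration on grid")

    @property
    def n_intervals(self) -> int:
        return round(self.period_T / self.dt)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_intervals + 1) * self.dt

    def period_mean(self) -> float:
        """Mean over points 0..N-1 (the wrapped endpoint is excluded)."""
        return float(np.mean(self.values[:-1]))


@dataclass(frozen=True)
class GeneAverages:
    """Literature cell-cycle average mRNA and protein concentrations."""

    gene_id: str
    mean_mrna: float  # molecules/cell
    mean_protein: float  # molecules/cell

    def __post_init__(self) -> None:
        if not (self.mean_mrna > 0 and self.mean_protein > 0):
            raise ValueError(
                f"{self.gene_id}: average concentrations must be strictly positive"
            )


def read_expression_table(path) -> tuple[list[ExpressionSeries], list[str]]:
    """Read a TSV expression matrix into per-gene series.

    The first column is ``gene``; the remaining column headers are time
    points in minutes.  Empty cells are treated as missing measurements
    and dropped from that gene's series.

    Returns
    -------
    (series, skipped) where ``skipped`` lists gene ids with fewer than
    two valid measurements.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected a gene column and at least 2 time columns")
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric time in header: {exc}") from exc
    gene_col = df.columns[0]
    dup = df[gene_col][df[gene_col].duplicated()]
    if len(dup):
        first_dup = dup.iloc[0]
        line = int(dup.index[0]) + 2  # header is line 1
        raise ValueError(f"{path}: duplicate gene id {first_dup!r} at line {line}")

    series: list[ExpressionSeries] = []
    skipped: list[str] = []
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    for gene, row in zip(df[gene_col], mat):
        ok = np.isfinite(row)
        if ok.sum() < 2:
            skipped.append(gene)
            continue
        series.append(ExpressionSeries(gene, times[ok], row[ok]))
    return series, skipped


def read_averages_table(path) -> dict[str, GeneAverages]:
    """Read a TSV with columns gene, mean_mrna, mean_protein."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "mean_mrna", "mean_protein"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out: dict[str, GeneAverages] = {}
    for rec in df.itertuples(index=False):
        if rec.gene in out:
            raise ValueError(f"{path}: duplicate gene id {rec.gene!r}")
        out[rec.gene] = GeneAverages(rec.gene, float(rec.mean_mrna), float(rec.mean_protein))
    return out


def log2_to_concentration(series: ExpressionSeries, mean_mrna: float) -> ExpressionSeries:
    """Convert measured log2 ratios to mRNA concentrations.

    M(t) = 2^L(t) * mean_mrna / mean(2^L), with the mean taken over the
    series' measured points.  The arithmetic mean of the output over the
    measured points therefore equals ``mean_mrna`` exactly.
    """
    if not mean_mrna > 0:
        raise ValueError(f"{series.gene_id}: mean_mrna must be positive")
    if not np.all(np.isfinite(series.values)):
        raise ValueError(f"{series.gene_id}: non-finite log2 ratio")
    ratios = np.exp2(series.values)
    conc = ratios * (mean_mrna / ratios.mean())
    return ExpressionSeries(series.gene_id, series.times, conc)


def interpolate_to_minute_grid(
    series: ExpressionSeries, period_T: float, dt: float = 1.0
) -> MinuteGrid:
    """Linearly interpolate a concentration series onto the grid 0..T.

    Beyond the measured window the series is treated as periodic with
    period ``T``: grid points after the last measurement interpolate
    between (t_last, v_last) and (t_first + T, v_first), and likewise
    before the first measurement.
    """
    t, v = series.times, series.values
    if t[-1] > period_T:
        raise ValueError(
            f"{series.gene_id}: last measurement at {t[-1]} min exceeds period "
            f"T={period_T}; truncate the series explicitly first"
        )
    if dt > np.min(np.diff(t)):
        raise ValueError(
            f"{series.gene_id}: dt={dt} exceeds the smallest sampling interval"
        )
    # periodic extension: a wrapped knot on each side the measurements miss
    t_ext, v_ext = t, v
    if t[0] > 0:
        t_ext = np.concatenate([[t[-1] - period_T], t_ext])
        v_ext = np.concatenate([[v[-1]], v_ext])
    if t[-1] < period_T:
        t_ext = np.concatenate([t_ext, [t[0] + period_T]])
        v_ext = np.concatenate([v_ext, [v[0]]])
    n = round(period_T / dt)
    grid_t = np.arange(n + 1) * dt
    grid_v = np.interp(grid_t, t_ext, v_ext)
    return MinuteGrid(series.gene_id, float(period_T), float(dt), grid_v)
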