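# Methods

## Kinetic model and boundary condition

The package models translation and degradation of each protein
independently with the linear kinetic equation

    d[P]/dt = k_trans [M](t) − k_d [P](t),

where `[M](t)` is the mRNA concentration [molecules/cell], `k_trans`
the translation rate [proteins·mRNA⁻¹·min⁻¹] and `k_d = ln2/ϑ_d` the
first-order degradation rate [min⁻¹] of a protein with half-life `ϑ_d`
[min]. The model deliberately omits ribosome density/occupancy and
codon-usage covariates: they enter only as descriptors whose
correlation with the estimated rates can be reported, not as model
inputs.

Instead of the steady-state closure `dP/dt = 0`, the equation is closed
with the periodic boundary condition `[P](0) = [P](T)`: after one
period `T` (one cell cycle, or one treatment-and-recovery course) the
system returns to baseline. Substituting `R = P/k_trans` removes the
unknown translation rate from the dynamics; `R` is solved first and
`k_trans = ⟨P⟩/⟨R⟩` is recovered afterwards from the literature average
protein concentration. Consequently the *shape* of the prediction comes
entirely from the expression time-course and the half-life, while its
*scale* is pinned to the average-abundance compendium.

## Numerics

**Discretisation.** The trapezoidal (Crank–Nicolson) rule on a uniform
grid of step `Δt` (default 1 min; `Δt` must divide `T`) gives

    R_{n+1} = a R_n + b (m_{n+1} + m_n),
    a = (2 − k_d Δt)/(2 + k_d Δt),  b = Δt/(2 + k_d Δt),

second-order accurate and A-stable; `k_d Δt < 2` is enforced so that
`a ∈ (−1, 1)`. The grid is closed (`N+1` points, `0..T`); because the
point at `T` duplicates the period start, all period averages use
points `0..N−1`.

**Fixed-point iteration.** One sweep over the period is the affine map
`R(T) = a^N R(0) + c`, a contraction with factor
`a^N ≈ exp(−k_d T)`. Starting from `R(0) = 0`, `R(T)` is fed back as
the next sweep's start until `|R(T) − R(0)| ≤ 5·10⁻¹⁰` (the default
`tol`). The iteration count therefore grows like
`log(1/tol)/(k_d T)`; for very stable proteins (`k_d T ≪ 1`) the
closed-form fixed point `R(0) = c/(1 − a^N)` is available
(`solve_periodic_R_closed_form`), is exact in one additional sweep, and
is used automatically by the pipeline when the iteration does not
converge. Two consequences are tested exactly rather than
approximately: the discrete conservation identity
`⟨R⟩_{0..N−1} = ⟨m⟩_{0..N−1}/k_d` (obtained by summing the recurrence
around the cycle), and its time-varying generalisation
`⟨k·R⟩ = ⟨m⟩`.

**Degenerate inputs.** `k_d Δt ≥ 2`, non-positive half-lives, all-zero
mRNA and `a^N` numerically 1 each raise informative errors; nothing is
silently clamped.

## Preprocessing

Measured log2 ratios `L(t)` are converted by
`M(t) = 2^{L(t)} ⟨M⟩ / ⟨2^L⟩`, with both averages taken arithmetically
over that gene's *measured* points, so the measured-point mean equals
the literature average exactly. Conversion precedes interpolation;
under uneven sampling the minute-grid mean may therefore differ
slightly from `⟨M⟩`, which is precisely what makes `TR_diff` non-zero
for real data. Missing cells are dropped per gene (piecewise-linear
interpolation across the gap is equivalent to imputing on the line).
Beyond the measured window the series is treated as periodic: the
segment from the last measurement to `t_first + T` interpolates toward
the first measured value. Wrap knots are added only when the
measurements do not already cover `t = 0` or `t = T`.

## Periodicity

The per-gene statistic is the floating-mean (generalised) Lomb–Scargle
periodogram normalised by the sample variance (ddof = 1), evaluated on
a candidate grid of 30–150 min in 1-min steps. Under a Gaussian
white-noise null the power at a fixed period is approximately
exponential with unit mean, so `z = exp(−power)` behaves as a p-value
(verified: KS distance to uniform ≈ 0.04 at n = 1000 simulated noise
genes). Treating `power = −log z` as a per-gene log-likelihood of
periodicity and summing across genes gives a total log-likelihood per
period; its argmax is the consensus period, with ties broken toward the
smaller period. A literal amplitude-form quadrature statistic
(trapezoidal integrals, overall square root) is retained under
`formula="amplitude"` for comparison; it is not scale-invariant and
its peak leaks a few minutes off the true period because it lacks the
phase correction, which is why the power form is the default for
likelihoods and significance.

## Half-life correction

Observed half-lives are mapped to rates `k_obs = ln2/ϑ_obs` (negative
observations give negative rates, infinite ones give zero). The
measurement is modelled as `N(k_true, σ_k²)` with
`σ_k = ln2/300 min⁻¹` — the rate of the longest reliably measurable
half-life; an alternative error scale is a parameter for sensitivity
analysis. Imposing positivity of the true rate, the corrected rate is
the truncated-normal mean

    k_corr = k_obs + σ_k · φ(α)/(1 − Φ(α)),  α = −k_obs/σ_k,

evaluated via `erfcx` so the inverse Mills ratio stays accurate for
strongly negative observations; a dense-quadrature oracle backs the
closed form in the tests to 1e-9 relative. The corrected half-life is
always positive and finite: an unmeasurably slow decay (`k_obs = 0`)
maps to `300·√(π/2) ≈ 376 min`. The relative correction is below 1%
for observed half-lives up to ~120 min, reaches ~3% at 150 min, and is
substantial beyond 300 min or for negative observations.

## Translation rates

`TR_ss = k_d ⟨P⟩/⟨M⟩` is the steady-state estimate; `TR_tc` is
definitionally the `k_trans` produced by the periodic solver (it is
packaged, not recomputed). By the conservation identity,
`TR_tc = k_d ⟨P⟩/⟨m_grid⟩`, so `TR_diff` measures exactly the
discrepancy between the interpolated-grid mRNA mean and the literature
average — zero on synthetic data that satisfies the model, positive
when sampling, synchronisation artefacts or time-varying degradation
intervene. Genes with `TR_diff > 0.1` are flagged divergent (the
reporting threshold is a parameter). Correlation reports use Pearson
and Spearman with the standard asymptotic p-values; for n ≤ 10 the
Spearman p-value is computed by full permutation enumeration.

## Step-function half-life fitting

Post-translational regulation is modelled as a periodic two-level
half-life: `ϑ¹` inside the closed, modulo-`T` window `[t₀, t₀+K]`, `ϑ²`
outside. The generalised trapezoidal step evaluates the rate at both
interval endpoints,

    R_{n+1} = [(2 − k_n Δt) R_n + Δt (m_{n+1}+m_n)] / (2 + k_{n+1} Δt),

and reduces bit-for-bit to the constant-rate recurrence when
`ϑ¹ = ϑ²`. Each candidate tuple is solved with the one-pass closed-form
fixed point (`R(0) = c/(1 − Π aₙ)`), vectorised across all `(t₀, K)`
windows for one `(ϑ¹, ϑ²)` pair at a time.

The fit criterion is the sum of squared differences between unit-mean
normalised profiles at the measured time points: band intensities from
a blot are relative, and unit-mean normalisation also cancels
`k_trans`. A `1 − Pearson r` criterion is available as a flag. The
default search is exhaustive — `ϑ¹, ϑ² ∈ {1..40}` min, `t₀ ∈ {0..T−1}`,
`K ∈ {1..T}`, 1-min steps (≈ 5.8M solves for `T = 60`, ~10 s
vectorised); a coarse-to-fine mode (5-min scan, then ±5 min refinement
at 1-min resolution) runs in ~0.1 s and is used for replicate studies.
Ties are broken lexicographically on `(ϑ¹, ϑ², t₀, K)` by scanning in
lexicographic order with strict-improvement updates. Note the model is
only partially identifiable from sparse, noisy profiles: swapping
`(ϑ¹, ϑ²)` while complementing the window yields nearly the same
trajectory, so analyses of fitted windows should classify by which
level is shorter, as the recovery studies here do.

## Synthetic data: what it does and does not emulate

The canonical generator produces sinusoidal transcription
`M(t) = m0 + A sin(2πt/T + φ)` with `m0 > A ≥ 0`, because the linear
model's periodic response to a sinusoid is available in closed form,

    P(t) = k_trans [ m0/k_d + A/√(k_d²+ω²) · sin(ωt + φ − arctan(ω/k_d)) ],

giving an independent oracle for the solver (observed convergence:
error ratio 4.0 when `Δt` halves). A square-wave generator covers
piecewise-constant forcing for the step-half-life machinery. Default
study conditions, chosen to mirror the granularity and error structure
of cell-cycle microarray experiments: `T = 60` min; sampling every
5 min across one period without duplicating the period boundary
(12 points); baselines 2–50 molecules/cell with amplitudes 20–80% of
baseline; half-lives log-uniform on 5–300 min; translation rates
0.05–5 proteins·mRNA⁻¹·min⁻¹; additive Gaussian log2 expression noise
(sd 0.2 in the noisy studies); bounded multiplicative protein
measurement noise, log-uniform within 2-fold. All randomness flows
through one seeded generator.

What passing these tests does *not* show: the generator satisfies the
model by construction — constant rates, stationary sinusoidal
transcription, independent genes, no synchrony decay, no
post-translational regulation except where injected as a step
half-life. Recovery on synthetic data therefore validates the
numerics and the estimators, not the biological adequacy of the model
for any particular real protein. In particular, `k_trans` recovery is
insensitive to expression-shape noise because the estimator depends on
the mRNA mean, which the normalisation pins to the literature average;
on real data the dominant errors come from that compendium and from
the half-lives, not from array noise.

## Known limitations

- Very dynamic expression (characteristic time comparable to `Δt`)
  violates the linear-interpolation premise; higher-resolution input
  reconstruction is out of scope.
- The half-life correction treats the reported degradation rate as the
  quantity with Gaussian error and ignores dilution by growth.
- The step-function fit considers a single window and two levels; more
  complex `ϑ(t)` shapes and joint multi-protein fits are out of scope.
- Identifier matching across the three input tables is exact-string;
  users must pre-map gene identifiers.
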