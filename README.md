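# protodyn

Predict dynamic protein abundance time-courses from gene-expression
time-courses and protein half-lives — without the steady-state
assumption.

## The problem

Protein concentrations are what matter physiologically, but they are
hard to measure genome-wide; mRNA levels are easy. The usual shortcut —
assume the proteome is at steady state, so `[P] = k_trans [M] / k_d` —
fails exactly where things are interesting: whenever transcript and
protein levels change dynamically, as during the cell cycle.

`protodyn` solves the kinetic equation

```
d[P_i]/dt = k_trans,i [M_i(t)] − k_d,i [P_i(t)],      k_d,i = ln(2)/ϑ_d,i
```

under a *return-to-baseline* boundary condition `[P_i](0) = [P_i](T)`
instead — true for cyclic phenomena (the cell cycle with period `T`)
and for treatment/recovery time courses. Dividing by the unknown
translation rate gives `R(t) = P(t)/k_trans`, which obeys a
`k_trans`-free equation. Trapezoidal discretisation yields the
recurrence

```
R(t+Δt) = (2 − k_d Δt)/(2 + k_d Δt) · R(t) + Δt/(2 + k_d Δt) · (M(t+Δt) + M(t))
```

which is swept over one period by fixed-point iteration (feeding `R(T)`
back as `R(0)`) until `|R(T) − R(0)| ≤ 5·10⁻¹⁰`. The translation rate
then follows from period averages, `k_trans = ⟨P⟩/⟨R⟩`, using a
literature value for the average protein concentration, and
`P(t) = k_trans R(t)` is the predicted minute-resolution protein
time-course.

Around this core the package provides:

- **io_preprocess** — read log2-ratio expression TSVs, convert to
  concentrations via `M(t) = 2^L(t) ⟨M⟩ / ⟨2^L⟩`, and linearly
  interpolate onto a 1-minute grid with periodic wrap.
- **periodicity** — floating-mean Lomb–Scargle periodograms for
  unevenly sampled series, `z = exp(−power)` significance, and a
  maximum-likelihood consensus period across genes.
- **halflife** — correct noisy (possibly negative or huge) observed
  half-lives via the mean of a truncated normal on the degradation
  rate, with `σ_k = ln2/300 min⁻¹`.
- **rates** — steady-state vs time-course translation rates and their
  relative divergence `TR_diff = |TR_ss − TR_tc| / min(TR_ss, TR_tc)`.
- **posttranslational** — fit a periodic two-level step-function
  half-life `(ϑ¹, ϑ², t₀, K)` to a measured (western-blot-like) protein
  profile by exhaustive grid search, detecting cell-cycle-stage-specific
  degradation.
- **synthetic** — seeded generators with known ground truth and the
  closed-form sinusoid-response oracle, so the whole pipeline is
  testable offline.

## Worked example

Simulate three genes with known kinetics, run the pipeline, and compare:

```
$ protodyn simulate --n-genes 3 --seed 42 --out data
$ protodyn run --expression data/expression.tsv --averages data/averages.tsv \
               --halflives data/halflives.tsv --period 60 --out run
$ head -4 run/rates.tsv
gene     tr_ss               tr_tc               tr_diff                 divergent
SYN0000  4.301342436290423   4.3013424362911525  1.695271867735034e-13   False
SYN0001  3.941018311120922   3.941018311121091   4.281987202820838e-14   False
SYN0002  3.3125462595487742  3.3125462595501878  4.2672187622378963e-13  False
```

Per-gene diagnostics live in `run/manifest.json`:

```
SYN0000 k_trans=4.3013 k_d=0.00798 sweeps=62 residual=3.8e-10
SYN0001 k_trans=3.9410 k_d=0.08204 sweeps=7  residual=1.2e-10
SYN0002 k_trans=3.3125 k_d=0.00488 sweeps=98 residual=4.8e-10
```

against the generating truth `k_trans = 4.3001, 3.9410, 3.2371`. The
short-half-life gene (8.4 min) is recovered to machine precision; the
145-min gene is off by 2.3% because the pipeline's half-life correction
(which assumes measurement error in the observed rate) slightly shifts
long half-lives. `tr_diff ≈ 0` here because the simulated genes satisfy
the model exactly; real genes with condition-specific regulation show
`tr_diff > 0.1` and are flagged `divergent`. `run/predictions.tsv`
holds the minute-resolution protein trajectories, and
`run/skipped.tsv` accounts for every input gene not predicted.

To probe post-translational regulation for one protein with a measured
profile (TSV with columns `t_min`, `intensity_au`):

```
$ protodyn fit-halflife --gene CLB2 --expression data/expression.tsv \
    --averages data/averages.tsv --measured clb2_blot.tsv --period 60 --out fit.json
```

which reports the best-fitting `(ϑ¹, ϑ², t₀, K)` — e.g. a 1-minute
half-life outside a stability window — along with the normalised
predicted and measured profiles.

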