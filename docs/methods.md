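# Methods

This note documents the models, parameter choices and numerical
decisions behind `npqcell`, and what the synthetic validation does and
does not establish about real data.

## Scoring model

A cell's F_m′ trace y ∈ ℝ⁹¹ (one sample per saturating pulse of the
reference 15-min high-light / 15-min dark protocol, pulses every 20 s
starting at t = 0) is first normalized to sum 1, making traces
comparable across cells of different brightness and turning each into a
probability-distribution-like vector with entries near 1/91.

**Dictionary.**  Traces are modelled as sparse linear combinations of
N_D = 10 learned unit-norm atoms by minimizing
½‖Y − DX‖²_F + λ‖X‖₁ with λ = 10⁻⁶.  The optimization alternates
exact per-column lasso (least-angle regression; `LassoLars` with
α = λ/T so the unscaled objective above is what is optimized) with a
block atom update d_j ← E_j x_j/‖E_j x_j‖, the exact minimizer of the
residual over unit-norm atoms.  Both half-steps decrease the objective,
so the recorded fit history is non-increasing; iteration stops at a
relative objective change below 10⁻⁸ (max 200 iterations).  Atoms are
initialized from data columns by a seeded farthest-point rule (first
column random, then greedy max–min distance): purely random columns can
draw duplicate waveforms and strand the alternating minimization in a
local minimum where one trace family has no atom.  Dead atoms (zero
code row) are re-seeded with the worst-reconstructed column, which
leaves the objective unchanged.

The *reconstruction error* of a trace is ‖y − Dx‖₂² on the
sum-normalized scale; the dictionary-size selection rule takes the
smallest candidate whose mean error over seeds is ≤ 2 × 10⁻⁴.  Under
the default synthetic conditions the 10-atom dictionary reaches
~4 × 10⁻⁶, two orders below the threshold, because the generator's
within-component kinetic dispersion is narrower than real data's.

**LDA.**  Class-size-weighted between-class scatter S_B and pooled
within-class scatter S_W are formed from the 10-dimensional codes of
all four labeled populations; the projection T ∈ ℝ¹⁰ˣ³ solves
S_B v = μ S_W v (c − 1 = 3 directions for c = 4 classes) via a
symmetric-definite generalized eigendecomposition.  S_W is regularized
as S_W + 10⁻⁴·(tr S_W/10)·I.  The scale-aware ridge matters: atoms are
highly collinear at λ = 10⁻⁶, so the code distribution has
near-degenerate directions along which both scatters are tiny; with a
negligible ridge the eigenproblem happily amplifies them (projection
column norms ~10³) and scores become sensitive to lasso active-set
switches.  The 10⁻⁴ relative ridge bounds column norms at ~5 and leaves
class separation and amplitude recovery unchanged.  Eigenvector signs
are fixed by making the largest-magnitude entry positive, for
determinism.

**Axis alignment.**  In LDA space the transfer matrix R's columns are
the first principal directions of the Pop-qT, Pop-qE and Pop-qI clouds
(in that axis order), each sign-oriented toward its class centroid
relative to the pooled other classes.  R is an oblique change of basis
— class clouds need not be orthogonal — guarded by a condition-number
bound (10³).  After the R⁻¹ transform the per-axis origins are the
means over the cells biologically guaranteed to lack each component:

* q̃T origin: pooled {Pop-qE, Pop-qI, Pop-0} (kinase-knockout
  populations, no state transitions);
* q̃E origin: Pop-qI only (never high-light treated, no LHCSR; Pop-0 is
  excluded because late protocol repeats can carry slight qE);
* q̃I origin: pooled {Pop-qE, Pop-qT, Pop-0} (late repeats,
  photoinhibition-free).

These three class-mean zero conditions hold to machine precision by
construction and are asserted to 10⁻¹⁰ in the tests.  A final sign
check flips an axis if its expressing class were to score negative.
Origins and R are frozen at training time; scoring new data never
recomputes them (no implicit batch correction).

## Synthetic generator

The generator emulates the four reference populations and mixed
WT-like populations with known ground truth.  A noise-free trace is

F(t_k) = F₀ · (1 − A_qE·e(t_k) + A_qT·g(t_k) − A_qI·h(t_k)),

an additive combination mirroring the linear-combination working
hypothesis the scoring pipeline tests (a multiplicative variant is
deliberately not the default).  The unit bases are piecewise
exponentials sampled at the pulse times, each phase continuing from the
previous phase's end value:

* **qE**: rise (1 − e^(−s/τ_rise))·(f + (1 − f)e^(−s/τ_transitory)) in
  light — the second factor produces the transitory maximum with
  partial in-light relaxation toward fraction f — and decay
  e^(−s/τ_relax) in dark.  Defaults τ_rise = 30 s, τ_transitory =
  300 s, f = 0.6, τ_relax = 30 s (seconds-scale onset/recovery).  In a
  light phase entered with value e₀ > 0 the basis continues as
  e₀ + (1 − e₀)·raw(s), identical to the plain product form on the
  single-light-phase reference protocol.
* **qT**: 1 − (1 − g₀)e^(−s/τ_rise) in light (τ_rise = 200 s),
  g₀·e^(−s/τ_relax) in dark (τ_relax = 300 s) — minutes-scale rise and
  relaxation.
* **qI**: as qT with τ_rise = 900 s but frozen in darkness (no
  recovery within the protocol).

Units: time constants in seconds, amplitudes dimensionless (fractional
F_m′ change), F₀ in arbitrary fluorescence units.

Per-cell amplitudes are log-normal around population medians —
positive support with a tunable coefficient of variation.  Defaults:
Pop-qE median A_qE = 0.45 (CV 0.35), Pop-qT median A_qT = 0.30
(CV 0.20), Pop-qI median A_qI = 0.35 (CV 0.25), WT co-expresses
A_qE = 0.35 and A_qT = 0.30; measurement noise is i.i.d. multiplicative
Gaussian with σ = 0.02 per sample.  The medians reproduce the typical
fractional F_m′ excursions of the four populations and the ~20%/~35–40%
cell-to-cell dispersions of qT/qE scores; amplitude draws that would
push F_m′ within 5% of zero (A_qE·max e + A_qI·max h ≥ 0.95) are
rejection-resampled, truncating the extreme log-normal upper tail.
Repeat pairs share per-cell amplitudes and differ only in noise
realization, modelling two consecutive acquisitions of the same
immobilized cells.  Movies render each cell as a constant-radius disk
(intensity ∝ F_m′) over a uniform background, one frame per pulse.

Everything is a pure function of (spec, protocol, seed); composite
experiments split a single master seed with `numpy` seed sequences.

## What the synthetic validation shows — and does not

Passing tests establish that the pipeline recovers what it is designed
to recover *when its own working hypothesis holds*: traces that truly
are linear combinations of stereotyped component kinetics, identical
kinetics across cells, disk-shaped non-overlapping cells, stationary
fields of view.  Real data add kinetic-shape dispersion between cells,
irregular morphology and touching cells, background structure and
photophysics the generator does not model; the reconstruction-error
margin and classification accuracy on synthetic data are therefore
upper bounds on real-data behavior, not predictions.

One genuine limitation surfaces even synthetically: sum-normalization
couples components.  A strong quencher shrinks the trace sum, which
rescales the whole normalized trace — including the qT bump — so the
q̃T score of a mixture behaves approximately like
A_qT·(a + b·A_qE) with b/a ≈ 1.3.  With the default WT dispersions
this keeps r(A_qT, q̃T) around 0.9 (0.86–0.94 across seeds) rather than
near 1, compresses score CVs by ~25% relative to amplitude CVs, and
attenuates planted qE–qT anticorrelations.  The coupling is a property
of any linear pipeline on ratio-normalized data, not of the
implementation.

## Numerical choices and defaults

| Parameter | Default | Notes |
|---|---|---|
| min cell area | 5 px | strictly smaller cells discarded |
| isolation D | 0.01 | nearest-neighbour threshold on sum-normalized traces; ties kept |
| N_D, λ | 10, 10⁻⁶ | dictionary size and sparsity penalty |
| n_samples | 300 | balanced dictionary subsample (75/class) |
| LDA ridge | 10⁻⁴ (relative) | scale-aware S_W shrinkage |
| R condition bound | 10³ | rejects near-degenerate class geometry |
| grid | 8×8, > 3 points | grid-trace maps; bounds default to the 1–99 percentile rectangle |
| trend fit | total least squares | both axes carry comparable noise; OLS selectable |
| variance test | median-centered Levene | robust; F-test selectable |

Other conventions: phases are half-open [start, start+duration) with
the final instant mapped to the last phase, so a pulse at the
light→dark boundary samples the dark phase; the first pulse fires at
t = 0 (hence 91 samples over 1800 s); isolation filtering runs on
sum-normalized traces *after* the area filter and *before*
subsampling; pulse-window frame aggregation is the mean; masks use 0
for background with consecutive labels 1..K; the dictionary is trained
on the balanced subsample while LDA uses all surviving labeled codes;
codes are not sign-constrained.

Problem sizes used in the validation suite and the reproduction script
— 300 cells per training population, 200 per held-out class, 300-cell
WT mixtures, 150-cell repeat pairs and 150-cell 512×512 movies — were
chosen to estimate every statistic comfortably while keeping a full run
in tens of seconds.
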