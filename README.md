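# npqcell

Single-cell phenotyping of nonphotochemical quenching (NPQ) from
chlorophyll-fluorescence time-lapse imaging.

## The problem

When a photosynthetic cell is hit by high light it protects itself
through several concurrent processes that all change its chlorophyll-a
fluorescence yield: **qE** (high-energy quenching — seconds-scale,
rapidly reversible heat dissipation driven by LHCSR proteins), **qT**
(state transitions — minutes-scale redistribution of LHCII antenna
between the photosystems, changing the PSII cross-section) and **qI**
(photoinhibition — slowly induced, essentially non-recovering quenching
from PSII photodamage).  In a pulse-amplitude-modulated experiment a
saturating pulse every 20 s probes the maximal fluorescence yield F_m′;
over a 15-min high-light / 15-min dark protocol this gives a 91-point
F_m′ trace per cell in which all active components are superimposed.

`npqcell` separates them.  Given movies (or pre-extracted traces) of
four reference populations each expressing at most one component —
*Pop-0* (none), *Pop-qE*, *Pop-qT*, *Pop-qI* — it learns a scoring map
that turns any F_m′ trace into a 3-vector (q̃T, q̃E, q̃I) of per-component
scores, then quantifies cell-to-cell heterogeneity and trait
correlations that population averages hide.

## The method

1. **Segmentation / extraction** — watershed segmentation of the first
   movie frame; per-cell mean intensity in each saturating-pulse window
   gives the F_m′ trace.
2. **Filtering** — cells smaller than 5 px discarded; traces normalized
   to sum 1; KD-tree outlier removal (a trace is dropped when its
   nearest neighbour is further than D = 0.01).
3. **Sparse dictionary learning** — a class-balanced subsample of
   n = 300 traces is factorized by

   min_{D,X} ½‖Y − DX‖²_F + λ‖X‖₁,   N_D = 10 unit-norm atoms, λ = 10⁻⁶,

   alternating least-angle-regression sparse coding with a block
   unit-norm atom update.  The code x ∈ ℝ¹⁰ of a trace is its feature
   vector.
4. **Discriminant projection** — multiclass LDA on the labeled codes
   (c = 4 classes) gives a projection T ∈ ℝ¹⁰ˣ³.  The principal
   directions of the Pop-qT / Pop-qE / Pop-qI clouds form an oblique
   transfer matrix R; axis origins are anchored by the populations that
   biologically lack each component.  A cell's score is
   R⁻¹·(Tᵗx) − origins.
5. **Heterogeneity statistics** — repeat-distance matrices
   D_ij = ‖score_i(repeat 3) − score_j(repeat 4)‖ separating measurement
   noise (diagonal) from biological dispersion (off-diagonal, Levene
   test), coefficients of variation, 8×8 grid-trace maps and total-least
   -squares qE–qT trend fits.

A first-class synthetic generator simulates all of this with known
ground truth: phenomenological qE/qT/qI kinetics, log-normal
cell-to-cell amplitude dispersion, multiplicative measurement noise,
aligned repeat pairs and rendered TIFF movies.

## Worked example

Train on four simulated reference populations, then score a synthetic
wild-type-like population co-expressing qE and qT:

```bash
for pop in Pop0 PopQE PopQT PopQI; do
  npqcell simulate --population $pop --n 300 --seed 1 --out $pop.csv
done
npqcell train --pop0 Pop0.csv --pop-qe PopQE.csv --pop-qt PopQT.csv \
              --pop-qi PopQI.csv --seed 1 --out model.json
npqcell simulate --population WT --n 200 --seed 42 --out wt.csv
npqcell score --model model.json --traces wt.csv --out wt_scores.csv
npqcell analyze --scores wt_scores.csv --out report.json
```

The training step reports

```
trained model -> model.json
  traces: 1200 in, 1 removed as isolated
  mean reconstruction error: 3.87e-06
```

i.e. the 10-atom dictionary reconstructs the sum-normalized training
traces far below the 2 × 10⁻⁴ selection threshold.  The analysis report
for the scored WT population reads

```json
"wt_scores.csv": {
  "n_cells": 200,
  "mean_qT": 0.353,  "cv_qT": 0.155,
  "mean_qE": 0.091,  "cv_qE": 0.455,
  "mean_qI": -0.011,
  "qT_qE_trend": {"slope": 0.102, "r": 0.058, "p": 0.415}
}
```

Both components are detected (positive mean q̃T and q̃E; q̃I at the
origin, as no photoinhibition was simulated), with ~16% cell-to-cell
variation in q̃T and ~46% in q̃E.  The trend entry shows that with
independently drawn amplitudes the score-space qE–qT correlation is
null; planting correlated amplitudes recovers the correlation (see
`tests/test_heterogeneity.py`).

The same pipeline runs from movies: `npqcell simulate --movie`,
`npqcell segment`, `npqcell extract`.

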