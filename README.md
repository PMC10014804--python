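# bilat

Analysis pipeline for studying how primary motor cortex (M1) represents
**unimanual versus bimanual arm movements** in intracortical spike
recordings from center-out motor-imagery tasks — together with a generative
cosine-tuning spike simulator, so that every stage of the analysis can be
validated by parameter recovery against known ground truth.

It is written for neurophysiologists and BCI researchers working with
sorted single-unit data from paradigms in which a participant imagines
center-out reaches with the ipsilateral arm, the contralateral arm, or both
arms simultaneously (8 unimanual target directions; 4 × 4 = 16 bimanual
direction pairs; separate blocks per task, several repetitions per target
configuration).

## What it computes

Starting from a spike-event table and a trial table, the pipeline:

1. **Preprocessing** — bins spikes in 20 ms bins, converts to rate (Hz),
   smooths with a 300 ms (SD) Gaussian kernel (truncated ±3 SD,
   edge-renormalized so constants pass through unchanged), selects units
   with grand mean rate > 1 Hz, and forms
   per-configuration *neural responses*
   `R(θ) = mean Go-phase rate − baseline`, where the baseline is the mean
   Prepare-phase rate. A unit is *task-related* when
   `|R| / SD(baseline) > 1` for at least one configuration.
2. **Tuning analysis** — per unit and task:
   - modulation depth `MD = max R − min R`,
   - preferred direction `PD = argmax_θ R(θ)` (grid argmax; a least-squares
     cosine fit is available for off-grid PDs),
   - between-arm `ΔPD` (circular distance, 0–180°),
   - contralateral preference index
     `(max|R|_contra − max|R|_ipsi) / (max|R|_contra + max|R|_ipsi)`
     (+1 = purely contralateral, −1 = purely ipsilateral),
   - bilateral Pearson correlation between the two arms' tuning curves
     (8-direction unimanual, the 4-direction unimanual subset, and 4-point
     bimanual marginal curves obtained by averaging over the other arm's
     directions),
   plus population classifications: preference quadrants across tasks,
   strongly-correlated fractions (cc > 0.75), MD-difference and PD-shift
   summaries.
3. **Decoding** — leave-one-out cross-validated linear SVMs (one-vs-rest)
   on per-trial response vectors: 8-direction unimanual decoders, the
   16-configuration bimanual decoder, and two 4-direction per-arm bimanual
   decoders; reported as row-normalized confusion matrices and Top-N
   accuracies.
4. **Statistics & report** — one-sample/paired t-tests of index and cc
   distributions against zero and across tasks, the OLS fit of
   contralateral on ipsilateral maximum responses (slope, R²), the
   ipsilateral-to-contralateral population response ratio, and a
   `summary.json`/`summary.md` bundle in which every number is recomputable
   from the emitted per-unit CSVs.

The **simulator** generates sessions from known per-unit ground truth:
baseline rate, per-arm cosine tuning `r(θ) = b + m·cos(θ − PD)` clipped at
zero, Poisson spiking through jittered Prepare (1.0–1.5 s), Go (2 s) and
Rest (1.5 s) phases, and a bimanual interaction in which each arm's
modulation is scaled by a gain (default g_ipsi = 0.4 < g_contra = 0.8) and
PDs rotate ±90° on half the units. These planted asymmetries are what the
analysis must recover.

## Worked example

```bash
bilat pipeline --seed 7 --out run/
```

simulates a default 100-unit session (one ipsilateral, one contralateral
and one bimanual block; 8 repetitions per configuration = 256 trials), runs
all stages, and writes `run/summary.md`, which for this seed reads (excerpt):

```
- units analyzed (task-related): 71

## Contralateral preference index
- unimanual: mean +0.028, median +0.017 (n=71)
- bimanual: mean +0.330, median +0.317 (n=71)
- paired_uni_vs_bi: t=-21.60, p=1.12e-32

## Bilateral tuning-curve correlation
- unimanual-4: mean +0.850, median +0.897, strong (cc>thr) fraction 0.775
- bimanual-4: mean +0.559, median +0.892, strong (cc>thr) fraction 0.662

## Decoding (LOOCV linear SVM, top-1 %)
- block1 (bimanual): 43.0% | per-arm ipsi 87.5%, contra 100.0%
```

Read: during unimanual blocks the population shows no meaningful arm
preference (index ≈ 0) and strongly correlated bilateral tuning; in the
bimanual block the planted asymmetric gain suppression shifts the
preference index contra-ward (+0.33, highly significant in the paired
test), the bilateral correlation drops, and the contralateral-direction
decoder outperforms the ipsilateral one — exactly the structure the
generator planted. Library use starts at
`bilat.simulate_session` / `bilat.run_pipeline`; each stage is also an
importable function (see module docstrings).

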