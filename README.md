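# taskphase

Neural populations in lateral prefrontal cortex carry, alongside
stimulus-selective activity, a separate population whose firing tracks the
*phase of the task*: units peak at trial start, after the first stimulus,
toward the expected stimulus switch, after the second stimulus, or at trial
end. `taskphase` is a tested reimplementation of the analysis pipeline that
identifies this organization in trial-aligned single-unit recordings from a
binocular flash suppression (BFS) task, and asks whether it is affected by
perceptual suppression:

1. **Preprocessing** — per-unit, per-condition PSTHs (Gaussian kernel,
   σ = 40 ms, 251 samples per condition), a rank-sum screen that removes
   stimulus-selective units, a low-activity filter (< 1.26 spikes/trial),
   and concatenation into a non-negative units × 1004 response matrix `R`
   (four conditions × 251 samples).
2. **Stability-constrained NNMF** — `R ≈ HW` fit with Lee–Seung
   multiplicative updates inside a split-half bootstrap: per iteration the
   population is randomly halved, both halves are factorized from a shared
   initialization, components are matched across halves by cosine
   similarity (> 0.5), matched components seed the next iteration and the
   rest are re-randomized. The dispersion of the last 15 iterations'
   components (aligned by kernel PCA) gives a per-component variability
   ratio; the number of canonical response patterns (CRPs) K is the
   largest whose median variability over many runs stays below 5%.
3. **CRP assignment** — each unit joins its maximum-cosine CRP; CRPs are
   ordered chronologically by peak latency; per unit, second-half spike
   counts in physical-alternation (PA) versus flash-suppression (FS)
   trials are compared with a rank-sum test.
4. **Noise correlations** — trial spike counts are z-scored per condition
   and concatenated; pairwise Pearson r_sc of simultaneously recorded
   units is analyzed by the *temporal distance* between the units' CRPs
   (0 / 1 / ≥2), split by sign, and contrasted across the phase-tuned /
   stimulus-selective population boundary (s-crp and s-stim versus
   crp-stim pairs), with PA- and FS-restricted variants.

Because trial-level recordings of this kind are rarely deposited, the
package ships a fully ground-truthed synthetic generator
(`taskphase.synthetic`) that emulates the BFS trial structure: phase-tuned
units drawn as jittered, amplitude-scaled templates (condition-invariant by
construction), stimulus-selective units following the perceptually dominant
stimulus, junk units, and trial-to-trial log-normal gains whose pairwise
correlation decays with temporal distance and is weak across the population
boundary. Every downstream stage is tested against this planted structure.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
their tables under `results/`:

```bash
python analysis/01_simulate.py          # synthetic BFS dataset + ground truth
python analysis/02_preprocess.py        # screen, filter, response matrix
python analysis/03_decompose.py         # stability NNMF, K selection
python analysis/04_assign_crps.py       # CRP assignment, chronology, PA/FS
python analysis/05_noise_correlations.py
```

On the default dataset (150 phase-tuned + 16 selective + 6 junk units,
20 trials/condition, seed 2026) this prints, abridged:

```
172 recorded units: 23 stimulus-selective (excluded), 6 below the 1.26 spikes/trial activity cut
response matrix: 144 units x 1004 samples (4 conditions x 251)

median component variability by K:
  K=2: 0.0245
  K=3: 0.1162
  K=4: 0.1668
  K=5: 0.0125 <-- selected
  K=6: 0.0527
  K=7: 0.0983
selected K = 5; the canonical response patterns explain 89.7% of the matrix
energy (residual 10.3%)

chronological CRP order (peak latency, unit count, PA/FS-equivalent fraction):
  rank 1: CRP 2 peaks at 96 ms,   29 units,  97% PA~FS
  rank 2: CRP 3 peaks at 504 ms,  30 units,  93% PA~FS
  rank 3: CRP 4 peaks at 976 ms,  28 units,  89% PA~FS
  rank 4: CRP 0 peaks at 1440 ms, 29 units, 100% PA~FS
  rank 5: CRP 1 peaks at 1896 ms, 28 units,  93% PA~FS
overall, 94% of units responded equivalently in PA and FS trials

mean r_sc by temporal distance (all conditions):
  td0: 0.0605 +- 0.0026 (n=2003)
  td1: 0.0309 +- 0.0020 (n=3334)
  td2plus: 0.0042 +- 0.0016 (n=4959)
population segregation:
  s-crp:    0.0605 +- 0.0026 (n=2003)
  s-stim:   0.0523 +- 0.0117 (n=121)
  crp-stim: 0.0100 +- 0.0020 (n=3312)
  s-crp vs crp-stim: t = 15.70, p = 2.45e-54
```

Reading: five CRPs tile the trial chronologically (including a ramp to the
1000 ms switch); the vast majority of units fire indistinguishably whether
the second stimulus physically replaces the first (PA) or perceptually
suppresses it (FS); noise correlations fall off with the temporal distance
between two units' CRPs; and correlations across the phase-tuned /
stimulus-selective boundary are several-fold weaker than within either
population — the two populations are functionally segregated.

The same pipeline is scriptable (`taskphase run-all --out mydir --seed 7`,
with `simulate` / `preprocess` / `decompose` / `assign` subcommands) and
accepts real data as a spike-time table or a precomputed response-matrix
CSV (`--matrix`; screening and correlation stages are then skipped, since
they need trial-level data).

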