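# Methods

`taskphase` reimplements, as a tested pipeline, an analysis of task-phase-
related activity in prefrontal single-unit recordings during binocular flash
suppression (BFS): stability-constrained non-negative matrix factorization
(NNMF) of trial-aligned response profiles into canonical response patterns
(CRPs), cosine assignment of units to CRPs, and spike-count noise-correlation
analyses of the resulting functional organization. Because the trial-level
recordings behind such analyses are generally not available, the package
includes a fully ground-truthed synthetic spike-train generator, and every
claim a test makes is a claim about what the pipeline recovers from planted
structure.

## Task and data model

Each trial spans 2000 ms from first-stimulus onset (fixation begins 300 ms
earlier; the analysis window excludes it). A first stimulus is shown
monocularly for 1000 ms; at the 1000 ms switch a second stimulus appears in
the other eye — with removal of the first in physical alternation (PA)
trials, without removal (and with perceptual suppression of the first) in
flash suppression (FS) trials. Four condition codes combine trial type with
stimulus order: FS polar-first, PA polar-first, FS face-first, PA
face-first — also the canonical block order of all concatenated
representations. Spike tables are long-format CSV (session, unit, condition,
trial, spike time in ms); "simultaneously recorded" means "same session".

## Preprocessing

* **PSTH**: per unit and condition, spikes from all trials are kernel-
  smoothed with a Gaussian of SD 40 ms, evaluated on the inclusive
  0–2000 ms grid with 8 ms step (251 samples), divided by the trial count,
  in spikes/s. Kernels are truncated at the window edges without
  renormalization; the attenuation is identical for all units.
* **Selectivity screen**: second-half (1001–2000 ms, implemented as the
  half-open window (1000, 2000]) trial spike counts of the two PA trial
  types are compared with a two-sided rank-sum test; p < 0.05 flags the
  unit stimulus-selective and excludes it from the CRP analysis. The
  preferred stimulus is the second stimulus of the trial type with the
  larger second-half counts. Rank-sum p-values use exact enumeration for
  group sizes ≤ 10 (no ties) and the tie-corrected, continuity-corrected
  normal approximation otherwise; all-tied data yield p = 1.
* **Activity filter**: units with a mean of < 1.26 spikes per trial
  (full 0–2000 ms window, pooled over all trials of all four conditions)
  are removed. The threshold is strict: a unit at exactly 1.26 is kept.
* **Response matrix**: the four condition PSTHs of each retained,
  non-selective unit are concatenated in the canonical order into one row
  of the non-negative units × 1004 matrix `R`.

## Stability-constrained NNMF

`R ≈ H W` with `H` (units × K) and `W` (K × 1004) non-negative. `W` is
initialized as |N(0, 1)| + 0.1; `H` by least squares (via pseudoinverse),
clipped at zero, plus 2.22e-16. Fitting uses Lee–Seung multiplicative
updates for the Frobenius objective; the objective is non-increasing and
fitting stops at a relative decrease below tolerance or an iteration cap.

Stability is enforced with a split-half bootstrap (default 50 iterations).
Per iteration the rows of `R` are randomly halved (first half receives the
extra row when odd); both halves are factorized from the current `W`
initialization with `H` re-initialized by clipped regression; the two
solutions are matched one-to-one by cosine similarity using an optimal
assignment. Matched pairs (similarity > 0.5) carry their average into the
next iteration's initialization; unmatched slots are re-randomized.

The last 15 iterations' components quantify stability. The history stores
*both half-solutions* per iteration: between-half disagreement is exactly
the signature of an unstable rank, and averaging it away would hide it.
The stored matrices are aligned by one kernel-PCA fit (RBF kernel,
bandwidth = median pairwise row distance; linear kernel available) on all
pooled rows, each matrix's rows sorted by their first-component projection;
a degenerate projection falls back to original row order. The
per-component variability ratio is the across-history variance divided by
the across-history mean square, both averaged over time; an all-zero
component is flagged with an infinite ratio. The aligned-history mean
initializes one final fit on the full `R`.

**Rank selection** repeats this procedure (default 100 runs) for K in
[2, 10]; the per-run summary is the mean variability across components, and
the selected K is the largest whose median across runs is below 5%; the
reported solution is the minimum-residual run at that K. Explained and
residual energy are ‖HW‖² / ‖R‖² and ‖R − HW‖² / ‖R‖², computed
independently (they are only approximately complementary, at stationarity).

Numerical choices the original description leaves open, fixed here: inner
(half-)fits run essentially to convergence (default cap 400 iterations at
relative tolerance 1e-7 in the study settings; module default 200 at 1e-5),
final fits 500 at 1e-6. Deep inner convergence matters: it lets each half
reach its own optimum, so a rank the data cannot support shows up as
between-half disagreement instead of being masked by a shared shallow
initialization basin. Seeds derive from one master seed through a
splittable sequence, so runs are independently reproducible; a worker-count
option parallelizes the run loop.

## CRP assignment and PA/FS comparison

Units are assigned to the CRP of maximum cosine similarity over the full
1004-sample profile (ties to the lowest index; all-zero profiles go to an
exclusion list). CRPs are ranked chronologically by the peak latency of
their condition-averaged 251-sample profile (ties by concatenated argmax,
then index; constant profiles rank last and are flagged). Per unit, pooled
second-half PA counts versus pooled FS counts enter a two-sided rank-sum
test; p > 0.05 means the unit responds equivalently under monocular and
suppressed stimulation. The peak-latency sorting averages each unit's four
condition blocks, orders units by argmax latency, and normalizes each
non-zero unit by its averaged profile's maximum (zero units sort last,
unnormalized).

## Noise correlations

Full-window trial counts are z-scored within each condition (sample SD,
n−1) and concatenated; a pair's r_sc is the Pearson correlation of the two
concatenated vectors. A zero-variance condition makes the pair's z-scores
undefined and excludes the pair; scopes restrict the computation to all
four, the two PA, or the two FS conditions. CRP–CRP pairs are grouped by
temporal distance |rank_i − rank_j| into bins {0}, {1}, {≥2}; group means,
SEMs, and all pairwise two-sample pooled-variance t-tests are reported,
plus the K×K mean-r_sc matrix by rank. The sign split partitions pairs
into r_sc ≥ 0 and r_sc < 0 (zero with the positives, a deterministic rule
for a measure-zero event) and repeats the binning per sign. Segregation
contrasts same-CRP pairs (s-crp), same-preference selective pairs (s-stim)
and cross-population pairs (crp-stim); the key tests are s-crp vs crp-stim
and s-stim vs crp-stim. Classes with fewer than two pairs skip their test.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, with
full ground truth:

* **Templates.** Five non-negative unit-peak profiles on the condition
  grid: Gaussian bumps (SD 150 ms) at 80, 540, 1460 and 1920 ms — evenly
  tiling trial start, post-first-stimulus, post-second-stimulus and trial
  end — plus a linear ramp to the 1000 ms switch with a Gaussian fall-off
  (SD 150 ms). Peak times are strictly increasing.
* **Phase-tuned units** take `amplitude × (baseline + (peak − baseline) ×
  template(t − jitter))`, identical across all four conditions. Per-unit
  peak jitter (default SD 60 ms) and log-normal amplitude (default log-SD
  0.4) make each template a realistic continuum of units rather than
  repeated copies — real populations tile a task phase. Default rates are
  low (baseline 1 spikes/s, peak 5): populations screened at 1.26 spikes
  per trial are dominated by sparsely firing units, and that spiking noise
  is what makes over-complete factorizations unstable; with noise-free or
  high-rate clusters a K+1-th component can lock onto a reproducible
  refinement and the largest-stable-K rule overshoots.
* **Stimulus-selective units** fire at the peak rate whenever their
  preferred stimulus is perceptually dominant (first half of
  preferred-first trials, second half of the others, identically in PA and
  FS — dominance is deterministic, no rivalry dynamics), baseline
  otherwise. **Junk units** fire at a constant 0.2 spikes/s and are
  removed by the activity filter.
* **Trial gains.** Each trial, each session draws one standard-normal
  factor per template group and per preference group; group factors are
  correlated as `coupling_decay^|Δtemplate|` between phase groups (a
  Kac–Murdock–Szegő matrix, always positive definite) and
  `coupling_cross_population / coupling_same_group` across the
  population boundary (feasibility is validated). A unit's latent mixes
  its group factor with weight sqrt(coupling_same_group) plus independent
  noise, giving exactly the configured pairwise latent correlations; gains
  are log-normal, `exp(gain_sd·u − gain_sd²/2)`, with unit mean. Spike
  times come from an inhomogeneous Poisson sampler (inversion of the
  cumulative intensity), so counts are exactly Poisson with mean
  gain × ∫rate dt.

Defaults: 20 trials per condition (enough for meaningful rank-sum tests at
desk scale), gain_sd 0.3, coupling_same_group 0.3, coupling_decay 0.5,
coupling_cross_population 0. With mean counts around 5–10 per trial these
give count-level same-group correlations near 0.1 — the order observed in
cortical recordings.

**What the generator does not emulate**, hence what passing tests do not
show about real data: no genuinely negative couplings (recorded data show
a flat negative-correlation branch; here any negative-subset structure is a
truncation artifact of sign-splitting a noisy estimator), no rivalry
dynamics or trial-to-trial perceptual variability, no cell-type structure,
no non-Poisson spiking (refractoriness, bursting), no eye-movement or
adaptation effects, and real CRPs are a parsimonious summary of messier
profiles than template-plus-jitter.

## Study designs and problem sizes

The desk-scale studies (in `taskphase.studies`) choose sizes that keep the
full test suite and the acceptance script in the tens of minutes on one
core while preserving each question's statistical meaning:

* **Rank recovery**: populations with 3, 4 or 5 planted templates, 30
  units per template plus 10 selective and 5 junk units, 20 trials per
  condition, peak rate 5× baseline; K scanned over [2, 7] with 5–6
  bootstrap-stabilized runs per K (20 bootstrap iterations, history 10),
  two master seeds per population; recovery required in ≥ 80% of
  experiments. Within-phase jitter scales with phase width (80/70/60 ms
  for 3/4/5 templates): fewer phases tile the trial more coarsely.
* **Correlation structure**: 6 sessions × (25 phase-tuned + 8 selective +
  2 junk) units, 200 trials per condition. Multiple sessions matter
  beyond realism: group-level correlation means average over sessions'
  independent latent-factor realizations, which is what makes pair-level
  SEs honest for group comparisons (with a single session, all same-group
  pairs share one factor realization and nominal 2-SE bands are
  anti-conservative).
* **Null calibration**: 500 constant-rate units (peak = baseline, no
  coupling, no gain noise), 20 trials per condition, for the
  false-positive rates of both rank-sum screens against binomial 99%
  bounds around 0.05.

## Known limitations

* The stability criterion discriminates ranks only on realistically noisy
  data; on noise-free low-rank matrices over-complete factorizations are
  degenerate and reproduce exactly, so the largest-stable-K rule is not
  meaningful there (the exact-recovery tests therefore scan only the
  planted rank).
* The 3-template rank-recovery margin is the narrowest: a 4th component
  can settle on splitting the single overlapping template pair, and its
  median variability sits closest to the 5% cutoff of all study designs.
* KPCA alignment assumes the first kernel component separates the K
  component clusters; with heavily overlapping components the alignment
  (and hence the variability estimate) degrades gracefully but is not
  guaranteed.
* Energy ratios are reported independently; explained + residual ≈ 1 only
  at convergence.
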