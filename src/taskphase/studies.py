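"""Predefined synthetic study designs used by the analysis scripts and tests.

Three desk-scale studies exercise the pipeline end to end:

* **Rank recovery** — populations with 3, 4 or 5 planted phase templates.
  Within-phase peak jitter scales with the width of a phase (fewer phases
  tile the trial more coarsely), so the population is a realistic continuum
  around each template rather than copies of it.
* **Correlation structure** — a larger-trial-count population with planted
  temporal-distance-decaying gain coupling and a decoupled
  stimulus-selective subpopulation, for the noise-correlation analyses.
* **Null calibration** — condition-invariant constant-rate units for the
  false-positive rates of the selectivity screen and the PA/FS comparison.

Firing rates are deliberately low (baseline 1 spikes/s, peak 5 spikes/s):
populations recorded extracellularly and screened at 1.26 spikes per trial
are dominated by sparsely firing units, and that spiking noise is what makes
over-complete factorizations unstable.
"""

from __future__ import annotations

import numpy as np

from . import nnmf
from . import preprocessing as prep
from .synthetic import SyntheticConfig, sample_population

#: planted-K rank-recovery designs: template subset and within-phase jitter
RANK_RECOVERY_DESIGNS = {
    3: {"template_ids": (0, 1, 4), "peak_jitter_sd_ms": 80.0},
    4: {"template_ids": (0, 1, 3, 4), "peak_jitter_sd_ms": 70.0},
    5: {"template_ids": (0, 1, 2, 3, 4), "peak_jitter_sd_ms": 60.0},
}

#: shared stability-run settings for K selection (half-fits run to
#: convergence: between-half disagreement is the instability signal)
K_SELECTION_SETTINGS = dict(
    n_bootstrap=20, history_len=10, inner_max_iter=400, inner_rel_tol=1e-7,
)


def rank_recovery_config(planted_k: int, seed: int,
                         units_per_template: int = 30) -> SyntheticConfig:
    design = RANK_RECOVERY_DESIGNS[planted_k]
    return SyntheticConfig(
        phase_tuned_per_template=units_per_template,
        n_stimulus_selective=10, n_junk=5,
        trials_per_condition=20, baseline_rate=1.0, peak_rate=5.0,
        seed=seed, **design,
    )


def run_rank_recovery(planted_k: int, seed: int, runs: int = 6,
                      k_range=range(2, 8)) -> dict:
    """Generate a planted-K population, preprocess, select K; report both."""
    cfg = rank_recovery_config(planted_k, seed)
    spikes, truth = sample_population(cfg)
    pre = prep.preprocess(spikes)
    R = pre["response_matrix"].R
    report = nnmf.select_k(R, k_range=k_range, runs=runs, seed=seed,
                           **K_SELECTION_SETTINGS)
    return {
        "planted_k": planted_k,
        "selected_k": report.selected_k,
        "median_by_k": report.median_by_k,
        "n_rows": R.shape[0],
        "report": report,
        "pre": pre,
        "truth": truth,
    }


def correlation_config(seed: int, trials: int = 200, n_sessions: int = 6,
                       units_per_template: int = 5,
                       n_selective: int = 8) -> SyntheticConfig:
    """Multi-session design: group-level correlation estimates average over
    sessions' independent latent-factor realizations, as pooling recording
    sessions does for real data."""
    return SyntheticConfig(
        n_sessions=n_sessions,
        phase_tuned_per_template=units_per_template,
        n_stimulus_selective=n_selective, n_junk=2,
        trials_per_condition=trials, baseline_rate=1.0, peak_rate=5.0,
        gain_sd=0.3, coupling_same_group=0.3, coupling_decay=0.5,
        coupling_cross_population=0.0, seed=seed,
    )


def null_calibration_config(seed: int, n_units: int = 500,
                            trials: int = 20) -> SyntheticConfig:
    """Condition-invariant units: peak = baseline, no coupling, no gain noise.

    Both screens are then exercised under their null hypotheses.
    """
    return SyntheticConfig(
        phase_tuned_per_template=int(np.ceil(n_units / 5)),
        n_stimulus_selective=0, n_junk=0,
        trials_per_condition=trials, baseline_rate=3.0, peak_rate=3.0,
        gain_sd=0.0, coupling_same_group=0.0, peak_jitter_sd_ms=0.0,
        amplitude_sd=0.0, seed=seed,
    )
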