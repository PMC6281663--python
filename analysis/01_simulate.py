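#!/usr/bin/env python
"""Generate the study's synthetic BFS dataset.

A five-template phase-tuned population (30 units per template) with a
stimulus-selective subpopulation and a few low-rate junk units, 20 trials
per condition, temporal-distance-decaying gain coupling, and no coupling
across the phase-tuned / stimulus-selective boundary.  Writes the spike
table, the ground-truth unit table and the generator configuration under
results/data/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from taskphase import synthetic as syn

OUT = ROOT / "results" / "data"


def main() -> None:
    cfg = syn.SyntheticConfig(
        phase_tuned_per_template=30, n_stimulus_selective=16, n_junk=6,
        trials_per_condition=20, baseline_rate=1.0, peak_rate=5.0,
        gain_sd=0.3, coupling_same_group=0.3, coupling_decay=0.5,
        coupling_cross_population=0.0, seed=2026,
    )
    spikes, truth = syn.sample_population(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    syn.write_spike_table(spikes, OUT / "spikes.csv")
    syn.write_ground_truth(truth, OUT / "ground_truth_units.csv",
                           OUT / "generator_config.yaml")
    n_units = spikes["unit_id"].nunique()
    by_class = truth.units["unit_class"].value_counts().to_dict()
    print(f"wrote {len(spikes):,} spikes from {n_units} units "
          f"({by_class}) to {OUT}")
    print("phase-tuned units are condition-invariant by construction; "
          "selective units follow the perceptually dominant stimulus.")


if __name__ == "__main__":
    main()
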