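#!/usr/bin/env python
"""Screen, filter and build the condition-concatenated response matrix.

Reads results/data/spikes.csv, runs the stimulus-selectivity screen
(second-half counts of the two PA trial types, rank sum, p < 0.05), removes
low-activity units (< 1.26 mean spikes per trial) and writes the units x
1004 response matrix of Gaussian-smoothed (40 ms SD) condition-concatenated
PSTHs.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from taskphase import preprocessing as prep
from taskphase import synthetic as syn

DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "preprocess"


def main() -> None:
    spikes = syn.read_spike_table(DATA / "spikes.csv")
    pre = prep.preprocess(spikes)
    OUT.mkdir(parents=True, exist_ok=True)
    pre["screen"].to_csv(OUT / "selectivity_screen.csv", index=False)
    prep.write_response_matrix(pre["response_matrix"], OUT / "response_matrix.csv")
    pd.DataFrame(pre["retained_units"], columns=["session_id", "unit_id"]).to_csv(
        OUT / "unit_map.csv", index=False)

    n_total = spikes["unit_id"].nunique()
    n_sel = int(pre["screen"]["selective"].sum())
    n_active = len(pre["active_units"])
    m = pre["response_matrix"]
    print(f"{n_total} recorded units: {n_sel} stimulus-selective (excluded), "
          f"{n_total - n_active} below the 1.26 spikes/trial activity cut")
    print(f"response matrix: {m.n_units} units x {m.R.shape[1]} samples "
          f"(4 conditions x 251) -> {OUT / 'response_matrix.csv'}")


if __name__ == "__main__":
    main()
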