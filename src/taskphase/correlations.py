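"""Spike-count noise correlations and their group structure.

For each unit, full-window trial spike counts are z-scored within each of
the four stimulus conditions separately (sample SD, n−1) and the z-scores
concatenated; the noise correlation r_sc of a simultaneously recorded pair
is the Pearson correlation of the two concatenated vectors.  A condition
with zero count variance yields undefined z-scores and the pair is excluded.

Three group analyses follow the structure of the recorded-population study:
(1) r_sc versus the *temporal distance* between the CRPs of the two units
(bins 0 / 1 / ≥2 of chronological-rank difference), (2) the same split
separately for positive and negative correlations, and (3) the segregation
contrast between within-population pairs (same CRP: s-crp; same preferred
stimulus: s-stim) and cross-population pairs (crp-stim).  Each analysis
supports condition scopes: all four conditions, PA only, or FS only.
Group comparisons use two-sample unpaired Student t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import unpaired_t_test
from .synthetic import CONDITIONS

#: condition subsets selectable as analysis scope
SCOPES = {
    "all": CONDITIONS,
    "PA": ("PA_polar_first", "PA_face_first"),
    "FS": ("FS_polar_first", "FS_face_first"),
}

PAIR_CLASSES = ("s-crp", "s-stim", "crp-stim", "other")


@dataclass
class GroupStats:
    """Summary of one group of pair correlations plus its pairwise tests."""

    label: str
    mean: float
    sem: float
    n: int
    tests: dict = field(default_factory=dict)  # other-label -> (t, p)

    @classmethod
    def from_values(cls, label: str, values: np.ndarray) -> "GroupStats":
        values = np.asarray(values, dtype=float)
        n = values.size
        if n == 0:
            return cls(label=label, mean=float("nan"), sem=float("nan"), n=0)
        sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return cls(label=label, mean=float(values.mean()), sem=sem, n=n)

    def to_dict(self) -> dict:
        return {
            "label": self.label, "mean": self.mean, "sem": self.sem, "n": self.n,
            "tests": {k: {"t": t, "p": p} for k, (t, p) in self.tests.items()},
        }


# ---------------------------------------------------------------------------
# z-scoring and pairwise correlation
# ---------------------------------------------------------------------------

def zscore_counts(counts_by_condition: dict, scope: str = "all") -> np.ndarray:
    """Concatenated per-condition z-scores of one unit's trial counts.

    Conditions are z-scored separately (sample SD) and concatenated in the
    canonical order restricted to ``scope``.  A zero-variance condition
    yields NaN entries, which propagate to pair exclusion downstream.
    """
    blocks = []
    for cond in SCOPES[scope]:
        x = np.asarray(counts_by_condition[cond], dtype=float)
        if x.size < 2:
            raise ValueError(f"condition {cond} needs >= 2 trials to z-score")
        sd = x.std(ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - x.mean()) / sd if sd > 0 else np.full(x.size, np.nan)
        blocks.append(z)
    return np.concatenate(blocks)


def pair_rsc(counts_i: dict, counts_j: dict, scope: str = "all") -> float | None:
    """Noise correlation of one unit pair, or ``None`` if excluded.

    Excluded when either unit has a zero-variance condition in scope (NaN
    z-scores) or fewer than 3 trials remain.
    """
    zi = zscore_counts(counts_i, scope)
    zj = zscore_counts(counts_j, scope)
    if zi.size != zj.size:
        raise ValueError("pair members must have matched trial counts")
    if zi.size < 3 or np.isnan(zi).any() or np.isnan(zj).any():
        return None
    r = np.corrcoef(zi, zj)[0, 1]
    return float(r)


# ---------------------------------------------------------------------------
# pair records
# ---------------------------------------------------------------------------

def _condition_count_matrices(counts: pd.DataFrame) -> dict:
    """Per (session, condition): units × trials count matrix and unit index."""
    out: dict = {}
    for (sid, cond), sub in counts.groupby(["session_id", "condition_code"]):
        mat = sub.pivot_table(index="unit_id", columns="trial_index",
                              values="count", fill_value=0)
        out[(sid, cond)] = (mat.to_numpy(dtype=float), list(mat.index))
    return out


def build_pair_records(
    counts: pd.DataFrame,
    unit_labels: pd.DataFrame,
    scope: str = "all",
) -> pd.DataFrame:
    """r_sc for every same-session unit pair, with class and temporal distance.

    ``unit_labels`` needs columns session_id, unit_id, population
    (``"crp"`` or ``"stim"``), and either ``chron_rank`` (CRP units) or
    ``pref_stimulus`` (selective units).  Pairs whose z-scores are undefined
    under ``scope`` are dropped (they carry no r_sc).
    """
    labels = unit_labels.set_index(["session_id", "unit_id"])
    mats = _condition_count_matrices(counts)

    records = []
    for sid in unit_labels["session_id"].unique():
        session_units = [u for (s, u) in labels.index if s == sid]
        # concatenated z-score matrix for the session, NaN marks exclusion
        z_blocks, unit_order = [], None
        ok = True
        for cond in SCOPES[scope]:
            if (sid, cond) not in mats:
                ok = False
                break
            mat, uids = mats[(sid, cond)]
            if unit_order is None:
                unit_order = uids
            mat = mat[[uids.index(u) for u in unit_order]]
            mean = mat.mean(axis=1, keepdims=True)
            sd = mat.std(axis=1, ddof=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), np.nan)
            z_blocks.append(z)
        if not ok or unit_order is None:
            continue
        Z = np.hstack(z_blocks)
        valid = ~np.isnan(Z).any(axis=1)
        idx_of = {u: i for i, u in enumerate(unit_order)}

        for a in range(len(session_units)):
            for b in range(a + 1, len(session_units)):
                ua, ub = session_units[a], session_units[b]
                if ua not in idx_of or ub not in idx_of:
                    continue
                ia, ib = idx_of[ua], idx_of[ub]
                if not (valid[ia] and valid[ib]) or Z.shape[1] < 3:
                    continue
                r = float(np.corrcoef(Z[ia], Z[ib])[0, 1])
                la, lb = labels.loc[(sid, ua)], labels.loc[(sid, ub)]
                pc, td = _classify_pair(la, lb)
                records.append((sid, ua, ub, r, Z.shape[1], pc, td, scope))
    return pd.DataFrame(records, columns=[
        "session_id", "unit_i", "unit_j", "r_sc", "n_trials_used",
        "pair_class", "temporal_distance", "condition_scope",
    ])


def _classify_pair(la: pd.Series, lb: pd.Series) -> tuple[str, float]:
    pa, pb = la["population"], lb["population"]
    if pa == "crp" and pb == "crp":
        td = abs(int(la["chron_rank"]) - int(lb["chron_rank"]))
        return ("s-crp" if td == 0 else "other"), float(td)
    if pa == "stim" and pb == "stim":
        same = la["pref_stimulus"] == lb["pref_stimulus"]
        return ("s-stim" if same else "other"), np.nan
    return "crp-stim", np.nan


# ---------------------------------------------------------------------------
# group analyses
# ---------------------------------------------------------------------------

def _td_bin(td: float) -> str | None:
    if np.isnan(td):
        return None
    if td == 0:
        return "td0"
    if td == 1:
        return "td1"
    return "td2plus"


def _attach_tests(groups: dict[str, GroupStats], values: dict[str, np.ndarray]) -> None:
    labels = list(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if values[a].size >= 2 and values[b].size >= 2:
                t, p = unpaired_t_test(values[a], values[b])
                groups[a].tests[b] = (t, p)
                groups[b].tests[a] = (t, p)


def temporal_distance_groups(pairs: pd.DataFrame, n_crps: int | None = None
                             ) -> tuple[dict[str, GroupStats], np.ndarray]:
    """Group CRP–CRP pair correlations by temporal-distance bins 0 / 1 / ≥2.

    Returns the per-bin stats (with all pairwise t-tests) and the K×K matrix
    of mean r_sc by the chronological ranks of the two CRPs (NaN where no
    pair exists); rank information is taken from ``crp_rank_i/j`` columns if
    present, otherwise only the binned stats are computed.
    """
    crp = pairs[~pairs["temporal_distance"].isna()]
    values = {
        bin_: crp.loc[crp["temporal_distance"].map(_td_bin) == bin_, "r_sc"].to_numpy()
        for bin_ in ("td0", "td1", "td2plus")
    }
    groups = {k: GroupStats.from_values(k, v) for k, v in values.items()}
    _attach_tests(groups, values)

    matrix = np.full((0, 0), np.nan)
    if n_crps and {"crp_rank_i", "crp_rank_j"}.issubset(pairs.columns):
        matrix = np.full((n_crps, n_crps), np.nan)
        for (ri, rj), sub in crp.groupby(["crp_rank_i", "crp_rank_j"]):
            i, j = int(ri) - 1, int(rj) - 1
            matrix[i, j] = matrix[j, i] = float(sub["r_sc"].mean())
    return groups, matrix


def sign_split_stats(pairs: pd.DataFrame) -> dict[str, dict[str, GroupStats]]:
    """Temporal-distance stats separately for positive and negative r_sc.

    r_sc values of exactly zero join the positive subset (deterministic
    convention for a measure-zero event).
    """
    crp = pairs[~pairs["temporal_distance"].isna()]
    out = {}
    for sign, sub in (("positive", crp[crp["r_sc"] >= 0]),
                      ("negative", crp[crp["r_sc"] < 0])):
        values = {
            bin_: sub.loc[sub["temporal_distance"].map(_td_bin) == bin_,
                          "r_sc"].to_numpy()
            for bin_ in ("td0", "td1", "td2plus")
        }
        groups = {k: GroupStats.from_values(k, v) for k, v in values.items()}
        _attach_tests(groups, values)
        out[sign] = groups
    return out


def segregation_stats(pairs: pd.DataFrame) -> dict[str, GroupStats]:
    """Within- versus cross-population correlation contrast.

    Groups: s-crp (same CRP), s-stim (same preferred stimulus), crp-stim
    (one unit from each population).  The two key comparisons are s-crp vs
    crp-stim and s-stim vs crp-stim; a class with fewer than two pairs has
    its test skipped.
    """
    values = {
        cls: pairs.loc[pairs["pair_class"] == cls, "r_sc"].to_numpy()
        for cls in ("s-crp", "s-stim", "crp-stim")
    }
    groups = {k: GroupStats.from_values(k, v) for k, v in values.items()}
    for cls in ("s-crp", "s-stim"):
        if values[cls].size >= 2 and values["crp-stim"].size >= 2:
            t, p = unpaired_t_test(values[cls], values["crp-stim"])
            groups[cls].tests["crp-stim"] = (t, p)
    return groups


def attach_crp_ranks(pairs: pd.DataFrame, unit_labels: pd.DataFrame) -> pd.DataFrame:
    """Add chronological ranks of both pair members (CRP units only)."""
    ranks = unit_labels.set_index(["session_id", "unit_id"])["chron_rank"]
    out = pairs.copy()
    out["crp_rank_i"] = [
        ranks.get((s, u), np.nan) for s, u in zip(out["session_id"], out["unit_i"])
    ]
    out["crp_rank_j"] = [
        ranks.get((s, u), np.nan) for s, u in zip(out["session_id"], out["unit_j"])
    ]
    return out
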