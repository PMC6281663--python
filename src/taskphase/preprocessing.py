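"""From spike trains to the screened, condition-concatenated response matrix.

The pipeline is: per-unit, per-condition Gaussian-smoothed trial-averaged
PSTHs on an inclusive 0–2000 ms grid with 8 ms step (251 samples); a
stimulus-selectivity screen on second-half (1001–2000 ms) spike counts of the
two physical-alternation trial types (rank-sum, p < 0.05 → the unit is
selective and excluded from the pattern analysis); a low-activity filter
removing units with a mean of < 1.26 spikes per trial (full window, pooled
over all four conditions); and concatenation of the four condition PSTHs into
one non-negative units × 1004 response matrix in the canonical condition
order (FS polar-first, PA polar-first, FS face-first, PA face-first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ALPHA, rank_sum_test
from .synthetic import CONDITIONS, GRID_MS, N_SAMPLES

#: default PSTH smoothing kernel SD (ms)
SIGMA_MS = 40.0
#: low-activity threshold: mean spikes per concatenated trial
ACTIVITY_THRESHOLD = 1.26
#: full analysis window and its second half (ms)
FULL_WINDOW = (0.0, 2000.0)
SECOND_HALF = (1000.0, 2000.0)


class MissingDataError(ValueError):
    """Raised when a unit lacks the trials or conditions an operation needs."""


@dataclass
class ResponseMatrix:
    """Non-negative units × 1004 matrix of condition-concatenated PSTHs."""

    R: np.ndarray
    unit_ids: list[str]
    session_ids: list[str]

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[1] != 4 * N_SAMPLES:
            raise ValueError("response matrix must have 4 x 251 = 1004 columns")
        if np.any(self.R < 0):
            raise ValueError("response matrix must be non-negative")
        if len(self.unit_ids) != self.R.shape[0]:
            raise ValueError("unit map must be a bijection onto the rows")

    @property
    def n_units(self) -> int:
        return self.R.shape[0]

    def condition_block(self, condition: str) -> np.ndarray:
        i = CONDITIONS.index(condition)
        return self.R[:, i * N_SAMPLES:(i + 1) * N_SAMPLES]


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

def compute_psth(trial_spike_times: list[np.ndarray], sigma_ms: float = SIGMA_MS,
                 grid: np.ndarray = GRID_MS) -> np.ndarray:
    """Trial-averaged Gaussian-kernel-smoothed firing rate (spikes/s).

    Each spike contributes a Gaussian density of SD ``sigma_ms`` evaluated on
    the grid (plain truncation at the window edges, no renormalization); the
    sum is divided by the trial count and scaled to spikes/s.
    """
    if len(trial_spike_times) == 0:
        raise MissingDataError("compute_psth requires at least one trial")
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be > 0")
    spikes = np.concatenate([np.asarray(t, dtype=float) for t in trial_spike_times]) \
        if any(len(t) for t in trial_spike_times) else np.empty(0)
    if spikes.size == 0:
        return np.zeros(grid.shape)
    d = grid[None, :] - spikes[:, None]
    dens = np.exp(-0.5 * (d / sigma_ms) ** 2) / (sigma_ms * np.sqrt(2 * np.pi))
    return 1000.0 * dens.sum(axis=0) / len(trial_spike_times)


def unit_condition_psths(spikes: pd.DataFrame, sigma_ms: float = SIGMA_MS,
                         n_trials: dict | None = None) -> dict:
    """PSTHs for every (session, unit, condition) present in a spike table.

    Trial counts per (session, condition) are inferred as
    ``max(trial_index) + 1`` across the session's units unless supplied, so
    silent trials still enter the trial average.
    """
    n_trials = n_trials or infer_trial_counts(spikes)
    psths: dict = {}
    grouped = spikes.groupby(["session_id", "unit_id", "condition_code"], sort=True)
    units = spikes[["session_id", "unit_id"]].drop_duplicates()
    per_group = {key: np.asarray(g["spike_time_ms"]) for key, g in grouped}
    trial_of = {key: np.asarray(g["trial_index"]) for key, g in grouped}
    for _, row in units.iterrows():
        sid, uid = row["session_id"], row["unit_id"]
        for cond in CONDITIONS:
            nt = n_trials[(sid, cond)]
            times = per_group.get((sid, uid, cond), np.empty(0))
            trials = trial_of.get((sid, uid, cond), np.empty(0, dtype=int))
            by_trial = [times[trials == t] for t in range(nt)]
            psths[(sid, uid, cond)] = compute_psth(by_trial, sigma_ms=sigma_ms)
    return psths


def infer_trial_counts(spikes: pd.DataFrame) -> dict:
    """``max(trial_index)+1`` per (session, condition), pooled over units."""
    counts = spikes.groupby(["session_id", "condition_code"])["trial_index"].max() + 1
    out = {}
    for sid in spikes["session_id"].unique():
        for cond in CONDITIONS:
            out[(sid, cond)] = int(counts.get((sid, cond), 0))
    return out


# ---------------------------------------------------------------------------
# trial spike counts
# ---------------------------------------------------------------------------

def trial_spike_counts(spikes: pd.DataFrame, window: tuple[float, float] = FULL_WINDOW,
                       n_trials: dict | None = None) -> pd.DataFrame:
    """Per (session, unit, condition, trial) spike counts in ``window``.

    The window is half-open on the left, ``(t0, t1]``, except that the full
    0–2000 ms window includes 0; trials without spikes appear with count 0.
    """
    n_trials = n_trials or infer_trial_counts(spikes)
    t = spikes["spike_time_ms"]
    lo, hi = window
    inside = (t > lo) & (t <= hi) if lo > 0 else (t >= lo) & (t <= hi)
    sub = spikes[inside]
    counted = sub.groupby(
        ["session_id", "unit_id", "condition_code", "trial_index"]
    ).size()

    units = spikes[["session_id", "unit_id"]].drop_duplicates()
    rows = []
    for _, row in units.iterrows():
        sid, uid = row["session_id"], row["unit_id"]
        for cond in CONDITIONS:
            for trial in range(n_trials[(sid, cond)]):
                rows.append((sid, uid, cond, trial,
                             int(counted.get((sid, uid, cond, trial), 0))))
    return pd.DataFrame(rows, columns=["session_id", "unit_id", "condition_code",
                                       "trial_index", "count"])


def counts_by_condition(counts: pd.DataFrame, session_id: str, unit_id: str) -> dict:
    """Count vectors per condition (ordered by trial index) for one unit."""
    sub = counts[(counts["session_id"] == session_id) & (counts["unit_id"] == unit_id)]
    return {
        cond: np.asarray(
            sub[sub["condition_code"] == cond].sort_values("trial_index")["count"],
            dtype=float,
        )
        for cond in CONDITIONS
    }


# ---------------------------------------------------------------------------
# screening and filtering
# ---------------------------------------------------------------------------

def screen_stimulus_selectivity(pa_polar_first_counts, pa_face_first_counts,
                                alpha: float = ALPHA) -> tuple[float, bool]:
    """Stimulus-selectivity screen on second-half counts of the two PA types.

    Returns the two-sided rank-sum p-value and the selective flag
    (p < alpha).  Selective units are excluded from the pattern analysis.
    """
    p = rank_sum_test(pa_polar_first_counts, pa_face_first_counts)
    return p, bool(p < alpha)


def screen_all_units(second_half_counts: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Run the selectivity screen over every unit of a counts table.

    ``pref_stimulus`` of a selective unit is the stimulus shown during the
    second half of the PA trial type with the larger mean count (the second
    stimulus of that trial type).
    """
    rows = []
    units = second_half_counts[["session_id", "unit_id"]].drop_duplicates()
    for _, row in units.iterrows():
        sid, uid = row["session_id"], row["unit_id"]
        by_cond = counts_by_condition(second_half_counts, sid, uid)
        a, b = by_cond["PA_polar_first"], by_cond["PA_face_first"]
        p, sel = screen_stimulus_selectivity(a, b, alpha=alpha)
        # second half of polar-first shows the face; of face-first, the polar
        pref = ""
        if sel:
            pref = "face" if a.mean() > b.mean() else "polar"
        rows.append((sid, uid, p, sel, pref))
    return pd.DataFrame(rows, columns=["session_id", "unit_id", "p_value",
                                       "selective", "pref_stimulus"])


def filter_low_activity(full_window_counts: pd.DataFrame,
                        threshold: float = ACTIVITY_THRESHOLD) -> pd.DataFrame:
    """Retain units with mean spikes/trial >= threshold (strict < removed).

    The mean pools every trial of all four conditions over the full window.
    """
    means = full_window_counts.groupby(["session_id", "unit_id"])["count"].mean()
    if means.isna().any():  # pragma: no cover - guarded by count construction
        raise MissingDataError("unit with zero trials in activity filter")
    kept = means[means >= threshold].reset_index().rename(columns={"count": "mean_count"})
    return kept


# ---------------------------------------------------------------------------
# response matrix
# ---------------------------------------------------------------------------

def build_response_matrix(psths: dict, retained_units: list[tuple[str, str]]) -> ResponseMatrix:
    """Concatenate the four condition PSTHs of the retained units into R."""
    rows, unit_ids, session_ids = [], [], []
    for sid, uid in retained_units:
        blocks = []
        for cond in CONDITIONS:
            key = (sid, uid, cond)
            if key not in psths:
                raise MissingDataError(f"unit {uid} (session {sid}) lacks condition {cond}")
            blocks.append(psths[key])
        rows.append(np.concatenate(blocks))
        unit_ids.append(uid)
        session_ids.append(sid)
    return ResponseMatrix(R=np.asarray(rows, dtype=float),
                          unit_ids=unit_ids, session_ids=session_ids)


def preprocess(spikes: pd.DataFrame, sigma_ms: float = SIGMA_MS,
               threshold: float = ACTIVITY_THRESHOLD, alpha: float = ALPHA) -> dict:
    """Full preprocessing stage: screen, filter, and assemble R.

    Returns a dict with the screen table, the retained-unit table, the trial
    counts (full window and second half) and the :class:`ResponseMatrix` of
    retained non-selective units.
    """
    n_trials = infer_trial_counts(spikes)
    full_counts = trial_spike_counts(spikes, FULL_WINDOW, n_trials)
    half_counts = trial_spike_counts(spikes, SECOND_HALF, n_trials)
    screen = screen_all_units(half_counts, alpha=alpha)
    active = filter_low_activity(full_counts, threshold=threshold)
    active_keys = set(zip(active["session_id"], active["unit_id"]))
    selective_keys = set(zip(screen.loc[screen["selective"], "session_id"],
                             screen.loc[screen["selective"], "unit_id"]))
    retained = [
        (sid, uid)
        for sid, uid in zip(screen["session_id"], screen["unit_id"])
        if (sid, uid) in active_keys and (sid, uid) not in selective_keys
    ]
    psths = unit_condition_psths(spikes, sigma_ms=sigma_ms, n_trials=n_trials)
    matrix = build_response_matrix(psths, retained)
    return {
        "screen": screen,
        "active_units": active,
        "retained_units": retained,
        "full_counts": full_counts,
        "second_half_counts": half_counts,
        "response_matrix": matrix,
        "n_trials": n_trials,
    }


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_response_matrix(matrix: ResponseMatrix, path) -> None:
    cols = [f"{cond}_t{int(t):04d}" for cond in CONDITIONS for t in GRID_MS]
    df = pd.DataFrame(matrix.R, columns=cols)
    df.insert(0, "session_id", matrix.session_ids)
    df.insert(1, "unit_id", matrix.unit_ids)
    df.to_csv(path, index=False, float_format="%.6f")


def read_response_matrix(path) -> ResponseMatrix:
    """Read a response matrix CSV (ours, or an externally supplied one).

    An external file may carry a bare units × 1004 numeric table; row labels
    are then synthesized.
    """
    df = pd.read_csv(path)
    if {"session_id", "unit_id"}.issubset(df.columns):
        R = df.drop(columns=["session_id", "unit_id"]).to_numpy(dtype=float)
        return ResponseMatrix(R=R, unit_ids=list(df["unit_id"].astype(str)),
                              session_ids=list(df["session_id"].astype(str)))
    R = df.to_numpy(dtype=float)
    ids = [f"u{i:04d}" for i in range(R.shape[0])]
    return ResponseMatrix(R=R, unit_ids=ids, session_ids=["external"] * R.shape[0])
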