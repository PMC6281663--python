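"""Assignment of units to canonical response patterns (CRPs).

Each unit is assigned to the CRP with maximum cosine similarity over its full
1004-sample concatenated profile.  CRPs are ordered chronologically by the
peak latency of their condition-averaged profile; a unit pair's *temporal
distance* is the absolute difference of the chronological ranks of their
CRPs.  A per-unit rank-sum test on second-half spike counts quantifies
whether the unit responds equivalently in physical-alternation and
flash-suppression trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nnmf import cosine_similarity_matrix
from .preprocessing import ResponseMatrix
from .stats import ALPHA, rank_sum_test
from .synthetic import GRID_MS, N_SAMPLES


@dataclass
class ChronologyMap:
    """Chronological ordering of CRPs by condition-averaged peak latency."""

    peak_times_ms: np.ndarray   # per CRP index
    ranks: np.ndarray           # CRP index -> rank 1..K (1 = earliest)
    flat_components: list       # constant profiles, ranked last and flagged

    def rank_of(self, crp_index: int) -> int:
        return int(self.ranks[crp_index])


def assign_units(matrix: ResponseMatrix, W: np.ndarray
                 ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Maximum-cosine assignment of every unit row to a CRP.

    Ties break to the lowest CRP index.  All-zero unit profiles cannot be
    assigned and are returned on a separate exclusion list.
    """
    S = cosine_similarity_matrix(matrix.R, np.asarray(W, dtype=float))
    best = np.argmax(S, axis=1)  # first maximum -> lowest CRP index on ties
    rows, excluded = [], []
    for i, (sid, uid) in enumerate(zip(matrix.session_ids, matrix.unit_ids)):
        if np.linalg.norm(matrix.R[i]) == 0:
            excluded.append((sid, uid))
            continue
        rows.append((sid, uid, int(best[i]), float(S[i, best[i]])))
    df = pd.DataFrame(rows, columns=["session_id", "unit_id", "crp_index",
                                     "cosine_similarity"])
    return df, excluded


def chronological_ranks(W: np.ndarray) -> ChronologyMap:
    """Rank CRPs by the peak latency of their condition-averaged profile.

    The peak time is the argmax of the mean of the four 251-sample condition
    blocks; ties break by the argmax over the full 1004-sample concatenation,
    then by component index.  Constant (flat) profiles are flagged and ranked
    last.
    """
    W = np.asarray(W, dtype=float)
    K = W.shape[0]
    if W.shape[1] != 4 * N_SAMPLES:
        raise ValueError("W must have 1004 columns (4 condition blocks)")
    avg = W.reshape(K, 4, N_SAMPLES).mean(axis=1)
    peak_times = GRID_MS[np.argmax(avg, axis=1)]
    concat_argmax = np.argmax(W, axis=1)
    flat = [k for k in range(K) if np.ptp(avg[k]) == 0]
    keys = [
        (1 if k in flat else 0, peak_times[k], concat_argmax[k], k)
        for k in range(K)
    ]
    order = sorted(range(K), key=lambda k: keys[k])
    ranks = np.empty(K, dtype=int)
    for rank, k in enumerate(order, start=1):
        ranks[k] = rank
    return ChronologyMap(peak_times_ms=peak_times, ranks=ranks, flat_components=flat)


def compare_pa_fs(pa_counts, fs_counts, alpha: float = ALPHA
                  ) -> tuple[float, bool, str]:
    """Second-half PA-vs-FS equivalence test for one unit.

    Returns (p, same_flag, direction): two-sided rank-sum p on the pooled PA
    versus pooled FS second-half spike counts, ``same_flag = (p > alpha)``
    and, for significant units, which condition fired more.
    """
    p = rank_sum_test(pa_counts, fs_counts)
    same = bool(p > alpha)
    if same:
        return p, True, "none"
    direction = "PA-higher" if np.mean(pa_counts) > np.mean(fs_counts) else "FS-higher"
    return p, False, direction


def pa_fs_table(assignments: pd.DataFrame, second_half_counts: pd.DataFrame,
                alpha: float = ALPHA) -> pd.DataFrame:
    """Per-unit PA/FS comparison for every assigned unit."""
    from .preprocessing import counts_by_condition

    rows = []
    for _, rec in assignments.iterrows():
        sid, uid = rec["session_id"], rec["unit_id"]
        by_cond = counts_by_condition(second_half_counts, sid, uid)
        pa = np.concatenate([by_cond["PA_polar_first"], by_cond["PA_face_first"]])
        fs = np.concatenate([by_cond["FS_polar_first"], by_cond["FS_face_first"]])
        p, same, direction = compare_pa_fs(pa, fs, alpha=alpha)
        rows.append((sid, uid, p, same, direction))
    return pd.DataFrame(rows, columns=["session_id", "unit_id", "pa_fs_p",
                                       "same_flag", "direction"])


def per_crp_summary(assignments: pd.DataFrame, pa_fs: pd.DataFrame,
                    chronology: ChronologyMap) -> pd.DataFrame:
    """Unit counts and PA/FS same-fraction per CRP, in chronological order."""
    merged = assignments.merge(pa_fs, on=["session_id", "unit_id"])
    rows = []
    for crp in sorted(merged["crp_index"].unique()):
        sub = merged[merged["crp_index"] == crp]
        rows.append({
            "crp_index": int(crp),
            "chron_rank": chronology.rank_of(int(crp)),
            "n_units": len(sub),
            "n_same": int(sub["same_flag"].sum()),
            "same_fraction": float(sub["same_flag"].mean()),
        })
    return pd.DataFrame(rows).sort_values("chron_rank").reset_index(drop=True)


def sort_units_by_peak(matrix: ResponseMatrix
                       ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Peak-latency ordering of units and unit-normalized condition images.

    Each unit's four condition blocks are averaged; units are ordered by the
    argmax latency of that average (all-zero units last).  The returned
    per-condition images divide each non-zero unit's profiles by the maximum
    of its averaged profile, so the averaged profile peaks at 1.
    """
    from .synthetic import CONDITIONS

    R = matrix.R
    n = R.shape[0]
    avg = R.reshape(n, 4, N_SAMPLES).mean(axis=1)
    peak_idx = np.argmax(avg, axis=1)
    norms = avg.max(axis=1)
    zero = norms == 0
    key = np.where(zero, N_SAMPLES + 1, peak_idx)
    order = np.argsort(key, kind="stable")
    scale = np.where(zero, 1.0, norms)[:, None]
    images = {
        cond: (R.reshape(n, 4, N_SAMPLES)[:, i, :] / scale)[order]
        for i, cond in enumerate(CONDITIONS)
    }
    return order, images
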