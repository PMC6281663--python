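"""Stability-constrained non-negative matrix factorization.

The response matrix ``R`` (units × 1004) is approximated as ``R ≈ H W`` with
``H`` (units × K) the non-negative weights and ``W`` (K × 1004) the canonical
response patterns (CRPs).  ``W`` is initialized as ``|N(0,1)| + 0.1`` and
``H`` by least-squares regression clipped at zero plus machine epsilon; the
factorization is optimized with Lee–Seung multiplicative updates for the
Frobenius objective.

Stability is enforced by a split-half bootstrap: at each of 50 bootstrap
iterations the rows of R are randomly partitioned into two halves, both
halves are factorized from the current W initialization, the two solutions'
components are matched one-to-one by cosine similarity, matched pairs
(similarity > 0.5) seed the next iteration's initialization and the rest are
re-randomized.  The components of the last 15 iterations — aligned by their
projection on the first kernel-PCA component of the pooled rows — yield a
per-component variability ratio (across-iteration variance over mean square,
both averaged over time); their average builds the initialization of one
final fit on the full matrix.

The number of components is selected by repeating this procedure over K and
many runs: the chosen K is the largest whose median across-run mean
variability is below 5%, and the reported solution is the run with minimum
residual error at that K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

_EPS_INIT = 2.22e-16  # offset added to the clipped least-squares H init
_EPS_DIV = 1e-12      # guard in multiplicative-update denominators


@dataclass
class Factorization:
    W: np.ndarray                 # (K, T) canonical response patterns
    H: np.ndarray                 # (n_units, K) weights
    residual_energy: float        # ||R - HW||^2 / ||R||^2
    explained_energy: float       # ||HW||^2 / ||R||^2
    n_iter: int = 0
    objective: list = field(default_factory=list, repr=False)

    @property
    def K(self) -> int:
        return self.W.shape[0]


@dataclass
class StabilityRun:
    """Result of one bootstrap-stabilized factorization at fixed K."""

    factorization: Factorization
    variability: np.ndarray       # per-component ratio
    mean_variability: float
    seed: int


@dataclass
class KSelectionReport:
    variability_by_k: dict        # K -> list of per-run mean variabilities
    median_by_k: dict             # K -> median across runs
    residual_by_k: dict           # K -> min residual energy across runs
    selected_k: int
    factorization: Factorization  # min-residual run at selected K
    cutoff: float


class KSelectionError(RuntimeError):
    """No K in the scanned range met the variability cutoff."""


# ---------------------------------------------------------------------------
# initialization and fitting
# ---------------------------------------------------------------------------

def _init_W(K: int, T: int, rng: np.random.Generator) -> np.ndarray:
    return np.abs(rng.standard_normal((K, T))) + 0.1


def _init_H(R: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Least-squares H for R ≈ H W, clipped at zero plus machine epsilon.

    The regression is solved through the pseudoinverse, so rank-deficient W
    never fails.
    """
    H, *_ = np.linalg.lstsq(W.T, R.T, rcond=None)
    return np.clip(H.T, 0.0, None) + _EPS_INIT


def init_factors(R: np.ndarray, K: int,
                 seed: int | np.random.Generator | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Random non-negative W0 (entries >= 0.1) and regression-based H0 > 0."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be non-negative")
    if not 1 <= K <= min(R.shape):
        raise ValueError("K must satisfy 1 <= K <= min(R.shape)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W0 = _init_W(K, R.shape[1], rng)
    return W0, _init_H(R, W0)


def fit_multiplicative(R: np.ndarray, W0: np.ndarray, H0: np.ndarray,
                       max_iter: int = 500, rel_tol: float = 1e-6) -> Factorization:
    """Lee–Seung multiplicative updates for the Frobenius objective.

    The objective ||R - HW||_F^2 is non-increasing across iterations; the fit
    stops at ``max_iter`` or when its relative decrease falls below
    ``rel_tol``.  An all-zero R is a documented degenerate case: H is driven
    to zero and both energies are 0 by convention.
    """
    R = np.asarray(R, dtype=float)
    W = np.array(W0, dtype=float)
    H = np.array(H0, dtype=float)
    r2 = float(np.sum(R * R))
    if r2 == 0.0:
        return Factorization(W=W, H=np.zeros_like(H), residual_energy=0.0,
                             explained_energy=0.0, n_iter=0, objective=[0.0])

    obj_hist = []
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        RWt = R @ W.T
        H *= RWt / (H @ (W @ W.T) + _EPS_DIV)
        HtR = H.T @ R
        W *= HtR / ((H.T @ H) @ W + _EPS_DIV)
        obj = float(np.sum((R - H @ W) ** 2))
        obj_hist.append(obj)
        if prev - obj < rel_tol * prev:
            break
        prev = obj
    hw2 = float(np.sum((H @ W) ** 2))
    return Factorization(W=W, H=H, residual_energy=obj_hist[-1] / r2,
                         explained_energy=hw2 / r2, n_iter=it, objective=obj_hist)


def energy_decomposition(R: np.ndarray, fact: Factorization) -> tuple[float, float]:
    """(explained, residual) energy of a factorization relative to ||R||^2.

    Both ratios are computed from their definitions; they are not assumed to
    sum to one (near-complementarity only holds at stationary points).
    """
    R = np.asarray(R, dtype=float)
    r2 = float(np.sum(R * R))
    if r2 == 0.0:
        raise ValueError("energy ratios are undefined for an all-zero matrix")
    HW = fact.H @ fact.W
    return float(np.sum(HW * HW)) / r2, float(np.sum((R - HW) ** 2)) / r2


# ---------------------------------------------------------------------------
# component matching and reordering
# ---------------------------------------------------------------------------

def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between rows; zero rows have similarity 0."""
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    S = A @ B.T
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    return S


def match_components(W_a: np.ndarray, W_b: np.ndarray, threshold: float = 0.5
                     ) -> list[tuple[int, int, float]]:
    """Optimal one-to-one component pairing by cosine similarity.

    Returns the pairs (row_a, row_b, similarity) of the assignment maximizing
    total similarity whose similarity exceeds ``threshold``.
    """
    if W_a.shape != W_b.shape:
        raise ValueError("matched matrices must share their shape")
    S = cosine_similarity_matrix(W_a, W_b)
    rows, cols = linear_sum_assignment(-S)
    return [(int(i), int(j), float(S[i, j])) for i, j in zip(rows, cols)
            if S[i, j] > threshold]


def _full_assignment(W_a: np.ndarray, W_b: np.ndarray) -> np.ndarray:
    """Column index of W_b assigned to each row of W_a (optimal pairing)."""
    S = cosine_similarity_matrix(W_a, W_b)
    _, cols = linear_sum_assignment(-S)
    return cols


def _kpca_projection(X: np.ndarray, kernel: str = "rbf") -> np.ndarray:
    """First kernel-principal-component projection of the rows of X.

    RBF bandwidth = median pairwise distance of the rows (linear kernel as
    option).  Degenerate inputs (identical rows) give a zero projection so
    downstream ordering falls back to the original index.
    """
    from sklearn.decomposition import KernelPCA

    X = np.asarray(X, dtype=float)
    if kernel == "rbf":
        from scipy.spatial.distance import pdist

        d = pdist(X)
        d = d[d > 0]
        if d.size == 0:
            return np.zeros(X.shape[0])
        gamma = 1.0 / (2.0 * np.median(d) ** 2)
        kpca = KernelPCA(n_components=1, kernel="rbf", gamma=gamma)
    elif kernel == "linear":
        kpca = KernelPCA(n_components=1, kernel="linear")
    else:
        raise ValueError(f"unknown KPCA kernel: {kernel!r}")
    try:
        proj = kpca.fit_transform(X)[:, 0]
    except Exception:  # degenerate spectrum
        return np.zeros(X.shape[0])
    return proj


def kpca_reorder(W_a: np.ndarray, W_b: np.ndarray, kernel: str = "rbf"
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Reorder both matrices' rows by their first-KPCA-component projection.

    The KPCA is fit on the pooled 2K rows, so matched components receive the
    same rank in both matrices.  Ties (e.g. identical rows) break stably by
    original row index.
    """
    if W_a.shape[0] != W_b.shape[0]:
        raise ValueError("row counts must match")
    pooled = np.vstack([W_a, W_b])
    proj = _kpca_projection(pooled, kernel=kernel)
    K = W_a.shape[0]
    order_a = np.argsort(proj[:K], kind="stable")
    order_b = np.argsort(proj[K:], kind="stable")
    return W_a[order_a], W_b[order_b]


def _align_history(history: list[np.ndarray], kernel: str = "rbf") -> np.ndarray:
    """Stack history matrices with rows consistently ordered across iterations.

    One KPCA is fit on the pooled rows of every stored matrix; each
    iteration's rows are then sorted by their projection, so a stable
    component occupies the same slot in every iteration.
    """
    K = history[0].shape[0]
    pooled = np.vstack(history)
    proj = _kpca_projection(pooled, kernel=kernel)
    out = []
    for i, W in enumerate(history):
        order = np.argsort(proj[i * K:(i + 1) * K], kind="stable")
        out.append(W[order])
    return np.stack(out)


def component_variability(W_history: np.ndarray) -> np.ndarray:
    """Per-component variability ratio over an aligned history.

    ``W_history`` has shape (n_iterations, K, T).  For each component the
    ratio is the across-iteration variance divided by the across-iteration
    mean square, both averaged across time.  An all-zero component is flagged
    unstable (ratio = inf).
    """
    W_history = np.asarray(W_history, dtype=float)
    var = W_history.var(axis=0, ddof=1).mean(axis=1)
    ms = (W_history**2).mean(axis=0).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ms > 0, var / np.where(ms > 0, ms, 1.0), np.inf)
    return ratio


# ---------------------------------------------------------------------------
# bootstrap stability procedure
# ---------------------------------------------------------------------------

def bootstrap_stability_run(
    R: np.ndarray,
    K: int,
    seed: int,
    n_bootstrap: int = 50,
    history_len: int = 15,
    cosine_threshold: float = 0.5,
    inner_max_iter: int = 200,
    inner_rel_tol: float = 1e-5,
    final_max_iter: int = 500,
    final_rel_tol: float = 1e-6,
    kernel: str = "rbf",
) -> StabilityRun:
    """One bootstrap-stabilized NNMF run at fixed K.

    Each bootstrap iteration fits the two random half-populations from the
    current W initialization (H re-initialized by clipped regression per
    half), matches the two solutions, carries the averages of matched pairs
    forward and re-randomizes the rest.  With an odd row count the first half
    receives the extra row.  The history keeps both half-solutions of each of
    the last ``history_len`` iterations (the components actually found), so
    between-half disagreement — the signature of an unstable rank — enters
    the variability; the KPCA-aligned history mean initializes the final
    full-matrix fit and its dispersion yields the per-component variability
    ratios.
    """
    R = np.asarray(R, dtype=float)
    n, T = R.shape
    if n < 2 * K:
        raise ValueError("bootstrap stability needs at least 2K rows in R")
    if n_bootstrap < history_len:
        raise ValueError("n_bootstrap must be >= history_len")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    W = _init_W(K, T, rng)
    history: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_bootstrap):
        perm = rng.permutation(n)
        n_first = (n + 1) // 2
        R1, R2 = R[perm[:n_first]], R[perm[n_first:]]
        f1 = fit_multiplicative(R1, W, _init_H(R1, W),
                                max_iter=inner_max_iter, rel_tol=inner_rel_tol)
        f2 = fit_multiplicative(R2, W, _init_H(R2, W),
                                max_iter=inner_max_iter, rel_tol=inner_rel_tol)
        assign = _full_assignment(f1.W, f2.W)
        S = cosine_similarity_matrix(f1.W, f2.W)
        history.append((f1.W, f2.W[assign]))
        W_next = np.empty_like(W)
        for i, j in enumerate(assign):
            if S[i, j] > cosine_threshold:
                W_next[i] = 0.5 * (f1.W[i] + f2.W[j])
            else:
                W_next[i] = _init_W(1, T, rng)[0]
        W = W_next
        if len(history) > history_len:
            history.pop(0)

    aligned = _align_history([m for pair in history for m in pair], kernel=kernel)
    variability = component_variability(aligned)
    W_init_final = aligned.mean(axis=0)
    final = fit_multiplicative(R, W_init_final, _init_H(R, W_init_final),
                               max_iter=final_max_iter, rel_tol=final_rel_tol)
    return StabilityRun(factorization=final, variability=variability,
                        mean_variability=float(np.mean(variability)), seed=seed)


def select_k(
    R: np.ndarray,
    k_range=range(2, 11),
    runs: int = 100,
    variability_cutoff: float = 0.05,
    seed: int = 0,
    n_jobs: int = 1,
    **run_kwargs,
) -> KSelectionReport:
    """Scan K, run the bootstrap procedure ``runs`` times each, select K.

    The per-run summary entering the median is the mean across components of
    the variability ratio.  The selected K is the largest with median < the
    cutoff; the reported factorization is the minimum-residual run at that K.
    Raises :class:`KSelectionError` (carrying the full variability table)
    when no K qualifies.
    """
    k_range = list(k_range)
    master = np.random.SeedSequence(seed)
    run_seeds: dict[int, list[int]] = {}
    for K, child in zip(k_range, master.spawn(len(k_range))):
        run_seeds[K] = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(runs)]

    def one(K: int, s: int) -> StabilityRun:
        return bootstrap_stability_run(R, K, seed=s, **run_kwargs)

    results: dict[int, list[StabilityRun]] = {}
    if n_jobs != 1:
        from joblib import Parallel, delayed

        flat = [(K, s) for K in k_range for s in run_seeds[K]]
        fitted = Parallel(n_jobs=n_jobs)(delayed(one)(K, s) for K, s in flat)
        for (K, _), res in zip(flat, fitted):
            results.setdefault(K, []).append(res)
    else:
        for K in k_range:
            results[K] = [one(K, s) for s in run_seeds[K]]

    variability_by_k = {K: [r.mean_variability for r in results[K]] for K in k_range}
    median_by_k = {K: float(np.median(v)) for K, v in variability_by_k.items()}
    residual_by_k = {
        K: float(min(r.factorization.residual_energy for r in results[K]))
        for K in k_range
    }
    admissible = [K for K in k_range if median_by_k[K] < variability_cutoff]
    if not admissible:
        raise KSelectionError(
            f"no K in {k_range} met median variability < {variability_cutoff}; "
            f"medians: {median_by_k}"
        )
    selected = max(admissible)
    best = min(results[selected], key=lambda r: r.factorization.residual_energy)
    return KSelectionReport(
        variability_by_k=variability_by_k,
        median_by_k=median_by_k,
        residual_by_k=residual_by_k,
        selected_k=selected,
        factorization=best.factorization,
        cutoff=variability_cutoff,
    )
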