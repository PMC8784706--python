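"""Archetypal analysis by alternating constrained least squares.

Data rows are approximated as convex combinations of k archetypes,
X ~ A.Z, where the score rows of A live on the probability simplex and the
archetypes themselves are convex combinations of data rows, Z = B.X. Both
simplex-constrained subproblems are solved as non-negative least squares on
a system augmented with a heavily weighted sum-to-one row. A robust variant
recomputes bisquare observation weights from residual norms at every outer
iteration so that gross outliers neither pull the archetype positions nor
get selected as hull vertices.

The user-facing entry point is the :class:`ArchetypalAnalysis` model whose
``fit`` returns an :class:`ArchetypeResults`; the module-level functions
expose the individual solver steps.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "ArchetypalAnalysis",
    "ArchetypeResults",
    "solve_simplex_weights",
    "fit_archetypes",
    "fit_robust_archetypes",
    "best_of_restarts",
    "project_scores",
]

_NEG_CLAMP = -1e-9


def _augmentation_weight(basis: np.ndarray) -> float:
    scale = float(np.max(np.abs(basis)))
    return 200.0 * (scale if scale > 0 else 1.0)


def _clamp_simplex(W: np.ndarray) -> np.ndarray:
    """Clamp tiny negative weights to 0 and renormalize rows to sum 1."""
    W = np.where((W < 0) & (W > _NEG_CLAMP), 0.0, W)
    W = np.clip(W, 0.0, None)
    s = W.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return W / s


def solve_simplex_weights(targets: np.ndarray, basis: np.ndarray,
                          ridge: np.ndarray | None = None) -> np.ndarray:
    """Simplex-constrained least squares for a batch of target rows.

    For each row t of ``targets`` solves  min ||t - w.basis||^2  subject to
    w >= 0 and sum(w) = 1, as non-negative least squares on the system
    augmented with a sum-to-one row of weight M = 200 x max|basis|.

    ``ridge``, if given, is a per-basis-row penalty vector lambda_i adding
    sum(lambda_i * w_i^2) to the objective (used by the robust fit to keep
    down-weighted observations out of the archetype hull).

    For a small basis (<= 8 rows) the exact optimum is found by enumerating
    active supports; otherwise an active-set NNLS is run per row.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[0] == 0:
        raise ValueError("basis must be a non-empty 2-D array")
    if targets.shape[1] != basis.shape[1]:
        raise ValueError("targets and basis have incompatible column counts")
    k = basis.shape[0]
    M = _augmentation_weight(basis)
    if k <= 8:
        W = _solve_by_support_enumeration(targets, basis, M, ridge)
    else:
        W = _solve_by_nnls(targets, basis, M, ridge)
    return _clamp_simplex(W)


def _solve_by_support_enumeration(T: np.ndarray, B: np.ndarray, M: float,
                                  ridge: np.ndarray | None) -> np.ndarray:
    n, k = T.shape[0], B.shape[0]
    G = B @ B.T + (M * M)
    if ridge is not None:
        G = G + np.diag(np.asarray(ridge, dtype=float))
    C = T @ B.T + (M * M)  # (n, k): cross terms incl. the augmentation row
    best_obj = np.full(n, np.inf)
    best_W = np.zeros((n, k))
    for size in range(1, k + 1):
        for support in itertools.combinations(range(k), size):
            S = list(support)
            G_S = G[np.ix_(S, S)]
            try:
                W_S = np.linalg.solve(G_S, C[:, S].T).T  # (n, size)
            except np.linalg.LinAlgError:
                W_S, *_ = np.linalg.lstsq(G_S, C[:, S].T, rcond=None)
                W_S = W_S.T
            feasible = np.all(W_S >= -1e-12, axis=1)
            if not feasible.any():
                continue
            obj = -2.0 * (W_S * C[:, S]).sum(axis=1) + np.einsum(
                "ni,ij,nj->n", W_S, G_S, W_S)
            better = feasible & (obj < best_obj - 1e-14)
            if better.any():
                best_obj[better] = obj[better]
                best_W[better] = 0.0
                best_W[np.ix_(better, S)] = W_S[better]
    return best_W


def _solve_by_nnls(T: np.ndarray, B: np.ndarray, M: float,
                   ridge: np.ndarray | None) -> np.ndarray:
    k = B.shape[0]
    design = np.vstack([B.T, np.full((1, k), M)])
    if ridge is not None:
        design = np.vstack([design, np.diag(np.sqrt(np.asarray(ridge, dtype=float)))])
    W = np.empty((T.shape[0], k))
    pad = design.shape[0] - B.shape[1] - 1
    for i, t in enumerate(T):
        rhs = np.concatenate([t, [M], np.zeros(pad)])
        W[i], _ = nnls(design, rhs)
    return W


def _bisquare_weights(residual_norms: np.ndarray, data_scale: float) -> np.ndarray:
    """Tukey bisquare weights, tuning constant c = 6 x median residual norm.

    The median is taken over rows with non-negligible residual: in
    archetypal analysis every row inside the current hull is fitted
    exactly, so the residual-norm distribution is zero-inflated and the
    plain median would collapse the constant and zero out every boundary
    row. The constant is additionally floored at 0.3 x the RMS data-row
    norm: a row is only ever treated as outlying if it sits far outside the
    hull relative to the overall data scale, which keeps boundary rows of
    clean (low-noise) data at full weight while still zeroing gross
    outliers several data-scales away.
    """
    positive = residual_norms[residual_norms > 1e-9 * data_scale]
    med = float(np.median(positive)) if positive.size else 0.0
    c = max(6.0 * med, 0.3 * data_scale)
    if c <= 0:
        return np.ones_like(residual_norms)
    u = np.clip(residual_norms / c, 0.0, 1.0)
    return (1.0 - u * u) ** 2


def _furthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Pick k well-separated data rows: random start, then greedy max-min."""
    n = X.shape[0]
    chosen = [int(rng.integers(n))]
    d = np.linalg.norm(X - X[chosen[0]], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(X - X[nxt], axis=1))
    return X[chosen].copy()


@dataclass
class ArchetypeResults:
    """Fitted archetypal decomposition.

    ``archetypes`` is the k x m matrix Z, ``scores`` the n x k simplex
    matrix A, ``mixers`` the k x n simplex matrix B with Z = B.X.
    """

    archetypes: np.ndarray
    scores: np.ndarray
    mixers: np.ndarray
    rss: float
    robust_weights: np.ndarray
    k: int
    iterations: int
    converged: bool
    seed: int | None
    rss_trace: list[float] = field(default_factory=list)
    column_names: list[str] | None = None
    model: "ArchetypalAnalysis | None" = None
    objective: float = float("nan")

    def project(self, X_new: np.ndarray) -> np.ndarray:
        """Score new observations against the fitted archetypes (A-step only)."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.archetypes.shape[1]:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model expects "
                f"{self.archetypes.shape[1]}")
        return solve_simplex_weights(X_new, self.archetypes)

    def summary(self) -> str:
        lines = [
            "Archetypal analysis results",
            "===========================",
            f"archetypes (k):      {self.k}",
            f"observations:        {self.scores.shape[0]}",
            f"phenotypes:          {self.archetypes.shape[1]}",
            f"RSS:                 {self.rss:.6g}",
            f"iterations:          {self.iterations}",
            f"converged:           {self.converged}",
            f"min robust weight:   {self.robust_weights.min():.3f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "archetypes": self.archetypes.tolist(),
            "scores": self.scores.tolist(),
            "rss": self.rss,
            "iterations": self.iterations,
            "converged": self.converged,
            "seed": self.seed,
            "column_names": self.column_names,
        }


class ArchetypalAnalysis:
    """Archetypal-analysis model for a subjects x phenotypes matrix.

    Parameters
    ----------
    X : array-like, shape (n, m)
        Finite data matrix (typically rank-normalized, residualized
        phenotypes).
    k : int
        Number of archetypes, 1 <= k <= n.
    robust : bool
        Use iteratively reweighted (bisquare) steps so outlying subjects do
        not dominate the archetype positions. Default True, matching the
        robust flavour used for patient stratification.
    tol : float
        Relative RSS change below which the alternation stops.
    max_iter : int
        Cap on alternating iterations.
    """

    def __init__(self, X: np.ndarray, k: int, *, robust: bool = True,
                 tol: float = 1e-6, max_iter: int = 200,
                 column_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if not 1 <= k <= X.shape[0]:
            raise ValueError(f"need 1 <= k <= n rows, got k={k}, n={X.shape[0]}")
        self.X = X
        self.k = int(k)
        self.robust = robust
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.column_names = column_names

    # ------------------------------------------------------------------
    def fit(self, *, seed: int | None = None, Z0: np.ndarray | None = None) -> ArchetypeResults:
        """Run the alternating scheme from one (seeded) initialization."""
        X, k = self.X, self.k
        n = X.shape[0]
        rng = np.random.default_rng(seed)
        if Z0 is None:
            if self.robust:
                # random rows of low outlyingness: the furthest-point
                # heuristic (or an unlucky uniform draw) would seed vertices
                # at the very outliers we want to resist, which then carry
                # zero residual and full weight forever
                d = np.linalg.norm(X - np.median(X, axis=0), axis=1)
                eligible = np.flatnonzero(d <= np.quantile(d, 0.75))
                if eligible.size < k:
                    eligible = np.arange(n)
                Z = X[rng.choice(eligible, size=k, replace=False)].copy()
            else:
                Z = _furthest_point_init(X, k, rng)
        else:
            Z = np.asarray(Z0, dtype=float).copy()
            if Z.shape != (k, X.shape[1]):
                raise ValueError("Z0 has wrong shape")
        B = solve_simplex_weights(Z, X)
        Z = B @ X
        weights = np.ones(n)
        xnorm2 = float(np.sum(X * X))
        floor = 1e-12 * max(xnorm2, 1.0)
        prev_obj = np.inf
        trace: list[float] = []
        best = None
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            A = solve_simplex_weights(X, Z)
            fitted = A @ Z
            resid = X - fitted
            rss = float(np.sum(resid * resid))
            rnorm = np.linalg.norm(resid, axis=1)
            if self.robust:
                weights = _bisquare_weights(rnorm, np.sqrt(xnorm2 / n))
                if weights.max() <= 0:  # never let the weights vanish entirely
                    weights = np.ones(n)
                obj = float(np.sum(weights * rnorm * rnorm))
            else:
                obj = rss
            trace.append(obj)
            if best is None or obj < best[0]:
                best = (obj, rss, A.copy(), Z.copy(), B.copy(), weights.copy())
            if not self.robust and obj > prev_obj * (1.0 + 1e-10):
                break  # plain alternation stalled; keep the best iterate
            if obj <= floor or (prev_obj < np.inf and
                                abs(prev_obj - obj) <= max(self.tol * prev_obj, floor)):
                converged = True
                break
            prev_obj = obj

            # robust step: substitute down-weighted rows by their fitted
            # values, so gross outliers stop steering the hull while clean
            # rows (weight ~1) pass through unchanged
            if self.robust:
                X_work = weights[:, None] * X + (1.0 - weights[:, None]) * fitted
            else:
                X_work = X
            # Z-step: least squares given the scores
            Z_ls, *_ = np.linalg.lstsq(A, X_work, rcond=None)
            # degenerate archetypes (no usage) restart at the worst-fit row
            usage = A.max(axis=0)
            dead = np.flatnonzero(usage < 1e-8)
            if dead.size:
                worst = np.argsort(-rnorm)
                for d, w_idx in zip(dead, worst):
                    Z_ls[d] = X_work[w_idx]
                warnings.warn(f"reinitialized {dead.size} unused archetype(s)",
                              RuntimeWarning, stacklevel=2)
            # B-step: express archetypes as convex mixtures of (cleaned) rows
            B = solve_simplex_weights(Z_ls, X_work)
            Z = B @ X_work

        obj, rss, A, Z, B, weights = best
        if self.robust:
            # re-anchor the archetypes on the original data rows so Z = B.X
            # holds over the data, ridge-penalizing down-weighted rows so the
            # anchoring cannot hand a vertex to an outlier
            scale2 = float(xnorm2 / n)
            B = solve_simplex_weights(Z, X, ridge=(1.0 - weights) * scale2)
            Z = B @ X
            A = solve_simplex_weights(X, Z)
            resid = X - A @ Z
            rss = float(np.sum(resid * resid))
        res = ArchetypeResults(
            archetypes=Z, scores=A, mixers=B, rss=rss,
            robust_weights=weights, k=k, iterations=it, converged=converged,
            seed=seed, rss_trace=trace, column_names=self.column_names,
            model=self)
        res.objective = obj
        return res

    # ------------------------------------------------------------------
    def fit_restarts(self, n_restarts: int = 100, *, seed: int | None = None
                     ) -> ArchetypeResults:
        """Best (lowest-RSS) model over deterministic multi-restart fits."""
        if n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        child_seeds = derive_seeds(seed, n_restarts)
        best = None
        for s in child_seeds:
            res = self.fit(seed=int(s))
            # for plain fits the objective IS the RSS; for robust fits the
            # weighted objective keeps outlier-chasing restarts from winning
            if best is None or res.objective < best.objective:
                best = res
        if not best.converged:
            warnings.warn("no restart converged; returning best-RSS model",
                          RuntimeWarning, stacklevel=2)
        return best


def derive_seeds(seed: int | None, n: int) -> np.ndarray:
    """Deterministic child seeds (< 2**31) for restarts/replicates."""
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    return ss.generate_state(n) % np.uint32(2 ** 31)


# ----------------------------------------------------------------------
# functional surface

def fit_archetypes(X, k, tol: float = 1e-6, max_iter: int = 200,
                   seed: int | None = None) -> ArchetypeResults:
    """Plain (non-robust) archetypal fit from one initialization."""
    return ArchetypalAnalysis(X, k, robust=False, tol=tol,
                              max_iter=max_iter).fit(seed=seed)


def fit_robust_archetypes(X, k, tol: float = 1e-6, max_iter: int = 200,
                          seed: int | None = None) -> ArchetypeResults:
    """Robust (bisquare-reweighted) archetypal fit from one initialization."""
    return ArchetypalAnalysis(X, k, robust=True, tol=tol,
                              max_iter=max_iter).fit(seed=seed)


def best_of_restarts(X, k, n_restarts: int, seed: int | None = None, *,
                     robust: bool = True, tol: float = 1e-6,
                     max_iter: int = 200) -> ArchetypeResults:
    """Best-RSS robust fit over ``n_restarts`` seeded restarts."""
    return ArchetypalAnalysis(X, k, robust=robust, tol=tol, max_iter=max_iter
                              ).fit_restarts(n_restarts, seed=seed)


def project_scores(result: ArchetypeResults, X_new) -> np.ndarray:
    """Simplex scores of new rows under a fitted model (A-step only)."""
    return result.project(X_new)
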