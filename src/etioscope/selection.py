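"""Model selection and stability for the archetypal decomposition.

The number of archetypes is chosen by combining an RSS scree over k with a
subsampling stability protocol: refit on random 90% subsamples, match the
replicate archetypes to the full-data reference by cosine similarity, and
score the agreement of the induced subject partitions with the adjusted
Rand index across a grid of membership thresholds. A greedy
correlation-pruning search finds the smallest phenotype subset whose
archetypes still match the full-model archetypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .archetypes import ArchetypalAnalysis, ArchetypeResults, derive_seeds
from .preprocess import PhenotypeMatrix, prune_by_correlation

__all__ = [
    "ScreeResult",
    "StabilityResult",
    "scree",
    "match_archetypes",
    "assign_labels",
    "adjusted_rand_index",
    "stability_by_subsampling",
    "find_minimal_parameter_set",
]

MIXED_LABEL = "mixed"

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


def _letters(k: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(k)]


@dataclass
class ScreeResult:
    """Best-of-restarts RSS per candidate number of archetypes."""

    k_values: list[int]
    best_rss: list[float]
    restarts: int
    models: dict = field(default_factory=dict, repr=False)

    def as_arrays(self):
        return np.asarray(self.k_values), np.asarray(self.best_rss)


def scree(X: np.ndarray, k_range=range(1, 11), n_restarts: int = 100,
          seed: int | None = None, *, robust: bool = True) -> ScreeResult:
    """RSS scree over k with nested initialization.

    Besides the seeded restarts, each k > min(k_range) gets one extra
    restart initialized from the best (k-1)-archetype solution plus the
    worst-fit data row, which enforces (up to tolerance) the monotone
    decrease of the best RSS in k.
    """
    k_values = sorted(k_range)
    if not k_values:
        raise ValueError("k_range must be non-empty")
    if k_values[-1] > X.shape[0]:
        raise ValueError("max(k_range) cannot exceed the number of rows")
    results: dict[int, ArchetypeResults] = {}
    prev_best: ArchetypeResults | None = None
    for k in k_values:
        model = ArchetypalAnalysis(X, k, robust=robust)
        best = model.fit_restarts(n_restarts, seed=seed)
        if prev_best is not None and prev_best.k == k - 1:
            resid = X - prev_best.scores @ prev_best.archetypes
            worst = int(np.argmax(np.linalg.norm(resid, axis=1)))
            Z0 = np.vstack([prev_best.archetypes, X[worst]])
            nested = model.fit(seed=int(derive_seeds(seed, 1)[0]), Z0=Z0)
            if nested.objective < best.objective:
                best = nested
        results[k] = best
        prev_best = best
    return ScreeResult(k_values=k_values,
                       best_rss=[results[k].rss for k in k_values],
                       restarts=n_restarts, models=results)


def match_archetypes(Z_ref: np.ndarray, Z_new: np.ndarray,
                     shared_columns: np.ndarray | list | None = None,
                     ref_names: list | None = None,
                     new_names: list | None = None):
    """One-to-one archetype matching by maximal total cosine similarity.

    Returns ``(permutation, similarities)`` such that archetype j of the
    new model corresponds to archetype permutation[j] of the reference.
    When the two models were fitted on different phenotype subsets, pass
    ``shared_columns`` (with ``ref_names`` / ``new_names``) to restrict the
    comparison to the common columns.
    """
    Z_ref = np.asarray(Z_ref, dtype=float)
    Z_new = np.asarray(Z_new, dtype=float)
    if Z_ref.shape[0] != Z_new.shape[0]:
        raise ValueError("models have different numbers of archetypes")
    if shared_columns is not None:
        if ref_names is None or new_names is None:
            raise ValueError("shared_columns requires ref_names and new_names")
        ref_idx = [list(ref_names).index(c) for c in shared_columns]
        new_idx = [list(new_names).index(c) for c in shared_columns]
        Z_ref = Z_ref[:, ref_idx]
        Z_new = Z_new[:, new_idx]
    elif Z_ref.shape[1] != Z_new.shape[1]:
        raise ValueError("column sets differ; pass shared_columns")
    ref_n = Z_ref / np.maximum(np.linalg.norm(Z_ref, axis=1, keepdims=True), 1e-300)
    new_n = Z_new / np.maximum(np.linalg.norm(Z_new, axis=1, keepdims=True), 1e-300)
    S = new_n @ ref_n.T  # (new, ref) cosine similarities
    rows, cols = linear_sum_assignment(-S)
    perm = np.empty(Z_ref.shape[0], dtype=int)
    perm[rows] = cols
    similarities = S[np.arange(len(perm)), perm]
    return perm, similarities


def assign_labels(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Label subjects by their dominant archetype at a membership cutoff.

    Returns the letter of the argmax archetype where the maximum score
    exceeds ``threshold``, else the sentinel ``"mixed"``; at threshold 0
    every subject receives an archetype label.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if np.max(np.abs(scores.sum(axis=1) - 1.0)) > 1e-4 or np.any(scores < -1e-4):
        raise ValueError("score rows must lie on the probability simplex")
    letters = np.asarray(_letters(scores.shape[1]), dtype=object)
    arg = scores.argmax(axis=1)
    top = scores[np.arange(scores.shape[0]), arg]
    labels = letters[arg]
    labels[top <= threshold] = MIXED_LABEL
    if threshold == 0.0:
        labels = letters[arg]
    return labels


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two labelings.

    1 for identical partitions, expectation 0 under independent random
    partitions; if both partitions are trivial (a single class, or all
    singletons) the index is 1 when they are equal as partitions and 0
    otherwise.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    return float(adjusted_rand_score(a, b))


@dataclass
class StabilityResult:
    """ARI distribution per membership threshold from subsampling."""

    k: int
    thresholds: list[float]
    ari_distribution: dict
    median_ari: dict
    replicates: int
    subsample_fraction: float
    reference: ArchetypeResults | None = None

    def median_at(self, threshold: float) -> float:
        key = min(self.median_ari, key=lambda t: abs(t - threshold))
        return self.median_ari[key]

    def to_frame(self):
        import pandas as pd
        rows = [{"k": self.k, "threshold": t, "replicate": r, "ari": v}
                for t in self.thresholds
                for r, v in enumerate(self.ari_distribution[t])]
        return pd.DataFrame(rows)


def stability_by_subsampling(X: np.ndarray, k: int, fraction: float = 0.9,
                             replicates: int = 100,
                             thresholds=DEFAULT_THRESHOLDS,
                             seed: int = 0, *,
                             reference: ArchetypeResults | None = None,
                             reference_restarts: int = 20,
                             replicate_restarts: int = 5,
                             mixed_policy: str = "pool",
                             robust: bool = True) -> StabilityResult:
    """Subsampling stability of the k-archetype solution.

    Fits a reference model on the full data, then repeatedly refits on
    random ``fraction`` subsamples (without replacement), matches replicate
    archetypes to the reference by cosine similarity and, for every
    membership threshold, computes the adjusted Rand index between the
    replicate labeling and the reference labeling restricted to the
    subsampled subjects. Subjects below threshold form a single "mixed"
    class (``mixed_policy="pool"``) or are dropped from the comparison
    (``"exclude"``). Replicate r derives its seed as seed + 1 + r.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if mixed_policy not in ("pool", "exclude"):
        raise ValueError("mixed_policy must be 'pool' or 'exclude'")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n_sub = int(round(fraction * n))
    if n_sub < k:
        raise ValueError("subsample smaller than the number of archetypes")
    if reference is None:
        reference = ArchetypalAnalysis(X, k, robust=robust).fit_restarts(
            reference_restarts, seed=seed)
    thresholds = [float(t) for t in thresholds]
    ref_labels = {t: assign_labels(reference.scores, t) for t in thresholds}

    dist: dict[float, list[float]] = {t: [] for t in thresholds}
    for r in range(replicates):
        rep_seed = seed + 1 + r
        rng = np.random.default_rng(rep_seed)
        idx = rng.choice(n, size=n_sub, replace=False)
        rep = ArchetypalAnalysis(X[idx], k, robust=robust).fit_restarts(
            replicate_restarts, seed=rep_seed)
        perm, _ = match_archetypes(reference.archetypes, rep.archetypes)
        # reorder replicate scores into the reference archetype order
        inv = np.empty(k, dtype=int)
        inv[perm] = np.arange(k)
        rep_scores = rep.scores[:, inv]
        for t in thresholds:
            rep_lab = assign_labels(rep_scores, t)
            ref_lab = ref_labels[t][idx]
            if mixed_policy == "exclude":
                keep = (rep_lab != MIXED_LABEL) & (ref_lab != MIXED_LABEL)
                if keep.sum() < 2:
                    dist[t].append(np.nan)
                    continue
                rep_lab, ref_lab = rep_lab[keep], ref_lab[keep]
            dist[t].append(adjusted_rand_index(ref_lab, rep_lab))
    medians = {t: float(np.nanmedian(dist[t])) for t in thresholds}
    return StabilityResult(k=k, thresholds=thresholds, ari_distribution=dist,
                           median_ari=medians, replicates=replicates,
                           subsample_fraction=fraction, reference=reference)


DEFAULT_PRUNING_CUTOFFS = (0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)


@dataclass
class PruningSearchResult:
    chosen_cutoff: float | None
    retained_columns: list[str]
    similarities: np.ndarray
    satisfied: bool
    per_cutoff: dict


def find_minimal_parameter_set(matrix: PhenotypeMatrix,
                               cutoffs=DEFAULT_PRUNING_CUTOFFS,
                               k: int = 4, similarity_threshold: float = 0.8,
                               seed: int = 0, *, n_restarts: int = 5,
                               reference: ArchetypeResults | None = None,
                               robust: bool = True) -> PruningSearchResult:
    """Smallest pruned phenotype set preserving all archetypes.

    For each correlation cutoff (descending): prune columns, refit k
    archetypes on the retained set, and match them to the full-model
    archetypes on the shared columns. The chosen cutoff is the last
    (lowest) one at which every matched cosine similarity exceeds
    ``similarity_threshold``; if none qualifies, the best attempt is
    returned with ``satisfied=False``.
    """
    cutoffs = list(cutoffs)
    if any(np.diff(cutoffs) >= 0):
        raise ValueError("cutoffs must be strictly descending")
    names = list(matrix.column_names)
    X = matrix.values
    if reference is None:
        reference = ArchetypalAnalysis(X, k, robust=robust,
                                       column_names=names).fit_restarts(
            n_restarts, seed=seed)
    per_cutoff = {}
    chosen = None
    for cutoff in cutoffs:
        retained = prune_by_correlation(matrix, cutoff)
        idx = [names.index(c) for c in retained]
        sub = ArchetypalAnalysis(X[:, idx], k, robust=robust,
                                 column_names=retained).fit_restarts(
            n_restarts, seed=seed)
        _, sims = match_archetypes(reference.archetypes, sub.archetypes,
                                   shared_columns=retained, ref_names=names,
                                   new_names=retained)
        ok = bool(np.all(sims > similarity_threshold))
        per_cutoff[cutoff] = {"retained": retained, "similarities": sims,
                              "satisfied": ok}
        if ok:
            chosen = cutoff
    if chosen is None:
        best = max(per_cutoff, key=lambda c: float(np.min(
            per_cutoff[c]["similarities"])))
        warnings.warn("no pruning cutoff preserved all archetypes above "
                      f"{similarity_threshold}; best attempt at {best}",
                      RuntimeWarning, stacklevel=2)
        info = per_cutoff[best]
        return PruningSearchResult(None, info["retained"],
                                   info["similarities"], False, per_cutoff)
    info = per_cutoff[chosen]
    return PruningSearchResult(chosen, info["retained"], info["similarities"],
                               True, per_cutoff)
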