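"""Extreme and mixed-etiology group assignment, and longitudinal flows.

Subjects whose top archetype score exceeds 0.6 form the extreme groups
(A-D); everyone else belongs to the mixed-etiology group, which is further
divided into 12 ordered primary/secondary groups ("AB", "CD", ...) by the
two highest-scoring archetypes, with dominance categories counting how
many scores reach 0.4. Transition flows count subjects moving between
groups across visits.
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "DominanceCategory",
    "assign_extreme_groups",
    "assign_mixed_groups",
    "make_assignments",
    "transition_flows",
    "cross_visit_score_correlations",
]

MIX_LABEL = "MIX"


class DominanceCategory(str, Enum):
    EXTREME = "extreme"
    SINGLE_DOMINATING = "single_dominating"
    TWO_DOMINATING = "two_dominating"
    NONE_DOMINATING = "none_dominating"


def _letters(k: int) -> np.ndarray:
    return np.asarray([chr(ord("A") + i) for i in range(k)], dtype=object)


def _check_simplex(scores: np.ndarray) -> np.ndarray:
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if np.max(np.abs(scores.sum(axis=1) - 1.0)) > 1e-4 or np.any(scores < -1e-4):
        raise ValueError("score rows must lie on the probability simplex")
    return scores


def assign_extreme_groups(scores: np.ndarray, threshold: float = 0.6) -> np.ndarray:
    """Extreme-archetype labels: the archetype scoring strictly above the
    threshold, else "MIX".

    For thresholds above 0.5 at most one score can exceed the cutoff
    (scores sum to one), so the label is unique; at or below 0.5 a warning
    is emitted and ties resolve to the first maximum.
    """
    scores = _check_simplex(scores)
    if threshold <= 0.5:
        warnings.warn("threshold <= 0.5: dominant archetype may not be unique; "
                      "using the first maximum", RuntimeWarning, stacklevel=2)
    letters = _letters(scores.shape[1])
    arg = scores.argmax(axis=1)
    top = scores[np.arange(scores.shape[0]), arg]
    labels = letters[arg].copy()
    labels[top <= threshold] = MIX_LABEL
    return labels


def assign_mixed_groups(scores: np.ndarray, dominance: float = 0.4,
                        extreme_threshold: float | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Ordered primary/secondary mixed-etiology labels and dominance categories.

    The mixed label concatenates the letters of the largest and
    second-largest scores (ties broken by the fixed archetype order
    A < B < C < D); the dominance category counts scores >= ``dominance``
    (0 -> none_dominating, 1 -> single_dominating, >= 2 -> two_dominating).
    If ``extreme_threshold`` is given, subjects with a score strictly above
    it are labelled by their single letter with category "extreme" instead.
    """
    scores = _check_simplex(scores)
    n, k = scores.shape
    letters = _letters(k)
    # stable argsort on negated scores: ties fall to the earlier archetype
    order = np.argsort(-scores, axis=1, kind="stable")
    primary, secondary = order[:, 0], order[:, 1]
    labels = np.asarray([letters[p] + letters[s]
                         for p, s in zip(primary, secondary)], dtype=object)
    n_dominating = (scores >= dominance).sum(axis=1)
    category = np.where(
        n_dominating == 0, DominanceCategory.NONE_DOMINATING.value,
        np.where(n_dominating == 1, DominanceCategory.SINGLE_DOMINATING.value,
                 DominanceCategory.TWO_DOMINATING.value)).astype(object)
    if extreme_threshold is not None:
        top = scores[np.arange(n), primary]
        extreme = top > extreme_threshold
        labels[extreme] = letters[primary[extreme]]
        category[extreme] = DominanceCategory.EXTREME.value
    return labels, category


def make_assignments(scores: pd.DataFrame, visit_month: float = 0.0,
                     threshold: float = 0.6, dominance: float = 0.4,
                     fold_extremes: bool = False) -> pd.DataFrame:
    """Per-subject group assignment table for one visit.

    ``scores`` is a subject-indexed DataFrame of simplex scores. With
    ``fold_extremes`` the mixed label of extreme subjects collapses to
    their single archetype letter (dominance category "extreme").
    """
    values = scores.to_numpy(dtype=float)
    extreme = assign_extreme_groups(values, threshold)
    mixed, category = assign_mixed_groups(
        values, dominance, extreme_threshold=threshold if fold_extremes else None)
    return pd.DataFrame({
        "subject_id": scores.index,
        "visit_month": visit_month,
        "extreme_label": extreme,
        "mixed_label": mixed,
        "dominance_category": category,
    })


def transition_flows(assignments: pd.DataFrame, min_count: int = 5,
                     group_column: str = "mixed_label") -> pd.DataFrame:
    """Counts of subjects flowing between groups at consecutive visits.

    ``assignments`` must carry subject_id, visit_month and the group
    column, with one row per (subject, visit). Flows below ``min_count``
    are retained but flagged (display convention: hide small flows).
    """
    if assignments.duplicated(["subject_id", "visit_month"]).any():
        raise ValueError("duplicate (subject, visit) assignment rows")
    months = sorted(assignments["visit_month"].unique())
    if len(months) < 2:
        raise ValueError("need assignments for at least 2 visits")
    rows = []
    for m_from, m_to in zip(months[:-1], months[1:]):
        a = assignments[assignments["visit_month"] == m_from]
        b = assignments[assignments["visit_month"] == m_to]
        merged = a.merge(b, on="subject_id", suffixes=("_from", "_to"))
        counts = (merged.groupby([f"{group_column}_from", f"{group_column}_to"])
                  .size().reset_index(name="count"))
        for _, row in counts.iterrows():
            rows.append({
                "visit_from": m_from, "visit_to": m_to,
                "group_from": row[f"{group_column}_from"],
                "group_to": row[f"{group_column}_to"],
                "count": int(row["count"]),
                "displayed": bool(row["count"] >= min_count),
            })
    return pd.DataFrame(rows)


def cross_visit_score_correlations(scores_by_visit: dict[float, pd.DataFrame]
                                   ) -> pd.DataFrame:
    """Pearson correlation of each archetype score across visit pairs.

    ``scores_by_visit`` maps visit month to a subject-indexed score
    DataFrame; correlations are computed on the subjects present at both
    visits of each pair (at least 3 required).
    """
    months = sorted(scores_by_visit)
    if len(months) < 2:
        raise ValueError("need scores for at least 2 visits")
    rows = []
    for i, m1 in enumerate(months):
        for m2 in months[i + 1:]:
            s1, s2 = scores_by_visit[m1], scores_by_visit[m2]
            common = s1.index.intersection(s2.index)
            if len(common) < 3:
                raise ValueError(
                    f"visits {m1} and {m2} share only {len(common)} subjects")
            for arch in s1.columns:
                r = float(np.corrcoef(s1.loc[common, arch],
                                      s2.loc[common, arch])[0, 1])
                rows.append({"visit_a": m1, "visit_b": m2, "archetype": arch,
                             "pearson_r": r, "n": len(common)})
    return pd.DataFrame(rows)
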