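"""Association screens: scores vs phenotypes, omics, medication and GRS.

Archetype scores sum to one and are therefore collinear: every association
is a marginal model of one score at a time, never a joint model of all k.
Continuous outcomes use OLS; extreme groups are compared with
Kruskal-Wallis and per-group Mann-Whitney tests (direction reported as the
rank-biserial correlation); medication status uses logistic regression
with a penalized fallback under separation; omics screens control the
false discovery rate with Benjamini-Hochberg within each dataset; genetic
risk scores are weighted risk-allele sums, optionally restricted to one of
the six mechanism partitions.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

__all__ = [
    "score_phenotype_association",
    "extreme_group_tests",
    "medication_odds",
    "bh_fdr",
    "omics_screen",
    "compute_grs",
    "compute_grs_table",
]


class CollinearScoresError(ValueError):
    """Raised when a joint model over all simplex scores is requested."""


def score_phenotype_association(scores: pd.DataFrame, outcome: pd.Series,
                                joint: bool = False) -> pd.DataFrame:
    """OLS of a continuous outcome on each archetype score (marginal models).

    ``joint=True`` is refused: the k scores sum to one, so a joint design
    with intercept is rank deficient by construction.
    """
    if joint:
        raise CollinearScoresError(
            "archetype scores sum to 1; a joint model of all scores with an "
            "intercept is rank deficient - fit marginal models instead")
    merged = scores.join(outcome.rename("_outcome"), how="inner")
    y = merged["_outcome"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("outcome has zero variance")
    rows = []
    for arch in scores.columns:
        x = sm.add_constant(merged[arch].to_numpy(dtype=float))
        fit = sm.OLS(y, x).fit()
        rows.append({"target_name": outcome.name or "outcome",
                     "archetype": arch, "estimate": fit.params[1],
                     "std_error": fit.bse[1], "p_value": fit.pvalues[1],
                     "n": int(len(y))})
    return pd.DataFrame(rows)


def extreme_group_tests(labels: np.ndarray, outcome: np.ndarray,
                        min_group: int = 2):
    """Kruskal-Wallis across groups plus per-group Mann-Whitney vs rest.

    Returns (kruskal_p, DataFrame) where the frame carries, per group, the
    two-sided Mann-Whitney p-value and the rank-biserial correlation
    (positive when the group tends to larger outcome values than the rest).
    Groups smaller than ``min_group`` are skipped with a warning.
    """
    labels = np.asarray(labels)
    outcome = np.asarray(outcome, dtype=float)
    groups = [g for g in pd.unique(labels)]
    samples, used = [], []
    for g in groups:
        vals = outcome[labels == g]
        if vals.size < min_group:
            warnings.warn(f"group {g!r} has {vals.size} subjects; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        samples.append(vals)
        used.append(g)
    if len(samples) < 2:
        raise ValueError("need at least 2 non-empty groups")
    kw_stat, kw_p = stats.kruskal(*samples)
    rows = []
    for g in used:
        in_g = outcome[labels == g]
        rest = outcome[labels != g]
        u, p = stats.mannwhitneyu(in_g, rest, alternative="two-sided")
        rank_biserial = 2.0 * u / (in_g.size * rest.size) - 1.0
        rows.append({"group": g, "n": int(in_g.size),
                     "mannwhitney_p": float(p),
                     "rank_biserial": float(rank_biserial)})
    return float(kw_p), pd.DataFrame(rows)


def medication_odds(scores: pd.DataFrame, status: pd.Series,
                    penalty_alpha: float = 1.0) -> pd.DataFrame:
    """Logistic regression of medication status on each archetype score.

    Returns odds ratios with 95% confidence intervals per archetype. Under
    (quasi-)separation the model falls back to an L2-penalized fit and the
    row is flagged (``penalized=True``; no finite CIs are reported there).
    """
    merged = scores.join(status.rename("_status"), how="inner")
    y = merged["_status"].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("status has a single class")
    rows = []
    for arch in scores.columns:
        x = sm.add_constant(merged[arch].to_numpy(dtype=float))
        penalized = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", RuntimeWarning)
                fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", False) or \
                    not np.all(np.isfinite(fit.bse)):
                raise PerfectSeparationError
            coef, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
        except Exception:  # separation, non-convergence, singular Hessian
            penalized = True
            fit = sm.Logit(y, x).fit_regularized(
                alpha=penalty_alpha, L1_wt=0.0, disp=0, maxiter=500)
            coef, se, p = fit.params[1], np.nan, np.nan
        rows.append({"archetype": arch, "odds_ratio": float(np.exp(coef)),
                     "ci_low": float(np.exp(coef - 1.96 * se)) if np.isfinite(se) else np.nan,
                     "ci_high": float(np.exp(coef + 1.96 * se)) if np.isfinite(se) else np.nan,
                     "p_value": float(p) if np.isfinite(p) else np.nan,
                     "penalized": penalized, "n": int(len(y))})
    return pd.DataFrame(rows)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving on input."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def omics_screen(scores: pd.DataFrame, features: pd.DataFrame,
                 metformin: pd.Series | None = None,
                 stratify_metformin: str | None = None) -> pd.DataFrame:
    """Per-feature, per-archetype OLS screen with BH-FDR within the dataset.

    ``stratify_metformin`` selects a sensitivity mode: ``"subset"``
    restricts to subjects without metformin, ``"covariate"`` adds the
    metformin indicator to every model (both require ``metformin``).
    Constant features are skipped and logged. q-values are computed
    jointly over all feature x archetype tests of the screen.
    """
    if stratify_metformin is not None:
        if stratify_metformin not in ("subset", "covariate"):
            raise ValueError("stratify_metformin must be None, 'subset' or 'covariate'")
        if metformin is None:
            raise ValueError("metformin status required for sensitivity modes")
    common = scores.index.intersection(features.index)
    S = scores.loc[common]
    F = features.loc[common]
    met = metformin.loc[common] if metformin is not None else None
    if stratify_metformin == "subset":
        keep = ~met.astype(bool)
        S, F = S[keep.to_numpy()], F[keep.to_numpy()]
        met = None

    n = len(S)
    Y = F.to_numpy(dtype=float)
    keep = np.ptp(Y, axis=0) > 0
    for feat in F.columns[~keep]:
        logger.info("feature %s constant; skipped", feat)
    Y = Y[:, keep]
    feat_names = list(F.columns[keep])
    rows = []
    for arch in S.columns:
        # one shared design for every feature of the screen, so the OLS
        # solves vectorize across the feature matrix
        cols = [np.ones(n), S[arch].to_numpy(dtype=float)]
        if stratify_metformin == "covariate":
            cols.append(met.to_numpy(dtype=float))
        X = np.column_stack(cols)
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ (X.T @ Y)                       # (p, n_features)
        resid = Y - X @ B
        dof = n - X.shape[1]
        sigma2 = np.sum(resid * resid, axis=0) / dof
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        tstat = np.divide(B[1], se, out=np.zeros_like(se), where=se > 0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        for j, feat in enumerate(feat_names):
            rows.append({"target_name": feat, "archetype": arch,
                         "estimate": B[1, j], "std_error": se[j],
                         "p_value": pvals[j], "n": n})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def compute_grs(dosages: pd.DataFrame, weights: pd.DataFrame,
                partition: str | None = None) -> pd.Series:
    """Weighted risk-allele sum per subject.

    ``weights`` needs columns snp/weight/partition; with ``partition`` the
    sum runs over that partition's SNPs only. SNPs in the weight table but
    absent from the dosage matrix raise an error naming the offenders.
    """
    w = weights if partition is None else weights[weights["partition"] == partition]
    missing = [s for s in w["snp"] if s not in dosages.columns]
    if missing:
        raise ValueError(f"SNPs missing from dosage matrix: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    values = dosages[list(w["snp"])].to_numpy(dtype=float) @ w["weight"].to_numpy(dtype=float)
    name = f"grs_{partition.lower()}" if partition else "grs_overall"
    return pd.Series(values, index=dosages.index, name=name)


def compute_grs_table(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Overall GRS plus one column per mechanism partition."""
    table = {"grs_overall": compute_grs(dosages, weights)}
    for part in pd.unique(weights["partition"]):
        table[f"grs_{part.lower()}"] = compute_grs(dosages, weights, part)
    return pd.DataFrame(table)
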