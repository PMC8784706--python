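"""Variable transformation, covariate residualization and correlation pruning.

Clustering inputs are prepared in three steps: every phenotype column is
mapped to normal quantiles of its fractional ranks (rank-based inverse
normal transformation with the Blom offset), the transformed columns are
residualized on sex genotype and recruitment center by ordinary least
squares, and, optionally, near-duplicate columns are removed by a greedy
pairwise-Pearson pruning rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats


class TransformState(str, Enum):
    RAW = "raw"
    RANK_NORMAL = "rank_normal"
    RESIDUALIZED = "residualized"


class DegenerateColumnError(ValueError):
    """A column cannot be transformed (e.g. constant)."""


class CollinearCovariatesError(ValueError):
    """The covariate design matrix is rank deficient."""


@dataclass
class PhenotypeMatrix:
    """Subjects x phenotypes matrix with covariates and transform state.

    ``values`` is an (n, m) float array, ``column_names`` the m phenotype
    identifiers, ``covariates`` a DataFrame indexed like the rows holding
    categorical covariates (sex genotype, recruitment center) and any
    numeric ones (age). Complete cases only: NaNs are rejected on
    construction.
    """

    values: np.ndarray
    column_names: list[str]
    covariates: pd.DataFrame | None = None
    transform_state: TransformState = TransformState.RAW
    subject_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x phenotypes)")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length does not match values")
        if self.values.shape[1] == 0:
            raise ValueError("need at least one phenotype column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype matrix contains missing/non-finite entries")
        if self.subject_ids is None:
            self.subject_ids = list(range(self.values.shape[0]))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names,
                            index=pd.Index(self.subject_ids, name="subject_id"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, phenotype_columns: list[str],
                   covariate_columns: list[str] | None = None) -> "PhenotypeMatrix":
        cov = df[covariate_columns].copy() if covariate_columns else None
        return cls(values=df[phenotype_columns].to_numpy(dtype=float),
                   column_names=list(phenotype_columns),
                   covariates=cov,
                   subject_ids=list(df.index))


def rank_inverse_normal(column: np.ndarray, *, blom_offset: float = 3.0 / 8.0,
                        name: str = "<column>") -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Values are ranked (ties averaged), converted to fractional ranks
    (r - 3/8) / (n + 1/4) and mapped through the standard normal quantile
    function. Strictly order-preserving for distinct inputs; a tie-free
    column maps to an exactly symmetric set of normal quantiles.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("rank_inverse_normal needs a 1-D vector of length >= 3")
    if np.ptp(x) == 0:
        raise DegenerateColumnError(f"column {name!r} is constant; cannot rank-normalize")
    ranks = stats.rankdata(x, method="average")
    frac = (ranks - blom_offset) / (x.size - 2.0 * blom_offset + 1.0)
    return stats.norm.ppf(frac)


def rank_normalize(matrix: PhenotypeMatrix, *, pool: np.ndarray | None = None) -> PhenotypeMatrix:
    """Rank-normalize every column of a phenotype matrix.

    ``pool`` optionally supplies additional rows (e.g. follow-up visits) so
    that several visits are transformed jointly on pooled ranks; the
    returned matrix keeps only the original rows.
    """
    out = np.empty_like(matrix.values)
    for j, name in enumerate(matrix.column_names):
        col = matrix.values[:, j]
        if pool is not None:
            stacked = np.concatenate([col, pool[:, j]])
            transformed = rank_inverse_normal(stacked, name=name)
            out[:, j] = transformed[: col.size]
        else:
            out[:, j] = rank_inverse_normal(col, name=name)
    return replace(matrix, values=out, transform_state=TransformState.RANK_NORMAL)


def _covariate_design(cov: pd.DataFrame, covariate_names: list[str]) -> np.ndarray:
    """One-hot encode categoricals (drop-first) and prepend an intercept."""
    pieces = [np.ones((len(cov), 1))]
    for name in covariate_names:
        if name not in cov.columns:
            raise KeyError(f"covariate {name!r} not present")
        col = cov[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            pieces.append(dummies.to_numpy())
        else:
            pieces.append(col.to_numpy(dtype=float)[:, None])
    return np.hstack(pieces)


def residualize(matrix: PhenotypeMatrix, covariate_names: list[str]) -> PhenotypeMatrix:
    """Replace every column by its OLS residual on the covariate design.

    Categorical covariates are one-hot encoded with an intercept. Residuals
    are orthogonal to every design column; applying the operation twice is
    a no-op.
    """
    if matrix.covariates is None:
        raise ValueError("matrix carries no covariates")
    D = _covariate_design(matrix.covariates, covariate_names)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise CollinearCovariatesError(
            f"covariate design is rank deficient (rank {rank} < {D.shape[1]} columns) "
            f"for covariates {covariate_names}")
    beta, *_ = np.linalg.lstsq(D, matrix.values, rcond=None)
    resid = matrix.values - D @ beta
    return replace(matrix, values=resid, transform_state=TransformState.RESIDUALIZED)


def prune_by_correlation(matrix: PhenotypeMatrix, cutoff: float) -> list[str]:
    """Greedy pruning of pairwise-correlated phenotype columns.

    While any pair of retained columns has |Pearson r| > cutoff, the pair
    with the largest |r| is inspected and the member with the larger mean
    absolute correlation to all other retained columns is dropped (ties:
    drop the later column in input order). Returns retained column names in
    original order.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    names = list(matrix.column_names)
    X = matrix.values
    corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    keep = list(range(len(names)))
    while len(keep) > 1:
        sub = np.abs(corr[np.ix_(keep, keep)])
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        mean_i = sub[i].sum() / (len(keep) - 1)
        mean_j = sub[j].sum() / (len(keep) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:  # equal mean |r|: drop the later column in input order
            drop = max(i, j)
        keep.pop(drop)
    kept_set = set(keep)
    return [names[i] for i in sorted(kept_set)]


def prepare_clustering_matrix(matrix: PhenotypeMatrix,
                              covariate_names: list[str] | None = None) -> PhenotypeMatrix:
    """Rank-normalize then residualize: the standard pre-clustering pipeline."""
    out = rank_normalize(matrix)
    if covariate_names:
        out = residualize(out, covariate_names)
    return out
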