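"""HbA1c disease-progression modelling.

Longitudinal HbA1c trajectories are described by a conditional linear
mixed-effects model: a linear transformation removes each subject's
cross-sectional level so that only the longitudinal information enters the
likelihood, and the transformed response is modelled as

    y*_ik = slope_i * t*_ik + beta' x*_ik + eps_ik,   slope_i ~ N(mu, sigma_s^2)

with fixed effects for BMI (constrained >= 0), metformin dose (intercept
and slope of a + b*dose, both <= 0), cumulative other-drug dose (a + b*dose,
both <= 0), insulin treatment (<= 0) and HbA1c assay delay. A medication
counts at a visit only if started at least 30 days earlier. Per-subject
slopes are reported as empirical-Bayes conditional means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375
MEDICATION_LAG_DAYS = 30.0

DRUG_CLASSES = ("metformin", "other_oral", "insulin")


@dataclass
class MedicationRecord:
    drug_class: str
    dose_fraction: float
    start_day: float
    stop_day: float | None = None

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise ValueError(f"unknown drug class {self.drug_class!r}")
        if not 0.0 <= self.dose_fraction <= 1.0:
            raise ValueError("dose_fraction must lie in [0, 1]")


@dataclass
class Hba1cVisit:
    month: float
    hba1c: float
    assay_delay_days: float = 0.0
    bmi: float = np.nan


@dataclass
class Hba1cSeries:
    """One subject's HbA1c visits and medication history."""

    subject_id: str
    visits: list[Hba1cVisit]
    medications: list[MedicationRecord] = field(default_factory=list)

    @property
    def n_visits(self) -> int:
        return len(self.visits)


def effective_dose(medications: list[MedicationRecord], month: float) -> dict:
    """Treatment covariates at a visit under the 30-day effectiveness lag.

    A drug contributes only if started at least 30 days before the visit
    and not stopped by then. Returns the metformin dose fraction, the
    cumulative other-oral dose fraction (summed over distinct drugs) and a
    0/1 insulin indicator.
    """
    visit_day = month * DAYS_PER_MONTH
    out = {"metformin": 0.0, "other_oral": 0.0, "insulin": 0.0}
    active_by_class: dict[str, int] = {"metformin": 0, "insulin": 0}
    for med in medications:
        active = (med.start_day <= visit_day - MEDICATION_LAG_DAYS
                  and (med.stop_day is None or med.stop_day >= visit_day))
        if not active:
            continue
        if med.drug_class in active_by_class:
            active_by_class[med.drug_class] += 1
            if active_by_class[med.drug_class] > 1:
                raise ValueError(
                    f"overlapping duplicate {med.drug_class} records at month {month}")
        if med.drug_class == "metformin":
            out["metformin"] = med.dose_fraction
        elif med.drug_class == "other_oral":
            out["other_oral"] += med.dose_fraction
        else:
            out["insulin"] = 1.0
    return out


_COVARIATES = ["month", "bmi", "met_ind", "met_dose", "oth_ind", "oth_dose",
               "insulin", "delay"]


def _series_frame(series: Hba1cSeries) -> pd.DataFrame:
    rows = []
    for v in series.visits:
        dose = effective_dose(series.medications, v.month)
        rows.append({
            "subject_id": series.subject_id,
            "month": v.month,
            "hba1c": v.hba1c,
            "bmi": v.bmi if np.isfinite(v.bmi) else 0.0,
            "met_ind": float(dose["metformin"] > 0),
            "met_dose": dose["metformin"],
            "oth_ind": float(dose["other_oral"] > 0),
            "oth_dose": dose["other_oral"],
            "insulin": dose["insulin"],
            "delay": v.assay_delay_days,
        })
    return pd.DataFrame(rows)


def conditional_transform(series_collection: list[Hba1cSeries]) -> pd.DataFrame:
    """Within-subject centering of the response and time-varying covariates.

    Produces the longitudinal component of the conditional decomposition:
    subject means are removed from HbA1c and from every covariate, so that
    cross-sectional (baseline-level) information cannot confound the slope
    estimates. Subjects with fewer than two visits are excluded (logged).
    """
    frames = []
    for s in series_collection:
        if s.n_visits < 2:
            logger.info("subject %s excluded: fewer than 2 HbA1c values",
                        s.subject_id)
            continue
        frames.append(_series_frame(s))
    if not frames:
        raise ValueError("no subject has >= 2 visits")
    df = pd.concat(frames, ignore_index=True)
    if df.duplicated(["subject_id", "month"]).any():
        raise ValueError("duplicate (subject, visit) rows")
    grouped = df.groupby("subject_id")
    for col in ["hba1c"] + _COVARIATES:
        df[col + "_c"] = df[col] - grouped[col].transform("mean")
    return df


_FIXED_NAMES = ["bmi", "met_ind", "met_dose", "oth_ind", "oth_dose",
                "insulin", "delay"]
# box constraints: BMI effect >= 0; treatment intercepts/slopes and the
# insulin effect <= 0; assay delay unconstrained
_BOUNDS = {"bmi": (0.0, None), "met_ind": (None, 0.0), "met_dose": (None, 0.0),
           "oth_ind": (None, 0.0), "oth_dose": (None, 0.0),
           "insulin": (None, 0.0), "delay": (None, None)}


@dataclass
class ProgressionFit:
    """Constrained mixed-model fit of HbA1c progression."""

    subject_ids: list
    subject_slopes: np.ndarray
    mu_slope: float
    sigma_slope: float
    fixed_effects: dict
    residual_sd: float
    loglik: float
    converged: bool
    boundary_effects: list[str]
    n_subjects: int
    n_observations: int
    mu_slope_se: float = np.nan

    def slopes_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids,
                             "slope_mmol_mol_per_month": self.subject_slopes})

    def summary(self) -> str:
        lines = [
            "HbA1c progression model (conditional linear mixed effects)",
            "==========================================================",
            f"subjects: {self.n_subjects}   observations: {self.n_observations}",
            f"mean slope (mmol/mol per month): {self.mu_slope:.4f}"
            f"  (SE {self.mu_slope_se:.4f})",
            f"slope SD:                        {self.sigma_slope:.4f}",
            f"residual SD (mmol/mol):          {self.residual_sd:.3f}",
            f"log-likelihood:                  {self.loglik:.2f}",
            "fixed effects:",
        ]
        for name, value in self.fixed_effects.items():
            flag = "  [at boundary]" if name in self.boundary_effects else ""
            lines.append(f"  {name:<10} {value:>10.4f}{flag}")
        if not self.converged:
            lines.append("WARNING: optimizer did not report convergence")
        return "\n".join(lines)


class ProgressionModel:
    """Conditional linear mixed model for HbA1c trajectories.

    Built from a collection of :class:`Hba1cSeries` (``from_series``) or
    from an already-transformed longitudinal design frame. The conditional
    transformation is realized internally through orthonormal
    within-subject contrasts (the same projection as mean-centering, with
    a nonsingular residual covariance).
    """

    def __init__(self, design: pd.DataFrame):
        self.design = design
        self._prepare()

    @classmethod
    def from_series(cls, series_collection: list[Hba1cSeries]) -> "ProgressionModel":
        return cls(conditional_transform(series_collection))

    def _prepare(self) -> None:
        """Project each subject onto orthonormal within-subject contrasts and
        stack subjects with equal visit counts for a vectorized likelihood."""
        self._subjects = []
        for sid, sub in self.design.groupby("subject_id", sort=True):
            n = len(sub)
            if n < 2:
                continue
            K = helmert(n, full=False)  # rows orthonormal, orthogonal to 1
            y = K @ sub["hba1c"].to_numpy()
            t = K @ sub["month"].to_numpy()
            Xf = K @ sub[_FIXED_NAMES].to_numpy()
            self._subjects.append((sid, y, t, Xf, n))
        if len(self._subjects) < 2:
            raise ValueError("need at least 2 subjects with >= 2 visits")
        self._groups = []
        by_n: dict[int, list] = {}
        for rec in self._subjects:
            by_n.setdefault(rec[4], []).append(rec)
        for n, recs in sorted(by_n.items()):
            Y = np.stack([r[1] for r in recs])            # (S, n-1)
            T = np.stack([r[2] for r in recs])            # (S, n-1)
            XF = np.stack([r[3] for r in recs])           # (S, n-1, p)
            self._groups.append((Y, T, XF, n))

    # -- likelihood ----------------------------------------------------
    def _nll(self, params: np.ndarray) -> float:
        mu, beta, sig_s, sig = self._split(params)
        s2, ss2 = sig * sig, sig_s * sig_s
        nll = 0.0
        for Y, T, XF, n in self._groups:
            R = Y - T * mu - XF @ beta                    # (S, n-1)
            ut2 = np.sum(T * T, axis=1)                   # (S,)
            denom = s2 + ss2 * ut2
            tr = np.sum(T * R, axis=1)
            quad = (np.sum(R * R, axis=1) - ss2 * tr * tr / denom) / s2
            logdet = (n - 2) * np.log(s2) + np.log(denom)
            nll += 0.5 * float(np.sum(logdet + quad + (n - 1) * np.log(2 * np.pi)))
        return nll

    @staticmethod
    def _split(params: np.ndarray):
        mu = params[0]
        beta = params[1:8]
        sig_s = np.exp(params[8])
        sig = np.exp(params[9])
        return mu, beta, sig_s, sig

    def fit(self, constrained: bool = True) -> ProgressionFit:
        pooled_t = np.concatenate([t for _, _, t, _, _ in self._subjects])
        pooled_y = np.concatenate([y for _, y, _, _, _ in self._subjects])
        denom = float(pooled_t @ pooled_t)
        mu0 = float(pooled_t @ pooled_y) / denom if denom > 0 else 0.0
        resid0 = pooled_y - mu0 * pooled_t
        sig0 = max(float(np.std(resid0)), 1e-3)
        x0 = np.concatenate([[mu0], np.zeros(7), [np.log(0.05)], [np.log(sig0)]])

        bounds = [(None, None)]
        bounds += [_BOUNDS[name] if constrained else (None, None)
                   for name in _FIXED_NAMES]
        bounds += [(np.log(1e-6), np.log(10.0)), (np.log(1e-4), np.log(100.0))]

        best = None
        for x_start in (x0, x0 + np.concatenate([[0.01], np.full(7, -0.01),
                                                 [0.5, 0.0]])):
            res = minimize(self._nll, x_start, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 500, "ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        res = best
        mu, beta, sig_s, sig = self._split(res.x)
        fixed = dict(zip(_FIXED_NAMES, beta))
        boundary = [name for name, value in fixed.items()
                    if constrained and _BOUNDS[name] != (None, None)
                    and abs(value) < 1e-9]
        if not res.success:
            warnings.warn(
                f"progression optimizer: {res.message} "
                f"(gradient norm {np.linalg.norm(res.jac):.2e})",
                RuntimeWarning, stacklevel=2)

        slopes, ids = self._eb_slopes(mu, beta, sig_s, sig)
        mu_se = self._mu_se(mu, beta, sig_s, sig)
        n_obs = sum(n for *_, n in self._subjects)
        return ProgressionFit(
            subject_ids=ids, subject_slopes=slopes, mu_slope=float(mu),
            sigma_slope=float(sig_s), fixed_effects=fixed,
            residual_sd=float(sig), loglik=float(-res.fun),
            converged=bool(res.success), boundary_effects=boundary,
            n_subjects=len(self._subjects), n_observations=n_obs,
            mu_slope_se=mu_se)

    def _eb_slopes(self, mu, beta, sig_s, sig):
        """Empirical-Bayes conditional means of the per-subject slopes."""
        s2, ss2 = sig * sig, sig_s * sig_s
        slopes, ids = [], []
        for sid, y, t, Xf, _ in self._subjects:
            r = y - Xf @ beta
            ut2 = float(t @ t)
            post_var = 1.0 / (1.0 / ss2 + ut2 / s2)
            post_mean = post_var * (mu / ss2 + float(t @ r) / s2)
            slopes.append(post_mean)
            ids.append(sid)
        return np.asarray(slopes), ids

    def _mu_se(self, mu, beta, sig_s, sig) -> float:
        s2, ss2 = sig * sig, sig_s * sig_s
        info = 0.0
        for _, y, t, Xf, _ in self._subjects:
            ut2 = float(t @ t)
            denom = s2 + ss2 * ut2
            info += (ut2 - ss2 * ut2 * ut2 / denom) / s2
        return float(1.0 / np.sqrt(info)) if info > 0 else np.nan


def fit_progression(series_collection: list[Hba1cSeries],
                    constrained: bool = True) -> ProgressionFit:
    """Convenience wrapper: transform, build and fit the progression model."""
    return ProgressionModel.from_series(series_collection).fit(constrained)


def slopes_vs_scores(slopes: pd.DataFrame | ProgressionFit, scores: pd.DataFrame,
                     strata: dict[str, np.ndarray] | None = None,
                     min_stratum: int = 10) -> pd.DataFrame:
    """Regress per-subject HbA1c slopes on each archetype score.

    ``scores`` is a subject-indexed DataFrame with one column per
    archetype; scores are simplex-collinear so each archetype is tested in
    its own marginal OLS model. ``strata`` maps stratum names to boolean
    masks over the merged subjects (e.g. treated/untreated); strata smaller
    than ``min_stratum`` are skipped with a warning.
    """
    import statsmodels.api as sm

    if isinstance(slopes, ProgressionFit):
        slopes = slopes.slopes_frame()
    merged = slopes.merge(scores, left_on="subject_id", right_index=True)
    y = merged["slope_mmol_mol_per_month"].to_numpy()
    archetypes = [c for c in scores.columns]
    strata = strata or {"all": np.ones(len(merged), dtype=bool)}
    rows = []
    for stratum, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < min_stratum:
            warnings.warn(f"stratum {stratum!r} has {mask.sum()} subjects; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        for arch in archetypes:
            x = sm.add_constant(merged.loc[mask, arch].to_numpy())
            fit = sm.OLS(y[mask], x).fit()
            ci = fit.conf_int()[1]
            rows.append({"stratum": stratum, "archetype": arch,
                         "estimate": fit.params[1], "std_error": fit.bse[1],
                         "p_value": fit.pvalues[1], "ci_low": ci[0],
                         "ci_high": ci[1], "n": int(mask.sum())})
    return pd.DataFrame(rows)
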