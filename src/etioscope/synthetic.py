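"""Synthetic cohort generator with ground truth for recovery tests.

Emulates the statistical structure the analysis pipeline assumes: a
baseline phenotype matrix built as convex mixtures of k latent archetype
profiles plus Gaussian noise, mixed-meal tolerance test curves simulated
from a known secretion model with multiplicative measurement noise (~1%
glucose, ~4% C-peptide), HbA1c trajectories with subject-specific slopes
and lagged medication effects, omics features with linear loadings on the
archetype weights, and biallelic genotype dosages with partitioned risk
weights. Every generator is a pure function of (configuration, seed) and
returns its ground truth so that parameter-recovery tests can close the
loop.

The default four archetype profiles are a frozen fixture derived from the
published phenotype summary of the four extreme patient groups of a newly
diagnosed type 2 diabetes cohort: A lean / insulin-deficient with high
insulin sensitivity, B low-lipid / low-biochemistry, C obese
hyperinsulinaemic / insulin-resistant, D hyperglycaemic with poor beta-cell
glucose sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .betacell import CpeptideKinetics, MMTTRecord
from .preprocess import PhenotypeMatrix
from .progression import (Hba1cSeries, Hba1cVisit, MedicationRecord,
                          effective_dose)

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "SecretionTruth",
    "generate_cohort",
    "generate_mmtt",
    "generate_hba1c",
    "generate_omics",
    "generate_genotypes",
    "PHENOTYPE_NAMES",
]


class ConfigurationError(ValueError):
    pass


# Frozen archetype fixture: (phenotype, cohort mean, cohort SD, and the
# z-scored direction of each archetype A-D relative to the cohort).
_PHENOTYPE_TABLE = [
    ("age_years", 61.97, 8.03, 0.35, 0.088, -0.136, -0.35),
    ("bmi_kg_m2", 30.44, 4.97, -1.01, 0.111, 0.61, 0.497),
    ("whr", 0.96, 0.08, -0.625, 0.125, 0.5, 0.375),
    ("bsa_m2", 2.07, 0.23, -0.87, 0.348, 0.435, 0.217),
    ("fasting_cpeptide_pmol_l", 1074.99, 392.22, -0.94, -0.999, 1.409, 0.621),
    ("fasting_hba1c_mmol_mol", 46.41, 5.71, -0.338, -0.135, -0.268, 1.687),
    ("fasting_glucose_mmol_l", 7.1, 1.39, -0.194, -2.122, -0.137, 1.705),
    ("fasting_insulin_pmol_l", 104.64, 67.23, -0.899, -0.746, 1.557, 0.578),
    ("fasting_hdl_mmol_l", 1.19, 0.38, 0.868, -1.395, -0.263, -0.395),
    ("fasting_ldl_mmol_l", 2.34, 0.96, 0.542, -1.198, -0.073, 0.198),
    ("fasting_tg_mmol_l", 1.51, 0.8, -0.338, -1.0, 0.35, 0.775),
    ("fasting_alt_u_l", 26.43, 14.03, -0.366, -0.747, 0.449, 0.709),
    ("fasting_ast_u_l", 25.61, 10.87, 0.04, -0.889, 0.213, 0.72),
    ("fasting_cholesterol_mmol_l", 4.23, 1.13, 0.637, -1.805, -0.053, 0.274),
    ("fasting_creatinine_umol_l", 75.19, 17.38, 0.245, -1.91, 0.157, 0.187),
    ("ucpcr_nmol_mmol", 3.38, 2.16, -0.315, -0.356, 0.75, -0.125),
    ("ucpep_nmol_l", 29.95, 22.94, -0.435, -0.077, 0.844, -0.054),
    ("ucreatinine_mmol_l", 9.72, 5.87, -0.293, 0.267, 0.313, 0.101),
    ("mmtt120_glucose_mmol_l", 8.72, 2.78, -0.432, -1.299, -0.144, 1.856),
    ("mmtt120_insulin_pmol_l", 451.03, 350.52, -0.653, -0.729, 1.416, 0.066),
    ("mean_glucose_mmol_l", 9.34, 2.01, -0.403, -1.587, -0.154, 1.756),
    ("mean_insulin_pmol_l", 458.01, 276.45, -0.749, -0.678, 1.731, -0.121),
    ("basal_isr_pmol_min_m2", 135.87, 47.45, -0.894, -1.025, 1.411, 0.626),
    ("total_secretion_nmol_m2", 44.14, 14.37, -0.568, -1.076, 1.442, -0.196),
    ("glucose_sensitivity", 83.67, 55.01, -0.07, -0.233, 0.941, -0.894),
    ("rate_sensitivity", 1115.08, 1044.94, -0.158, -0.327, 0.574, -0.252),
    ("potentiation_ratio", 1.41, 0.57, 0.614, -0.456, -0.211, -0.491),
    ("stumvoll_index", 5.51, 2.71, 1.041, 0.775, -1.196, -0.734),
    ("matsuda_index", 2.94, 2.21, 1.077, 1.941, -0.81, -0.647),
    ("ogis_2h_ml_min_m2", 297.17, 69.03, 0.546, 2.867, -0.738, -0.949),
    ("basal_insulin_clearance", 1.61, 1.02, 0.824, 0.039, -0.549, -0.324),
    ("insulin_clearance", 0.93, 0.3, 1.2, 0.1, -1.033, -0.233),
]

PHENOTYPE_NAMES = [row[0] for row in _PHENOTYPE_TABLE]
_COHORT_MEANS = np.array([row[1] for row in _PHENOTYPE_TABLE])
_COHORT_SDS = np.array([row[2] for row in _PHENOTYPE_TABLE])
_ARCHETYPE_Z = np.array([[row[3 + a] for row in _PHENOTYPE_TABLE]
                         for a in range(4)])
# extreme-group means average ~0.7 weight on their archetype, so the latent
# vertices sit ~1.4x further out than the printed group means
_VERTEX_SCALE = 1.4

ARCHETYPE_LABELS = ("A", "B", "C", "D")

# true HbA1c fixed effects used by generate_hba1c (signs follow the
# progression model's constraints)
TRUE_FIXED_EFFECTS = {
    "bmi": 0.05,        # mmol/mol per kg/m2 (within-subject change)
    "met_ind": -1.0,    # metformin: a + b*dose, both negative
    "met_dose": -1.5,
    "oth_ind": -0.5,
    "oth_dose": -1.0,
    "insulin": -2.0,
    "delay": 0.02,      # mmol/mol per day of assay delay
}


@dataclass
class CohortConfig:
    """Generator configuration; defaults mirror the study conditions."""

    n_subjects: int = 726
    n_phenotypes: int = 32
    k_true: int = 4
    dirichlet_alpha: float = 0.5
    noise_sd: float = 0.3
    seed: int = 0
    visit_months: tuple = (0, 9, 18, 27, 36)
    centers: int = 4
    covariate_effect_sd: float = 0.0
    # plant one pure subject per archetype so the latent vertices are
    # attainable data rows (exact-recovery tests at noise_sd = 0)
    include_vertex_subjects: bool = False
    # HbA1c generation
    hba1c_baseline_mean: float = 46.4
    hba1c_baseline_sd: float = 5.0
    hba1c_residual_sd: float = 2.0
    slope_mean: float = 0.02
    slope_sd: float = 0.05
    slope_loadings: tuple = (-0.03, 0.0, 0.01, 0.04)
    metformin_rate: float = 0.45
    other_drug_rate: float = 0.15
    insulin_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < self.k_true:
            raise ConfigurationError("n_subjects must be >= k_true")
        if self.n_subjects <= 0 or self.n_phenotypes <= 0 or self.k_true <= 0:
            raise ConfigurationError("dimensions must be positive")
        if self.dirichlet_alpha <= 0:
            raise ConfigurationError("dirichlet_alpha must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.centers <= 0:
            raise ConfigurationError("centers must be positive")


@dataclass
class SecretionTruth:
    """Ground-truth secretion parameters for one simulated subject.

    The true dose-response is linear, f(G) = max(S8 + gs*(G-8), 0); the
    potentiation factor is exponential in time with mean one over the test
    and the stated 2h/baseline ratio; the glucose excursion is a log-normal
    shaped bump over the basal level peaking between 30 and 60 minutes.
    """

    glucose_sensitivity: float = 80.0   # pmol/min/m2 per mmol/L
    secretion_at_8mmol: float = 150.0   # pmol/min/m2
    rate_sensitivity: float = 1100.0    # pmol/m2 per mmol/L
    potentiation_ratio: float = 1.5
    basal_glucose: float = 7.1          # mmol/L
    glucose_peak_amplitude: float = 4.5  # mmol/L above basal
    glucose_peak_minute: float = 45.0
    glucose_peak_width: float = 0.55    # log-time SD of the bump
    insulin_clearance: float = 0.9      # L/min/m2 (quasi-steady insulin)

    def glucose_curve(self, minutes: np.ndarray) -> np.ndarray:
        t = np.asarray(minutes, dtype=float)
        bump = np.zeros_like(t)
        pos = t > 0
        lt = np.log(t[pos] / self.glucose_peak_minute)
        bump[pos] = np.exp(-0.5 * (lt / self.glucose_peak_width) ** 2)
        return self.basal_glucose + self.glucose_peak_amplitude * bump

    def glucose_derivative(self, minutes: np.ndarray) -> np.ndarray:
        t = np.asarray(minutes, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        lt = np.log(t[pos] / self.glucose_peak_minute)
        bump = np.exp(-0.5 * (lt / self.glucose_peak_width) ** 2)
        out[pos] = (-self.glucose_peak_amplitude * bump * lt
                    / (self.glucose_peak_width ** 2 * t[pos]))
        return out

    def dose_response(self, glucose: np.ndarray) -> np.ndarray:
        # floored at a small positive basal secretion: beta cells never
        # secrete exactly zero, and a zero basal would yield degenerate
        # (non-positive) fasting C-peptide records
        g = np.asarray(glucose, dtype=float)
        return np.maximum(self.secretion_at_8mmol
                          + self.glucose_sensitivity * (g - 8.0), 5.0)

    def potentiation(self, minutes: np.ndarray, span: float = 120.0) -> np.ndarray:
        t = np.asarray(minutes, dtype=float)
        b = np.log(self.potentiation_ratio) / span
        p = np.exp(b * t)
        grid = np.linspace(0.0, span, 241)
        mean = np.trapezoid(np.exp(b * grid), grid) / span
        return p / mean

    def isr_curve(self, minutes: np.ndarray) -> np.ndarray:
        g = self.glucose_curve(minutes)
        dg = self.glucose_derivative(minutes)
        return (self.potentiation(minutes) * self.dose_response(g)
                + self.rate_sensitivity * np.clip(dg, 0.0, None))


@dataclass
class SyntheticTruth:
    """Everything the generators know and the pipeline must recover."""

    archetype_profiles: np.ndarray
    weights: np.ndarray
    slopes: np.ndarray | None = None
    secretion_params: list | None = None
    omics_loadings: np.ndarray | None = None
    omics_null_mask: np.ndarray | None = None
    fixed_effects: dict = field(default_factory=lambda: dict(TRUE_FIXED_EFFECTS))

    def __post_init__(self) -> None:
        W = self.weights
        if np.any(W < 0) or np.max(np.abs(W.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("weights rows must be non-negative and sum to 1")


def _archetype_profiles(config: CohortConfig, rng: np.random.Generator):
    """Latent profiles in raw phenotype units (k_true x n_phenotypes)."""
    k, m = config.k_true, config.n_phenotypes
    if k == 4 and m == 32:
        z = _ARCHETYPE_Z * _VERTEX_SCALE
        names = list(PHENOTYPE_NAMES)
        means, sds = _COHORT_MEANS, _COHORT_SDS
    else:
        z = rng.normal(scale=1.4, size=(k, m))
        names = [f"phenotype_{j + 1:02d}" for j in range(m)]
        means, sds = np.zeros(m), np.ones(m)
    return means + sds * z, names


def generate_cohort(config: CohortConfig) -> tuple[PhenotypeMatrix, SyntheticTruth]:
    """Phenotype matrix X = W.Z + E with Dirichlet weights and ground truth."""
    rng = np.random.default_rng(config.seed)
    Z, names = _archetype_profiles(config, rng)
    n, k = config.n_subjects, config.k_true
    W = rng.dirichlet(np.full(k, config.dirichlet_alpha), size=n)
    if config.include_vertex_subjects:
        W[:k] = np.eye(k)
    spread = Z.std(axis=0)
    X = W @ Z + config.noise_sd * spread * rng.standard_normal((n, Z.shape[1]))

    centers = rng.integers(config.centers, size=n)
    sex = np.where(rng.random(n) < 0.41, "XX", "XY")
    if config.covariate_effect_sd > 0:
        col_scale = np.where(spread > 0, spread, 1.0)
        center_eff = rng.normal(scale=config.covariate_effect_sd,
                                size=(config.centers, Z.shape[1])) * col_scale
        sex_eff = rng.normal(scale=config.covariate_effect_sd,
                             size=Z.shape[1]) * col_scale
        X = X + center_eff[centers] + np.where(sex == "XX", 1.0, 0.0)[:, None] * sex_eff

    covariates = pd.DataFrame({
        "sex_genotype": sex,
        "center": [f"center_{c + 1}" for c in centers],
    }, index=pd.RangeIndex(n))
    matrix = PhenotypeMatrix(values=X, column_names=names, covariates=covariates,
                             subject_ids=[f"S{i + 1:04d}" for i in range(n)])

    slopes = (config.slope_mean
              + W @ np.asarray(config.slope_loadings[:k])
              + config.slope_sd * rng.standard_normal(n))
    secretion = _secretion_truths(W, rng)
    truth = SyntheticTruth(archetype_profiles=Z, weights=W, slopes=slopes,
                           secretion_params=secretion)
    return matrix, truth


def _secretion_truths(W: np.ndarray, rng: np.random.Generator) -> list[SecretionTruth]:
    """Per-subject secretion parameters tied to the archetype weights.

    Directions follow the cohort phenotypes: high C-score raises secretion
    and glucose sensitivity; high D-score lowers glucose sensitivity and
    raises glycaemia.
    """
    n, k = W.shape
    wC = W[:, 2] if k >= 3 else np.zeros(n)
    wD = W[:, 3] if k >= 4 else np.zeros(n)
    out = []
    for i in range(n):
        gs = 80.0 * np.exp(0.55 * wC[i] - 0.9 * wD[i]
                           + 0.25 * rng.standard_normal())
        out.append(SecretionTruth(
            glucose_sensitivity=gs,
            secretion_at_8mmol=150.0 * np.exp(0.5 * wC[i]
                                              + 0.15 * rng.standard_normal()),
            rate_sensitivity=max(1100.0 * np.exp(0.4 * wC[i]
                                 + 0.4 * rng.standard_normal()), 0.0),
            potentiation_ratio=float(np.clip(
                1.5 * np.exp(0.15 * rng.standard_normal() - 0.2 * wD[i]),
                1.05, 3.0)),
            basal_glucose=float(np.clip(
                7.1 + 2.2 * wD[i] - 0.3 * W[i, 0] + 0.4 * rng.standard_normal(),
                4.5, 14.0)),
            glucose_peak_amplitude=float(np.clip(
                4.5 + 2.5 * wD[i] + 0.6 * rng.standard_normal(), 2.0, 10.0)),
            insulin_clearance=float(np.clip(
                0.9 * np.exp(-0.4 * wC[i] + 0.1 * rng.standard_normal()),
                0.3, 2.5)),
        ))
    return out


DEFAULT_MMTT_MINUTES = (0, 30, 60, 90, 120)


def generate_mmtt(truth_params: SecretionTruth,
                  sampling_minutes=DEFAULT_MMTT_MINUTES,
                  noise_glucose: float = 0.01, noise_cpeptide: float = 0.04,
                  seed: int = 0, subject_id: str = "S0001",
                  kinetics: CpeptideKinetics | None = None) -> MMTTRecord:
    """Simulate one MMTT record by forward convolution of the true ISR.

    C-peptide is the convolution of the true secretion rate with the
    two-exponential kinetics kernel (steady state before t=0); insulin
    follows quasi-steady clearance of ISR. Multiplicative log-normal noise
    is applied at the stated fractions (defaults ~1% glucose, ~4%
    C-peptide).
    """
    if noise_glucose < 0 or noise_cpeptide < 0:
        raise ConfigurationError("noise fractions must be >= 0")
    minutes = np.asarray(sampling_minutes, dtype=float)
    if minutes[0] != 0 or np.any(np.diff(minutes) <= 0) or minutes[-1] < 120:
        raise ConfigurationError(
            "sampling_minutes must increase strictly from 0 and span >= 120")
    kin = kinetics or CpeptideKinetics()
    rng = np.random.default_rng(seed)

    grid = np.arange(0.0, minutes[-1] + 1e-9, 1.0)  # 1-min forward grid
    isr = truth_params.isr_curve(grid)
    from .betacell import simulate_cpeptide
    cp_grid = simulate_cpeptide(isr, kin, grid)
    glucose = truth_params.glucose_curve(minutes)
    cpeptide = np.interp(minutes, grid, cp_grid)
    insulin = np.interp(minutes, grid, isr) / truth_params.insulin_clearance

    glucose = glucose * np.exp(noise_glucose * rng.standard_normal(minutes.size))
    cpeptide = cpeptide * np.exp(noise_cpeptide * rng.standard_normal(minutes.size))
    insulin = insulin * np.exp(noise_cpeptide * rng.standard_normal(minutes.size))
    return MMTTRecord(subject_id=subject_id, minutes=minutes, glucose=glucose,
                      cpeptide=cpeptide, insulin=insulin)


def generate_hba1c(truth: SyntheticTruth, config: CohortConfig,
                   noise: bool = True) -> list[Hba1cSeries]:
    """HbA1c series: baseline + slope*t + lagged treatment effects + noise."""
    if truth.slopes is None:
        raise ValueError("truth carries no slopes")
    n = truth.weights.shape[0]
    rng = np.random.default_rng(config.seed + 1)
    k = truth.weights.shape[1]
    wA = truth.weights[:, 0]
    wD = truth.weights[:, 3] if k >= 4 else np.zeros(n)
    fx = truth.fixed_effects
    series = []
    for i in range(n):
        meds = []
        p_met = config.metformin_rate * np.clip(
            0.5 + 1.5 * wD[i] - 0.8 * wA[i], 0.05, 2.0)
        if rng.random() < p_met:
            start = (rng.uniform(-180, -30) if rng.random() < 0.5
                     else rng.uniform(0, 900))
            meds.append(MedicationRecord("metformin",
                                         float(rng.choice([0.25, 0.5, 0.75, 1.0])),
                                         start_day=float(start)))
        if rng.random() < config.other_drug_rate:
            meds.append(MedicationRecord("other_oral",
                                         float(rng.choice([0.25, 0.5])),
                                         start_day=float(rng.uniform(100, 900))))
        if rng.random() < config.insulin_rate:
            meds.append(MedicationRecord("insulin", 1.0,
                                         start_day=float(rng.uniform(300, 1000))))
        baseline = (config.hba1c_baseline_mean
                    + config.hba1c_baseline_sd * rng.standard_normal())
        bmi0 = 30.4 + 4.9 * rng.standard_normal()
        visits = []
        for month in config.visit_months:
            bmi = bmi0 + 0.1 * month * rng.standard_normal() * 0.2
            delay = float(rng.integers(0, 10))
            dose = effective_dose(meds, month)
            value = (baseline + truth.slopes[i] * month
                     + fx["bmi"] * (bmi - bmi0)
                     + (fx["met_ind"] + fx["met_dose"] * dose["metformin"]
                        if dose["metformin"] > 0 else 0.0)
                     + (fx["oth_ind"] + fx["oth_dose"] * dose["other_oral"]
                        if dose["other_oral"] > 0 else 0.0)
                     + fx["insulin"] * dose["insulin"]
                     + fx["delay"] * delay)
            if noise:
                value += config.hba1c_residual_sd * rng.standard_normal()
            visits.append(Hba1cVisit(month=float(month), hba1c=float(value),
                                     assay_delay_days=delay, bmi=float(bmi)))
        series.append(Hba1cSeries(subject_id=f"S{i + 1:04d}", visits=visits,
                                  medications=meds))
    return series


def generate_omics(truth: SyntheticTruth, n_features: int, n_null: int,
                   effect_sd: float, seed: int = 0) -> pd.DataFrame:
    """Omics features with linear loadings on archetype weights.

    The first ``n_features - n_null`` features load on the archetype
    weights with N(0, effect_sd) coefficients; the rest are pure noise.
    Loadings and the null mask are recorded on ``truth``.
    """
    if n_null > n_features:
        raise ValueError("n_null cannot exceed n_features")
    rng = np.random.default_rng(seed)
    W = truth.weights
    n, k = W.shape
    loadings = np.zeros((n_features, k))
    n_signal = n_features - n_null
    loadings[:n_signal] = rng.normal(scale=effect_sd, size=(n_signal, k))
    values = W @ loadings.T + rng.standard_normal((n, n_features))
    truth.omics_loadings = loadings
    truth.omics_null_mask = np.arange(n_features) >= n_signal
    cols = [f"feature_{j + 1:05d}" for j in range(n_features)]
    return pd.DataFrame(values, columns=cols,
                        index=[f"S{i + 1:04d}" for i in range(n)])


GRS_PARTITIONS = ("IS1", "IS2", "IA", "BMI", "LIPID", "MIX")


def generate_genotypes(n_subjects: int, n_snps: int,
                       freq_range: tuple = (0.05, 0.95),
                       seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biallelic dosages (0/1/2) and a risk-weight table with partitions.

    Dosages are binomial(2, f) at per-SNP risk-allele frequencies drawn
    uniformly from ``freq_range``; the weight table carries per-SNP effect
    sizes and one of the six mechanism-partition labels (IS1, IS2, IA,
    BMI, LIPID, MIX).
    """
    lo, hi = freq_range
    if not (0.0 <= lo < hi <= 1.0):
        raise ConfigurationError("freq_range must be within [0, 1]")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, freqs, size=(n_subjects, n_snps)).astype(float)
    snps = [f"rs{j + 1:06d}" for j in range(n_snps)]
    weights = pd.DataFrame({
        "snp": snps,
        "weight": np.abs(rng.normal(loc=0.05, scale=0.03, size=n_snps)),
        "risk_allele_freq": freqs,
        "partition": [GRS_PARTITIONS[j % len(GRS_PARTITIONS)]
                      for j in range(n_snps)],
    })
    dosage_df = pd.DataFrame(dosages, columns=snps,
                             index=[f"S{i + 1:04d}" for i in range(n_subjects)])
    return dosage_df, weights
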