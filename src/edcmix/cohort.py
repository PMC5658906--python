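"""Synthetic pregnancy-cohort generator.

Real individual-level data for this kind of multi-pollutant birth-weight
analysis are typically not public, so every downstream stage here is
exercised on synthetic cohorts that reproduce the statistical structure
the analysis assumes:

* per-chemical concentrations marginally log-normal, calibrated to the
  catalog's geometric mean (GM) and geometric standard deviation (GSD);
* positive within-class dependence induced by a Gaussian copula with a
  block-exchangeable correlation matrix (``rho_within`` inside a class,
  ``rho_between`` across classes);
* up to two gestational sampling visits per chemical, sharing a
  participant-level latent value with visit noise set by an intraclass
  correlation (``visit_icc``);
* limit-of-detection (LOD) censoring flags (true values are retained so
  the downstream LOD/sqrt(2) substitution can be tested against truth);
* categorical covariates drawn from declared marginal frequencies, and
  birth weight generated from a linear model whose chemical
  coefficients are class-level Gaussian random effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import ChemicalMeta, HIERARCHICAL_CLASSES

__all__ = [
    "CohortConfig",
    "TruthSpec",
    "ExposurePanel",
    "simulate_covariates",
    "simulate_exposures",
    "simulate_outcome",
    "default_truth",
    "null_truth",
    "recovery_truth",
    "default_ga_curve",
]

# Table-1-style marginal frequencies for the categorical covariates.
DEFAULT_COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "race": {"white": 0.617, "black_other": 0.383},
    "sex": {"female": 0.537, "male": 0.463},
    "education": {"ge_high_school": 0.893, "lt_high_school": 0.107},
    "cotinine": {"le3": 0.888, "gt3": 0.112},
    "income": {"ge_25k": 0.677, "lt_25k": 0.323},
    "employment": {"employed": 0.807, "unemployed": 0.193},
    "insurance": {"private": 0.708, "public_none": 0.292},
    "marital": {"partner": 0.645, "no_partner": 0.355},
    "vitamins": {"yes": 0.85, "no": 0.15},
}

# Sampling-visit pattern: urinary phthalate metabolites / BPA and the
# metals were measured at both gestational visits; the serum and
# lipid-normalized biomarkers once.
DEFAULT_VISITS_BY_CLASS: dict[str, int] = {
    "PHTHALATE_BPA": 2,
    "METAL": 2,
    "PCB": 1,
    "PFAS": 1,
    "PBDE": 1,
    "OCP": 1,
    "OPP": 1,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for one synthetic cohort.

    ``rho_within``/``rho_between`` parameterize the block-exchangeable
    latent (copula) correlation; ``visit_icc`` is the correlation between
    the two visit measurements of the same chemical in the same
    participant.  Gestational age is truncated-normal in weeks.
    """

    n_participants: int = 272
    seed: int = 0
    rho_within: float = 0.5
    rho_between: float = 0.1
    visit_icc: float = 0.6
    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_MARGINALS.items()
        }
    )
    ga_mean_weeks: float = 39.0
    ga_sd_weeks: float = 1.8
    ga_range_weeks: tuple[float, float] = (24.0, 43.0)
    age_mean: float = 29.5
    age_sd: float = 5.6
    age_range: tuple[float, float] = (18.0, 45.0)
    bmi_log_mean: float = math.log(26.2)
    bmi_log_sd: float = 0.21
    visits_by_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VISITS_BY_CLASS)
    )

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if not 0.0 <= self.rho_within < 1.0:
            raise ValueError("rho_within must lie in [0, 1)")
        if not 0.0 <= self.rho_between <= self.rho_within:
            raise ValueError("need 0 <= rho_between <= rho_within")
        if not 0.0 < self.visit_icc <= 1.0:
            raise ValueError("visit_icc must lie in (0, 1]")
        for cov, freqs in self.covariate_marginals.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"covariate {cov!r}: frequencies sum to {total}, not 1"
                )


def default_ga_curve(ga_weeks: np.ndarray) -> np.ndarray:
    """Default smooth gestational-age effect on birth weight (grams).

    Roughly linear fetal growth (~185 g/week) near term with mild
    concavity, centred so the effect is zero at 39 weeks.
    """
    d = np.asarray(ga_weeks, dtype=float) - 39.0
    return 185.0 * d - 7.0 * d**2


@dataclass(frozen=True)
class TruthSpec:
    """Generative coefficients for the synthetic birth-weight model.

    Chemical effects are grams per 1 SD of the visit-averaged log10
    concentration; per-chemical coefficients are drawn once per cohort
    as Normal(mu_beta[class], sigma_beta[class]).  Fixed-covariate
    effects are grams per design-column unit.
    """

    mu_beta_per_class: dict[str, float]
    sigma_beta_per_class: dict[str, float]
    fixed_covariate_betas: dict[str, float]
    ga_effect: Callable[[np.ndarray], np.ndarray] = default_ga_curve
    intercept: float = 3000.0
    residual_sd: float = 500.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma_beta_per_class.values()):
            raise ValueError("sigma_beta_per_class entries must be >= 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


def default_truth() -> TruthSpec:
    """Near-null truth echoing the magnitudes reported for this cohort.

    Class means and heterogeneities are set to the published class-level
    point estimates (small, mostly indistinguishable from zero);
    covariate effects follow the published adjusted estimates.
    """
    return TruthSpec(
        mu_beta_per_class={
            "PHTHALATE_BPA": 1.0,
            "PFAS": -11.0,
            "PCB": 0.2,
            "PBDE": -4.0,
            "OCP": 7.0,
        },
        sigma_beta_per_class={
            "PHTHALATE_BPA": 10.0,
            "PFAS": 24.0,
            "PCB": 5.0,
            "PBDE": 12.0,
            "OCP": 18.0,
        },
        fixed_covariate_betas={
            "DEP": 14.0,
            "DMP": -57.0,
            "Pb": -45.0,
            "Hg": 5.0,
            "race_black_other": -98.0,
            "age_years": 6.0,
            "sex_female": -201.0,
            "edu_lt_high_school": -124.0,
            "cotinine_gt3": -77.0,
            "income_lt_25k": -36.0,
            "unemployed": -84.0,
            "insurance_public_none": 91.0,
            "unmarried": -67.0,
            "vitamins_yes": 139.0,
            "bmi": 19.6,
        },
        intercept=3000.0,
        residual_sd=500.0,
    )


def null_truth() -> TruthSpec:
    """Global-null truth: every chemical effect exactly zero.

    Covariate and gestational-age effects are retained so the null
    applies to the chemical mixture, not to the whole outcome model.
    """
    base = default_truth()
    zero = {cl: 0.0 for cl in HIERARCHICAL_CLASSES}
    fixed = dict(base.fixed_covariate_betas)
    for chem in ("DEP", "DMP", "Pb", "Hg"):
        fixed[chem] = 0.0
    return replace(
        base,
        mu_beta_per_class=zero,
        sigma_beta_per_class=dict(zero),
        fixed_covariate_betas=fixed,
    )


def recovery_truth() -> TruthSpec:
    """Truth with effects sized to be estimable at moderate n.

    Parameter-recovery simulations need class effects that the data can
    actually pin down; this variant uses larger class means and a
    tighter residual than :func:`default_truth` while keeping the same
    covariate structure.
    """
    base = default_truth()
    return replace(
        base,
        mu_beta_per_class={
            "PHTHALATE_BPA": 30.0,
            "PFAS": -40.0,
            "PCB": 10.0,
            "PBDE": -20.0,
            "OCP": 25.0,
        },
        sigma_beta_per_class={
            "PHTHALATE_BPA": 15.0,
            "PFAS": 25.0,
            "PCB": 8.0,
            "PBDE": 15.0,
            "OCP": 20.0,
        },
        residual_sd=350.0,
    )


@dataclass
class ExposurePanel:
    """Participant x chemical x visit concentrations with censoring flags.

    ``concentration`` holds the true simulated values (native units,
    strictly positive); entries that fell strictly below the chemical's
    LOD are flagged in ``censored``.  Unmeasured visits are NaN in
    ``concentration`` and False in ``censored``.
    """

    concentration: np.ndarray  # (n, n_chem, n_visit)
    censored: np.ndarray  # bool, same shape
    chemicals: list[str]
    chem_classes: list[str]
    lod: np.ndarray  # (n_chem,)
    visits_per_chemical: np.ndarray  # (n_chem,), 1 or 2

    def __post_init__(self) -> None:
        if self.concentration.shape != self.censored.shape:
            raise ValueError("concentration/censored shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.any(self.concentration[np.isfinite(self.concentration)] <= 0):
                raise ValueError("concentrations must be positive")

    @property
    def n_participants(self) -> int:
        return self.concentration.shape[0]

    def subset(self, indices: np.ndarray) -> "ExposurePanel":
        """Panel restricted to the given participant rows."""
        idx = np.asarray(indices)
        return ExposurePanel(
            concentration=self.concentration[idx],
            censored=self.censored[idx],
            chemicals=list(self.chemicals),
            chem_classes=list(self.chem_classes),
            lod=self.lod,
            visits_per_chemical=self.visits_per_chemical,
        )

    def realized_censoring_fractions(self) -> pd.Series:
        """Fraction of measured values below the LOD, per chemical."""
        measured = np.isfinite(self.concentration)
        with np.errstate(invalid="ignore"):
            frac = self.censored.sum(axis=(0, 2)) / measured.sum(axis=(0, 2))
        return pd.Series(frac, index=self.chemicals, name="censoring_fraction")

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long-format view: participant, chemical, visit, value, censored."""
        n, p, v = self.concentration.shape
        part, chem, visit = np.meshgrid(
            np.arange(n), np.arange(p), np.arange(1, v + 1), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "participant": part.ravel(),
                "chemical": np.asarray(self.chemicals)[chem.ravel()],
                "visit": visit.ravel(),
                "value": self.concentration.ravel(),
                "censored": self.censored.ravel(),
            }
        )
        return df.dropna(subset=["value"]).reset_index(drop=True)

    @classmethod
    def from_long_dataframe(
        cls, df: pd.DataFrame, catalog: Sequence[ChemicalMeta]
    ) -> "ExposurePanel":
        """Rebuild a panel from the long CSV schema written above."""
        by_name = {c.name: c for c in catalog}
        chems = [c for c in df["chemical"].unique()]
        order = {name: j for j, name in enumerate(chems)}
        n = int(df["participant"].max()) + 1
        n_visit = int(df["visit"].max())
        conc = np.full((n, len(chems), n_visit), np.nan)
        cens = np.zeros((n, len(chems), n_visit), dtype=bool)
        rows = df["participant"].to_numpy(int)
        cols = df["chemical"].map(order).to_numpy(int)
        vis = df["visit"].to_numpy(int) - 1
        conc[rows, cols, vis] = df["value"].to_numpy(float)
        cens[rows, cols, vis] = df["censored"].to_numpy(bool)
        visits = np.array(
            [int(np.isfinite(conc[:, j, :]).any(axis=0).sum()) for j in range(len(chems))]
        )
        return cls(
            concentration=conc,
            censored=cens,
            chemicals=chems,
            chem_classes=[by_name[c].chem_class for c in chems],
            lod=np.array([by_name[c].lod_native for c in chems]),
            visits_per_chemical=visits,
        )


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float,
    lo: float, hi: float,
) -> np.ndarray:
    """Truncated-normal draws by inverse-CDF (deterministic given rng)."""
    from scipy.stats import norm

    a, b = norm.cdf(lo, mean, sd), norm.cdf(hi, mean, sd)
    u = rng.uniform(a, b, size=n)
    return norm.ppf(u, mean, sd)


def simulate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Draw participant covariates from the configured marginals.

    Covariates are drawn independently of one another — adequate for
    exercising the analysis machinery, though real demographic variables
    are of course correlated (see the methods note).
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_participants
    out: dict[str, np.ndarray] = {}
    for cov in sorted(config.covariate_marginals):
        freqs = config.covariate_marginals[cov]
        cats = list(freqs)
        probs = np.array([freqs[c] for c in cats], dtype=float)
        probs = probs / probs.sum()
        out[cov] = rng.choice(cats, size=n, p=probs)
    out["age_years"] = _truncated_normal(
        rng, n, config.age_mean, config.age_sd, *config.age_range
    )
    out["bmi"] = np.exp(rng.normal(config.bmi_log_mean, config.bmi_log_sd, size=n))
    out["ga_weeks"] = _truncated_normal(
        rng, n, config.ga_mean_weeks, config.ga_sd_weeks, *config.ga_range_weeks
    )
    cols = [
        "race", "age_years", "sex", "education", "cotinine", "income",
        "employment", "insurance", "marital", "vitamins", "bmi", "ga_weeks",
    ]
    df = pd.DataFrame(out)
    return df[cols] if n > 0 else pd.DataFrame(columns=cols)


def block_exchangeable_correlation(
    chem_classes: Sequence[str], rho_within: float, rho_between: float
) -> np.ndarray:
    """Latent correlation matrix: ``rho_within`` inside a class,
    ``rho_between`` across classes, unit diagonal."""
    classes = np.asarray(chem_classes)
    same = classes[:, None] == classes[None, :]
    R = np.where(same, rho_within, rho_between)
    np.fill_diagonal(R, 1.0)
    return R


def simulate_exposures(
    config: CohortConfig, catalog: Sequence[ChemicalMeta]
) -> ExposurePanel:
    """Draw the concentration panel for every catalog chemical with GM/GSD.

    The participant-level latent log concentration is exactly
    Normal(ln GM, ln GSD) per chemical; visit measurements add
    independent noise scaled so corr(visit1, visit2) = ``visit_icc``.
    Values strictly below the LOD are flagged censored but stored at
    their true simulated value.
    """
    chems = [c for c in catalog if c.gm is not None and c.gsd is not None]
    if not chems:
        raise ValueError("no catalog entries with gm and gsd available")
    names = [c.name for c in chems]
    classes = [c.chem_class for c in chems]
    p = len(chems)
    n = config.n_participants

    R = block_exchangeable_correlation(classes, config.rho_within, config.rho_between)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "latent correlation matrix is not positive definite "
            f"(rho_within={config.rho_within}, rho_between={config.rho_between})"
        ) from exc

    rng = np.random.default_rng([config.seed, 2])
    z = rng.standard_normal((n, p)) @ L.T

    ln_gm = np.array([c.ln_gm for c in chems])
    ln_gsd = np.array([c.ln_gsd for c in chems])
    latent_log = ln_gm + ln_gsd * z  # (n, p), natural-log scale

    # visit noise: var tau^2 with icc = s^2 / (s^2 + tau^2)
    icc = config.visit_icc
    tau = ln_gsd * math.sqrt((1.0 - icc) / icc)
    n_visit_max = 2
    visits = np.array(
        [config.visits_by_class.get(cls, 1) for cls in classes], dtype=int
    )
    noise = rng.standard_normal((n, p, n_visit_max)) * tau[None, :, None]
    log_conc = latent_log[:, :, None] + noise
    conc = np.exp(log_conc)
    # blank out unmeasured second visits
    conc[:, visits < 2, 1] = np.nan

    lod = np.array([c.lod_native for c in chems])
    with np.errstate(invalid="ignore"):
        censored = conc < lod[None, :, None]
    censored &= np.isfinite(conc)

    return ExposurePanel(
        concentration=conc,
        censored=censored,
        chemicals=names,
        chem_classes=classes,
        lod=lod,
        visits_per_chemical=visits,
    )


def simulate_outcome(
    X: pd.DataFrame,
    class_map: dict[str, str],
    C: pd.DataFrame,
    ga_weeks: np.ndarray,
    truth: TruthSpec,
    seed: int,
) -> tuple[np.ndarray, pd.Series]:
    """Generate birth weight from standardized exposures and covariates.

    ``X`` must already be on the analysis scale (standardized
    visit-averaged log10), so the class-level truth applies per SD.
    Per-chemical coefficients are drawn once per cohort as
    Normal(mu_beta[class], sigma_beta[class]) and returned for
    recovery testing.

    Returns
    -------
    (y, beta_draws)
        Birth weight in grams, and the drawn per-chemical coefficients
        indexed by exposure column.
    """
    if len(X) != len(C) or len(X) != len(np.asarray(ga_weeks)):
        raise ValueError(
            f"dimension mismatch: X has {len(X)} rows, C has {len(C)}, "
            f"ga_weeks has {len(np.asarray(ga_weeks))}"
        )
    unmapped = [c for c in X.columns if c not in class_map]
    if unmapped:
        raise ValueError(f"exposure columns missing from class_map: {unmapped}")

    rng = np.random.default_rng([seed, 3])
    betas = np.empty(X.shape[1])
    for j, col in enumerate(X.columns):
        cls = class_map[col]
        betas[j] = rng.normal(
            truth.mu_beta_per_class.get(cls, 0.0),
            truth.sigma_beta_per_class.get(cls, 0.0),
        )
    beta_draws = pd.Series(betas, index=X.columns, name="beta_true")

    fixed = np.array(
        [truth.fixed_covariate_betas.get(col, 0.0) for col in C.columns]
    )
    y = (
        truth.intercept
        + X.to_numpy(float) @ betas
        + C.to_numpy(float) @ fixed
        + truth.ga_effect(np.asarray(ga_weeks, dtype=float))
        + rng.normal(0.0, truth.residual_sd, size=len(X))
    )
    return y, beta_draws
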