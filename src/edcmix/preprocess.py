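"""Raw concentrations -> analysis design matrix.

The pipeline order is fixed and matters: censored values are first
substituted with LOD/sqrt(2), then concentrations are log10
transformed, then the (up to two) visit values are averaged, and only
then is each chemical standardized to mean 0 / SD 1.  Substituting
after the log transform, or averaging before it, gives different
numbers.

The per-chemical SD of the visit-averaged log10 value is retained so
that coefficients estimated per SD can later be re-expressed per
10-fold concentration increase (grams per unit log10).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import ChemicalMeta, apply_inclusion
from .cohort import ExposurePanel

__all__ = [
    "AnalysisMatrix",
    "substitute_lod",
    "log10_and_average",
    "molar_sum_opp",
    "standardize",
    "ga_spline_basis",
    "covariate_design",
    "assemble_design",
]

# molecular weights (g/mol) of the two organophosphate metabolites
MW_DEP = 154.10
MW_DMP = 126.05

#: covariate design columns, in report order, with their reference levels
#: implied by the indicator coding (white, male, >= high school, cotinine
#: <= 3 ng/ml, income >= $25k, employed, private insurance, living with
#: partner, no prenatal vitamins).
COVARIATE_COLUMNS = [
    "race_black_other",
    "age_years",
    "sex_female",
    "edu_lt_high_school",
    "cotinine_gt3",
    "income_lt_25k",
    "unemployed",
    "insurance_public_none",
    "unmarried",
    "vitamins_yes",
    "bmi",
]


def substitute_lod(value, censored_flag, lod):
    """Replace below-LOD values with LOD/sqrt(2); pass detects through.

    Vectorized over arrays; ``lod`` broadcasts against ``value``.
    Values exactly at the LOD count as detected (the censored flag, not
    a comparison, decides).
    """
    lod_arr = np.asarray(lod, dtype=float)
    if np.any(lod_arr <= 0):
        raise ValueError("lod must be > 0")
    value = np.asarray(value, dtype=float)
    censored = np.asarray(censored_flag, dtype=bool)
    out = np.where(censored, lod_arr / math.sqrt(2.0), value)
    if out.ndim == 0:
        return float(out)
    return out


def log10_and_average(visit_values) -> float | np.ndarray:
    """Mean of log10 over the available visits.

    Accepts a 1-d sequence of visit values for one participant-chemical
    (NaN = visit not measured; a single visit yields its own log10), or
    an (n, chem, visit) array averaged over the last axis.
    """
    arr = np.asarray(visit_values, dtype=float)
    finite = np.isfinite(arr)
    if np.any(arr[finite] <= 0):
        raise ValueError(
            "non-positive concentration: LOD substitution must precede log10"
        )
    with np.errstate(invalid="ignore"):
        out = np.nanmean(np.log10(arr), axis=-1)
    if out.ndim == 0:
        return float(out)
    return out


def molar_sum_opp(
    dep_conc, dmp_conc, mw_dep: float = MW_DEP, mw_dmp: float = MW_DMP
):
    """Molar sum of the DEP and DMP metabolite concentrations.

    ``dep_conc/mw_dep + dmp_conc/mw_dmp``; with mass concentrations in
    ug/L and molecular weights in g/mol the result is in umol/L.
    """
    if mw_dep <= 0 or mw_dmp <= 0:
        raise ValueError("molecular weights must be > 0")
    dep = np.asarray(dep_conc, dtype=float)
    dmp = np.asarray(dmp_conc, dtype=float)
    if np.any(dep[np.isfinite(dep)] < 0) or np.any(dmp[np.isfinite(dmp)] < 0):
        raise ValueError("concentrations must be non-negative")
    out = dep / mw_dep + dmp / mw_dmp
    if out.ndim == 0:
        return float(out)
    return out


def standardize(
    column, name: str = "column"
) -> tuple[np.ndarray, float, float]:
    """Center and scale to mean 0, SD 1 (sample SD, n-1 denominator).

    Returns ``(standardized, mean, sd)``; the SD feeds the per-10-fold
    back-transformation downstream.
    """
    x = np.asarray(column, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if not sd > 0:
        raise ValueError(f"cannot standardize constant column {name!r}")
    return (x - mean) / sd, mean, sd


def ga_spline_basis(ga_weeks, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis for gestational age.

    ``df`` columns spanning the natural cubic splines (boundary knots at
    the data min/max, interior knots at quantiles, via patsy's ``cr``)
    orthogonal to the constant, so the basis can sit next to an
    intercept without collinearity.  ``df=1`` degenerates to a single
    centred linear column.
    """
    from patsy import dmatrix

    x = np.asarray(ga_weeks, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    n_distinct = np.unique(x).size
    if df >= n_distinct:
        raise ValueError(
            f"spline df={df} requires more than {n_distinct} distinct GA values"
        )
    if df == 1:
        return (x - x.mean())[:, None]
    # cr's span always contains the constant: build df+1 columns, centre
    # them, and keep the df leading singular directions.
    raw = np.asarray(
        dmatrix("cr(x, df=k) - 1", {"x": x, "k": df + 1}, return_type="matrix")
    )
    centred = raw - raw.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    basis = u[:, :df] * s[:df]
    # sign convention: first nonzero loading of each column positive
    for j in range(df):
        col = basis[:, j]
        nz = col[np.abs(col) > 1e-12]
        if nz.size and nz[0] < 0:
            basis[:, j] = -col
    assert basis.shape == (x.size, df)
    return basis


def covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Indicator-code the covariate table against declared reference levels."""
    C = pd.DataFrame(index=covariates.index)
    C["race_black_other"] = (covariates["race"] == "black_other").astype(float)
    C["age_years"] = covariates["age_years"].astype(float)
    C["sex_female"] = (covariates["sex"] == "female").astype(float)
    C["edu_lt_high_school"] = (
        covariates["education"] == "lt_high_school"
    ).astype(float)
    C["cotinine_gt3"] = (covariates["cotinine"] == "gt3").astype(float)
    C["income_lt_25k"] = (covariates["income"] == "lt_25k").astype(float)
    C["unemployed"] = (covariates["employment"] == "unemployed").astype(float)
    C["insurance_public_none"] = (
        covariates["insurance"] == "public_none"
    ).astype(float)
    C["unmarried"] = (covariates["marital"] == "no_partner").astype(float)
    C["vitamins_yes"] = (covariates["vitamins"] == "yes").astype(float)
    C["bmi"] = covariates["bmi"].astype(float)
    return C[COVARIATE_COLUMNS]


@dataclass
class AnalysisMatrix:
    """Everything a model fit needs, on the analysis scale.

    ``X``: standardized visit-averaged log10 exposures for the
    hierarchically modelled chemicals; ``C``: demographic covariate
    design plus the log10-standardized fixed chemicals (OPPs, Pb, Hg);
    ``B``: gestational-age spline basis (None when GA is excluded);
    ``sd_log10``: per-chemical SD of the visit-averaged log10 value,
    for rescaling per-SD coefficients to per-10-fold.
    """

    y: Optional[np.ndarray]
    X: pd.DataFrame
    C: pd.DataFrame
    B: Optional[np.ndarray]
    sd_log10: pd.Series
    class_map: dict[str, str]
    ga_weeks: Optional[np.ndarray] = None
    n_dropped: int = 0
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in self.X.columns:
            if col not in self.class_map:
                raise ValueError(f"X column {col!r} missing from class_map")
        if np.any(self.sd_log10 <= 0):
            bad = self.sd_log10[self.sd_log10 <= 0].index.tolist()
            raise ValueError(f"non-positive sd_log10 for {bad}")

    @property
    def n(self) -> int:
        return len(self.X)

    def validate_standardization(self, tol: float = 1e-8) -> None:
        """Assert each X column has mean 0 and SD 1 (sample convention)."""
        arr = self.X.to_numpy(float)
        means = arr.mean(axis=0)
        sds = arr.std(axis=0, ddof=1)
        if np.max(np.abs(means)) > tol or np.max(np.abs(sds - 1)) > tol:
            raise AssertionError("X columns are not standardized")

    def design(self) -> tuple[np.ndarray, list[str]]:
        """Full design [1 | X | C | B] and its column names."""
        parts = [np.ones((self.n, 1)), self.X.to_numpy(float),
                 self.C.to_numpy(float)]
        names = ["intercept"] + list(self.X.columns) + list(self.C.columns)
        if self.B is not None:
            parts.append(self.B)
            names += [f"ga_spline_{k + 1}" for k in range(self.B.shape[1])]
        return np.hstack(parts), names

    def save(self, csv_path: str | Path, sidecar_path: str | Path) -> None:
        """Write one flat CSV plus a JSON sidecar of column roles."""
        df = pd.concat(
            [
                pd.Series(self.y, index=self.X.index, name="birth_weight_g")
                if self.y is not None else pd.DataFrame(index=self.X.index),
                self.X,
                self.C,
            ],
            axis=1,
        )
        if self.B is not None:
            for k in range(self.B.shape[1]):
                df[f"ga_spline_{k + 1}"] = self.B[:, k]
        df.to_csv(csv_path, index=False)
        sidecar = {
            "exposure_columns": list(self.X.columns),
            "covariate_columns": list(self.C.columns),
            "n_spline_columns": 0 if self.B is None else int(self.B.shape[1]),
            "class_map": self.class_map,
            "sd_log10": {k: float(v) for k, v in self.sd_log10.items()},
            "n_dropped": int(self.n_dropped),
            "options": self.options,
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def _processed_log10(
    panel: ExposurePanel, chem_names: Sequence[str]
) -> pd.DataFrame:
    """Substitute LOD/sqrt(2), log10, and visit-average selected chemicals."""
    idx = [panel.chemicals.index(name) for name in chem_names]
    conc = panel.concentration[:, idx, :]
    cens = panel.censored[:, idx, :]
    lod = panel.lod[idx]
    substituted = substitute_lod(conc, cens, lod[None, :, None])
    avg = log10_and_average(substituted)
    return pd.DataFrame(avg, columns=list(chem_names))


def assemble_design(
    panel: ExposurePanel,
    covariates: pd.DataFrame,
    catalog: Sequence[ChemicalMeta],
    outcome: Optional[np.ndarray] = None,
    *,
    inclusion_mode: str = "flag",
    opp_mode: str = "separate",
    include_ga: bool = True,
    spline_df: int = 3,
) -> AnalysisMatrix:
    """Build the :class:`AnalysisMatrix` from a raw panel and covariates.

    Applies inclusion, processes every included chemical
    (substitute -> log10 -> visit-average -> standardize), codes the
    covariates, and attaches the GA spline basis.  The OPPs can enter as
    two separate columns (default, ``opp_mode="separate"``) or as a
    single log10-standardized molar sum (``opp_mode="molar_sum"``).
    Participants with any missing field are dropped (complete case) and
    counted in ``n_dropped``.
    """
    if opp_mode not in {"separate", "molar_sum"}:
        raise ValueError(f"unknown opp_mode {opp_mode!r}")
    hier, fixed = apply_inclusion(catalog, mode=inclusion_mode)
    hier_names = [c.name for c in hier]
    fixed_names = [c.name for c in fixed]

    hier_log = _processed_log10(panel, hier_names)
    fixed_log = _processed_log10(panel, fixed_names)

    C_cov = covariate_design(covariates).reset_index(drop=True)
    y = None if outcome is None else np.asarray(outcome, dtype=float)

    # complete-case filter over every field entering the model
    blocks = [hier_log, fixed_log, C_cov,
              covariates[["ga_weeks"]].reset_index(drop=True)]
    mask = np.ones(len(hier_log), dtype=bool)
    for b in blocks:
        mask &= np.isfinite(b.to_numpy(float)).all(axis=1)
    if y is not None:
        mask &= np.isfinite(y)
    n_dropped = int((~mask).sum())
    if mask.sum() == 0:
        raise ValueError("no participants with complete data")

    hier_log = hier_log.loc[mask].reset_index(drop=True)
    fixed_log = fixed_log.loc[mask].reset_index(drop=True)
    C_cov = C_cov.loc[mask].reset_index(drop=True)
    ga = covariates["ga_weeks"].to_numpy(float)[mask]
    if y is not None:
        y = y[mask]

    sd_log10: dict[str, float] = {}
    X = pd.DataFrame(index=hier_log.index)
    for name in hier_names:
        X[name], _, sd = standardize(hier_log[name], name=name)
        sd_log10[name] = sd

    fixed_cols = pd.DataFrame(index=fixed_log.index)
    if opp_mode == "molar_sum":
        opp_names = [c.name for c in fixed if c.chem_class == "OPP"]
        other = [c.name for c in fixed if c.chem_class != "OPP"]
        if set(opp_names) >= {"DEP", "DMP"}:
            # molar sum on the native scale, then log10 and standardize
            dep = 10.0 ** fixed_log["DEP"].to_numpy()
            dmp = 10.0 ** fixed_log["DMP"].to_numpy()
            ms = np.log10(molar_sum_opp(dep, dmp))
            fixed_cols["OPP_molar_sum"], _, sd = standardize(ms, name="OPP_molar_sum")
            sd_log10["OPP_molar_sum"] = sd
        for name in other:
            fixed_cols[name], _, sd = standardize(fixed_log[name], name=name)
            sd_log10[name] = sd
    else:
        for name in fixed_names:
            fixed_cols[name], _, sd = standardize(fixed_log[name], name=name)
            sd_log10[name] = sd

    C = pd.concat([fixed_cols, C_cov], axis=1)
    B = ga_spline_basis(ga, df=spline_df) if include_ga else None

    class_by_name = {c.name: c.chem_class for c in hier}
    am = AnalysisMatrix(
        y=y,
        X=X,
        C=C,
        B=B,
        sd_log10=pd.Series(sd_log10),
        class_map={name: class_by_name[name] for name in hier_names},
        ga_weeks=ga,
        n_dropped=n_dropped,
        options={
            "inclusion_mode": inclusion_mode,
            "opp_mode": opp_mode,
            "include_ga": include_ga,
            "spline_df": spline_df,
        },
    )
    am.validate_standardization()
    return am
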