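"""Config-driven orchestration: simulate -> preprocess -> fit -> report.

Reproduces the analysis designs end-to-end on synthetic cohorts: the
primary hierarchical fit (class-level and per-chemical summaries on
both the per-SD and per-10-fold scales), the sensitivity designs
(gestational age excluded; sex-stratified), the penalized comparison
arm, and a parameter-recovery study that loops simulate -> fit and
reports bias, RMSE, and credible-interval coverage for the class-level
hyperparameters.

All outputs are plain CSV/JSON; a run is fully determined by its
:class:`RunConfig` (including the seed), so identical configs produce
byte-identical report CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import load_catalog
from .cohort import (
    CohortConfig,
    ExposurePanel,
    TruthSpec,
    default_truth,
    null_truth,
    recovery_truth,
    simulate_covariates,
    simulate_exposures,
    simulate_outcome,
)
from .bhlm import (
    BHLMSpec,
    PosteriorDraws,
    build_model,
    rescale_per_tenfold,
    sample_posterior,
    summarize,
)
from .penalized import penalized_analysis
from .preprocess import AnalysisMatrix, assemble_design

__all__ = [
    "RunConfig",
    "ConvergenceError",
    "CohortBundle",
    "generate_cohort",
    "run_primary",
    "run_sensitivity",
    "run_recovery_study",
]

TRUTH_PRESETS = {
    "default": default_truth,
    "null": null_truth,
    "recovery": recovery_truth,
}


class ConvergenceError(RuntimeError):
    """Raised when the sampler fails the split-R-hat gate."""


def validate_report(df: pd.DataFrame, kind: str) -> None:
    """Check a report table against the packaged column schema."""
    from importlib import resources

    schema = json.loads(
        (resources.files("edcmix") / "data" / "report_schema.json").read_text()
    )
    if kind not in schema:
        raise ValueError(f"unknown report kind {kind!r}")
    missing = [c for c in schema[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} report missing columns: {missing}")


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: cohort, truth, design toggles, estimators."""

    n_participants: int = 272
    seed: int = 0
    truth: str = "default"  # preset name; see TRUTH_PRESETS
    rho_within: float = 0.5
    rho_between: float = 0.1
    visit_icc: float = 0.6
    include_ga: bool = True
    opp_mode: str = "separate"
    spline_df: int = 3
    sex_stratified: bool = False
    estimators: tuple[str, ...] = ("bhlm",)
    chains: int = 2
    iterations: int = 2000
    warmup: int = 500
    enet_alpha: float = 0.5
    k_folds: int = 10
    rhat_gate: float = 1.05
    min_stratum_n: int = 50
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.estimators:
            raise ValueError("at least one estimator required")
        bad = set(self.estimators) - {"bhlm", "lasso", "enet"}
        if bad:
            raise ValueError(f"unknown estimators: {sorted(bad)}")
        if self.truth not in TRUTH_PRESETS:
            raise ValueError(
                f"unknown truth preset {self.truth!r}; "
                f"choose from {sorted(TRUTH_PRESETS)}"
            )

    def truth_spec(self) -> TruthSpec:
        return TRUTH_PRESETS[self.truth]()

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_participants=self.n_participants,
            seed=self.seed,
            rho_within=self.rho_within,
            rho_between=self.rho_between,
            visit_icc=self.visit_icc,
        )

    def sampler_spec(self) -> BHLMSpec:
        return BHLMSpec(
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            seed=self.seed,
        )


@dataclass
class CohortBundle:
    """A simulated cohort plus its assembled analysis matrix."""

    covariates: pd.DataFrame
    panel: ExposurePanel
    matrix: AnalysisMatrix
    beta_true: pd.Series
    truth: TruthSpec


def generate_cohort(
    config: RunConfig,
    truth: Optional[TruthSpec] = None,
    include_ga: Optional[bool] = None,
) -> CohortBundle:
    """Simulate covariates, exposures, and outcome; assemble the design."""
    truth = truth if truth is not None else config.truth_spec()
    include_ga = config.include_ga if include_ga is None else include_ga
    catalog = load_catalog()
    ccfg = config.cohort_config()
    covariates = simulate_covariates(ccfg)
    panel = simulate_exposures(ccfg, catalog)
    matrix = assemble_design(
        panel,
        covariates,
        catalog,
        outcome=None,
        opp_mode=config.opp_mode,
        include_ga=include_ga,
        spline_df=config.spline_df,
    )
    y, beta_true = simulate_outcome(
        matrix.X, matrix.class_map, matrix.C, matrix.ga_weeks,
        truth, config.seed,
    )
    matrix.y = y
    return CohortBundle(
        covariates=covariates,
        panel=panel,
        matrix=matrix,
        beta_true=beta_true,
        truth=truth,
    )


def fit_bhlm(
    matrix: AnalysisMatrix, spec: BHLMSpec, rhat_gate: float = 1.05
) -> PosteriorDraws:
    """Fit the hierarchical model and enforce the convergence gate."""
    model = build_model(matrix, spec)
    posterior = sample_posterior(model)
    diag = posterior.diagnostics()
    worst = float(diag["rhat"].max())
    if worst > rhat_gate:
        bad = diag.loc[diag["rhat"] > rhat_gate, "parameter"].tolist()
        raise ConvergenceError(
            f"split R-hat gate {rhat_gate} failed (max {worst:.3f}) "
            f"for parameters: {bad[:10]}"
        )
    return posterior


def _class_report(
    posterior: PosteriorDraws, matrix: AnalysisMatrix
) -> pd.DataFrame:
    """Class-level and fixed-coefficient summary on both scales."""
    per_sd_rows = []
    hyper = posterior.hyper_draws()
    mu_cols = [c for c in hyper.columns if c.startswith("mu_beta")]
    sigma_cols = [c for c in hyper.columns if c.startswith("sigma_beta")]
    per_sd_rows.append(summarize(hyper[mu_cols]))
    per_sd_rows.append(summarize(hyper[sigma_cols]))
    fixed_cols = [c for c in matrix.C.columns]
    fixed_draws = pd.DataFrame(
        {c: posterior.coefficient_draws(c) for c in fixed_cols}
    )
    per_sd_rows.append(summarize(fixed_draws))
    per_sd = pd.concat(per_sd_rows, ignore_index=True)

    _, class_tenfold = rescale_per_tenfold(posterior)
    # fixed chemicals also carry an sd_log10 entry -> rescale those rows too
    chem_fixed = [c for c in fixed_cols if c in matrix.sd_log10.index]
    fixed_tenfold = summarize(
        fixed_draws[chem_fixed] / matrix.sd_log10[chem_fixed],
        scale="per_tenfold",
    )
    return pd.concat(
        [per_sd, class_tenfold, fixed_tenfold], ignore_index=True
    )


def _round_report(df: pd.DataFrame, decimals: int = 6) -> pd.DataFrame:
    """Round float columns so report CSVs are byte-stable."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(decimals)
    return out


def run_primary(config: RunConfig, outdir: Optional[str | Path] = None
                ) -> dict[str, object]:
    """Run the primary analysis design and write the report bundle.

    Emits a class-level summary CSV (posterior mean, SD, 95% and 50%
    equi-tailed intervals, per-SD and per-10-fold scales), a
    per-chemical coefficient CSV, a pairwise exposure-correlation CSV,
    and a JSON manifest with seeds, diagnostics, and versions.
    """
    t0 = time.monotonic()
    outdir = Path(outdir or config.outdir or "results/primary")
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_cohort(config)
    matrix = bundle.matrix

    report: dict[str, object] = {"config": config, "bundle": bundle}
    manifest: dict[str, object] = {
        "seed": config.seed,
        "n_participants": matrix.n,
        "n_dropped": matrix.n_dropped,
        "estimators": list(config.estimators),
        "truth_preset": config.truth,
        "options": matrix.options,
        "versions": _versions(),
    }

    corr = matrix.X.corr()
    corr.round(6).to_csv(outdir / "exposure_correlations.csv")

    if "bhlm" in config.estimators:
        posterior = fit_bhlm(matrix, config.sampler_spec(), config.rhat_gate)
        class_summary = _class_report(posterior, matrix)
        chem_sd = summarize(posterior.exposure_draws())
        chem_tenfold, _ = rescale_per_tenfold(posterior)
        chem_summary = pd.concat([chem_sd, chem_tenfold], ignore_index=True)
        chem_summary.insert(
            1, "chem_class",
            chem_summary["parameter"].map(matrix.class_map),
        )
        validate_report(class_summary, "class_summary")
        validate_report(chem_summary, "chemical_summary")
        _round_report(class_summary).to_csv(
            outdir / "class_summary.csv", index=False
        )
        _round_report(chem_summary).to_csv(
            outdir / "chemical_summary.csv", index=False
        )
        diag = posterior.diagnostics()
        manifest["sampler"] = {
            "chains": config.chains,
            "iterations": config.iterations,
            "warmup": config.warmup,
            "max_rhat": float(diag["rhat"].max()),
            "min_ess_bulk": float(diag["ess_bulk"].min()),
        }
        report.update(
            posterior=posterior,
            class_summary=class_summary,
            chem_summary=chem_summary,
        )

    for est in ("lasso", "enet"):
        if est in config.estimators:
            alpha = 1.0 if est == "lasso" else config.enet_alpha
            fit = penalized_analysis(
                matrix, alpha=alpha, k_folds=config.k_folds, seed=config.seed
            )
            _round_report(fit.refit_estimates).to_csv(
                outdir / f"{est}_refit.csv", index=False
            )
            sel = pd.DataFrame({"selected": fit.selected})
            sel.to_csv(outdir / f"{est}_selected.csv", index=False)
            with open(outdir / f"{est}_cv.json", "w") as fh:
                json.dump(
                    {
                        "alpha": alpha,
                        "chosen_lambda": fit.chosen_lambda,
                        "n_selected": len(fit.selected),
                        "k_folds": config.k_folds,
                    },
                    fh,
                    indent=2,
                )
            report[f"{est}_fit"] = fit

    manifest["elapsed_s"] = round(time.monotonic() - t0, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    report["outdir"] = outdir
    return report


def run_sensitivity(config: RunConfig, outdir: Optional[str | Path] = None
                    ) -> dict[str, dict]:
    """Sensitivity designs: GA-spline excluded, and/or sex-stratified.

    Outputs use the same schema as the primary run so reports can be
    diffed directly.  Strata below ``min_stratum_n`` are skipped with a
    warning.
    """
    import warnings

    outdir = Path(outdir or config.outdir or "results/sensitivity")
    results: dict[str, dict] = {}

    ga_cfg = dataclasses.replace(config, include_ga=False)
    results["ga_excluded"] = run_primary(ga_cfg, outdir / "ga_excluded")

    if config.sex_stratified:
        bundle = generate_cohort(config)
        catalog = load_catalog()
        sex = bundle.covariates["sex"].to_numpy()
        for stratum in ("male", "female"):
            idx = np.flatnonzero(sex == stratum)
            if len(idx) < config.min_stratum_n:
                warnings.warn(
                    f"stratum {stratum!r} has n={len(idx)} < "
                    f"{config.min_stratum_n}; skipped",
                    stacklevel=2,
                )
                continue
            sub_cov = bundle.covariates.iloc[idx].reset_index(drop=True)
            sub_panel = bundle.panel.subset(idx)
            sub_matrix = assemble_design(
                sub_panel,
                sub_cov,
                catalog,
                outcome=np.asarray(bundle.matrix.y)[idx],
                opp_mode=config.opp_mode,
                include_ga=config.include_ga,
                spline_df=config.spline_df,
            )
            # sex is constant within a stratum; drop its design column
            sub_matrix.C = sub_matrix.C.drop(columns=["sex_female"])
            sub_out = Path(outdir) / f"sex_{stratum}"
            sub_out.mkdir(parents=True, exist_ok=True)
            posterior = fit_bhlm(
                sub_matrix, config.sampler_spec(), config.rhat_gate
            )
            class_summary = _class_report(posterior, sub_matrix)
            _round_report(class_summary).to_csv(
                sub_out / "class_summary.csv", index=False
            )
            results[f"sex_{stratum}"] = {
                "posterior": posterior,
                "class_summary": class_summary,
                "n": sub_matrix.n,
                "outdir": sub_out,
            }
    return results


def run_recovery_study(
    config: RunConfig,
    n_replicates: int = 30,
    truth: Optional[TruthSpec] = None,
    outdir: Optional[str | Path] = None,
) -> dict[str, object]:
    """Simulate -> fit loop; bias, RMSE, and CI coverage for mu/sigma.

    Each replicate draws a fresh cohort (seed offset from the config
    seed), fits the hierarchical model, and records the class-level
    posterior summaries.  Replicates failing the convergence gate are
    excluded and counted.  Coverage is reported per class and pooled
    over classes (the pooled figure has finer granularity at modest
    replicate counts).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    truth = truth if truth is not None else (
        recovery_truth() if config.truth == "recovery" else config.truth_spec()
    )
    rows = []
    n_failed = 0
    for r in range(n_replicates):
        rcfg = dataclasses.replace(config, seed=config.seed + 1000 + r)
        bundle = generate_cohort(rcfg, truth=truth)
        try:
            posterior = fit_bhlm(
                bundle.matrix, rcfg.sampler_spec(), config.rhat_gate
            )
        except ConvergenceError:
            n_failed += 1
            continue
        hyper = posterior.hyper_draws()
        for cl in posterior.class_labels:
            mu_true = truth.mu_beta_per_class.get(cl, 0.0)
            sg_true = truth.sigma_beta_per_class.get(cl, 0.0)
            for param, draws, tv in (
                ("mu_beta", hyper[f"mu_beta[{cl}]"], mu_true),
                ("sigma_beta", hyper[f"sigma_beta[{cl}]"], sg_true),
            ):
                q = np.quantile(draws, [0.025, 0.25, 0.5, 0.75, 0.975])
                rows.append(
                    {
                        "replicate": r,
                        "class": cl,
                        "parameter": param,
                        "truth": tv,
                        "post_mean": float(np.mean(draws)),
                        "post_median": float(q[2]),
                        "ci95_lower": float(q[0]),
                        "ci95_upper": float(q[4]),
                        "ci50_lower": float(q[1]),
                        "ci50_upper": float(q[3]),
                    }
                )
    reps = pd.DataFrame(rows)
    if reps.empty:
        raise ConvergenceError("every replicate failed the convergence gate")
    reps["cover95"] = (reps["ci95_lower"] <= reps["truth"]) & (
        reps["truth"] <= reps["ci95_upper"]
    )
    reps["cover50"] = (reps["ci50_lower"] <= reps["truth"]) & (
        reps["truth"] <= reps["ci50_upper"]
    )
    reps["error"] = reps["post_mean"] - reps["truth"]

    metrics = (
        reps.groupby(["parameter", "class"])
        .agg(
            truth=("truth", "first"),
            bias=("error", "mean"),
            rmse=("error", lambda e: float(np.sqrt(np.mean(e**2)))),
            coverage95=("cover95", "mean"),
            coverage50=("cover50", "mean"),
            median_estimate=("post_median", "median"),
        )
        .reset_index()
    )
    validate_report(metrics, "recovery_metrics")
    mu_rows = reps[reps["parameter"] == "mu_beta"]
    pooled = {
        "mu_beta_pooled_coverage95": float(mu_rows["cover95"].mean()),
        "mu_beta_pooled_coverage50": float(mu_rows["cover50"].mean()),
        "n_replicates": int(n_replicates),
        "n_converged": int(reps["replicate"].nunique()),
        "n_failed_convergence": int(n_failed),
    }
    out = {"metrics": metrics, "replicates": reps, **pooled}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _round_report(metrics).to_csv(outdir / "recovery_metrics.csv",
                                      index=False)
        _round_report(reps).to_csv(outdir / "recovery_replicates.csv",
                                   index=False)
        payload = dict(pooled)
        payload["per_class"] = json.loads(metrics.to_json(orient="records"))
        with open(outdir / "recovery_metrics.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    return out


def _versions() -> dict[str, str]:
    import numpy
    import pandas as pd_
    import scipy

    return {
        "edcmix": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd_.__version__,
    }
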