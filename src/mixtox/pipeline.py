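"""Orchestration: plates -> viability -> IC50 curves -> interaction table.

`run_single_analysis` produces the single-exposure IC50 report (one row per
compound x exposure time); `run_mixture_analysis` produces the
observed-vs-predicted interaction report with a consistency appendix.
Both are deterministic given the config seed and log the package version,
config hash and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

import pandas as pd

from . import io as mio
from .config import RunConfig
from .dose_response import DoseResponseCurve, fit_4pl
from .mixture import (
    classify_interaction,
    predict_bliss,
    predict_effect_summation,
    predict_loewe,
    reconstruct_singles_from_binaries,
)

__all__ = ["SingleAnalysisResult", "MixtureAnalysisResult",
           "run_single_analysis", "run_mixture_analysis"]

log = logging.getLogger("mixtox")

CURVE_REPORT_COLUMNS = (
    "compound", "exposure_h", "ic50_mM", "ci_low_mM", "ci_high_mM", "r2",
    "converged", "n_points",
)
INTERACTION_REPORT_COLUMNS = (
    "exposure_h", "mixture", "observed_pct", "predicted_pct", "interaction",
    "p_value", "model",
)


def _package_version() -> str:
    try:
        return version("mixtox")
    except PackageNotFoundError:
        return "unknown"


def _log_run(config: RunConfig, stage: str) -> None:
    log.info(
        "%s: mixtox %s, config %s, seed %d",
        stage, _package_version(), config.config_hash(), config.seed,
    )


@dataclass
class SingleAnalysisResult:
    """IC50 report plus any compounds whose fit failed."""

    report: pd.DataFrame
    curves: dict[tuple[str, float], DoseResponseCurve]
    failures: dict[tuple[str, float], str] = field(default_factory=dict)


def run_single_analysis(config: RunConfig) -> SingleAnalysisResult:
    """Fit a 4PL per compound x exposure and build the IC50 report.

    Compounds whose fit raises are listed in ``failures`` and the run
    continues.
    """
    if config.dose_table is None:
        raise ValueError("config.dose_table is required for single analysis")
    _log_run(config, "single-exposure analysis")
    datasets = mio.read_dose_response_table(config.dose_table)
    if config.exposure_h is not None:
        datasets = {k: v for k, v in datasets.items() if k[1] == config.exposure_h}
    rows, curves, failures = [], {}, {}
    kwargs = config.fit.estimator_kwargs()
    for key in sorted(datasets):
        data = datasets[key]
        try:
            curve = fit_4pl(data, random_state=config.seed, **kwargs)
        except Exception as exc:  # noqa: BLE001 - failures reported, run continues
            failures[key] = f"{type(exc).__name__}: {exc}"
            log.warning("fit failed for %s at %s h: %s", key[0], key[1], exc)
            continue
        curves[key] = curve
        rows.append(dict(
            compound=curve.compound, exposure_h=curve.exposure_h,
            ic50_mM=curve.ic50, ci_low_mM=curve.ic50_ci95[0],
            ci_high_mM=curve.ic50_ci95[1], r2=curve.r2,
            converged=curve.converged, n_points=curve.n_points,
        ))
    report = pd.DataFrame(rows, columns=list(CURVE_REPORT_COLUMNS))
    return SingleAnalysisResult(report=report, curves=curves, failures=failures)


@dataclass
class MixtureAnalysisResult:
    """Interaction report plus the binary-consistency appendix."""

    report: pd.DataFrame
    skipped: dict[str, str] = field(default_factory=dict)
    consistency: dict[float, dict] = field(default_factory=dict)


def _single_viabilities(config: RunConfig) -> dict[tuple[str, float], float]:
    """Measured mean single-exposure viability per (compound, dose)."""
    if config.singles_table is None:
        return {}
    df = mio.read_table(config.singles_table)
    required = {"compound", "dose_mM", "viability_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"singles table missing columns: {sorted(missing)}")
    return {
        (str(comp), float(dose)): float(grp["viability_pct"].mean())
        for (comp, dose), grp in df.groupby(["compound", "dose_mM"])
    }


def run_mixture_analysis(
    config: RunConfig,
    curves: dict[str, DoseResponseCurve] | None = None,
) -> MixtureAnalysisResult:
    """Predict each mixture, test observed vs predicted, classify.

    Single-agent viabilities V_i come from measured singles at the mixture
    concentrations (matched on compound and dose); with
    ``interaction.use_fitted_curves`` (or for the Loewe model) they come
    from the fitted curves instead.  Mixtures whose inputs are missing are
    skipped with a logged reason.  When an exposure block contains >= 6
    binary predictions, a consistency appendix reports the
    least-squares reconstruction of the single-agent inhibitions and its
    residual norm.
    """
    if config.mixture_design_table is None or config.observed_table is None:
        raise ValueError("mixture analysis needs design and observed tables")
    _log_run(config, "mixture analysis")
    exposure = config.exposure_h if config.exposure_h is not None else 24.0
    designs = mio.read_mixture_designs(config.mixture_design_table, exposure)
    observed = mio.read_observed_replicates(config.observed_table)
    singles = _single_viabilities(config)
    opts = config.interaction

    if (opts.model == "loewe" or opts.use_fitted_curves) and not curves:
        if config.dose_table is None:
            raise ValueError(
                "curve-based predictions need fitted curves or a dose_table"
            )
        fitted = run_single_analysis(config)
        curves = {c: k for (c, _h), k in fitted.curves.items()}

    rows, skipped = [], {}
    predictions = {}
    for mixture_id, design in designs.items():
        if mixture_id not in observed:
            skipped[mixture_id] = "no observed replicates"
            log.warning("skipping %s: no observed replicates", mixture_id)
            continue
        try:
            if opts.model == "loewe":
                pred = predict_loewe(curves, design)
            else:
                if opts.use_fitted_curves:
                    vmap = {
                        c.compound: float(curves[c.compound].predict(
                            c.concentration_mM))
                        for c in design.components
                    }
                else:
                    vmap = {}
                    for c in design.components:
                        key = (c.compound, c.concentration_mM)
                        if key not in singles:
                            raise KeyError(
                                f"no measured single viability for {c.compound} "
                                f"at {c.concentration_mM} mM"
                            )
                        vmap[c.compound] = singles[key]
                predict = (predict_effect_summation
                           if opts.model == "effect_summation" else predict_bliss)
                pred = predict(vmap, design=design)
        except Exception as exc:  # noqa: BLE001 - skipped mixtures are reported
            skipped[mixture_id] = f"{type(exc).__name__}: {exc}"
            log.warning("skipping %s: %s", mixture_id, exc)
            continue
        call = classify_interaction(observed[mixture_id], pred, alpha=opts.alpha)
        predictions[frozenset(design.compounds)] = pred.predicted_viability
        rows.append(dict(
            exposure_h=design.exposure_h, mixture=design.label,
            observed_pct=call.observed_mean, predicted_pct=call.predicted,
            interaction=call.label, p_value=call.p_value, model=pred.model,
        ))
    report = pd.DataFrame(rows, columns=list(INTERACTION_REPORT_COLUMNS))

    consistency: dict[float, dict] = {}
    binaries = {k: v for k, v in predictions.items() if len(k) == 2}
    if len(binaries) >= 6:
        rec = reconstruct_singles_from_binaries(binaries)
        consistency[exposure] = {
            "implied_viabilities": rec.implied_viabilities,
            "residual_norm": rec.residual_norm,
            "n_equations": rec.n_equations,
        }
    return MixtureAnalysisResult(report=report, skipped=skipped,
                                 consistency=consistency)
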