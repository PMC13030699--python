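"""Four-parameter logistic (4PL) concentration-response fitting and IC50 CIs.

The model for viability V (percent) at dose d (mM) is

    V(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

with hill > 0 so the response decreases with dose (viability-assay
convention) and V(ic50) = (top + bottom) / 2 exactly — ic50 is the curve
midpoint.  Zero-dose control points are allowed: (0 / ic50)^hill is taken
as 0, so V(0) = top and no log transform of doses is needed inside the
model.

Fitting minimizes the sum of squared residuals over replicate-level points
(replicates are never dose-averaged, preserving the error degrees of
freedom for the confidence interval).  The optimizer works in log10(ic50)
for stability, with soft sanity bounds bottom in [-10, 50] and top in
[50, 150] by default; either asymptote can be fixed.

Confidence intervals for the IC50 come from the curvature of the residual
surface in log10(ic50) (Wald interval in log space with a t quantile at
N - p degrees of freedom), or from a seeded bootstrap that resamples
replicates within dose and refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "four_pl",
    "DoseResponseDataset",
    "DoseResponseCurve",
    "FourParamLogistic",
    "DegenerateFitError",
    "fit_4pl",
    "ic50_confidence_interval",
    "PotencyRanking",
    "rank_potency",
]

_PARAM_NAMES = ("bottom", "top", "log10_ic50", "hill")


class DegenerateFitError(ValueError):
    """The dataset cannot identify a 4PL curve (flat response, bad doses...)."""


def four_pl(
    d: np.ndarray | float,
    bottom: float,
    top: float,
    hill: float,
    ic50: float,
) -> np.ndarray | float:
    """Evaluate the 4PL viability curve at dose(s) ``d`` (mM)."""
    d = np.asarray(d, dtype=float)
    ratio = np.zeros_like(d)
    pos = d > 0
    ratio[pos] = (d[pos] / ic50) ** hill
    out = bottom + (top - bottom) / (1.0 + ratio)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DoseResponseDataset:
    """Replicate-level dose-viability data for one compound and exposure time.

    ``dose_mM`` and ``viability_pct`` are parallel arrays, one entry per
    replicate well; zero doses mark vehicle controls.
    """

    compound: str
    exposure_h: float
    dose_mM: np.ndarray
    viability_pct: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dose_mM, dtype=float)
        v = np.asarray(self.viability_pct, dtype=float)
        object.__setattr__(self, "dose_mM", d)
        object.__setattr__(self, "viability_pct", v)
        if d.shape != v.shape or d.ndim != 1:
            raise ValueError("dose_mM and viability_pct must be equal-length 1-D")
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(d))):
            raise ValueError("doses and viabilities must be finite")
        if np.any(d < 0):
            raise ValueError("doses must be >= 0")
        if self.exposure_h <= 0:
            raise ValueError("exposure_h must be positive")

    @property
    def n_distinct_doses(self) -> int:
        return int(np.unique(self.dose_mM[self.dose_mM > 0]).size)


@dataclass
class DoseResponseCurve:
    """A fitted 4PL curve: the single-exposure IC50 report row."""

    compound: str
    exposure_h: float
    bottom: float
    top: float
    hill: float
    ic50: float
    ic50_ci95: tuple[float, float]
    r2: float
    n_points: int
    converged: bool
    _estimator: "FourParamLogistic | None" = field(
        default=None, repr=False, compare=False
    )

    def predict(self, dose_mM: np.ndarray | float) -> np.ndarray | float:
        return four_pl(dose_mM, self.bottom, self.top, self.hill, self.ic50)


class FourParamLogistic(RegressorMixin, BaseEstimator):
    """Scikit-learn style 4PL dose-response regressor.

    Parameters
    ----------
    bottom_bounds, top_bounds, hill_bounds
        Box constraints for the asymptotes and slope.  Defaults are soft
        sanity bounds for a percent-viability assay.
    fix_bottom, fix_top
        If given, the asymptote is held at that value instead of fitted.
    ci_method
        ``"asymptotic_log"`` (Wald in log10(ic50), t quantile at N - p df)
        or ``"bootstrap"`` (resample replicates within dose, refit,
        percentile interval).
    n_boot
        Bootstrap resamples (>= 999 recommended).
    random_state
        Seeds start-point jitter and the bootstrap.

    Attributes
    ----------
    bottom_, top_, hill_, ic50_ : float
        Fitted parameters (midpoint parameterization: the curve passes
        through (top_ + bottom_) / 2 at ic50_).
    ic50_ci95_ : tuple of float
        95% confidence interval for ic50_ (mM).
    r2_ : float
        1 - SSres / SStot on the replicate-level training points.
    converged_ : bool
        False if the optimizer stalled; parameters are then best-effort.
    """

    def __init__(
        self,
        bottom_bounds: tuple[float, float] = (-10.0, 50.0),
        top_bounds: tuple[float, float] = (50.0, 150.0),
        hill_bounds: tuple[float, float] = (0.05, 10.0),
        fix_bottom: float | None = None,
        fix_top: float | None = None,
        ci_method: Literal["asymptotic_log", "bootstrap"] = "asymptotic_log",
        n_boot: int = 999,
        random_state: int | None = None,
    ):
        self.bottom_bounds = bottom_bounds
        self.top_bounds = top_bounds
        self.hill_bounds = hill_bounds
        self.fix_bottom = fix_bottom
        self.fix_top = fix_top
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.random_state = random_state

    # -- internal parameter plumbing ------------------------------------

    def _free_mask(self) -> np.ndarray:
        return np.array([self.fix_bottom is None, self.fix_top is None, True, True])

    def _full_params(self, free: np.ndarray) -> np.ndarray:
        full = np.empty(4)
        it = iter(free)
        full[0] = next(it) if self.fix_bottom is None else self.fix_bottom
        full[1] = next(it) if self.fix_top is None else self.fix_top
        full[2] = next(it)
        full[3] = next(it)
        return full

    @staticmethod
    def _model(full: np.ndarray, d: np.ndarray) -> np.ndarray:
        bottom, top, log10_ic50, hill = full
        return four_pl(d, bottom, top, hill, 10.0 ** log10_ic50)

    def _initial_guess(self, d: np.ndarray, v: np.ndarray) -> np.ndarray:
        # dose-averaged means anchor the asymptotes; the dose nearest the
        # half-way response seeds log10(ic50)
        doses = np.unique(d)
        means = np.array([v[d == dd].mean() for dd in doses])
        top0 = float(np.clip(means.max(), *self.top_bounds))
        bottom0 = float(np.clip(means.min(), *self.bottom_bounds))
        if self.fix_top is not None:
            top0 = self.fix_top
        if self.fix_bottom is not None:
            bottom0 = self.fix_bottom
        half = (top0 + bottom0) / 2.0
        nz = doses > 0
        mid = doses[nz][np.argmin(np.abs(means[nz] - half))]
        return np.array([bottom0, top0, np.log10(mid), 1.0])

    def _bounds(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dpos = d[d > 0]
        lo_ic50 = np.log10(dpos.min()) - np.log10(50.0)
        hi_ic50 = np.log10(dpos.max()) + np.log10(50.0)
        lo = np.array([self.bottom_bounds[0], self.top_bounds[0], lo_ic50,
                       self.hill_bounds[0]])
        hi = np.array([self.bottom_bounds[1], self.top_bounds[1], hi_ic50,
                       self.hill_bounds[1]])
        mask = self._free_mask()
        return lo[mask], hi[mask]

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y) -> "FourParamLogistic":
        """Fit the curve to doses ``X`` (mM) and viabilities ``y`` (percent)."""
        d = np.asarray(X, dtype=float).reshape(-1)
        v = np.asarray(y, dtype=float).reshape(-1)
        if d.shape != v.shape:
            raise ValueError("X and y must have the same length")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(v))):
            raise ValueError("doses and viabilities must be finite")
        if np.any(d < 0):
            raise ValueError("doses must be >= 0")
        if not np.any(d > 0):
            raise DegenerateFitError("dataset has no positive doses")
        if np.unique(d[d > 0]).size < 5:
            raise DegenerateFitError(
                "need >= 5 distinct non-zero doses for a 4-parameter fit"
            )
        if np.allclose(v, v[0]):
            raise DegenerateFitError("all viabilities identical; curve unidentifiable")

        mask = self._free_mask()
        x0_full = self._initial_guess(d, v)
        lo, hi = self._bounds(d)

        def residuals(free: np.ndarray) -> np.ndarray:
            return self._model(self._full_params(free), d) - v

        rng = np.random.default_rng(self.random_state)
        best = None
        x0 = np.clip(x0_full[mask], lo, hi)
        starts = [x0]
        for _ in range(3):  # seeded jitters used only if the first start fails
            starts.append(np.clip(x0 + rng.normal(0, 0.15, x0.size) * (hi - lo) / 4,
                                  lo, hi))
        for i, start in enumerate(starts):
            res = optimize.least_squares(
                residuals, start, bounds=(lo, hi), method="trf", xtol=1e-12,
                ftol=1e-12, gtol=1e-12,
            )
            if best is None or res.cost < best.cost:
                best = res
            if i == 0 and res.success:
                break

        full = self._full_params(best.x)
        self.bottom_, self.top_ = float(full[0]), float(full[1])
        self.log10_ic50_, self.hill_ = float(full[2]), float(full[3])
        self.ic50_ = float(10.0 ** full[2])
        self.converged_ = bool(best.success)
        self.n_points_ = d.size
        self.dof_ = d.size - int(mask.sum())
        ss_res = float(np.sum(best.fun ** 2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot
        self._X_, self._y_, self._result_ = d, v, best
        self.ic50_ci95_ = self._confidence_interval(self.ci_method)
        return self

    def predict(self, X) -> np.ndarray:
        d = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(
            four_pl(d, self.bottom_, self.top_, self.hill_, self.ic50_)
        )

    # -- confidence intervals --------------------------------------------

    def _confidence_interval(self, method: str) -> tuple[float, float]:
        if method == "asymptotic_log":
            ci = self._asymptotic_ci()
            if ci is not None:
                return ci
            warnings.warn(
                "residual curvature not invertible; falling back to bootstrap CI",
                RuntimeWarning,
                stacklevel=2,
            )
            method = "bootstrap"
        if method == "bootstrap":
            return self._bootstrap_ci()
        raise ValueError(f"unknown ci_method {method!r}")

    def _asymptotic_ci(self) -> tuple[float, float] | None:
        res = self._result_
        J = res.jac
        jtj = J.T @ J
        if self.dof_ <= 0:
            return None
        try:
            cov = np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            return None
        s2 = float(np.sum(res.fun ** 2)) / self.dof_
        idx = int(np.flatnonzero(self._free_mask())
                  .tolist().index(2))  # position of log10_ic50 among free params
        var = cov[idx, idx] * s2
        if not np.isfinite(var) or var < 0:
            return None
        se = np.sqrt(var)
        tq = stats.t.ppf(0.975, self.dof_)
        lo = 10.0 ** (self.log10_ic50_ - tq * se)
        hi = 10.0 ** (self.log10_ic50_ + tq * se)
        return float(lo), float(hi)

    def _bootstrap_ci(self) -> tuple[float, float]:
        d, v = self._X_, self._y_
        rng = np.random.default_rng(self.random_state)
        groups = [np.flatnonzero(d == dd) for dd in np.unique(d)]
        boot_ic50 = np.empty(self.n_boot)
        warm = FourParamLogistic(**{**self.get_params(), "ci_method": "asymptotic_log"})
        for b in range(self.n_boot):
            idx = np.concatenate([rng.choice(g, size=g.size, replace=True)
                                  for g in groups])
            boot_ic50[b] = _quick_refit(warm, d[idx], v[idx], self)
        lo, hi = np.percentile(boot_ic50, [2.5, 97.5])
        return float(lo), float(hi)

    def ic50_confidence_interval(
        self, method: Literal["asymptotic_log", "bootstrap"] | None = None
    ) -> tuple[float, float]:
        """Recompute the 95% IC50 interval with the given method."""
        return self._confidence_interval(method or self.ci_method)


def _quick_refit(template: FourParamLogistic, d, v, warm_from: FourParamLogistic):
    """One bootstrap refit, warm-started at the original solution."""
    lo, hi = template._bounds(d)
    mask = template._free_mask()
    full0 = np.array([warm_from.bottom_, warm_from.top_,
                      warm_from.log10_ic50_, warm_from.hill_])
    x0 = np.clip(full0[mask], lo, hi)

    def residuals(free):
        return template._model(template._full_params(free), d) - v

    res = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    return 10.0 ** template._full_params(res.x)[2]


def fit_4pl(
    data: DoseResponseDataset,
    **fit_options,
) -> DoseResponseCurve:
    """Fit a 4PL curve to one dataset and return the report-row summary.

    ``fit_options`` are forwarded to :class:`FourParamLogistic` (bounds,
    fixed asymptotes, ``ci_method``, ``n_boot``, ``random_state``).
    """
    est = FourParamLogistic(**fit_options).fit(data.dose_mM, data.viability_pct)
    return DoseResponseCurve(
        compound=data.compound,
        exposure_h=data.exposure_h,
        bottom=est.bottom_,
        top=est.top_,
        hill=est.hill_,
        ic50=est.ic50_,
        ic50_ci95=est.ic50_ci95_,
        r2=est.r2_,
        n_points=est.n_points_,
        converged=est.converged_,
        _estimator=est,
    )


def ic50_confidence_interval(
    curve: DoseResponseCurve,
    data: DoseResponseDataset | None = None,
    method: Literal["asymptotic_log", "bootstrap"] = "asymptotic_log",
    **fit_options,
) -> tuple[float, float]:
    """95% IC50 interval for a fitted curve.

    Uses the estimator attached by :func:`fit_4pl` when available;
    otherwise refits ``data`` with ``fit_options``.
    """
    est = curve._estimator
    if est is None:
        if data is None:
            raise ValueError("need the dataset to recompute a CI for a bare curve")
        est = FourParamLogistic(**fit_options).fit(data.dose_mM, data.viability_pct)
    return est.ic50_confidence_interval(method)


@dataclass(frozen=True)
class PotencyRanking:
    """Compounds ordered by ascending IC50 (most potent first)."""

    compounds: tuple[str, ...]
    ic50s: tuple[float, ...]
    ties: tuple[tuple[str, str], ...]

    def __iter__(self):
        return iter(self.compounds)


def rank_potency(
    curves: Sequence[DoseResponseCurve], *, allow_mixed_exposure: bool = False
) -> PotencyRanking:
    """Order compounds by potency: ascending IC50, lower = more cytotoxic.

    Ties are broken lexicographically by compound name and flagged in the
    result.  Mixing exposure times raises unless explicitly allowed.
    """
    if len(curves) < 2:
        if not curves:
            raise ValueError("need at least one curve")
    exposures = {c.exposure_h for c in curves}
    if len(exposures) > 1 and not allow_mixed_exposure:
        raise ValueError(
            f"curves span exposure times {sorted(exposures)}; "
            "pass allow_mixed_exposure=True to rank anyway"
        )
    ordered = sorted(curves, key=lambda c: (c.ic50, c.compound))
    ties = tuple(
        (a.compound, b.compound)
        for a, b in zip(ordered, ordered[1:])
        if a.ic50 == b.ic50
    )
    return PotencyRanking(
        compounds=tuple(c.compound for c in ordered),
        ic50s=tuple(c.ic50 for c in ordered),
        ties=ties,
    )
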