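"""Mixture-effect prediction and interaction classification.

Three reference models predict the viability of a k-component co-exposure
from single-agent data:

* **Effect summation** — component inhibitions add:
  ``predicted = 100 - sum_i (100 - V_i)``, where V_i is the measured
  single-exposure viability (percent) of component i at its mixture
  concentration.  This is the additivity model used for the bundled
  reference interaction table (there labelled "Concentration Addition");
  it can predict below 0 for strong inhibitions, and such values are
  returned unclamped but flagged.
* **Bliss independence** — survival fractions multiply:
  ``predicted = 100 * prod_i (V_i / 100)``; always in [0, 100] for
  V_i in [0, 100], and agrees with summation to first order when all
  inhibitions are small.
* **Loewe concentration addition** — the classical isobole model: the
  predicted effect level y solves ``sum_i c_i / EC_{y,i} = 1`` where
  EC_{y,i} is the dose at which component i's fitted 4PL curve alone gives
  viability y.  Satisfies the sham-combination axiom (a compound "mixed"
  with itself predicts its own curve).

Observed mixture replicates are compared against the prediction with a
two-sided one-sample t-test (the prediction treated as a known constant):
synergistic if observed is significantly lower, antagonistic if
significantly higher, additive otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .dose_response import DoseResponseCurve

__all__ = [
    "MixtureComponent",
    "MixtureDesign",
    "MixturePrediction",
    "InteractionCall",
    "ReconstructionResult",
    "predict_effect_summation",
    "predict_bliss",
    "predict_loewe",
    "classify_interaction",
    "reconstruct_singles_from_binaries",
]


@dataclass(frozen=True)
class MixtureComponent:
    compound: str
    concentration_mM: float
    fraction_of_ic50: float = 0.5

    def __post_init__(self):
        if self.concentration_mM <= 0:
            raise ValueError("component concentrations must be > 0")


@dataclass(frozen=True)
class MixtureDesign:
    """A k-component co-exposure (k >= 2) at fixed component concentrations."""

    components: tuple[MixtureComponent, ...]
    exposure_h: float = 24.0

    def __post_init__(self):
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) < 2:
            raise ValueError("a mixture design needs >= 2 components")
        names = [c.compound for c in comps]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compound in mixture design")

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(c.compound for c in self.components)

    @property
    def label(self) -> str:
        return "+".join(self.compounds)


@dataclass
class MixturePrediction:
    """A model-predicted mixture viability and the inputs it came from."""

    model: Literal["effect_summation", "bliss", "loewe"]
    predicted_viability: float
    inputs_used: dict
    design: MixtureDesign | None = None
    below_zero: bool = False


def _as_viability_map(singles: Mapping[str, float] | Iterable[float]) -> dict:
    if isinstance(singles, Mapping):
        out = {str(k): float(v) for k, v in singles.items()}
    else:
        out = {f"component_{i + 1}": float(v) for i, v in enumerate(singles)}
    if not out:
        raise ValueError("need at least one single-exposure viability")
    if not all(math.isfinite(v) for v in out.values()):
        raise ValueError("single-exposure viabilities must be finite")
    return out


def predict_effect_summation(
    singles: Mapping[str, float] | Iterable[float],
    design: MixtureDesign | None = None,
) -> MixturePrediction:
    """Additivity by summing inhibitions: ``100 - sum_i (100 - V_i)``.

    Algebraically identical to ``[1 - sum_i (1 - V_i/100)] * 100``.  A
    below-zero prediction is returned unclamped with ``below_zero=True``.
    """
    vmap = _as_viability_map(singles)
    predicted = 100.0 - sum(100.0 - v for v in vmap.values())
    return MixturePrediction(
        model="effect_summation",
        predicted_viability=predicted,
        inputs_used=vmap,
        design=design,
        below_zero=predicted < 0,
    )


def predict_bliss(
    singles: Mapping[str, float] | Iterable[float],
    design: MixtureDesign | None = None,
) -> MixturePrediction:
    """Bliss independence: survival fractions multiply."""
    vmap = _as_viability_map(singles)
    clipped = {k: min(max(v, 0.0), 100.0) for k, v in vmap.items()}
    if clipped != vmap:
        warnings.warn(
            "single viabilities outside [0, 100] clipped for Bliss prediction",
            RuntimeWarning,
            stacklevel=2,
        )
    predicted = 100.0 * float(np.prod([v / 100.0 for v in clipped.values()]))
    return MixturePrediction(
        model="bliss", predicted_viability=predicted, inputs_used=clipped,
        design=design,
    )


class LoeweNoSolutionError(RuntimeError):
    """The Loewe condition has no root in the shared response range."""


def predict_loewe(
    curves: Mapping[str, DoseResponseCurve],
    design: MixtureDesign,
    tol: float = 1e-8,
) -> MixturePrediction:
    """Loewe concentration addition from fitted single-agent 4PL curves.

    Solves ``sum_i c_i / EC_{y,i} - 1 = 0`` for the viability level y by
    bracketed root-finding inside (max_i bottom_i, min_i top_i); the
    equi-effective dose is the 4PL inverse
    ``EC_y = ic50 * ((top - y) / (y - bottom))^(1/hill)``.
    """
    comps = design.components
    missing = [c.compound for c in comps if c.compound not in curves]
    if missing:
        raise KeyError(f"no fitted curve for mixture component(s): {missing}")
    use = [(curves[c.compound], c.concentration_mM) for c in comps]
    for curve, _ in use:
        if not curve.converged:
            raise ValueError(f"curve for {curve.compound!r} did not converge")

    y_lo = max(c.bottom for c, _ in use)
    y_hi = min(c.top for c, _ in use)
    if y_lo >= y_hi:
        raise LoeweNoSolutionError(
            "component curves have no overlapping response range"
        )

    def ec(curve: DoseResponseCurve, y: float) -> float:
        return curve.ic50 * ((curve.top - y) / (y - curve.bottom)) ** (1.0 / curve.hill)

    def condition(y: float) -> float:
        return sum(c_i / ec(curve, y) for curve, c_i in use) - 1.0

    eps = (y_hi - y_lo) * 1e-12
    a, b = y_lo + eps, y_hi - eps
    fa, fb = condition(a), condition(b)
    # condition decreases in y (EC_y grows toward the top asymptote):
    # fa > 0 > fb whenever the doses are inside the curves' active range
    if fa * fb > 0:
        raise LoeweNoSolutionError(
            f"no sign change in ({y_lo:.3f}, {y_hi:.3f}): "
            f"condition spans [{fb:.3g}, {fa:.3g}]"
        )
    y_star = optimize.brentq(condition, a, b, xtol=1e-12, rtol=8.9e-16)
    if abs(condition(y_star)) > tol:
        raise LoeweNoSolutionError("root did not reach requested tolerance")
    return MixturePrediction(
        model="loewe",
        predicted_viability=float(y_star),
        inputs_used={c.compound: curves[c.compound] for c in comps},
        design=design,
    )


@dataclass
class InteractionCall:
    """Observed-vs-predicted comparison for one mixture."""

    observed_mean: float
    observed_replicates: tuple[float, ...]
    predicted: float
    mean_difference: float  # observed - predicted, percentage points
    t_stat: float
    p_value: float
    label: Literal["additive", "synergistic", "antagonistic"]
    alpha: float
    n: int
    model: str = "effect_summation"


class IndeterminateVarianceError(ValueError):
    """Zero replicate variance with a non-zero mean difference: untestable."""


def classify_interaction(
    observed: Sequence[float] | np.ndarray,
    prediction: MixturePrediction | float,
    alpha: float = 0.05,
) -> InteractionCall:
    """Two-sided one-sample t-test of observed replicates vs the prediction.

    The predicted value is treated as a known constant.  Labels follow the
    viability convention: observed significantly *below* predicted means
    stronger-than-additive killing (synergistic); significantly above means
    antagonistic; otherwise additive.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need >= 2 observed replicate viabilities")
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed viabilities must be finite")
    if isinstance(prediction, MixturePrediction):
        pred = prediction.predicted_viability
        model = prediction.model
    else:
        pred, model = float(prediction), "effect_summation"
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    diff = obs - pred
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        if math.isclose(mean_diff, 0.0, abs_tol=1e-12):
            t_stat, p_value = 0.0, 1.0
        else:
            raise IndeterminateVarianceError(
                "replicates have zero variance but a non-zero mean difference"
            )
    else:
        t_res = stats.ttest_1samp(diff, 0.0, alternative="two-sided")
        t_stat, p_value = float(t_res.statistic), float(t_res.pvalue)

    if p_value < alpha and mean_diff < 0:
        label = "synergistic"
    elif p_value < alpha and mean_diff > 0:
        label = "antagonistic"
    else:
        label = "additive"
    return InteractionCall(
        observed_mean=float(obs.mean()),
        observed_replicates=tuple(obs.tolist()),
        predicted=pred,
        mean_difference=mean_diff,
        t_stat=t_stat,
        p_value=p_value,
        label=label,
        alpha=alpha,
        n=obs.size,
        model=model,
    )


@dataclass
class ReconstructionResult:
    """Least-squares single-agent inhibitions implied by binary predictions."""

    compounds: tuple[str, ...]
    inhibitions: dict[str, float]  # percentage points
    implied_viabilities: dict[str, float]  # 100 - inhibition
    residual_norm: float
    n_equations: int

    def predict_effect_summation(self, components: Iterable[str]) -> float:
        """Effect-summation prediction for any subset of the compounds."""
        return 100.0 - sum(self.inhibitions[c] for c in components)


def reconstruct_singles_from_binaries(
    binary_predictions: Mapping[frozenset[str] | tuple[str, str], float],
) -> ReconstructionResult:
    """Recover single-agent inhibitions from binary effect-summation predictions.

    Under effect summation every binary prediction is
    ``100 - (I_i + I_j)``, so the printed pairwise predictions define the
    linear system ``I_i + I_j = 100 - predicted_ij``.  Solving it by least
    squares yields the implied single-agent inhibitions, and the residual
    norm measures how internally consistent the set of predictions is: a
    consistent table reproduces itself almost exactly, while measurements
    taken in separate batches leave a large residual.
    """
    pairs = {frozenset(k): float(v) for k, v in binary_predictions.items()}
    if len(pairs) != len(binary_predictions):
        raise ValueError("duplicate (unordered) compound pairs in input")
    if any(len(p) != 2 for p in pairs):
        raise ValueError("every key must be an unordered pair of two compounds")
    compounds = tuple(sorted(set().union(*pairs)))
    k = len(compounds)
    if len(pairs) < k:
        raise ValueError(
            f"{len(pairs)} equations cannot determine {k} compounds"
        )
    idx = {c: i for i, c in enumerate(compounds)}
    A = np.zeros((len(pairs), k))
    b = np.empty(len(pairs))
    for row, (pair, predicted) in enumerate(sorted(pairs.items(),
                                                   key=lambda kv: sorted(kv[0]))):
        for c in pair:
            A[row, idx[c]] = 1.0
        b[row] = 100.0 - predicted
    rank = np.linalg.matrix_rank(A)
    if rank < k:
        counts = {c: int(A[:, idx[c]].sum()) for c in compounds}
        thin = [c for c, n in counts.items() if n < 2]
        raise ValueError(
            f"rank-deficient system (rank {rank} < {k}); "
            f"compounds with insufficient pair coverage: {thin or compounds}"
        )
    inhibitions, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.linalg.norm(A @ inhibitions - b))
    inhib = {c: float(inhibitions[idx[c]]) for c in compounds}
    return ReconstructionResult(
        compounds=compounds,
        inhibitions=inhib,
        implied_viabilities={c: 100.0 - v for c, v in inhib.items()},
        residual_norm=residual,
        n_equations=len(pairs),
    )
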