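"""Seeded synthetic plate experiments with known ground truth.

Emulates the study design end to end: four compounds with 4PL
concentration-response curves, graded single-compound doses read in
replicate wells (n = 5-7 in the real assay; 6 by default here), and
fixed-ratio mixtures with every component at 0.5 x its IC50.  Because the
generating curves, noise level and interaction mode are known, every
pipeline stage — viability normalization, 4PL fitting, mixture prediction,
interaction testing — can be checked for recovery of the truth.

Noise is Gaussian on viability by default.  In ``absorbance_mode`` the
noise is instead injected on the raw A570/A600 readings of simulated
96-well plates (including blank and control wells), and viability noise
emerges through the normalization formula — this exercises the plate
module in round-trip tests.

Seeds are explicit function arguments, never hidden state: the same seed
reproduces the same dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .dose_response import DoseResponseDataset, four_pl
from .mixture import MixtureComponent, MixtureDesign
from .reference import COMPOUNDS, reference_ic50

__all__ = [
    "CurveParams",
    "MixtureTruth",
    "GroundTruth",
    "NoiseModel",
    "default_ground_truth",
    "default_mixture_designs",
    "SimulatedSingles",
    "SimulatedMixture",
    "simulate_single_exposures",
    "simulate_mixture_exposures",
]

# Realistic cytotoxicity sigmoids are steep; per-compound slopes in ~2-2.6
# (set once; see docs/methods.md)
_DEFAULT_HILLS = {"CLO": 2.2, "IMI": 2.6, "ENR": 1.8, "OFX": 2.4}


@dataclass(frozen=True)
class CurveParams:
    """True 4PL parameters of one compound."""

    bottom: float
    top: float
    hill: float
    ic50_mM: float

    def __post_init__(self):
        if self.ic50_mM <= 0 or self.hill <= 0:
            raise ValueError("ic50 and hill must be > 0")

    def viability(self, dose_mM) -> np.ndarray | float:
        return four_pl(dose_mM, self.bottom, self.top, self.hill, self.ic50_mM)


@dataclass(frozen=True)
class MixtureTruth:
    """How a simulated mixture's true effect combines its components.

    ``synergy_factor`` multiplies the summed inhibition: 1 is additive,
    > 1 synergistic, < 1 antagonistic (only meaningful for the summation
    modes).
    """

    interaction_mode: Literal[
        "summation_additive", "bliss_additive", "synergy_factor"
    ] = "summation_additive"
    synergy_factor: float = 1.0

    def __post_init__(self):
        if self.synergy_factor <= 0:
            raise ValueError("synergy_factor must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """True curves per compound plus per-mixture interaction modes."""

    curves: Mapping[str, CurveParams]
    mixtures: Mapping[str, MixtureTruth] = field(default_factory=dict)

    def mixture_truth(self, design: MixtureDesign) -> MixtureTruth:
        return self.mixtures.get(design.label, MixtureTruth())

    def true_mixture_viability(self, design: MixtureDesign) -> float:
        """Noise-free mixture viability under the design's interaction mode."""
        singles = {
            c.compound: float(self.curves[c.compound].viability(c.concentration_mM))
            for c in design.components
        }
        truth = self.mixture_truth(design)
        if truth.interaction_mode == "bliss_additive":
            return 100.0 * float(np.prod([v / 100.0 for v in singles.values()]))
        total_inhibition = sum(100.0 - v for v in singles.values())
        return 100.0 - truth.synergy_factor * total_inhibition


def default_ground_truth(
    exposure_h: int = 24,
    mixtures: Mapping[str, MixtureTruth] | None = None,
) -> GroundTruth:
    """The default scenario: published IC50s as truth, full viability range.

    Curves use bottom = 0, top = 100 and per-compound hill slopes around 2;
    IC50s are the bundled reference values at the requested exposure time.
    """
    curves = {
        c: CurveParams(
            bottom=0.0, top=100.0, hill=_DEFAULT_HILLS[c],
            ic50_mM=reference_ic50(c, exposure_h),
        )
        for c in COMPOUNDS
    }
    return GroundTruth(curves=curves, mixtures=dict(mixtures or {}))


def default_mixture_designs(
    truth: GroundTruth,
    exposure_h: float = 24.0,
    fraction_of_ic50: float = 0.5,
) -> list[MixtureDesign]:
    """All 6 binary, 4 ternary and 1 quaternary fixed-ratio designs."""
    from itertools import combinations

    names = sorted(truth.curves)
    designs = []
    for k in (2, 3, 4):
        for combo in combinations(names, k):
            designs.append(
                MixtureDesign(
                    components=tuple(
                        MixtureComponent(
                            compound=c,
                            concentration_mM=fraction_of_ic50
                            * truth.curves[c].ic50_mM,
                            fraction_of_ic50=fraction_of_ic50,
                        )
                        for c in combo
                    ),
                    exposure_h=exposure_h,
                )
            )
    return designs


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise specification.

    ``viability_sd`` is the Gaussian sd in percentage points applied
    directly to viabilities.  With ``absorbance_mode`` the generator
    instead emits 96-well plates whose A570/A600 readings carry Gaussian
    noise of sd ``absorbance_sd`` (every well, including blanks and
    controls), with the stated blank/control means; viability noise then
    emerges through the normalization formula.
    """

    viability_sd: float = 5.0
    absorbance_mode: bool = False
    absorbance_sd: float = 0.0
    blank_a570: float = 0.1
    blank_a600: float = 0.05
    control_a570: float = 1.2
    control_a600: float = 0.4

    def __post_init__(self):
        if self.viability_sd < 0 or self.absorbance_sd < 0:
            raise ValueError("noise sds must be >= 0")

    @property
    def control_signal(self) -> float:
        return (self.control_a570 - self.blank_a570) - (
            self.control_a600 - self.blank_a600
        )


@dataclass
class SimulatedSingles:
    """Single-exposure simulation output: datasets, optional plates, truth."""

    datasets: dict[str, DoseResponseDataset]
    plates: pd.DataFrame | None
    truth: GroundTruth
    seed: int
    exposure_h: float

    def manifest(self) -> dict:
        """Ground truth and seed for every generated dataset (JSON-able)."""
        return {
            "seed": self.seed,
            "exposure_h": self.exposure_h,
            "compounds": {
                name: {
                    "bottom": p.bottom, "top": p.top,
                    "hill": p.hill, "ic50_mM": p.ic50_mM,
                    "n_points": int(self.datasets[name].dose_mM.size),
                }
                for name, p in self.truth.curves.items()
                if name in self.datasets
            },
        }


def _default_doses(truth: GroundTruth) -> dict[str, np.ndarray]:
    # 8 log-spaced doses spanning 0.1x-4x the true ic50
    return {
        name: np.geomspace(0.1 * p.ic50_mM, 4.0 * p.ic50_mM, 8)
        for name, p in truth.curves.items()
    }


def simulate_single_exposures(
    truth: GroundTruth,
    doses: Mapping[str, Iterable[float]] | None = None,
    n_replicates: int = 6,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    exposure_h: float = 24.0,
    include_zero_dose: bool = False,
) -> SimulatedSingles:
    """Simulate graded single-compound exposures with replicate wells.

    Viability at each dose is the true 4PL value plus Gaussian noise (or
    absorbance-level noise in ``absorbance_mode``); ``include_zero_dose``
    adds vehicle-control points at dose 0.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    dose_map = {
        name: np.asarray(list(d), dtype=float)
        for name, d in (doses or _default_doses(truth)).items()
    }
    for name, d in dose_map.items():
        if name not in truth.curves:
            raise KeyError(f"doses given for unknown compound {name!r}")
        if np.any(d <= 0):
            raise ValueError("doses must be > 0 (zero dose via include_zero_dose)")
    rng = np.random.default_rng(seed)
    datasets: dict[str, DoseResponseDataset] = {}
    plate_rows: list[dict] = []

    for name in sorted(dose_map):
        params = truth.curves[name]
        d = dose_map[name]
        if include_zero_dose:
            d = np.concatenate([[0.0], d])
        all_doses = np.repeat(d, n_replicates)
        true_v = np.asarray(params.viability(all_doses), dtype=float)

        if not noise.absorbance_mode:
            v = true_v + rng.normal(0.0, noise.viability_sd, true_v.size)
        else:
            v = _plate_viabilities(
                name, all_doses, true_v, noise, rng, plate_rows
            )
        datasets[name] = DoseResponseDataset(
            compound=name, exposure_h=exposure_h, dose_mM=all_doses,
            viability_pct=v,
        )

    plates = pd.DataFrame(plate_rows) if plate_rows else None
    return SimulatedSingles(
        datasets=datasets, plates=plates, truth=truth, seed=seed,
        exposure_h=exposure_h,
    )


def _plate_viabilities(compound, all_doses, true_v, noise, rng, plate_rows):
    """Emit one simulated 96-well plate; return formula-derived viabilities.

    Treated-well signals are scaled so the noise-free plate reproduces the
    true viabilities exactly; the returned values re-apply the
    normalization arithmetic to the noisy readings, so they match what
    :func:`mixtox.plate.compute_viability` computes from the same plate.
    """
    plate_id = f"sim-{compound}"
    n_blank, n_control = 4, 6
    blank570 = noise.blank_a570 + rng.normal(0, noise.absorbance_sd, n_blank)
    blank600 = noise.blank_a600 + rng.normal(0, noise.absorbance_sd, n_blank)
    ctrl570 = noise.control_a570 + rng.normal(0, noise.absorbance_sd, n_control)
    ctrl600 = noise.control_a600 + rng.normal(0, noise.absorbance_sd, n_control)
    for i in range(n_blank):
        plate_rows.append(dict(plate_id=plate_id, well=f"B{i + 1}", role="blank",
                               condition_id=None, a570=blank570[i],
                               a600=blank600[i]))
    for i in range(n_control):
        plate_rows.append(dict(plate_id=plate_id, well=f"C{i + 1}", role="control",
                               condition_id=None, a570=ctrl570[i],
                               a600=ctrl600[i]))
    # target noise-free signal per treated well
    target_signal = true_v / 100.0 * noise.control_signal
    a600_t = noise.control_a600 + rng.normal(0, noise.absorbance_sd, true_v.size)
    a570_t = (
        target_signal + noise.blank_a570
        + (a600_t - noise.blank_a600)
        + rng.normal(0, noise.absorbance_sd, true_v.size)
    )
    a570_t = np.maximum(a570_t, 0.0)
    for i, dose in enumerate(all_doses):
        plate_rows.append(dict(
            plate_id=plate_id, well=f"T{i + 1}", role="treated",
            condition_id=f"{compound}@{dose:.6g}", a570=a570_t[i], a600=a600_t[i],
        ))
    # re-derive viability through the normalization arithmetic
    b570, b600 = blank570.mean(), blank600.mean()
    denom = ((ctrl570 - b570) - (ctrl600 - b600)).mean()
    signal = (a570_t - b570) - (a600_t - b600)
    return signal / denom * 100.0


@dataclass
class SimulatedMixture:
    """Observed replicates for one mixture plus its generating truth."""

    design: MixtureDesign
    observed: np.ndarray
    true_viability: float
    singles_true: dict[str, float]
    truth_spec: MixtureTruth


def simulate_mixture_exposures(
    truth: GroundTruth,
    designs: Iterable[MixtureDesign],
    n_replicates: int = 6,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> dict[str, SimulatedMixture]:
    """Simulate observed replicate viabilities for fixed-ratio mixtures.

    Each mixture's true viability follows its :class:`MixtureTruth` mode
    (inhibitions summed and scaled by the synergy factor, or Bliss
    survival product); replicates add Gaussian viability noise.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    out: dict[str, SimulatedMixture] = {}
    for design in designs:
        missing = [c for c in design.compounds if c not in truth.curves]
        if missing:
            raise KeyError(f"unknown compound(s) in design: {missing}")
        singles = {
            c.compound: float(truth.curves[c.compound].viability(c.concentration_mM))
            for c in design.components
        }
        true_v = truth.true_mixture_viability(design)
        observed = true_v + rng.normal(0.0, noise.viability_sd, n_replicates)
        out[design.label] = SimulatedMixture(
            design=design,
            observed=observed,
            true_viability=true_v,
            singles_true=singles,
            truth_spec=truth.mixture_truth(design),
        )
    return out
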