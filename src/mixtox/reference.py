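"""Published reference values for the four-compound SK-N-SH cytotoxicity study.

The study exposed human neuroblastoma SK-N-SH cells to two neonicotinoid
insecticides — clothianidin (CLO) and imidacloprid (IMI) — and two
fluoroquinolone antibiotics — enrofloxacin (ENR) and ofloxacin (OFX) —
singly and in fixed-ratio mixtures (each component at 0.5 x its IC50).
These constants are the printed study results: single-compound IC50s with
95% CIs and R^2 at 24 h and 48 h, and observed / effect-summation-predicted
viabilities with interaction calls for all eleven mixtures at both times.

The raw plate data behind these numbers are not public, so the tables serve
as fixtures for internal-consistency checks (see
:func:`mixtox.mixture.reconstruct_singles_from_binaries`) and as realistic
ground-truth parameters for the synthetic generator.
"""

from __future__ import annotations

import pandas as pd

COMPOUNDS = ("CLO", "IMI", "ENR", "OFX")

# compound, exposure_h, ic50_mM, ci_low_mM, ci_high_mM, r2
_IC50_ROWS = [
    ("CLO", 24, 5.356, 5.192, 5.521, 0.969),
    ("IMI", 24, 4.754, 4.660, 4.850, 0.989),
    ("ENR", 24, 1.446, 1.361, 1.535, 0.980),
    ("OFX", 24, 2.742, 2.637, 2.852, 0.990),
    ("CLO", 48, 4.029, 3.581, 4.208, 0.963),
    ("IMI", 48, 3.631, 3.502, 3.757, 0.978),
    ("ENR", 48, 0.826, 0.787, 0.869, 0.988),
    ("OFX", 48, 2.005, 1.960, 2.056, 0.991),
]

# exposure_h, components, observed_viability_pct, predicted_viability_pct,
# interaction, p_value (p stored as string to preserve "<0.001")
_INTERACTION_ROWS = [
    (24, ("CLO", "ENR"), 69.334, 74.030, "additive", "0.228"),
    (24, ("CLO", "OFX"), 55.997, 70.645, "synergistic", "<0.001"),
    (24, ("IMI", "ENR"), 40.630, 72.312, "synergistic", "<0.001"),
    (24, ("IMI", "OFX"), 60.906, 68.928, "synergistic", "0.014"),
    (24, ("CLO", "IMI"), 53.087, 69.088, "synergistic", "<0.001"),
    (24, ("ENR", "OFX"), 38.430, 73.869, "synergistic", "<0.001"),
    (24, ("CLO", "IMI", "ENR"), 47.299, 57.715, "synergistic", "0.003"),
    (24, ("CLO", "IMI", "OFX"), 45.674, 54.331, "synergistic", "0.012"),
    (24, ("ENR", "OFX", "CLO"), 29.968, 59.272, "synergistic", "<0.001"),
    (24, ("ENR", "OFX", "IMI"), 39.141, 57.554, "synergistic", "<0.001"),
    (24, ("ENR", "OFX", "CLO", "IMI"), 12.401, 54.000, "synergistic", "<0.001"),
    (48, ("CLO", "ENR"), 84.677, 85.997, "additive", "0.736"),
    (48, ("CLO", "OFX"), 62.381, 80.529, "synergistic", "<0.001"),
    (48, ("IMI", "ENR"), 85.054, 78.920, "additive", "0.058"),
    (48, ("IMI", "OFX"), 61.307, 73.453, "synergistic", "<0.001"),
    (48, ("CLO", "IMI"), 43.628, 78.920, "synergistic", "<0.001"),
    (48, ("ENR", "OFX"), 7.138, 82.368, "synergistic", "<0.001"),
    (48, ("CLO", "IMI", "ENR"), 59.566, 78.256, "synergistic", "0.002"),
    (48, ("CLO", "IMI", "OFX"), 28.910, 72.789, "synergistic", "<0.001"),
    (48, ("ENR", "OFX", "CLO"), 56.082, 74.930, "synergistic", "<0.001"),
    (48, ("ENR", "OFX", "IMI"), 50.131, 67.854, "synergistic", "<0.001"),
    (48, ("ENR", "OFX", "CLO", "IMI"), 8.763, 65.051, "synergistic", "<0.001"),
]


def reference_ic50_table() -> pd.DataFrame:
    """Single-exposure IC50 table (one row per compound x exposure time)."""
    return pd.DataFrame(
        _IC50_ROWS,
        columns=["compound", "exposure_h", "ic50_mM", "ci_low_mM", "ci_high_mM", "r2"],
    )


def reference_interaction_table() -> pd.DataFrame:
    """Mixture-interaction table: observed vs effect-summation-predicted viability."""
    df = pd.DataFrame(
        _INTERACTION_ROWS,
        columns=[
            "exposure_h",
            "components",
            "observed_pct",
            "predicted_pct",
            "interaction",
            "p_value",
        ],
    )
    df["mixture"] = df["components"].map("+".join)
    return df[
        ["exposure_h", "mixture", "components", "observed_pct", "predicted_pct",
         "interaction", "p_value"]
    ]


def reference_ic50(compound: str, exposure_h: int = 24) -> float:
    """IC50 (mM) of one compound at one exposure time."""
    for comp, hrs, ic50, *_ in _IC50_ROWS:
        if comp == compound and hrs == exposure_h:
            return ic50
    raise KeyError(f"no reference IC50 for {compound!r} at {exposure_h} h")


def binary_predictions(exposure_h: int = 24) -> dict[frozenset[str], float]:
    """The six two-compound predicted viabilities at one exposure time.

    Keyed by unordered compound pair; the input format expected by
    :func:`mixtox.mixture.reconstruct_singles_from_binaries`.
    """
    out = {
        frozenset(components): predicted
        for hrs, components, _obs, predicted, _lab, _p in _INTERACTION_ROWS
        if hrs == exposure_h and len(components) == 2
    }
    if not out:
        raise KeyError(f"no reference binary mixtures at {exposure_h} h")
    return out


def higher_order_predictions(exposure_h: int = 24) -> dict[tuple[str, ...], float]:
    """Predicted viabilities of the ternary and quaternary mixtures."""
    return {
        components: predicted
        for hrs, components, _obs, predicted, _lab, _p in _INTERACTION_ROWS
        if hrs == exposure_h and len(components) > 2
    }
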