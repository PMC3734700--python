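"""Transition-state-theory selectivity conversions and comparison report.

Under transition-state theory a barrier difference between the two
enantiomer-forming pathways maps to the product enantiomeric excess:

    ddg = R * T * ln[(1 + ee) / (1 - ee)]

with R = 1.98720425e-3 kcal/(mol K).  Signed convention throughout:
``ee_signed`` > 0 and ``ddg`` > 0 mean excess of the S,S product
(C1 attack favored); negative means R,R (C2 attack favored).

``boltzmann_ee`` generalizes the two-state relation to several
transition-state conformers per face by Boltzmann-weighting each
ensemble (Curtin-Hammett); for singleton ensembles it reduces exactly to
``ddg_to_ee``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energetics import BarrierRecord

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "SelectivityRecord",
    "ComparisonRow",
    "ee_to_ddg",
    "ddg_to_ee",
    "boltzmann_ee",
    "selectivity_report",
    "signs_agree",
]

GAS_CONSTANT_KCAL = 1.98720425e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.15  # K


@dataclass(frozen=True)
class SelectivityRecord:
    """One variant's selectivity, either measured or calculated."""

    variant: str
    ee_signed: float
    ddg: float
    temperature: float = DEFAULT_TEMPERATURE
    source: str = "experiment"
    favored_product: str = ""

    def __post_init__(self):
        if not -1.0 < self.ee_signed < 1.0:
            raise ValueError(f"{self.variant}: ee must lie strictly inside (-1, 1)")
        # R,R excess (negative ee) must carry a negative ddg and vice versa
        if self.ee_signed * self.ddg < 0:
            raise ValueError(f"{self.variant}: ee and ddg signs disagree")

    @classmethod
    def from_ee(cls, variant, ee_signed, temperature=DEFAULT_TEMPERATURE, source="experiment"):
        ddg = ee_to_ddg(ee_signed, temperature)
        favored = "SS" if ee_signed > 0 else ("RR" if ee_signed < 0 else "")
        return cls(variant, ee_signed, ddg, temperature, source, favored)

    @classmethod
    def from_ddg(cls, variant, ddg, temperature=DEFAULT_TEMPERATURE, source="experiment"):
        ee = ddg_to_ee(ddg, temperature)
        favored = "SS" if ee > 0 else ("RR" if ee < 0 else "")
        return cls(variant, ee, ddg, temperature, source, favored)


@dataclass(frozen=True)
class ComparisonRow:
    variant: str
    ddE_calc: float
    ddG_expt: float
    agree: bool


def ee_to_ddg(ee_signed: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert signed enantiomeric excess to a barrier difference (kcal/mol).

    Positive ee (S,S excess) gives a positive ddg; R,R excess gives a
    negative one.  Errors outside (-1, 1); warns above |ee| = 0.999 where
    the logarithm explodes.
    """
    if not -1.0 < ee_signed < 1.0:
        raise ValueError(f"ee must lie strictly inside (-1, 1), got {ee_signed}")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if abs(ee_signed) > 0.999:
        warnings.warn(f"|ee| = {abs(ee_signed)} is near 1; converted energy is ill-conditioned")
    return GAS_CONSTANT_KCAL * temperature * math.log((1.0 + ee_signed) / (1.0 - ee_signed))


def ddg_to_ee(ddg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Exact inverse of :func:`ee_to_ddg`; output strictly inside (-1, 1)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    ee = math.tanh(ddg / (2.0 * GAS_CONSTANT_KCAL * temperature))
    # tanh saturates to +/-1.0 in floating point; keep the open interval
    limit = float(np.nextafter(1.0, 0.0))
    return max(-limit, min(limit, ee))


def boltzmann_ee(ts_energies_RR, ts_energies_SS, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Signed ee from Boltzmann-weighted transition-state ensembles.

    Each face's flux is the Boltzmann-weighted sum over its TS conformer
    energies (kcal/mol); ee = (W_SS - W_RR) / (W_SS + W_RR).
    """
    e_rr = np.asarray(list(ts_energies_RR), dtype=float)
    e_ss = np.asarray(list(ts_energies_SS), dtype=float)
    if e_rr.size == 0 or e_ss.size == 0:
        raise ValueError("both transition-state ensembles must be non-empty")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rt = GAS_CONSTANT_KCAL * temperature
    ref = min(e_rr.min(), e_ss.min())  # shift for numerical stability
    w_rr = np.exp(-(e_rr - ref) / rt).sum()
    w_ss = np.exp(-(e_ss - ref) / rt).sum()
    return float((w_ss - w_rr) / (w_ss + w_rr))


def signs_agree(a: float, b: float) -> bool:
    """Same-sign test; an exact zero agrees with anything."""
    if a == 0.0 or b == 0.0:
        return True
    return (a > 0) == (b > 0)


def selectivity_report(
    barrier_records: list[BarrierRecord],
    experimental_records: list[SelectivityRecord],
    temperature: float = DEFAULT_TEMPERATURE,
):
    """Compare calculated barrier differences with experiment.

    Returns ``(table, summary)``: a DataFrame with one row per matched
    variant (calculated ddE, experimental ddG, sign-agreement flag) and a
    plain-text summary counting agreements and naming any unmatched
    variants on either side.
    """
    calc = {r.variant: r for r in barrier_records}
    expt = {r.variant: r for r in experimental_records}
    rows = []
    for variant in calc:
        if variant not in expt:
            continue
        dde = calc[variant].delta_delta
        ddg = expt[variant].ddg
        rows.append(ComparisonRow(variant, dde, ddg, signs_agree(dde, ddg)))
    table = pd.DataFrame(
        [{"variant": r.variant, "ddE_calc": r.ddE_calc, "ddG_expt": r.ddG_expt, "agree": r.agree} for r in rows],
        columns=["variant", "ddE_calc", "ddG_expt", "agree"],
    )
    n_agree = int(table["agree"].sum()) if len(table) else 0
    lines = [
        f"temperature: {temperature} K",
        f"variants compared: {len(table)}",
        f"sign agreements: {n_agree}/{len(table)}",
    ]
    only_calc = sorted(set(calc) - set(expt))
    only_expt = sorted(set(expt) - set(calc))
    if only_calc:
        lines.append("calculated but no experiment: " + ", ".join(only_calc))
    if only_expt:
        lines.append("experiment but not calculated: " + ", ".join(only_expt))
    return table, "\n".join(lines)
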