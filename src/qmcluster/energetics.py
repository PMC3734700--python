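"""Corrected total energies, activation barriers, and barrier differences.

Total energies combine a two-level protocol: the zero-point correction
comes from the optimisation-level result while the electronic energy and
the solvation and dispersion corrections come from the large-basis
single-point result.  The component sources are configurable.

Sign convention for the barrier difference: ``delta_delta_barrier =
barrier(TS_C2) - barrier(TS_C1)``; the C2 attack yields the R,R product,
so a negative value means R,R-favored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .qm import QMResult

__all__ = [
    "StationaryPoint",
    "ReactionProfile",
    "BarrierRecord",
    "total_energy",
    "barrier",
    "delta_delta_barrier",
    "barrier_record",
    "POINT_LABELS",
]

POINT_LABELS = ("ES", "TS_C1", "TS_C2", "product")

#: which result (opt / sp) each energy component is read from
DEFAULT_COMPONENT_SOURCES = {
    "electronic_energy": "sp",
    "zpe": "opt",
    "solvation_correction": "sp",
    "dispersion_correction": "sp",
}


@dataclass
class StationaryPoint:
    """One stationary point with optimisation- and single-point results."""

    label: str
    opt: QMResult
    sp: QMResult

    def __post_init__(self):
        if self.label not in POINT_LABELS:
            raise ValueError(f"unknown stationary-point label {self.label!r}")
        if self.label.startswith("TS"):
            self.opt.validate_as_ts()


@dataclass
class ReactionProfile:
    """All stationary points for one enzyme variant."""

    variant: str
    points: list[StationaryPoint] = field(default_factory=list)
    temperature_note: str = ""

    def __post_init__(self):
        labels = [p.label for p in self.points]
        if labels.count("ES") != 1:
            raise ValueError(f"profile {self.variant}: needs exactly one ES (has {labels.count('ES')})")

    def point(self, label: str) -> StationaryPoint:
        matches = [p for p in self.points if p.label == label]
        if not matches:
            raise KeyError(f"profile {self.variant}: no stationary point {label!r}")
        if len(matches) == 1:
            return matches[0]
        # multiple conformers: Curtin-Hammett, the lowest defines the pathway
        return min(matches, key=total_energy)


@dataclass
class BarrierRecord:
    variant: str
    barrier_C1: float
    barrier_C2: float
    delta_delta: float

    def __post_init__(self):
        if abs(self.delta_delta - (self.barrier_C2 - self.barrier_C1)) > 1e-9:
            raise ValueError(
                f"{self.variant}: delta_delta {self.delta_delta} inconsistent with barriers"
            )


def total_energy(point: StationaryPoint, sources: dict[str, str] | None = None) -> float:
    """Corrected total energy (kcal/mol) of a stationary point."""
    sources = sources or DEFAULT_COMPONENT_SOURCES
    for tag, result in (("opt", point.opt), ("sp", point.sp)):
        if not result.converged:
            raise ValueError(f"unconverged {tag} result for job {result.job_id}")
    total = 0.0
    for component, src in sources.items():
        total += getattr(point.opt if src == "opt" else point.sp, component)
    return total


def barrier(profile: ReactionProfile, ts_label: str, sources=None) -> float:
    """Activation barrier total_energy(TS) - total_energy(ES), kcal/mol."""
    es = profile.point("ES")
    ts = profile.point(ts_label)
    return total_energy(ts, sources) - total_energy(es, sources)


def delta_delta_barrier(profile: ReactionProfile, sources=None) -> float:
    """barrier(TS_C2) - barrier(TS_C1); negative means R,R-favored."""
    return barrier(profile, "TS_C2", sources) - barrier(profile, "TS_C1", sources)


def barrier_record(profile: ReactionProfile, sources=None) -> BarrierRecord:
    b1 = barrier(profile, "TS_C1", sources)
    b2 = barrier(profile, "TS_C2", sources)
    return BarrierRecord(profile.variant, b1, b2, b2 - b1)


def round_report(value: float, decimals: int = 1) -> float:
    """Rounding used in output tables (0.1 kcal/mol report precision)."""
    return round(value, decimals)
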