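"""Bundled demonstration dataset: a seven-variant epoxide-hydrolase
engineering campaign (wild type plus three R,R-selective and three
S,S-selective rounds).

The activation barriers and experimental selectivities here are the
published reference values for this campaign; they serve as inputs for
the lookup-engine demonstration pipeline and for regression tests of the
energy bookkeeping.  All energies kcal/mol.
"""

from __future__ import annotations

from .builder import VariantSpec
from .qm import QMResult, make_job_id
from .selectivity import DEFAULT_TEMPERATURE, SelectivityRecord

__all__ = [
    "VARIANTS",
    "REFERENCE_BARRIERS",
    "EXPERIMENTAL_SELECTIVITY",
    "reference_results",
    "experimental_records",
    "toy_variant_specs",
]

VARIANTS = ("WT", "R1", "R2", "R3", "S1", "S2", "S3")

#: (barrier via TS_C1 [S,S pathway], barrier via TS_C2 [R,R pathway]), kcal/mol
REFERENCE_BARRIERS: dict[str, tuple[float, float]] = {
    "WT": (15.7, 15.6),
    "R1": (14.3, 13.1),
    "R2": (14.0, 13.6),
    "R3": (15.3, 14.3),
    "S1": (14.7, 16.1),
    "S2": (13.9, 17.5),
    "S3": (13.2, 16.6),
}

#: experimental selectivity: ("ee", signed fraction) where the measured ee
#: is published directly, ("ddg", kcal/mol) where only the converted
#: energy difference is available.  Negative = R,R excess.
EXPERIMENTAL_SELECTIVITY: dict[str, tuple[str, float]] = {
    "WT": ("ee", -0.14),
    "R1": ("ee", -0.66),
    "R2": ("ee", -0.73),
    "R3": ("ddg", -1.3),
    "S1": ("ddg", +1.0),
    "S2": ("ee", +0.91),
    "S3": ("ee", +0.93),
}


def reference_results(variants=VARIANTS, level: str = "table") -> list[QMResult]:
    """Synthesize a per-point energy-component table whose assembled
    barriers equal :data:`REFERENCE_BARRIERS`.

    The split over components (electronic / ZPE / solvation / dispersion)
    is arbitrary but fixed, so component bookkeeping is exercised while
    the assembled barriers land on the reference values exactly.
    """
    records = []
    for idx, variant in enumerate(variants):
        b1, b2 = REFERENCE_BARRIERS[variant]
        es = {
            "electronic_energy": -(20.0 + idx),
            "zpe": 1.25,
            "solvation_correction": -0.75,
            "dispersion_correction": -0.50,
        }
        records.append(
            QMResult(
                job_id=make_job_id(variant, "ES", "minimize", level),
                converged=True,
                imaginary_mode_count=0,
                **es,
            )
        )
        for label, barrier_value in (("TS_C1", b1), ("TS_C2", b2)):
            records.append(
                QMResult(
                    job_id=make_job_id(variant, label, "saddle-search", level),
                    electronic_energy=es["electronic_energy"] + barrier_value + 0.8,
                    zpe=es["zpe"] - 0.3,
                    solvation_correction=es["solvation_correction"] - 0.2,
                    dispersion_correction=es["dispersion_correction"] - 0.3,
                    converged=True,
                    imaginary_mode_count=1,
                )
            )
    return records


def experimental_records(temperature: float = DEFAULT_TEMPERATURE) -> list[SelectivityRecord]:
    out = []
    for variant, (kind, value) in EXPERIMENTAL_SELECTIVITY.items():
        if kind == "ee":
            out.append(SelectivityRecord.from_ee(variant, value, temperature))
        else:
            out.append(SelectivityRecord.from_ddg(variant, value, temperature))
    return out


def toy_variant_specs() -> list[VariantSpec]:
    """Variant ladder mapped onto the toy site's mutable pocket residues.

    Mirrors the campaign's structure (two branches, one to three rounds,
    cumulative mutations) at toy-site numbering.
    """
    r1 = ["A:5:LEU>ILE", "A:6:ILE>CYS"]
    r2 = r1 + ["A:7:MET>CYS"]
    r3 = r2 + ["A:4:ASN>SER"]
    s1 = ["A:5:LEU>CYS", "A:6:ILE>VAL"]
    s2 = s1 + ["A:7:MET>PHE"]
    s3 = s2 + ["A:4:ASN>SER"]
    return [
        VariantSpec.parse("R1", r1),
        VariantSpec.parse("R2", r2),
        VariantSpec.parse("R3", r3),
        VariantSpec.parse("S1", s1),
        VariantSpec.parse("S2", s2),
        VariantSpec.parse("S3", s3),
    ]
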