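"""Synthetic toy active site: a desk-scale stand-in for a real crystal
structure.

The generated site mimics the catalytic architecture the workflow is
built for: an epoxide-like ligand (five-membered carbocycle bridged by an
oxygen on C1/C2), an acidic carboxylate hydrogen-bond-distanced to the
epoxide oxygen, a second carboxylate poised to activate a nucleophilic
water, two polar water-positioning residues, and a shell of hydrophobic
pocket residues.  Heavy atoms only; hydrogens are added downstream.

The generator is deterministic for a given parameter set (byte-identical
PDB output) and returns a ground-truth manifest with atom counts and
probe atom serials.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .structure import Atom, Residue, Structure
from .templates import TEMPLATES

__all__ = ["ToySiteParams", "generate_toy_site", "POCKET_CYCLE"]

POCKET_CYCLE = ("LEU", "ILE", "MET", "VAL", "PHE")

LIGAND_KEY = ("A", 201, "")
WATER_KEY = ("A", 101, "")


@dataclass(frozen=True)
class ToySiteParams:
    seed: int = 1
    n_pocket_residues: int = 3
    pocket_radius: float = 6.0
    ligand: str = "EPX"
    noise: float = 0.05


def _rotation_between(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector v onto unit vector u."""
    v = v / np.linalg.norm(v)
    u = u / np.linalg.norm(u)
    c = float(np.dot(v, u))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees about any axis perpendicular to v
        axis = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(v, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, math.pi)
    axis = np.cross(v, u)
    s = np.linalg.norm(axis)
    axis = axis / s
    return _axis_rotation(axis, math.atan2(s, c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)


def _place_residue(name, key, contact_atom, target, outward, spin, noise, rng):
    """Instantiate a template so `contact_atom` lands exactly on `target`
    with the backbone oriented along `outward`; jitter the other atoms."""
    tpl = TEMPLATES[name]
    contact = tpl.coords[contact_atom]
    v = tpl.coords["CA"] - contact
    R = _axis_rotation(outward / np.linalg.norm(outward), spin) @ _rotation_between(v, outward)
    atoms = []
    for i, (aname, pos) in enumerate(tpl.coords.items(), start=1):
        placed = R @ (pos - contact) + target
        if aname != contact_atom and noise > 0:
            placed = placed + rng.normal(0.0, noise, size=3)
        elem = "S" if aname.startswith("S") else aname[0]
        atoms.append(Atom(serial=i, name=aname, element=elem, position=placed, residue_key=key))
    return Residue(name, key, atoms)


def generate_toy_site(params: ToySiteParams):
    """Build the toy site; returns ``(Structure, manifest)``."""
    rng = np.random.default_rng(params.seed)
    if params.ligand != "EPX":
        raise ValueError(f"unknown ligand type {params.ligand!r}")

    lig_tpl = TEMPLATES["EPX"]
    lig_atoms = []
    for i, (aname, pos) in enumerate(lig_tpl.coords.items(), start=1):
        lig_atoms.append(
            Atom(serial=i, name=aname, element=aname[0], position=pos.copy(), residue_key=LIGAND_KEY)
        )
    ligand = Residue("EPX", LIGAND_KEY, lig_atoms)

    epo = lig_tpl.coords["O"]
    c1 = lig_tpl.coords["C1"]
    c2 = lig_tpl.coords["C2"]
    mid = 0.5 * (c1 + c2)

    # nucleophilic water: backside of C2 relative to the epoxide oxygen
    attack_dir = c2 - epo
    attack_dir /= np.linalg.norm(attack_dir)
    water_pos = c2 + 3.0 * attack_dir
    water = Residue(
        "HOH", WATER_KEY, [Atom(1, "O", "O", water_pos.copy(), residue_key=WATER_KEY)]
    )

    out_w = attack_dir
    p1 = np.cross(out_w, [0.0, 0.0, 1.0])
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(out_w, p1)

    def unit(v):
        return v / np.linalg.norm(v)

    targets = [
        # acid carboxylate donates to the epoxide oxygen
        ("ASP", ("A", 1, ""), "OD1", epo + 2.70 * unit(epo - mid)),
        # base carboxylate activates the water (within H-bond distance)
        ("ASP", ("A", 2, ""), "OD1", water_pos + 2.80 * out_w),
        # water-positioning residues
        ("TYR", ("A", 3, ""), "OH", water_pos + 2.80 * unit(0.3 * out_w + p1)),
        ("ASN", ("A", 4, ""), "ND2", water_pos + 3.00 * unit(0.3 * out_w - p1 + 0.6 * p2)),
    ]
    for i in range(params.n_pocket_residues):
        name = POCKET_CYCLE[i % len(POCKET_CYCLE)]
        theta = 2.0 * math.pi * i / max(params.n_pocket_residues, 1) + 0.7
        pos = params.pocket_radius * np.array(
            [math.cos(theta), math.sin(theta), 0.25 * (-1) ** i]
        )
        targets.append((name, ("A", 5 + i, ""), "CB", pos))

    residues = []
    for name, key, contact, target in targets:
        outward = unit(np.asarray(target, float))
        spin = float(rng.uniform(0.0, 2.0 * math.pi))
        residues.append(
            _place_residue(name, key, contact, np.asarray(target, float), outward, spin, params.noise, rng)
        )

    structure = Structure(
        residues=residues, ligands=[water, ligand], title=f"toy active site seed={params.seed}"
    )
    structure.renumber()
    structure.validate()

    by = {(r.key, a.name): a.serial for r in structure.all_residues() for a in r.atoms}
    manifest = {
        "params": asdict(params),
        "n_atoms": structure.n_atoms,
        "residues": [
            {"key": f"{r.key[0]}:{r.key[1]}", "name": r.name, "n_atoms": len(r.atoms)}
            for r in structure.all_residues()
        ],
        "probes": {
            "water_O": by[(WATER_KEY, "O")],
            "ligand_C1": by[(LIGAND_KEY, "C1")],
            "ligand_C2": by[(LIGAND_KEY, "C2")],
            "epoxide_O": by[(LIGAND_KEY, "O")],
            "base_OD1": by[(("A", 2, ""), "OD1")],
        },
        "distances": {
            "water_to_base_OD1": float(
                np.linalg.norm(water_pos - structure.residue(("A", 2, "")).atom("OD1").position)
            ),
            "water_to_C2": 3.0,
        },
    }
    return structure, manifest
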