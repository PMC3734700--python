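"""Construction of truncated, capped, coordinate-locked cluster models.

A :class:`ClusterRecipe` names the residues to keep, where to cut them,
and which atoms to lock; :func:`build_cluster` carves that model out of a
full structure, replaces each severed bond with a link hydrogen, and
freezes the truncation points so downstream geometry optimisation
preserves the crystal-frame shape of the site.  :func:`mutate_residue`
and :func:`apply_variant` derive mutant models by template side-chain
replacement on the otherwise untouched parent model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import dihedral
from .structure import (
    CAP_NAME_PREFIX,
    Atom,
    Residue,
    ResidueKey,
    Structure,
    format_residue_key,
)
from .templates import TEMPLATES, TITRATABLE, chi1_atom, nerf_place

__all__ = [
    "TruncationRule",
    "ClusterRecipe",
    "ClusterModel",
    "VariantSpec",
    "build_cluster",
    "place_cap_hydrogen",
    "add_hydrogens",
    "mutate_residue",
    "apply_variant",
    "CAP_BOND_LENGTHS",
]

#: link-hydrogen bond length by the element of the kept (attachment) atom, Angstrom
CAP_BOND_LENGTHS = {"C": 1.10, "N": 1.01, "O": 0.96, "S": 1.34}

_SCHEMES = ("alpha-cut", "beta-cut", "backbone-keep")


@dataclass(frozen=True)
class TruncationRule:
    """One severed bond: keep ``cut_bond[0]``, discard everything on the
    ``cut_bond[1]`` side, place one cap hydrogen along the old bond."""

    residue_key: ResidueKey
    cut_bond: tuple[str, str]
    scheme: str = "alpha-cut"

    def __post_init__(self):
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown truncation scheme {self.scheme!r}")


@dataclass
class ClusterRecipe:
    """Everything needed to carve a cluster model out of a structure."""

    include: list[ResidueKey]
    truncations: list[TruncationRule] = field(default_factory=list)
    ligand_key: ResidueKey | None = None
    charge: int = 0
    multiplicity: int = 1
    #: explicit locked atoms as (residue key, atom name); None means the
    #: default policy (caps + their attachment atoms)
    frozen_atoms: list[tuple[ResidueKey, str]] | None = None
    #: residue key -> protonation state tag for titratable residues
    protonation: dict[ResidueKey, str] = field(default_factory=dict)

    def __post_init__(self):
        included = set(self.include)
        if self.ligand_key is not None:
            included.add(self.ligand_key)
        for rule in self.truncations:
            if rule.residue_key not in included:
                raise ValueError(
                    f"truncation rule targets {format_residue_key(rule.residue_key)} "
                    "which is not an included residue"
                )


@dataclass
class ClusterModel:
    """A carved cluster model plus its provenance."""

    structure: Structure
    recipe: ClusterRecipe
    variant_label: str = "WT"
    report: dict = field(default_factory=dict)

    @property
    def cap_atoms(self) -> list[Atom]:
        return [a for a in self.structure.atoms() if a.is_cap]

    @property
    def frozen_atoms(self) -> list[Atom]:
        return [a for a in self.structure.atoms() if a.is_frozen]

    def validate(self) -> None:
        for a in self.cap_atoms:
            if not a.is_frozen:
                raise ValueError(f"cap atom {a.name} is not frozen")
        self.structure.validate()

    def copy(self) -> "ClusterModel":
        return ClusterModel(self.structure.copy(), self.recipe, self.variant_label, dict(self.report))


@dataclass(frozen=True)
class VariantSpec:
    """A named set of point mutations, e.g. a directed-evolution round."""

    name: str
    mutations: tuple = ()

    @staticmethod
    def parse(name: str, items: list[str]) -> "VariantSpec":
        """Parse mutations written as ``"A:5:LEU>ILE"``."""
        from .structure import parse_residue_key

        muts = []
        for item in items:
            loc, _, change = item.rpartition(":")
            src, _, dst = change.partition(">")
            if not (loc and src and dst):
                raise ValueError(f"cannot parse mutation {item!r}")
            muts.append((parse_residue_key(loc), src.upper(), dst.upper()))
        return VariantSpec(name, tuple(muts))


# ---------------------------------------------------------------------------
# bond perception (distance based; adequate for idealized template geometry)


def _bond_cutoff(e1: str, e2: str) -> float:
    if "H" in (e1, e2):
        return 1.25
    if "S" in (e1, e2):
        return 1.95
    return 1.75


def residue_bonds(res: Residue) -> list[tuple[str, str]]:
    pairs = []
    for i, a in enumerate(res.atoms):
        for b in res.atoms[i + 1 :]:
            d = float(np.linalg.norm(a.position - b.position))
            if d < _bond_cutoff(a.element.upper(), b.element.upper()):
                pairs.append((a.name, b.name))
    return pairs


def _neighbors(res: Residue) -> dict[str, list[str]]:
    nb: dict[str, list[str]] = {a.name: [] for a in res.atoms}
    for a, b in residue_bonds(res):
        nb[a].append(b)
        nb[b].append(a)
    return nb


# ---------------------------------------------------------------------------
# truncation


def place_cap_hydrogen(kept: Atom, removed: Atom, bond_length: float | None = None) -> Atom:
    """Construct the link hydrogen replacing the ``kept -> removed`` bond.

    The cap sits on the severed bond vector at ``bond_length`` from the
    kept atom (defaulting per the kept atom's element) and is born both
    ``is_cap`` and ``is_frozen``.
    """
    if bond_length is None:
        bond_length = CAP_BOND_LENGTHS.get(kept.element.upper(), 1.10)
    vec = removed.position - kept.position
    norm = float(np.linalg.norm(vec))
    if norm < 1e-8:
        raise ValueError(
            f"cannot place cap: atoms {kept.name} and {removed.name} are coincident"
        )
    pos = kept.position + bond_length * vec / norm
    return Atom(
        serial=0,
        name=CAP_NAME_PREFIX,
        element="H",
        position=pos,
        residue_key=kept.residue_key,
        is_frozen=True,
        is_cap=True,
    )


def _truncate_residue(res: Residue, rule: TruncationRule, cap_index: int) -> Residue:
    kept_name, removed_name = rule.cut_bond
    if not res.has_atom(kept_name) or not res.has_atom(removed_name):
        missing = [n for n in rule.cut_bond if not res.has_atom(n)]
        raise ValueError(
            f"truncation of {format_residue_key(res.key)}: cut-bond atoms {missing} absent"
        )
    kept = res.atom(kept_name)
    removed = res.atom(removed_name)
    d = float(np.linalg.norm(kept.position - removed.position))
    if d >= 2.0:
        raise ValueError(
            f"cut bond {kept_name}-{removed_name} in {format_residue_key(res.key)} "
            f"spans {d:.2f} A; not a plausible bond"
        )
    # atoms reachable from `removed` without passing through `kept` go away
    nb = _neighbors(res)
    doomed = {removed_name}
    stack = [removed_name]
    while stack:
        for nxt in nb[stack.pop()]:
            if nxt != kept_name and nxt not in doomed:
                doomed.add(nxt)
                stack.append(nxt)
    cap = place_cap_hydrogen(kept, removed)
    cap = replace(cap, name=f"{CAP_NAME_PREFIX}{cap_index}", position=cap.position.copy())
    survivors = [a for a in res.atoms if a.name not in doomed]
    return Residue(res.name, res.key, survivors + [cap])


def build_cluster(structure: Structure, recipe: ClusterRecipe) -> ClusterModel:
    """Carve a capped, coordinate-locked cluster model out of ``structure``.

    Only the recipe's residues (plus the ligand) are retained; each
    truncation rule removes the discarded side of its cut bond and adds
    exactly one cap hydrogen.  Cap atoms are always frozen; by default
    their attachment atoms are too, unless the recipe lists an explicit
    frozen set.
    """
    wanted = list(recipe.include)
    if recipe.ligand_key is not None and recipe.ligand_key not in wanted:
        wanted.append(recipe.ligand_key)
    missing = [k for k in wanted if not structure.has_residue(k)]
    if missing:
        raise ValueError(
            "recipe names residues absent from the structure: "
            + ", ".join(format_residue_key(k) for k in missing)
        )

    rules_by_key: dict[ResidueKey, list[TruncationRule]] = {}
    for rule in recipe.truncations:
        rules_by_key.setdefault(rule.residue_key, []).append(rule)

    ligand_keys = {r.key for r in structure.ligands}
    out = Structure(title=f"cluster model ({len(wanted)} residues)")
    cap_index = 0
    attachments: list[tuple[ResidueKey, str]] = []
    for key in wanted:
        res = structure.residue(key).copy()
        for rule in rules_by_key.get(key, []):
            cap_index += 1
            res = _truncate_residue(res, rule, cap_index)
            attachments.append((key, rule.cut_bond[0]))
        (out.ligands if key in ligand_keys else out.residues).append(res)

    # locking policy
    if recipe.frozen_atoms is None:
        lock = set(attachments)
    else:
        lock = set(recipe.frozen_atoms)
    for res in out.all_residues():
        for a in res.atoms:
            if a.is_cap or (res.key, a.name) in lock:
                a.is_frozen = True
    out.renumber()

    model = ClusterModel(
        structure=out,
        recipe=recipe,
        variant_label="WT",
        report={
            "atom_count": out.n_atoms,
            "n_caps": cap_index,
            "frozen": [(format_residue_key(a.residue_key), a.name) for a in out.atoms() if a.is_frozen],
            "warnings": [],
        },
    )
    model.validate()
    if cap_index != len(recipe.truncations):
        raise AssertionError("cap count does not match truncation-rule count")
    return model


# ---------------------------------------------------------------------------
# hydrogen addition


def _h_directions(pos, nb_units, n_add, geom, second_shell):
    """Unit vectors for hydrogens completing the coordination of an atom."""
    k = len(nb_units)
    if k == 0:
        # free atom (water oxygen): deterministic global-frame placement
        ang = math.radians(104.5 if geom == "sp3" else 120.0)
        base = np.array([1.0, 0.0, 0.0])
        dirs = [base]
        for i in range(1, n_add):
            c, s = math.cos(i * ang), math.sin(i * ang)
            dirs.append(np.array([c, s, 0.0]))
        return dirs[:n_add]
    if k == 1:
        u = nb_units[0]
        theta = 109.47 if geom == "sp3" else 120.0
        if second_shell is not None:
            ref = second_shell
        else:
            ref = pos + _any_perpendicular(u)
        nb_pos = pos + u
        phis = [180.0, 60.0, -60.0] if geom == "sp3" else [0.0, 180.0]
        return [
            (nerf_place(ref, nb_pos, pos, 1.0, theta, phi) - pos) for phi in phis[:n_add]
        ]
    if k == 2:
        u1, u2 = nb_units
        bis = -(u1 + u2)
        bn = np.linalg.norm(bis)
        bis = bis / bn if bn > 1e-8 else _any_perpendicular(u1)
        if geom == "sp2" or n_add == 1 and geom == "sp2":
            return [bis]
        perp = np.cross(u1, u2)
        pn = np.linalg.norm(perp)
        perp = perp / pn if pn > 1e-8 else _any_perpendicular(bis)
        w = math.radians(54.25)  # half the H-X-H tetrahedral-ish angle
        dirs = [math.cos(w) * bis + math.sin(w) * perp, math.cos(w) * bis - math.sin(w) * perp]
        return [d / np.linalg.norm(d) for d in dirs[:n_add]]
    # k >= 3: single hydrogen opposite the neighbor centroid
    s = -sum(nb_units)
    n = np.linalg.norm(s)
    s = s / n if n > 1e-8 else _any_perpendicular(nb_units[0])
    return [s]


def _any_perpendicular(u):
    trial = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(u, trial)
    return p / np.linalg.norm(p)


_H_BOND_LENGTH = {"C": 1.090, "N": 1.010, "O": 0.960, "S": 1.340}


def add_hydrogens(model: ClusterModel, protonation: dict[ResidueKey, str] | None = None) -> ClusterModel:
    """Template-based hydrogen completion.

    Every titratable residue in the model (Asp/Glu/His/Tyr/Cys/Arg/Lys)
    must have a declared protonation state; there is no silent default.
    Atoms that already carry their full hydrogen complement are left
    untouched, so the operation is idempotent.  Added hydrogens are never
    frozen unless they sit on a frozen cap-attachment atom.
    """
    protonation = dict(protonation or {})
    out = model.copy()
    missing_state = []
    unknown = []
    for res in out.structure.all_residues():
        if res.name not in TEMPLATES:
            unknown.append(f"{res.name} {format_residue_key(res.key)}")
            continue
        if res.name in TITRATABLE and res.key not in protonation:
            missing_state.append(f"{res.name} {format_residue_key(res.key)}")
    if unknown:
        raise ValueError("no hydrogen template for residue(s): " + ", ".join(unknown))
    if missing_state:
        raise ValueError(
            "protonation state not declared for titratable residue(s): "
            + ", ".join(missing_state)
        )

    serial = max((a.serial for a in out.structure.atoms()), default=0)
    for res in out.structure.all_residues():
        # states declared for keys holding non-titratable residues are ignored
        state = protonation.get(res.key) if res.name in TITRATABLE else None
        table = TEMPLATES[res.name].hydrogen_table(state)
        nb = _neighbors(res)
        new_atoms: list[Atom] = []
        for atom in res.atoms:
            if atom.element.upper() == "H":
                continue
            n_target, geom = table.get(atom.name, (0, "sp3"))
            bonded = [res.atom(n) for n in nb[atom.name]]
            # caps replace a severed heavy neighbor, not a template hydrogen
            n_existing_h = sum(1 for b in bonded if b.element.upper() == "H" and not b.is_cap)
            n_add = n_target - n_existing_h
            if n_add <= 0:
                continue
            heavies = [b for b in bonded if b.element.upper() != "H"]
            nb_units = []
            for b in bonded:
                v = b.position - atom.position
                nb_units.append(v / np.linalg.norm(v))
            second_shell = None
            if heavies:
                ref_names = [n for n in nb[heavies[0].name] if n != atom.name]
                if ref_names:
                    second_shell = res.atom(ref_names[0]).position
            length = _H_BOND_LENGTH.get(atom.element.upper(), 1.09)
            has_cap_neighbor = any(b.is_cap for b in bonded)
            for i, direction in enumerate(
                _h_directions(atom.position, nb_units, n_add, geom, second_shell), start=1
            ):
                serial += 1
                suffix = atom.name[1:] if len(atom.name) > 1 else ""
                name = f"H{suffix}{n_existing_h + i}"
                while res.has_atom(name) or any(a.name == name for a in new_atoms):
                    name += "'"
                new_atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element="H",
                        position=atom.position + length * np.asarray(direction),
                        residue_key=res.key,
                        is_frozen=atom.is_frozen and has_cap_neighbor,
                    )
                )
        res.atoms.extend(new_atoms)
    out.structure.renumber()
    out.report = dict(out.report)
    out.report["atom_count"] = out.structure.n_atoms
    return out


# ---------------------------------------------------------------------------
# mutation

_BACKBONE = ("N", "CA", "C", "O")


def mutate_residue(model: ClusterModel, mutation, templates=None) -> ClusterModel:
    """Apply one point mutation by template side-chain replacement.

    Backbone and C-beta positions of the parent are preserved exactly;
    the replacement side chain is taken from the idealized template,
    superposed on the parent's N/CA/CB attachment frame, and rotated
    about CA-CB so the parent's chi1 is inherited where both residue
    types define one.  Hydrogens belonging to the replaced side chain are
    discarded (rerun :func:`add_hydrogens` afterwards).  A new atom closer
    than 1.0 A to any retained atom raises a clash warning in the report,
    not an error — downstream optimisation is expected to relax it.
    """
    templates = templates or TEMPLATES
    key, src, dst = mutation
    src, dst = src.upper(), dst.upper()
    out = model.copy()
    res = out.structure.residue(key)
    if res.name != src:
        raise ValueError(
            f"mutation {src}->{dst} at {format_residue_key(key)}: residue is {res.name}"
        )
    if src == dst:
        return out
    if dst not in templates:
        raise ValueError(f"no side-chain template for {dst}")
    tpl = templates[dst]

    keep = set(_BACKBONE)
    if res.has_atom("CB") and "CB" in tpl.coords:
        keep.add("CB")
    keep.update(a.name for a in res.atoms if a.is_cap)

    frame = ("N", "CA", "CB") if "CB" in keep else ("N", "CA", "C")
    for n in frame:
        if not res.has_atom(n):
            raise ValueError(
                f"cannot mutate {format_residue_key(key)}: frame atom {n} missing"
            )
        if n not in tpl.coords:
            raise ValueError(f"template {dst} lacks frame atom {n}")

    # drop old side chain + every hydrogen not attached to a kept heavy atom
    nb = _neighbors(res)
    kept_atoms = []
    for a in res.atoms:
        if a.element.upper() == "H" and not a.is_cap:
            parents = [n for n in nb[a.name] if res.atom(n).element.upper() != "H"]
            if parents and parents[0] in keep and parents[0] in _BACKBONE:
                kept_atoms.append(a)
        elif a.name in keep:
            kept_atoms.append(a)

    # rigid transform template -> parent frame
    from .geometry import superpose

    P = np.array([tpl.coords[n] for n in frame])
    Q = np.array([res.atom(n).position for n in frame])
    R, t, _ = superpose(P, Q)

    new_names = [
        n for n in tpl.coords if n not in _BACKBONE and not (n == "CB" and "CB" in keep)
    ]
    placed = {n: R @ tpl.coords[n] + t for n in new_names}

    # inherit chi1 from the parent where both side chains define it
    g_src, g_dst = chi1_atom(src), chi1_atom(dst)
    if g_src and g_dst and "CB" in keep and res.has_atom(g_src) and g_dst in placed:
        n_pos = res.atom("N").position
        ca = res.atom("CA").position
        cb = res.atom("CB").position
        chi_parent = dihedral(n_pos, ca, cb, res.atom(g_src).position)
        chi_now = dihedral(n_pos, ca, cb, placed[g_dst])
        axis = cb - ca
        axis = axis / np.linalg.norm(axis)
        ang = -math.radians(chi_parent - chi_now)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        rot = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
        placed = {n: rot @ (p - cb) + cb for n, p in placed.items()}

    serial = max(a.serial for a in out.structure.atoms())
    clash_warnings = []
    retained_positions = [
        (a, r.key) for r in out.structure.all_residues() for a in r.atoms
        if not (r.key == key and a not in kept_atoms)
    ]
    new_atoms = []
    for n in sorted(placed, key=lambda x: list(tpl.coords).index(x)):
        serial += 1
        elem = "S" if n.startswith("S") else n[0]
        atom = Atom(serial, n, elem, placed[n], residue_key=key)
        for other, okey in retained_positions:
            if okey == key and other.name in frame:
                continue
            if float(np.linalg.norm(atom.position - other.position)) < 1.0:
                clash_warnings.append(
                    f"{dst} {format_residue_key(key)}: new atom {n} within 1.0 A of "
                    f"{other.name} {format_residue_key(okey)}"
                )
        new_atoms.append(atom)

    pool = out.structure.residues
    if not any(r.key == key for r in pool):
        pool = out.structure.ligands
    i = next(i for i, r in enumerate(pool) if r.key == key)
    pool[i] = Residue(dst, key, kept_atoms + new_atoms)

    out.structure.renumber()
    out.report = dict(out.report)
    out.report.setdefault("warnings", [])
    for w in clash_warnings:
        warnings.warn(w)
        out.report["warnings"] = list(out.report["warnings"]) + [w]
    out.report["atom_count"] = out.structure.n_atoms
    return out


def apply_variant(model: ClusterModel, variant: VariantSpec, templates=None) -> ClusterModel:
    """Apply a variant's mutations in order and relabel the model."""
    out = model.copy()
    for mutation in variant.mutations:
        out = mutate_residue(out, mutation, templates)
    out.variant_label = variant.name
    return out
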