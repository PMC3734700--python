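"""Idealized residue templates built from internal coordinates.

Each supported residue type carries:

* heavy-atom coordinates generated once from a z-matrix (bond length /
  bond angle / dihedral, NeRF placement), in a local frame with the
  backbone nitrogen at the origin;
* the number and geometry class (sp3/sp2) of hydrogens expected on each
  heavy atom, with per-protonation-state overrides for titratable
  residues.

The templates cover the 18 standard amino acids needed by the workflow
(all but Pro/Trp), water, and the epoxide-like toy substrate ``EPX``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResidueTemplate",
    "TEMPLATES",
    "TITRATABLE",
    "nerf_place",
    "chi1_atom",
    "expected_hydrogen_count",
]


def nerf_place(a, b, c, r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Place atom d bonded to c with |cd| = r, angle(b,c,d) = theta and
    dihedral(a,b,c,d) = phi (natural extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("nerf_place: reference atoms are collinear")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(phi), r * math.sin(theta) * math.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class ResidueTemplate:
    name: str
    coords: dict[str, np.ndarray]
    #: atom -> (n hydrogens, "sp3" | "sp2") in the default protonation state
    hydrogens: dict[str, tuple[int, str]]
    #: state tag -> {atom: (n, geom)} overrides
    states: dict[str, dict[str, tuple[int, str]]] = field(default_factory=dict)
    default_state: str = ""

    @property
    def heavy_atoms(self) -> list[str]:
        return list(self.coords)

    def hydrogen_table(self, state: str | None = None) -> dict[str, tuple[int, str]]:
        table = dict(self.hydrogens)
        tag = state if state is not None else self.default_state
        if tag:
            if tag not in self.states:
                raise ValueError(f"{self.name}: unknown protonation state {tag!r}")
            table.update(self.states[tag])
        return table


# --- backbone scaffold (shared by all amino-acid templates) -----------------

_N = np.array([0.0, 0.0, 0.0])
_CA = np.array([1.458, 0.0, 0.0])
_C = _CA + 1.525 * np.array([math.cos(math.radians(69.0)), math.sin(math.radians(69.0)), 0.0])


def _backbone() -> dict[str, np.ndarray]:
    coords = {"N": _N.copy(), "CA": _CA.copy(), "C": _C.copy()}
    coords["O"] = nerf_place(coords["N"], coords["CA"], coords["C"], 1.231, 120.5, -45.0)
    return coords


def _with_cb(coords: dict[str, np.ndarray]) -> None:
    # improper C-N-CA-CB dihedral of +122.6 deg gives the L configuration
    coords["CB"] = nerf_place(coords["C"], coords["N"], coords["CA"], 1.530, 110.5, 122.6)


def _side(coords, name, a, b, c, r, theta, phi):
    coords[name] = nerf_place(coords[a], coords[b], coords[c], r, theta, phi)


CHI1 = -60.0  # default rotamer for template side chains


def _build_amino(name: str, builder, hydrogens, states=None, default_state="") -> ResidueTemplate:
    coords = _backbone()
    if name != "GLY":
        _with_cb(coords)
    if builder is not None:
        builder(coords)
    base = {"N": (1, "sp3"), "CA": (1 if name != "GLY" else 2, "sp3"), "C": (0, "sp2"), "O": (0, "sp2")}
    if name != "GLY":
        base["CB"] = (2, "sp3")
    base.update(hydrogens)
    return ResidueTemplate(name, coords, base, states or {}, default_state)


def _ring6(coords, stem, names, r=1.39):
    """Attach a planar six-ring: stem-CG already placed; names = CD1..CZ."""
    cd1, cd2, ce1, ce2, cz = names
    _side(coords, cd1, "CA", "CB", "CG", r, 120.8, 90.0)
    _side(coords, cd2, "CA", "CB", "CG", r, 120.8, -90.0)
    _side(coords, ce1, "CB", "CG", cd1, r, 120.0, 180.0)
    _side(coords, ce2, "CB", "CG", cd2, r, 120.0, 180.0)
    _side(coords, cz, "CG", cd1, ce1, r, 120.0, 0.0)


def _make_templates() -> dict[str, ResidueTemplate]:
    t: dict[str, ResidueTemplate] = {}

    t["GLY"] = _build_amino("GLY", None, {})
    t["ALA"] = _build_amino("ALA", None, {"CB": (3, "sp3")})

    def ser(c):
        _side(c, "OG", "N", "CA", "CB", 1.417, 110.8, CHI1)

    t["SER"] = _build_amino("SER", ser, {"OG": (1, "sp3")})

    def thr(c):
        _side(c, "OG1", "N", "CA", "CB", 1.433, 109.6, CHI1)
        _side(c, "CG2", "N", "CA", "CB", 1.521, 110.5, CHI1 + 122.0)

    t["THR"] = _build_amino("THR", thr, {"CB": (1, "sp3"), "OG1": (1, "sp3"), "CG2": (3, "sp3")})

    def cys(c):
        _side(c, "SG", "N", "CA", "CB", 1.808, 114.4, CHI1)

    t["CYS"] = _build_amino(
        "CYS",
        cys,
        {"SG": (1, "sp3")},
        states={"neutral": {}, "anionic": {"SG": (0, "sp3")}},
        default_state="neutral",
    )

    def val(c):
        _side(c, "CG1", "N", "CA", "CB", 1.521, 110.5, CHI1)
        _side(c, "CG2", "N", "CA", "CB", 1.521, 110.5, CHI1 + 122.0)

    t["VAL"] = _build_amino("VAL", val, {"CB": (1, "sp3"), "CG1": (3, "sp3"), "CG2": (3, "sp3")})

    def leu(c):
        _side(c, "CG", "N", "CA", "CB", 1.530, 116.3, CHI1)
        _side(c, "CD1", "CA", "CB", "CG", 1.521, 110.7, 180.0)
        _side(c, "CD2", "CA", "CB", "CG", 1.521, 110.7, 60.0)

    t["LEU"] = _build_amino(
        "LEU", leu, {"CG": (1, "sp3"), "CD1": (3, "sp3"), "CD2": (3, "sp3")}
    )

    def ile(c):
        _side(c, "CG1", "N", "CA", "CB", 1.530, 110.4, CHI1)
        _side(c, "CG2", "N", "CA", "CB", 1.521, 110.5, CHI1 + 122.0)
        _side(c, "CD1", "CA", "CB", "CG1", 1.513, 113.8, 170.0)

    t["ILE"] = _build_amino(
        "ILE", ile, {"CB": (1, "sp3"), "CG1": (2, "sp3"), "CG2": (3, "sp3"), "CD1": (3, "sp3")}
    )

    def met(c):
        _side(c, "CG", "N", "CA", "CB", 1.520, 114.1, CHI1)
        _side(c, "SD", "CA", "CB", "CG", 1.803, 112.7, 180.0)
        _side(c, "CE", "CB", "CG", "SD", 1.791, 100.6, 180.0)

    t["MET"] = _build_amino("MET", met, {"CG": (2, "sp3"), "SD": (0, "sp3"), "CE": (3, "sp3")})

    def phe(c):
        _side(c, "CG", "N", "CA", "CB", 1.502, 113.8, CHI1)
        _ring6(c, "CG", ["CD1", "CD2", "CE1", "CE2", "CZ"])

    t["PHE"] = _build_amino(
        "PHE",
        phe,
        {"CG": (0, "sp2"), "CD1": (1, "sp2"), "CD2": (1, "sp2"), "CE1": (1, "sp2"), "CE2": (1, "sp2"), "CZ": (1, "sp2")},
    )

    def tyr(c):
        phe(c)
        _side(c, "OH", "CD1", "CE1", "CZ", 1.376, 119.9, 180.0)

    t["TYR"] = _build_amino(
        "TYR",
        tyr,
        {"CG": (0, "sp2"), "CD1": (1, "sp2"), "CD2": (1, "sp2"), "CE1": (1, "sp2"), "CE2": (1, "sp2"), "CZ": (0, "sp2"), "OH": (1, "sp3")},
        states={"neutral": {}, "anionic": {"OH": (0, "sp3")}},
        default_state="neutral",
    )

    def asp(c):
        _side(c, "CG", "N", "CA", "CB", 1.516, 112.6, CHI1)
        _side(c, "OD1", "CA", "CB", "CG", 1.249, 118.4, 0.0)
        _side(c, "OD2", "CA", "CB", "CG", 1.249, 118.4, 180.0)

    t["ASP"] = _build_amino(
        "ASP",
        asp,
        {"CG": (0, "sp2"), "OD1": (0, "sp2"), "OD2": (0, "sp2")},
        states={"anionic": {}, "neutral": {"OD2": (1, "sp2")}},
        default_state="anionic",
    )

    def glu(c):
        _side(c, "CG", "N", "CA", "CB", 1.520, 114.1, CHI1)
        _side(c, "CD", "CA", "CB", "CG", 1.516, 112.6, 180.0)
        _side(c, "OE1", "CB", "CG", "CD", 1.249, 118.4, 0.0)
        _side(c, "OE2", "CB", "CG", "CD", 1.249, 118.4, 180.0)

    t["GLU"] = _build_amino(
        "GLU",
        glu,
        {"CG": (2, "sp3"), "CD": (0, "sp2"), "OE1": (0, "sp2"), "OE2": (0, "sp2")},
        states={"anionic": {}, "neutral": {"OE2": (1, "sp2")}},
        default_state="anionic",
    )

    def asn(c):
        _side(c, "CG", "N", "CA", "CB", 1.516, 112.6, CHI1)
        _side(c, "OD1", "CA", "CB", "CG", 1.231, 120.8, 0.0)
        _side(c, "ND2", "CA", "CB", "CG", 1.328, 116.4, 180.0)

    t["ASN"] = _build_amino("ASN", asn, {"CG": (0, "sp2"), "OD1": (0, "sp2"), "ND2": (2, "sp2")})

    def gln(c):
        _side(c, "CG", "N", "CA", "CB", 1.520, 114.1, CHI1)
        _side(c, "CD", "CA", "CB", "CG", 1.516, 112.6, 180.0)
        _side(c, "OE1", "CB", "CG", "CD", 1.231, 120.8, 0.0)
        _side(c, "NE2", "CB", "CG", "CD", 1.328, 116.4, 180.0)

    t["GLN"] = _build_amino("GLN", gln, {"CG": (2, "sp3"), "CD": (0, "sp2"), "OE1": (0, "sp2"), "NE2": (2, "sp2")})

    def lys(c):
        _side(c, "CG", "N", "CA", "CB", 1.520, 114.1, CHI1)
        _side(c, "CD", "CA", "CB", "CG", 1.520, 111.3, 180.0)
        _side(c, "CE", "CB", "CG", "CD", 1.520, 111.3, 180.0)
        _side(c, "NZ", "CG", "CD", "CE", 1.489, 111.9, 180.0)

    t["LYS"] = _build_amino(
        "LYS",
        lys,
        {"CG": (2, "sp3"), "CD": (2, "sp3"), "CE": (2, "sp3"), "NZ": (3, "sp3")},
        states={"cationic": {}, "neutral": {"NZ": (2, "sp3")}},
        default_state="cationic",
    )

    def arg(c):
        _side(c, "CG", "N", "CA", "CB", 1.520, 114.1, CHI1)
        _side(c, "CD", "CA", "CB", "CG", 1.520, 111.3, 180.0)
        _side(c, "NE", "CB", "CG", "CD", 1.461, 112.0, 180.0)
        _side(c, "CZ", "CG", "CD", "NE", 1.329, 124.2, 180.0)
        _side(c, "NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0)
        _side(c, "NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0)

    t["ARG"] = _build_amino(
        "ARG",
        arg,
        {"CG": (2, "sp3"), "CD": (2, "sp3"), "NE": (1, "sp2"), "CZ": (0, "sp2"), "NH1": (2, "sp2"), "NH2": (2, "sp2")},
        states={"cationic": {}, "neutral": {"NH2": (1, "sp2")}},
        default_state="cationic",
    )

    def his(c):
        _side(c, "CG", "N", "CA", "CB", 1.497, 113.8, CHI1)
        _side(c, "ND1", "CA", "CB", "CG", 1.378, 122.7, 90.0)
        _side(c, "CD2", "CA", "CB", "CG", 1.356, 131.1, -90.0)
        _side(c, "CE1", "CB", "CG", "ND1", 1.323, 109.0, 180.0)
        _side(c, "NE2", "CB", "CG", "CD2", 1.374, 107.2, 180.0)

    t["HIS"] = _build_amino(
        "HIS",
        his,
        {"CG": (0, "sp2"), "ND1": (1, "sp2"), "CD2": (1, "sp2"), "CE1": (1, "sp2"), "NE2": (0, "sp2")},
        states={
            "HID": {},
            "HIE": {"ND1": (0, "sp2"), "NE2": (1, "sp2")},
            "HIP": {"NE2": (1, "sp2")},
        },
        default_state="HID",
    )

    # water
    t["HOH"] = ResidueTemplate("HOH", {"O": np.zeros(3)}, {"O": (2, "sp3")})

    # epoxide-like toy substrate: cyclopentene-oxide analogue.
    # Five-membered carbocycle C1..C5 in a plane, epoxide O bridging C1-C2.
    ring_r = 1.530 / (2.0 * math.sin(math.pi / 5.0))
    epx: dict[str, np.ndarray] = {}
    for i in range(5):
        ang = 2.0 * math.pi * i / 5.0
        epx[f"C{i + 1}"] = np.array([ring_r * math.cos(ang), ring_r * math.sin(ang), 0.0])
    mid = 0.5 * (epx["C1"] + epx["C2"])
    half = 0.5 * np.linalg.norm(epx["C1"] - epx["C2"])
    height = math.sqrt(max(1.430**2 - half**2, 0.0))
    epx["O"] = mid + np.array([0.0, 0.0, height])
    t["EPX"] = ResidueTemplate(
        "EPX",
        epx,
        {"C1": (1, "sp3"), "C2": (1, "sp3"), "C3": (2, "sp3"), "C4": (2, "sp3"), "C5": (2, "sp3"), "O": (0, "sp3")},
    )
    return t


TEMPLATES: dict[str, ResidueTemplate] = _make_templates()

#: residues whose protonation state must be declared explicitly
TITRATABLE = frozenset({"ASP", "GLU", "HIS", "TYR", "CYS", "ARG", "LYS"})

#: first side-chain heavy atom bonded to CB, used to define chi1
_CHI1_GAMMA = {
    "SER": "OG",
    "THR": "OG1",
    "CYS": "SG",
    "VAL": "CG1",
    "ILE": "CG1",
    "LEU": "CG",
    "MET": "CG",
    "PHE": "CG",
    "TYR": "CG",
    "ASP": "CG",
    "GLU": "CG",
    "ASN": "CG",
    "GLN": "CG",
    "LYS": "CG",
    "ARG": "CG",
    "HIS": "CG",
}


def chi1_atom(resname: str) -> str | None:
    """Name of the gamma heavy atom defining chi1, or None (Gly/Ala)."""
    return _CHI1_GAMMA.get(resname)


def expected_hydrogen_count(resname: str, present_heavy: list[str], state: str | None = None) -> int:
    """Total hydrogens the template predicts for the present heavy atoms."""
    tpl = TEMPLATES[resname]
    table = tpl.hydrogen_table(state)
    return sum(table.get(name, (0, "sp3"))[0] for name in present_heavy)
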