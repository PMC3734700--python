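"""Geometric diagnostics for optimized structures.

Distances, the nucleophilic-attack angle probe, least-squares rigid
superposition, and the conformer-consistency check used to verify that
spectator groups stay in the same local minimum across stationary points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import ResidueKey, Structure, format_residue_key

__all__ = [
    "AngleProbe",
    "OverlayReport",
    "angle",
    "dihedral",
    "distance",
    "superpose",
    "conformer_consistency",
]


@dataclass(frozen=True)
class AngleProbe:
    """Three atom selectors ``(residue key, atom name)`` defining an angle.

    The canonical use is the nucleophilic attack angle: attacking O,
    attacked C (vertex), leaving/epoxide O.
    """

    a: tuple[ResidueKey, str]
    b: tuple[ResidueKey, str]
    c: tuple[ResidueKey, str]
    label: str = ""

    def measure(self, structure: Structure) -> float:
        pts = []
        for key, name in (self.a, self.b, self.c):
            pts.append(structure.residue(key).atom(name).position)
        return angle(*pts)


@dataclass
class OverlayReport:
    """Result of a conformer-consistency overlay."""

    per_residue_rmsd: dict[ResidueKey, float]
    frozen_rmsd: float
    flagged: list[ResidueKey] = field(default_factory=list)
    threshold: float = 0.3


def distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle(a, b, c) -> float:
    """Angle a-b-c in degrees, in [0, 180]; errors on a zero-length arm."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle undefined: zero-length arm")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    return float(np.degrees(np.arctan2(y, x)))


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (Kabsch).

    Parameters
    ----------
    mobile, reference : (n, 3) arrays
        Paired coordinates, n >= 3 and not collinear.

    Returns
    -------
    rotation : (3, 3) proper rotation matrix (det = +1)
    translation : (3,) vector
    rmsd : float
        Root-mean-square deviation over the pairs after applying
        ``x -> rotation @ x + translation`` to ``mobile``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("superpose needs two equally sized (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("superpose needs at least 3 atom pairs")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinearity: centered cloud must span a plane
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise ValueError("superpose subset is collinear")
    H = Pc.T @ Qc
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def superpose_structures(mobile: Structure, reference: Structure, pairs):
    """Superpose structures on serial pairs ``[(mobile serial, ref serial)]``."""
    m_by = {a.serial: a for a in mobile.atoms()}
    r_by = {a.serial: a for a in reference.atoms()}
    P = np.array([m_by[i].position for i, _ in pairs])
    Q = np.array([r_by[j].position for _, j in pairs])
    return superpose(P, Q)


def conformer_consistency(
    point_a: Structure,
    point_b: Structure,
    exclude: list[ResidueKey] | None = None,
    threshold: float = 0.3,
) -> OverlayReport:
    """Check that spectator residues occupy the same local minimum.

    Superposes ``point_b`` onto ``point_a`` using the frozen atoms as the
    common crystallographic frame, then computes per-residue heavy-atom
    RMSD for every residue not listed in ``exclude`` (the reacting
    groups).  Residues above ``threshold`` are flagged.
    """
    exclude = set(exclude or [])

    def atom_map(s: Structure):
        out = {}
        for r in s.all_residues():
            if r.key in exclude:
                continue
            for a in r.atoms:
                out[(r.key, a.name)] = a
        return out

    ma = atom_map(point_a)
    mb = atom_map(point_b)
    if set(ma) != set(mb):
        diff = sorted(
            f"{format_residue_key(k)}/{n}" for k, n in set(ma).symmetric_difference(set(mb))
        )
        raise ValueError(f"atom sets differ after exclusions: {diff}")

    frozen_keys = [k for k, a in ma.items() if a.is_frozen and mb[k].is_frozen]
    if len(frozen_keys) >= 3:
        P = np.array([mb[k].position for k in frozen_keys])
        Q = np.array([ma[k].position for k in frozen_keys])
        R, t, frozen_rmsd = superpose(P, Q)
    else:  # no usable frozen frame: compare in the given frames
        R, t, frozen_rmsd = np.eye(3), np.zeros(3), 0.0

    per_residue: dict[ResidueKey, float] = {}
    flagged: list[ResidueKey] = []
    for res in point_a.all_residues():
        if res.key in exclude:
            continue
        heavy = [a.name for a in res.atoms if a.element.upper() != "H"]
        if not heavy:
            continue
        Qa = np.array([ma[(res.key, n)].position for n in heavy])
        Pb = np.array([mb[(res.key, n)].position for n in heavy])
        moved = (R @ Pb.T).T + t
        rmsd = float(np.sqrt(np.mean(np.sum((moved - Qa) ** 2, axis=1))))
        per_residue[res.key] = rmsd
        if rmsd > threshold:
            flagged.append(res.key)
    return OverlayReport(per_residue, frozen_rmsd, flagged, threshold)
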