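"""Engine-agnostic QM job specification, execution contract, results.

The pipeline never talks to a quantum-chemistry program directly.  It
emits :class:`QMJobSpec` objects and consumes :class:`QMResult` records
(all energies in kcal/mol).  Two reference engines ship with the package:

``LookupEngine``
    Replays a results table keyed by job id.  Used for every end-to-end
    test; real calculations are ingested the same way via
    :func:`parse_results_table`.

``ToyEngine``
    A deterministic closed-form surrogate potential (harmonic bonds plus
    pairwise soft exponential repulsion) with an analytic gradient and a
    frozen-atom-aware minimizer, so optimisation plumbing is testable
    without any electronic-structure code.

Engines converting from hartree must do so at ingestion
(627.509474 kcal/mol per hartree); everything downstream is kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize

from .builder import ClusterModel
from .structure import Structure

__all__ = [
    "QMJobSpec",
    "QMResult",
    "build_job",
    "run_engine",
    "LookupEngine",
    "ToyEngine",
    "parse_results_table",
    "write_results_table",
    "HARTREE_TO_KCAL",
    "TSValidationError",
]

HARTREE_TO_KCAL = 627.509474

TASKS = ("minimize", "saddle-search", "single-point")


class TSValidationError(ValueError):
    """A saddle-search result that is not a first-order saddle point."""


@dataclass
class QMJobSpec:
    job_id: str
    geometry: Structure
    task: str
    level: str
    charge: int = 0
    multiplicity: int = 1
    frozen_ids: frozenset[int] = field(default_factory=frozenset)
    dielectric: float | None = None

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        ids = {a.serial for a in self.geometry.atoms()}
        if not set(self.frozen_ids) <= ids:
            raise ValueError("frozen ids are not a subset of geometry atom ids")
        if not float(self.charge).is_integer():
            raise ValueError("charge must be an integer")


@dataclass
class QMResult:
    """Energy components (kcal/mol) and outcome of one QM job."""

    job_id: str
    electronic_energy: float = 0.0
    zpe: float = 0.0
    solvation_correction: float = 0.0
    dispersion_correction: float = 0.0
    converged: bool = True
    final_geometry: Structure | None = None
    imaginary_mode_count: int | None = None

    def validate_as_ts(self) -> None:
        """Accept as a transition state only a true first-order saddle."""
        if self.imaginary_mode_count is None:
            warnings.warn(
                f"job {self.job_id}: imaginary mode count unknown; accepting as TS unverified"
            )
            return
        if self.imaginary_mode_count != 1:
            raise TSValidationError(
                f"job {self.job_id}: {self.imaginary_mode_count} imaginary modes (need exactly 1)"
            )


def make_job_id(variant: str, point: str, task: str, level: str) -> str:
    return ":".join((variant, point, task, level))


def build_job(
    model: ClusterModel,
    task: str,
    level: str,
    dielectric: float | None = None,
    point_label: str = "",
) -> QMJobSpec:
    """Build a job spec for a cluster model; the id is deterministic in
    (variant label, stationary-point label, task, level)."""
    if model.structure.n_atoms == 0:
        raise ValueError("cannot build a job for an empty model")
    frozen = frozenset(a.serial for a in model.structure.atoms() if a.is_frozen)
    return QMJobSpec(
        job_id=make_job_id(model.variant_label, point_label, task, level),
        geometry=model.structure,
        task=task,
        level=level,
        charge=model.recipe.charge,
        multiplicity=model.recipe.multiplicity,
        frozen_ids=frozen,
        dielectric=dielectric,
    )


def run_engine(spec: QMJobSpec, engine) -> QMResult:
    """Execute a job through an engine honouring the result contract."""
    if not engine.supports(spec.task):
        raise ValueError(f"engine {type(engine).__name__} does not support task {spec.task!r}")
    result = engine.run(spec)
    if result.job_id != spec.job_id:
        raise ValueError(
            f"engine returned job id {result.job_id!r} for spec {spec.job_id!r}"
        )
    return result


# ---------------------------------------------------------------------------
# reference engines


class LookupEngine:
    """Replays pre-computed results keyed by job id.  Pure by construction."""

    def __init__(self, results: dict[str, QMResult]):
        self.results = dict(results)

    @classmethod
    def from_table(cls, path) -> "LookupEngine":
        return cls({r.job_id: r for r in parse_results_table(path)})

    def supports(self, task: str) -> bool:
        return task in TASKS

    def run(self, spec: QMJobSpec) -> QMResult:
        if spec.job_id not in self.results:
            raise KeyError(f"no result for job id {spec.job_id!r} in lookup table")
        return replace(self.results[spec.job_id])


class ToyEngine:
    """Closed-form surrogate potential for desk-scale testing.

    ``E = sum_bonds k (r - r0)^2 + sum_{i<j} A exp(-r_ij / rho)`` with the
    bond list perceived once from the input geometry (pairs closer than
    1.3x the covalent-radius sum).  Distances only, so the energy is
    invariant under rigid motion.  ``minimize`` runs gradient-based
    descent on the unfrozen coordinates.
    """

    COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05}

    def __init__(self, k: float = 300.0, repulsion_a: float = 25.0, repulsion_rho: float = 0.35,
                 gtol: float = 1e-2, maxiter: int = 5000):
        self.k = k
        self.repulsion_a = repulsion_a
        self.repulsion_rho = repulsion_rho
        self.gtol = gtol
        self.maxiter = maxiter

    def supports(self, task: str) -> bool:
        return task in ("minimize", "single-point")

    def reference_length(self, e1: str, e2: str) -> float:
        return self.COVALENT_RADII.get(e1.upper(), 0.76) + self.COVALENT_RADII.get(e2.upper(), 0.76)

    def _bonds(self, elements, positions):
        pos = np.asarray(positions, dtype=float)
        radii = np.array([self.COVALENT_RADII.get(e.upper(), 0.76) for e in elements])
        iu, ju = np.triu_indices(len(elements), k=1)
        r0 = radii[iu] + radii[ju]
        dist = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        mask = dist < 1.3 * r0
        return list(zip(iu[mask].tolist(), ju[mask].tolist(), r0[mask].tolist()))

    def energy_and_gradient(self, elements, positions, bonds):
        pos = np.asarray(positions, dtype=float)
        n = len(pos)
        grad = np.zeros_like(pos)
        energy = 0.0
        if bonds:
            bi = np.array([b[0] for b in bonds])
            bj = np.array([b[1] for b in bonds])
            r0 = np.array([b[2] for b in bonds])
            d = pos[bi] - pos[bj]
            r = np.linalg.norm(d, axis=1)
            energy += float(self.k * np.sum((r - r0) ** 2))
            g = (2.0 * self.k * (r - r0) / r)[:, None] * d
            np.add.at(grad, bi, g)
            np.add.at(grad, bj, -g)
        iu, ju = np.triu_indices(n, k=1)
        d = pos[iu] - pos[ju]
        r = np.linalg.norm(d, axis=1)
        e = self.repulsion_a * np.exp(-r / self.repulsion_rho)
        energy += float(np.sum(e))
        g = (-(e / self.repulsion_rho) / r)[:, None] * d
        np.add.at(grad, iu, g)
        np.add.at(grad, ju, -g)
        return energy, grad

    def run(self, spec: QMJobSpec) -> QMResult:
        atoms = spec.geometry.atoms()
        elements = [a.element for a in atoms]
        pos0 = np.array([a.position for a in atoms])
        bonds = self._bonds(elements, pos0)

        if spec.task == "single-point":
            energy, _ = self.energy_and_gradient(elements, pos0, bonds)
            return QMResult(spec.job_id, electronic_energy=float(energy), final_geometry=spec.geometry)

        if spec.task != "minimize":
            raise ValueError(f"ToyEngine cannot run task {spec.task!r}")
        free = np.array([a.serial not in spec.frozen_ids for a in atoms])
        x_fixed = pos0.copy()

        def fun(x):
            pos = x_fixed.copy()
            pos[free] = x.reshape(-1, 3)
            e, g = self.energy_and_gradient(elements, pos, bonds)
            return e, g[free].ravel()

        if free.any():
            res = _scipy_minimize(
                fun, pos0[free].ravel(), jac=True, method="L-BFGS-B",
                options={"maxiter": self.maxiter, "ftol": 1e-10, "gtol": self.gtol},
            )
            final = x_fixed.copy()
            final[free] = res.x.reshape(-1, 3)
            converged = bool(res.success)
        else:
            final = x_fixed
            converged = True
        energy, _ = self.energy_and_gradient(elements, final, bonds)
        geom = spec.geometry.copy()
        for a, p in zip(geom.atoms(), final):
            a.position = p.copy()
        return QMResult(
            spec.job_id,
            electronic_energy=float(energy),
            converged=converged,
            final_geometry=geom,
            imaginary_mode_count=0,
        )


# ---------------------------------------------------------------------------
# results-table I/O

_TABLE_COLUMNS = ["job_id", "electronic_energy", "zpe", "solvation", "dispersion", "converged", "n_imag"]


def parse_results_table(path) -> list[QMResult]:
    """Read a delimited results table (kcal/mol) into QMResult records.

    Expected tab/whitespace-delimited columns:
    ``job_id electronic_energy zpe solvation dispersion converged n_imag``
    (``n_imag`` empty or ``NA`` when unknown).  Lines starting with ``#``
    are comments.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results table {path}: missing column(s) {missing}")
    if df["job_id"].duplicated().any():
        dups = sorted(df.loc[df["job_id"].duplicated(), "job_id"])
        raise ValueError(f"results table {path}: duplicate job id(s) {dups}")
    records = []
    for row in df.itertuples(index=False):
        n_imag = getattr(row, "n_imag")
        n_imag = None if pd.isna(n_imag) else int(n_imag)
        converged = str(getattr(row, "converged")).strip().lower() in ("true", "1", "yes")
        records.append(
            QMResult(
                job_id=str(row.job_id),
                electronic_energy=float(row.electronic_energy),
                zpe=float(row.zpe),
                solvation_correction=float(row.solvation),
                dispersion_correction=float(row.dispersion),
                converged=converged,
                imaginary_mode_count=n_imag,
            )
        )
    return records


def write_results_table(results, path, header_comment: str = "") -> None:
    """Write QMResult records in the format parse_results_table reads."""
    with open(path, "w") as fh:
        fh.write("# energies in kcal/mol\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for r in results:
            n_imag = "NA" if r.imaginary_mode_count is None else str(r.imaginary_mode_count)
            fh.write(
                f"{r.job_id}\t{r.electronic_energy:.6f}\t{r.zpe:.6f}\t"
                f"{r.solvation_correction:.6f}\t{r.dispersion_correction:.6f}\t"
                f"{str(r.converged).lower()}\t{n_imag}\n"
            )
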