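"""End-to-end workflow: config, staged pipeline, report bundle.

Stages (each writes its artifact to the output directory and every
artifact header names the config hash and seed, so a rerun with the same
config is byte-identical under the lookup engine):

1. build the wild-type cluster model from the structure + recipe
2. derive each mutant model
3. add hydrogens per the declared protonation states
4. emit the QM job manifest
5. collect results through the chosen engine
6. assemble the barrier table
7. compare with experiment in the selectivity report
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .builder import (
    ClusterModel,
    ClusterRecipe,
    TruncationRule,
    VariantSpec,
    add_hydrogens,
    apply_variant,
    build_cluster,
)
from .energetics import ReactionProfile, StationaryPoint, barrier_record
from .qm import LookupEngine, ToyEngine, build_job, run_engine, write_results_table
from .selectivity import DEFAULT_TEMPERATURE, SelectivityRecord, selectivity_report
from .structure import parse_residue_key, read_pdb, write_pdb

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "load_experimental_table"]

log = logging.getLogger("qmcluster")

POINTS = ("ES", "TS_C1", "TS_C2")


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and offending item."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    structure_path: Path
    recipe: ClusterRecipe
    variants: list[VariantSpec] = field(default_factory=list)
    engine: str = "lookup"
    results_table: Path | None = None
    experimental_table: Path | None = None
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 1
    config_hash: str = ""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = path.read_bytes()
        data = yaml.safe_load(raw)
        base = path.parent

        rdata = data["recipe"]
        truncations = [
            TruncationRule(
                residue_key=parse_residue_key(t["residue"]),
                cut_bond=(t["keep"], t["remove"]),
                scheme=t.get("scheme", "alpha-cut"),
            )
            for t in rdata.get("truncations", [])
        ]
        frozen = rdata.get("frozen")
        if frozen is not None:
            frozen = [(parse_residue_key(k), n) for k, n in (f.rsplit("/", 1) for f in frozen)]
        recipe = ClusterRecipe(
            include=[parse_residue_key(k) for k in rdata["include"]],
            truncations=truncations,
            ligand_key=parse_residue_key(rdata["ligand"]) if "ligand" in rdata else None,
            charge=int(rdata.get("charge", 0)),
            multiplicity=int(rdata.get("multiplicity", 1)),
            frozen_atoms=frozen,
            protonation={parse_residue_key(k): v for k, v in rdata.get("protonation", {}).items()},
        )
        variants = [VariantSpec.parse(v["name"], v.get("mutations", [])) for v in data.get("variants", [])]

        def resolve(key):
            p = data.get(key)
            return (base / p) if p else None

        cfg = cls(
            structure_path=base / data["structure"],
            recipe=recipe,
            variants=variants,
            engine=data.get("engine", "lookup"),
            results_table=resolve("results_table"),
            experimental_table=resolve("experimental"),
            temperature=float(data.get("temperature", DEFAULT_TEMPERATURE)),
            seed=int(data.get("seed", 1)),
            config_hash=hashlib.sha256(raw).hexdigest()[:16],
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not Path(self.structure_path).exists():
            raise FileNotFoundError(f"structure file not found: {self.structure_path}")
        if self.engine not in ("lookup", "toy"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.engine == "lookup":
            if self.results_table is None or not Path(self.results_table).exists():
                raise FileNotFoundError(f"lookup engine needs a results table: {self.results_table}")
        if self.experimental_table is not None and not Path(self.experimental_table).exists():
            raise FileNotFoundError(f"experimental table not found: {self.experimental_table}")

    def make_engine(self):
        if self.engine == "lookup":
            return LookupEngine.from_table(self.results_table)
        return ToyEngine()

    def header(self) -> str:
        return f"config={self.config_hash} seed={self.seed}"


def load_experimental_table(path, temperature=DEFAULT_TEMPERATURE) -> list[SelectivityRecord]:
    """Read experimental selectivities from a delimited table.

    Columns: ``variant`` plus either ``ee_percent`` + ``favored``
    (RR/SS) or ``ddg`` (kcal/mol); a row may fill either pair.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if "variant" not in df.columns:
        raise ValueError(f"experimental table {path}: missing 'variant' column")
    records = []
    for row in df.itertuples(index=False):
        ddg = getattr(row, "ddg", None)
        if ddg is not None and not pd.isna(ddg):
            records.append(SelectivityRecord.from_ddg(str(row.variant), float(ddg), temperature))
            continue
        ee = float(getattr(row, "ee_percent")) / 100.0
        favored = str(getattr(row, "favored")).upper()
        if favored not in ("RR", "SS"):
            raise ValueError(f"experimental table {path}: favored must be RR or SS, got {favored!r}")
        signed = ee if favored == "SS" else -ee
        records.append(SelectivityRecord.from_ee(str(row.variant), signed, temperature))
    return records


# ---------------------------------------------------------------------------
# staged pipeline


def build_models(config: RunConfig) -> dict[str, ClusterModel]:
    """Stages 1-3: WT model, mutants, hydrogen completion."""
    try:
        structure = read_pdb(config.structure_path)
    except Exception as exc:
        raise PipelineError("read-structure", str(exc)) from exc
    try:
        wt = build_cluster(structure, config.recipe)
    except Exception as exc:
        raise PipelineError("build-model", str(exc)) from exc

    models = {"WT": wt}
    for variant in config.variants:
        try:
            models[variant.name] = apply_variant(wt, variant)
        except Exception as exc:
            raise PipelineError("mutate", f"variant {variant.name}: {exc}") from exc
    for name in list(models):
        try:
            models[name] = add_hydrogens(models[name], config.recipe.protonation)
        except Exception as exc:
            raise PipelineError("protonate", f"variant {name}: {exc}") from exc
    return models


def build_jobs(config: RunConfig, models: dict[str, ClusterModel], engine):
    """Stage 4: one job per (variant, stationary point)."""
    level = "table" if config.engine == "lookup" else "toy"
    ts_task = "saddle-search" if engine.supports("saddle-search") else "single-point"
    jobs = []
    for name, model in models.items():
        for point in POINTS:
            task = "minimize" if point == "ES" else ts_task
            jobs.append((point, build_job(model, task, level, point_label=point)))
    return jobs


def collect_results(jobs, engine):
    """Stage 5: run every job through the engine."""
    results = {}
    for point, spec in jobs:
        try:
            results[spec.job_id] = (point, run_engine(spec, engine))
        except Exception as exc:
            raise PipelineError("collect", f"job {spec.job_id}: {exc}") from exc
    return results


def assemble_profiles(models, jobs, results) -> list[ReactionProfile]:
    """Stage 6 input: group results into per-variant reaction profiles."""
    profiles = []
    for name in models:
        points = []
        for point, spec in jobs:
            if spec.job_id in results and spec.job_id.startswith(f"{name}:"):
                _, res = results[spec.job_id]
                points.append(StationaryPoint(point, opt=res, sp=res))
        profiles.append(ReactionProfile(variant=name, points=points))
    return profiles


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage, writing the report bundle into ``outdir``.

    Returns a dict of output paths.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header()
    out: dict[str, Path] = {}

    log.info("stage build-models")
    models = build_models(config)
    for name, model in models.items():
        path = outdir / f"model_{name}.pdb"
        model.structure.title = f"{name} cluster model [{header}]"
        write_pdb(model.structure, path)
        out[f"model_{name}"] = path
    warnings_seen = [w for m in models.values() for w in m.report.get("warnings", [])]

    engine = config.make_engine()
    jobs = build_jobs(config, models, engine)
    manifest = {
        "header": header,
        "jobs": [
            {
                "job_id": spec.job_id,
                "point": point,
                "task": spec.task,
                "level": spec.level,
                "charge": spec.charge,
                "multiplicity": spec.multiplicity,
                "n_atoms": spec.geometry.n_atoms,
                "n_frozen": len(spec.frozen_ids),
            }
            for point, spec in jobs
        ],
    }
    out["jobs"] = outdir / "jobs.json"
    out["jobs"].write_text(json.dumps(manifest, indent=1) + "\n")

    log.info("stage collect (%d jobs, %s engine)", len(jobs), config.engine)
    results = collect_results(jobs, engine)
    out["results"] = outdir / "results_collected.tsv"
    write_results_table([r for _, r in results.values()], out["results"], header_comment=header)
    unconverged = [r.job_id for _, r in results.values() if not r.converged]

    log.info("stage barriers")
    profiles = assemble_profiles(models, jobs, results)
    try:
        records = [barrier_record(p) for p in profiles]
    except Exception as exc:
        raise PipelineError("barriers", str(exc)) from exc
    btab = pd.DataFrame(
        {
            "variant": [r.variant for r in records],
            "TS_C1": [round(r.barrier_C1, 1) for r in records],
            "TS_C2": [round(r.barrier_C2, 1) for r in records],
            "ddE_calc": [round(r.delta_delta, 1) for r in records],
        }
    )
    out["barriers"] = outdir / "barriers.tsv"
    with open(out["barriers"], "w") as fh:
        fh.write(f"# {header}\n# energies kcal/mol\n")
        btab.to_csv(fh, sep="\t", index=False)

    log.info("stage selectivity")
    if config.experimental_table is not None:
        expt = load_experimental_table(config.experimental_table, config.temperature)
        table, summary = selectivity_report(records, expt, config.temperature)
        out["selectivity"] = outdir / "selectivity.tsv"
        with open(out["selectivity"], "w") as fh:
            fh.write(f"# {header}\n# ddE_calc vs ddG_expt, kcal/mol\n")
            table.round(3).to_csv(fh, sep="\t", index=False)
        summary_lines = [f"[{header}]", summary]
        if warnings_seen:
            summary_lines.append("builder warnings:\n" + "\n".join(f"  - {w}" for w in warnings_seen))
        if unconverged:
            summary_lines.append("unconverged jobs:\n" + "\n".join(f"  - {j}" for j in unconverged))
        out["summary"] = outdir / "summary.txt"
        out["summary"].write_text("\n".join(summary_lines) + "\n")
    return out
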