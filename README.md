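# qmcluster

Tooling for the quantum-chemical *cluster approach* to enzymatic
enantioselectivity: build truncated, hydrogen-capped, coordinate-locked
active-site models (wild type and point mutants) from a protein structure,
manage engine-agnostic QM jobs and corrected energies, and convert
activation-barrier differences to enantiomeric excess (and back) to produce
selectivity comparison reports.

The package never runs electronic-structure calculations itself. Jobs are
described by `QMJobSpec` records and results ingested as `QMResult` records
(kcal/mol); two reference engines ship with the package so the whole pipeline
is testable offline:

* **LookupEngine** — replays a results table keyed by job id (the intended
  route for real DFT results too: run them elsewhere, tabulate, replay).
* **ToyEngine** — a deterministic closed-form surrogate potential (harmonic
  bonds + soft pairwise repulsion) with a frozen-atom-aware minimizer.

## Layout

| module | contents |
|---|---|
| `qmcluster.structure` | `Atom`/`Residue`/`Structure`, PDB and XYZ I/O, frozen-flag persistence via `REMARK 250 FROZEN` |
| `qmcluster.builder` | truncation/capping (`build_cluster`, `place_cap_hydrogen`), template hydrogen addition, point mutation and variants |
| `qmcluster.templates` | idealized residue templates (18 standard amino acids, water, epoxide-like substrate) |
| `qmcluster.qm` | job specs, engines, results-table parsing |
| `qmcluster.energetics` | corrected total energies, activation barriers, barrier differences |
| `qmcluster.selectivity` | ee ↔ ΔΔG transition-state-theory conversion, Boltzmann-weighted TS ensembles, comparison report |
| `qmcluster.geometry` | angle/dihedral probes, Kabsch superposition, conformer-consistency overlay |
| `qmcluster.toysite` | deterministic synthetic active-site generator (fixture-scale stand-in for a crystal structure) |
| `qmcluster.pipeline` / `qmcluster.cli` | YAML run config, staged pipeline, `qmcluster` CLI |
| `qmcluster.datasets` | bundled seven-variant demonstration campaign (reference barriers + experimental selectivities) |

## CLI

Generate a self-contained demo bundle (toy site PDB, lookup-engine results
table, experimental table, run config), then run the pipeline:

```bash
qmcluster make-fixture --out demo --seed 1
qmcluster report --config demo/config.yaml --out run
cat run/barriers.tsv run/selectivity.tsv run/summary.txt
```

One verb exists per stage: `build-model`, `mutate`, `jobs`, `collect`,
`barriers`, `selectivity`, `report`, `make-fixture`. Common flags:
`--config`, `--out`, `--temperature` (K, default 298.15), `--engine
{lookup,toy}`, `--seed`. Reruns with the same config are byte-identical
under the lookup engine; every artifact header carries the config hash and
seed.

### Results-table format

Whitespace-delimited text with a header, energies kcal/mol, `#` comments:

```
job_id  electronic_energy  zpe  solvation  dispersion  converged  n_imag
WT:ES:minimize:table  -20.0  1.25  -0.75  -0.5  true  0
```

Job ids are deterministic: `variant:point:task:level`.

### Conventions

* Coordinates Å, energies kcal/mol, temperature K (default 298.15).
* `ΔΔE = barrier(TS_C2) − barrier(TS_C1)`; C2 attack yields the R,R
  product, so negative means R,R-favored. Signed ee uses the same
  convention: positive = S,S excess.
* Total energy = single-point electronic energy + opt-level ZPE +
  single-point solvation and dispersion corrections (configurable).
* Cap (link) hydrogens are written with an `HCP` name prefix and are always
  frozen; frozen serials round-trip through `REMARK 250 FROZEN` records.
* Protonation states of titratable residues are explicit inputs — there is
  no silent default.

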