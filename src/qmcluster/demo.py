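"""Write a self-contained demonstration bundle (toy site + lookup-engine
results + experimental table + run config) into a directory, so the full
pipeline runs with no external inputs."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .datasets import EXPERIMENTAL_SELECTIVITY, reference_results, toy_variant_specs
from .qm import write_results_table
from .structure import format_residue_key, write_pdb
from .toysite import ToySiteParams, generate_toy_site

__all__ = ["make_demo_bundle"]


def _variant_to_yaml(spec) -> dict:
    return {
        "name": spec.name,
        "mutations": [
            f"{format_residue_key(key)}:{src}>{dst}" for key, src, dst in spec.mutations
        ],
    }


def make_demo_bundle(outdir, seed: int = 1, n_pocket_residues: int = 3,
                     pocket_radius: float = 6.0, noise: float = 0.05) -> dict[str, Path]:
    """Generate the bundle; returns a dict of written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = ToySiteParams(
        seed=seed, n_pocket_residues=n_pocket_residues,
        pocket_radius=pocket_radius, noise=noise,
    )
    structure, manifest = generate_toy_site(params)
    paths = {
        "structure": outdir / "toy_site.pdb",
        "manifest": outdir / "toy_site_manifest.json",
        "results": outdir / "results_table.tsv",
        "experimental": outdir / "experimental.tsv",
        "config": outdir / "config.yaml",
    }
    write_pdb(structure, paths["structure"])
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    write_results_table(reference_results(), paths["results"], header_comment=f"seed={seed}")

    with open(paths["experimental"], "w") as fh:
        fh.write(f"# experimental selectivities, seed={seed}\n")
        fh.write("variant\tee_percent\tfavored\tddg\n")
        for variant, (kind, value) in EXPERIMENTAL_SELECTIVITY.items():
            if kind == "ee":
                favored = "SS" if value > 0 else "RR"
                fh.write(f"{variant}\t{abs(value) * 100:.1f}\t{favored}\tNA\n")
            else:
                fh.write(f"{variant}\tNA\tNA\t{value:+.1f}\n")

    # pocket residues A:5.. stay untruncated so they remain mutable
    config = {
        "structure": "toy_site.pdb",
        "recipe": {
            "include": [f"A:{i}" for i in range(1, 5 + n_pocket_residues)] + ["A:101"],
            "ligand": "A:201",
            "charge": -2,
            "multiplicity": 1,
            "truncations": [
                {"residue": "A:1", "keep": "CB", "remove": "CA", "scheme": "alpha-cut"},
                {"residue": "A:2", "keep": "CB", "remove": "CA", "scheme": "alpha-cut"},
                {"residue": "A:3", "keep": "CB", "remove": "CA", "scheme": "alpha-cut"},
            ],
            "protonation": {
                "A:1": "anionic",
                "A:2": "anionic",
                "A:3": "neutral",
                "A:5": "neutral",
                "A:6": "neutral",
                "A:7": "neutral",
            },
        },
        "variants": [_variant_to_yaml(v) for v in toy_variant_specs()],
        "engine": "lookup",
        "results_table": "results_table.tsv",
        "experimental": "experimental.tsv",
        "temperature": 298.15,
        "seed": seed,
    }
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths
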