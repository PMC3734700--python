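import pytest

from qmcluster.builder import ClusterRecipe, TruncationRule, build_cluster
from qmcluster.demo import make_demo_bundle
from qmcluster.toysite import ToySiteParams, generate_toy_site

TOY_PARAMS = ToySiteParams(seed=1, n_pocket_residues=3, pocket_radius=6.0, noise=0.05)

#: protonation declarations covering every titratable key in the toy site,
#: including keys that only become titratable after mutation (Cys)
TOY_PROTONATION = {
    ("A", 1, ""): "anionic",
    ("A", 2, ""): "anionic",
    ("A", 3, ""): "neutral",
    ("A", 5, ""): "neutral",
    ("A", 6, ""): "neutral",
    ("A", 7, ""): "neutral",
}


@pytest.fixture(scope="session")
def toy_site():
    """(Structure, manifest) for the canonical toy site, seed 1."""
    return generate_toy_site(TOY_PARAMS)


def standard_recipe(**overrides) -> ClusterRecipe:
    """The demo-bundle recipe: all toy residues, three alpha-cuts."""
    kwargs = dict(
        include=[("A", i, "") for i in range(1, 8)] + [("A", 101, "")],
        truncations=[
            TruncationRule(("A", 1, ""), ("CB", "CA")),
            TruncationRule(("A", 2, ""), ("CB", "CA")),
            TruncationRule(("A", 3, ""), ("CB", "CA")),
        ],
        ligand_key=("A", 201, ""),
        charge=-2,
        multiplicity=1,
        protonation=dict(TOY_PROTONATION),
    )
    kwargs.update(overrides)
    return ClusterRecipe(**kwargs)


@pytest.fixture(scope="session")
def wt_model(toy_site):
    structure, _ = toy_site
    return build_cluster(structure, standard_recipe())


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """Self-contained demo bundle (toy PDB, lookup table, config)."""
    d = tmp_path_factory.mktemp("demo")
    make_demo_bundle(d, seed=1)
    return d
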