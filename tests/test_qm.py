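import math

import numpy as np
import pytest

from qmcluster.datasets import reference_results
from qmcluster.qm import (
    LookupEngine,
    QMJobSpec,
    QMResult,
    ToyEngine,
    TSValidationError,
    build_job,
    parse_results_table,
    run_engine,
    write_results_table,
)
from qmcluster.structure import Atom, Residue, Structure


def _structure(positions, elements=None, frozen=None):
    frozen = frozen or set()
    elements = elements or ["C"] * len(positions)
    atoms = [
        Atom(i + 1, f"{e}{i + 1}", e, np.array(p, dtype=float), ("A", 1, ""), is_frozen=(i + 1) in frozen)
        for i, (e, p) in enumerate(zip(elements, positions))
    ]
    return Structure(residues=[Residue("LIG", ("A", 1, ""), atoms)])


class TestJobSpec:
    def test_frozen_ids_copied_from_model(self, wt_model):
        spec = build_job(wt_model, "saddle-search", "opt-small-basis", point_label="TS_C1")
        expected = {a.serial for a in wt_model.structure.atoms() if a.is_frozen}
        assert set(spec.frozen_ids) == expected and len(expected) == 6

    def test_deterministic_job_id(self, wt_model):
        s1 = build_job(wt_model, "minimize", "opt", point_label="ES")
        s2 = build_job(wt_model, "minimize", "opt", point_label="ES")
        assert s1.job_id == s2.job_id == "WT:ES:minimize:opt"

    def test_distinct_variants_distinct_ids(self, wt_model):
        mutant = wt_model.copy()
        mutant.variant_label = "R1"
        assert (
            build_job(wt_model, "minimize", "opt", point_label="ES").job_id
            != build_job(mutant, "minimize", "opt", point_label="ES").job_id
        )

    def test_frozen_ids_must_exist(self):
        s = _structure([(0, 0, 0), (1.5, 0, 0)])
        with pytest.raises(ValueError, match="frozen ids"):
            QMJobSpec("x", s, "minimize", "opt", frozen_ids=frozenset({99}))

    def test_unknown_task_rejected(self):
        s = _structure([(0, 0, 0)])
        with pytest.raises(ValueError, match="task"):
            QMJobSpec("x", s, "orbit", "opt")


class TestLookupEngine:
    def test_fixture_components_verbatim(self):
        engine = LookupEngine({r.job_id: r for r in reference_results()})
        spec_geometry = _structure([(0, 0, 0)])
        spec = QMJobSpec("WT:TS_C1:saddle-search:table", spec_geometry, "saddle-search", "table")
        res = run_engine(spec, engine)
        assert res.electronic_energy == pytest.approx(-20.0 + 15.7 + 0.8)
        assert res.zpe == pytest.approx(0.95)
        assert res.imaginary_mode_count == 1

    def test_missing_entry_names_job_id(self):
        engine = LookupEngine({})
        spec = QMJobSpec("nope:ES:minimize:table", _structure([(0, 0, 0)]), "minimize", "table")
        with pytest.raises(KeyError, match="nope:ES:minimize:table"):
            run_engine(spec, engine)

    def test_pure(self):
        engine = LookupEngine({r.job_id: r for r in reference_results()})
        spec = QMJobSpec("WT:ES:minimize:table", _structure([(0, 0, 0)]), "minimize", "table")
        a = run_engine(spec, engine)
        b = run_engine(spec, engine)
        assert a == b

    def test_mismatched_id_contract(self):
        class Liar:
            def supports(self, task):
                return True

            def run(self, spec):
                return QMResult("other")

        spec = QMJobSpec("x:ES:minimize:t", _structure([(0, 0, 0)]), "minimize", "t")
        with pytest.raises(ValueError, match="job id"):
            run_engine(spec, Liar())


class TestToyEngine:
    def test_two_atom_closed_form(self):
        engine = ToyEngine()
        r0 = engine.reference_length("C", "C")
        spec = QMJobSpec("t:p:single-point:toy", _structure([(0, 0, 0), (r0, 0, 0)]), "single-point", "toy")
        res = run_engine(spec, engine)
        # at the reference bond length only the soft repulsion remains
        expected = engine.repulsion_a * math.exp(-r0 / engine.repulsion_rho)
        assert res.electronic_energy == pytest.approx(expected, abs=1e-12)

    def test_minimize_descends(self):
        engine = ToyEngine()
        s = _structure([(0, 0, 0), (1.9, 0, 0), (0.1, 1.8, 0)])
        start, _ = (
            engine.energy_and_gradient(
                ["C"] * 3, np.array([a.position for a in s.atoms()]), engine._bonds(["C"] * 3, np.array([a.position for a in s.atoms()]))
            )
        )
        res = run_engine(QMJobSpec("t:p:minimize:toy", s, "minimize", "toy"), engine)
        assert res.electronic_energy <= start
        assert res.converged

    def test_minimize_never_moves_frozen_atoms(self):
        engine = ToyEngine()
        s = _structure([(0, 0, 0), (1.9, 0, 0), (0.1, 1.8, 0)], frozen={1, 2})
        spec = QMJobSpec("t:p:minimize:toy", s, "minimize", "toy", frozen_ids=frozenset({1, 2}))
        res = run_engine(spec, engine)
        for before, after in zip(s.atoms(), res.final_geometry.atoms()):
            if before.is_frozen:
                np.testing.assert_array_equal(before.position, after.position)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        engine = ToyEngine()
        rng = np.random.default_rng(4)
        pos = rng.normal(scale=1.2, size=(6, 3))
        e1 = run_engine(
            QMJobSpec("a:p:single-point:toy", _structure(pos), "single-point", "toy"), engine
        ).electronic_energy
        R = Rotation.random(random_state=np.random.RandomState(0)).as_matrix()
        moved = (R @ pos.T).T + np.array([5.0, -3.0, 1.0])
        e2 = run_engine(
            QMJobSpec("a:p:single-point:toy", _structure(moved), "single-point", "toy"), engine
        ).electronic_energy
        assert e2 == pytest.approx(e1, abs=1e-8)

    def test_gradient_matches_finite_differences(self):
        engine = ToyEngine()
        rng = np.random.default_rng(8)
        pos = rng.normal(scale=1.5, size=(4, 3))
        elements = ["C", "O", "N", "C"]
        bonds = engine._bonds(elements, pos)
        _, grad = engine.energy_and_gradient(elements, pos, bonds)
        h = 1e-6
        for i in range(4):
            for k in range(3):
                p1, p2 = pos.copy(), pos.copy()
                p1[i, k] += h
                p2[i, k] -= h
                e1, _ = engine.energy_and_gradient(elements, p1, bonds)
                e2, _ = engine.energy_and_gradient(elements, p2, bonds)
                assert grad[i, k] == pytest.approx((e1 - e2) / (2 * h), abs=1e-5)

    def test_saddle_search_unsupported(self):
        spec = QMJobSpec("t:p:saddle-search:toy", _structure([(0, 0, 0)]), "saddle-search", "toy")
        with pytest.raises(ValueError, match="does not support"):
            run_engine(spec, ToyEngine())


class TestTSValidation:
    def test_two_imaginary_modes_rejected(self):
        res = QMResult("x", imaginary_mode_count=2)
        with pytest.raises(TSValidationError, match="2 imaginary"):
            res.validate_as_ts()

    def test_unknown_count_warns(self):
        res = QMResult("x", imaginary_mode_count=None)
        with pytest.warns(UserWarning, match="unverified"):
            res.validate_as_ts()

    def test_single_mode_accepted(self):
        QMResult("x", imaginary_mode_count=1).validate_as_ts()


class TestResultsTable:
    def test_21_row_fixture_roundtrip(self, tmp_path):
        results = reference_results()
        assert len(results) == 21  # 7 variants x 3 stationary points
        p = tmp_path / "results.tsv"
        write_results_table(results, p)
        back = parse_results_table(p)
        assert len(back) == 21
        assert back[0].job_id == results[0].job_id
        assert back[3].electronic_energy == pytest.approx(results[3].electronic_energy)

    def test_unconverged_row_retained(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_results_table([QMResult("a:ES:minimize:t", converged=False)], p)
        back = parse_results_table(p)
        assert len(back) == 1 and back[0].converged is False

    def test_duplicate_job_id_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_results_table([QMResult("dup"), QMResult("dup")], p)
        with pytest.raises(ValueError, match="duplicate"):
            parse_results_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("job_id\telectronic_energy\na\t1.0\n")
        with pytest.raises(ValueError, match="missing column"):
            parse_results_table(p)
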