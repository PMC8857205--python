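"""Ensemble metrics: superposition, pairwise RMSD, distances, waters."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from redorlab.ensemble import (
    count_pocket_waters,
    ensemble_distance,
    pairwise_rmsd,
    superpose,
)
from redorlab.structures import (
    AtomSelector,
    Selection,
    StructureEnsemble,
    StructureModel,
    load_ensemble,
    write_ensemble_pdb,
)


def _points_model(model_id, coords):
    m = StructureModel(model_id)
    for i, xyz in enumerate(coords, start=1):
        m.add_atom("A", i, "ALA", "CA", "C", xyz)
    return m


@pytest.fixture
def cloud():
    rng = np.random.default_rng(1)
    return rng.uniform(-5, 5, (12, 3))


class TestSuperpose:
    def test_identical_models_give_zero_rmsd(self, cloud):
        a = _points_model("a", cloud)
        _, _, rmsd = superpose(a, a, Selection())
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_translation_removed(self, cloud):
        a = _points_model("a", cloud)
        b = _points_model("b", cloud + np.array([5.0, 0.0, 0.0]))
        _, _, rmsd = superpose(a, b, Selection())
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rigid_transform_fully_recovered(self, cloud):
        rot = Rotation.from_euler("zyx", [30, 45, 10], degrees=True)
        b_coords = cloud @ rot.as_matrix().T + np.array([1.0, -2.0, 3.0])
        a = _points_model("a", cloud)
        b = _points_model("b", b_coords)
        r, t, rmsd = superpose(a, b, Selection())
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(b_coords @ r.T + t, cloud, atol=1e-6)

    def test_optimum_beats_random_rotations(self, cloud):
        """The fitted RMSD is a lower bound over sampled rigid transforms."""
        rng = np.random.default_rng(2)
        noisy = cloud + rng.normal(0, 0.5, cloud.shape)
        a = _points_model("a", cloud)
        b = _points_model("b", noisy)
        _, _, rmsd = superpose(a, b, Selection())
        ca, cb = cloud.mean(0), noisy.mean(0)
        for quat in Rotation.random(500, rng=3):
            trial = (noisy - cb) @ quat.as_matrix().T + ca
            trial_rmsd = np.sqrt(np.mean(np.sum((cloud - trial) ** 2, axis=1)))
            assert rmsd <= trial_rmsd + 1e-9

    def test_degenerate_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        a = _points_model("a", line)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superpose(a, a, Selection())


class TestPairwiseRmsd:
    def test_identical_models_give_zero(self, cloud):
        ens = StructureEnsemble([_points_model(str(i), cloud) for i in range(4)])
        mean, sd = pairwise_rmsd(ens, Selection())
        assert mean == pytest.approx(0.0, abs=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_perturbation_scale_recovered(self, toy_complex):
        """Pairwise RMSD reflects the generator's per-atom perturbation."""
        mean, _ = pairwise_rmsd(toy_complex.ensemble, Selection.parse("backbone"))
        # independent perturbations of RMS 0.5 A differ by ~0.5*sqrt(2)
        assert 0.4 < mean < 0.9

    def test_mean_invariant_to_model_order(self, cloud):
        rng = np.random.default_rng(4)
        models = [
            _points_model(str(i), cloud + rng.normal(0, 1, cloud.shape))
            for i in range(4)
        ]
        m1, _ = pairwise_rmsd(StructureEnsemble(models), Selection())
        m2, _ = pairwise_rmsd(StructureEnsemble(models[::-1]), Selection())
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_fewer_than_two_models_rejected(self, cloud):
        with pytest.raises(ValueError):
            pairwise_rmsd(StructureEnsemble([_points_model("1", cloud)]), Selection())


class TestEnsembleDistance:
    def _two_atom_ensemble(self, n=3, d=3.0):
        models = []
        for i in range(n):
            m = StructureModel(str(i))
            m.add_atom("A", 1, "ALA", "CA", "C", [0, 0, 0])
            m.add_atom("B", 1, "ALA", "CA", "C", [d, 0, 0])
            models.append(m)
        return StructureEnsemble(models)

    def test_constant_distance_gives_zero_sd(self):
        ens = self._two_atom_ensemble(d=3.0)
        mean, sd = ensemble_distance(
            ens, AtomSelector("A", 1, "CA"), AtomSelector("B", 1, "CA")
        )
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(0.0)

    def test_pair_distance_symmetric(self):
        ens = self._two_atom_ensemble()
        a, b = AtomSelector("A", 1, "CA"), AtomSelector("B", 1, "CA")
        assert ensemble_distance(ens, a, b) == ensemble_distance(ens, b, a)

    def test_min_over_set_matches_brute_force(self, toy_complex):
        p = AtomSelector("L", 1, "P")
        fs = list(toy_complex.fluorine_sites)
        mean, _ = ensemble_distance(toy_complex.ensemble, p, fs, "min_over_b")
        per_model = []
        for model in toy_complex.ensemble:
            pp = model.position(p)
            per_model.append(
                min(np.linalg.norm(pp - model.position(f)) for f in fs)
            )
        assert mean == pytest.approx(np.mean(per_model))

    def test_unresolved_selection_rejected(self):
        ens = self._two_atom_ensemble()
        with pytest.raises(KeyError):
            ensemble_distance(
                ens, AtomSelector("A", 1, "CA"), AtomSelector("Z", 9, "XX")
            )


class TestPocketWaters:
    def test_counts_match_construction(self, toy_complex):
        n = count_pocket_waters(
            toy_complex.ensemble[0],
            Selection(chains={"L"}),
            toy_complex.z_bound_atoms,
        )
        assert n == toy_complex.n_waters_inside

    def test_no_waters_gives_zero(self, cloud):
        m = _points_model("1", cloud)
        m.add_atom("L", 1, "TPP", "P", "P", [0, 0, 0])
        n = count_pocket_waters(
            m,
            Selection(chains={"L"}),
            (AtomSelector("A", 1, "CA"), AtomSelector("A", 2, "CA")),
        )
        assert n == 0

    def test_monotone_in_cutoff(self, toy_complex):
        model = toy_complex.ensemble[0]
        counts = [
            count_pocket_waters(
                model, Selection(chains={"L"}), toy_complex.z_bound_atoms,
                cutoff_angstrom=c,
            )
            for c in (5.0, 10.0, 15.0, 30.0)
        ]
        assert counts == sorted(counts)

    def test_missing_bound_atom_rejected(self, toy_complex):
        with pytest.raises(KeyError):
            count_pocket_waters(
                toy_complex.ensemble[0],
                Selection(chains={"L"}),
                (AtomSelector("Z", 1, "CA"), AtomSelector("Z", 2, "CA")),
            )


class TestPdbRoundTrip:
    def test_write_then_load_preserves_models_and_coords(
        self, toy_complex, tmp_path
    ):
        path = tmp_path / "toy.pdb"
        write_ensemble_pdb(toy_complex.ensemble, path)
        loaded = load_ensemble(path)
        assert len(loaded) == len(toy_complex.ensemble)
        orig = toy_complex.ensemble[0]
        key = orig.atom_keys[0]
        sel = AtomSelector(*key)
        assert np.allclose(
            loaded[0].position(sel), orig.position(sel), atol=1.5e-3
        )

    def test_water_and_ligand_survive_round_trip(self, toy_complex, tmp_path):
        path = tmp_path / "toy.pdb"
        write_ensemble_pdb(toy_complex.ensemble, path)
        loaded = load_ensemble(path)
        n = count_pocket_waters(
            loaded[0],
            Selection(chains={"L"}),
            toy_complex.z_bound_atoms,
        )
        assert n == toy_complex.n_waters_inside
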