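"""Ambiguous restraint construction, violation scoring, disambiguation."""

import numpy as np
import pytest

from redorlab.restraints import (
    AmbiguousRestraint,
    build_restraints,
    disambiguate,
    effective_distance,
    score_structures,
    violation,
)
from redorlab.spinsim import DistanceFit
from redorlab.structures import AtomSelector, StructureEnsemble, StructureModel


def _model(model_id, proton_xyz, fluorine_xyzs):
    m = StructureModel(model_id)
    m.add_atom("A", 1, "ALA", "H", "H", proton_xyz)
    for i, xyz in enumerate(fluorine_xyzs, start=1):
        m.add_atom("L", 1, "TPP", f"F{i}", "F", xyz)
    return m


PROTON = AtomSelector("A", 1, "H")
FLUORINES = tuple(AtomSelector("L", 1, f"F{i}") for i in range(1, 5))


def _restraint(**kw):
    defaults = dict(
        proton_site=PROTON,
        fluorine_sites=FLUORINES,
        kind="measured",
        lower=3.0,
        upper=7.0,
    )
    defaults.update(kw)
    return AmbiguousRestraint(**defaults)


def _model_with_f_distances(model_id, distances):
    """Proton at origin, fluorines on +x at the given distances."""
    return _model(
        model_id,
        [0.0, 0.0, 0.0],
        [[d, 0.0, 0.0] for d in distances],
    )


class TestEffectiveDistance:
    def test_minimum_over_four_fluorines(self):
        m = _model_with_f_distances("1", [5.0, 6.0, 7.0, 8.0])
        assert effective_distance(m, _restraint()) == pytest.approx(5.0)

    def test_assigned_pair_overrides_minimum(self):
        m = _model_with_f_distances("1", [5.0, 6.0, 7.0, 8.0])
        r = _restraint(assigned_fluorine=FLUORINES[2])
        assert effective_distance(m, r) == pytest.approx(7.0)

    def test_missing_atom_error_names_selector(self):
        m = StructureModel("1")
        m.add_atom("A", 1, "ALA", "H", "H", [0, 0, 0])
        with pytest.raises(KeyError, match="L:1:F1"):
            effective_distance(m, _restraint())

    def test_exactly_four_fluorines_required(self):
        with pytest.raises(ValueError):
            AmbiguousRestraint(
                proton_site=PROTON,
                fluorine_sites=FLUORINES[:3],
                kind="measured",
                lower=3.0,
                upper=7.0,
            )


class TestViolation:
    def test_satisfied_restraint_has_zero_violation(self):
        m = _model_with_f_distances("1", [5.0, 6.0, 7.0, 8.0])
        assert violation(m, _restraint(lower=3.0, upper=7.0)) == 0.0

    def test_upper_bound_excess(self):
        m = _model_with_f_distances("1", [6.0, 8.0, 9.0, 10.0])
        assert violation(m, _restraint(lower=3.0, upper=5.0)) == pytest.approx(1.0)

    def test_lower_bound_shortfalls_summed_per_fluorine(self):
        m = _model_with_f_distances("1", [9.0, 10.0, 11.0, 12.0])
        r = _restraint(kind="lower_bound", lower=10.0, upper=float("inf"))
        assert violation(m, r) == pytest.approx(1.0)

    def test_violation_zero_iff_bounds_satisfied(self):
        rng = np.random.default_rng(0)
        r = _restraint(lower=4.0, upper=6.0)
        for _ in range(50):
            dists = np.sort(rng.uniform(2.0, 10.0, 4))
            m = _model_with_f_distances("1", dists)
            v = violation(m, r)
            satisfied = 4.0 <= dists.min() <= 6.0
            assert v >= 0.0
            assert (v == 0.0) == satisfied


class TestScoring:
    def test_all_satisfied_gives_zero_reports_in_input_order(self):
        models = [
            _model_with_f_distances(str(i), [5.0, 6.0, 7.0, 8.0]) for i in (1, 2)
        ]
        reports, rank_sum, rank_count = score_structures(
            StructureEnsemble(models), [_restraint()]
        )
        assert [r.sum_violation for r in reports] == [0.0, 0.0]
        assert rank_sum == [0, 1] and rank_count == [0, 1]

    def test_violating_model_ranked_last_under_both_criteria(self):
        good = _model_with_f_distances("good", [5.0, 6.0, 7.0, 8.0])
        bad = _model_with_f_distances("bad", [8.0, 9.0, 10.0, 11.0])
        reports, rank_sum, rank_count = score_structures(
            StructureEnsemble([bad, good]), [_restraint(lower=3.0, upper=7.0)]
        )
        assert reports[0].sum_violation == pytest.approx(1.0)
        assert rank_sum[0] == 1 and rank_count[0] == 1

    def test_ranking_consistent_under_model_permutation(self):
        rng = np.random.default_rng(3)
        models = [
            _model_with_f_distances(f"m{i}", np.sort(rng.uniform(4, 12, 4)))
            for i in range(6)
        ]
        restraints = [_restraint(lower=6.0, upper=6.5)]
        reports, rank_a, _ = score_structures(StructureEnsemble(models), restraints)
        sums = [r.sum_violation for r in reports]
        assert len(set(sums)) == len(sums)  # distinct, so order is unambiguous
        perm = [models[i] for i in (3, 1, 5, 0, 4, 2)]
        _, rank_b, _ = score_structures(StructureEnsemble(perm), restraints)
        ids_a = [models[i].model_id for i in rank_a]
        ids_b = [perm[i].model_id for i in rank_b]
        assert ids_a == ids_b

    def test_best_of_many_models_found_by_exhaustive_check(self):
        """Ranking agrees with brute-force ordering on a random ensemble."""
        rng = np.random.default_rng(9)
        models = [
            _model_with_f_distances(f"m{i}", np.sort(rng.uniform(3, 12, 4)))
            for i in range(10)
        ]
        restraints = [
            _restraint(lower=4.0, upper=6.0),
            _restraint(kind="lower_bound", lower=10.0, upper=float("inf"),
                       target=None),
        ]
        reports, rank_sum, _ = score_structures(
            StructureEnsemble(models), restraints
        )
        sums = [r.sum_violation for r in reports]
        brute = sorted(range(len(sums)), key=lambda i: (sums[i], i))
        assert rank_sum == brute

    def test_empty_inputs_rejected(self):
        m = _model_with_f_distances("1", [5, 6, 7, 8])
        with pytest.raises(ValueError):
            score_structures(StructureEnsemble([m]), [])


class TestBuildRestraints:
    @staticmethod
    def _site_map(fits):
        return {f.site_id: (PROTON, FLUORINES) for f in fits}

    @staticmethod
    def _fit(site, weak):
        if weak:
            return DistanceFit(site, 12.0, 10.0, 40.0, {}, True)
        return DistanceFit(site, 5.0, 4.0, 6.0, {}, False)

    def test_92_weak_fits_expand_to_368_constraints(self):
        fits = [self._fit(f"w{i}", True) for i in range(92)]
        rs = build_restraints(fits, self._site_map(fits))
        assert len(rs) == 368
        assert all(r.kind == "lower_bound" for r in rs)

    def test_counting_rule_weak_and_measured(self):
        fits = [self._fit("w1", True), self._fit("w2", True), self._fit("m1", False)]
        rs = build_restraints(fits, self._site_map(fits))
        assert len(rs) == 9
        assert sum(r.kind == "measured" for r in rs) == 1

    def test_empty_fits_give_empty_list(self):
        assert build_restraints([], {}) == []

    def test_missing_site_mapping_rejected(self):
        fits = [self._fit("orphan", False)]
        with pytest.raises(KeyError, match="orphan"):
            build_restraints(fits, {})

    def test_measured_bounds_taken_from_fit_interval(self):
        fits = [self._fit("m1", False)]
        (r,) = build_restraints(fits, self._site_map(fits))
        assert (r.lower, r.upper) == (4.0, 6.0)
        assert r.target == 5.0


class TestDisambiguate:
    def test_unique_nearest_fluorine_assigned(self):
        m = _model_with_f_distances("ref", [5.0, 6.0, 7.0, 8.0])
        (r,) = disambiguate([_restraint()], m)
        assert r.assigned_fluorine == FLUORINES[0]

    def test_exact_tie_stays_ambiguous_with_warning(self):
        m = _model(
            "ref", [0, 0, 0],
            [[5, 0, 0], [-5, 0, 0], [0, 7, 0], [0, -8, 0]],
        )
        with pytest.warns(UserWarning, match="tie"):
            (r,) = disambiguate([_restraint()], m)
        assert r.assigned_fluorine is None

    def test_assignment_matches_brute_force_nearest_neighbour(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            fxyz = rng.uniform(-10, 10, (4, 3))
            m = _model("ref", [0, 0, 0], fxyz)
            (r,) = disambiguate([_restraint()], m)
            brute = int(np.argmin(np.linalg.norm(fxyz, axis=1)))
            assert r.assigned_fluorine == FLUORINES[brute]

    def test_disambiguation_preserves_sum_violation_on_reference(self):
        rng = np.random.default_rng(6)
        m = _model("ref", [0, 0, 0], rng.uniform(-9, 9, (4, 3)))
        restraints = [_restraint(lower=4.0, upper=6.0)]
        before = violation(m, restraints[0])
        (after_r,) = disambiguate(restraints, m)
        assert violation(m, after_r) == pytest.approx(before)
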