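"""REDOR simulator: coupling constants, analytic oracle, fitting."""

import numpy as np
import pytest

from redorlab.constants import GAMMA_19F, GAMMA_1H
from redorlab.powder import PowderScheme
from redorlab.spinsim import (
    CurveLibrary,
    RedorCurve,
    RedorSequenceParams,
    SpinPairGeometry,
    build_curve_library,
    dipolar_coupling,
    fit_distance,
    redor_universal_curve,
    simulate_redor,
    snap_to_rotor_cycles,
)


class TestDipolarCoupling:
    def test_hand_computed_hf_coupling_at_3p8_angstrom(self):
        # (mu0/4pi) * gH * gF * hbar / (2 pi r^3) evaluated by hand: 2.06 kHz
        d = dipolar_coupling(SpinPairGeometry(3.8))
        assert d == pytest.approx(2060.6, abs=1.0)

    def test_inverse_cube_scaling(self):
        d1 = dipolar_coupling(SpinPairGeometry(1.0))
        d2 = dipolar_coupling(SpinPairGeometry(2.0))
        assert d2 / d1 == pytest.approx(1.0 / 8.0, rel=1e-12)

    def test_vanishes_at_large_distance(self):
        assert dipolar_coupling(SpinPairGeometry(1e4)) < 1e-6

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_distance_rejected(self, bad):
        with pytest.raises(ValueError):
            SpinPairGeometry(bad)


class TestUniversalCurve:
    def test_zero_coupling_gives_zero_dephasing(self):
        assert redor_universal_curve(0.0, 1.0) == pytest.approx(0.0, abs=1e-9)
        assert redor_universal_curve(500.0, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_long_time_asymptote_is_unity(self):
        lam = np.linspace(5.0, 50.0, 200)
        vals = redor_universal_curve(lam, 1.0)
        assert np.all(np.abs(vals - 1.0) < 0.1)
        assert np.mean(vals[-50:]) == pytest.approx(1.0, abs=0.02)

    def test_overshoot_bounded(self):
        lam = np.linspace(0.0, 10.0, 2000)
        vals = redor_universal_curve(lam, 1.0)
        assert np.all(vals >= -1e-9)
        assert np.all(vals <= 1.06)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            redor_universal_curve(-1.0, 1.0)


class TestSimulator:
    def test_ideal_pulse_matches_analytic_curve(self, ideal_seq):
        """Numerical powder propagation vs Bessel-form universal curve."""
        seq = RedorSequenceParams(
            powder=PowderScheme("spiral", 512, 16), csa_span_ppm=0.0
        )
        for r in (4.0, 5.0, 7.0, 9.0, 12.0):
            geom = SpinPairGeometry(r)
            sim = simulate_redor(geom, seq).s_ratio
            ana = 1.0 - redor_universal_curve(
                dipolar_coupling(geom), np.array(seq.mixing_times_s)
            )
            assert np.max(np.abs(sim - ana)) < 1e-3

    def test_zero_coupling_limit_no_dephasing(self, ideal_seq):
        s = simulate_redor(SpinPairGeometry(40.0), ideal_seq).s_ratio
        assert np.allclose(s, 1.0, atol=1e-3)

    def test_dephasing_monotone_in_coupling_at_fixed_time(self, ideal_library):
        """At 1.68 ms the 3.8 A curve dephases more than the 9.0 A curve."""
        s_38 = ideal_library.curve(3.8).s_ratio[0]
        s_90 = ideal_library.curve(9.0).s_ratio[0]
        assert s_38 < s_90

    def test_finite_pulse_limit_reduces_to_ideal(self):
        ps = PowderScheme("spiral", 64, 8)
        seq_fp = RedorSequenceParams(
            powder=ps, csa_span_ppm=0.0, pulse_length_deph_s=2e-7,
            flip_angle_grid_deg=(180.0,),
        )
        seq_id = RedorSequenceParams(powder=ps, csa_span_ppm=0.0)
        g = SpinPairGeometry(6.0)
        s_fp = simulate_redor(g, seq_fp).s_ratio
        s_id = simulate_redor(g, seq_id).s_ratio
        assert np.max(np.abs(s_fp - s_id)) < 2e-3

    def test_powder_convergence_on_doubling(self):
        vals = {}
        for n in (256, 512):
            seq = RedorSequenceParams(
                powder=PowderScheme("spiral", n, 16), csa_span_ppm=0.0
            )
            vals[n] = simulate_redor(SpinPairGeometry(6.0), seq).s_ratio
        assert np.max(np.abs(vals[256] - vals[512])) < 5e-3

    def test_flip_angle_weights_normalized(self):
        for grid in [(180.0,), tuple(range(180, 144, -5)), (180.0, 160.0)]:
            seq = RedorSequenceParams(flip_angle_grid_deg=grid)
            assert seq.flip_angle_weights().sum() == pytest.approx(1.0)

    def test_unsynchronized_mixing_time_rejected(self):
        with pytest.raises(ValueError, match="rotor"):
            RedorSequenceParams(mixing_times_s=(1.01e-3,))

    def test_snap_to_rotor_cycles(self):
        snapped = snap_to_rotor_cycles([1.68e-3, 2.53e-3, 3.78e-3], 38_000.0)
        cycles = [round(t * 38_000.0) for t in snapped]
        assert cycles == [64, 96, 144]


class TestCurveLibrary:
    def test_default_grid_has_121_entries(self, ideal_library):
        assert len(ideal_library.distances) == 121
        assert ideal_library.distances[0] == pytest.approx(3.0)
        assert ideal_library.distances[-1] == pytest.approx(15.0)

    def test_library_consistent_with_direct_simulation(
        self, ideal_library, ideal_seq
    ):
        direct = simulate_redor(SpinPairGeometry(5.0), ideal_seq).s_ratio
        assert np.array_equal(ideal_library.curve(5.0).s_ratio, direct)

    def test_cache_round_trip_bitwise(self, ideal_library, tmp_path):
        path = tmp_path / "lib.npz"
        ideal_library.save(path)
        loaded = CurveLibrary.load(path)
        assert np.array_equal(loaded.s_matrix, ideal_library.s_matrix)
        assert np.array_equal(loaded.distances, ideal_library.distances)
        assert loaded.params_hash == ideal_library.params_hash

    def test_empty_grid_rejected(self, ideal_seq):
        with pytest.raises(ValueError):
            build_curve_library(ideal_seq, grid=np.array([]))


class TestFitDistance:
    def test_noiseless_round_trip(self, ideal_library):
        curve = ideal_library.curve(5.0)
        fit = fit_distance(curve, ideal_library)
        assert fit.best_distance == pytest.approx(5.0)
        assert fit.lower <= 5.0 <= fit.upper
        assert not fit.is_lower_bound_only

    def test_flat_curve_reported_as_lower_bound(self, ideal_library):
        curve = RedorCurve(
            "flat", ideal_library.mixing_times_s, np.ones(3)
        )
        fit = fit_distance(curve, ideal_library)
        assert fit.is_lower_bound_only
        assert fit.lower == 10.0
        assert fit.upper == 40.0

    def test_overlap_widens_lower_uncertainty(self, ideal_library):
        base = ideal_library.curve(5.0)
        plain = fit_distance(base, ideal_library)
        overlapped = RedorCurve(
            "ov", base.mixing_times_s, base.s_ratio, overlapped=True
        )
        wide = fit_distance(overlapped, ideal_library)
        assert wide.lower <= plain.lower
        assert wide.upper == plain.upper

    def test_best_distance_is_grid_minimum(self, ideal_library):
        rng = np.random.default_rng(7)
        curve = RedorCurve(
            "noisy",
            ideal_library.mixing_times_s,
            ideal_library.curve(6.0).s_ratio + rng.normal(0, 0.05, 3),
        )
        fit = fit_distance(curve, ideal_library)
        prof = fit.rmsd_profile
        assert prof[fit.best_distance] == pytest.approx(min(prof.values()))

    def test_unknown_mixing_time_rejected(self, ideal_library):
        curve = RedorCurve("bad", np.array([9.9e-3]), np.array([0.5]))
        with pytest.raises(ValueError, match="mixing time"):
            fit_distance(curve, ideal_library)

    def test_simulate_then_fit_recovers_within_bounds_under_noise(
        self, ideal_library
    ):
        """Truth lies inside the reported interval for >=95% of replicates."""
        rng = np.random.default_rng(42)
        n_rep, hits = 200, 0
        for _ in range(n_rep):
            true_d = float(
                ideal_library.distances[
                    np.argmin(
                        np.abs(ideal_library.distances - rng.uniform(3.5, 8.5))
                    )
                ]
            )
            noisy = ideal_library.curve(true_d).s_ratio + rng.normal(0, 0.05, 3)
            fit = fit_distance(
                RedorCurve("rt", ideal_library.mixing_times_s, noisy),
                ideal_library,
            )
            if fit.lower <= true_d <= fit.upper:
                hits += 1
        assert hits / n_rep >= 0.95
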