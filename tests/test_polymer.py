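"""Worm-like-chain mechanics: closed forms, inversions, contour arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from synaptrap.polymer import (
    ConstructState,
    DsParams,
    SsParams,
    ThermalContext,
    ds_contour_from_bp,
    expected_contour_change,
    ext_wlc_extension,
    ext_wlc_force,
    fit_segment_contour,
    hairpin_release,
    hybrid_extension,
    hybrid_force,
    ms_wlc_force,
    ss_wlc_extension,
    tether_states,
)


def implicit_ext_wlc_x(F, ds, th):
    """Bisection oracle: solve the implicit extensible WLC for x at force F,
    independent of the Cardano inversion."""
    def resid(x):
        l = x / ds.contour_length - F / ds.stretch_modulus
        return th.kBT / ds.persistence_length * (
            1.0 / (4.0 * (1.0 - l) ** 2) - 0.25 + l) - F
    hi = ds.contour_length * (1.0 + F / ds.stretch_modulus) * 0.999999
    return brentq(resid, 0.0, hi, xtol=1e-10)


class TestSsChain:
    def test_zero_extension_zero_force(self, ss100, thermal):
        assert ms_wlc_force(0.0, ss100, thermal) == 0.0

    def test_half_extension_value(self, ss100, thermal):
        # kBT/pss * (1/(4*(1/2)^2) - 1/4 + 1/2) = (4.11/2) * 1.25
        assert ms_wlc_force(50.0, ss100, thermal) == pytest.approx(2.56875,
                                                                   abs=1e-9)

    def test_monotone_in_extension(self, ss100, thermal):
        x = np.linspace(0.0, 99.0, 300)
        f = ms_wlc_force(x, ss100, thermal)
        assert np.all(np.diff(f) > 0)

    @pytest.mark.parametrize("x", [-1.0, 100.0, 150.0])
    def test_domain_errors(self, x, ss100, thermal):
        with pytest.raises(ValueError):
            ms_wlc_force(x, ss100, thermal)

    def test_inverse_of_half_extension(self, ss100, thermal):
        assert ss_wlc_extension(2.56875, ss100, thermal) == pytest.approx(
            50.0, abs=1e-9)

    def test_zero_force_zero_extension(self, ss100, thermal):
        assert ss_wlc_extension(0.0, ss100, thermal) == 0.0

    def test_zero_length_segment(self, thermal):
        ss = SsParams(0.0)
        for F in (0.0, 5.0, 40.0):
            assert ss_wlc_extension(F, ss, thermal) == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(F=st.floats(0.01, 60.0))
    def test_round_trip(self, F, thermal):
        ss = SsParams(100.0)
        x = ss_wlc_extension(F, ss, thermal)
        assert ms_wlc_force(x, ss, thermal) == pytest.approx(F, abs=1e-6)


class TestDsChain:
    def test_zero(self, handle_params, thermal):
        assert ext_wlc_extension(0.0, handle_params, thermal) == 0.0
        assert ext_wlc_force(0.0, handle_params, thermal) == 0.0

    def test_marko_siggia_limit(self, thermal):
        # K -> inf at half extension: F = 1.25 kBT / p
        ds = DsParams(1700.0, 50.0, 1e12)
        assert ext_wlc_force(850.0, ds, thermal) == pytest.approx(
            1.25 * 4.11 / 50.0, rel=1e-6)

    def test_extension_bounded_by_enthalpic_limit(self, handle_params,
                                                  thermal):
        for F in (0.5, 10.0, 40.0):
            x = ext_wlc_extension(F, handle_params, thermal)
            assert x < handle_params.contour_length * (
                1.0 + F / handle_params.stretch_modulus)

    def test_cardano_matches_bisection_oracle(self, handle_params, thermal):
        for F in np.linspace(0.1, 60.0, 60):
            x_oracle = implicit_ext_wlc_x(F, handle_params, thermal)
            x_cardano = ext_wlc_extension(F, handle_params, thermal)
            assert abs(x_cardano - x_oracle) < 0.1

    def test_round_trip_force(self, handle_params, thermal):
        for F in np.linspace(0.1, 60.0, 40):
            x = ext_wlc_extension(F, handle_params, thermal)
            assert ext_wlc_force(x, handle_params, thermal) == pytest.approx(
                F, abs=1e-6)

    def test_negative_force_rejected(self, handle_params, thermal):
        with pytest.raises(ValueError):
            ext_wlc_extension(-1.0, handle_params, thermal)


class TestHybrid:
    def test_offsets_only_at_zero_force(self, handle_params, thermal):
        state = ConstructState(handle_params, SsParams(0.0),
                               (("synapse", 10.5),))
        assert hybrid_extension(0.0, state, thermal) == pytest.approx(10.5)
        assert hybrid_force(10.5, state, thermal) == 0.0

    def test_series_sum_definition(self, handle_params, ss100, thermal):
        state = ConstructState(handle_params, ss100, (("hp", 2.0),))
        total = hybrid_extension(10.0, state, thermal)
        parts = (ext_wlc_extension(10.0, handle_params, thermal)
                 + ss_wlc_extension(10.0, ss100, thermal) + 2.0)
        assert total == pytest.approx(parts, abs=1e-9)

    def test_round_trip(self, handle_params, ss100, thermal):
        state = ConstructState(handle_params, ss100)
        x = hybrid_extension(5.0, state, thermal)
        assert hybrid_force(x, state, thermal) == pytest.approx(5.0, abs=1e-6)

    def test_monotone(self, handle_params, ss100, thermal):
        state = ConstructState(handle_params, ss100)
        F = np.linspace(0.0, 50.0, 200)
        x = hybrid_extension(F, state, thermal)
        assert np.all(np.diff(x) > 0)

    def test_below_offsets_rejected(self, handle_params, thermal):
        state = ConstructState(handle_params, SsParams(0.0),
                               (("synapse", 10.5),))
        with pytest.raises(ValueError):
            hybrid_force(5.0, state, thermal)


class TestContourArithmetic:
    def test_disassembly_fingerprint(self, states):
        # (114 nt x 0.68 + 2 x 2 nm) - 10.5 nm = 71 nm
        dl = expected_contour_change(states["synapse"],
                                     states["hairpin_bound"])
        assert dl == pytest.approx(71.0, abs=0.05)

    def test_hairpin_bound_end_to_end(self, states):
        assert states["hairpin_bound"].contour_coordinate == pytest.approx(
            81.5, abs=0.05)

    def test_identical_states_zero(self, states):
        assert expected_contour_change(states["synapse"],
                                       states["synapse"]) == 0.0

    def test_antisymmetry(self, states):
        names = list(states)
        for a in names:
            for b in names:
                assert expected_contour_change(states[a], states[b]) == \
                    pytest.approx(-expected_contour_change(states[b],
                                                           states[a]))

    def test_single_hairpin_release(self):
        for n in (20, 63, 114):
            assert hairpin_release(n) == pytest.approx(0.68 * n - 2.0)

    def test_five_kbp_handle_contour(self):
        assert ds_contour_from_bp(5000) == pytest.approx(1700.0)

    def test_substate_contour_change(self, states):
        dl = expected_contour_change(states["synapse"], states["substate"])
        assert dl == pytest.approx(44.6, abs=1e-9)


class TestSegmentFit:
    def make_points(self, state, thermal, n=40, fmin=3.0, fmax=25.0):
        F = np.linspace(fmin, fmax, n)
        return np.column_stack([hybrid_extension(F, state, thermal), F])

    def test_recovers_known_ss_contour(self, states, thermal):
        truth = states["hairpin_bound"]
        pts = self.make_points(truth, thermal)
        template = tether_states(spacer_nt=60)["hairpin_bound"]
        fit = fit_segment_contour(pts, template, free=("ss",), th=thermal)
        assert fit.success
        assert fit.state.ss.contour_length == pytest.approx(
            truth.ss.contour_length, abs=0.5)
        assert fit.rms_residual < 1e-6

    def test_recovers_spacer_from_zero_template(self, states, thermal):
        # released 114-nt spacer: fitted ssDNA contour = 77.5 nm
        truth = states["hairpin_bound"]
        pts = self.make_points(truth, thermal)
        template = tether_states(spacer_nt=0)["hairpin_bound"]
        fit = fit_segment_contour(pts, template, free=("ss",), th=thermal)
        assert fit.state.ss.contour_length == pytest.approx(77.52, abs=0.5)

    def test_too_few_points_rejected(self, states, thermal):
        pts = self.make_points(states["hairpin_bound"], thermal, n=4)
        with pytest.raises(ValueError):
            fit_segment_contour(pts, states["hairpin_bound"], th=thermal)

    def test_narrow_force_span_rejected(self, states, thermal):
        pts = self.make_points(states["hairpin_bound"], thermal, n=10,
                               fmin=10.0, fmax=11.0)
        with pytest.raises(ValueError):
            fit_segment_contour(pts, states["hairpin_bound"], th=thermal)


@settings(derandomize=True, max_examples=30)
@given(lss=st.floats(10.0, 300.0), pss=st.floats(0.5, 5.0),
       F=st.floats(0.1, 50.0))
def test_ss_inversion_property(lss, pss, F):
    """Exact cubic inversion round-trips for arbitrary valid parameters."""
    th = ThermalContext()
    ss = SsParams(lss, pss)
    x = ss_wlc_extension(F, ss, th)
    assert 0 <= x < lss
    assert ms_wlc_force(x, ss, th) == pytest.approx(F, rel=1e-9, abs=1e-9)
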