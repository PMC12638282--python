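"""Latent-state solver: Srel forms, trajectories, RRS-weighted dose, closed forms."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flash_esd import (
    ESDParameters,
    ModelVariant,
    make_constant,
    make_pulsed,
    make_split,
    rrs,
    rrs_closed_form_constant_rate,
    rrs_weighted_dose,
    set_parameters_map,
    solve_state,
    srel,
)
from flash_esd.core import ALL_VARIANTS


class TestSrel:
    @pytest.mark.parametrize(
        "rrs_form,q,smin,shape,expected",
        [
            ("RRS1", 0.5, 0.65, None, 1.0),
            ("RRS1", 0.0, 0.65, None, 0.65),        # Theta(0) = 0
            ("RRS3", 0.5, 0.5, 1.0, 5.0 / 6.0),
            ("RRS2", 0.3, 0.6, 1.0, 0.72),
        ],
    )
    def test_values(self, rrs_form, q, smin, shape, expected):
        variant = ModelVariant("ESD1", rrs_form)
        params = ESDParameters(g=1.0, r=0.1, smin=smin, shape=shape)
        assert srel(q, variant, params) == pytest.approx(expected)

    @pytest.mark.parametrize("rrs_form,shape", [("RRS1", None), ("RRS2", 2.0), ("RRS3", 0.7)])
    def test_endpoints(self, rrs_form, shape):
        variant = ModelVariant("ESD1", rrs_form)
        params = ESDParameters(g=1.0, r=0.1, smin=0.55, shape=shape)
        assert srel(params.q0, variant, params) == pytest.approx(1.0)
        assert srel(0.0, variant, params) == pytest.approx(0.55)

    def test_out_of_range_q(self):
        variant = ModelVariant("ESD1", "RRS1")
        params = ESDParameters(g=1.0, r=0.1, smin=0.5)
        with pytest.raises(ValueError):
            srel(1.5, variant, params)
        with pytest.raises(ValueError):
            srel(-0.5, variant, params)

    def test_missing_shape(self):
        with pytest.raises(ValueError, match="shape"):
            srel(0.5, ModelVariant("ESD1", "RRS2"), ESDParameters(g=1, r=0.1, smin=0.5))


class TestVariant:
    def test_rejects_degenerate_pair(self):
        with pytest.raises(ValueError, match="degenerate"):
            ModelVariant("ESD2", "RRS1")

    def test_free_parameter_counts(self):
        assert ModelVariant("ESD1", "RRS1").n_free_params == 3
        assert ModelVariant("ESD3", "RRS1").n_free_params == 3
        assert ModelVariant("ESD1", "RRS2").n_free_params == 4
        assert ModelVariant("ESD2", "RRS3").n_free_params == 4

    def test_eight_variants(self):
        assert len(ALL_VARIANTS) == 8

    def test_from_string_roundtrip(self):
        assert str(ModelVariant.from_string("ESD3_RRS2")) == "ESD3_RRS2"
        with pytest.raises(ValueError):
            ModelVariant.from_string("ESD9_RRS1")


class TestSolveState:
    def test_no_depletion_below_recovery_threshold(self, best_params):
        # g*Ddot < r: the pool never empties and the dose is unweighted
        prof = make_constant(22.0, 0.11)
        # ESD1: discontinuous recovery beats depletion, Q pinned at Q0
        traj1 = solve_state(prof, ModelVariant("ESD1", "RRS1"), best_params)
        assert np.all(traj1.q == best_params.q0)
        # ESD3: proportional recovery settles Q at Q0 - g*Ddot/r, still > 0
        traj3 = solve_state(prof, ModelVariant("ESD3", "RRS1"), best_params)
        q_eq = best_params.q0 - best_params.g * 0.11 / best_params.r
        assert traj3.q[-1] == pytest.approx(q_eq, rel=1e-6)
        for traj in (traj1, traj3):
            assert np.allclose(traj.srel, 1.0)
            assert rrs_weighted_dose(traj) == pytest.approx(prof.total_dose, rel=1e-12)

    def test_esd1_linear_depletion_time(self, esd1_rrs1, best_params):
        prof = make_constant(37.0, 110.0)
        traj = solve_state(prof, esd1_rrs1, best_params)
        t0 = 1.0 / (0.22 * 110.0 - 0.29)
        assert traj.times[1] == pytest.approx(t0, rel=1e-12)
        assert traj.q[1] == 0.0
        assert traj.q[-1] == 0.0  # slides at depletion for the rest

    def test_esd2_exponential_and_never_depletes(self, best_params):
        variant = ModelVariant("ESD2", "RRS2")
        params = ESDParameters(g=0.22, r=0.29, smin=0.65, shape=1.0)
        rate, dose = 2.0, 10.0
        traj = solve_state(make_constant(dose, rate), variant, params)
        k = params.g * rate + params.r
        q_eq = params.r * params.q0 / k
        expected = q_eq + (params.q0 - q_eq) * math.exp(-k * dose / rate)
        assert traj.q[-1] == pytest.approx(expected, rel=1e-12)
        assert np.all(traj.q > 0)

    def test_trajectory_invariants_on_suite(self, default_suite, best_params):
        params4 = ESDParameters(g=0.22, r=0.29, smin=0.65, shape=1.3)
        for prof in default_suite[::5]:
            for variant in ALL_VARIANTS:
                p = best_params if not variant.needs_shape else params4
                traj = solve_state(prof, variant, p)
                assert np.all(traj.q >= 0) and np.all(traj.q <= p.q0)
                assert np.all(traj.srel >= p.smin - 1e-12)
                assert np.all(traj.srel <= 1 + 1e-12)
                assert np.all(np.diff(traj.cumulative_drrs) >= -1e-12)
                final = traj.cumulative_drrs[-1]
                d = prof.total_dose
                assert p.smin * d - 1e-9 <= final <= d + 1e-9


class TestRRSWeightedDose:
    def test_saturated_high_rate_delivery(self, esd1_rrs1, best_params):
        traj = solve_state(make_constant(37.0, 110.0), esd1_rrs1, best_params)
        d_before = 110.0 / (0.22 * 110.0 - 0.29)  # dose until depletion
        expected = d_before + 0.65 * (37.0 - d_before)
        assert rrs_weighted_dose(traj) == pytest.approx(expected, rel=1e-12)
        assert rrs_weighted_dose(traj) == pytest.approx(25.660, abs=5e-4)

    def test_short_exposure_is_unweighted(self, esd1_rrs1, best_params):
        # 4 Gy at 110 Gy/s: exposure shorter than the depletion time
        prof = make_constant(4.0, 110.0)
        assert rrs(prof, esd1_rrs1, best_params) == pytest.approx(1.0, rel=1e-12)

    def test_floor(self, esd1_rrs1, best_params, default_suite):
        for prof in default_suite[::7]:
            value = rrs(prof, esd1_rrs1, best_params)
            assert best_params.smin - 1e-12 <= value <= 1 + 1e-12


class TestClosedForm:
    def test_matches_numeric_on_grid(self, esd1_rrs1):
        # reduced version of the acceptance grid
        for g, r, smin, dose, rate in itertools.product(
            [0.1, 0.3], [0.0, 0.3, 1.0], [0.5, 0.8], [5.0, 40.0], [0.3, 10.0, 110.0]
        ):
            params = ESDParameters(g=g, r=r, smin=smin)
            numeric = rrs(make_constant(dose, rate), esd1_rrs1, params)
            closed = rrs_closed_form_constant_rate(dose, rate, params)
            assert numeric == pytest.approx(closed, abs=1e-9)

    def test_below_threshold_branch(self):
        params = ESDParameters(g=0.22, r=0.29, smin=0.65)
        assert rrs_closed_form_constant_rate(3.0, 110.0, params) == 1.0
        # g*rate <= r: no depletion at any dose
        assert rrs_closed_form_constant_rate(500.0, 1.0, params) == 1.0

    def test_example_values(self):
        params = ESDParameters(g=0.22, r=0.29, smin=0.65)
        assert rrs_closed_form_constant_rate(37.0, 110.0, params) == pytest.approx(
            0.35 * 110.0 / (37.0 * 23.91) + 0.65, rel=1e-9
        )
        params0 = ESDParameters(g=0.22, r=0.0, smin=0.65)
        assert rrs_closed_form_constant_rate(10.0, 5.0, params0) == pytest.approx(
            0.35 / (10.0 * 0.22) + 0.65, rel=1e-12
        )

    def test_wrong_variant_rejected(self, best_params):
        with pytest.raises(ValueError, match="ESD1_RRS1"):
            rrs_closed_form_constant_rate(
                10.0, 5.0, best_params, variant=ModelVariant("ESD3", "RRS1")
            )


class TestMonotonicity:
    def test_rrs_non_increasing_in_dose_rate(self, esd1_rrs1, best_params):
        rates = np.geomspace(0.05, 300.0, 40)
        values = [rrs(make_constant(30.0, rate), esd1_rrs1, best_params) for rate in rates]
        assert np.all(np.diff(values) <= 1e-12)

    def test_rrs_non_increasing_in_dose_saturating_to_smin(self, esd1_rrs1, best_params):
        doses = np.geomspace(1.0, 5000.0, 50)
        values = [rrs(make_constant(d, 110.0), esd1_rrs1, best_params) for d in doses]
        assert np.all(np.diff(values) <= 1e-12)
        assert values[-1] == pytest.approx(best_params.smin, abs=1e-3)


class TestSETMap:
    def test_negligible_recovery(self):
        params = ESDParameters(g=0.22, r=0.0, smin=0.65)
        fmf_min, d_t = set_parameters_map(params)
        assert fmf_min == 0.65
        assert d_t == pytest.approx(1.0 / 0.22)

    def test_with_recovery_at_rate(self):
        params = ESDParameters(g=0.22, r=0.29, smin=0.65)
        fmf_min, d_t = set_parameters_map(params, dose_rate=110.0)
        assert fmf_min == 0.65
        assert d_t == pytest.approx(110.0 / (0.22 * 110.0 - 0.29))

    def test_no_depletion_regime_is_an_error(self):
        params = ESDParameters(g=0.22, r=0.29, smin=0.65)
        with pytest.raises(ValueError, match="depletion"):
            set_parameters_map(params, dose_rate=1.0)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    dose=st.floats(1.0, 60.0),
    rate=st.floats(0.05, 150.0),
    g=st.floats(0.05, 0.5),
    r=st.floats(0.0, 1.5),
    smin=st.floats(0.3, 0.95),
)
def test_closed_form_equals_solver_property(dose, rate, g, r, smin):
    variant = ModelVariant("ESD1", "RRS1")
    params = ESDParameters(g=g, r=r, smin=smin)
    numeric = rrs(make_constant(dose, rate), variant, params)
    assert numeric == pytest.approx(
        rrs_closed_form_constant_rate(dose, rate, params), abs=1e-9
    )
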