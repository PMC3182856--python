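import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lsrqs import (
    KineticParameters,
    KnockoutSet,
    ModelSpec,
    ModelVariant,
    promoter_activity,
    rhs,
    integrate_timecourse,
)
from lsrqs.model import STATE_VARS, initial_state, knockouts_from_label, scenario_label

IDX = {n: i for i, n in enumerate(STATE_VARS)}


class TestPromoterActivity:
    def test_zero_repressors_gives_kop(self, defaults):
        assert promoter_activity(0.0, 0.0, defaults, ModelVariant.REG_BINDING) == 7.0

    def test_half_maximal_at_k1(self, defaults):
        for n in (1.0, 2.0, 4.0):
            p = defaults.replace(nOP=n)
            assert promoter_activity(p.k1, 0.0, p, "first") == pytest.approx(p.k_op / 2)

    def test_full_repression_limit(self, defaults):
        assert promoter_activity(1e12, 0.0, defaults, "first") == pytest.approx(0.0, abs=1e-30)

    def test_reg_variant_multiplies_second_factor(self, defaults):
        base = promoter_activity(1.0, 0.0, defaults, "reg_binding")
        with_g = promoter_activity(1.0, 65.0, defaults, "reg_binding")
        assert with_g == pytest.approx(base / 2)

    def test_first_variant_ignores_g(self, defaults):
        assert promoter_activity(1.0, 1e6, defaults, "first") == promoter_activity(
            1.0, 0.0, defaults, "first"
        )

    def test_negative_input_rejected(self, defaults):
        with pytest.raises(ValueError):
            promoter_activity(-1.0, 0.0, defaults)
        with pytest.raises(ValueError):
            promoter_activity(0.0, -1.0, defaults)

    def test_zero_k1_with_repressor_rejected(self, defaults):
        with pytest.raises(ValueError):
            promoter_activity(1.0, 0.0, defaults.replace(k1=0.0))

    @given(
        r1=st.floats(0.0, 100.0),
        r2=st.floats(0.0, 100.0),
        g=st.floats(0.0, 100.0),
        k1=st.floats(0.01, 10.0),
        n=st.floats(1.0, 6.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_decreasing_in_R(self, r1, r2, g, k1, n):
        lo, hi = sorted((r1, r2))
        p = KineticParameters(k1=k1, nOP=n)
        a_lo = promoter_activity(lo, g, p, "reg_binding")
        a_hi = promoter_activity(hi, g, p, "reg_binding")
        assert a_hi <= a_lo + 1e-12

    @given(g1=st.floats(0.0, 500.0), g2=st.floats(0.0, 500.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_G(self, defaults, g1, g2):
        lo, hi = sorted((g1, g2))
        assert promoter_activity(0.5, hi, defaults, "reg_binding") <= promoter_activity(
            0.5, lo, defaults, "reg_binding"
        ) + 1e-12


class TestRhs:
    def test_all_zero_state_structure(self, defaults, intact_spec):
        dy = rhs(np.zeros(9), defaults, intact_spec)
        # only synthesis terms fire from the empty state
        assert dy[IDX["OP"]] == pytest.approx(defaults.k_op)
        assert dy[IDX["G"]] == pytest.approx(defaults.k_op)
        assert dy[IDX["Y"]] == pytest.approx(defaults.k_op)
        assert dy[IDX["R"]] == pytest.approx(defaults.k_r)
        for name in ("Ap", "U", "Aout", "C_R", "C_G"):
            assert dy[IDX[name]] == 0.0

    def test_alternative_flux_only(self, defaults, intact_spec):
        state = np.zeros(9)
        state[IDX["Aout"]] = 10.0
        dy = rhs(state, defaults, intact_spec)
        assert dy[IDX["Aout"]] == pytest.approx(-defaults.k_f * 10.0)

    def test_hand_computed_vector(self, defaults, intact_spec):
        # independent hand evaluation at OP=1, G=0, R=1, Ap=1, Aout=10:
        #   P   = 7/(1+(1/0.2)^4) = 7/626
        #   dOP = P - 0.02
        #   dG  = P
        #   dR  = 2/(1+(1/0.1)^4) - 0.02 - 0.05*1*1
        #   dAp = (0.01*1+0.01)*10 - 0.05
        #   dAout = -0.2, dC_R = 0.05, dC_G = 0, dY = P
        state = np.zeros(9)
        state[IDX["OP"]], state[IDX["R"]] = 1.0, 1.0
        state[IDX["Ap"]], state[IDX["Aout"]] = 1.0, 10.0
        dy = rhs(state, defaults, intact_spec)
        P = 7.0 / 626.0
        expected = {
            "OP": P - 0.02,
            "G": P,
            "R": 2.0 / 10001.0 - 0.02 - 0.05,
            "Ap": 0.2 - 0.05,
            "U": 0.0,
            "Aout": -0.2,
            "C_R": 0.05,
            "C_G": 0.0,
            "Y": P,
        }
        for name, value in expected.items():
            assert dy[IDX[name]] == pytest.approx(value, rel=1e-12), name

    def test_nonfinite_state_raises(self, defaults, intact_spec):
        from lsrqs.model import apply_knockouts

        f = apply_knockouts(intact_spec)
        state = np.zeros(9)
        state[0] = np.nan
        with pytest.raises(FloatingPointError):
            f(0.0, state)

    def test_inadmissible_params_rejected(self, intact_spec):
        bad = KineticParameters(k1=-1.0)
        with pytest.raises(ValueError, match="k1"):
            rhs(np.zeros(9), bad, intact_spec)


class TestKnockouts:
    def test_lsrR_knockout_removes_repressor(self, defaults):
        spec = ModelSpec(ModelVariant.REG_BINDING, KnockoutSet(lsrR=True), defaults)
        traj = integrate_timecourse(spec, 40.0)
        assert np.all(traj.species("R") == 0.0)

    def test_lsrK_knockout_blocks_phosphorylation(self, defaults):
        spec = ModelSpec(ModelVariant.REG_BINDING, KnockoutSet(lsrK=True), defaults)
        traj = integrate_timecourse(spec, 40.0)
        assert np.all(traj.species("Ap") == 0.0)
        assert traj.species("U")[-1] > 0  # flux routed to the inert pool

    def test_lsrK_knockout_dose_decoupled(self, defaults):
        spec = ModelSpec(ModelVariant.REG_BINDING, KnockoutSet(lsrK=True), defaults)
        t1 = integrate_timecourse(spec, 1.0)
        t40 = integrate_timecourse(spec, 40.0)
        np.testing.assert_allclose(t1.reporter, t40.reporter, rtol=1e-6, atol=1e-9)

    def test_operon_knockout_aout_closed_form(self, defaults):
        # with the transporter gone the external pool drains through the
        # alternative path only: Aout(t) = A0 * exp(-k_f t)
        spec = ModelSpec(ModelVariant.REG_BINDING, KnockoutSet(lsr_operon=True), defaults)
        traj = integrate_timecourse(spec, 10.0)
        expected = 10.0 * np.exp(-defaults.k_f * traj.times)
        np.testing.assert_allclose(traj.species("Aout"), expected, rtol=1e-6)

    def test_operon_knockout_keeps_reporter(self, defaults):
        spec = ModelSpec(ModelVariant.REG_BINDING, KnockoutSet(lsr_operon=True), defaults)
        traj = integrate_timecourse(spec, 40.0)
        assert np.all(traj.species("OP") == 0.0)
        assert np.all(traj.species("G") == 0.0)
        assert traj.reporter.max() > 0  # promoter fusion still reports

    def test_unknown_knockout_name(self):
        with pytest.raises(ValueError, match="luxS"):
            KnockoutSet.from_names(["luxS"])

    def test_scenario_labels_round_trip(self):
        for ko in (
            KnockoutSet(),
            KnockoutSet(lsrR=True),
            KnockoutSet(lsr_operon=True, lsrK=True),
        ):
            assert knockouts_from_label(scenario_label(ko)) == ko


class TestInvariants:
    @pytest.mark.parametrize("dose", [0.0, 1.0, 40.0])
    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_non_negativity(self, defaults, variant, dose):
        traj = integrate_timecourse(ModelSpec(variant, KnockoutSet(), defaults), dose)
        assert traj.states.min() >= -1e-9

    @given(
        k1=st.floats(0.05, 10.0),
        k4=st.floats(1.0, 100.0),
        k_imp=st.floats(1e-3, 0.1),
        dose=st.floats(0.0, 40.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_non_negativity_random_params(self, k1, k4, k_imp, dose):
        p = KineticParameters(k1=k1, k4=k4, k_imp=k_imp)
        traj = integrate_timecourse(ModelSpec(ModelVariant.REG_BINDING, KnockoutSet(), p), dose)
        assert traj.states.min() >= -1e-9

    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_ai2_pool_monotone(self, defaults, variant):
        traj = integrate_timecourse(ModelSpec(variant, KnockoutSet(), defaults), 40.0)
        aout = traj.species("Aout")
        assert np.all(np.diff(aout) <= 1e-9)
        pool = sum(traj.species(n) for n in ("Aout", "Ap", "U", "C_R", "C_G"))
        assert np.all(np.diff(pool) <= 1e-9)

    def test_reg_binding_with_k5_zero_equals_no_binding(self, defaults):
        p = defaults.replace(k5=0.0)
        t_rb = integrate_timecourse(ModelSpec(ModelVariant.REG_BINDING, KnockoutSet(), p), 40.0)
        t_rnb = integrate_timecourse(
            ModelSpec(ModelVariant.REG_NO_BINDING, KnockoutSet(), defaults), 40.0
        )
        np.testing.assert_allclose(t_rb.states, t_rnb.states, rtol=1e-7, atol=1e-9)

    def test_large_k4_converges_to_first(self, defaults):
        # as the second repressor loses its grip (k4 -> inf) the no-binding
        # variant collapses onto the single-repressor topology
        t_first = integrate_timecourse(
            ModelSpec(ModelVariant.FIRST, KnockoutSet(), defaults), 40.0
        )
        shared = [IDX[n] for n in STATE_VARS if n not in ("G", "C_G")]
        dists = []
        for k4 in (1e5, 1e7):
            t_reg = integrate_timecourse(
                ModelSpec(ModelVariant.REG_NO_BINDING, KnockoutSet(), defaults.replace(k4=k4)),
                40.0,
            )
            dists.append(np.max(np.abs(t_reg.states[:, shared] - t_first.states[:, shared])))
        assert dists[1] < dists[0]
        assert dists[1] < 1e-2
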