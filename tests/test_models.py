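"""Structural model layer: closed forms, inhibition function, coupled RHS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from piglet_pkpd.models import (
    DegenerateParametersError,
    IndirectResponse,
    OneCptPK,
    StructuralModel,
    TwoCptPK,
    inhibition,
    plasma_conc_one_cpt,
    plasma_conc_two_cpt,
    rhs,
)
from piglet_pkpd.secondary import tmax_cmax

KETO_PK = dict(ka=5.63, ke=0.20, v=302.11, dose=3.0)
FLU_PK = dict(ka=6.68, ke=0.16, k12=0.11, k21=0.16, v=636.17, dose=2.2)
PGE2_IDR = dict(kin=207.20, kout=2.34, imax=0.9733, ic50=0.08, gamma=2.07)


class TestOneCompartment:
    def test_no_drug_before_absorption(self):
        pk = OneCptPK(**KETO_PK)
        assert plasma_conc_one_cpt(0.0, pk) == 0.0

    def test_peak_matches_published_exposure(self):
        # Ka 5.63, Ke 0.20, V 302.11, 3.0 mg/kg -> Tmax 0.61 h, Cmax 8.78 ug/ml
        pk = OneCptPK(**KETO_PK)
        tmax, cmax = tmax_cmax(pk)
        assert tmax == pytest.approx(0.61, abs=0.005)
        assert cmax == pytest.approx(8.78, abs=0.005)

    def test_closed_form_agrees_with_ode_oracle(self):
        # independent integration of the two-state absorption system
        pk = OneCptPK(**KETO_PK)

        def deriv(t, y):
            depot, c = y
            return [-pk.ka * depot, pk.ka * depot / pk.v - pk.ke * c]

        sol = solve_ivp(deriv, (0, 24), [pk.dose * 1000.0, 0.0], rtol=1e-12, atol=1e-14,
                        t_eval=[24.0])
        assert plasma_conc_one_cpt(24.0, pk) == pytest.approx(sol.y[1, -1], rel=1e-8)

    def test_auc_identity(self):
        pk = OneCptPK(**KETO_PK)
        assert pk.expsum().auc_inf() == pytest.approx(
            pk.dose * 1000.0 / (pk.ke * pk.v), rel=1e-12
        )

    def test_vanishes_at_long_times(self):
        pk = OneCptPK(**KETO_PK)
        assert plasma_conc_one_cpt(500.0, pk) == pytest.approx(0.0, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            plasma_conc_one_cpt(-1.0, OneCptPK(**KETO_PK))

    def test_flip_flop_degeneracy_rejected(self):
        with pytest.raises(DegenerateParametersError):
            OneCptPK(ka=0.2, ke=0.2, v=300.0, dose=3.0)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            OneCptPK(ka=-1.0, ke=0.2, v=300.0, dose=3.0)


class TestTwoCompartment:
    def test_macro_rates_solve_characteristic_quadratic(self):
        # alpha, beta are the roots of x^2 - 0.43 x + 0.0256
        pk = TwoCptPK(**FLU_PK)
        alpha, beta = pk.macro_rates()
        roots = sorted(np.roots([1.0, -0.43, 0.0256]))
        assert beta == pytest.approx(roots[0], rel=1e-12)
        assert alpha == pytest.approx(roots[1], rel=1e-12)

    def test_peak_matches_published_exposure(self):
        pk = TwoCptPK(**FLU_PK)
        t = np.linspace(0, 4, 4001)
        c = plasma_conc_two_cpt(t, pk)
        assert t[np.argmax(c)] == pytest.approx(0.51, abs=0.01)
        assert c.max() == pytest.approx(3.03, abs=0.01)

    def test_reduces_to_one_compartment_as_k12_vanishes(self):
        one = OneCptPK(**KETO_PK)
        two = TwoCptPK(ka=5.63, ke=0.20, k12=1e-10, k21=0.5, v=302.11, dose=3.0)
        t = np.linspace(0, 48, 100)
        np.testing.assert_allclose(
            plasma_conc_two_cpt(t, two), plasma_conc_one_cpt(t, one), rtol=1e-6, atol=1e-12
        )

    def test_exact_auc_matches_quadrature(self):
        es = TwoCptPK(**FLU_PK).expsum()
        numeric, _ = quad(es, 0.0, 48.0, limit=200)
        assert es.auc(0.0, 48.0) == pytest.approx(numeric, rel=1e-9)


class TestInhibition:
    def test_zero_drug_no_inhibition(self):
        assert inhibition(0.0, IndirectResponse(**PGE2_IDR)) == 0.0

    @given(gamma=st.floats(0.2, 8.0))
    @settings(max_examples=25, deadline=None)
    def test_half_maximal_at_ic50_for_any_hill_exponent(self, gamma):
        idr = IndirectResponse(kin=100.0, kout=1.0, imax=0.8, ic50=0.3, gamma=gamma)
        assert inhibition(0.3, idr) == pytest.approx(0.4, rel=1e-12)

    def test_direct_formula(self):
        idr = IndirectResponse(**PGE2_IDR)
        expected = 0.9733 * 0.16**2.07 / (0.16**2.07 + 0.08**2.07)
        assert inhibition(0.16, idr) == pytest.approx(expected, rel=1e-12)

    @given(ce=st.floats(0.0, 1e6), ce2=st.floats(0.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, ce, ce2):
        idr = IndirectResponse(**PGE2_IDR)
        lo, hi = sorted([ce, ce2])
        f_lo, f_hi = float(inhibition(lo, idr)), float(inhibition(hi, idr))
        assert 0.0 <= f_lo <= idr.imax
        assert f_lo <= f_hi + 1e-15

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            inhibition(-0.1, IndirectResponse(**PGE2_IDR))


def _models():
    from piglet_pkpd.config import load_population

    return [load_population(n).structural for n in
            ("ketoprofen_pge2", "ketoprofen_cortisol", "flunixin_cortisol")]


class TestCoupledSystem:
    @pytest.mark.parametrize("model", _models(), ids=lambda m: m.name)
    def test_baseline_is_steady_state(self, model):
        y0 = model.initial_state()
        y0[0] = 0.0  # no drug in the depot
        dy = rhs(model, y0, 0.0)
        assert dy[-1] == pytest.approx(0.0, abs=1e-12)

    def test_isf_influx_rate(self, keto_pge2):
        # dCe/dt = Ke0in * C with C = 1, Ce = 0 (published Ke0in = 0.012 1/h)
        model = keto_pge2.structural
        y = np.array([0.0, 1.0, 0.0, model.idr.baseline])
        dy = rhs(model, y, 0.0)
        assert dy[2] == pytest.approx(0.012, rel=1e-12)

    @pytest.mark.parametrize("model", _models(), ids=lambda m: m.name)
    def test_stiff_integration_matches_closed_form_pk(self, model):
        t = np.linspace(0.0, 48.0, 49)
        sol = solve_ivp(model.rhs, (0, 48), model.initial_state(), method="LSODA",
                        t_eval=t, rtol=1e-10, atol=1e-12)
        closed = model.plasma_expsum()(t)
        scale = closed.max()
        np.testing.assert_allclose(sol.y[1], closed, rtol=1e-6, atol=1e-6 * scale)

    def test_state_shape_mismatch_rejected(self, keto_pge2):
        with pytest.raises(ValueError):
            rhs(keto_pge2.structural, np.zeros(3), 0.0)

    def test_topology_mismatch_rejected(self, keto_pge2):
        with pytest.raises(TypeError):
            StructuralModel(
                name="flunixin_cortisol",
                pk=OneCptPK(**KETO_PK),
                idr=IndirectResponse(**PGE2_IDR),
                link=None,
            )

    def test_replace_params_round_trip(self, flunixin):
        model = flunixin.structural
        new = model.replace_params(Ke=0.3, IC50=0.1)
        assert new.pk.ke == 0.3
        assert new.idr.ic50 == 0.1
        assert model.pk.ke == 0.16  # original untouched
        with pytest.raises(KeyError):
            model.replace_params(Ke0in=0.1)  # not a parameter of this topology
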