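"""Model families: step maps, gain identity, classification, hypotheses."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import popswitch as ps
from popswitch.models import (
    allen_clark_companion,
    is_irreducible,
    primitivity_exponent,
    steady_state_gain_p,
)


def _tiny_lure(p_target=0.5, g=None):
    """One-strategy scalar Lur'e model with a prescribed critical slope."""
    A = np.array([[[0.0]]])
    b = np.array([[1.0 / p_target]])
    f = np.array([[1.0]])
    C = np.array([[1.0]])
    return ps.StageStructuredLureModel(
        A=A, b=b, f=f, g=(g or ps.RickerNonlinearity(1.3026, 22.834),), C=C
    )


class TestStepMaps:
    def test_origin_is_fixed_for_all_families(self, ac_model, pielou_model, fixture_model):
        assert np.all(ps.lure_step(fixture_model, 1, np.zeros(7)) == 0)
        assert np.all(ac_model.step(2, np.zeros(3)) == 0)
        assert ps.pielou_step(pielou_model, 1, 0.0, 0.0) == (0.0, 0.0)

    def test_ricker_peak_value(self):
        g = ps.RickerNonlinearity(sigma=1.3026, rcc=22.834)
        assert g(22.834) == pytest.approx(1.3026 * 22.834 / math.e)
        assert g(22.834) == pytest.approx(10.942, abs=5e-4)

    def test_invalid_inputs_rejected(self, fixture_model):
        with pytest.raises(ValueError):
            fixture_model.step(0, np.ones(7))
        with pytest.raises(ValueError):
            fixture_model.step(1, -np.ones(7))
        with pytest.raises(ValueError):
            ps.pielou_step(ps.pielou_demo(), 1, -0.1, 0.2)

    @given(st.integers(0, 2**31 - 1))
    def test_positivity_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        fixture = ps.make_fixture(ps.FixtureSpec(seed=1))
        x = rng.uniform(0, 50, 7)
        for h in (1, 2, 3):
            assert np.all(fixture.step(h, x) >= 0)
        ac = ps.allen_clark_demo()
        z = rng.uniform(0, 5, 3)
        for h in (1, 2, 3):
            assert np.all(ac.step(h, z) >= 0)
        pm = ps.pielou_demo()
        w = rng.uniform(0, 3, 2)
        for h in (1, 2):
            out = pm.step(h, w)
            assert np.all(out >= 0)
            # saturating-times-exponential terms are bounded by (a_h, b_h)
            assert out[0] <= pm.a[h - 1] and out[1] <= pm.b[h - 1]

    def test_pielou_worked_value(self, pielou_model):
        # a=0.8, c=0.6 at (x1, x2) = (0, 1): 0.8/1.6 * e^0 = 0.5; x1=0 kills F2
        assert ps.pielou_step(pielou_model, 1, 0.0, 1.0) == pytest.approx((0.5, 0.0))

    def test_monotone_measurement(self, fixture_model, pielou_model):
        rng = np.random.default_rng(0)
        for _ in range(20):
            z1 = rng.uniform(0, 10, 7)
            z2 = z1 + rng.uniform(0, 5, 7)
            assert np.all(fixture_model.observe(z1) <= fixture_model.observe(z2))
        assert np.all(pielou_model.observe([1, 2]) == [1, 2])


class TestCompanionForm:
    def test_structure(self, ac_model):
        A, b, f, c = allen_clark_companion(ac_model, 1)
        assert A.shape == (3, 3)
        assert ps.spectral_radius(A) == pytest.approx(0.1)  # triangular: diagonal
        assert b[0] == ac_model.beta[0] and np.all(b[1:] == 0)
        assert np.all(f == [1, 0, 0]) and np.all(c == [0, 0, 1])

    @pytest.mark.parametrize("h", [1, 2, 3])
    def test_matches_scalar_recursion(self, ac_model, h):
        """Oracle: the scalar delayed recursion, iterated directly."""
        i = h - 1
        al, be = ac_model.alpha[i], ac_model.beta[i]
        ka, uu = ac_model.kappa[i], ac_model.u[i]
        hist = [0.3, 0.1, 0.05]  # z(0), z(-1), z(-2)
        z = list(reversed(hist))  # chronological: z(-2), z(-1), z(0)
        for t in range(100):
            w = z[-3]
            z.append(al * z[-1] + be * w * math.exp(-ka * uu * w))
        x = np.array(hist, dtype=float)
        for t in range(100):
            x = ac_model.step(h, x)
        assert x[0] == pytest.approx(z[-1], rel=1e-12)
        assert x[1] == pytest.approx(z[-2], rel=1e-12)


class TestGainAndClassification:
    def test_gain_closed_form(self, ac_model):
        """p = (1 - alpha) / beta for the companion triple."""
        for h, expected in ((1, 0.15), (2, 1.2), (3, 0.075)):
            A, b, _f, c = allen_clark_companion(ac_model, h)
            assert steady_state_gain_p(A, b, c) == pytest.approx(expected, abs=1e-10)

    @given(
        st.floats(0.01, 0.99),
        st.floats(0.1, 20.0),
        st.integers(0, 5),
    )
    def test_gain_identity_randomized(self, alpha, beta, k):
        m = ps.AllenClarkModel(alpha=[alpha], beta=[beta], kappa=[1.0], u=[1.0], k=k)
        A, b, _f, c = allen_clark_companion(m, 1)
        assert steady_state_gain_p(A, b, c) == pytest.approx((1 - alpha) / beta, abs=1e-10)

    def test_gain_precondition(self):
        with pytest.raises(ValueError):
            steady_state_gain_p(np.array([[1.2]]), [1.0], [1.0])
        with pytest.raises(ValueError):
            steady_state_gain_p(np.array([[0.5]]), [0.0], [1.0])

    def test_allen_clark_verdicts(self, ac_model):
        verdicts = [ps.classify_strategy(ac_model, h).verdict for h in (1, 2, 3)]
        assert verdicts == ["persistent", "extinct", "persistent"]

    def test_trout_cod_verdicts(self, fixture_model):
        verdicts = [ps.classify_strategy(fixture_model, h).verdict for h in (1, 2, 3)]
        assert verdicts == ["extinct", "persistent", "persistent"]
        for h in (1, 2, 3):
            c = ps.classify_strategy(fixture_model, h)
            assert c.p == pytest.approx(0.4792, abs=1e-9)
            assert c.bounded and c.certified
            if c.verdict == "persistent":
                assert c.slope_at_zero > c.p
            if c.verdict == "extinct":
                assert c.sup_slope < c.p

    @pytest.mark.parametrize(
        "h,verdict",
        [(1, "extinct"), (2, "persistent"), (3, "persistent")],
    )
    def test_classification_matches_long_run(self, fixture_model, h, verdict):
        """Extinct strategies decay; persistent ones keep a positive floor."""
        x0 = ps.trout_cod_initial_states()[0]
        floor = ps.fixed_strategy_tail_minimum(fixture_model, h, x0, 5000, 2500)
        if verdict == "extinct":
            assert floor < 1e-6
        else:
            assert floor > 1.0


class TestEquilibrium:
    def test_ricker_closed_form_vs_bisection(self, fixture_model):
        z_star, x_star = ps.lure_nonzero_equilibrium(fixture_model, 2)
        assert z_star == pytest.approx(22.835, abs=2e-3)
        # independent oracle: bisection on g(z) - p z
        g = fixture_model.g[1]
        p = 0.4792
        lo, hi = 1e-9, 1e4
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) - p * mid > 0:
                lo = mid
            else:
                hi = mid
        assert z_star == pytest.approx(0.5 * (lo + hi), abs=1e-8)
        assert abs(g(z_star) - p * z_star) < 1e-10
        # true fixed point of the step map
        assert np.allclose(fixture_model.step(2, x_star), x_star, atol=1e-9)

    def test_degenerate_secant_rejected(self):
        # g(z) = 2 z e^{-z} with p = 2: secant equation only solved at z = 0
        m = _tiny_lure(p_target=2.0, g=ps.RickerNonlinearity(sigma=2.0, rcc=1.0))
        with pytest.raises(ValueError):
            ps.lure_nonzero_equilibrium(m, 1)

    def test_generic_root_residual(self, ac_model):
        for h in (1, 3):
            z_star, x_star = ps.lure_nonzero_equilibrium(ac_model, h)
            g = ac_model.g[h - 1]
            p = ps.classify_strategy(ac_model, h).p
            assert abs(g(z_star) - p * z_star) < 1e-10
            assert np.allclose(ac_model.step(h, x_star), x_star, atol=1e-9)


class TestStructuralHypotheses:
    def test_allen_clark_minorant(self, ac_model):
        rep = ps.check_structural_hypotheses(ac_model)
        assert rep.h1_bound and rep.rho_X1 < 1
        # minorant has a recruitment link plus the progression chain
        assert rep.irreducible
        # positive trace (alpha on the diagonal) makes it primitive
        assert rep.primitive and rep.primitivity_exponent >= 1
        assert rep.certified

    def test_fixture_report(self, fixture_model):
        rep = ps.check_structural_hypotheses(fixture_model)
        assert rep.h1_bound and rep.irreducible and rep.primitive

    def test_reducible_matrix_detected(self):
        block = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert not is_irreducible(block)
        assert primitivity_exponent(block) is None

    def test_pielou_uniform_bound(self, pielou_model):
        rep = ps.check_structural_hypotheses(pielou_model)
        assert rep.h1_bound and rep.rho_X1 == 0.0
        assert np.all(rep.X2 == [0.8, 0.9])
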