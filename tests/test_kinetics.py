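"""Single-codon elongation cycle: rates, generator, dwell times, fidelity."""

import numpy as np
import pandas as pd
import pytest

from elokin.cognacy import COGNATE, NEAR, NON, CognacyMatrix
from elokin.errors import (
    DegenerateStateError,
    NoAbsorptionError,
    UndefinedFidelityError,
    ValidationError,
)
from elokin.fixtures import generate_fixture, random_generator_rates
from elokin.kinetics import (
    ABSORBING,
    KineticParams,
    accommodation_probabilities,
    binding_rates,
    build_generator,
    codon_profile,
    dwell_times,
    effective_accommodation_rates,
    elongation_profile,
    mean_first_passage_time,
    transition_probabilities,
)

def kp_simple(**kw):
    """A plain parameter set, overridable per test."""
    base = dict(
        kappa_on=1.0,
        omega_off=5.0,
        omega_rec=4.0,
        omega_21=1.0,
        omega_23=3.0,
        omega_con=2.0,
        omega_40=0.5,
        omega_45=2.5,
        omega_76=6.0,
        omega_78=0.7,
        omega_90=3.0,
        omega_9_10=0.4,
        omega_pro=2.0,
    )
    base.update(kw)
    return KineticParams(**base)


class TestBindingRates:
    def test_single_cognate_trna(self):
        m = CognacyMatrix(("AAA",), ("t0",), np.array([[COGNATE]], dtype=np.int8))
        kp = kp_simple(kappa_on=0.1)
        assert binding_rates({"t0": 2.0}, m, "AAA", kp) == (pytest.approx(0.2), 0.0, 0.0)

    def test_zero_concentrations_give_zero_rates(self, small_fixture):
        m, kp, _, cs = small_fixture
        zeros = pd.Series(0.0, index=list(m.trnas))
        assert binding_rates(zeros, m, m.codons[0], kp) == (0.0, 0.0, 0.0)

    def test_matches_set_enumeration_oracle(self, rng):
        m, kp, _, cs = generate_fixture(11, n_trnas=10, n_codons=10)
        x = pd.Series(rng.uniform(0.1, 5.0, 10), index=list(m.trnas))
        for c in m.codons:
            co, nr, no = m.trnas_for_codon(c)
            expected = tuple(
                kp.kappa_on * sum(x[a] for a in s) for s in (co, nr, no)
            )
            got = binding_rates(x, m, c, kp)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        m = CognacyMatrix(("AAA",), ("t0",), np.array([[COGNATE]], dtype=np.int8))
        with pytest.raises(ValidationError, match="negative"):
            binding_rates({"t0": -1.0}, m, "AAA", kp_simple())


class TestGenerator:
    def test_exactly_twenty_arcs(self):
        g = build_generator((1.0, 1.0, 1.0), kp_simple())
        assert int((g.W > 0).sum()) == 20

    def test_arc_topology(self):
        g = build_generator((1.0, 1.0, 1.0), kp_simple())
        targets = {i: set(np.flatnonzero(g.W[i] > 0)) for i in range(12)}
        assert targets == {
            0: {1, 6, 11},
            1: {0, 2},
            2: {1, 3},
            3: {4},
            4: {0, 5},
            5: {ABSORBING},
            6: {0, 7},
            7: {6, 8},
            8: {9},
            9: {0, 10},
            10: {ABSORBING},
            11: {0},
        }

    def test_zero_near_and_non_binding_unreachable_branches(self):
        g = build_generator((1.0, 0.0, 0.0), kp_simple())
        reach = g.reachable()
        assert not reach[6:12].any()
        assert reach[[0, 1, 2, 3, 4, 5, ABSORBING]].all()

    def test_state_11_single_exit(self):
        g = build_generator((1.0, 1.0, 1.0), kp_simple())
        pi = transition_probabilities(g)
        assert pi[11, 0] == 1.0


class TestTransitionProbabilities:
    def test_single_arc_state_has_probability_one(self):
        pi = transition_probabilities(build_generator((1, 1, 1), kp_simple()))
        assert pi[3, 4] == 1.0

    def test_equal_rates_split_half(self):
        kp = kp_simple(omega_40=2.5, omega_45=2.5)
        pi = transition_probabilities(build_generator((1, 1, 1), kp))
        assert pi[4, 5] == pytest.approx(0.5)

    def test_rows_sum_to_one_and_match_division_oracle(self, rng):
        for seed in range(5):
            kp = random_generator_rates(np.random.default_rng(seed))
            g = build_generator(tuple(rng.uniform(0.1, 10, 3)), kp)
            pi = transition_probabilities(g)
            out = g.W.sum(axis=1)
            for i in range(12):
                assert pi[i].sum() == pytest.approx(1.0, abs=1e-12)
                np.testing.assert_allclose(pi[i], g.W[i] / out[i], rtol=1e-14)

    def test_degenerate_reachable_state_raises(self):
        # omega_pro = 0 leaves reachable state 5 with no exit
        g = build_generator((1.0, 0.0, 0.0), kp_simple(omega_pro=0.0))
        with pytest.raises(DegenerateStateError):
            transition_probabilities(g)


class TestDwellTimes:
    def test_pure_chain_dwell_and_total(self):
        r = 3.0
        kp = kp_simple(
            omega_off=0.0,
            omega_rec=r,
            omega_21=0.0,
            omega_23=r,
            omega_con=r,
            omega_40=0.0,
            omega_45=r,
            omega_pro=r,
        )
        g = build_generator((r, 0.0, 0.0), kp)
        dwell, t_elo = dwell_times(g)
        assert t_elo == pytest.approx(6.0 / r, rel=1e-12)
        np.testing.assert_allclose(dwell[:6], np.full(6, 1.0 / r), rtol=1e-12)
        np.testing.assert_allclose(dwell[6:], 0.0, atol=1e-15)

    def test_unreachable_branch_has_zero_dwell(self):
        g = build_generator((2.0, 0.0, 0.0), kp_simple())
        dwell, _ = dwell_times(g)
        assert (dwell[6:12] == 0).all()

    def test_no_absorbing_path_raises(self):
        g = build_generator((0.0, 0.0, 1.0), kp_simple())
        with pytest.raises(NoAbsorptionError):
            dwell_times(g)

    def test_dwell_sum_and_auxiliary_identity_on_random_generators(self):
        """Sum of dwell times equals the mean first-passage time, and the
        auxiliary-process stationary distribution equals the dwell fractions,
        on many random rate sets (both checked to 1e-10 relative)."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            kp = random_generator_rates(rng)
            g = build_generator(tuple(rng.uniform(0.05, 20.0, 3)), kp)
            dwell, t_elo = dwell_times(g, cross_check_tol=1e-10)
            assert dwell.sum() == pytest.approx(t_elo, rel=1e-10)
            mfpt = mean_first_passage_time(g)
            assert t_elo == pytest.approx(mfpt, rel=1e-12)

    def test_cognate_pool_increase_never_slows_codon(self):
        m, kp, _, cs = generate_fixture(3)
        x = cs.X_total.copy()
        prof = elongation_profile(x, m, kp)
        a = list(m.trnas)[0]
        bumped = x.copy()
        bumped[a] += 5.0
        prof2 = elongation_profile(bumped, m, kp)
        for c in m.codons_for_trna(a)[0]:
            i = list(m.codons).index(c)
            assert prof2.t_elo[i] <= prof.t_elo[i] * (1 + 1e-9)


class TestEffectiveRates:
    def test_zero_near_binding_zero_near_rate(self):
        g = build_generator((1.0, 0.0, 0.5), kp_simple())
        _, w_nr = effective_accommodation_rates(g)
        assert w_nr == 0.0

    def test_fast_forward_limit(self):
        # no recognition reversal, no rejection: omega_co -> omega_01 * pi_12
        kp = kp_simple(omega_21=0.0, omega_40=0.0, omega_23=1e9)
        g = build_generator((2.0, 0.0, 0.0), kp)
        pi = transition_probabilities(g)
        w_co, _ = effective_accommodation_rates(g, pi)
        assert w_co == pytest.approx(2.0 * pi[1, 2], rel=1e-6)

    def test_matches_first_step_absorption_oracle(self):
        """omega_co equals the binding rate times the probability (computed by
        first-step analysis on the jump chain) that a bound cognate complex
        accommodates before dissociating."""
        rng = np.random.default_rng(77)
        for _ in range(20):
            kp = random_generator_rates(rng)
            g = build_generator(tuple(rng.uniform(0.1, 10, 3)), kp)
            pi = transition_probabilities(g)
            # absorption probability h1: from state 1 reach state 5 before 0
            # h1 = pi12 h2; h2 = pi21 h1 + pi23 h3; h3 = h4; h4 = pi45
            A = np.array([[1.0, -pi[1, 2]], [-pi[2, 1], 1.0]])
            b = np.array([0.0, pi[2, 3] * pi[4, 5]])
            h1 = np.linalg.solve(A, b)[0]
            w_co, w_nr = effective_accommodation_rates(g, pi)
            assert w_co == pytest.approx(g.omega_01 * h1, rel=1e-10)
            # near branch mirror
            A = np.array([[1.0, -pi[6, 7]], [-pi[7, 6], 1.0]])
            b = np.array([0.0, pi[7, 8] * pi[9, 10]])
            h6 = np.linalg.solve(A, b)[0]
            assert w_nr == pytest.approx(g.omega_06 * h6, rel=1e-10)


class TestAccommodationProbabilities:
    def test_no_near_rate_gives_maximal_fidelity(self):
        assert accommodation_probabilities(1.5, 0.0) == (1.0, 0.0)

    def test_equal_rates_split(self):
        assert accommodation_probabilities(0.3, 0.3) == pytest.approx((0.5, 0.5))

    def test_normalization_is_exact(self, rng):
        for _ in range(50):
            p_co, p_nr = accommodation_probabilities(*rng.uniform(1e-6, 10, 2))
            assert p_co + p_nr == 1.0

    def test_both_zero_raises(self):
        with pytest.raises(UndefinedFidelityError):
            accommodation_probabilities(0.0, 0.0)


def test_codon_profile_consistency(small_fixture):
    """The bundled per-codon profile agrees with its own parts."""
    m, kp, _, cs = small_fixture
    c = m.codons[0]
    prof = codon_profile(cs.X_total, m, c, kp)
    assert prof.t_elo == pytest.approx(prof.dwell.sum(), rel=1e-10)
    assert prof.omega_elo == pytest.approx(1.0 / prof.t_elo)
    assert prof.P_co + prof.P_nr == 1.0
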