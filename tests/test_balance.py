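"""Self-consistent free ternary-complex balance."""

import numpy as np
import pandas as pd
import pytest

from elokin.balance import (
    CellState,
    RechargingParams,
    free_tc_update,
    free_eftu,
    phi_constants,
    solve_self_consistent,
    tau_constants,
)
from elokin.cognacy import COGNATE, NEAR, NON
from elokin.errors import ValidationError
from elokin.fixtures import generate_fixture
from elokin.kinetics import (
    EFTU_STATES,
    KineticParams,
    elongation_profile,
    pool_sums,
)


def kp_unit(**kw):
    base = dict(
        kappa_on=1.0,
        omega_off=1.0,
        omega_rec=1.0,
        omega_21=0.0,
        omega_23=1.0,
        omega_con=1.0,
        omega_40=0.0,
        omega_45=1.0,
        omega_76=0.0,
        omega_78=1.0,
        omega_90=0.0,
        omega_9_10=1.0,
        omega_pro=1.0,
    )
    base.update(kw)
    return KineticParams(**base)


RP = RechargingParams(kappa_ass=1.0, omega_dis=0.0, omega_re=1.0)


class TestTauConstants:
    def test_unit_rates_and_unit_probabilities(self):
        # zero reject rates force all branch probabilities to 1
        tau_co, tau_nr, tau_no = tau_constants(kp_unit())
        assert tau_co == pytest.approx(4.0)
        assert tau_nr == pytest.approx(4.0)
        assert tau_no == pytest.approx(2.0)

    def test_diverges_as_accommodation_probability_vanishes(self):
        taus = []
        for w40 in (0.0, 1.0, 10.0, 100.0):
            taus.append(tau_constants(kp_unit(omega_40=w40))[0])
        assert all(b > a for a, b in zip(taus, taus[1:]))

    def test_matches_term_by_term_recomputation(self, rng):
        from elokin.fixtures import random_generator_rates

        for seed in range(10):
            kp = random_generator_rates(np.random.default_rng(seed))
            pi_23 = kp.omega_23 / (kp.omega_21 + kp.omega_23)
            pi_45 = kp.omega_45 / (kp.omega_40 + kp.omega_45)
            pi_78 = kp.omega_78 / (kp.omega_76 + kp.omega_78)
            pi_910 = kp.omega_9_10 / (kp.omega_90 + kp.omega_9_10)
            tau_co, tau_nr, tau_no = tau_constants(kp)
            assert tau_co == pytest.approx(
                1 / (kp.omega_rec * pi_23 * pi_45)
                + 1 / (kp.omega_23 * pi_45)
                + 1 / (kp.omega_con * pi_45)
                + 1 / kp.omega_45,
                rel=1e-12,
            )
            assert tau_nr == pytest.approx(
                1 / (kp.omega_rec * pi_78 * pi_910)
                + 1 / (kp.omega_78 * pi_910)
                + 1 / (kp.omega_con * pi_910)
                + 1 / kp.omega_9_10,
                rel=1e-12,
            )
            assert tau_no == pytest.approx(
                1 / (kp.omega_rec * pi_23 * pi_45) + 1 / (kp.omega_off * pi_45),
                rel=1e-12,
            )


class TestPhiConstants:
    def test_zero_elongation_limits(self):
        assert phi_constants("2-3-2", 0.0, 1.0, 1.0, RP, 10.0, 1.0) == (2.0, 2.0)
        assert phi_constants("2-1-2", 0.0, 1.0, 1.0, RP, 10.0, 1.0) == (1.0, 1.0)

    @pytest.mark.parametrize("pathway", ["2-1-2", "2-3-2"])
    def test_difference_identity(self, pathway, rng):
        for _ in range(20):
            w, tco, tnr, ef, wpro = rng.uniform(0.1, 10.0, 5)
            phi_co, phi_nr = phi_constants(pathway, w, tco, tnr, RP, ef, wpro)
            assert phi_co - phi_nr == pytest.approx(w * (tco - tnr), rel=1e-9, abs=1e-12)

    def test_matches_symbolic_reevaluation(self, rng):
        rp = RechargingParams(kappa_ass=3.0, omega_dis=0.1, omega_re=7.0)
        for _ in range(10):
            w, tco, tnr, ef, wpro = rng.uniform(0.1, 10.0, 5)
            cyc = 1 / rp.omega_re + 1 / (rp.kappa_ass * ef)
            got = phi_constants("2-3-2", w, tco, tnr, rp, ef, wpro)
            assert got == pytest.approx((2 + w * (tco + cyc), 2 + w * (tnr + cyc)))
            got = phi_constants("2-1-2", w, tco, tnr, rp, ef, wpro)
            assert got == pytest.approx(
                (1 + w * (tco + 1 / wpro + cyc), 1 + w * (tnr + 1 / wpro + cyc))
            )

    def test_zero_recharge_rate_rejected(self):
        with pytest.raises(ValidationError):
            phi_constants("2-3-2", 1.0, 1.0, 1.0, RechargingParams(1.0, 0.0, 0.0), 1.0, 1.0)


class TestFreeEFTu:
    def test_empty_pools_return_total(self, small_fixture):
        m, kp, rp, cs = small_fixture
        prof = elongation_profile(cs.X_total, m, kp)
        cs0 = CellState(
            growth_rate=cs.growth_rate,
            X_total=cs.X_total,
            R=0.0,
            E_total=cs.E_total,
            p=cs.p,
            pathway=cs.pathway,
        )
        zeros = pd.Series(0.0, index=list(m.trnas))
        assert free_eftu(cs0, zeros, prof) == pytest.approx(cs.E_total)

    def test_never_exceeds_total(self, small_fixture):
        m, kp, rp, cs = small_fixture
        prof = elongation_profile(cs.X_total, m, kp)
        e = free_eftu(cs, 0.1 * cs.X_total, prof)
        assert 0 <= e <= cs.E_total

    def test_conservation_audit_at_solution(self, small_fixture):
        """Free EF-Tu + EF-Tu in free TCs + EF-Tu on ribosomes = total pool,
        with the bound term accumulated independently from occupancies."""
        m, kp, rp, cs = small_fixture
        sol = solve_self_consistent(cs, kp, rp, m)
        p = cs.p.reindex(list(sol.profile.codons)).to_numpy()
        t_mean = float(p @ sol.profile.t_elo)
        bound = cs.R * sum(
            p[i] * sol.profile.dwell[i, j]
            for i in range(len(p))
            for j in EFTU_STATES
        ) / t_mean
        total = sol.E_free + float(sol.X_hat.sum()) + bound
        assert total == pytest.approx(cs.E_total, rel=1e-10)


class TestFreeTCUpdate:
    def _setup(self, seed=13):
        m, kp, rp, cs = generate_fixture(seed, n_trnas=5, n_codons=7)
        prof = elongation_profile(cs.X_total, m, kp)
        return m, kp, rp, cs, prof

    def test_no_ribosomes_no_dissociation_fixed_point(self):
        m, kp, _, cs, prof = self._setup()
        rp = RechargingParams(kappa_ass=2.0, omega_dis=0.0, omega_re=5.0)
        cs0 = CellState(cs.growth_rate, cs.X_total, 0.0, cs.E_total, cs.p, cs.pathway)
        out = free_tc_update(cs.X_total, cs0, kp, rp, m, prof, 2.0, 2.0, cs.E_total, 10.0)
        pd.testing.assert_series_equal(out, cs.X_total, check_names=False)

    def test_no_ribosomes_uniform_dissociation_scaling(self):
        m, kp, _, cs, prof = self._setup()
        rp = RechargingParams(kappa_ass=2.0, omega_dis=0.5, omega_re=5.0)
        cs0 = CellState(cs.growth_rate, cs.X_total, 0.0, cs.E_total, cs.p, cs.pathway)
        e_free = 4.0
        out = free_tc_update(cs.X_total, cs0, kp, rp, m, prof, 2.0, 2.0, e_free, 10.0)
        factor = 1.0 / (1.0 + rp.omega_dis / (rp.kappa_ass * e_free))
        np.testing.assert_allclose(out.to_numpy(), factor * cs.X_total.to_numpy(), rtol=1e-12)

    def test_matches_set_enumeration_oracle(self):
        """Each species' sequestration sum recomputed by explicit loops over
        the cognacy sets equals the vectorized implementation."""
        m, kp, rp, cs, prof = self._setup(21)
        x = cs.X_total * 0.7
        phi_co, phi_nr, e_free, w_elo = 3.0, 2.5, 5.0, 8.0
        out = free_tc_update(x, cs, kp, rp, m, prof, phi_co, phi_nr, e_free, w_elo)
        tau_no = tau_constants(kp)[2]
        pmap = dict(zip(prof.codons, range(len(prof.codons))))
        for j, b in enumerate(m.trnas):
            co_b, nr_b, no_b = m.codons_for_trna(b)
            seq = 0.0
            for c in co_b:
                k = pmap[c]
                s = sum(x[a] for a in m.trnas_for_codon(c)[0])
                seq += phi_co * prof.P_co[k] * cs.p[c] / s
            for c in nr_b:
                k = pmap[c]
                s = sum(x[a] for a in m.trnas_for_codon(c)[1])
                if prof.P_nr[k] > 0 and s > 0:
                    seq += phi_nr * prof.P_nr[k] * cs.p[c] / s
            for c in no_b:
                k = pmap[c]
                s = sum(x[a] for a in m.trnas_for_codon(c)[0])
                seq += w_elo * tau_no * prof.P_co[k] * cs.p[c] / s
            expected = cs.X_total[b] / (
                1.0 + rp.omega_dis / (rp.kappa_ass * e_free) + cs.R * seq
            )
            assert out[b] == pytest.approx(expected, rel=1e-10)


class TestSolver:
    def test_trivial_limit_converges_in_one_sweep(self):
        m, kp, _, cs = generate_fixture(4)
        rp = RechargingParams(kappa_ass=5.0, omega_dis=0.0, omega_re=10.0)
        cs0 = CellState(cs.growth_rate, cs.X_total, 0.0, cs.E_total, cs.p, cs.pathway)
        sol = solve_self_consistent(cs0, kp, rp, m)
        assert sol.iterations == 1
        pd.testing.assert_series_equal(sol.X_hat, cs.X_total, check_names=False)

    @pytest.mark.parametrize("seed", [1, 4, 6])
    def test_fixed_point_bounds_and_self_consistency(self, seed):
        m, kp, rp, cs = generate_fixture(seed)
        sol = solve_self_consistent(cs, kp, rp, m)
        assert (sol.X_hat > 0).all()
        assert (sol.X_hat <= cs.X_total * (1 + 1e-12)).all()
        # the overall rate used in the sequestration factors matches the
        # usage-weighted rate of the returned profile
        p = cs.p.reindex(list(sol.profile.codons)).to_numpy()
        w_from_profile = 1.0 / float(p @ sol.profile.t_elo)
        assert abs(sol.omega_elo - w_from_profile) / w_from_profile <= 1e-9

    def test_initialization_independence(self):
        m, kp, rp, cs = generate_fixture(6)
        tol = 1e-10
        a = solve_self_consistent(cs, kp, rp, m, tol=tol)
        b = solve_self_consistent(cs, kp, rp, m, tol=tol, x0=0.5 * cs.X_total)
        rel = ((a.X_hat - b.X_hat).abs() / a.X_hat).max()
        assert rel <= 10 * tol

    def test_usage_increase_depletes_cognate_pool(self):
        """Raising one codon's usage weakly decreases the free pool of its
        cognate tRNA species."""
        from elokin.perturb import reweight_usage

        m, kp, rp, cs = generate_fixture(6)
        target = m.codons[0]
        cognates = m.trnas_for_codon(target)[0]
        base = solve_self_consistent(cs, kp, rp, m)
        hi = solve_self_consistent(
            cs.with_usage(reweight_usage(cs.p, target, min(0.5, cs.p[target] * 3 + 0.1))),
            kp,
            rp,
            m,
        )
        for a in cognates:
            assert hi.X_hat[a] <= base.X_hat[a] * (1 + 1e-9)

    def test_pinned_mode_reproduces_self_consistent_rate(self):
        """Pinning the overall rate at the self-consistent value must give
        back the same fixed point."""
        m, kp, rp, cs = generate_fixture(4)
        free = solve_self_consistent(cs, kp, rp, m)
        pinned = solve_self_consistent(
            cs, kp, rp, m, omega_elo_mode="pinned", pinned_omega_elo=free.omega_elo
        )
        assert pinned.omega_elo == free.omega_elo
        rel = ((pinned.X_hat - free.X_hat).abs() / free.X_hat).max()
        assert rel <= 1e-6

    def test_ecoli_free_fractions_bounded(self, solution_232, ecoli_232):
        cs = ecoli_232[3]
        ff = solution_232.free_fraction
        assert ((ff > 0) & (ff <= 1)).all()
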