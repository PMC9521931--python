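import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coupledgames as cg
from coupledgames import meanfield as mf
from coupledgames.meanfield import PositivityError


@pytest.fixture(scope="module")
def cfg_sd(pd_base, snow_drift):
    return mf.DynamicsConfig(pd_base, snow_drift, nu=0.005)


@pytest.fixture(scope="module")
def cfg_sh(pd_base, stag_hunt):
    return mf.DynamicsConfig(pd_base, stag_hunt, nu=0.005)


class TestExpectedPayoffs:
    def test_uniform_distribution_row_means(self, m_sd):
        pi = mf.expected_payoffs(mf.center_distribution(), m_sd)
        assert np.allclose(pi, m_sd.entries.mean(axis=1))
        assert np.isclose(pi[0], 4.0)  # Cuu against the center state

    def test_monomorphic_ddd(self, m_sd):
        f = np.zeros(8)
        f[7] = 1.0
        pi = mf.expected_payoffs(f, m_sd)
        assert pi[7] == 4.0  # Ddd against Ddd

    def test_base_payoff_shift(self):
        z = cg.SymmetricGame2x2(0, 0, 0, 0, ("C", "D"))
        zb = cg.SymmetricGame2x2(0, 0, 0, 0, ("d", "u"))
        m = cg.build_direct_matrix(z, zb)
        assert np.allclose(mf.expected_payoffs(mf.center_distribution(), m, pi0=1.0), 1.0)

    def test_negative_payoff_raises_naming_strategy(self, snow_drift):
        hg = cg.helping_game(2.0, 1.0)  # S = -1 without pi0
        m = cg.build_direct_matrix(hg, snow_drift)
        f = np.zeros(8)
        f[4] = 1.0  # against Duu, Cuu earns S + P_B = -1
        with pytest.raises(PositivityError, match="Cuu"):
            mf.expected_payoffs(f, m)


class TestStep:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(raw=st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=8, max_size=8))
    def test_simplex_conservation(self, cfg_sd, raw):
        f = np.array(raw)
        f /= f.sum()
        out = mf.step(f, cfg_sd)
        assert abs(out.sum() - 1.0) < 1e-12
        assert (out >= 0).all()

    def test_batched_conservation_over_long_runs(self, cfg_sd):
        # one million total step applications on random states
        rng = np.random.default_rng(0)
        x = mf.sample_simplex(10_000, rng)
        x, _, _, _, _ = mf.evolve_batch(x, cfg_sd.matrix.entries, cfg_sd.nu, 0.0, tol=0.0, max_iter=100)
        assert np.abs(x.sum(axis=1) - 1.0).max() < 1e-10
        assert (x >= 0).all()

    def test_monomorphic_state_fixed_without_mutation(self, pd_base, snow_drift):
        cfg = mf.DynamicsConfig(pd_base, snow_drift, nu=0.0)
        f = np.zeros(8)
        f[7] = 1.0
        assert np.allclose(mf.step(f, cfg), f)

    def test_mixed_equilibria_are_replicator_fixed_points(self, snow_drift, m_sh, pd_base):
        # nu = 0: every verified mixed NE has vanishing step residual
        hg = cg.helping_game(2.0, 1.0)
        profiles = [
            (mf.DynamicsConfig(hg, snow_drift, nu=0.0, pi0=5.0),
             cg.closed_form_equilibrium(hg, snow_drift, "AC4").probabilities),
            (mf.DynamicsConfig(pd_base, cg.preset("stag_hunt"), nu=0.0),
             cg.solve_mixed_on_support(m_sh, ["Cud", "Ddu"]).probabilities),
        ]
        for cfg, probs in profiles:
            assert np.abs(mf.step(probs, cfg) - probs).sum() < 1e-10


class TestRunToStationarity:
    def test_center_goes_cooperative_for_snow_drift(self, cfg_sd):
        r = mf.run_to_stationarity(mf.center_distribution(), cfg_sd)
        assert r.converged and r.label == "cooperative"
        assert r.residual < cfg_sd.tol

    def test_center_goes_defective_for_stag_hunt(self, cfg_sh):
        r = mf.run_to_stationarity(mf.center_distribution(), cfg_sh)
        assert r.converged and r.label == "defective"

    def test_hard_with_cooperators_init_goes_defective(self, cfg_sd):
        d0 = np.full(8, 0.01 / 8)
        d0[5] += 0.99  # Dud: the defection-favoring norm
        r = mf.run_to_stationarity(d0 / d0.sum(), cfg_sd)
        assert r.label == "defective"


class TestClassifyState:
    def test_extremes_and_floor(self, cfg_sd):
        f = np.zeros(8)
        f[7] = 1.0
        assert mf.classify_state(f, cfg_sd) == "defective"
        f = np.zeros(8)
        f[0] = 1.0
        assert mf.classify_state(f, cfg_sd) == "fully_cooperative"
        assert mf.classify_state(mf.center_distribution(), cfg_sd) == "cooperative"


class TestStability:
    def test_cooperative_fixed_point_is_stable(self, cfg_sd):
        r = mf.run_to_stationarity(mf.center_distribution(), cfg_sd)
        stable, radius, _ = mf.assess_stability(r.distribution, cfg_sd)
        assert stable and radius < 1.0

    def test_duu_not_evolutionarily_stable_in_stag_hunt(self, pd_base, stag_hunt):
        # mutant Dud earns the same payoff as resident Duu
        cfg = mf.DynamicsConfig(pd_base, stag_hunt, nu=0.0)
        f = np.zeros(8)
        f[4] = 1.0
        stable, radius, neutral = mf.assess_stability(f, cfg)
        assert not stable
        assert neutral  # a neutral direction exists

    def test_perturbations_contract_toward_stable_fixed_point(self, cfg_sd):
        r = mf.run_to_stationarity(mf.center_distribution(), cfg_sd)
        rng = np.random.default_rng(2)
        pert = rng.normal(scale=1e-4, size=8)
        pert -= pert.mean()
        x = np.clip(r.distribution + pert, 1e-12, None)
        x /= x.sum()
        d_before = np.abs(x - r.distribution).sum()
        for _ in range(50):
            x = mf.step(x, cfg_sd)
        assert np.abs(x - r.distribution).sum() < d_before

    def test_non_fixed_point_rejected(self, cfg_sd):
        with pytest.raises(ValueError):
            mf.assess_stability(mf.center_distribution(), cfg_sd)


class TestBasin:
    def test_same_seed_identical_report(self, cfg_sd):
        a = mf.estimate_basin(cfg_sd, 64, seed=9, max_iter=100_000)
        b = mf.estimate_basin(cfg_sd, 64, seed=9, max_iter=100_000)
        assert a.fractions == b.fractions

    def test_snow_drift_basin_larger_than_stag_hunt(self, cfg_sd, cfg_sh):
        a = mf.estimate_basin(cfg_sd, 400, seed=3, max_iter=150_000)
        b = mf.estimate_basin(cfg_sh, 400, seed=3, max_iter=150_000)
        assert a.fractions["cooperative"] > b.fractions["cooperative"]

    def test_conditioning_bins(self, cfg_sd):
        rep = mf.estimate_basin(cfg_sd, 200, seed=4, conditioning="rho_C_init", max_iter=150_000)
        assert len(rep.bins) == 10
        assert all(b["n"] >= 0 for b in rep.bins)


class TestInvariancesOfTheStationaryState:
    def test_eta_symmetry_of_stationary_cooperation(self, pd_base, snow_drift):
        rc = {}
        for eta in (0.2, 0.8):
            cfg = mf.DynamicsConfig(pd_base, snow_drift, nu=0.005, eta=eta)
            r = mf.run_to_stationarity(mf.center_distribution(), cfg)
            rc[eta] = float(r.distribution[:4].sum())
        assert abs(rc[0.2] - rc[0.8]) < 1e-8

    def test_cost_only_dependence(self, snow_drift):
        # equal cost, different benefit: identical stationary state in the
        # small-mutation limit (nu=1e-8 keeps the distortion ~1e-7)
        outs = []
        for b in (1.0, 3.0):
            cfg = mf.DynamicsConfig(cg.helping_game(b, 0.8), snow_drift, nu=1e-8, pi0=5.0)
            r = mf.run_to_stationarity(mf.center_distribution(), cfg)
            assert r.converged
            outs.append(r.distribution)
        assert np.abs(outs[0] - outs[1]).max() < 1e-6


def test_positivity_enforced_at_construction(snow_drift):
    with pytest.raises(PositivityError):
        mf.DynamicsConfig(cg.helping_game(2.0, 1.0), snow_drift, pi0=0.0)
    mf.DynamicsConfig(cg.helping_game(2.0, 1.0), snow_drift, pi0=5.0)
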