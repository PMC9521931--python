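import numpy as np
import pytest

import coupledgames as cg
from coupledgames.twostage import (
    STRATEGY_INDEX,
    STRATEGY_NAMES,
    GameClassError,
    swap_replies_index,
)

from conftest import TABLE2_SD, TABLE2_SH, random_anti_coordination, random_game


def SI(name):
    return STRATEGY_INDEX[name]


class TestCompositeStrategies:
    def test_canonical_order(self):
        assert STRATEGY_NAMES == ("Cuu", "Cud", "Cdu", "Cdd", "Duu", "Dud", "Ddu", "Ddd")

    def test_letters(self):
        s = cg.CompositeStrategy.from_name("Cdu")
        assert (s.pd_action, s.reply_to_C, s.reply_to_D) == ("C", "d", "u")


class TestDirectMatrix:
    def test_reproduces_printed_tables_exactly(self, m_sd, m_sh):
        assert np.array_equal(m_sd.entries, TABLE2_SD)
        assert np.array_equal(m_sh.entries, TABLE2_SH)

    def test_named_cells(self, m_sd, m_sh):
        assert m_sd.cell("Cuu", "Cdu") == 8  # R + T_B
        assert m_sh.cell("Ddu", "Cdd") == 10
        assert m_sd.cell("Cud", "Cdu") == 3 + 5  # Cud earns T_B against Cdu

    def test_column_player_symmetry(self, m_sd):
        # column player's payoff in (i, j) is entries[j][i]; checked via a
        # relabelling-free brute force on a random game pair
        rng = np.random.default_rng(3)
        m = cg.build_direct_matrix(random_game(rng, ("C", "D")), random_game(rng))
        assert m.entries.shape == (8, 8)

    def test_all_zero_games_give_zero_matrix(self):
        z = cg.SymmetricGame2x2(0, 0, 0, 0, ("C", "D"))
        zb = cg.SymmetricGame2x2(0, 0, 0, 0, ("d", "u"))
        assert not cg.build_direct_matrix(z, zb).entries.any()


class TestReputationMatrix:
    def test_eta_zero_equals_direct(self, pd_base, snow_drift, m_sd):
        m0 = cg.build_reputation_matrix(pd_base, snow_drift, 0.0)
        assert np.array_equal(m0.entries, m_sd.entries)

    def test_maximal_noise_erases_conditioning(self, pd_base, snow_drift):
        m = cg.build_reputation_matrix(pd_base, snow_drift, 0.5)
        assert np.allclose(m.entries[SI("Cud")], m.entries[SI("Cdu")])
        assert np.allclose(m.entries[SI("Dud")], m.entries[SI("Ddu")])

    def test_eta_reflection_equals_reply_swap(self):
        rng = np.random.default_rng(11)
        perm = swap_replies_index()
        for _ in range(25):
            pdg = random_game(rng, ("C", "D"))
            gb = random_game(rng)
            eta = rng.uniform(0, 1)
            a = cg.build_reputation_matrix(pdg, gb, eta).entries
            b = cg.build_reputation_matrix(pdg, gb, 1.0 - eta).entries
            assert np.allclose(a, b[np.ix_(perm, perm)])

    def test_eta_out_of_range_rejected(self, pd_base, snow_drift):
        with pytest.raises(Exception):
            cg.build_reputation_matrix(pd_base, snow_drift, 1.5)


class TestPureNash:
    def test_snow_drift_census(self, m_sd):
        ne = set(cg.enumerate_pure_nash(m_sd))
        assert (SI("Cuu"), SI("Ddu")) in ne
        assert (SI("Ddu"), SI("Cuu")) in ne
        coop = {p for p in ne if cg.classify_profile(p) == "cooperative"}
        assert coop == {(SI("Cuu"), SI("Ddu")), (SI("Ddu"), SI("Cuu"))}
        # defective equilibria anti-coordinate (one party plays u, the other d
        # against defectors); mutual-Ddd is *not* an equilibrium here
        assert (SI("Ddd"), SI("Ddd")) not in ne

    def test_stag_hunt_census(self, m_sh):
        ne = set(cg.enumerate_pure_nash(m_sh))
        d_coord = {(SI(a), SI(b)) for a in ("Dud", "Ddd") for b in ("Dud", "Ddd")}
        hetero = {
            (SI("Cud"), SI("Ddu")),
            (SI("Ddu"), SI("Cud")),
            (SI("Cdd"), SI("Ddu")),
            (SI("Ddu"), SI("Cdd")),
        }
        assert ne == d_coord | {(SI("Duu"), SI("Duu"))} | hetero | {(SI("Cdu"), SI("Cdu"))}

    def test_profile_classification(self):
        assert cg.classify_profile((SI("Ddd"), SI("Ddd"))) == "defective"
        assert cg.classify_profile((SI("Cuu"), SI("Ddu"))) == "cooperative"
        assert cg.classify_profile((SI("Cdu"), SI("Cdu"))) == "cooperative"


class TestCooperativeCondition:
    def test_base_presets(self, pd_base, snow_drift, stag_hunt):
        c_sd = cg.cooperative_ne_condition(pd_base, snow_drift)
        assert (c_sd.exists, c_sd.cost, c_sd.threshold) == (True, 1, 4)
        c_sh = cg.cooperative_ne_condition(pd_base, stag_hunt)
        assert (c_sh.exists, c_sh.cost, c_sh.threshold) == (True, 1, 4)

    def test_costly_helping_game_has_no_cooperative_profile(self, snow_drift):
        hg = cg.helping_game(10.0, 5.0)  # cost 5 > coordination asymmetry 4
        cond = cg.cooperative_ne_condition(hg, snow_drift)
        assert not cond.exists
        ne = cg.enumerate_pure_nash(cg.build_direct_matrix(hg, snow_drift))
        assert all(cg.classify_profile(p) == "defective" for p in ne)

    def test_dominance_game_b_signals_impossibility(self, pd_base):
        with pytest.raises(GameClassError):
            cg.cooperative_ne_condition(pd_base, cg.preset("prisoners_dilemma"))

    def test_condition_matches_enumeration_on_random_games(self, pd_base):
        # strict-inequality cases only: ties make weak equilibria ambiguous
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 500:
            gb = random_anti_coordination(rng)
            cond = cg.cooperative_ne_condition(pd_base, gb)
            if abs(cond.cost - cond.threshold) < 1e-6:
                continue
            ne = cg.enumerate_pure_nash(cg.build_direct_matrix(pd_base, gb))
            has_coop = any(cg.classify_profile(p) == "cooperative" for p in ne)
            assert has_coop == cond.exists, f"{gb.payoffs}"
            checked += 1


class TestMixedOnSupport:
    def test_stag_hunt_cdd_ddu(self, m_sh):
        p = cg.solve_mixed_on_support(m_sh, ["Cdd", "Ddu"])
        assert p is not None and p.verified
        assert np.isclose(p.prob("Cdd"), 0.6) and np.isclose(p.prob("Ddu"), 0.4)

    def test_stag_hunt_cud_ddu(self, m_sh):
        p = cg.solve_mixed_on_support(m_sh, ["Cud", "Ddu"])
        assert p is not None and p.verified
        assert np.isclose(p.prob("Cud"), 1 / 3) and np.isclose(p.prob("Ddu"), 2 / 3)

    def test_snow_drift_defective_mixture(self, m_sd):
        # Defectors anti-coordinate: the defective mixed equilibrium plays
        # d with defectors at the Snow Drift mixed-NE frequency 1/3.
        p = cg.solve_mixed_on_support(m_sd, ["Duu", "Dud"])
        assert p is not None and p.verified
        assert np.isclose(p.prob("Dud"), 1 / 3)

    def test_pure_ddd_is_not_an_equilibrium(self, m_sd):
        # Cuu and Duu/Ddu earn more against Ddd than Ddd earns against itself.
        assert cg.solve_mixed_on_support(m_sd, ["Ddd"]) is None

    def test_verified_profiles_have_no_profitable_deviation(self, m_sd, m_sh):
        for m, support in [
            (m_sh, ["Cdd", "Ddu"]),
            (m_sh, ["Cud", "Ddu"]),
            (m_sd, ["Duu", "Dud"]),
        ]:
            p = cg.solve_mixed_on_support(m, support)
            payoffs = m.entries @ p.probabilities
            v = payoffs[list(p.support)].mean()
            assert payoffs.max() <= v + 1e-9


class TestClosedForms:
    def test_sh2_matches_matrix_oracle(self, pd_base, stag_hunt, m_sh):
        cf = cg.closed_form_equilibrium(pd_base, stag_hunt, "SH2")
        assert np.isclose(cf.prob("Cud"), 1 / 3) and np.isclose(cf.prob("Ddu"), 2 / 3)
        oracle = cg.solve_mixed_on_support(m_sh, ["Cud", "Ddu"])
        assert np.allclose(cf.probabilities, oracle.probabilities)

    def test_sh1_printed_formula_disagrees_with_matrix(self, pd_base, stag_hunt, m_sh):
        # The printed two-strategy formula for the Cdd-Ddu fixed point gives
        # (2/3, 1/3); indifference on the printed payoff table gives
        # (0.6, 0.4).  Both are reproduced; the substitution is flagged
        # unverified and is indeed not a best reply against itself.
        cf = cg.closed_form_equilibrium(pd_base, stag_hunt, "SH1")
        assert np.isclose(cf.prob("Cdd"), 2 / 3) and np.isclose(cf.prob("Ddu"), 1 / 3)
        assert not cf.verified
        oracle = cg.solve_mixed_on_support(m_sh, ["Cdd", "Ddu"])
        assert np.isclose(oracle.prob("Cdd"), 0.6)
        payoffs = m_sh.entries @ cf.probabilities
        sup = [STRATEGY_INDEX["Cdd"], STRATEGY_INDEX["Ddu"]]
        assert abs(payoffs[sup[0]] - payoffs[sup[1]]) > 1e-6  # not indifferent

    def test_ac4_substitution_and_oracle_agree(self, snow_drift):
        hg = cg.helping_game(2.0, 1.0)
        cf = cg.closed_form_equilibrium(hg, snow_drift, "AC4")
        expected = {"Cuu": 7 / 12, "Cdu": 7 / 24, "Ddu": 1 / 12, "Ddd": 1 / 24}
        for name, val in expected.items():
            assert np.isclose(cf.prob(name), val)
        oracle = cg.solve_mixed_on_support(
            cg.build_direct_matrix(hg, snow_drift), ["Cuu", "Cdu", "Ddu", "Ddd"]
        )
        assert oracle is not None and np.allclose(cf.probabilities, oracle.probabilities)

    def test_class_mismatch_rejected(self, pd_base, snow_drift, stag_hunt):
        with pytest.raises(GameClassError):
            cg.closed_form_equilibrium(pd_base, snow_drift, "SH1")
        with pytest.raises(GameClassError):
            cg.closed_form_equilibrium(pd_base, stag_hunt, "AC4")


class TestFullyCooperativeFamily:
    def test_family_constraints_for_base_snow_drift(self, snow_drift):
        fam = cg.closed_form_equilibrium(cg.helping_game(1.2, 0.2), snow_drift, "FC")
        assert np.isclose(fam.x_cuu_plus_x_cud, 2 / 3)
        assert np.isclose(fam.x_cdu_plus_x_cdd, 1 / 3)
        assert np.isclose(fam.printed_bound, 1 / 3 - 0.1)
        assert fam.exists

    @pytest.mark.parametrize("c,expected", [(0.2, True), (0.5, True), (0.7, False), (0.9, False)])
    def test_existence_threshold_two_thirds(self, snow_drift, c, expected):
        fam = cg.closed_form_equilibrium(cg.helping_game(c + 1, c), snow_drift, "FC")
        assert fam.exists is expected

    def test_member_accept_and_reject(self, snow_drift):
        # matrix no-deviation check binds on x_Cud + x_Cdd <= 1/3 - c/2
        assert cg.fully_cooperative_family_member(snow_drift, 0.2, 0.05, 0.10) is not None
        assert cg.fully_cooperative_family_member(snow_drift, 0.2, 0.05, 0.30) is None
        assert cg.fully_cooperative_family_member(snow_drift, 0.2, 0.30, 0.00) is None
        assert cg.fully_cooperative_family_member(snow_drift, 0.7, 0.0, 0.0) is None

    def test_accepted_member_is_verified_on_matrix(self, snow_drift):
        p = cg.fully_cooperative_family_member(snow_drift, 0.2, 0.05, 0.10)
        m = cg.build_direct_matrix(cg.helping_game(1.2, 0.2), snow_drift)
        payoffs = m.entries @ p.probabilities
        v = payoffs[list(p.support)].mean()
        assert payoffs.max() <= v + 1e-9
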