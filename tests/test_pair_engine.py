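import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multiplexcoop import pair_engine as pe
from multiplexcoop.games import GameSpec

from conftest import random_linked, random_unlinked


GAMES = GameSpec.donation((5.0, 3.0), (1.0, 1.0))


class TestBuildTransition:
    def test_alld_vs_alld_absorbs_at_dddd(self):
        M, v0 = pe.build_transition(pe.LinkedStrategy.alld(), pe.LinkedStrategy.alld())
        np.testing.assert_allclose(M[:, 15], 1.0)
        np.testing.assert_allclose(M[:, :15], 0.0)
        assert v0[15] == 1.0

    def test_allc_vs_allc_absorbs_at_cccc(self):
        M, v0 = pe.build_transition(pe.LinkedStrategy.allc(), pe.LinkedStrategy.allc())
        np.testing.assert_allclose(M[:, 0], 1.0)
        assert v0[0] == 1.0

    def test_interior_strategies_give_positive_matrix(self, rng):
        si = pe.LinkedStrategy(p0=np.full(2, 0.5),
                               cond=rng.uniform(0.1, 0.9, (2, 4)))
        sj = pe.LinkedStrategy(p0=np.full(2, 0.5),
                               cond=rng.uniform(0.1, 0.9, (2, 4)))
        M, v0 = pe.build_transition(si, sj)
        assert (M > 0).all()
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_rejects_unlinked(self):
        with pytest.raises(TypeError):
            pe.build_transition(pe.UnlinkedStrategy.allc(), pe.LinkedStrategy.allc())


class TestVisitDistribution:
    def test_absorbing_chain_point_mass(self):
        M, _ = pe.build_transition(pe.LinkedStrategy.alld(), pe.LinkedStrategy.alld())
        v0 = np.zeros(16)
        v0[0] = 1.0  # cooperative start still absorbs at DDDD
        v = pe.visit_distribution(M, v0, 1.0)
        assert v[15] == pytest.approx(1.0)

    def test_discounted_limit_matches_cesaro(self, rng):
        """w -> 1- discounted distribution converges to the Cesàro result."""
        si, sj = random_linked(rng), random_linked(rng)
        M, v0 = pe.build_transition(si, sj)
        v_disc = pe.visit_distribution(M, v0, 1 - 1e-6)
        v_ces = pe.visit_distribution(M, v0, 1.0)
        np.testing.assert_allclose(v_disc, v_ces, atol=1e-5)

    def test_periodic_chain_cycle_average(self):
        # deterministic 2-cycle: Cesàro average puts 1/2 on each state
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        v = pe.visit_distribution(M, np.array([1.0, 0.0]), 1.0)
        np.testing.assert_allclose(v, [0.5, 0.5], atol=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            pe.visit_distribution(np.array([[0.5, 0.4], [0.5, 0.5]]),
                                  np.array([1.0, 0.0]), 1.0)
        with pytest.raises(ValueError):
            pe.visit_distribution(np.eye(2), np.array([0.7, 0.7]), 1.0)


class TestPairOutcome:
    def test_mutual_cooperation(self):
        po = pe.pair_outcome(pe.LinkedStrategy.allc(), pe.LinkedStrategy.allc(),
                             GAMES, w=1.0)
        np.testing.assert_allclose(po.pi_ij, [4.0, 2.0])
        np.testing.assert_allclose(po.gamma_ij, 1.0)
        np.testing.assert_allclose(po.gamma_ji, 1.0)

    def test_alld_exploits_allc_unlinked(self):
        po = pe.pair_outcome(pe.UnlinkedStrategy.alld(), pe.UnlinkedStrategy.allc(),
                             GAMES, w=1.0)
        assert po.pi_ij[0] == pytest.approx(5.0)   # T for the defector
        assert po.pi_ji[0] == pytest.approx(-1.0)  # S for the cooperator
        assert po.gamma_ij[0] == pytest.approx(0.0)
        assert po.gamma_ji[0] == pytest.approx(1.0)

    def test_worked_single_layer_defector_pair(self, toy_strategies):
        """Resident (1,0,0,1;1,0,0,1) vs (0,0,0,0;1,0,0,1): the chain locks
        into the state where the resident defects in both games and the
        defector cooperates only in game 2, paying the resident b2 and the
        defector -c2."""
        po = pe.pair_outcome(toy_strategies["resident"],
                             toy_strategies["single_layer_defector"],
                             GAMES, w=1.0)
        assert po.v[1, 2] == pytest.approx(1.0)  # layer-2 state (D, C)
        assert po.pi_ij[1] == pytest.approx(3.0)    # b2
        assert po.pi_ji[1] == pytest.approx(-1.0)   # -c2

    def test_visit_normalization_and_symmetry(self, rng):
        for _ in range(20):
            si, sj = random_linked(rng), random_linked(rng)
            po = pe.pair_outcome(si, sj, GAMES, w=1.0)
            rev = pe.pair_outcome(sj, si, GAMES, w=1.0)
            np.testing.assert_allclose(po.v.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(po.v[:, [0, 2, 1, 3]], rev.v, atol=1e-9)
            np.testing.assert_allclose(po.pi_ij, rev.pi_ji, atol=1e-9)
            np.testing.assert_allclose(po.gamma_ij, rev.gamma_ji, atol=1e-9)

    def test_donation_identity(self, rng):
        """pi_ij = b*gamma_ji - c*gamma_ij holds exactly for donation games."""
        b = np.array([5.0, 3.0])
        c = np.array([1.0, 1.0])
        for _ in range(20):
            si, sj = random_linked(rng), random_linked(rng)
            po = pe.pair_outcome(si, sj, GAMES, w=1.0)
            np.testing.assert_allclose(
                po.pi_ij, b * po.gamma_ji - c * po.gamma_ij, atol=1e-10)

    def test_mixing_types_rejected(self):
        with pytest.raises(TypeError):
            pe.pair_outcome(pe.LinkedStrategy.allc(), pe.UnlinkedStrategy.allc(),
                            GAMES)

    def test_monte_carlo_rollout_agreement(self, rng):
        """Engine visit distributions match a sampled rollout within 3 SE."""
        n = 100_000
        for _ in range(3):
            si, sj = random_linked(rng), random_linked(rng)
            po = pe.pair_outcome(si, sj, GAMES, w=1.0)
            emp = pe.rollout_pair(si, sj, n, rng)
            se = np.sqrt(np.maximum(po.v * (1 - po.v), 1e-12) / n)
            # rollout samples are autocorrelated; allow a generous factor
            assert np.all(np.abs(emp - po.v) < 3 * se + 5e-3)


class TestEmbedding:
    def test_embedding_definition(self):
        u = pe.UnlinkedStrategy.from_tuple((1, 1, 0, 1, 1, 0))
        l = pe.embed_unlinked(u)
        np.testing.assert_allclose(l.cond[0], [1, 1, 0, 0])
        np.testing.assert_allclose(l.cond[1], [1, 0, 1, 0])
        np.testing.assert_allclose(
            pe.embed_unlinked(pe.UnlinkedStrategy.alld()).as_tuple(),
            pe.LinkedStrategy.alld().as_tuple())

    @pytest.mark.parametrize("w", [1.0, 0.7])
    def test_linked_engine_on_embedded_equals_unlinked(self, rng, w):
        for _ in range(10):
            ui, uj = random_unlinked(rng), random_unlinked(rng)
            po_u = pe.pair_outcome(ui, uj, GAMES, w=w)
            po_l = pe.pair_outcome(pe.embed_unlinked(ui), pe.embed_unlinked(uj),
                                   GAMES, w=w)
            np.testing.assert_allclose(po_u.v, po_l.v, atol=1e-12)
            np.testing.assert_allclose(po_u.pi_ij, po_l.pi_ij, atol=1e-12)
            np.testing.assert_allclose(po_u.gamma_ij, po_l.gamma_ij, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=12, max_size=12))
    def test_embedding_equivalence_property(self, vals):
        ui = pe.UnlinkedStrategy.from_tuple(vals[:6])
        uj = pe.UnlinkedStrategy.from_tuple(vals[6:])
        po_u = pe.pair_outcome(ui, uj, GAMES, w=0.9)
        po_l = pe.pair_outcome(pe.embed_unlinked(ui), pe.embed_unlinked(uj),
                               GAMES, w=0.9)
        np.testing.assert_allclose(po_u.v, po_l.v, atol=1e-12)


class TestPerceptionError:
    def test_zero_error_is_identity(self, rng):
        s = random_linked(rng)
        out = pe.apply_perception_error(s, pe.PerceptionError.none())
        np.testing.assert_allclose(out.cond, s.cond)
        np.testing.assert_allclose(out.p0, s.p0)

    def test_full_flip_swaps_conditionals(self, rng):
        s = random_linked(rng)
        out = pe.apply_perception_error(s, pe.PerceptionError(np.ones(2)))
        np.testing.assert_allclose(out.cond[:, 0], s.cond[:, 3])  # CC <-> DD
        np.testing.assert_allclose(out.cond[:, 1], s.cond[:, 2])  # CD <-> DC

    def test_half_error_symmetrizes_one_layer(self, rng):
        u = random_unlinked(rng)
        out = pe.apply_perception_error(u, pe.PerceptionError(np.array([0.5, 0.0])))
        assert out.pC[0] == pytest.approx((u.pC[0] + u.pD[0]) / 2)
        assert out.pD[0] == pytest.approx(out.pC[0])
        assert out.pC[1] == u.pC[1] and out.pD[1] == u.pD[1]

    def test_initial_probabilities_untouched(self, rng):
        s = random_linked(rng)
        out = pe.apply_perception_error(s, pe.PerceptionError(np.array([0.3, 0.7])))
        np.testing.assert_allclose(out.p0, s.p0)


def test_strategy_validation():
    with pytest.raises(ValueError):
        pe.LinkedStrategy(p0=np.array([0.5, 1.5]), cond=np.zeros((2, 4)))
    with pytest.raises(ValueError):
        pe.UnlinkedStrategy(p0=np.zeros(2), pC=np.full(2, -0.1), pD=np.zeros(2))
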