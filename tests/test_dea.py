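"""DEA linear programs against independently coded second formulations."""

import numpy as np
import pytest
from scipy.optimize import linprog

import healthdea as hd
from conftest import random_dea_instance

# ---------------------------------------------------------------------------
# independent oracle formulations (kept deliberately different from the
# implementation: CCR via the dual multiplier program, SBM via the
# slack-variable form, super-SBM via the excess-variable form)

def ccr_multiplier_oracle(inst, o):
    """max u.y_o  s.t.  v.x_o = 1,  u.Y_j - v.X_j <= 0,  u, v >= 0."""
    X, Y = inst.X, inst.Y
    m, n, s = inst.n_inputs, inst.n_dmus, inst.n_outputs
    c = np.concatenate([np.zeros(m), -Y[:, o]])
    A_ub = np.column_stack([-X.T, Y.T])
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(n),
                  A_eq=np.concatenate([X[:, o], np.zeros(s)])[None, :],
                  b_eq=[1.0], bounds=[(0, None)] * (m + s), method="highs")
    assert res.success
    return -res.fun


def sbm_slack_oracle(inst, o):
    """min 1 - (1/m) sum s_i/x_io  s.t.  X lam + s = x_o, Y lam >= y_o."""
    X, Y = inst.X, inst.Y
    m, n, s_dim = inst.n_inputs, inst.n_dmus, inst.n_outputs
    x_o, y_o = X[:, o], Y[:, o]
    c = np.concatenate([np.zeros(n), -1.0 / (m * x_o)])
    A_eq = np.column_stack([X, np.eye(m)])
    res = linprog(c, A_eq=A_eq, b_eq=x_o,
                  A_ub=np.column_stack([-Y, np.zeros((s_dim, m))]),
                  b_ub=-y_o, bounds=[(0, None)] * (n + m), method="highs")
    assert res.success
    return 1.0 + res.fun


def super_sbm_excess_oracle(inst, o):
    """min 1 + (1/m) sum t_i/x_io with xbar = x_o + t, t >= 0."""
    X, Y = inst.X, inst.Y
    m, n, s_dim = inst.n_inputs, inst.n_dmus, inst.n_outputs
    x_o, y_o = X[:, o], Y[:, o]
    others = [j for j in range(n) if j != o]
    Xo, Yo = X[:, others], Y[:, others]
    c = np.concatenate([np.zeros(n - 1), 1.0 / (m * x_o)])
    A_ub = np.block([
        [Xo, -np.eye(m)],                      # Xo lam - t <= x_o
        [-Yo, np.zeros((s_dim, m))],           # -Yo lam <= -y_o
    ])
    b_ub = np.concatenate([x_o, -y_o])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                  bounds=[(0, None)] * (n - 1 + m), method="highs")
    if res.status == 2:
        return float("inf")
    assert res.success
    return 1.0 + res.fun


# ---------------------------------------------------------------------------

class TestCCR:
    def test_single_dmu_is_efficient(self):
        inst = hd.DEAInstance(X=[[2.0], [3.0]], Y=[[5.0]])
        res = hd.ccr_input(inst, 0)
        assert res.theta == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res.total_slacks, 0.0, atol=1e-8)

    def test_doubled_inputs_halve_theta(self):
        inst = hd.DEAInstance(X=[[1.0, 2.0], [1.0, 2.0]], Y=[[1.0, 1.0]])
        assert hd.ccr_input(inst, 1).theta == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_multiplier_dual(self, seed):
        inst = random_dea_instance(np.random.default_rng(seed))
        for o in range(inst.n_dmus):
            theta = hd.ccr_input(inst, o).theta
            assert theta == pytest.approx(ccr_multiplier_oracle(inst, o),
                                          abs=1e-7)

    def test_total_slack_nonnegative_and_consistent(self):
        inst = random_dea_instance(np.random.default_rng(77))
        for o in range(inst.n_dmus):
            res = hd.ccr_input(inst, o)
            assert np.all(res.total_slacks >= -1e-9)
            assert np.allclose(res.total_slacks,
                               inst.X[:, o] - res.input_targets, atol=1e-7)


class TestSBM:
    def test_hand_example(self):
        # B wastes half of input 1: delta = mean(1/2, 1) = 0.75
        inst = hd.DEAInstance(X=[[1.0, 2.0], [1.0, 1.0]], Y=[[1.0, 1.0]])
        assert hd.sbm_input(inst, 1).delta == pytest.approx(0.75, abs=1e-9)

    def test_efficient_dmu_scores_one(self):
        inst = hd.DEAInstance(X=[[1.0, 2.0], [1.0, 1.0]], Y=[[1.0, 1.0]])
        score = hd.sbm_input(inst, 0)
        assert score.delta == pytest.approx(1.0, abs=1e-9)
        assert score.efficient

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_slack_formulation_and_bounded_by_ccr(self, seed):
        inst = random_dea_instance(np.random.default_rng(100 + seed))
        for o in range(inst.n_dmus):
            delta = hd.sbm_input(inst, o).delta
            assert delta == pytest.approx(sbm_slack_oracle(inst, o), abs=1e-7)
            assert delta <= hd.ccr_input(inst, o).theta + 1e-7


class TestSuperSBM:
    def test_twin_efficient_dmus_score_one(self):
        inst = hd.DEAInstance(X=[[1.0, 1.0], [1.0, 1.0]], Y=[[1.0, 1.0]])
        assert hd.super_sbm_input(inst, 0).delta == pytest.approx(1.0, abs=1e-9)

    def test_hand_example_scores_two(self):
        inst = hd.DEAInstance(X=[[1.0, 2.0], [1.0, 2.0]], Y=[[1.0, 1.0]])
        assert hd.super_sbm_input(inst, 0).delta == pytest.approx(2.0, abs=1e-9)

    def test_sole_producer_unbounded(self):
        # only DMU 0 produces output 2: no reference set can match it
        inst = hd.DEAInstance(X=[[1.0, 1.0]], Y=[[1.0, 1.0], [1.0, 0.0]])
        assert hd.super_sbm_input(inst, 0).delta == float("inf")

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_excess_formulation(self, seed):
        inst = random_dea_instance(np.random.default_rng(200 + seed))
        for o in range(inst.n_dmus):
            mine = hd.super_sbm_input(inst, o).delta
            ref = super_sbm_excess_oracle(inst, o)
            if np.isinf(ref):
                assert np.isinf(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-7)

    @pytest.mark.parametrize("seed", [40, 44, 45, 52])
    def test_removing_inefficient_dmu_preserves_super_scores(self, seed):
        # seeds chosen so the instance holds both efficient and
        # inefficient units
        rng = np.random.default_rng(seed)
        inst = random_dea_instance(rng, n_max=6)
        scores = [hd.sbm_input(inst, o).delta for o in range(inst.n_dmus)]
        worst = int(np.argmin(scores))
        assert scores[worst] < 1 - 1e-9
        keep = [j for j in range(inst.n_dmus) if j != worst]
        reduced = hd.DEAInstance(X=inst.X[:, keep], Y=inst.Y[:, keep])
        for new_o, old_o in enumerate(keep):
            if scores[old_o] >= 1 - 1e-9:
                assert (hd.super_sbm_input(reduced, new_o).delta
                        == pytest.approx(hd.super_sbm_input(inst, old_o).delta,
                                         abs=1e-7))


class TestCompositeScoreAndInvariances:
    def test_dominated_dmu_below_one_unique_best_above_one(self):
        inst = hd.DEAInstance(X=[[1.0, 3.0], [1.0, 3.0]], Y=[[1.0, 1.0]])
        assert hd.efficiency_score(inst, 1).delta < 1.0
        assert hd.efficiency_score(inst, 0).delta > 1.0
        assert hd.efficiency_score(inst, 0).mode == "super"

    @pytest.mark.parametrize("seed", range(10))
    def test_units_invariance(self, seed):
        rng = np.random.default_rng(300 + seed)
        inst = random_dea_instance(rng)
        X2 = inst.X.copy()
        Y2 = inst.Y.copy()
        X2[0] *= 1000.0      # e.g. beds counted in thousands
        Y2[0] *= 0.001
        inst2 = hd.DEAInstance(X=X2, Y=Y2)
        for o in range(inst.n_dmus):
            assert (hd.efficiency_score(inst2, o).delta
                    == pytest.approx(hd.efficiency_score(inst, o).delta,
                                     rel=1e-6))
            assert (hd.ccr_input(inst2, o).theta
                    == pytest.approx(hd.ccr_input(inst, o).theta, abs=1e-7))

    def test_adding_dominated_dmu_changes_no_score(self):
        rng = np.random.default_rng(17)
        inst = random_dea_instance(rng)
        before = [hd.efficiency_score(inst, o).delta for o in range(inst.n_dmus)]
        dominated = np.column_stack([inst.X, inst.X[:, 0] * 2.0])
        Y_ext = np.column_stack([inst.Y, inst.Y[:, 0] * 0.5])
        ext = hd.DEAInstance(X=dominated, Y=Y_ext)
        after = [hd.efficiency_score(ext, o).delta for o in range(inst.n_dmus)]
        assert np.allclose(before, after, atol=1e-7)

    def test_adding_dominating_dmu_weakly_decreases_standard_scores(self):
        rng = np.random.default_rng(19)
        inst = random_dea_instance(rng)
        before = [hd.sbm_input(inst, o).delta for o in range(inst.n_dmus)]
        strong_x = inst.X.min(axis=1) * 0.5
        strong_y = inst.Y.max(axis=1) * 2.0
        ext = hd.DEAInstance(X=np.column_stack([inst.X, strong_x]),
                             Y=np.column_stack([inst.Y, strong_y]))
        after = [hd.sbm_input(ext, o).delta for o in range(inst.n_dmus)]
        assert np.all(np.asarray(after) <= np.asarray(before) + 1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            hd.DEAInstance(X=[[1.0, 0.0]], Y=[[1.0, 1.0]])

    def test_discriminative_power_rule(self):
        inst = hd.DEAInstance(X=np.ones((3, 5)), Y=np.ones((4, 5)))
        with pytest.raises(ValueError, match="discriminative"):
            inst.validate_discriminative_power()
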