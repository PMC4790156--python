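import numpy as np
import pytest

from confcount.discretize import ConformerDefinition, DihedralTrajectory
from confcount.free_energy import (
    UndefinedFreeEnergyError,
    cpd,
    convergence_trend,
    delta_F_conf,
    delta_F_snap,
    pairwise_ddF,
    scaling_data,
)
from confcount.macrostates import build_macrostates, count_conformers_per_macrostate


class TestDeltaF:
    def test_equal_populations_zero(self):
        assert delta_F_snap(100, 100) == 0.0

    def test_tenfold_ratio(self):
        assert delta_F_snap(1000, 100) == pytest.approx(np.log(10), abs=1e-9)

    def test_zero_count_raises(self):
        with pytest.raises(UndefinedFreeEnergyError):
            delta_F_snap(0, 10)

    def test_conf_estimator_same_form(self):
        assert delta_F_conf(50, 50) == 0.0
        assert delta_F_conf(100, 100 * np.e) == pytest.approx(-1.0, abs=1e-12)

    def test_antisymmetry_and_path_consistency(self):
        counts = [120, 37, 980]
        f_ab = delta_F_snap(counts[0], counts[1])
        f_ba = delta_F_snap(counts[1], counts[0])
        f_bc = delta_F_snap(counts[1], counts[2])
        f_ac = delta_F_snap(counts[0], counts[2])
        assert f_ab == pytest.approx(-f_ba, abs=1e-12)
        assert f_ac == pytest.approx(f_ab + f_bc, abs=1e-12)


def _mset_with_counts(traj, cd, order_params=(0,), width=18.0):
    mset = build_macrostates(traj, order_params, width)
    count_conformers_per_macrostate(mset, traj, cd)
    return mset


class TestPairwiseDdf:
    def test_row_count(self, random_traj):
        cd = ConformerDefinition("c", (1, 2))
        mset = _mset_with_counts(random_traj, cd)
        m = mset.n_observed
        table = pairwise_ddF(mset, "c")
        assert len(table) == m * (m - 1) // 2

    def test_ddf_is_difference_of_estimates(self, random_traj):
        cd = ConformerDefinition("c", (1, 2))
        table = pairwise_ddF(_mset_with_counts(random_traj, cd), "c")
        assert np.allclose(table.ddF, table.dF_snap - table.dF_conf)

    def test_pair_swap_negates(self, random_traj):
        """Antisymmetry: recomputing with roles swapped flips every sign."""
        cd = ConformerDefinition("c", (1, 2))
        mset = _mset_with_counts(random_traj, cd)
        table = pairwise_ddF(mset, "c")
        n_snap = mset.counts
        n_conf = mset.conformer_counts["c"]
        for row in table.head(10).itertuples():
            fwd = delta_F_snap(n_snap[row.macrostate_j], n_snap[row.macrostate_i])
            rev = delta_F_snap(n_snap[row.macrostate_i], n_snap[row.macrostate_j])
            assert fwd == pytest.approx(-rev, abs=1e-12)
            assert fwd == pytest.approx(row.dF_snap, abs=1e-12)

    def test_path_consistency_across_pairs(self, random_traj):
        cd = ConformerDefinition("c", (1, 2))
        mset = _mset_with_counts(random_traj, cd)
        table = pairwise_ddF(mset, "c")
        f = {(r.macrostate_i, r.macrostate_j): r.dF_snap for r in table.itertuples()}
        obs = np.flatnonzero(mset.observed)
        a, b, c = obs[0], obs[1], obs[2]
        assert f[(c, a)] == pytest.approx(f[(b, a)] + f[(c, b)], abs=1e-12)
        assert all(i > j for i, j in f)

    def test_iswd_limit_all_zero(self, injective_traj, injective_conf_def):
        mset = _mset_with_counts(injective_traj, injective_conf_def)
        table = pairwise_ddF(mset, injective_conf_def.name)
        assert np.all(table.ddF == 0.0)

    def test_needs_two_observed(self):
        traj = DihedralTrajectory(np.zeros((5, 2)) + 10.0)
        cd = ConformerDefinition("c", (1,))
        mset = _mset_with_counts(traj, cd)
        with pytest.raises(ValueError):
            pairwise_ddF(mset, "c")


class TestCPD:
    def test_all_zeros_step_at_zero(self):
        curve = cpd(np.zeros(10), x_max=2.0)
        assert curve.evaluate(0.0) == 1.0
        assert curve.auc == pytest.approx(2.0)

    def test_absolute_values_used(self):
        curve = cpd(np.array([-1.0, 1.0]))
        assert curve.x[-1] == 1.0
        assert curve.evaluate(0.999) == 0.0
        assert curve.evaluate(1.0) == 1.0

    def test_shift_never_increases_auc(self, rng):
        """Stochastic dominance: adding +eps to |values| lowers the CPD."""
        v = rng.exponential(size=200)
        base = cpd(v, x_max=10.0)
        shifted = cpd(v + 0.25, x_max=10.0)
        assert shifted.auc <= base.auc

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cpd([])


class TestScaling:
    def test_iswd_identity_line(self, injective_traj, injective_conf_def):
        mset = _mset_with_counts(injective_traj, injective_conf_def)
        fit = scaling_data(mset, injective_conf_def.name)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_saturated_conformers_flatten_y(self, rng):
        """When N_conf saturates, heavy macrostates deviate below identity."""
        # one torsion sharply peaked: one window dominates but the conformer
        # space within it saturates at 3**1 states of a second torsion
        ang0 = rng.normal(0.0, 12.0, size=5000).clip(-179, 179)
        ang1 = rng.uniform(-180, 180, size=5000)
        traj = DihedralTrajectory(np.column_stack([ang0, ang1]))
        cd = ConformerDefinition("c", (1,))
        mset = _mset_with_counts(traj, cd, width=36.0)
        fit = scaling_data(mset, "c")
        # heaviest macrostate: x small; y cannot go below -ln(3/total) => point
        # sits above the identity line through the origin-normalized axes
        i = np.argmin(fit.x)
        assert fit.y[i] > fit.x[i]
        assert fit.slope < 1.0

    def test_too_few_points_rejected(self):
        traj = DihedralTrajectory(np.array([[0.0, 1.0], [100.0, 2.0]]))
        cd = ConformerDefinition("c", (1,))
        mset = _mset_with_counts(traj, cd)
        with pytest.raises(ValueError):
            scaling_data(mset, "c")


class TestConvergenceTrend:
    def test_single_fraction_rejected(self, random_traj):
        cd = ConformerDefinition("c", (1,))
        with pytest.raises(ValueError):
            convergence_trend(random_traj, cd, [1.0])

    def test_injective_definition_stays_at_max(self, injective_traj, injective_conf_def):
        trend = convergence_trend(injective_traj, injective_conf_def,
                                  [0.5, 1.0], order_params=[0])
        fine = trend[trend.conf_def == injective_conf_def.name]
        # deviations are identically zero, so AUC equals the full range at
        # every subset size (degenerate shrinking case)
        assert np.allclose(fine.auc, fine.auc.iloc[0])
        assert fine.classification.iloc[0] == "shrinking"
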