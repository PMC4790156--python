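import numpy as np
import pytest
from scipy import integrate

from confcount import synthetic as syn
from confcount.discretize import ConformerDefinition
from confcount.macrostates import MacrostateSelector


class TestDoubleWell:
    def test_symmetric_wells_split_evenly(self):
        spec = syn.DoubleWellSpec(delta_U=0.0)
        s = syn.sample_double_well(spec, 100000, seed=1)
        n_a = np.sum(s.labels == "A")
        n_wells = np.sum(s.labels != "barrier")
        se = 0.5 * np.sqrt(n_wells)
        assert abs(n_a - n_wells / 2) < 3 * se

    def test_population_ratio_matches_quadrature_oracle(self):
        """N_B/N_A converges to the Boltzmann integral ratio of the wells."""
        spec = syn.DoubleWellSpec(delta_U=2.0)
        s = syn.sample_double_well(spec, 200000, seed=2)
        za, _ = integrate.quad(lambda x: np.exp(-spec.energy(x)), *spec.well_A)
        zb, _ = integrate.quad(lambda x: np.exp(-spec.energy(x)), *spec.well_B)
        n_a, n_b = np.sum(s.labels == "A"), np.sum(s.labels == "B")
        ratio = n_b / n_a
        se = ratio * np.sqrt(1 / n_a + 1 / n_b)
        assert abs(ratio - zb / za) < 3 * se
        assert zb / za == pytest.approx(np.exp(-2.0), rel=1e-10)

    def test_energies_recomputable(self):
        spec = syn.DoubleWellSpec()
        s = syn.sample_double_well(spec, 1000, seed=3)
        assert np.array_equal(s.energies, spec.energy(s.x))

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            syn.sample_double_well(syn.DoubleWellSpec(), 0, seed=0)

    def test_malformed_spec_rejected(self):
        with pytest.raises(ValueError):
            syn.DoubleWellSpec(well_width=0.6)  # wells overlap
        with pytest.raises(ValueError):
            syn.DoubleWellSpec(barrier_height=1.0, delta_U=2.0)

    def test_uniform_conformers_violate_iswd(self):
        """Deep unequal wells: δΔF(B→A) -> -ΔU under any uniform grid."""
        spec = syn.DoubleWellSpec(delta_U=2.0)
        s = syn.sample_double_well(spec, 400000, seed=4)
        for n_cells in (20, 40, 80):
            r = syn.double_well_ddf(s, n_cells=n_cells)
            assert r["ddF"] == pytest.approx(-2.0, abs=0.05)


class TestTorsionSystemSampling:
    def test_flat_energies_uniform(self):
        ts = syn.TorsionSystem(site_energies=np.zeros((1, 36)))
        s = syn.sample_torsion_system(ts, 72000, seed=5)
        counts = np.bincount(s.grid_indices[:, 0], minlength=36)
        assert np.all(np.abs(counts - 2000) < 4 * np.sqrt(2000))

    def test_two_torsions_factorize(self):
        ts = syn.popc_like_system(seed=6, n_torsions=2, grid_size=12)
        s = syn.sample_torsion_system(ts, 100000, seed=7)
        p = ts.marginals()
        joint = np.zeros((12, 12))
        np.add.at(joint, (s.grid_indices[:, 0], s.grid_indices[:, 1]), 1)
        joint /= joint.sum()
        expected = np.outer(p[0], p[1])
        # total-variation distance shrinks at the Monte-Carlo rate
        assert 0.5 * np.abs(joint - expected).sum() < 0.02

    def test_mcmc_matches_enumeration(self):
        """Coupled 3-torsion system: MCMC marginals vs brute-force grid."""
        ts = syn.popc_like_system(seed=8, n_torsions=3, grid_size=12,
                                  coupled=True, coupling_strength=1.0)
        s = syn.sample_torsion_system(ts, 6000, seed=9, sampler="mcmc",
                                      thinning=3 * 4)
        p = syn._joint_distribution(ts, syn.DEFAULT_ENUMERATION_CAP)
        for j in range(3):
            exact = p.sum(axis=tuple(k for k in range(3) if k != j))
            emp = np.bincount(s.grid_indices[:, j], minlength=12) / 6000
            assert 0.5 * np.abs(emp - exact).sum() < 0.05

    def test_exact_factorized_requires_uncoupled(self):
        ts = syn.popc_like_system(seed=1, n_torsions=2, grid_size=12, coupled=True)
        with pytest.raises(ValueError):
            syn.sample_torsion_system(ts, 10, seed=0)

    def test_energies_recomputable_and_deterministic(self):
        ts = syn.popc_like_system(seed=10, n_torsions=3, grid_size=24)
        s1 = syn.sample_torsion_system(ts, 500, seed=11)
        s2 = syn.sample_torsion_system(ts, 500, seed=11)
        assert np.array_equal(s1.trajectory.angles, s2.trajectory.angles)
        assert np.array_equal(ts.energy_of(s1.grid_indices), s1.energies)


class TestExactWeights:
    def test_flat_window_weight(self):
        ts = syn.TorsionSystem(site_energies=np.zeros((1, 360)))
        sel = MacrostateSelector(order_param=0, lo=-180.0, hi=-162.0)
        assert syn.exact_macrostate_weight(ts, sel) == pytest.approx(18 / 360, rel=1e-12)

    def test_full_circle_weight_one(self):
        ts = syn.popc_like_system(seed=1, n_torsions=2, grid_size=36)
        sel = MacrostateSelector(order_param=1, lo=-180.0, hi=180.0)
        assert syn.exact_macrostate_weight(ts, sel) == pytest.approx(1.0, rel=1e-12)

    def test_sampling_frequency_matches_weight(self):
        ts = syn.popc_like_system(seed=12, n_torsions=2, grid_size=36)
        sel = MacrostateSelector(order_param=0, lo=-18.0, hi=36.0)
        w = syn.exact_macrostate_weight(ts, sel)
        n = 100000
        s = syn.sample_torsion_system(ts, n, seed=13)
        ang = s.trajectory.angles[:, 0]
        emp = np.mean((ang >= sel.lo) & (ang < sel.hi))
        assert abs(emp - w) < 3 * np.sqrt(w * (1 - w) / n)

    def test_cap_enforced(self):
        ts = syn.popc_like_system(seed=1, n_torsions=4, grid_size=360,
                                  coupled=True)
        sel = MacrostateSelector(order_param=0, lo=0.0, hi=18.0)
        with pytest.raises(syn.EnumerationCapError):
            syn.exact_macrostate_weight(ts, sel)


class TestExactEntropyReport:
    def _sel(self, lo=-180.0, hi=-60.0):
        return MacrostateSelector(order_param=0, lo=lo, hi=hi)

    def test_flat_system_uniform_weights(self):
        ts = syn.TorsionSystem(site_energies=np.zeros((2, 36)))
        cd = ConformerDefinition("c", (0, 1))
        r = syn.exact_entropy_report(ts, self._sel(), cd)
        assert r.D_KL == pytest.approx(0.0, abs=1e-12)
        assert r.S_conf == pytest.approx(np.log(r.n_conf), rel=1e-12)

    def test_single_conformer_macrostate(self):
        """A window inside one arc with a single-torsion conformer definition:
        S_conf = 0 and S_total = <S_intra>."""
        ts = syn.popc_like_system(seed=14, n_torsions=1, grid_size=36)
        cd = ConformerDefinition("c", (0,))
        r = syn.exact_entropy_report(ts, self._sel(-180.0, -120.0), cd)
        assert r.n_conf == 1
        assert r.S_conf == 0.0
        assert r.S_total == pytest.approx(r.mean_S_intra, rel=1e-12)

    def test_decomposition_matches_direct_shannon(self):
        """Grouped S_conf + <S_intra> equals the microstate Shannon entropy."""
        ts = syn.popc_like_system(seed=15, n_torsions=3, grid_size=12,
                                  coupled=True, coupling_strength=0.8)
        cd = ConformerDefinition("c", (0, 1, 2))
        r = syn.exact_entropy_report(ts, self._sel(), cd, method="enumerate")
        assert r.S_conf + r.mean_S_intra == pytest.approx(r.S_total, rel=1e-10)
        assert r.S_conf == pytest.approx(r.S_Boltz - r.D_KL, rel=1e-12)

    def test_factorized_agrees_with_enumeration(self):
        ts = syn.popc_like_system(seed=16, n_torsions=2, grid_size=24)
        cd = ConformerDefinition("c", (0, 1))
        sel = self._sel(-36.0, 18.0)
        rf = syn.exact_entropy_report(ts, sel, cd, method="factorized")
        re = syn.exact_entropy_report(ts, sel, cd, method="enumerate")
        for attr in ("weight", "S_conf", "S_Boltz", "D_KL", "mean_S_intra",
                     "S_total", "mean_U"):
            assert getattr(rf, attr) == pytest.approx(getattr(re, attr), abs=1e-10)
        assert rf.n_conf == re.n_conf
        assert np.allclose(np.sort(rf.P), np.sort(re.P))


class TestEEC:
    def test_same_macrostate_all_zero(self):
        ts = syn.popc_like_system(seed=17, n_torsions=2, grid_size=24)
        cd = ConformerDefinition("c", (0, 1))
        sel = MacrostateSelector(order_param=0, lo=-60.0, hi=0.0)
        rep = syn.eec_check(ts, sel, sel, cd)
        assert rep.dU == rep.dS_intra == rep.dS_conf == rep.dF_exact == 0.0

    def test_flat_system_trivial_compensation(self):
        ts = syn.TorsionSystem(site_energies=np.zeros((2, 36)))
        cd = ConformerDefinition("c", (0, 1))
        a = MacrostateSelector(order_param=0, lo=-180.0, hi=-60.0)
        b = MacrostateSelector(order_param=0, lo=60.0, hi=180.0)
        rep = syn.eec_check(ts, a, b, cd)
        assert rep.dU == pytest.approx(0.0, abs=1e-12)
        assert rep.dS_intra == pytest.approx(0.0, abs=1e-12)

    def test_thermodynamic_closure_on_rugged_system(self):
        ts = syn.popc_like_system(seed=18, n_torsions=3, grid_size=12,
                                  coupled=True, coupling_strength=1.2)
        cd = ConformerDefinition("c", (0, 1, 2))
        a = MacrostateSelector(order_param=0, lo=-180.0, hi=-90.0)
        b = MacrostateSelector(order_param=0, lo=30.0, hi=120.0)
        rep = syn.eec_check(ts, a, b, cd, method="enumerate")
        assert rep.closure == pytest.approx(0.0, abs=1e-10)

    def test_exact_iswd_construction_compensates(self):
        """Equal-arc-mass profiles: ΔU is nonzero yet exactly cancelled by
        Δ<S_intra>, so the EEC residual vanishes."""
        ts = syn.equal_arc_mass_system(seed=19, n_torsions=2, grid_size=36,
                                       roughness=3.0)
        cd = ConformerDefinition("c", (0, 1))
        a = MacrostateSelector(order_param=0, lo=-180.0, hi=-60.0)
        b = MacrostateSelector(order_param=0, lo=60.0, hi=180.0)
        rep = syn.eec_check(ts, a, b, cd)
        assert rep.dF_exact == pytest.approx(0.0, abs=1e-12)
        assert rep.residual == pytest.approx(0.0, abs=1e-10)
        assert rep.dU == pytest.approx(rep.dS_intra, abs=1e-10)


class TestGatedSystem:
    def test_window_weights_proportional_to_conformer_counts(self):
        gs = syn.GatedSystem.random(seed=20, n_gated=6)
        k = np.array([gs.conformer_count(v) for v in range(20)])
        assert np.allclose(gs.window_weights(), k / k.sum())

    def test_sampled_window_populations_track_weights(self):
        gs = syn.GatedSystem.random(seed=21, n_gated=6)
        n = 200000
        s = syn.sample_gated_system(gs, n, seed=22)
        win = ((s.trajectory.angles[:, 0] + 180.0) // 18).astype(int).clip(0, 19)
        counts = np.bincount(win, minlength=20)
        # stratified stream: counts are near-exact, discrepancy O(log n)
        assert np.all(np.abs(counts - n * gs.window_weights()) < 25)

    def test_arcs_respect_gates(self):
        gs = syn.GatedSystem.random(seed=23, n_gated=4)
        s = syn.sample_gated_system(gs, 5000, seed=24)
        from confcount.discretize import assign_torsional_states

        states = assign_torsional_states(s.trajectory, gs.boundaries)
        win = ((s.trajectory.angles[:, 0] + 180.0) // 18).astype(int).clip(0, 19)
        for t in range(500):
            for jg in range(4):
                assert states[t, jg + 1] in gs.allowed[jg][win[t]]

    def test_determinism(self):
        gs = syn.GatedSystem.random(seed=25, n_gated=4)
        s1 = syn.sample_gated_system(gs, 1000, seed=26)
        s2 = syn.sample_gated_system(gs, 1000, seed=26)
        assert np.array_equal(s1.trajectory.angles, s2.trajectory.angles)
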