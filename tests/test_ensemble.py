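import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from deltasolv.constants import R_KJMOL_K
from deltasolv.core import MolecularSystem
from deltasolv.ensemble import (ConformerRecord, UndefinedDihedralError,
                                balance_statistics, boltzmann_populations,
                                classify_rotamer, dihedral_angle, ir_spectrum,
                                kabsch_rmsd, prune_ensemble)
from deltasolv.thermo import FreeEnergyRecord


def record(coords, g, label=None):
    fe = FreeEnergyRecord(e_backend=g, e_model=0.0, e_gb=0.0,
                          temperature=298.15, s_vib=0.0, g_total=g)
    n = len(coords)
    return ConformerRecord(
        system=MolecularSystem(["C"] * n, np.asarray(coords, float)),
        free_energy=fe, label=label)


def chain_coords(seed, n=5):
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(scale=1.0, size=(n, 3)) + [1.5, 0, 0], axis=0)
    return x


class TestRMSD:
    def test_matches_independent_kabsch_oracle(self):
        """scipy-based RMSD vs a hand-written SVD Kabsch."""
        rng = np.random.default_rng(0)
        for seed in range(10):
            a = chain_coords(seed)
            b = chain_coords(seed + 100)
            # oracle
            ac, bc = a - a.mean(0), b - b.mean(0)
            U, S, Vt = np.linalg.svd(bc.T @ ac)
            d = np.sign(np.linalg.det(U @ Vt))
            D = np.diag([1, 1, d])
            R = U @ D @ Vt
            oracle = np.sqrt(((bc @ R - ac) ** 2).sum() / len(a))
            assert kabsch_rmsd(a, b) == pytest.approx(oracle, rel=1e-8)

    def test_zero_for_rigid_motion(self):
        a = chain_coords(1)
        R = Rotation.random(random_state=5).as_matrix()
        assert kabsch_rmsd(a, a @ R.T + 2.0) < 1e-8

    def test_matches_mdtraj(self):
        mdtraj = pytest.importorskip("mdtraj")
        a, b = chain_coords(2), chain_coords(3)
        top = mdtraj.Topology()
        ch = top.add_chain()
        res = top.add_residue("LIG", ch)
        for i in range(len(a)):
            top.add_atom(f"C{i}", mdtraj.element.carbon, res)
        traj = mdtraj.Trajectory(np.stack([a, b]) / 10.0, top)  # nm
        ref = float(mdtraj.rmsd(traj, traj, 0)[1]) * 10.0
        assert kabsch_rmsd(a, b) == pytest.approx(ref, rel=1e-4)


class TestPrune:
    def test_duplicates_keep_lowest_g(self):
        a = chain_coords(1)
        kept = prune_ensemble([record(a, 5.0), record(a, 1.0)])
        assert len(kept) == 1
        assert kept[0].g_total == 1.0

    def test_distant_pair_both_retained(self):
        a = chain_coords(1)
        b = a + np.array([5.0, 0, 0]) * np.arange(len(a))[:, None]
        assert kabsch_rmsd(a, b) > 2.0
        kept = prune_ensemble([record(a, 0.0), record(b, 1.0)])
        assert len(kept) == 2
        assert kept[0].g_total <= kept[1].g_total

    def test_idempotent(self):
        recs = [record(chain_coords(s), float(s % 3)) for s in range(8)]
        once = prune_ensemble(recs)
        twice = prune_ensemble(once)
        assert [id(r) for r in twice] == [id(r) for r in once]

    def test_input_order_irrelevant(self):
        recs = [record(chain_coords(s), float(s)) for s in range(6)]
        recs += [record(recs[2].system.coordinates, 10.0)]
        kept1 = prune_ensemble(recs)
        kept2 = prune_ensemble(list(reversed(recs)))
        g1 = [r.g_total for r in kept1]
        g2 = [r.g_total for r in kept2]
        assert g1 == g2

    def test_mismatched_atom_counts_rejected(self):
        with pytest.raises(ValueError, match="atom counts"):
            prune_ensemble([record(chain_coords(0, 4), 0.0),
                            record(chain_coords(0, 5), 1.0)])


class TestRotamer:
    def dihedral_system(self, phi):
        from deltasolv.fixtures import make_toy_system, set_dihedral
        s = make_toy_system("chain-4", seed=0)
        return set_dihedral(s, (0, 1, 2, 3), phi)

    @pytest.mark.parametrize("phi,label", [
        (0.0, "gauche"),
        (np.pi, "trans"),
        (2.0999, "gauche"),
        (2.1, "trans"),          # boundary: open interval
        (-2.1, "trans"),
        (2.5, "trans"),
    ])
    def test_window_rule(self, phi, label):
        s = self.dihedral_system(phi)
        assert classify_rotamer(s, (0, 1, 2, 3)) == label

    def test_collinear_rejected(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]],
                          dtype=float)
        with pytest.raises(UndefinedDihedralError):
            dihedral_angle(coords, 0, 1, 2, 3)

    def test_dihedral_range(self):
        for phi in [-3.0, -1.0, 0.5, 2.9]:
            s = self.dihedral_system(phi)
            val = dihedral_angle(s.coordinates, 0, 1, 2, 3)
            assert val == pytest.approx(phi, abs=1e-8)


class TestBoltzmann:
    def test_equal_g_half_half(self):
        recs = [record(chain_coords(0), 3.0), record(chain_coords(1), 3.0)]
        w, _ = boltzmann_populations(recs, 300.0)
        np.testing.assert_allclose(w, 0.5)

    def test_rt_ln2_gives_two_thirds(self):
        T = 298.15
        dg = R_KJMOL_K * T * np.log(2.0)
        recs = [record(chain_coords(0), 0.0), record(chain_coords(1), dg)]
        w, _ = boltzmann_populations(recs, T)
        assert abs(w[0] - 2.0 / 3.0) <= 1e-12
        assert abs(w[1] - 1.0 / 3.0) <= 1e-12

    def test_huge_gap_no_overflow(self):
        T = 298.15
        dg = 50.0 * R_KJMOL_K * T
        recs = [record(chain_coords(0), 0.0), record(chain_coords(1), dg)]
        w, _ = boltzmann_populations(recs, T)
        assert w[1] < 1e-20 and np.isfinite(w).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_state_aggregation(self):
        recs = [record(chain_coords(i), 0.0,
                       label="gauche" if i < 2 else "trans")
                for i in range(3)]
        _, states = boltzmann_populations(recs, 300.0)
        assert states["gauche"] == pytest.approx(2.0 / 3.0)
        assert sum(states.values()) == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.floats(50, 1000))
    def test_weights_always_normalized(self, gs, T):
        recs = [record(chain_coords(i), g) for i, g in enumerate(gs)]
        w, _ = boltzmann_populations(recs, T)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(w >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            boltzmann_populations([], 300.0)


class TestBalance:
    def test_identity_series(self):
        x = [1.0, -0.5, 2.0, 0.25]
        comp = balance_statistics(x, x)
        assert comp.pcc == pytest.approx(1.0, abs=1e-12)
        assert comp.slope == pytest.approx(1.0, abs=1e-12)

    def test_linear_map_recovers_slope(self):
        exp = np.array([1.0, 2.0, 4.0, -1.0, 0.5])
        pred = 0.34 * exp + 7.0
        comp = balance_statistics(pred, exp)
        assert comp.pcc == pytest.approx(1.0, abs=1e-12)
        assert comp.slope == pytest.approx(0.34, abs=1e-12)
        np.testing.assert_allclose(comp.predicted_centered.mean(), 0.0,
                                   atol=1e-10)
        np.testing.assert_allclose(comp.experimental_centered.mean(), 0.0,
                                   atol=1e-10)

    def test_anticorrelated_log_slope_minus_inf(self):
        exp = np.array([1.0, 2.0, 3.0, 4.0])
        comp = balance_statistics(-2.0 * exp, exp)
        assert comp.pcc < 0 and comp.slope < 0
        assert comp.log_slope == float("-inf")

    def test_exclusions_applied_before_stats(self):
        exp = np.array([1.0, 2.0, 3.0, 100.0])
        pred = np.array([1.0, 2.0, 3.0, -50.0])
        comp = balance_statistics(pred, exp, exclusions=[3])
        assert comp.excluded == [3]
        assert comp.pcc == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            balance_statistics([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_least_squares_oracle(self, seed):
        """PCC/slope vs explicit normal-equation and covariance formulas."""
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        comp = balance_statistics(y, x)
        xc, yc = x - x.mean(), y - y.mean()
        slope_o = (xc @ yc) / (xc @ xc)
        pcc_o = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert comp.slope == pytest.approx(slope_o, abs=1e-10)
        assert comp.pcc == pytest.approx(pcc_o, abs=1e-10)


class TestSpectrum:
    def test_single_mode_peak_and_area(self):
        spec = ir_spectrum([(1.0, np.array([1500.0]))], sigma=5.0)
        assert spec.wavenumbers[np.argmax(spec.intensity)] == pytest.approx(
            1500.0, abs=1.0)
        assert spec.area() == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_peak_areas_equal_weights(self):
        spec = ir_spectrum([(0.7, np.array([1000.0])),
                            (0.3, np.array([3000.0]))], sigma=5.0)
        mid = (spec.wavenumbers > 2000.0)
        lo = np.trapezoid(spec.intensity[~mid], spec.wavenumbers[~mid])
        hi = np.trapezoid(spec.intensity[mid], spec.wavenumbers[mid])
        assert lo == pytest.approx(0.7, abs=1e-3)
        assert hi == pytest.approx(0.3, abs=1e-3)

    @pytest.mark.parametrize("sigma", [1.0, 5.0, 40.0])
    def test_area_invariant_under_broadening(self, sigma):
        sticks = [(0.6, np.array([800.0, 1200.0])),
                  (0.4, np.array([2500.0]))]
        spec = ir_spectrum(sticks, sigma=sigma)
        total = 0.6 * 2 + 0.4
        assert spec.area() == pytest.approx(total, rel=1e-3)

    def test_empty_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            spec = ir_spectrum([(1.0, np.array([]))], sigma=5.0)
        assert np.all(spec.intensity == 0.0)
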