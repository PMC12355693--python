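import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from deltasolv.core import SolventSpec
from deltasolv.correction import (CallableSolventModel, DeltaCorrection,
                                  ReferenceModelConfig, UnsupportedSolventError,
                                  build_reference_gnn, correction,
                                  train_on_delta_forces)
from deltasolv.fixtures import (AnalyticSolventField, make_delta_force_dataset,
                                make_toy_system)

from conftest import random_system


@pytest.fixture
def ref_model():
    m = build_reference_gnn(ReferenceModelConfig(
        solvents=("water", "chloroform"), seed=5))
    rng = np.random.default_rng(8)
    m.coef = rng.normal(scale=0.5, size=m.n_params)
    return m


class TestCorrection:
    def test_self_subtraction_is_zero(self, gb_water, water):
        s = random_system(0, n=4)
        mock = CallableSolventModel.from_gb(gb_water)
        field = correction(s, water, mock, gb_water)
        assert field.energy_corr == 0.0
        np.testing.assert_array_equal(field.forces_corr, 0.0)

    def test_direct_subtraction(self, gb_water, water):
        s = random_system(1, n=3)
        e_gb = gb_water.energy(s)
        mock = CallableSolventModel(
            lambda sys_, solv: (e_gb - 2.0, np.zeros((sys_.n_atoms, 3))))
        field = correction(s, water, mock, gb_water)
        assert field.energy_corr == pytest.approx(-2.0, abs=1e-12)

    def test_forces_componentwise_difference(self, gb_water, water):
        s = random_system(2, n=4)
        rng = np.random.default_rng(0)
        f_mock = rng.normal(size=(4, 3))
        mock = CallableSolventModel(lambda sys_, solv: (0.0, f_mock))
        field = correction(s, water, mock, gb_water)
        f_gb = -gb_water.energy_gradient(s)[1]
        np.testing.assert_array_equal(field.forces_corr, f_mock - f_gb)

    def test_unsupported_solvent_lists_supported(self, gb_water):
        s = random_system(3, n=3)
        mock = CallableSolventModel(lambda sys_, solv: (0.0, np.zeros((3, 3))),
                                    supported_solvents=["water"])
        with pytest.raises(UnsupportedSolventError, match="water"):
            correction(s, SolventSpec("dmso", 46.7), mock, gb_water)

    def test_linear_in_model_output(self, gb_water, water):
        s = random_system(4, n=3)
        e_gb, g_gb = gb_water.energy_gradient(s)
        for c in [1.0, 2.5, -3.0]:
            mock = CallableSolventModel(
                lambda sys_, solv, c=c: (c * 10.0, np.zeros((3, 3))))
            field = correction(s, water, mock, gb_water)
            assert field.energy_corr == pytest.approx(c * 10.0 - e_gb)

    def test_hessian_present_iff_requested(self, gb_water, water):
        s = random_system(5, n=3)
        mock = CallableSolventModel.from_gb(gb_water)
        assert correction(s, water, mock, gb_water).hessian_corr is None
        field = correction(s, water, mock, gb_water, with_hessian=True)
        assert field.hessian_corr.shape == (9, 9)
        np.testing.assert_allclose(field.hessian_corr, 0.0, atol=1e-9)


class TestReferenceModel:
    def test_rotation_equivariance(self, ref_model, water):
        s = random_system(6, n=5)
        e0, f0 = ref_model.energy_forces(s, water)
        R = Rotation.random(random_state=4).as_matrix()
        e1, f1 = ref_model.energy_forces(
            s.with_coordinates(s.coordinates @ R.T), water)
        assert e1 == pytest.approx(e0, rel=1e-12, abs=1e-12)
        scale = max(np.abs(f0).max(), 1e-12)
        assert np.abs(f1 - f0 @ R.T).max() / scale < 1e-8

    def test_translation_invariance(self, ref_model, water):
        s = random_system(7, n=4)
        e0, f0 = ref_model.energy_forces(s, water)
        e1, f1 = ref_model.energy_forces(
            s.with_coordinates(s.coordinates + np.array([3.0, -1.0, 0.5])),
            water)
        assert e1 == pytest.approx(e0, rel=1e-12)
        np.testing.assert_allclose(f1, f0, atol=1e-10)

    def test_seeded_construction_reproducible(self, water):
        cfg = ReferenceModelConfig(solvents=("water",), seed=42)
        m1, m2 = build_reference_gnn(cfg), build_reference_gnn(cfg)
        assert np.array_equal(m1.W, m2.W) and np.array_equal(m1.b, m2.b)
        s = random_system(8, n=4)
        m1.coef = m2.coef = np.ones(m1.n_params)
        e1, f1 = m1.energy_forces(s, water)
        e2, f2 = m2.energy_forces(s, water)
        assert e1 == e2 and np.array_equal(f1, f2)

    def test_forces_match_complex_step(self, ref_model, water):
        """Forces are the exact negative gradient of the energy (machine
        precision via complex-step differentiation)."""
        s = random_system(9, n=4)
        _, f = ref_model.energy_forces(s, water)
        h = 1e-20
        x0 = s.coordinates.ravel().astype(complex)
        for k in range(x0.size):
            xc = x0.copy()
            xc[k] += 1j * h
            df = -np.imag(ref_model.energy_complex(xc, s, water)) / h
            assert abs(df - f.ravel()[k]) <= 1e-6 * max(abs(df), 1.0)

    def test_forces_match_finite_differences(self, ref_model, water):
        s = random_system(10, n=4)
        e, f = ref_model.energy_forces(s, water)
        h = 1e-5
        x0 = s.coordinates.ravel()
        for k in range(0, x0.size, 4):
            xp = x0.copy(); xp[k] += h
            xm = x0.copy(); xm[k] -= h
            df = -(ref_model.energy_forces(
                s.with_coordinates(xp.reshape(-1, 3)), water)[0]
                - ref_model.energy_forces(
                    s.with_coordinates(xm.reshape(-1, 3)), water)[0]) / (2 * h)
            assert df == pytest.approx(f.ravel()[k], rel=1e-4, abs=1e-6)

    def test_serialization_round_trip(self, ref_model, water, tmp_path):
        s = random_system(11, n=4)
        e0, f0 = ref_model.energy_forces(s, water)
        path = tmp_path / "model.json"
        ref_model.save(path)
        from deltasolv.correction import ReferenceGraphModel
        loaded = ReferenceGraphModel.load(path)
        e1, f1 = loaded.energy_forces(s, water)
        assert e1 == pytest.approx(e0, rel=1e-14)
        np.testing.assert_allclose(f1, f0, rtol=1e-12, atol=1e-12)

    def test_mock_and_reference_interchangeable(self, ref_model, gb_water,
                                                water):
        """Wrapping the reference model's outputs in a mock yields identical
        corrections — the pipeline only sees the contract."""
        s = random_system(12, n=4)
        mock = CallableSolventModel(
            lambda sys_, solv: ref_model.energy_forces(sys_, solv))
        d_ref = DeltaCorrection(ref_model, gb_water).evaluate(s, water)
        d_mock = DeltaCorrection(mock, gb_water).evaluate(s, water)
        assert d_ref.energy_corr == d_mock.energy_corr
        np.testing.assert_array_equal(d_ref.forces_corr, d_mock.forces_corr)


class TestTraining:
    @pytest.fixture(scope="class")
    def training_setup(self):
        solvents = [SolventSpec("water", 78.5), SolventSpec("chloroform", 4.81)]
        systems = [make_toy_system("chain-6", seed=i) for i in range(4)]
        field = AnalyticSolventField()
        return solvents, systems, field

    def test_noiseless_recovery_below_5_percent(self, training_setup):
        solvents, systems, field = training_setup
        data = make_delta_force_dataset(field, systems, solvents,
                                        n_frames=80, seed=1)
        model = build_reference_gnn(ReferenceModelConfig(
            solvents=("water", "chloroform"), seed=0))
        res = train_on_delta_forces(model, data, epochs=400, seed=2)
        assert res.rmse_test < 0.05 * res.target_rms
        assert res.rmse_val < 0.05 * res.target_rms

    def test_memorization_of_single_frame(self, training_setup):
        solvents, systems, field = training_setup
        data = make_delta_force_dataset(field, systems, solvents,
                                        n_frames=1, seed=3)
        model = build_reference_gnn(ReferenceModelConfig(
            solvents=("water", "chloroform"), seed=0))
        res = train_on_delta_forces(model, data, epochs=600, seed=0,
                                    split=(1.0, 0.0, 0.0))
        assert res.loss_trace[-1] < 1e-3 * res.loss_trace[0]

    def test_cannot_beat_noise_floor(self, training_setup):
        solvents, systems, field = training_setup
        sigma = 2.0
        data = make_delta_force_dataset(field, systems, solvents,
                                        n_frames=80, noise_sigma=sigma,
                                        seed=1)
        model = build_reference_gnn(ReferenceModelConfig(
            solvents=("water", "chloroform"), seed=0))
        res = train_on_delta_forces(model, data, epochs=400, seed=2)
        assert res.rmse_test >= sigma * 0.9

    def test_loss_trace_non_increasing(self, training_setup):
        solvents, systems, field = training_setup
        data = make_delta_force_dataset(field, systems, solvents,
                                        n_frames=30, seed=5)
        model = build_reference_gnn(ReferenceModelConfig(
            solvents=("water", "chloroform"), seed=0))
        res = train_on_delta_forces(model, data, epochs=100, seed=2)
        trace = np.array(res.loss_trace)
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_empty_dataset_rejected(self):
        model = build_reference_gnn(ReferenceModelConfig(seed=0))
        with pytest.raises(ValueError, match="empty"):
            train_on_delta_forces(model, [], epochs=1)
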