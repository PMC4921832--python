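"""Wiener and random-forest demultiplexers, image demultiplexing, model I/O."""

import inspect

import numpy as np
import pytest

import specdemux as sd


def _square_setup(seed=0, n=4):
    """p = n case with a well-conditioned invertible S."""
    grid = sd.make_wavelength_grid(500, 500 + 5 * (n - 1), 5)
    rng = np.random.default_rng(seed)
    S = np.eye(n) + rng.uniform(0, 0.3 / n, (n, n))
    sens = sd.SpectralSensitivity(grid, tuple(f"ch{i}" for i in range(n)), S)
    spectra = [sd.ReflectanceSpectrum(grid, rng.uniform(0, 1, n)) for _ in range(20)]
    return grid, sens, spectra


class TestTrainWiener:
    def test_square_invertible_recovers_inverse(self):
        _, sens, spectra = _square_setup()
        model = sd.train_wiener(spectra, sens, ridge_eps=0.0)
        np.testing.assert_allclose(model.W, np.linalg.inv(sens.matrix),
                                   rtol=0, atol=1e-8)
        for s in spectra:
            c = sd.forward(sens, s)
            out = sd.demultiplex_wiener(model, c)
            np.testing.assert_allclose(out.values, s.values, rtol=0, atol=1e-8)

    def test_toy_case_matches_normal_equations_oracle(self):
        # p=2, n=3, m=4 with integer spectra: compare against a least-squares
        # solve of min ||A - W C||_F done independently
        grid = sd.make_wavelength_grid(500, 510, 5)
        S = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        sens = sd.SpectralSensitivity(grid, ("a", "b"), S)
        A = np.array([[1, 0, 0, 1], [0, 1, 0, 1], [0, 0, 1, 1]], dtype=float)
        spectra = [sd.ReflectanceSpectrum(grid, col) for col in A.T]
        model = sd.train_wiener(spectra, sens, ridge_eps=0.0)
        C = S @ A
        W_oracle = np.linalg.lstsq(C.T, A.T, rcond=None)[0].T
        np.testing.assert_allclose(model.W, W_oracle, rtol=0, atol=1e-10)

    def test_rank_deficient_training_raises_without_ridge(self, grid61, sens):
        one = sd.ReflectanceSpectrum(grid61, np.full(61, 0.5))
        with pytest.raises(sd.SingularMatrixError, match="ridge"):
            sd.train_wiener([one, one, one], sens, ridge_eps=0.0)
        model = sd.train_wiener([one, one, one], sens, ridge_eps=1e-8)
        assert np.all(np.isfinite(model.W))

    def test_training_set_mse_beats_perturbed_maps(self, grid61, sens):
        # Wiener optimality: no perturbation of W does better on its own
        # training set
        cfg = sd.SpectraGenConfig(n_spectra=100, seed=8, grid=grid61)
        spectra = sd.generate_random_spectra(cfg)
        model = sd.train_wiener(spectra, sens, ridge_eps=0.0)
        A = np.array([s.values for s in spectra])
        C = sd.forward_matrix(sens, A)
        base_mse = np.mean((A - C @ model.W.T) ** 2)
        rng = np.random.default_rng(13)
        for _ in range(20):
            Wp = model.W + rng.normal(0, 1e-3, model.W.shape)
            assert np.mean((A - C @ Wp.T) ** 2) >= base_mse

    def test_empty_training_set_rejected(self, sens):
        with pytest.raises(sd.ValidationError):
            sd.train_wiener([], sens)


class TestDemultiplexWiener:
    def test_zero_measurement_gives_zero_spectrum(self, small_wiener):
        c = sd.SensorMeasurement(small_wiener.channels, np.zeros(3))
        assert not sd.demultiplex_wiener(small_wiener, c).values.any()

    def test_matches_matrix_vector_loop_oracle(self, small_wiener):
        rng = np.random.default_rng(21)
        c = sd.SensorMeasurement(small_wiener.channels, rng.uniform(0, 5, 3))
        out = sd.demultiplex_wiener(small_wiener, c).values
        expected = np.zeros(len(small_wiener.grid))
        for k in range(expected.size):
            for j in range(3):
                expected[k] += small_wiener.W[k, j] * c.values[j]
        np.testing.assert_allclose(out, np.clip(expected, 0, 1), rtol=0, atol=1e-12)

    def test_channel_mismatch_rejected(self, small_wiener):
        c = sd.SensorMeasurement(("a", "b"), np.zeros(2))
        with pytest.raises(sd.ChannelMismatchError):
            sd.demultiplex_wiener(small_wiener, c)

    def test_output_clipped_to_unit_interval(self, small_wiener):
        c = sd.SensorMeasurement(small_wiener.channels, np.full(3, 100.0))
        out = sd.demultiplex_wiener(small_wiener, c).values
        assert np.all((out >= 0) & (out <= 1))


class TestTrainForest:
    def test_constant_target_is_memorized(self, sens, grid61):
        rng = np.random.default_rng(30)
        s = sd.ReflectanceSpectrum(grid61, rng.uniform(0, 1, 61))
        c = sd.forward(sens, s)
        model = sd.train_forest([(c, s)] * 10, n_trees=10, seed=0)
        out = sd.demultiplex_forest(model, c)
        np.testing.assert_allclose(out.values, s.values, rtol=0, atol=1e-8)

    def test_full_scale_default_requests_8000_trees(self):
        assert sd.DEFAULT_N_TREES == 8000
        sig = inspect.signature(sd.train_forest)
        assert sig.parameters["n_trees"].default == 8000

    def test_well_separated_clusters_map_back_to_own_spectrum(self, grid61, sens):
        # three distinct spectra with well-separated measurements: the forest
        # should act like a nearest-neighbor lookup
        rng = np.random.default_rng(31)
        centers = [450.0, 550.0, 650.0]
        spectra = [
            sd.ReflectanceSpectrum(
                grid61, 0.9 * np.exp(-((grid61.values - c) ** 2) / (2 * 30**2)))
            for c in centers
        ]
        pairs = []
        for s in spectra:
            c = sd.forward(sens, s)
            pairs.extend([(c, s)] * 30)
        model = sd.train_forest(pairs, n_trees=200, seed=1)
        for s in spectra:
            out = sd.demultiplex_forest(model, sd.forward(sens, s))
            assert np.max(np.abs(out.values - s.values)) < 0.01

    def test_empty_pairs_rejected(self):
        with pytest.raises(sd.ValidationError):
            sd.train_forest([], n_trees=10, seed=0)

    def test_per_output_mode_trains_one_forest_per_wavelength(self, grid61):
        grid = sd.make_wavelength_grid(500, 520, 5)  # 5 outputs
        sens5 = sd.synth_sensitivity(grid)
        cfg = sd.SpectraGenConfig(n_spectra=30, seed=2, grid=grid)
        pairs = sd.generate_training_pairs(sens5, cfg)
        model = sd.train_forest(pairs, n_trees=10, seed=0, per_output=True)
        assert model.per_output and len(model.model) == 5
        assert model.n_trees == 10  # 2 trees x 5 outputs
        out = model.predict_batch(np.zeros((1, 3)))
        assert out.shape == (1, 5)


class TestDemultiplexForest:
    def test_repeated_calls_are_identical(self, small_forest):
        c = sd.SensorMeasurement(small_forest.channels, np.array([1.0, 2.0, 3.0]))
        a = sd.demultiplex_forest(small_forest, c)
        b = sd.demultiplex_forest(small_forest, c)
        np.testing.assert_array_equal(a.values, b.values)

    def test_prediction_within_training_range(self, small_forest, small_pairs):
        Y = np.array([s.values for _, s in small_pairs])
        lo, hi = Y.min(axis=0), Y.max(axis=0)
        rng = np.random.default_rng(40)
        c = sd.SensorMeasurement(small_forest.channels, rng.uniform(0, 20, 3))
        out = sd.demultiplex_forest(small_forest, c).values
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_beats_wiener_on_held_out_spectra(self, sens, grid61,
                                              reduced_forest, reduced_wiener):
        # at the reduced training scale the non-linear forest reconstructs
        # held-out spectra better than the linear Wiener demultiplexer
        cfg = sd.SpectraGenConfig(n_spectra=100, seed=77, grid=grid61)
        Y = np.array([s.values for s in sd.generate_random_spectra(cfg)])
        X = sd.forward_matrix(sens, Y)
        psnr_f = sd.mean_psnr((Y, reduced_forest.predict_batch(X)))
        psnr_w = sd.mean_psnr((Y, reduced_wiener.predict_batch(X)))
        assert psnr_f > psnr_w

    def test_channel_mismatch_rejected(self, small_forest):
        with pytest.raises(sd.ChannelMismatchError):
            sd.demultiplex_forest(
                small_forest, sd.SensorMeasurement(("a",), np.zeros(1)))


class TestDemultiplexImage:
    def test_uniform_image_gives_uniform_cube(self, small_wiener):
        img = np.broadcast_to([0.2, 0.4, 0.1], (3, 5, 3)).copy()
        cube = sd.demultiplex_image(small_wiener, img)
        np.testing.assert_allclose(
            cube.data, np.broadcast_to(cube.data[0, 0], cube.data.shape),
            rtol=0, atol=1e-12)

    @pytest.mark.parametrize("model_fixture", ["small_wiener", "small_forest"])
    def test_matches_pixelwise_scalar_calls(self, model_fixture, request):
        model = request.getfixturevalue(model_fixture)
        rng = np.random.default_rng(50)
        img = rng.uniform(0, 5, (2, 2, 3))
        cube = sd.demultiplex_image(model, img)
        for i in range(2):
            for j in range(2):
                c = sd.SensorMeasurement(model.channels, img[i, j])
                ref = sd.demultiplex(model, c).values
                np.testing.assert_allclose(cube.data[i, j], ref, rtol=0, atol=1e-12)

    def test_zero_image_through_wiener_gives_zero_cube(self, small_wiener):
        cube = sd.demultiplex_image(small_wiener, np.zeros((2, 3, 3)))
        assert not cube.data.any()

    def test_channel_mismatch_rejected(self, small_wiener):
        with pytest.raises(sd.ChannelMismatchError):
            sd.demultiplex_image(small_wiener, np.zeros((2, 2, 4)))


class TestExtractBand:
    @pytest.mark.parametrize("wavelength", [490.0, 550.0, 610.0])
    def test_reference_bands_are_valid_slices(self, grid61, wavelength):
        rng = np.random.default_rng(60)
        cube = sd.SpectralCube(grid61, rng.uniform(0, 1, (3, 4, 61)))
        band = sd.extract_band(cube, wavelength)
        k = grid61.index_of(wavelength)
        np.testing.assert_array_equal(band, cube.data[:, :, k])

    def test_off_grid_wavelength_names_neighbors(self, grid61):
        cube = sd.SpectralCube(grid61, np.zeros((2, 2, 61)))
        with pytest.raises(sd.OffGridError, match="490.*495"):
            sd.extract_band(cube, 492.0)

    def test_uniform_cube_slice_is_constant(self, grid61):
        cube = sd.SpectralCube(grid61, np.full((2, 2, 61), 0.3))
        assert np.all(sd.extract_band(cube, 550.0) == 0.3)


class TestModelIO:
    def test_wiener_round_trip_is_exact(self, tmp_path, small_wiener):
        path = tmp_path / "w.joblib"
        sd.save_model(small_wiener, path)
        back = sd.load_model(path)
        assert isinstance(back, sd.WienerDemultiplexer)
        np.testing.assert_array_equal(back.W, small_wiener.W)
        assert back.grid == small_wiener.grid
        assert back.channels == small_wiener.channels

    def test_forest_round_trip_predictions_identical(self, tmp_path, small_forest):
        path = tmp_path / "f.joblib"
        sd.save_model(small_forest, path)
        back = sd.load_model(path)
        rng = np.random.default_rng(70)
        X = rng.uniform(0, 10, (100, 3))
        np.testing.assert_array_equal(back.predict_batch(X),
                                      small_forest.predict_batch(X))

    def test_truncated_file_rejected(self, tmp_path, small_wiener):
        path = tmp_path / "w.joblib"
        sd.save_model(small_wiener, path)
        path.write_bytes(path.read_bytes()[:20])
        with pytest.raises(sd.ModelFormatError):
            sd.load_model(path)

    def test_foreign_payload_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "other.joblib"
        joblib.dump({"whatever": 1}, path)
        with pytest.raises(sd.ModelFormatError):
            sd.load_model(path)

    def test_wiener_csv_export(self, tmp_path, small_wiener):
        path = tmp_path / "W.csv"
        sd.write_wiener_csv(small_wiener, path)
        table = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_array_equal(table[:, 0], small_wiener.grid.values)
        np.testing.assert_allclose(table[:, 1:], small_wiener.W, rtol=0, atol=1e-9)
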