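"""Camera adaptation, stO2 estimation, trajectories and synthetic cubes."""

import numpy as np
import pytest

from tissuelight.application import (
    CameraModel,
    LabeledHSICube,
    SpectrumLibrary,
    adapt_to_camera,
    build_trajectories,
    estimate_sto2,
    estimate_sto2_map,
    generate_synthetic_cube,
)
from tissuelight.pipelines import organ_space


@pytest.fixture(scope="module")
def camera():
    return CameraModel.gaussian_bands(fine_step_nm=1.0)


class TestCameraModel:
    def test_default_band_layout(self, camera):
        assert camera.n_bands == 100
        assert camera.band_centers[0] == 500.0
        assert camera.band_centers[-1] == 995.0
        assert np.all(np.diff(camera.band_centers) == 5.0)

    def test_flat_spectrum_preserved(self, camera):
        w = np.linspace(450, 1050, 301)
        bands = adapt_to_camera(w, np.full(301, 0.3), camera)
        assert np.allclose(bands, 0.3, atol=1e-12)

    def test_delta_bands_are_pure_resampling(self):
        cam = CameraModel.delta_bands([500.0, 600.0, 700.0])
        w = np.linspace(450, 750, 301)
        spectrum = 0.001 * (w - 450)
        bands = adapt_to_camera(w, spectrum, cam)
        assert np.allclose(bands, [0.05, 0.15, 0.25], atol=1e-12)

    def test_gaussian_bands_exact_on_linear_spectrum(self, camera):
        """Symmetric kernels reproduce a linear spectrum at band centers."""
        w = np.linspace(450, 1050, 601)
        spectrum = 0.1 + 0.0005 * (w - 450)
        bands = adapt_to_camera(w, spectrum, camera)
        expected = 0.1 + 0.0005 * (camera.band_centers - 450)
        assert np.allclose(bands, expected, atol=1e-6)

    def test_linearity_in_input(self, camera, rng):
        w = np.linspace(450, 1050, 301)
        s1, s2 = rng.random(301), rng.random(301)
        b = adapt_to_camera(w, 0.3 * s1 + 0.5 * s2, camera)
        assert np.allclose(b, 0.3 * adapt_to_camera(w, s1, camera)
                           + 0.5 * adapt_to_camera(w, s2, camera), atol=1e-12)

    def test_uncovered_support_rejected(self, camera):
        w = np.linspace(600, 900, 100)
        with pytest.raises(ValueError, match="support"):
            adapt_to_camera(w, np.full(100, 0.5), camera)


def library_of(spectra, sto2):
    spectra = np.asarray(spectra, float)
    return SpectrumLibrary(spectra, np.asarray(sto2, float),
                           np.arange(spectra.shape[1], dtype=float))


class TestEstimateStO2:
    def test_exact_member_match(self, rng):
        spectra = rng.random((50, 10))
        lib = library_of(spectra, rng.random(50))
        est, dist = estimate_sto2(spectra[17], lib)
        assert est == lib.sto2[17]
        assert dist == 0.0

    def test_rejection_beyond_threshold(self):
        lib = library_of(np.zeros((5, 8)), np.linspace(0, 1, 5))
        est, dist = estimate_sto2(np.full(8, 0.5), lib, d_max=0.02)
        assert est is None
        assert dist == pytest.approx(0.5)

    def test_matches_brute_force_double_loop(self, rng):
        pixels = rng.random((200, 12))
        spectra = rng.random((300, 12))
        lib = library_of(spectra, rng.random(300))
        est, dist = estimate_sto2_map(pixels, lib, d_max=0.15)
        for i in (0, 17, 63, 199):
            best_j, best_d = 0, np.inf
            for j in range(300):
                d = np.mean(np.abs(pixels[i] - spectra[j]))
                if d < best_d:
                    best_j, best_d = j, d
            assert dist[i] == best_d
            if best_d <= 0.15:
                assert est[i] == lib.sto2[best_j]
            else:
                assert np.isnan(est[i])

    def test_tie_break_lowest_index(self):
        s = np.tile(np.linspace(0, 1, 6), (3, 1))  # three identical spectra
        lib = library_of(s, [0.9, 0.5, 0.1])
        est, _ = estimate_sto2(s[0], lib)
        assert est == 0.9

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            estimate_sto2(np.zeros(4), library_of(np.empty((0, 4)), []))


def make_cube(image, labels, classes, subject="s", t=0.0, phase="baseline"):
    return LabeledHSICube(image=image, label_map=labels, class_names=classes,
                          band_centers=np.arange(image.shape[-1], dtype=float),
                          subject_id=subject, timepoint=t, phase=phase)


class TestTrajectories:
    def test_single_class_exact_recovery(self, rng):
        spectrum = rng.random(8)
        lib = library_of(np.vstack([spectrum, rng.random((20, 8))]),
                         np.concatenate([[0.42], rng.random(20)]))
        image = np.tile(spectrum, (4, 4, 1))
        cube = make_cube(image, np.zeros((4, 4), int), ("liver",))
        traj = build_trajectories([cube], lib)
        t = traj[("s", "liver")]
        assert t.mean_sto2 == [pytest.approx(0.42)]
        assert t.valid_pixel_fraction == [1.0]

    def test_all_rejected_pixels(self):
        lib = library_of(np.zeros((3, 8)), [0.1, 0.2, 0.3])
        image = np.full((2, 2, 8), 0.9)
        cube = make_cube(image, np.zeros((2, 2), int), ("muscle",))
        traj = build_trajectories([cube], lib, d_max=0.02)
        t = traj[("s", "muscle")]
        assert np.isnan(t.mean_sto2[0])
        assert t.valid_pixel_fraction == [0.0]

    def test_permutation_invariance_over_pixels(self, rng):
        spectra = rng.random((30, 8))
        lib = library_of(spectra, rng.random(30))
        image = spectra[rng.integers(0, 30, (6, 6))]
        labels = np.zeros((6, 6), int)
        cube1 = make_cube(image, labels, ("organ",))
        perm = rng.permutation(36)
        image2 = image.reshape(36, 8)[perm].reshape(6, 6, 8)
        cube2 = make_cube(image2, labels, ("organ",))
        t1 = build_trajectories([cube1], lib)[("s", "organ")]
        t2 = build_trajectories([cube2], lib)[("s", "organ")]
        assert t1.mean_sto2[0] == pytest.approx(t2.mean_sto2[0])

    def test_raising_threshold_never_loses_pixels(self, rng):
        lib = library_of(rng.random((40, 8)), rng.random(40))
        image = rng.random((5, 5, 8))
        cube = make_cube(image, np.zeros((5, 5), int), ("organ",))
        fractions = [build_trajectories([cube], lib, d_max=d)[("s", "organ")]
                     .valid_pixel_fraction[0] for d in (0.01, 0.05, 0.2, 0.5)]
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_absent_organ_skipped(self, rng):
        lib = library_of(rng.random((10, 8)), rng.random(10))
        image = rng.random((2, 2, 8))
        cube = make_cube(image, np.zeros((2, 2), int), ("a", "b"))
        traj = build_trajectories([cube], lib, d_max=1.0)
        assert ("s", "a") in traj and ("s", "b") not in traj


class TestSyntheticCube:
    def flat_forward(self, level):
        def forward(phys, wavelengths):
            # deterministic analytic forward: flat spectrum set by stO2
            return np.full(len(wavelengths), level + 0.2 * phys[0].sto2)

        return forward

    def test_point_mass_physiology_identical_pixels(self, table):
        cam = CameraModel.delta_bands(np.linspace(500, 995, 20))
        space = organ_space(0.5, half_width=1e-9)
        # point-mass: collapse every bound to (almost) zero width
        cube = generate_synthetic_cube({"o": space}, cam, self.flat_forward(0.3),
                                       table, seed=0, shape=(4, 4), noise_sd=0.0)
        flat = cube.image.reshape(16, -1)
        assert np.allclose(flat, flat[0], atol=1e-9)

    def test_seed_reproducibility(self, table):
        cam = CameraModel.delta_bands(np.linspace(500, 995, 10))
        specs = {"a": organ_space(0.3), "b": organ_space(0.7)}
        c1 = generate_synthetic_cube(specs, cam, self.flat_forward(0.2), table,
                                     seed=5, shape=(4, 6), noise_sd=0.01)
        c2 = generate_synthetic_cube(specs, cam, self.flat_forward(0.2), table,
                                     seed=5, shape=(4, 6), noise_sd=0.01)
        assert np.array_equal(c1.image, c2.image)
        assert np.array_equal(c1.label_map, c2.label_map)
        assert np.array_equal(c1.true_sto2_map, c2.true_sto2_map)

    def test_labels_tile_all_organs(self, table):
        cam = CameraModel.delta_bands(np.linspace(500, 995, 10))
        specs = {"a": organ_space(0.2), "b": organ_space(0.5), "c": organ_space(0.8)}
        cube = generate_synthetic_cube(specs, cam, self.flat_forward(0.2), table,
                                       seed=1, shape=(6, 9))
        assert set(np.unique(cube.label_map)) == {0, 1, 2}
        assert cube.class_names == ("a", "b", "c")
        # hidden ground truth stays near the organ's generating stO2
        for ci, s in enumerate((0.2, 0.5, 0.8)):
            vals = cube.true_sto2_map[cube.label_map == ci]
            assert np.all(np.abs(vals - s) <= 0.011)

    def test_noise_clipped_to_unit_interval(self, table):
        cam = CameraModel.delta_bands(np.linspace(500, 995, 10))
        cube = generate_synthetic_cube({"o": organ_space(0.9)}, cam,
                                       self.flat_forward(0.98), table,
                                       seed=2, shape=(4, 4), noise_sd=0.2)
        assert cube.image.max() <= 1.0 and cube.image.min() >= 0.0
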