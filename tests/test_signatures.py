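"""Signature extraction, difference spectra and band-of-interest discovery."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from vinesense.containers import GeoTransform, PlantRecord, SpectralCube, SpectralSignature
from vinesense.signatures import (
    bands_of_interest,
    class_signatures,
    difference_spectrum,
    mean_signature,
    plant_pixel_mask,
    propose_indices,
)
from vinesense.synthetic import (
    VineyardConfig,
    generate_reflectance_cube,
    healthy_endmember,
    infested_endmember,
)


def _cube(values, cell=0.1, origin=(0.0, None)):
    rows, cols, bands = values.shape
    oy = origin[1] if origin[1] is not None else rows * cell
    return SpectralCube(values, np.linspace(400, 1000, bands),
                        GeoTransform(origin[0], oy, cell))


class TestPixelMask:
    def test_disc_on_aligned_grid_counts_29_cells(self):
        # trunk at a cell centre, radius 0.3 m, 0.1 m cells:
        # lattice offsets with i^2 + j^2 <= 9 -> 29 centres
        cube = _cube(np.zeros((11, 11, 3)))
        plant = PlantRecord(tree_number=1, x=0.55, y=0.55)
        mask = plant_pixel_mask(cube, plant, radius=0.3)
        assert mask.sum() == 29

    def test_polygon_covering_cube_selects_all(self):
        cube = _cube(np.zeros((4, 5, 3)))
        mask = plant_pixel_mask(cube, geometry=box(-1, -1, 10, 10))
        assert mask.all()

    def test_degenerate_polygon_selects_nothing(self, caplog):
        cube = _cube(np.zeros((4, 4, 3)))
        degenerate = Polygon([(0, 0), (1, 1), (0, 0)])
        with caplog.at_level("WARNING"):
            mask = plant_pixel_mask(cube, geometry=degenerate)
        assert not mask.any()


class TestMeanSignature:
    def test_single_pixel_mean_is_that_spectrum(self, rng):
        cube = _cube(rng.uniform(0, 1, (4, 4, 6)))
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 1] = True
        sig = mean_signature(cube, mask, "one")
        np.testing.assert_array_equal(sig.mean, cube.values[2, 1])
        np.testing.assert_array_equal(sig.sd, 0.0)
        assert sig.n_pixels == 1

    def test_noiseless_plant_equals_endmember(self):
        config = VineyardConfig(seed=5, n_rows=1, vines_per_row=3, noise_sd=0.0,
                                infestation_rate=0.0)
        cube, truth = generate_reflectance_cube(config)
        plant = truth.plants[1]
        mask = plant_pixel_mask(cube, plant, radius=0.25)
        sig = mean_signature(cube, mask)
        np.testing.assert_allclose(
            sig.mean, healthy_endmember(config.wavelengths).mean,
            rtol=0, atol=1e-14,
        )

    def test_noisy_mean_within_clt_bound(self):
        config = VineyardConfig(seed=5, n_rows=1, vines_per_row=3, noise_sd=0.02,
                                infestation_rate=0.0, cube_cell=0.05)
        cube, truth = generate_reflectance_cube(config)
        mask = plant_pixel_mask(cube, truth.plants[0], radius=0.28)
        sig = mean_signature(cube, mask)
        assert sig.n_pixels >= 80
        truth_mean = healthy_endmember(config.wavelengths).mean
        se = config.noise_sd / np.sqrt(sig.n_pixels)
        # a few of 274 bands may straggle just past 3 SE; none far beyond
        frac_in = np.mean(np.abs(sig.mean - truth_mean) <= 3 * se)
        assert frac_in > 0.98
        assert np.abs(sig.mean - truth_mean).max() < 5 * se

    def test_nodata_pixels_excluded(self, rng):
        cube = _cube(rng.uniform(0.1, 1, (3, 3, 4)))
        cube.values[0, 0, :] = cube.nodata
        mask = np.ones((3, 3), dtype=bool)
        sig = mean_signature(cube, mask)
        assert sig.n_pixels == 8


class TestClassSignatures:
    def test_single_class_equals_pooled_mean(self, rng):
        cube = _cube(rng.uniform(0, 1, (12, 12, 5)))
        plants = [PlantRecord(tree_number=i + 1, x=0.35 + 0.5 * i, y=0.6)
                  for i in range(2)]
        sigs = class_signatures(cube, plants, ["a", "a"], radius=0.2)
        assert len(sigs) == 1
        mask = np.zeros((12, 12), dtype=bool)
        for p in plants:
            mask |= plant_pixel_mask(cube, p, radius=0.2)
        np.testing.assert_allclose(sigs[0].mean, mean_signature(cube, mask).mean)

    def test_pooled_equals_count_weighted_member_mean(self, rng):
        cube = _cube(rng.uniform(0, 1, (20, 20, 5)))
        plants = [PlantRecord(tree_number=1, x=0.5, y=0.5),
                  PlantRecord(tree_number=2, x=1.5, y=1.5)]
        pooled = class_signatures(cube, plants, ["c", "c"], radius=0.3)[0]
        members = [mean_signature(cube, plant_pixel_mask(cube, p, radius=0.3))
                   for p in plants]
        weights = np.array([m.n_pixels for m in members], dtype=float)
        expected = sum(w * m.mean for w, m in zip(weights, members)) / weights.sum()
        np.testing.assert_allclose(pooled.mean, expected, atol=1e-12)
        assert pooled.n_pixels == int(weights.sum())

    def test_two_classes_from_distinct_endmembers(self):
        config = VineyardConfig(seed=9, n_rows=2, vines_per_row=6, noise_sd=0.0,
                                infestation_rate=0.4)
        cube, truth = generate_reflectance_cube(config)
        labels = ["infested" if i else "healthy" for i in truth.infested]
        sigs = {s.label: s for s in class_signatures(cube, truth.plants, labels)}
        w = config.wavelengths
        np.testing.assert_allclose(sigs["healthy"].mean, healthy_endmember(w).mean,
                                   rtol=0, atol=1e-14)
        np.testing.assert_allclose(sigs["infested"].mean, infested_endmember(w).mean,
                                   rtol=0, atol=1e-14)

    def test_default_scenario_reproduces_chlorophyll_well_ordering(self):
        config = VineyardConfig(seed=10, n_rows=3, vines_per_row=8,
                                infestation_rate=0.3)
        cube, truth = generate_reflectance_cube(config)
        labels = ["infested" if i else "healthy" for i in truth.infested]
        sigs = {s.label: s for s in class_signatures(cube, truth.plants, labels)}
        w = config.wavelengths
        i670 = np.argmin(np.abs(w - 670))
        i800 = np.argmin(np.abs(w - 800))
        assert sigs["infested"].mean[i670] > sigs["healthy"].mean[i670]
        assert sigs["infested"].mean[i800] < sigs["healthy"].mean[i800]


class TestDifferenceSpectrum:
    def _sig(self, w, mean, label=""):
        return SpectralSignature(w, mean, np.zeros_like(w), 10, label)

    def test_identical_signatures_give_zero(self):
        w = np.linspace(400, 1000, 50)
        sig = self._sig(w, np.sin(w / 100))
        diff = difference_spectrum(sig, sig)
        np.testing.assert_array_equal(diff.mean, 0.0)

    def test_antisymmetric(self, rng):
        w = np.linspace(400, 1000, 50)
        a = self._sig(w, rng.uniform(0, 1, 50))
        b = self._sig(w, rng.uniform(0, 1, 50))
        np.testing.assert_array_equal(difference_spectrum(a, b).mean,
                                      -difference_spectrum(b, a).mean)

    def test_constructed_offset_recovered(self):
        w = np.linspace(400, 1000, 50)
        base = np.full(50, 0.3)
        diff = difference_spectrum(self._sig(w, base + 0.07), self._sig(w, base))
        np.testing.assert_allclose(diff.mean, 0.07)

    def test_sd_combines_in_quadrature(self):
        w = np.linspace(400, 1000, 10)
        a = SpectralSignature(w, np.zeros(10), np.full(10, 3.0), 5, "a")
        b = SpectralSignature(w, np.zeros(10), np.full(10, 4.0), 5, "b")
        np.testing.assert_allclose(difference_spectrum(a, b).sd, 5.0)


class TestBandsOfInterest:
    def _diff(self, w, mean):
        return SpectralSignature(w, mean, np.zeros_like(w), 10, "d")

    def test_monotone_sign_change_gives_one_crossing(self):
        w = np.linspace(400, 1000, 274)
        diff = self._diff(w, np.linspace(-1, 1, 274))
        bands = bands_of_interest(diff, smoothing_window=1)
        crossings = [b for b in bands if b.kind == "zero_crossing"]
        assert len(crossings) == 1
        assert crossings[0].wavelength == pytest.approx(700.0, abs=2.2)

    def test_planted_extrema_recovered_within_band_spacing(self):
        w = np.linspace(400, 1000, 274)
        mean = (0.05 * np.exp(-0.5 * ((w - 522) / 15) ** 2)
                - 0.04 * np.exp(-0.5 * ((w - 671) / 15) ** 2)
                + 0.06 * np.exp(-0.5 * ((w - 782) / 15) ** 2))
        bands = bands_of_interest(self._diff(w, mean), smoothing_window=5)
        maxima = sorted(b.wavelength for b in bands if b.kind == "max_difference")
        spacing = w[1] - w[0]
        for target in (522.0, 671.0, 782.0):
            assert min(abs(m - target) for m in maxima) <= spacing

    def test_flat_nonzero_difference_has_no_features(self):
        w = np.linspace(400, 1000, 100)
        bands = bands_of_interest(self._diff(w, np.full(100, 0.2)),
                                  smoothing_window=3)
        assert bands == []

    def test_invariant_to_common_constant_offset(self, rng):
        w = np.linspace(400, 1000, 274)
        a = rng.uniform(0.2, 0.6, 274)
        b = rng.uniform(0.2, 0.6, 274)
        sig = lambda m: SpectralSignature(w, m, np.zeros(274), 10)
        d1 = difference_spectrum(sig(a), sig(b))
        d2 = difference_spectrum(sig(a + 0.5), sig(b + 0.5))
        b1 = bands_of_interest(d1)
        b2 = bands_of_interest(d2)
        assert [(x.wavelength, x.kind) for x in b1] == [
            (x.wavelength, x.kind) for x in b2
        ]

    def test_window_longer_than_grid_rejected(self):
        w = np.linspace(400, 1000, 5)
        from vinesense.errors import ValidationError
        with pytest.raises(ValidationError):
            bands_of_interest(self._diff(w, np.zeros(5)), smoothing_window=9)


class TestProposeIndices:
    def test_pair_504_522_reproduces_first_phylloxera_index(self, rng):
        (prop,) = propose_indices([504.0, 522.0])
        from vinesense.indices import REGISTRY
        R = {504.0: rng.uniform(0.01, 1, 50), 522.0: rng.uniform(0.01, 1, 50)}
        np.testing.assert_allclose(
            prop.formula(R), REGISTRY["PI1"].formula(R), atol=1e-15
        )
        assert set(prop.required_wavelengths) == {504.0, 522.0}

    def test_single_band_proposes_nothing(self):
        assert propose_indices([671.0]) == []

    def test_k_bands_give_k_choose_2_proposals(self):
        bands = [450.0, 500.0, 550.0, 600.0, 650.0]
        assert len(propose_indices(bands)) == 10

    def test_duplicate_bands_deduplicated(self):
        assert len(propose_indices([500.0, 500.0, 600.0])) == 1
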