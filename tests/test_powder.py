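"""Pseudo-powder patterns and geometry grid scans."""

import numpy as np
import pytest

import stillindex as si
from stillindex.io import ImageModel
from stillindex.powder import (powder_fit_score, pseudo_powder,
                               scan_beam_centre, scan_detector_distance,
                               scan_wavelength, theoretical_pattern)


@pytest.fixture(scope="module")
def bev_images():
    """Low-resolution large-cell stills, simulated at the true 85 mm."""
    spec = si.bev_toy_spec()
    return spec, [si.simulate_image(spec, si.simulate.image_rng(7, k))[0]
                  for k in range(6)]


@pytest.fixture(scope="module")
def bev_theory_lengths():
    spec = si.bev_toy_spec()
    theory = si.enumerate_theoretical_vectors(spec.cell, spec.spacegroup, 0.06)
    return [t for t, _ in theoretical_pattern(theory)]


class TestPseudoPowder:
    def test_two_spots_single_count(self):
        spec = si.cpv17_toy_spec()
        img = ImageModel.from_pixels(
            "x", [[600.0, 700.0], [640.0, 710.0]], spec.geometry, spec.beam)
        pat = pseudo_powder([img], d_max=0.1)
        assert pat.n_vectors == 1
        assert pat.counts.sum() == 1

    def test_i23_peak_at_sqrt2_over_a(self):
        spec = si.cpv17_toy_spec(jitter_px=0.0, noise_fraction=0.0)
        imgs = [si.simulate_image(spec, si.simulate.image_rng(20, k))[0]
                for k in range(4)]
        pat = pseudo_powder(imgs, d_max=0.02, bin_width=2e-4)
        target = np.sqrt(2) / 106.1
        peak_centre = pat.bin_centres[np.argmax(pat.counts)]
        assert abs(peak_centre - target) <= 2e-4

    def test_counts_invariant_to_image_order(self):
        spec = si.cpv17_toy_spec()
        imgs = [si.simulate_image(spec, si.simulate.image_rng(21, k))[0]
                for k in range(3)]
        a = pseudo_powder(imgs, d_max=0.1)
        b = pseudo_powder(imgs[::-1], d_max=0.1)
        assert np.array_equal(a.counts, b.counts)

    def test_axially_absent_length_appears_off_axis(self):
        """A 6_1 screw forbids (0,0,l) reflections for l != 6n, yet the
        c* distance still occurs between general reflection pairs and so
        shows up in the pseudo-powder pattern."""
        cell = si.UnitCell(92.9, 92.9, 130.4, 90, 90, 120)
        sg = si.SpaceGroupInfo.from_symbol("P6122")
        theory = si.enumerate_theoretical_vectors(cell, sg, 0.012)
        uniq, _ = theory.unique_lengths()
        assert np.any(np.abs(uniq - 1 / 130.4) < 1e-9)
        geom = si.DetectorGeometry(175.0, (882, 882), 0.11, 1765, 1765)
        spec = si.SimulationSpec(cell=cell, spacegroup=sg, geometry=geom,
                                 beam=si.Beam(1.27, 1e-3), rlp_radius=5e-3,
                                 jitter_px=0.0, noise_fraction=0.0,
                                 d_max=0.25)
        imgs = [si.simulate_image(spec, si.simulate.image_rng(5, k))[0]
                for k in range(6)]
        pat = pseudo_powder(imgs, d_max=0.012, bin_width=2e-4)
        window = np.abs(pat.bin_centres - 1 / 130.4) <= 2e-4
        assert pat.counts[window].sum() >= 1

    def test_requires_at_least_one_image(self):
        with pytest.raises(ValueError):
            pseudo_powder([], d_max=0.1)


class TestTheoreticalPattern:
    def test_i23_first_three_lengths(self):
        cell = si.UnitCell(106.1, 106.1, 106.1)
        sg = si.SpaceGroupInfo.from_symbol("I23")
        theory = si.enumerate_theoretical_vectors(cell, sg, 0.025)
        lengths = [t for t, _ in theoretical_pattern(theory)][:3]
        a = 106.1
        assert lengths == pytest.approx(
            [np.sqrt(2) / a, np.sqrt(4) / a, np.sqrt(6) / a], rel=1e-9)

    def test_empty_theory_empty_pattern(self):
        empty = si.TheoreticalVectors(np.empty((0, 3)), np.empty((0, 3)))
        assert theoretical_pattern(empty) == []

    def test_f23_first_length(self):
        cell = si.UnitCell(437.0, 437.0, 437.0)
        sg = si.SpaceGroupInfo.from_symbol("F23")
        theory = si.enumerate_theoretical_vectors(cell, sg, 0.005)
        first = theoretical_pattern(theory)[0][0]
        assert first == pytest.approx(np.sqrt(3) / 437.0, rel=1e-9)


class TestPowderFitScore:
    def test_perfect_observation_scores_one(self, bev_images,
                                            bev_theory_lengths):
        spec, imgs = bev_images
        pat = pseudo_powder(imgs, d_max=0.06)
        # observations simulated exactly at this geometry
        assert powder_fit_score(pat, bev_theory_lengths) > 0.95

    def test_uniform_random_lengths_score_near_coverage(self, rng):
        # theory at 0.02 and 0.04, tolerance windows 2*5e-4 wide each:
        # a uniform length on (0, 0.05) falls inside with p = 0.04
        lengths = rng.uniform(0, 0.05, size=20000)
        counts, edges = np.histogram(lengths,
                                     bins=np.arange(0, 0.05 + 1e-4, 1e-4))
        pat = si.PowderPattern(bin_edges=edges, counts=counts, n_images=1)
        score = powder_fit_score(pat, [0.02, 0.04], tol=5e-4)
        assert score == pytest.approx(0.04, abs=0.01)

    def test_true_geometry_beats_misrecorded(self, bev_images,
                                             bev_theory_lengths):
        spec, imgs = bev_images
        wrong = [im.with_geometry(spec.geometry.replace_distance(105.0))
                 for im in imgs]
        s_true = powder_fit_score(pseudo_powder(imgs, 0.06),
                                  bev_theory_lengths)
        s_wrong = powder_fit_score(pseudo_powder(wrong, 0.06),
                                   bev_theory_lengths)
        assert s_true > s_wrong

    def test_empty_pattern_rejected(self):
        pat = si.PowderPattern(bin_edges=np.array([0.0, 1e-4]),
                               counts=np.array([0]), n_images=1)
        with pytest.raises(ValueError):
            powder_fit_score(pat, [0.02])


@pytest.fixture(scope="module")
def cpv_images():
    spec = si.cpv17_toy_spec()
    imgs = [si.simulate_image(spec, si.simulate.image_rng(22, k))[0]
            for k in range(4)]
    theory = si.enumerate_theoretical_vectors(spec.cell, spec.spacegroup,
                                              0.10)
    return imgs, [t for t, _ in theoretical_pattern(theory)]


class TestGeometryScans:
    def test_distance_recovered_from_20mm_misrecord(self, bev_images,
                                                    bev_theory_lengths):
        spec, imgs = bev_images
        mis = [im.with_geometry(spec.geometry.replace_distance(105.0))
               for im in imgs]
        best, scores = scan_detector_distance(
            mis, np.arange(75.0, 115.1, 1.0), bev_theory_lengths, d_max=0.06)
        assert abs(best - 85.0) <= 1.0

    def test_grid_with_only_recorded_distance_returns_it(self, bev_images,
                                                         bev_theory_lengths):
        spec, imgs = bev_images
        best, _ = scan_detector_distance(imgs, [85.0], bev_theory_lengths,
                                         d_max=0.06)
        assert best == 85.0

    def test_wavelength_scan_peaks_at_truth(self, cpv_images):
        imgs, lengths = cpv_images
        grid = np.arange(1.41, 1.515, 0.01)
        best, _ = scan_wavelength(imgs, grid, lengths, d_max=0.10)
        assert abs(best - 1.46) <= 0.0101

    def test_beam_centre_scan_peaks_at_truth(self, cpv_images):
        imgs, lengths = cpv_images
        grid = np.arange(-20.0, 20.1, 4.0)
        best, _ = scan_beam_centre(imgs, grid, lengths, d_max=0.10)
        assert abs(best) <= 4.0

    def test_distance_scan_peaks_at_truth_cpv(self, cpv_images):
        imgs, lengths = cpv_images
        best, _ = scan_detector_distance(imgs, np.arange(95.0, 107.1, 1.0),
                                         lengths, d_max=0.10)
        assert abs(best - 101.2) <= 1.0

    def test_no_vectors_is_an_error(self):
        spec = si.cpv17_toy_spec()
        img = ImageModel.from_pixels("e", [[600.0, 700.0]], spec.geometry,
                                     spec.beam)
        with pytest.raises(ValueError, match="no vectors"):
            scan_detector_distance([img], [100.0, 101.0], [0.013],
                                   d_max=0.19)

    def test_empty_grid_rejected(self, bev_images, bev_theory_lengths):
        spec, imgs = bev_images
        with pytest.raises(ValueError):
            scan_detector_distance(imgs, [], bev_theory_lengths, d_max=0.06)
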