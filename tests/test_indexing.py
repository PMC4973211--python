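"""Candidate pairs, cluster and network indexing, multi-lattice cycles."""

import numpy as np
import pytest

import stillindex as si
from stillindex.indexing import (IndexingParams, candidate_pairs,
                                 cluster_index, grow_network, index_image,
                                 multi_cycle, network_index, _matched_pool)
from stillindex.orientation import similarity_metric
from stillindex.vectors import ToleranceModel


@pytest.fixture(scope="module")
def priors():
    spec = si.cpv17_toy_spec()
    return si.CrystalPriors.build(spec.cell, spec.spacegroup, d_max=0.10)


def _image(spec, master, k):
    return si.simulate_image(spec, si.simulate.image_rng(master, k))


class TestCandidatePairs:
    def _toy_theory_and_vectors(self, obs_angle_deg, thr_angle_deg):
        L = 0.02
        thr_i = np.array([L, 0.0, 0.0])
        a = np.radians(thr_angle_deg)
        thr_j = L * np.array([np.cos(a), np.sin(a), 0.0])
        theory = si.TheoreticalVectors(np.array([[1, 1, 0], [0, 1, 1]]),
                                       np.array([thr_i, thr_j]))
        o = np.radians(obs_angle_deg)
        v1 = si.SpotVector(0, 1, thr_i.copy(), L,
                           matches=np.array([0, 1]))
        v2 = si.SpotVector(2, 3, L * np.array([np.cos(o), np.sin(o), 0.0]),
                           L, matches=np.array([0, 1]))
        return theory, [v1, v2]

    def test_angle_within_tolerance_accepted(self):
        theory, vecs = self._toy_theory_and_vectors(60.0, 60.5)
        out = candidate_pairs(vecs, theory, pair_angle_tol=1.0)
        assert (0, 1, 0, 1) in out

    def test_angle_outside_tolerance_rejected(self):
        theory, vecs = self._toy_theory_and_vectors(60.0, 62.0)
        out = candidate_pairs(vecs, theory, pair_angle_tol=1.0)
        assert (0, 1, 0, 1) not in out

    def test_near_parallel_pairs_excluded(self):
        theory, vecs = self._toy_theory_and_vectors(0.5, 0.5)
        assert candidate_pairs(vecs, theory, pair_angle_tol=1.0) == []

    def test_single_lattice_pairs_all_have_assignments(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.0, noise_fraction=0.0)
        img, truth = _image(spec, 32, 0)
        params = IndexingParams()
        matched = _matched_pool(img.spots, params, priors, img.beam)[:12]
        cands = candidate_pairs(matched, priors.theory, 1.0)
        paired = {(a, b) for a, b, _, _ in cands}
        deltas = np.array([v.delta for v in matched])
        units = deltas / np.linalg.norm(deltas, axis=1, keepdims=True)
        for a in range(len(matched)):
            for b in range(a + 1, len(matched)):
                ang = np.degrees(np.arccos(
                    np.clip(abs(units[a] @ units[b]), -1, 1)))
                if ang > 2.0:   # non-degenerate observed pair
                    assert (a, b) in paired

    def test_matches_exhaustive_enumeration_small_image(self, priors):
        """Oracle: on a small spot set the candidate list equals the brute
        force over all vector pairs x theory assignments."""
        spec = si.cpv17_toy_spec(jitter_px=0.0, noise_fraction=0.0)
        img, _ = _image(spec, 32, 1)
        img.spots = img.spots[:8]
        params = IndexingParams()
        matched = _matched_pool(img.spots, params, priors, img.beam)
        cands = set(candidate_pairs(matched, priors.theory, 1.0))
        th_unit = priors.theory.cart / priors.theory.lengths[:, None]
        brute = set()
        for a in range(len(matched)):
            for b in range(a + 1, len(matched)):
                da, db = matched[a].delta, matched[b].delta
                ca = da / np.linalg.norm(da)
                cb = db / np.linalg.norm(db)
                ang_obs = np.degrees(np.arccos(np.clip(ca @ cb, -1, 1)))
                if ang_obs < 1.0 or ang_obs > 179.0:
                    continue
                for ti in matched[a].matches:
                    for tj in matched[b].matches:
                        ang_thr = np.degrees(np.arccos(np.clip(
                            th_unit[ti] @ th_unit[tj], -1, 1)))
                        if abs(ang_thr - ang_obs) <= 1.0:
                            brute.add((a, b, int(ti), int(tj)))
        assert cands == brute


class TestClusterIndex:
    def test_noise_free_top_cluster_matches_truth(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.0, noise_fraction=0.0)
        img, truth = _image(spec, 33, 0)
        sols = cluster_index(img, IndexingParams(method="cluster"), priors)
        assert sols
        m = similarity_metric(sols[0].U, truth.U[0], priors.lattice_ops)
        assert m <= 0.25

    def test_two_lattice_image_yields_two_distinct_solutions(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.3, noise_fraction=0.1,
                                 n_lattices=2)
        img, truth = _image(spec, 4, 1)
        sols = cluster_index(img, IndexingParams(method="cluster",
                                                 max_lattices=2), priors)
        assert len(sols) == 2
        assert similarity_metric(sols[0].U, sols[1].U,
                                 priors.lattice_ops) > 0.25
        rep = si.evaluate_solutions(truth, sols, priors.lattice_ops)
        assert rep["matched"] == 2

    def test_pure_noise_yields_nothing(self, priors, rng):
        spec = si.cpv17_toy_spec()
        px = np.column_stack([rng.uniform(0, 1765, 80),
                              rng.uniform(0, 1765, 80)])
        img = si.ImageModel.from_pixels("noise", px, spec.geometry, spec.beam)
        assert cluster_index(img, IndexingParams(method="cluster"),
                             priors) == []


class TestGrowNetwork:
    def test_noise_free_network_reaches_threshold(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.0, noise_fraction=0.0)
        img, truth = _image(spec, 34, 0)
        params = IndexingParams()
        matched = _matched_pool(img.spots, params, priors, img.beam)
        assert len(matched) >= 25
        for seed in sorted(range(len(matched)),
                           key=lambda k: (len(matched[k].matches),
                                          -matched[k].length)):
            net = grow_network(seed, matched, params, priors)
            if net is not None:
                break
        assert net is not None
        assert net.size >= params.network_threshold
        m = similarity_metric(net.consensus.U, truth.U[0],
                              priors.lattice_ops)
        assert m <= 0.25

    def test_undersized_pool_reports_too_small(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.0, noise_fraction=0.0)
        img, _ = _image(spec, 34, 1)
        params = IndexingParams()
        matched = _matched_pool(img.spots, params, priors, img.beam)[:15]
        for seed in range(len(matched)):
            assert grow_network(seed, matched, params, priors) is None

    def test_common_spot_off_reproduces_or_enlarges(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.0, noise_fraction=0.0)
        img, _ = _image(spec, 34, 2)
        on = IndexingParams(require_common_spot=True)
        off = IndexingParams(require_common_spot=False)
        matched = _matched_pool(img.spots, on, priors, img.beam)
        seeds = sorted(range(len(matched)),
                       key=lambda k: (len(matched[k].matches),
                                      -matched[k].length))[:5]
        for seed in seeds:
            n_on = grow_network(seed, matched, on, priors)
            n_off = grow_network(seed, matched, off, priors)
            if n_on is not None:
                assert n_off is not None
                assert n_off.size >= min(n_on.size, 30)


class TestNetworkIndex:
    def test_three_lattices_recovered_distinctly(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.3, noise_fraction=0.1,
                                 n_lattices=3)
        img, truth = _image(spec, 2, 0)
        sols = network_index(img, IndexingParams(max_lattices=3), priors)
        assert len(sols) == 3
        for a in range(3):
            for b in range(a + 1, 3):
                assert similarity_metric(sols[a].U, sols[b].U,
                                         priors.lattice_ops) > 0.25
        rep = si.evaluate_solutions(truth, sols, priors.lattice_ops)
        assert rep["matched"] == 3

    def test_max_lattices_one_returns_at_most_one(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.3, noise_fraction=0.1,
                                 n_lattices=3)
        img, _ = _image(spec, 2, 1)
        sols = network_index(img, IndexingParams(max_lattices=1), priors)
        assert len(sols) <= 1

    def test_no_spots_no_solutions(self, priors):
        spec = si.cpv17_toy_spec()
        img = si.ImageModel.from_pixels("empty", np.empty((0, 2)),
                                        spec.geometry, spec.beam)
        assert network_index(img, IndexingParams(), priors) == []

    def test_deterministic_given_identical_input(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.3, noise_fraction=0.1)
        img, _ = _image(spec, 35, 0)
        a = network_index(img, IndexingParams(), priors)
        b = network_index(img, IndexingParams(), priors)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.U, y.U)

    def test_no_symmetry_duplicates_in_output(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.3, noise_fraction=0.1,
                                 n_lattices=2)
        for k in range(3):
            img, _ = _image(spec, 36, k)
            sols = network_index(img, IndexingParams(max_lattices=3), priors)
            for a in range(len(sols)):
                for b in range(a + 1, len(sols)):
                    for O in priors.lattice_ops:
                        assert similarity_metric(sols[a].U @ O, sols[b].U,
                                                 priors.lattice_ops) > 0.25


class TestMultiCycle:
    def test_single_cycle_equals_plain_indexing(self, priors):
        spec = si.cpv17_toy_spec(jitter_px=0.3, noise_fraction=0.1)
        imgs = [_image(spec, 37, k)[0] for k in range(3)]
        params = IndexingParams()
        sols, cum = multi_cycle(imgs, [params], priors)
        plain = [index_image(im, params, priors) for im in imgs]
        assert len(cum) == 1
        for a, b in zip(sols, plain):
            assert len(a) == len(b)
            for x, y in zip(a, b):
                assert np.array_equal(x.U, y.U)

    def test_cumulative_fraction_non_decreasing(self, priors):
        spec = si.cpv17_toy_spec(rlp_radius=8e-4, jitter_px=0.7,
                                 noise_fraction=0.5)
        imgs = [_image(spec, 6, k)[0] for k in range(8)]
        schedule = [
            IndexingParams(tolerance=ToleranceModel(fixed_tol=2e-4),
                           network_threshold=25),
            IndexingParams(tolerance=ToleranceModel(fixed_tol=3e-4),
                           network_threshold=15, require_common_spot=False),
            IndexingParams(tolerance=ToleranceModel(fixed_tol=5e-4),
                           network_threshold=12, require_common_spot=False),
            IndexingParams(method="cluster",
                           tolerance=ToleranceModel(fixed_tol=5e-4)),
        ]
        _, cum = multi_cycle(imgs, schedule, priors)
        assert all(b >= a for a, b in zip(cum, cum[1:]))

    def test_hard_images_gain_from_later_cycles(self, priors):
        """A schedule that tightens tolerance and relaxes the network
        threshold indexes strictly more than its first cycle alone."""
        spec = si.cpv17_toy_spec(rlp_radius=8e-4, jitter_px=0.7,
                                 noise_fraction=0.5)
        pairs = [_image(spec, 6, k) for k in range(10)]
        imgs = [p[0] for p in pairs]
        truths = [p[1] for p in pairs]
        schedule = [
            IndexingParams(tolerance=ToleranceModel(fixed_tol=2e-4),
                           network_threshold=25),
            IndexingParams(tolerance=ToleranceModel(fixed_tol=3e-4),
                           network_threshold=15, require_common_spot=False),
            IndexingParams(tolerance=ToleranceModel(fixed_tol=5e-4),
                           network_threshold=12, require_common_spot=False),
            IndexingParams(method="cluster",
                           tolerance=ToleranceModel(fixed_tol=5e-4)),
        ]
        sols, cum = multi_cycle(imgs, schedule, priors)
        assert cum[-1] > cum[0]
        correct = sum(
            si.evaluate_solutions(t, s, priors.lattice_ops)["matched"]
            for t, s in zip(truths, sols))
        assert correct >= 6   # later cycles find genuinely correct lattices

    def test_empty_schedule_rejected(self, priors):
        with pytest.raises(ValueError):
            multi_cycle([], [], priors)


class TestParams:
    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError):
            IndexingParams(method="guesswork")

    def test_duplicate_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            IndexingParams(duplicate_metric_threshold=3.0)
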