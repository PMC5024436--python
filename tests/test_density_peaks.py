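"""Density-peak clustering: rho/delta against brute-force oracles, feature
image, candidate selection, pruning, cluster assignment."""

import math

import numpy as np
import pytest

from somapeaks.density_peaks import (
    CenterSelectConfig,
    DensityConfig,
    analyze_region,
    assign_clusters,
    build_feature_image,
    compute_delta,
    compute_rho,
    density_field,
    compute_rho_image,
    feature_density,
    locate_somas,
    prune_candidates,
    region_diameter,
    select_candidates,
)
from somapeaks.phantom import generate_stack, pair_spec
from somapeaks.preprocess import despeckle, binarize, estimate_background, extract_regions
from somapeaks.types import RegionPointSet, VolumeStack


def region_from(indices, intensities, vox=(2.0, 2.0, 2.0)):
    idx = np.asarray(indices)
    return RegionPointSet(
        indices=idx,
        positions_um=(idx + 0.5) * np.asarray(vox),
        intensities=np.asarray(intensities, float),
        region_id=1,
    )


def rho_oracle(region, sigma):
    """Direct double-loop evaluation of the kernel-density sum."""
    pos, I = region.positions_um, region.intensities
    R = 2 * sigma
    coef = 1 / (math.sqrt(2 * math.pi) * sigma)
    raw = np.zeros(len(pos))
    for i in range(len(pos)):
        for j in range(len(pos)):
            d = np.linalg.norm(pos[i] - pos[j])
            if d <= R:
                raw[i] += I[j] * coef * math.exp(-(d**2) / (2 * sigma**2))
    return raw / raw.max()


def delta_oracle(region, rho):
    """O(n^2) minimum-distance-to-higher-density, ties by ascending voxel order."""
    pos = region.positions_um
    n = len(pos)
    key = region.linear_indices
    diam = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            diam = max(diam, np.linalg.norm(pos[i] - pos[j]))
    delta = np.ones(n)
    for i in range(n):
        best = np.inf
        for j in range(n):
            higher = rho[j] > rho[i] or (rho[j] == rho[i] and key[j] < key[i])
            if j != i and higher:
                best = min(best, np.linalg.norm(pos[i] - pos[j]))
        if np.isfinite(best):
            delta[i] = best / diam
    return delta


class TestRho:
    def test_single_point(self):
        r = region_from([[3, 3, 3]], [140.0])
        assert compute_rho(r).tolist() == [1.0]

    def test_two_distant_equal_points(self):
        # distance 40 um > R = 8 um: identical raw values, both normalise to 1
        r = region_from([[0, 0, 0], [0, 0, 20]], [150.0, 150.0])
        assert compute_rho(r).tolist() == [1.0, 1.0]

    def test_matches_bruteforce(self, random_region):
        region = random_region(n=200, seed=1)
        got = compute_rho(region, DensityConfig(sigma=4.0, support="region"))
        want = rho_oracle(region, 4.0)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_image_support_equals_field_sampling(self):
        """Image-supported rho is the truncated-kernel convolution at region voxels."""
        r = np.random.default_rng(2)
        stack = VolumeStack(r.poisson(100, (12, 12, 12)).astype(np.uint16), (2.0, 2.0, 2.0))
        field = density_field(stack, DensityConfig(sigma=3.0))
        # oracle at one voxel: direct sum over all voxels within R
        idx = np.argwhere(np.ones(stack.shape, bool))
        pos = (idx + 0.5) * 2.0
        p = np.array([11.0, 11.0, 11.0])
        d = np.linalg.norm(pos - p, axis=1)
        keep = d <= 6.0
        coef = 1 / (math.sqrt(2 * math.pi) * 3.0)
        want = (stack.data.reshape(-1)[keep] * coef * np.exp(-d[keep] ** 2 / 18.0)).sum()
        assert field[5, 5, 5] == pytest.approx(want, rel=1e-6)


class TestDelta:
    def test_global_max_is_one(self, random_region):
        region = random_region(n=50, seed=3)
        rho = compute_rho(region, DensityConfig(support="region"))
        delta, nn = compute_delta(region, rho)
        top = np.argmax(rho)
        assert delta[top] == 1.0 and nn[top] == -1

    def test_two_point_region_both_one(self):
        r = region_from([[0, 0, 0], [0, 0, 3]], [150.0, 120.0])
        rho = compute_rho(r)
        delta, _ = compute_delta(r, rho)
        # the lower point's nearest-higher distance equals the diameter
        assert delta.tolist() == [1.0, 1.0]

    def test_single_point(self):
        r = region_from([[1, 1, 1]], [99.0])
        delta, nn = compute_delta(r, compute_rho(r))
        assert delta.tolist() == [1.0] and nn.tolist() == [-1]

    @pytest.mark.parametrize("n,seed", [(60, 4), (200, 5), (500, 6)])
    def test_matches_bruteforce(self, random_region, n, seed):
        region = random_region(n=n, seed=seed)
        rho = compute_rho(region, DensityConfig(support="region"))
        delta, nn = compute_delta(region, rho)
        np.testing.assert_allclose(delta, delta_oracle(region, rho), rtol=1e-9)

    def test_tied_densities_deterministic(self):
        """Exact density ties resolve by voxel order: exactly one delta = 1."""
        r = region_from([[0, 0, 0], [0, 0, 1], [0, 0, 10]], [150.0, 150.0, 150.0])
        rho = np.array([1.0, 1.0, 1.0])
        delta, _ = compute_delta(r, rho)
        assert (delta == 1.0).sum() == 1
        # earlier voxel order ranks as higher density
        np.testing.assert_allclose(delta, [1.0, 2.0 / 20.0, 18.0 / 20.0])


class TestFeatureImage:
    def test_mass_conservation_interior(self):
        """An interior blob's smoothed mass is fully conserved (the unit-sum
        kernel only loses mass at the grid border)."""
        rho = np.concatenate([np.full(50, 0.5), [1.0]])
        delta = np.concatenate([np.full(50, 0.5), [1.0]])
        img = build_feature_image(rho, delta)
        window = img[495:506, 495:506]  # 11x11 kernel support around bin (500, 500)
        assert window.sum() == pytest.approx(50 / 51, abs=1e-9)

    def test_single_point_region_central_weight(self):
        cfg = CenterSelectConfig()
        img = build_feature_image(np.array([1.0]), np.array([1.0]), cfg)
        g = np.exp(-(np.arange(-5, 6) ** 2) / 18.0)
        central = (g.max() / g.sum()) ** 2
        lam = feature_density(np.array([1.0]), np.array([1.0]), img, cfg)
        assert lam[0] == pytest.approx(central, rel=1e-9)

    def test_crowded_bin_rejected_isolated_kept(self):
        """A 100-point co-located blob has Lambda far above the selection
        threshold; a lone far-away feature point stays below it."""
        rho = np.concatenate([np.full(100, 0.2), [1.0]])
        delta = np.concatenate([np.full(100, 0.1), [1.0]])
        cfg = CenterSelectConfig()
        img = build_feature_image(rho, delta, cfg)
        lam = feature_density(rho, delta, img, cfg)
        assert lam[0] > 1.5 * cfg.thre_selective
        assert lam[-1] < cfg.thre_selective

    def test_out_of_range_clamped(self):
        img = build_feature_image(np.array([0.5, 1.0]), np.array([0.5, 1.0]))
        lam = feature_density(np.array([2.0]), np.array([2.0]), img)
        assert lam.shape == (1,)


class TestSelection:
    def test_high_lambda_excluded(self):
        cand = select_candidates(np.array([1.0]), np.array([0.5]), diameter=40.0)
        assert len(cand) == 0

    def test_small_delta_excluded(self):
        # delta * diameter = 2 um < R_min = 3 um
        cand = select_candidates(
            np.array([0.05]), np.array([0.0]), diameter=40.0, cfg=CenterSelectConfig(R_min=3.0)
        )
        assert len(cand) == 0

    def test_zero_diameter_region_yields_nothing(self):
        assert len(select_candidates(np.array([1.0]), np.array([0.0]), 0.0)) == 0

    def test_single_soma_global_max_selected(self):
        """End-to-end on one clean simulated soma: its density maximum is the
        sole selected centre."""
        spec = pair_spec(snr=6.0, d=26.0, seed=4)
        spec.somas = [spec.somas[0]]
        stack, truth = generate_stack(spec)
        C = estimate_background(stack)
        regions = [
            r for r in extract_regions(despeckle(binarize(stack, C)), stack) if len(r) > 52
        ]
        assert len(regions) == 1
        feats = analyze_region(
            regions[0],
            DensityConfig(),
            CenterSelectConfig(R_min=8.0),
            field=density_field(stack, DensityConfig()),
        )
        assert len(feats.centers) == 1
        center_pos = regions[0].positions_um[feats.centers[0]]
        assert np.linalg.norm(center_pos - truth.centers_um[0]) < 8.0


class TestPruning:
    def test_close_pair_keeps_higher_density(self):
        pos = np.array([[0.0, 0, 0], [0, 0, 2.0]])
        rho = np.array([0.9, 1.0])
        keep = prune_candidates(np.array([0, 1]), pos, rho, np.array([0, 1]), R_min=3.0)
        assert keep.tolist() == [1]

    def test_distant_pair_kept(self):
        pos = np.array([[0.0, 0, 0], [0, 0, 10.0]])
        keep = prune_candidates(np.array([0, 1]), pos, np.array([1.0, 0.5]), np.array([0, 1]), 3.0)
        assert sorted(keep.tolist()) == [0, 1]

    def test_single_candidate(self):
        keep = prune_candidates(np.array([7]), np.zeros((8, 3)), np.arange(8.0), np.arange(8), 3.0)
        assert keep.tolist() == [7]

    def test_chain_traversal(self):
        """Three candidates in a 2-um chain: the strongest deletes its
        neighbour; the far end, never deleted, survives."""
        pos = np.array([[0.0, 0, 0], [0, 0, 2.0], [0, 0, 4.0]])
        rho = np.array([1.0, 0.9, 0.8])
        keep = prune_candidates(np.array([0, 1, 2]), pos, rho, np.arange(3), R_min=3.0)
        assert keep.tolist() == [0, 2]


def assignment_oracle(region, rho, nn_higher, centers):
    """Single-sweep assignment in descending density order (the classic
    density-peak rule): each point inherits its nearest-higher neighbour's
    label; valid whenever the density maximum is a centre."""
    order = np.lexsort((region.linear_indices, -rho))
    labels = np.full(len(rho), -1)
    labels[centers] = np.arange(len(centers))
    for i in order:
        if labels[i] < 0:
            labels[i] = labels[nn_higher[i]]
    return labels


class TestAssignment:
    def test_single_center_labels_all(self, random_region):
        region = random_region(n=80, seed=8)
        rho = compute_rho(region, DensityConfig(support="region"))
        _, nn = compute_delta(region, rho)
        labels = assign_clusters(region, rho, nn, np.array([int(np.argmax(rho))]))
        assert (labels == 0).all()

    def test_no_centers_unlabeled(self, random_region):
        region = random_region(n=10, seed=9)
        rho = compute_rho(region, DensityConfig(support="region"))
        _, nn = compute_delta(region, rho)
        assert (assign_clusters(region, rho, nn, np.array([], dtype=int)) == -1).all()

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_single_sweep_oracle(self, random_region, seed):
        region = random_region(n=150, seed=seed)
        rho = compute_rho(region, DensityConfig(support="region"))
        _, nn = compute_delta(region, rho)
        top = int(np.argmax(rho))
        others = np.setdiff1d(np.arange(len(rho)), [top])
        centers = np.array([top, others[0]])
        got = assign_clusters(region, rho, nn, centers)
        want = assignment_oracle(region, rho, nn, centers)
        assert np.array_equal(got, want)

    def test_partition_invariants(self, random_region):
        """Total partition, one centre per cluster, higher-density links stay
        within the cluster."""
        region = random_region(n=200, seed=14)
        rho = compute_rho(region, DensityConfig(support="region"))
        _, nn = compute_delta(region, rho)
        order = np.lexsort((region.linear_indices, -rho))
        centers = order[:3]
        labels = assign_clusters(region, rho, nn, centers)
        assert (labels >= 0).all()
        for c_label, c in enumerate(centers):
            assert labels[c] == c_label
        for i in range(len(rho)):
            if i not in centers and nn[i] >= 0:
                assert labels[i] == labels[nn[i]]


class TestLocateSomas:
    def test_blank_stack_no_detections(self, flat_stack):
        dets, label_map = locate_somas(flat_stack, [])
        assert dets == [] and (label_map == 0).all()

    def test_separated_pair_two_clusters(self):
        """d=26, SNR=6: two clusters, each covering one true sphere's majority."""
        spec = pair_spec(snr=6.0, d=26.0, seed=2)
        stack, truth = generate_stack(spec)
        C = estimate_background(stack)
        regions = [
            r for r in extract_regions(despeckle(binarize(stack, C)), stack) if len(r) > 52
        ]
        dets, label_map = locate_somas(
            stack, regions, DensityConfig(), CenterSelectConfig(R_min=8.0)
        )
        assert len(dets) == 2
        for det in dets:
            dists = np.linalg.norm(truth.centers_um - det.center_um, axis=1)
            true_c = truth.centers_um[np.argmin(dists)]
            member_d = np.linalg.norm(det.member_positions_um - true_c, axis=1)
            assert (member_d <= 10.0 + 2 * 3**0.5).mean() > 0.9  # members hug their sphere

    def test_labels_unique_and_match_map(self):
        spec = pair_spec(snr=6.0, d=22.0, seed=6)
        stack, _ = generate_stack(spec)
        C = estimate_background(stack)
        regions = [
            r for r in extract_regions(despeckle(binarize(stack, C)), stack) if len(r) > 52
        ]
        dets, label_map = locate_somas(
            stack, regions, DensityConfig(), CenterSelectConfig(R_min=8.0)
        )
        labels = [d.label for d in dets]
        assert len(set(labels)) == len(labels)
        assert set(np.unique(label_map)) == {0, *labels}

    def test_centers_are_member_voxels(self):
        spec = pair_spec(snr=4.0, d=18.0, seed=5)
        stack, _ = generate_stack(spec)
        C = estimate_background(stack)
        regions = [
            r for r in extract_regions(despeckle(binarize(stack, C)), stack) if len(r) > 52
        ]
        dets, _ = locate_somas(stack, regions, DensityConfig(), CenterSelectConfig(R_min=8.0))
        for det in dets:
            assert any(np.allclose(det.center_um, p) for p in det.member_positions_um)


def test_region_diameter_matches_bruteforce(random_region):
    region = random_region(n=600, seed=21)
    pos = region.positions_um
    brute = max(
        np.linalg.norm(pos[i] - pos[j]) for i in range(len(pos)) for j in range(i + 1, len(pos))
    )
    assert region_diameter(pos) == pytest.approx(brute, rel=1e-12)
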