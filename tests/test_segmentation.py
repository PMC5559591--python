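"""Harmonic label propagation: affinity weights, solver oracle, segmentation."""

import numpy as np
import pytest

from necrofract.errors import GraphError, ParameterError
from necrofract.segmentation import (
    SeedLabels,
    auto_seed,
    build_affinity_graph,
    harmonic_label_propagation,
    segment_necrosis,
)
from necrofract.synthetic import PhantomSpec, make_tumor_phantom


def dense_harmonic(weights: np.ndarray, labels: dict[int, float]) -> np.ndarray:
    """Independent brute-force solve of the clamped Laplacian system."""
    n = weights.shape[0]
    L = np.diag(weights.sum(axis=1)) - weights
    f = np.full(n, np.nan)
    for node, value in labels.items():
        f[node] = value
    u = np.isnan(f)
    f[u] = np.linalg.solve(L[np.ix_(u, u)], weights[np.ix_(u, ~u)] @ f[~u])
    return f


class TestAffinityGraph:
    def test_constant_image_unit_weights(self):
        graph = build_affinity_graph(np.ones((3, 3)), np.ones((3, 3), bool), connectivity=4)
        assert np.allclose(graph.weights.data, 1.0)
        assert graph.weights.nnz == 2 * 12  # 12 undirected 4-neighbor edges

    def test_weight_at_one_sigma(self):
        image = np.array([[0.0, 0.3]])
        mask = np.ones((1, 2), bool)
        graph = build_affinity_graph(image, mask, sigma=0.3)
        assert graph.weights[0, 1] == pytest.approx(np.exp(-1.0))

    def test_matches_brute_force_double_loop(self, noisy_phantom):
        image, tumor, _ = noisy_phantom
        crop_img = image[40:45, 40:45]
        crop_mask = np.ones((5, 5), bool)
        graph = build_affinity_graph(crop_img, crop_mask, sigma=0.2, connectivity=8)
        W = graph.weights.toarray()
        flat = crop_img.ravel()
        for a in range(25):
            ra, ca = divmod(a, 5)
            for b in range(25):
                rb, cb = divmod(b, 5)
                if a != b and max(abs(ra - rb), abs(ca - cb)) == 1:
                    expected = np.exp(-((flat[a] - flat[b]) ** 2) / 0.2**2)
                else:
                    expected = 0.0
                assert W[a, b] == pytest.approx(expected, abs=1e-12)

    def test_default_sigma_is_neighbor_difference_std(self):
        rng = np.random.default_rng(0)
        image = rng.random((6, 6))
        mask = np.ones((6, 6), bool)
        graph = build_affinity_graph(image, mask, connectivity=4)
        diffs = np.concatenate(
            [(image[:, 1:] - image[:, :-1]).ravel(), (image[1:, :] - image[:-1, :]).ravel()]
        )
        assert graph.sigma == pytest.approx(np.std(diffs))

    def test_single_pixel_mask_rejected(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        with pytest.raises(GraphError):
            build_affinity_graph(np.ones((3, 3)), mask)


class TestHarmonicPropagation:
    def test_path_midpoint_is_half(self):
        image = np.zeros((1, 3))
        mask = np.ones((1, 3), bool)
        graph = build_affinity_graph(image, mask, sigma=1.0, connectivity=4)
        seeds = SeedLabels(necrosis_seeds=np.array([2]), tumor_seeds=np.array([0]))
        field = harmonic_label_propagation(graph, seeds)
        assert field.values[1] == pytest.approx(0.5)

    def test_single_neighbor_of_seed(self):
        # 3-pixel path where the unlabeled end node's only neighbor is the
        # label-1 seed: its harmonic value is that neighbor's label
        image = np.zeros((1, 3))
        mask = np.ones((1, 3), bool)
        graph = build_affinity_graph(image, mask, sigma=1.0, connectivity=4)
        seeds = SeedLabels(necrosis_seeds=np.array([1]), tumor_seeds=np.array([0]))
        field = harmonic_label_propagation(graph, seeds)
        assert field.values[2] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_solve_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(3, 8, size=2)
        image = rng.random((h, w))
        mask = rng.random((h, w)) < 0.85
        mask[0, 0] = mask[-1, -1] = True
        graph = build_affinity_graph(image, mask, connectivity=8)
        pix = graph.node_pixels
        nec = np.array([pix[0]])
        tum = np.array([pix[-1]])
        seeds = SeedLabels(necrosis_seeds=nec, tumor_seeds=tum)
        try:
            field = harmonic_label_propagation(graph, seeds)
        except GraphError:
            return  # disconnected component without a seed: contract honored
        labels = {0: 1.0, graph.n_nodes - 1: 0.0}
        dense = dense_harmonic(graph.weights.toarray(), labels)
        assert np.abs(field.values - dense).max() < 1e-8

    def test_maximum_principle(self):
        rng = np.random.default_rng(7)
        image = rng.random((10, 10))
        mask = np.ones((10, 10), bool)
        graph = build_affinity_graph(image, mask)
        seeds = SeedLabels(
            necrosis_seeds=graph.node_pixels[:3], tumor_seeds=graph.node_pixels[-3:]
        )
        field = harmonic_label_propagation(graph, seeds)
        assert field.values.min() >= 0.0 and field.values.max() <= 1.0

    def test_relabeling_invariance_under_transpose(self):
        rng = np.random.default_rng(1)
        image = rng.random((6, 9))
        mask = np.ones((6, 9), bool)
        graph = build_affinity_graph(image, mask, sigma=0.3)
        seeds = SeedLabels(necrosis_seeds=np.array([0]), tumor_seeds=np.array([53]))
        field = harmonic_label_propagation(graph, seeds).to_image()
        graph_t = build_affinity_graph(image.T, mask.T, sigma=0.3)
        r0, c0 = 0, 0
        r1, c1 = divmod(53, 9)
        seeds_t = SeedLabels(
            necrosis_seeds=np.array([c0 * 6 + r0]), tumor_seeds=np.array([c1 * 6 + r1])
        )
        field_t = harmonic_label_propagation(graph_t, seeds_t).to_image()
        assert np.allclose(field, field_t.T)

    def test_component_without_seed_names_size(self):
        image = np.zeros((3, 5))
        mask = np.zeros((3, 5), bool)
        mask[:, :2] = True   # 6-pixel component
        mask[:, 3:] = True   # 6-pixel component, unseeded
        graph = build_affinity_graph(image, mask, sigma=1.0, connectivity=4)
        seeds = SeedLabels(necrosis_seeds=np.array([0]), tumor_seeds=np.array([5]))
        with pytest.raises(GraphError, match="6"):
            harmonic_label_propagation(graph, seeds)


class TestSegmentNecrosis:
    def test_noiseless_phantom_recovers_truth_exactly(self, noiseless_phantom):
        image, tumor, truth = noiseless_phantom
        seeds = auto_seed(image, tumor)
        segmented = segment_necrosis(image, tumor, seeds)
        assert np.array_equal(segmented, truth)

    def test_threshold_one_yields_nothing_beyond_seeds(self, noiseless_phantom):
        image, tumor, truth = noiseless_phantom
        seeds = auto_seed(image, tumor)
        segmented = segment_necrosis(image, tumor, seeds, threshold=1.0)
        seed_mask = np.zeros_like(tumor)
        seed_mask.flat[seeds.necrosis_seeds] = True
        assert not (segmented & ~seed_mask).any()

    def test_output_subset_of_tumor(self, noisy_phantom):
        image, tumor, _ = noisy_phantom
        seeds = auto_seed(image, tumor)
        segmented = segment_necrosis(image, tumor, seeds)
        assert not (segmented & ~tumor).any()

    def test_dice_against_truth_on_noisy_phantoms(self):
        dices = []
        for seed in range(3):
            spec = PhantomSpec(canvas_size=96, boundary_roughness=2.0, n_holes=4, seed=seed)
            image, tumor, truth = make_tumor_phantom(spec)
            seeds = auto_seed(image, tumor)
            segmented = segment_necrosis(image, tumor, seeds)
            dices.append(2 * (segmented & truth).sum() / (segmented.sum() + truth.sum()))
        assert min(dices) >= 0.90

    def test_dice_degrades_with_noise_on_average(self):
        from necrofract.synthetic import NECROSIS_LEVEL, RIM_LEVEL
        from necrofract.util import derive_rng

        def mean_dice(noise_sigma, n=5):
            out = []
            for seed in range(n):
                spec = PhantomSpec(canvas_size=96, boundary_roughness=1.5, n_holes=3, seed=seed)
                image, tumor, truth = make_tumor_phantom(spec)
                clean = np.full(image.shape, 0.05)
                clean[tumor] = RIM_LEVEL
                clean[truth] = NECROSIS_LEVEL
                noisy = np.clip(
                    clean + derive_rng(seed, "noise").normal(0, noise_sigma, clean.shape), 0, 1
                )
                seeds = auto_seed(noisy, tumor)
                seg = segment_necrosis(noisy, tumor, seeds)
                out.append(2 * (seg & truth).sum() / (seg.sum() + truth.sum()))
            return np.mean(out)

        assert mean_dice(0.02) >= mean_dice(0.18)


class TestAutoSeed:
    def test_two_level_image_partitions_exactly(self):
        rng = np.random.default_rng(0)
        mask = np.ones((8, 8), bool)
        image = np.where(rng.random((8, 8)) < 0.5, 0.2, 0.8)
        seeds = auto_seed(image, mask)
        dark = np.flatnonzero(image.ravel() == 0.2)
        bright = np.flatnonzero(image.ravel() == 0.8)
        assert np.array_equal(np.sort(seeds.necrosis_seeds), dark)
        assert np.array_equal(np.sort(seeds.tumor_seeds), bright)

    def test_constant_image_rejected(self):
        with pytest.raises(ParameterError):
            auto_seed(np.ones((8, 8)), np.ones((8, 8), bool))

    def test_crossing_quantiles_rejected(self):
        with pytest.raises(ParameterError):
            auto_seed(np.random.default_rng(0).random((8, 8)), np.ones((8, 8), bool), 0.9, 0.1)

    def test_tiny_mask_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[0, :3] = True
        with pytest.raises(ParameterError):
            auto_seed(np.random.default_rng(0).random((8, 8)), mask)

    def test_noiseless_phantom_seeds_inside_truth(self, noiseless_phantom):
        image, tumor, truth = noiseless_phantom
        seeds = auto_seed(image, tumor)
        assert truth.ravel()[seeds.necrosis_seeds].all()

    def test_seed_labels_validation(self):
        with pytest.raises(ParameterError):
            SeedLabels(necrosis_seeds=np.array([1]), tumor_seeds=np.array([1]))
        with pytest.raises(ParameterError):
            SeedLabels(necrosis_seeds=np.array([], dtype=int), tumor_seeds=np.array([1]))
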