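import numpy as np
import pytest

from tjmetrics.morphometry import (
    clone_zigzag_summary,
    compute_zigzag_index,
    extract_network,
    sample_windows,
    segment_junctions,
)
from tjmetrics.morphometry.zigzag import network_zigzag_index
from tjmetrics.network import EdgeMorphometry, measure_sides, truth_zigzag_index
from tjmetrics.simulate import MonolayerSpec, generate_monolayer
from tjmetrics.simulate.monolayer import generate_truth_network


def _morph(pairs):
    return {
        i: EdgeMorphometry(side_id=i, L_TJ_um=tj, L_St_um=st)
        for i, (tj, st) in enumerate(pairs)
    }


class TestComputeIndex:
    def test_ratio_of_sums_not_mean_of_ratios(self):
        morph = _morph([(3, 2), (5, 4)])
        zi = compute_zigzag_index({0, 1}, morph)
        assert zi.value == pytest.approx(8 / 6)
        assert zi.value != pytest.approx((3 / 2 + 5 / 4) / 2)
        assert zi.n_sides == 2

    def test_all_straight_gives_one(self):
        morph = _morph([(2.0, 2.0), (5.5, 5.5), (1.1, 1.1)])
        assert compute_zigzag_index({0, 1, 2}, morph).value == pytest.approx(1.0)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            compute_zigzag_index(set(), _morph([(3, 2)]))

    def test_permutation_invariance_bit_identical(self):
        rng = np.random.default_rng(4)
        st = rng.uniform(1, 5, size=30)
        morph = _morph([(s * rng.uniform(1.0, 2.0), s) for s in st])
        ids = list(morph)
        a = compute_zigzag_index(ids, morph).value
        b = compute_zigzag_index(ids[::-1], morph).value
        rng.shuffle(ids)
        c = compute_zigzag_index(ids, morph).value
        assert a == b == c


class TestWindows:
    def test_window_covering_whole_field_gets_all_interior_sides(self, small_image):
        net = small_image.truth
        sets, _ = sample_windows(
            net, (60.0, 60.0), window_area_um2=60.0 * 60.0, n_windows=1, seed=0
        )
        assert sets[0] == {s.id for s in net.interior_sides()}

    def test_fixed_seed_reproducible(self, small_image):
        net = small_image.truth
        a = sample_windows(net, (60.0, 60.0), n_windows=5, seed=42)
        b = sample_windows(net, (60.0, 60.0), n_windows=5, seed=42)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_border_sides_never_included(self, small_image):
        net = small_image.truth
        border_ids = {s.id for s in net.sides.values() if s.border}
        sets, _ = sample_windows(net, (60.0, 60.0), n_windows=5, seed=3)
        for ids in sets:
            assert not ids & border_ids

    def test_both_vertices_inside_rule(self, small_image):
        net = small_image.truth
        sets, wins = sample_windows(net, (60.0, 60.0), n_windows=3, seed=1)
        for ids, win in zip(sets, wins):
            for sid in ids:
                s = net.sides[sid]
                assert win.contains(*net.vertices[s.v1])
                assert win.contains(*net.vertices[s.v2])

    def test_window_too_large_raises(self, small_image):
        with pytest.raises(ValueError, match="exceeds the field"):
            sample_windows(small_image.truth, (60.0, 60.0), window_area_um2=1e5)

    def test_paper_scale_pooled_side_count(self):
        # dense mosaic: five 840-µm² windows pool > 80 sides
        spec = MonolayerSpec(
            field_width_um=100.0, field_height_um=100.0, n_cells=150, seed=2
        )
        net = generate_truth_network(spec)
        sets, _ = sample_windows(net, (100.0, 100.0), window_area_um2=840.0, n_windows=5, seed=0)
        pooled = set().union(*sets)
        assert len(pooled) >= 80


class TestCloneSummary:
    def test_single_sample_no_se(self):
        s = clone_zigzag_summary([[1.2, 1.4]])
        assert s.sample_values[0] == pytest.approx(1.3)
        assert s.mean == pytest.approx(1.3)
        assert s.se is None
        assert s.n == 1

    def test_three_samples_textbook_se(self):
        s = clone_zigzag_summary([[1.2], [1.3], [1.4]])
        assert s.mean == pytest.approx(1.3)
        assert s.se == pytest.approx(0.1 / np.sqrt(3))
        assert s.n == 3

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            clone_zigzag_summary([])
        with pytest.raises(ValueError):
            clone_zigzag_summary([[1.2], []])

    def test_simulated_samples_near_truth(self, zigzag_spec):
        # sampling-theory oracle: clone mean within 2 SE of the truth index
        from dataclasses import replace

        per_sample = []
        truths = []
        for seed in (21, 22, 23):
            spec = replace(zigzag_spec, seed=seed)
            img = generate_monolayer(spec)
            truths.append(truth_zigzag_index(img.truth))
            ch = img.channels["junction"]
            net = extract_network(
                segment_junctions(ch, spec.pixel_size_um),
                spec.pixel_size_um,
                intensity=ch,
            )
            morph = measure_sides(net.interior_sides())
            sets, wins = sample_windows(net, (60.0, 60.0), n_windows=5, seed=seed)
            per_sample.append(
                [compute_zigzag_index(ids, morph, w).value for ids, w in zip(sets, wins)]
            )
        summary = clone_zigzag_summary(per_sample)
        # truth varies a little per seed; compare to its average; guard SE > 0
        se = max(summary.se, 0.01)
        assert abs(summary.mean - np.mean(truths)) <= 2 * se + 0.05 * np.mean(truths)


class TestPipelineVsOracle:
    def test_monotonic_ordering_recovered(self, small_spec):
        from dataclasses import replace

        estimates = []
        truths = []
        for amp in (0.3, 0.8, 1.3):
            spec = replace(small_spec, tortuosity_amplitude_um=amp)
            img = generate_monolayer(spec)
            truths.append(truth_zigzag_index(img.truth))
            ch = img.channels["junction"]
            net = extract_network(
                segment_junctions(ch, spec.pixel_size_um), spec.pixel_size_um, intensity=ch
            )
            estimates.append(network_zigzag_index(net).value)
        assert truths[0] < truths[1] < truths[2]
        assert estimates[0] < estimates[1] < estimates[2]
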