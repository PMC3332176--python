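"""Fuzzy cluster-count preselection: sets, rules, inference, seeding."""

import warnings

import numpy as np
import pytest

from dermseg import preselect as pre
from oracles import brute_force_infer


class TestGaussianSets:
    def test_membership_is_one_at_center(self):
        assert pre.gauss_membership(15.0, pre.DISTANCE_SETS[0]) == pytest.approx(1.0)

    def test_one_sigma_value(self):
        # distance/minimum has center 15, spread 16; x = 31 is one sigma out
        assert pre.gauss_membership(31.0, pre.DISTANCE_SETS[0]) == pytest.approx(
            np.exp(-0.5), rel=1e-12
        )

    def test_vanishes_far_away(self):
        assert pre.gauss_membership(1e9, pre.DISTANCE_SETS[0]) == 0.0
        assert pre.gauss_membership(-1e9, pre.DISTANCE_SETS[0]) == 0.0

    def test_linguistic_variable_parameters(self):
        """Spot-check the loaded set parameters of all three variables."""
        short = dict((s.label, s) for s in pre.DISTANCE_SETS)["short"]
        assert (short.center, short.spread) == (105.0, 30.0)
        medium = dict((s.label, s) for s in pre.SIZE_SETS)["medium"]
        assert (medium.center, medium.spread) == (6.53e5, 1.968e5)
        some = dict((s.label, s) for s in pre.CLUSTER_SETS)["some"]
        assert (some.center, some.spread) == (16.0, 5.0)

    def test_nonpositive_spread_rejected(self):
        with pytest.raises(ValueError, match="spread must be positive"):
            pre.GaussianFuzzySet("bad", 0.0, 0.0)


class TestChannelDistances:
    def test_identical_channels(self):
        img = np.tile(np.arange(12.0).reshape(3, 4)[..., None], (1, 1, 3))
        d = pre.channel_pair_distances(img)
        assert (d.d_rb, d.d_rg, d.d_gb) == (0.0, 0.0, 0.0)

    def test_unit_differences_count_pixels(self):
        img = np.zeros((2, 3, 3))
        img[..., 1] = 1.0  # G differs from R and B by 1 at every pixel
        d = pre.channel_pair_distances(img)
        assert (d.d_rb, d.d_rg, d.d_gb) == (0.0, 6.0, 6.0)

    def test_channel_permutation_swaps_distances(self, rng):
        img = rng.uniform(0, 255, (4, 4, 3))
        d = pre.channel_pair_distances(img)
        swapped = pre.channel_pair_distances(img[..., [0, 2, 1]])  # swap G and B
        assert swapped.d_rg == pytest.approx(d.d_rb)
        assert swapped.d_rb == pytest.approx(d.d_rg)
        assert swapped.d_gb == pytest.approx(d.d_gb)


class TestChannelFusion:
    def test_equal_r_and_b(self):
        img = np.zeros((2, 2, 3))
        img[..., 0] = img[..., 2] = 40.0
        img[..., 1] = 90.0
        assert np.array_equal(pre.fuse_similar_channels(img), np.full((2, 2), 40.0))

    def test_all_equal_returns_that_channel(self):
        img = np.full((3, 3, 3), 17.0)
        assert np.array_equal(pre.fuse_similar_channels(img), np.full((3, 3), 17.0))

    def test_two_zero_channels(self):
        img = np.zeros((1, 2, 3))
        img[..., 1] = [3.0, 4.0]
        assert np.array_equal(pre.fuse_similar_channels(img), np.zeros((1, 2)))


class TestInference:
    def test_minimum_distance_min_size_gives_very_few(self):
        assert pre.infer_cluster_count(15.0, 9000.0) == 2

    def test_maximum_distance_max_size_gives_too_many(self):
        assert pre.infer_cluster_count(255.0, 1.44e6) == 33

    def test_output_always_in_defuzzification_range(self, rng):
        for _ in range(50):
            n = pre.infer_cluster_count(float(rng.uniform(0, 255)), float(rng.uniform(1, 2e6)))
            assert 2 <= n <= 40

    def test_matches_brute_force_oracle_on_grid(self):
        rb = pre.default_rule_base()
        for d0 in np.linspace(0, 255, 10):
            for s0 in np.linspace(1e3, 1.5e6, 10):
                assert pre.infer_cluster_count(d0, s0, rb) == brute_force_infer(d0, s0, rb)

    def test_roughly_monotone_in_distance(self):
        """More intensity range never drops the count by more than one
        consequent-set step on a sampled grid."""
        max_gap = 10  # largest spacing between adjacent cluster-set centers
        for s0 in (9000.0, 3.015e5, 1.44e6):
            counts = [pre.infer_cluster_count(d, s0) for d in np.linspace(0, 255, 25)]
            assert min(np.diff(counts)) >= -max_gap

    def test_rule_base_covers_grid_exactly_once(self):
        rb = pre.default_rule_base()
        assert len(rb.rules) == 30
        with pytest.raises(ValueError, match="exactly once"):
            pre.FuzzyRuleBase(rules=rb.rules[:-1] + [rb.rules[0]])

    def test_rule_base_file_round_trip(self, tmp_path):
        rb = pre.default_rule_base()
        path = tmp_path / "rules.txt"
        path.write_text(
            "# custom rules\n"
            + "\n".join(f"{d}, {s} -> {c}" for d, s, c in rb.rules)
            + "\n"
        )
        loaded = pre.load_rule_base(str(path))
        assert loaded.rules == rb.rules


class TestSeeding:
    @pytest.mark.parametrize(
        "v_min,D,N,expected",
        [
            (0.0, 250.0, 5, [50.0, 100.0, 150.0, 200.0, 250.0]),
            (10.0, 100.0, 2, [60.0, 110.0]),
            (42.0, 13.0, 1, [55.0]),
        ],
    )
    def test_equidistant_centers(self, v_min, D, N, expected):
        assert np.allclose(pre.initial_centers(v_min, D, N), expected)

    def test_spacing_is_uniform(self, rng):
        v_min, D, N = 7.0, float(rng.uniform(1, 255)), int(rng.integers(2, 20))
        c = pre.initial_centers(v_min, D, N)
        assert np.allclose(np.diff(c), D / N)
        assert c[-1] == pytest.approx(v_min + D)


class TestCPSFCM:
    def test_two_intensity_image_separates_levels(self):
        img = np.full((20, 20, 3), 200.0)
        img[5:15, 5:15, :] = 50.0
        res = pre.cpsfcm(img)
        low = res.labels[img[..., 0] == 50.0]
        high = res.labels[img[..., 0] == 200.0]
        assert len(np.unique(low)) == 1
        assert len(np.unique(high)) == 1
        assert low[0] != high[0]

    def test_constant_image_degenerates_with_warning(self):
        img = np.full((8, 8, 3), 99.0)
        with pytest.warns(UserWarning, match="constant image"):
            res = pre.cpsfcm(img)
        assert res.preselection.N == 1
        assert np.all(res.labels == res.labels.flat[0])

    def test_deterministic_repeat(self, rng):
        img = rng.uniform(0, 255, (16, 16, 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b = pre.cpsfcm(img), pre.cpsfcm(img)
        assert np.array_equal(a.labels, b.labels)
        assert a.preselection.N == b.preselection.N
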