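"""Sketch model: binarization, patch statistics, feature selection, sketches."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fastvision.sketch import (
    BACKGROUND,
    FeatureSet,
    PatchDistribution,
    binarize,
    code_to_pattern,
    entropy_contribution,
    extract_patch_distribution,
    generate_sketch,
    pattern_to_code,
    select_features_exact,
    select_features_greedy,
    sketch_density,
)


def brute_force_select(dist: dict, N: int, W: float):
    """Independent oracle: enumerate all subsets with itertools."""
    items = sorted(dist.items())
    total = sum(p for _, p in items)
    items = [(c, p / total) for c, p in items if p > 0]
    best_ent, best_set = 0.0, ()
    for r in range(0, min(N, len(items)) + 1):
        for combo in combinations(items, r):
            if sum(p for _, p in combo) > W + 1e-12:
                continue
            ent = sum(-p * np.log2(p) for _, p in combo)
            key = tuple(sorted(c for c, _ in combo))
            if ent > best_ent + 1e-12 or (
                abs(ent - best_ent) <= 1e-12 and key < best_set
            ):
                best_ent, best_set = ent, key
    return best_set, best_ent


class TestPatternCodes:
    def test_roundtrip_bijective_all_512(self):
        seen = set()
        for code in range(512):
            patch = code_to_pattern(code)
            assert pattern_to_code(patch) == code
            seen.add(patch.tobytes())
        assert len(seen) == 512

    def test_row_major_top_left_msb(self):
        patch = np.zeros((3, 3), dtype=np.uint8)
        patch[0, 0] = 1
        assert pattern_to_code(patch) == 256
        patch = np.zeros((3, 3), dtype=np.uint8)
        patch[2, 2] = 1
        assert pattern_to_code(patch) == 1

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError):
            code_to_pattern(512)
        with pytest.raises(ValueError):
            pattern_to_code(np.full((3, 3), 2))


class TestBinarize:
    def test_uniform_above_fixed_threshold_all_white(self):
        img = np.full((5, 5), 200)
        assert binarize(img, "fixed", threshold=128).pixels.min() == 1

    def test_fixed_threshold_splits_columns(self):
        img = np.array([[10, 200], [10, 200]])
        out = binarize(img, "fixed", threshold=128).pixels
        assert out.tolist() == [[0, 1], [0, 1]]

    def test_median_ramp_splits_in_half(self):
        ramp = np.arange(256).reshape(16, 16)
        out = binarize(ramp, "median")
        assert int(out.pixels.sum()) == 128
        assert out.provenance == "median"

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.empty((0, 0)))


class TestPatchDistribution:
    def test_all_white_5x5_nine_centers(self):
        dist = extract_patch_distribution([np.ones((5, 5), dtype=np.uint8)])
        assert dist.total == 9
        assert dist.counts[511] == 9

    def test_all_black_3x3_single_center(self):
        dist = extract_patch_distribution([np.zeros((3, 3), dtype=np.uint8)])
        assert dist.total == 1
        assert dist.counts[0] == 1

    def test_checkerboard_window_enumeration(self, checkerboard4):
        # independent oracle: walk the four 3x3 windows by hand
        expected = {}
        for r in range(1, 3):
            for c in range(1, 3):
                win = checkerboard4[r - 1 : r + 2, c - 1 : c + 2]
                code = int("".join(str(b) for b in win.ravel()), 2)
                expected[code] = expected.get(code, 0) + 1
        dist = extract_patch_distribution([checkerboard4])
        assert dist.total == 4
        assert set(expected.values()) == {2}
        for code, cnt in expected.items():
            assert dist.counts[code] == cnt

    def test_total_sums_hw_minus_2_over_images(self, rng):
        imgs = [rng.integers(0, 2, (h, w)) for h, w in [(3, 7), (10, 4), (6, 6)]]
        dist = extract_patch_distribution(imgs)
        assert dist.total == sum((h - 2) * (w - 2) for h, w in [(3, 7), (10, 4), (6, 6)])

    def test_probabilities_sum_to_one(self, rng):
        dist = extract_patch_distribution([rng.integers(0, 2, (20, 20))])
        assert abs(dist.probs.sum() - 1.0) < 1e-12

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            extract_patch_distribution([np.ones((2, 5), dtype=np.uint8)])


class TestEntropyContribution:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.5, 0.5), (1.0, 0.0), (0.0, 0.0), (0.2, 0.2 * np.log2(5.0))],
    )
    def test_known_values(self, p, expected):
        assert entropy_contribution(p) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            entropy_contribution(1.5)


class TestFeatureSelection:
    def test_uniform_ties_break_by_code(self):
        dist = {7: 0.25, 3: 0.25, 500: 0.25, 40: 0.25}
        fs = select_features_greedy(dist, 2, 1.0, refine=False)
        assert sorted(fs.codes) == [3, 7]
        assert fs.entropy_bits == pytest.approx(1.0)

    def test_worked_five_pattern_example(self, five_pattern_dist):
        expected_ent = 0.2 * np.log2(5) + 0.1 * np.log2(10)
        for select in (
            lambda: select_features_greedy(five_pattern_dist, 2, 0.3, refine=False),
            lambda: select_features_greedy(five_pattern_dist, 2, 0.3),
            lambda: select_features_exact(five_pattern_dist, 2, 0.3),
        ):
            fs = select()
            assert sorted(fs.codes) == [1, 3]  # the p=0.2 and p=0.1 patterns
            assert fs.entropy_bits == pytest.approx(expected_ent, abs=1e-12)

    def test_exact_unconstrained_takes_whole_support(self, five_pattern_dist):
        fs = select_features_exact(five_pattern_dist, 5, 1.0)
        assert sorted(fs.codes) == [0, 1, 2, 3, 4]

    def test_exact_certain_pattern_violates_bandwidth(self):
        fs = select_features_exact({9: 1.0}, 3, 0.5)
        assert fs.codes == ()
        assert fs.entropy_bits == 0.0

    def test_exact_refuses_large_alphabet(self, rng):
        dist = {int(c): 1.0 for c in range(21)}
        with pytest.raises(ValueError):
            select_features_exact(dist, 5, 0.5)

    def test_exact_matches_independent_enumeration(self, rng):
        for _ in range(30):
            m = int(rng.integers(3, 9))
            probs = rng.dirichlet(np.ones(m))
            codes = rng.choice(512, m, replace=False)
            dist = {int(c): float(p) for c, p in zip(codes, probs)}
            N = int(rng.integers(1, m + 1))
            W = float(rng.uniform(0.1, 1.0))
            fs = select_features_exact(dist, N, W)
            oracle_set, oracle_ent = brute_force_select(dist, N, W)
            assert tuple(sorted(fs.codes)) == oracle_set
            assert fs.entropy_bits == pytest.approx(oracle_ent, abs=1e-10)

    def test_exact_entropy_monotone_in_N_and_W(self, rng):
        probs = rng.dirichlet(np.ones(8))
        dist = {i: float(p) for i, p in enumerate(probs)}
        ents_N = [select_features_exact(dist, N, 0.6).entropy_bits for N in range(1, 9)]
        assert all(b >= a - 1e-12 for a, b in zip(ents_N, ents_N[1:]))
        ents_W = [
            select_features_exact(dist, 4, W).entropy_bits
            for W in np.linspace(0.05, 1.0, 12)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(ents_W, ents_W[1:]))

    def test_refinement_fixes_heavy_pattern_trap(self):
        # a high-value heavy pattern crowds out two lighter ones
        dist = {0: 0.3, 1: 0.15, 2: 0.15, 3: 0.2, 4: 0.2}
        plain = select_features_greedy(dist, 5, 0.3, refine=False)
        refined = select_features_greedy(dist, 5, 0.3)
        exact = select_features_exact(dist, 5, 0.3)
        assert plain.entropy_bits < exact.entropy_bits
        assert refined.entropy_bits == pytest.approx(exact.entropy_bits, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_greedy_always_feasible(self, seed):
        r = np.random.default_rng(seed)
        m = int(r.integers(2, 20))
        probs = r.dirichlet(np.ones(m))
        dist = {int(c): float(p) for c, p in zip(r.choice(512, m, replace=False), probs)}
        N = int(r.integers(1, m + 1))
        W = float(r.uniform(0.01, 1.0))
        fs = select_features_greedy(dist, N, W)
        assert len(fs) <= N
        assert fs.total_prob <= W + 1e-12
        assert len(set(fs.codes)) == len(fs.codes)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            select_features_greedy({}, 5, 0.5)


class TestSketch:
    def _all_patterns(self):
        probs = tuple(1.0 / 512 for _ in range(512))
        return FeatureSet(
            codes=tuple(range(512)), probs=probs, N=512, W=1.0,
            total_prob=1.0, entropy_bits=9.0,
        )

    def test_empty_featureset_blank_sketch(self, rng):
        img = rng.integers(0, 2, (8, 8))
        fs = FeatureSet(codes=(), probs=(), N=1, W=0.5)
        s = generate_sketch(img, fs)
        assert s.retained_count == 0
        assert sketch_density(s) == 0.0

    def test_all_patterns_identity_on_interior(self, rng):
        img = rng.integers(0, 2, (10, 12))
        s = generate_sketch(img, self._all_patterns())
        assert s.retained_count == 8 * 10
        assert np.array_equal(s.pixels[1:-1, 1:-1], img[1:-1, 1:-1].astype(np.int8))
        assert (s.pixels[0] == BACKGROUND).all()
        assert (s.pixels[:, -1] == BACKGROUND).all()
        assert sketch_density(s) == 1.0

    def test_checkerboard_single_pattern_retains_two(self, checkerboard4):
        dist = extract_patch_distribution([checkerboard4])
        code = int(np.nonzero(dist.counts)[0][0])
        fs = FeatureSet(
            codes=(code,), probs=(0.5,), N=1, W=0.5, total_prob=0.5,
            entropy_bits=0.5,
        )
        s = generate_sketch(checkerboard4, fs)
        assert s.retained_count == 2
        assert sketch_density(s) == 0.5

    def test_density_undefined_without_centers(self):
        from fastvision.sketch import Sketch

        s = Sketch(np.full((2, 5), BACKGROUND, dtype=np.int8))
        with pytest.raises(ValueError):
            sketch_density(s)
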