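import numpy as np
import pytest

from rflkit.formats import CountMatrix, CoverageTrack, ParameterError
from rflkit.rnaseq_mito import (
    CleavageParams,
    contrast_cluster,
    detect_cleavage,
    normalize_coverage,
    pca_samples,
    size_factors,
    tpm,
)
from rflkit.synthetic_data import simulate_counts, simulate_coverage

from oracles import size_factors_formula, tpm_formula


def _cm(counts, lengths=None, samples=None):
    counts = np.asarray(counts, dtype=float)
    n, m = counts.shape
    return CountMatrix(
        transcript_ids=[f"t{i}" for i in range(n)],
        sample_ids=samples or [f"s{j}" for j in range(m)],
        counts=counts,
        lengths=np.asarray(lengths if lengths is not None else [100.0] * n),
    )


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        cm = _cm([[10, 10], [20, 20], [5, 5]])
        f = size_factors(cm)
        assert f["s0"] == pytest.approx(1.0) and f["s1"] == pytest.approx(1.0)

    def test_doubled_sample_factor_ratio_two(self):
        cm = _cm([[10, 20], [30, 60], [7, 14]])
        f = size_factors(cm)
        assert f["s1"] / f["s0"] == pytest.approx(2.0)

    def test_random_matrices_match_formula_oracle(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 1000, size=(30, 5)).astype(float)
            cm = _cm(counts)
            ours = size_factors(cm)
            ref = size_factors_formula(counts, cm.sample_ids)
            for s in cm.sample_ids:
                assert ours[s] == pytest.approx(ref[s], rel=1e-9)

    def test_all_zero_gene_handling(self):
        cm = _cm([[0, 0], [10, 20]])
        f = size_factors(cm)   # the zero gene is excluded, not fatal
        assert f["s1"] / f["s0"] == pytest.approx(2.0)

    def test_no_all_positive_gene_errors(self):
        with pytest.raises(ParameterError):
            size_factors(_cm([[0, 1], [1, 0]]))

    def test_single_sample_rejected(self):
        with pytest.raises(ParameterError):
            size_factors(_cm([[1.0], [2.0]]))


class TestTpm:
    def test_single_transcript_is_one_million(self):
        t = tpm(_cm([[50, 10]]))
        assert np.allclose(t, 1e6)

    def test_length_normalisation_ratio(self):
        t = tpm(_cm([[30, 30], [30, 30]], lengths=[1000, 2000]))
        assert t[0, 0] == pytest.approx(2e6 / 3)
        assert t[1, 0] == pytest.approx(1e6 / 3)

    def test_columns_sum_to_one_million(self, rng):
        counts = rng.integers(0, 500, size=(40, 6)).astype(float)
        counts[0] += 1  # avoid an all-zero column
        cm = _cm(counts, lengths=rng.integers(200, 3000, 40).astype(float))
        t = tpm(cm)
        assert np.allclose(t.sum(axis=0), 1e6, atol=1e-6)
        assert np.allclose(t, tpm_formula(cm.counts, cm.lengths), rtol=1e-9)


class TestContrastCluster:
    def test_equal_counts_give_zero_ratios(self):
        cm = _cm(np.full((5, 4), 20.0))
        ids, ratios, labels = contrast_cluster(
            cm, [("s0", "s1", "early"), ("s2", "s3", "mid")])
        assert np.allclose(ratios, 0.0)
        assert labels == ["early", "mid"]

    def test_planted_blocks_are_contiguous(self):
        # strong planted blocks (the suppressed CMS-ORF pattern is
        # near-silencing, well beyond 2-fold)
        cm, truth = simulate_counts(n_genes=40, effect_size=6.0, seed=4)
        contrasts = [(f"fertile_{i}", f"sterile_{i}", f"st{i}")
                     for i in (1, 2, 3)]
        ids, ratios, _ = contrast_cluster(cm, contrasts)
        up = set(truth.planted["up_genes"])
        down = set(truth.planted["down_genes"])
        pos_up = sorted(ids.index(g) for g in up)
        pos_down = sorted(ids.index(g) for g in down)
        assert pos_up[-1] - pos_up[0] == len(up) - 1
        assert pos_down[-1] - pos_down[0] == len(down) - 1

    def test_row_permutation_invariance(self, rng):
        cm, _ = simulate_counts(n_genes=30, seed=8)
        contrasts = [(f"fertile_{i}", f"sterile_{i}", f"st{i}") for i in (1, 2)]
        ids1, ratios1, _ = contrast_cluster(cm, contrasts)
        perm = rng.permutation(30)
        cm2 = CountMatrix(
            transcript_ids=[cm.transcript_ids[i] for i in perm],
            sample_ids=cm.sample_ids,
            counts=cm.counts[perm],
            lengths=cm.lengths[perm],
        )
        ids2, ratios2, _ = contrast_cluster(cm2, contrasts)
        m1 = dict(zip(ids1, map(tuple, np.round(ratios1, 9))))
        m2 = dict(zip(ids2, map(tuple, np.round(ratios2, 9))))
        assert m1 == m2

    def test_missing_sample_rejected(self):
        cm = _cm(np.full((5, 2), 10.0))
        with pytest.raises(ParameterError):
            contrast_cluster(cm, [("s0", "nope", "x")])


class TestPca:
    def test_planted_groups_separate_on_pc1(self):
        cm, truth = simulate_counts(n_genes=200, effect_size=4.0, seed=2)
        coords, fracs = pca_samples(cm)
        groups = truth.planted["groups"]
        fert = [coords[j, 0] for j, s in enumerate(cm.sample_ids)
                if groups[s] == "fertile"]
        ster = [coords[j, 0] for j, s in enumerate(cm.sample_ids)
                if groups[s] == "sterile"]
        assert max(fert) < min(ster) or max(ster) < min(fert)
        assert fracs[0] > 0.5

    def test_duplicated_sample_coincides(self):
        counts = np.array([[10, 10, 50], [40, 40, 5], [7, 7, 30]], dtype=float)
        cm = _cm(counts)
        coords, _ = pca_samples(cm)
        assert np.allclose(coords[0], coords[1], atol=1e-9)

    def test_variance_fractions_monotone_and_bounded(self, rng):
        counts = rng.integers(1, 300, size=(30, 6)).astype(float)
        _, fracs = pca_samples(_cm(counts))
        assert np.all(np.diff(fracs) <= 1e-12)
        assert fracs.sum() <= 1.0 + 1e-9


class TestNormalizeCoverage:
    def test_constant_depth(self):
        t = CoverageTrack(ref_id="m", strand="+", depth=np.full(10, 8.0))
        n = normalize_coverage(t)
        assert np.allclose(n.depth, 1.0) and n.normalised
        assert n.norm_mean == pytest.approx(8.0)

    def test_half_and_half(self):
        t = CoverageTrack(ref_id="m", strand="+",
                          depth=np.array([10.0] * 5 + [0.0] * 5))
        n = normalize_coverage(t)
        assert np.allclose(n.depth[:5], 2.0) and np.allclose(n.depth[5:], 0.0)

    def test_masked_block_excluded_from_scaling(self):
        depth = np.array([4.0] * 50 + [400.0] * 10 + [4.0] * 40)
        t = CoverageTrack(ref_id="m", strand="+", depth=depth,
                          masks=[(50, 60)])
        n = normalize_coverage(t)
        assert np.allclose(n.depth[:50], 1.0)
        # unit mean over unmasked positions
        assert n.depth[n.unmasked()].mean() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self):
        t = CoverageTrack(ref_id="m", strand="+", depth=np.arange(1.0, 11.0))
        once = normalize_coverage(t)
        twice = normalize_coverage(once)
        assert np.array_equal(once.depth, twice.depth)

    def test_all_masked_rejected(self):
        t = CoverageTrack(ref_id="m", strand="+", depth=np.ones(5),
                          masks=[(0, 5)])
        with pytest.raises(ParameterError):
            normalize_coverage(t)


class TestDetectCleavage:
    def test_flat_equal_tracks_fail(self, rng):
        depth = rng.poisson(100, 2000).astype(float)
        f = normalize_coverage(CoverageTrack("m", "+", depth.copy()))
        s = normalize_coverage(CoverageTrack("m", "+",
                                             rng.poisson(100, 2000).astype(float)))
        call = detect_cleavage(f, s, CleavageParams())
        assert not call.passed

    def test_planted_transition_recovered(self):
        tracks, truth = simulate_coverage(ref_len=4000, cleavage_pos=2000,
                                          seed=3)
        fert, ster = tracks["restored"]
        call = detect_cleavage(normalize_coverage(fert),
                               normalize_coverage(ster), CleavageParams())
        assert call.passed
        assert abs(call.position - 2000) <= 2

    def test_reverse_strand_position_mapping(self):
        tracks, _ = simulate_coverage(ref_len=4000, cleavage_pos=1500,
                                      strand="-", seed=6)
        fert, ster = tracks["restored"]
        call = detect_cleavage(normalize_coverage(fert),
                               normalize_coverage(ster), CleavageParams(),
                               transcript_strand="-")
        assert call.passed and abs(call.position - 1500) <= 2

    def test_search_region_restricts_call(self):
        tracks, _ = simulate_coverage(ref_len=4000, cleavage_pos=2000, seed=3)
        fert, ster = tracks["restored"]
        params = CleavageParams(search_region=(1800, 2200))
        call = detect_cleavage(normalize_coverage(fert),
                               normalize_coverage(ster), params)
        assert 1800 <= call.position < 2200

    def test_low_sterile_depth_fails_gate(self):
        tracks, _ = simulate_coverage(ref_len=3000, cleavage_pos=1500,
                                      depth=4.0, seed=5)
        fert, ster = tracks["restored"]
        call = detect_cleavage(normalize_coverage(fert),
                               normalize_coverage(ster),
                               CleavageParams(min_depth=10))
        assert not call.passed

    def test_region_shorter_than_two_windows_rejected(self):
        t = normalize_coverage(CoverageTrack("m", "+", np.ones(200)))
        with pytest.raises(ParameterError):
            detect_cleavage(t, t, CleavageParams(window_w=50,
                                                 search_region=(10, 60)))

    def test_unnormalised_inputs_rejected(self):
        t = CoverageTrack("m", "+", np.ones(500))
        with pytest.raises(ParameterError):
            detect_cleavage(t, t, CleavageParams())
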