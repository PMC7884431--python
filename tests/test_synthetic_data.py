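import numpy as np
import pytest

from rflkit.orthocluster import align_identity
from rflkit.rnaseq_mito import CleavageParams, detect_cleavage, normalize_coverage
from rflkit.synthetic_data import (
    simulate_chimeric_genomes,
    simulate_counts,
    simulate_coverage,
    simulate_divergent_pair,
    simulate_ppr_target,
    simulate_rfl_panel,
)


class TestDeterminism:
    def test_rfl_panel_same_seed_identical(self):
        a = simulate_rfl_panel(seed=42)
        b = simulate_rfl_panel(seed=42)
        assert [(g.id, g.dna) for g in a[0]] == [(g.id, g.dna) for g in b[0]]
        assert a[2].planted == b[2].planted

    def test_chimeric_genomes_same_seed_identical(self):
        a = simulate_chimeric_genomes(base_len=8000, n_extra_orfs=1, seed=42)
        b = simulate_chimeric_genomes(base_len=8000, n_extra_orfs=1, seed=42)
        assert a[0].sequence == b[0].sequence
        assert a[3].planted == b[3].planted

    def test_coverage_and_counts_same_seed_identical(self):
        t1, _ = simulate_coverage(ref_len=500, cleavage_pos=250, seed=7)
        t2, _ = simulate_coverage(ref_len=500, cleavage_pos=250, seed=7)
        assert np.array_equal(t1["restored"][0].depth, t2["restored"][0].depth)
        c1, _ = simulate_counts(seed=7)
        c2, _ = simulate_counts(seed=7)
        assert np.array_equal(c1.counts, c2.counts)

    def test_different_seeds_differ(self):
        a = simulate_rfl_panel(seed=1)[0]
        b = simulate_rfl_panel(seed=2)[0]
        assert [g.dna for g in a] != [g.dna for g in b]


class TestRflPanel:
    def test_identity_structure(self):
        genes, _, truth = simulate_rfl_panel(n_families=3, seed=13)
        part = truth.planted["partition"]
        by_family = {}
        for g in genes:
            by_family.setdefault(part[g.id], []).append(g)
        fams = sorted(by_family)
        # within-family pairwise identity >= 97%
        f0 = [g for g in by_family[fams[0]] if len(g.protein) > 700]
        identity, _, _ = align_identity(f0[0].protein, f0[1].protein)
        assert identity >= 0.97
        # between-family identity <= 90%
        f1 = [g for g in by_family[fams[1]] if len(g.protein) > 700]
        identity, _, _ = align_identity(f0[0].protein, f1[0].protein)
        assert identity <= 0.90

    def test_specific_family_absent_or_partial_in_maintainers(self):
        genes, panel, truth = simulate_rfl_panel(seed=21)
        part = truth.planted["partition"]
        fam = truth.planted["restorer_specific_family"]
        restorers = set(panel.restorers(truth.planted["mode"]))
        for g in genes:
            if part[g.id] == fam and g.genotype not in restorers:
                assert len(g.protein) < 500
        for r in restorers:
            assert any(part[g.id] == fam and g.genotype == r and
                       len(g.protein) >= 500 for g in genes)

    def test_protein_sizes_match_study_conditions(self):
        genes, _, truth = simulate_rfl_panel(seed=2)
        counts = truth.planted["motif_counts"]
        for g in genes:
            if g.id in counts and len(g.protein) >= 500:
                assert 741 <= len(g.protein) <= 790
                assert 17 <= counts[g.id] <= 20

    def test_invalid_identity_bounds_rejected(self):
        with pytest.raises(ValueError):
            simulate_rfl_panel(within_id=0.9, between_id=0.95)


class TestChimericGenomes:
    def test_genomes_identical_outside_plants(self):
        ga, gb, _, truth = simulate_chimeric_genomes(
            base_len=8000, n_extra_orfs=0, seed=3)
        u0, u1 = truth.planted["unique_interval"]
        # upstream of the chimera start the genomes agree
        assert ga.sequence[:u0 - 3 * 96] == gb.sequence[:u0 - 3 * 96]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_chimeric_genomes(unique_len_nt=100)  # not codon-aligned
        with pytest.raises(ValueError):
            simulate_chimeric_genomes(prefix_codons=200, donor_codons=150)
        with pytest.raises(ValueError):
            simulate_chimeric_genomes(base_len=4000, n_extra_orfs=9)

    def test_truth_codon_arithmetic(self):
        _, _, _, truth = simulate_chimeric_genomes(base_len=8000,
                                                   n_extra_orfs=0, seed=1)
        p = truth.planted
        assert p["chimera_codons"] == p["prefix_codons"] + \
            p["unique_len_nt"] // 3 - 1
        s, e = p["chimera_orf"]
        assert (e - s) // 3 == p["chimera_codons"]


class TestPprTarget:
    def test_site_is_argmax_of_planted_pairs(self, code_table):
        from oracles import argmax_window

        _, tx, truth = simulate_ppr_target(seed=5, table=code_table)
        pairs = [tuple(p) for p in truth.planted["pairs"]]
        best_start, _ = argmax_window(pairs, tx.sequence, code_table)
        assert best_start == truth.planted["site"][0]

    def test_protein_carries_planted_pairs(self, code_table, models):
        from rflkit.ppr_annotate import annotate_protein, extract_code_pairs

        prot, _, truth = simulate_ppr_target(seed=8, table=code_table)
        gene = annotate_protein("p", "g", prot.sequence, models=models)
        pairs = extract_code_pairs(gene.architecture, prot.sequence)
        assert pairs == [tuple(p) for p in truth.planted["pairs"]]


class TestCoverageAndCounts:
    def test_fold_one_gives_no_call(self):
        tracks, _ = simulate_coverage(ref_len=3000, cleavage_pos=1500,
                                      fold=1.0, seed=2)
        fert, ster = tracks["restored"]
        call = detect_cleavage(normalize_coverage(fert),
                               normalize_coverage(ster),
                               CleavageParams(min_fold=3.0))
        assert not call.passed

    def test_masked_rrna_block_overcovered(self):
        tracks, _ = simulate_coverage(ref_len=2000, cleavage_pos=1000,
                                      masks=[(100, 200)], seed=4)
        fert, _ = tracks["restored"]
        assert fert.depth[100:200].mean() > 10 * fert.depth[1500:].mean()

    def test_zero_effect_ratios_centred(self):
        cm, truth = simulate_counts(n_genes=300, effect_size=1.0, seed=9)
        fert = cm.counts[:, :3].mean(axis=1)
        ster = cm.counts[:, 3:].mean(axis=1)
        ratios = np.log2((fert + 0.5) / (ster + 0.5))
        assert abs(np.median(ratios)) < 0.15

    def test_library_multipliers_recovered_at_scale(self):
        from rflkit.rnaseq_mito import size_factors

        cm, truth = simulate_counts(n_genes=500, seed=12)
        sf = size_factors(cm)
        lib = truth.planted["lib_multipliers"]
        for s in cm.sample_ids:
            assert abs(sf[s] / lib[s] - 1.0) < 0.05


class TestDivergentPair:
    def test_planted_divergences_measured(self):
        a, b, truth = simulate_divergent_pair(seed=3)
        identity_p, _, _ = align_identity(a.protein, b.protein)
        identity_d, _, _ = align_identity(a.dna, b.dna, alphabet="dna")
        assert identity_p == pytest.approx(truth.planted["protein_identity"],
                                           abs=0.01)
        assert identity_d == pytest.approx(truth.planted["dna_identity"],
                                           abs=0.01)

    def test_code_pair_differences_planted(self, models):
        from rflkit.ppr_annotate import annotate_protein, extract_code_pairs

        a, b, truth = simulate_divergent_pair(seed=6)
        pa = extract_code_pairs(
            annotate_protein("a", "g", a.protein, models=models).architecture,
            a.protein)
        pb = extract_code_pairs(
            annotate_protein("b", "g", b.protein, models=models).architecture,
            b.protein)
        assert len(pa) == len(pb) == truth.planted["n_motifs"]
        diffs = sum(1 for x, y in zip(pa, pb) if x != y)
        assert diffs == truth.planted["pair_diff_motifs"]
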