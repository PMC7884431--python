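import pytest

from rflkit.formats import ParameterError, SeqRecord
from rflkit.orthocluster import Orthogroup
from rflkit.rf_select import (
    GenotypePanel,
    GenotypePhenotype,
    IntervalConstraint,
    flag_frameshift_pairs,
    place_in_interval,
    read_panel,
    select_candidates,
)
from rflkit.synthetic_data import simulate_rfl_panel

from conftest import random_dna


def _panel(restorers, maintainers, timo=()):
    phen = {}
    for g in restorers:
        phen[g] = GenotypePhenotype(carries_Rf1=True, is_timopheevii=g in timo)
    for g in maintainers:
        phen[g] = GenotypePhenotype(maintainer=True, is_timopheevii=g in timo)
    return GenotypePanel(genotypes=list(phen), phenotype=phen)


def _group(gid, members):
    return Orthogroup(group_id=gid, representative=members[0][1],
                      members=members)


class TestPlaceInInterval:
    def _contigs(self, rng):
        seq = random_dna(rng, 6000)
        rec = SeqRecord(id="scaffold1", sequence=seq, alphabet="dna")
        return seq, [(rec, "chr1A", 1_000_000)]

    def test_gene_inside_interval(self, rng):
        seq, contigs = self._contigs(rng)
        gene = SeqRecord(id="g", sequence=seq[1000:1800], alphabet="dna")
        interval = IntervalConstraint("chr1A", 1_000_500, 1_003_000)
        assert place_in_interval(gene, contigs, interval) == "in"

    def test_gene_downstream_of_interval(self, rng):
        seq, contigs = self._contigs(rng)
        gene = SeqRecord(id="g", sequence=seq[4000:4800], alphabet="dna")
        interval = IntervalConstraint("chr1A", 1_000_000, 1_002_000)
        assert place_in_interval(gene, contigs, interval) == "out"

    def test_duplicated_gene_is_unknown(self, rng):
        gene_seq = random_dna(rng, 600)
        backbone = random_dna(rng, 2000)
        seq = backbone[:500] + gene_seq + backbone[500:1500] + gene_seq \
            + backbone[1500:]
        # two identical loci 1+ kb apart on different chromosomes
        recs = [
            (SeqRecord(id="c1", sequence=seq[:1200], alphabet="dna"), "chr1A", 0),
            (SeqRecord(id="c2", sequence=seq[1200:], alphabet="dna"), "chr1B", 0),
        ]
        gene = SeqRecord(id="g", sequence=gene_seq, alphabet="dna")
        interval = IntervalConstraint("chr1A", 0, 2000)
        assert place_in_interval(gene, recs, interval) == "unknown"

    def test_empty_reference_unknown(self, rng):
        gene = SeqRecord(id="g", sequence=random_dna(rng, 300), alphabet="dna")
        interval = IntervalConstraint("chr1A", 0, 100)
        assert place_in_interval(gene, [], interval) == "unknown"

    def test_low_identity_unknown(self, rng):
        seq, contigs = self._contigs(rng)
        gene = SeqRecord(id="g", sequence=random_dna(rng, 800), alphabet="dna")
        interval = IntervalConstraint("chr1A", 1_000_000, 1_006_000)
        assert place_in_interval(gene, contigs, interval) == "unknown"


class TestSelectCandidates:
    def test_minimal_candidate_passes_all_rules(self):
        panel = _panel(["A", "B", "T"], ["C"], timo=["T"])
        g1 = _group("g1", [("A", "A.x", "full_length"),
                           ("B", "B.x", "full_length"),
                           ("T", "T.x", "full_length")])
        reports = select_candidates([g1], panel, {"g1": "in"}, mode="Rf1")
        assert reports[0].verdict == "candidate"
        assert all(reports[0].rule_results.values())

    def test_full_length_in_maintainer_rejects(self):
        panel = _panel(["A", "B", "T"], ["C"], timo=["T"])
        g1 = _group("g1", [("A", "A.x", "full_length"),
                           ("B", "B.x", "full_length"),
                           ("T", "T.x", "full_length"),
                           ("C", "C.x", "full_length")])
        r = select_candidates([g1], panel, {"g1": "in"}, mode="Rf1")[0]
        assert r.verdict == "rejected"
        assert not r.rule_results["nonrestorer_absent"]

    def test_published_screen_outcome(self):
        """Four groups pass presence+interval; the two frameshift-split,
        sub-500-codon groups fail the length rule, leaving two candidates."""
        panel = _panel(["R197", "R0932E", "R0934F", "Ttimo"], ["Anapurna"],
                       timo=["Ttimo"])
        restorers = ["R197", "R0932E", "R0934F", "Ttimo"]
        groups, placements = [], {}
        for gid, status in [("79", "full_length"), ("104", "full_length"),
                            ("185", "partial"), ("268", "partial")]:
            groups.append(_group(gid, [(g, f"{g}.{gid}", status)
                                       for g in restorers]))
            placements[gid] = "in"
        reports = select_candidates(groups, panel, placements, mode="Rf1")
        verdicts = {r.group_id: r.verdict for r in reports}
        assert verdicts == {"79": "candidate", "104": "candidate",
                            "185": "rejected", "268": "rejected"}
        by_id = {r.group_id: r for r in reports}
        for gid in ("185", "268"):
            assert by_id[gid].rule_results["restorer_present"]
            assert by_id[gid].rule_results["in_interval"]
            assert not by_id[gid].rule_results["length_ok"]

    def test_rf1_requires_timopheevii_member(self):
        panel = _panel(["A", "T"], ["C"], timo=["T"])
        g1 = _group("g1", [("A", "A.x", "full_length")])
        r = select_candidates([g1], panel, {"g1": "in"}, mode="Rf1")[0]
        assert not r.rule_results["provenance_ok"]

    def test_rf3_identical_timopheevii_member_disqualifies(self):
        phen = {
            "P": GenotypePhenotype(carries_Rf3=True),
            "T": GenotypePhenotype(is_timopheevii=True),
            "C": GenotypePhenotype(maintainer=True),
        }
        panel = GenotypePanel(genotypes=list(phen), phenotype=phen)
        g1 = _group("g1", [("P", "P.x", "full_length"),
                           ("T", "T.x", "full_length")])
        seqs_same = {"P.x": "ATGAAACCC", "T.x": "ATGAAACCC"}
        seqs_near = {"P.x": "ATGAAACCC", "T.x": "ATGAAACCG"}
        r_same = select_candidates([g1], panel, {"g1": "in"}, mode="Rf3",
                                   sequences=seqs_same)[0]
        r_near = select_candidates([g1], panel, {"g1": "in"}, mode="Rf3",
                                   sequences=seqs_near)[0]
        assert not r_same.rule_results["provenance_ok"]
        assert r_near.rule_results["provenance_ok"]

    def test_missing_genotype_raises(self):
        panel = _panel(["A"], ["C"])
        g1 = _group("g1", [("Z", "Z.x", "full_length")])
        with pytest.raises(ParameterError):
            select_candidates([g1], panel, {"g1": "in"}, mode="Rf1")

    def test_monotone_in_maintainer_members(self):
        """Adding a full-length member in a maintainer never turns a
        rejected group into a candidate."""
        panel = _panel(["A", "T"], ["C"], timo=["T"])
        for members in (
            [("A", "A.x", "full_length")],
            [("A", "A.x", "partial"), ("T", "T.x", "full_length")],
            [("A", "A.x", "full_length"), ("T", "T.x", "full_length")],
        ):
            before = select_candidates([_group("g", members)], panel,
                                       {"g": "in"}, mode="Rf1")[0].verdict
            after = select_candidates(
                [_group("g", members + [("C", "C.x", "full_length")])],
                panel, {"g": "in"}, mode="Rf1")[0].verdict
            assert not (before == "rejected" and after == "candidate")

    def test_verdict_is_pure_function_of_rules(self):
        panel = _panel(["A", "T"], ["C"], timo=["T"])
        g1 = _group("g1", [("A", "A.x", "full_length"),
                           ("T", "T.x", "full_length")])
        for placement in ("in", "out", "unknown"):
            r = select_candidates([g1], panel, {"g1": placement}, mode="Rf1")[0]
            assert (r.verdict == "candidate") == all(r.rule_results.values())


class TestFrameshiftPairs:
    def test_nearby_partials_flagged(self):
        groups = [
            _group("g1", [("A", "a1", "partial")]),
            _group("g2", [("A", "a2", "partial")]),
        ]
        coords = {"a1": ("c1", 0, 1000, "+"), "a2": ("c1", 1200, 2200, "+")}
        assert flag_frameshift_pairs(groups, coords) == [(("g1", "g2"), "c1")]

    def test_different_contigs_not_flagged(self):
        groups = [
            _group("g1", [("A", "a1", "partial")]),
            _group("g2", [("A", "a2", "partial")]),
        ]
        coords = {"a1": ("c1", 0, 1000, "+"), "a2": ("c2", 1200, 2200, "+")}
        assert flag_frameshift_pairs(groups, coords) == []

    def test_opposite_strands_not_flagged(self):
        groups = [
            _group("g1", [("A", "a1", "partial")]),
            _group("g2", [("A", "a2", "partial")]),
        ]
        coords = {"a1": ("c1", 0, 1000, "+"), "a2": ("c1", 1200, 2200, "-")}
        assert flag_frameshift_pairs(groups, coords) == []

    def test_generator_split_gene_recovered(self):
        from rflkit.orthocluster import greedy_cluster

        genes, _, truth = simulate_rfl_panel(
            n_families=3, frameshift_family=2, seed=7)
        coords = {k: tuple(v)
                  for k, v in truth.planted["frameshift_coords"].items()}

        class _G:
            def __init__(self, g):
                self.id, self.protein = g.id, g.protein
                self.genotype, self.status = g.genotype, (
                    "partial" if len(g.protein) < 500 else "full_length")

        groups = greedy_cluster([_G(g) for g in genes])
        flagged = flag_frameshift_pairs(groups, coords)
        assert flagged, "split-gene halves were not flagged"


class TestPanelIO:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "genotype\tcarries_Rf1\tcarries_Rf3\tmaintainer\tis_timopheevii\n"
            "R197\t1\t0\t0\t0\nAnapurna\t0\t0\t1\t0\nTtimo\t1\t0\t0\t1\n"
        )
        panel = read_panel(p)
        assert panel.restorers("Rf1") == ["R197", "Ttimo"]
        assert panel.timopheevii() == ["Ttimo"]

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("geno\tother\n")
        with pytest.raises(ParameterError):
            read_panel(p)
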