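"""Restorer-candidate selection over orthogroups and genotype panels.

A restorer gene candidate is an orthogroup whose full-length, putatively
functional members segregate with the restoration phenotype: present in
the restorer genotypes, absent from (or only partial in) the maintainer
genotypes, located inside the genetically mapped interval, and with the
provenance expected for the gene (an Rf1-type candidate group should
contain a Triticum timopheevii representative; an Rf3-type group should
not contain a T. timopheevii member identical to a restorer member).

Five named rule booleans are reported per group:

* ``restorer_present`` -- the restorer genotypes contain a member of the
  group (all of them by default; any-restorer relaxation available);
* ``nonrestorer_absent`` -- no non-restorer genotype holds a full-length
  member;
* ``in_interval`` -- the group places inside the mapped interval;
* ``provenance_ok`` -- the T. timopheevii origin rule for the mode;
* ``length_ok`` -- at least one restorer member is full-length (partial,
  <500-aa proteins are considered unlikely to be functional).

The verdict is ``candidate`` iff all five hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import infix_similarity
from .formats import ParameterError, reverse_complement

__all__ = [
    "GenotypePhenotype",
    "GenotypePanel",
    "IntervalConstraint",
    "CandidateReport",
    "read_panel",
    "place_in_interval",
    "select_candidates",
    "flag_frameshift_pairs",
]

RULE_NAMES = (
    "restorer_present",
    "nonrestorer_absent",
    "in_interval",
    "provenance_ok",
    "length_ok",
)


@dataclass
class GenotypePhenotype:
    carries_Rf1: bool = False
    carries_Rf3: bool = False
    maintainer: bool = False
    is_timopheevii: bool = False


@dataclass
class GenotypePanel:
    genotypes: list[str]
    phenotype: dict[str, GenotypePhenotype]

    def restorers(self, mode: str) -> list[str]:
        key = f"carries_{mode}"
        return [g for g in self.genotypes if getattr(self.phenotype[g], key)]

    def non_restorers(self, mode: str) -> list[str]:
        key = f"carries_{mode}"
        return [g for g in self.genotypes if not getattr(self.phenotype[g], key)]

    def timopheevii(self) -> list[str]:
        return [g for g in self.genotypes if self.phenotype[g].is_timopheevii]


@dataclass
class IntervalConstraint:
    chrom: str
    start: int
    end: int
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParameterError("interval start must be < end")


@dataclass
class CandidateReport:
    group_id: str
    rule_results: dict[str, bool]
    verdict: str
    reasons: list[str] = field(default_factory=list)


_TRUE = {"1", "true", "yes", "y", "t"}


def read_panel(path) -> GenotypePanel:
    """Read a panel TSV: genotype, carries_Rf1, carries_Rf3, maintainer,
    is_timopheevii (header required)."""
    genotypes: list[str] = []
    phen: dict[str, GenotypePhenotype] = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        expected = ["genotype", "carries_Rf1", "carries_Rf3", "maintainer",
                    "is_timopheevii"]
        if header != expected:
            raise ParameterError(f"panel header must be {expected}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            g, rf1, rf3, maint, timo = line.split("\t")
            genotypes.append(g)
            phen[g] = GenotypePhenotype(
                carries_Rf1=rf1.lower() in _TRUE,
                carries_Rf3=rf3.lower() in _TRUE,
                maintainer=maint.lower() in _TRUE,
                is_timopheevii=timo.lower() in _TRUE,
            )
    return GenotypePanel(genotypes=genotypes, phenotype=phen)


def place_in_interval(gene_dna, reference_contigs, interval: IntervalConstraint,
                      min_identity: float = 0.90, ambiguity_margin: float = 0.01,
                      locus_window: int = 10_000) -> str:
    """Locate a gene on anchored reference contigs and test the interval.

    ``reference_contigs`` is a list of (SeqRecord, chrom, absolute_offset)
    triples.  Both strands are searched with a full-query infix alignment;
    the placement is the midpoint of the best hit.  Returns "in", "out",
    or "unknown" (best identity below ``min_identity``, or a second hit at
    a different locus scoring within ``ambiguity_margin`` of the best).
    """
    if not reference_contigs:
        return "unknown"
    query = gene_dna.sequence
    hits = []  # (similarity, chrom, abs_midpoint)
    for rec, chrom, offset in reference_contigs:
        for q in (query, reverse_complement(query)):
            sim, s, e = infix_similarity(q, rec.sequence)
            if sim > 0:
                hits.append((sim, chrom, offset + (s + e) // 2))
    if not hits:
        return "unknown"
    hits.sort(reverse=True)
    best = hits[0]
    if best[0] < min_identity:
        return "unknown"
    for sim, chrom, mid in hits[1:]:
        same_locus = chrom == best[1] and abs(mid - best[2]) <= locus_window
        if not same_locus and best[0] - sim <= ambiguity_margin:
            return "unknown"
    inside = best[1] == interval.chrom and interval.start <= best[2] < interval.end
    return "in" if inside else "out"


def _identical_full_shorter(a: str, b: str) -> bool:
    """100% identity over the full length of the shorter sequence."""
    if not a or not b:
        return False
    return a in b if len(a) <= len(b) else b in a


def select_candidates(groups, panel: GenotypePanel, placements: dict,
                      mode: str, full_length_min_aa: int = 500,
                      require_all_restorers: bool = True,
                      sequences: dict | None = None) -> list[CandidateReport]:
    """Apply the five selection rules to every orthogroup.

    ``placements`` maps group_id -> "in"/"out"/"unknown"; ``sequences``
    (gene id -> dna or protein string) is needed for the Rf3 identity-by-
    descent provenance rule and may be omitted, in which case a
    T. timopheevii member never disqualifies a group (near-identical
    members do not disqualify by design).
    """
    if mode not in ("Rf1", "Rf3"):
        raise ParameterError("mode must be 'Rf1' or 'Rf3'")
    restorers = set(panel.restorers(mode))
    non_restorers = set(panel.non_restorers(mode))
    timo = set(panel.timopheevii())
    reports = []
    for group in groups:
        for g, _, _ in group.members:
            if g not in panel.phenotype:
                raise ParameterError(
                    f"genotype {g!r} in group {group.group_id} missing from panel"
                )
        by_geno = group.statuses_by_genotype()
        present = {g for g in by_geno}
        fl_genotypes = {g for g, sts in by_geno.items() if "full_length" in sts}

        if require_all_restorers:
            restorer_present = restorers <= present
        else:
            restorer_present = bool(restorers & present)
        nonrestorer_absent = not (fl_genotypes & non_restorers)
        in_interval = placements.get(group.group_id, "unknown") == "in"
        length_ok = bool(fl_genotypes & restorers)

        if mode == "Rf1":
            provenance_ok = bool(present & timo)
        else:
            provenance_ok = True
            if sequences is not None:
                timo_seqs = [sequences[i] for g, i, _ in group.members
                             if g in timo and i in sequences]
                rest_seqs = [sequences[i] for g, i, _ in group.members
                             if g in restorers and i in sequences]
                for ts in timo_seqs:
                    if any(_identical_full_shorter(ts, rs) for rs in rest_seqs):
                        provenance_ok = False
                        break

        rules = {
            "restorer_present": restorer_present,
            "nonrestorer_absent": nonrestorer_absent,
            "in_interval": in_interval,
            "provenance_ok": provenance_ok,
            "length_ok": length_ok,
        }
        verdict = "candidate" if all(rules.values()) else "rejected"
        reasons = [name for name, ok in rules.items() if not ok]
        reports.append(CandidateReport(group_id=group.group_id,
                                       rule_results=rules,
                                       verdict=verdict,
                                       reasons=reasons))
    return reports


def flag_frameshift_pairs(groups, contig_coords: dict,
                          max_gap: int = 1000) -> list[tuple[tuple[str, str], str]]:
    """Pairs of partial RFL genes that look like one frameshift-split gene.

    ``contig_coords`` maps gene id -> (contig, start, end, strand).  Two
    partial members of *different* groups lying on the same contig, on the
    same strand and within ``max_gap`` bp are flagged together with the
    contig name.
    """
    partials = []
    for group in groups:
        for _, gene_id, status in group.members:
            if status in ("partial", "frameshifted") and gene_id in contig_coords:
                contig, s, e, strand = contig_coords[gene_id]
                partials.append((group.group_id, gene_id, contig, s, e, strand))
    flagged = []
    seen = set()
    for i in range(len(partials)):
        for j in range(i + 1, len(partials)):
            ga, _, ca, sa, ea, stra = partials[i]
            gb, _, cb, sb, eb, strb = partials[j]
            if ga == gb or ca != cb or stra != strb:
                continue
            gap = max(sa, sb) - min(ea, eb)
            if gap <= max_gap:
                key = (tuple(sorted((ga, gb))), ca)
                if key not in seen:
                    seen.add(key)
                    flagged.append((tuple(sorted((ga, gb))), ca))
    return flagged
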