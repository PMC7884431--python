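"""Mitochondrial genome comparison: lineage-specific regions, ORFs and
chimeric-ORF annotation.

Cytoplasmic-male-sterility determinants are typically chimeric
mitochondrial ORFs fusing the 5' part of a conserved gene (here an
atp8-like donor) to a novel, often hydrophobic extension that exists in
only one lineage.  This module finds the regions of one genome absent
from another (k-mer screen with exact anchor refinement), decides which
ORFs are lineage-specific (no near-full-coverage match in the other
genome even when sub-fragments such as the donor prefix are shared), and
annotates a chimera against candidate donor CDSs by codon-exact
shared-prefix length.

Codon accounting: an ORF's ``codons`` excludes its stop codon, while the
unique region of a chimera is a genomic interval that normally contains
the stop.  Both tallies are reported: for a chimera with a 96-codon donor
prefix and a 552-nt unique region, the ORF is 279 codons (96 + 183
coding) and the unique region holds 184 codons (183 coding + stop).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from ._align import infix_similarity
from .formats import ParameterError, SeqRecord, reverse_complement
from .orf_scan import Orf

__all__ = [
    "UniqueRegionParams",
    "ChimeraAnnotation",
    "unique_regions",
    "species_specific_orfs",
    "annotate_chimera",
]


@dataclass
class UniqueRegionParams:
    mode: str = "anchor"      # anchor (precise boundaries) | kmer
    k: int = 31
    min_len: int = 50

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not (15 <= self.k <= 63):
            raise ParameterError("k must be odd and within [15, 63]")
        if self.mode not in ("kmer", "anchor"):
            raise ParameterError(f"unknown unique-region mode {self.mode!r}")

    @property
    def flank_trim(self) -> int:
        return self.k - 1


@dataclass
class ChimeraAnnotation:
    orf_id: str
    donor_gene: str | None
    shared_prefix_codons: int
    shared_5prime_flank_nt: int
    unique_region: tuple[int, int] | None   # genomic, 0-based half-open
    unique_nt: int
    unique_codons: int                      # codons (incl. stop) fully inside
    orf_codons: int                         # coding codons, stop excluded


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _absent_runs(a: str, bset: set[str], k: int):
    """Maximal runs of window starts in `a` whose k-mer is absent from b.

    Returns (s0, s1) inclusive start-coordinate runs.
    """
    runs = []
    run_start = None
    n_starts = len(a) - k + 1
    for j in range(n_starts):
        absent = a[j:j + k] not in bset
        if absent and run_start is None:
            run_start = j
        elif not absent and run_start is not None:
            runs.append((run_start, j - 1))
            run_start = None
    if run_start is not None:
        runs.append((run_start, n_starts - 1))
    return runs


def _merge_position_intervals(intervals, max_gap: int):
    merged = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _locate_unique(kmer: str, b: str, b_rc: str):
    """Position of `kmer` in b if it occurs exactly once (either strand)."""
    hits = []
    start = b.find(kmer)
    while start != -1:
        hits.append(("+", start))
        start = b.find(kmer, start + 1)
    start = b_rc.find(kmer)
    while start != -1:
        hits.append(("-", start))
        start = b_rc.find(kmer, start + 1)
    if len(hits) != 1:
        return None
    return hits[0]


def unique_regions(genome_a: SeqRecord, genome_b: SeqRecord,
                   params: UniqueRegionParams | None = None):
    """Intervals of genome_a absent from genome_b (either strand).

    k-mer mode marks every window of `a` whose k-mer is missing from `b`,
    merges nearby runs, trims k-1 flanking positions from each end and
    reports runs >= min_len.  Anchor mode refines each raw run by exact
    inward extension of the flanking matches, recovering planted insert
    boundaries exactly; anchors that are not unique in `b` fall back to
    the k-mer boundaries with a warning.
    """
    params = params or UniqueRegionParams()
    k = params.k
    a, b = genome_a.sequence, genome_b.sequence
    if len(a) < k or len(b) < k:
        raise ParameterError("genomes must be at least k long")
    b_rc = reverse_complement(b)
    bset = _kmer_set(b, k) | _kmer_set(b_rc, k)
    start_runs = _absent_runs(a, bset, k)
    # start-coordinate runs -> raw position intervals
    raw = _merge_position_intervals(
        [(s0, s1 + k) for s0, s1 in start_runs], max_gap=k
    )
    out = []
    for rs, re_ in raw:
        if params.mode == "kmer":
            s, e = rs + params.flank_trim, re_ - params.flank_trim
        else:
            s, e = _anchor_refine(a, b, b_rc, rs, re_, k, params.flank_trim)
        if e - s >= params.min_len:
            out.append((s, e))
    return out


def _anchor_refine(a, b, b_rc, rs, re_, k, flank_trim):
    """Exact insert boundaries from inward extension of flanking anchors."""
    # defaults: the k-mer-mode trimmed boundaries
    s_fallback, e_fallback = rs + flank_trim, re_ - flank_trim
    s_out, e_out = s_fallback, e_fallback

    if rs >= 1:
        anchor = a[rs - 1:rs - 1 + k]
        loc = _locate_unique(anchor, b, b_rc)
        if loc is None:
            warnings.warn("left anchor not unique in reference; "
                          "using k-mer boundary", stacklevel=2)
        else:
            strand, q = loc
            ref = b if strand == "+" else b_rc
            i = 0
            while (rs - 1 + k + i < len(a) and q + k + i < len(ref)
                   and a[rs - 1 + k + i] == ref[q + k + i]):
                i += 1
            s_out = rs - 1 + k + i
    if re_ <= len(a) - k:
        j0 = re_ - k  # last absent window start; the next start is present
        anchor = a[j0 + 1:j0 + 1 + k]
        loc = _locate_unique(anchor, b, b_rc)
        if loc is None:
            warnings.warn("right anchor not unique in reference; "
                          "using k-mer boundary", stacklevel=2)
        else:
            strand, r = loc
            ref = b if strand == "+" else b_rc
            j = 0
            while (j0 - j >= 0 and r - 1 - j >= 0
                   and a[j0 - j] == ref[r - 1 - j]):
                j += 1
            e_out = j0 + 1 - j
    return s_out, e_out


def species_specific_orfs(orfs, genome_a: SeqRecord, genome_b: SeqRecord,
                          identity_t: float = 0.95, cover_t: float = 0.95):
    """ORFs of genome_a with no near-complete counterpart in genome_b.

    An ORF is specific iff no single placement of the whole ORF in
    genome_b (either strand) reaches ``identity_t * cover_t`` edit
    similarity -- a chimera whose donor prefix is shared but whose
    extension is not therefore stays specific.
    """
    threshold = identity_t * cover_t
    b_rc = reverse_complement(genome_b.sequence)
    specific = []
    for orf in orfs:
        nt = genome_a.sequence[orf.start:orf.end]
        sim_f, _, _ = infix_similarity(nt, genome_b.sequence)
        sim_r, _, _ = infix_similarity(nt, b_rc)
        if max(sim_f, sim_r) < threshold:
            specific.append(orf)
    return specific


def _codon_prefix_run(a_nt: str, b_nt: str) -> int:
    run = 0
    for i in range(0, min(len(a_nt), len(b_nt)) - 2, 3):
        if a_nt[i:i + 3] == b_nt[i:i + 3]:
            run += 1
        else:
            break
    return run


def _orf_gene_nt(orf: Orf, genome: SeqRecord, with_stop: bool) -> str:
    """ORF nucleotides 5'->3' in gene orientation, optionally with stop."""
    if orf.strand == "+":
        end = orf.end + (3 if with_stop and not orf.open_end else 0)
        return genome.sequence[orf.start:min(end, len(genome.sequence))]
    start = orf.start - (3 if with_stop and not orf.open_end else 0)
    return reverse_complement(genome.sequence[max(start, 0):orf.end])


def annotate_chimera(orf: Orf, donor_cds, genome: SeqRecord,
                     orf_flank5: str | None = None,
                     donor_flank5: str | None = None,
                     unique_intervals=None) -> ChimeraAnnotation:
    """Annotate a (putatively chimeric) ORF against candidate donor CDSs.

    The donor is the CDS sharing the longest run of identical leading
    codons with the ORF (ties to the longest CDS); if no CDS shares even
    the first codon the donor is None.  When 5' flanking sequences are
    supplied, the maximal identical upstream extension is reported.  The
    unique region is the genomic span of the ORF (plus its stop codon)
    downstream of the shared prefix, optionally intersected with
    ``unique_intervals`` from :func:`unique_regions`.
    """
    gene_nt = _orf_gene_nt(orf, genome, with_stop=False)
    best_run, best_donor, best_len = 0, None, -1
    for cds in donor_cds:
        run = _codon_prefix_run(gene_nt, cds.sequence)
        if run > best_run or (run == best_run > 0 and len(cds) > best_len):
            best_run, best_donor, best_len = run, cds.id, len(cds)

    flank_nt = 0
    if orf_flank5 and donor_flank5:
        n = min(len(orf_flank5), len(donor_flank5))
        while flank_nt < n and orf_flank5[-1 - flank_nt] == donor_flank5[-1 - flank_nt]:
            flank_nt += 1

    # genomic span of everything 3' of the shared prefix, stop included
    stop_nt = 0 if orf.open_end else 3
    if orf.strand == "+":
        u = (orf.start + 3 * best_run, orf.end + stop_nt)
    else:
        u = (orf.start - stop_nt, orf.end - 3 * best_run)
    if unique_intervals:
        best_overlap = None
        for s, e in unique_intervals:
            os_, oe = max(s, u[0]), min(e, u[1])
            if oe > os_ and (best_overlap is None
                             or oe - os_ > best_overlap[1] - best_overlap[0]):
                best_overlap = (os_, oe)
        u = best_overlap if best_overlap else u
    unique_nt = max(0, u[1] - u[0])

    # codons (stop included) whose genomic triplet lies fully inside u
    codon_starts = []
    if orf.strand == "+":
        codon_starts = list(range(orf.start, orf.end + stop_nt, 3))
        inside = [s for s in codon_starts if s >= u[0] and s + 3 <= u[1]]
    else:
        codon_starts = list(range(orf.end - 3, orf.start - stop_nt - 1, -3))
        inside = [s for s in codon_starts if s >= u[0] and s + 3 <= u[1]]
    unique_codons = len(inside)

    return ChimeraAnnotation(
        orf_id=orf.id,
        donor_gene=best_donor,
        shared_prefix_codons=best_run,
        shared_5prime_flank_nt=flank_nt,
        unique_region=u if unique_nt else None,
        unique_nt=unique_nt,
        unique_codons=unique_codons,
        orf_codons=orf.codons,
    )
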