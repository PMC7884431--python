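"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of (parameters, seed) and returns its
data together with a :class:`SyntheticTruth` sidecar describing what was
planted, so recovery can be checked exactly.  The defaults emulate the
study conditions of the wheat T-CMS restorer system:

* RFL capture panels: multi-genotype families of 741-790-codon proteins
  carrying 17-20 tandem 35-aa P-class PPR motifs, with within-family
  protein identity >= 97% and between-family identity <= 90%, one family
  full-length only in restorer genotypes;
* mitochondrial genome pairs differing by a chimeric ORF (96 donor codons
  + a 552-nt unique hydrophobic extension, i.e. a 279-codon reading
  frame) and by additional lineage-specific ORFs of > 100 codons;
* strand-specific coverage tracks with a sharp low -> high fertile/
  sterile transition at a planted cleavage position (~100x depth);
* negative-binomial count matrices with fertile/sterile block structure
  and planted library-size multipliers.

Sequences are generated with substitutions only by default so identity
arithmetic is exact; generators resample locally when a random draw
would violate its own contract (e.g. an accidental in-frame stop, an
incidental open reading frame crossing an insert junction, or a k-mer
collision that would blur a planted unique region).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .formats import CountMatrix, CoverageTrack, SeqRecord
from .orf_scan import CODON_MAP, OrfParams, find_orfs
from .ppr_annotate import AA_ORDER, MotifModel, _builtin_models
from .ppr_code import BASES, PprCodeTable, default_code_table
from .rf_select import GenotypePanel, GenotypePhenotype

__all__ = [
    "SyntheticTruth",
    "default_panel",
    "simulate_rfl_panel",
    "simulate_chimeric_genomes",
    "simulate_ppr_target",
    "simulate_coverage",
    "simulate_counts",
    "simulate_divergent_pair",
]

_NT = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in CODON_MAP.items():
    if _aa != "*":
        _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _v in _CODONS_BY_AA.values():
    _v.sort()

# codons for hydrophobic residues (F L I V M A W), the composition bias of
# CMS-associated ORF extensions
_HYDROPHOBIC_CODONS = sorted(
    c for aa in "FLIVMAW" for c in _CODONS_BY_AA[aa]
)


@dataclass
class SyntheticTruth:
    seed: int
    planted: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "planted": self.planted}, fh,
                      indent=1, sort_keys=True, default=_jsonable)
            fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def _random_dna(rng, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, n)])


def _random_codons(rng, n: int, pool=None, pool_frac: float = 0.5) -> str:
    """n random sense codons, optionally biased toward a codon pool.

    A pure pool draw would starve some shifted reading frames of stop
    codons, so pooled draws are mixed with uniform sense codons.
    """
    out = []
    while len(out) < n:
        if pool is not None and rng.random() < pool_frac:
            out.append(pool[rng.integers(0, len(pool))])
            continue
        c = _random_dna(rng, 3)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


def _reverse_translate(rng, protein: str) -> str:
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(0, len(_CODONS_BY_AA[aa]))]
        for aa in protein
    )


def translate_simple(dna: str) -> str:
    return "".join(CODON_MAP[dna[i:i + 3]] for i in range(0, len(dna) - 2, 3))


# ---------------------------------------------------------------------------
# RFL capture panel
# ---------------------------------------------------------------------------

def default_panel() -> GenotypePanel:
    """The study-style genotype panel: three Rf1/Rf3 restorer accessions,
    a T. timopheevii line, and maintainers."""
    rows = {
        "R197": GenotypePhenotype(carries_Rf1=True),
        "R0932E": GenotypePhenotype(carries_Rf1=True),
        "R0934F": GenotypePhenotype(carries_Rf1=True, carries_Rf3=True),
        "Ttimopheevii": GenotypePhenotype(carries_Rf1=True, is_timopheevii=True),
        "Anapurna": GenotypePhenotype(maintainer=True),
        "Fielder": GenotypePhenotype(maintainer=True),
    }
    return GenotypePanel(genotypes=list(rows), phenotype=rows)


def _sample_motif(rng, model: MotifModel) -> str:
    """One 35-aa motif: consensus-dominated draw from the profile."""
    out = []
    for j in range(model.n_cols):
        col = model.log_odds[:, j]
        top = int(np.argmax(col))
        if col[top] <= 0.5:  # free (code) column: any residue
            out.append(AA_ORDER[rng.integers(0, 20)])
            continue
        u = rng.random()
        tolerated = [i for i in range(20) if 0 < col[i] < col[top]]
        if u < 0.70 or not tolerated:
            out.append(AA_ORDER[top])
        elif u < 0.90:
            out.append(AA_ORDER[tolerated[rng.integers(0, len(tolerated))]])
        else:
            out.append(AA_ORDER[rng.integers(0, 20)])
    return "".join(out)


def _founder_protein(rng, model: MotifModel, n_motifs: int,
                     total_codons: int) -> tuple[str, int]:
    """A full-length RFL-like founder: M + N-extension + motif array + tail.

    Returns (protein, motif_array_start).
    """
    motifs = "".join(_sample_motif(rng, model) for _ in range(n_motifs))
    remaining = total_codons - 1 - len(motifs)
    n_ext = max(30, int(round(remaining * 0.7)))
    n_tail = remaining - n_ext
    aa_pool = np.array(list(AA_ORDER))
    ext = "".join(aa_pool[rng.integers(0, 20, n_ext)])
    tail = "".join(aa_pool[rng.integers(0, 20, max(0, n_tail))])
    return "M" + ext + motifs + tail, 1 + n_ext


def _mutate_dna(rng, dna: str, n_nonsyn: int, n_syn: int) -> str:
    """Substitution-only mutation of a coding sequence.

    Nonsynonymous changes swap a codon to a codon of a different residue;
    synonymous changes swap within the residue's codon set.  The start
    codon is never touched and no stop is ever created.
    """
    codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
    n_codons = len(codons)
    positions = rng.choice(np.arange(1, n_codons), size=min(
        n_nonsyn + n_syn, n_codons - 1), replace=False)
    for i, pos in enumerate(positions):
        old_aa = CODON_MAP[codons[pos]]
        if i < n_nonsyn:
            while True:
                aa = AA_ORDER[rng.integers(0, 20)]
                if aa != old_aa:
                    break
            opts = _CODONS_BY_AA[aa]
        else:
            opts = _CODONS_BY_AA[old_aa]
        codons[pos] = opts[rng.integers(0, len(opts))]
    return "".join(codons)


@dataclass
class SyntheticGene:
    id: str
    genotype: str
    dna: str
    protein: str
    family: int


def simulate_rfl_panel(n_families: int = 5, panel: GenotypePanel | None = None,
                       within_id: float = 0.97, between_id: float = 0.90,
                       restorer_specific: int = 0, mode: str = "Rf1",
                       nonrestorer_state: str = "mixed",
                       frameshift_family: int | None = None,
                       motif_model: MotifModel | None = None,
                       seed: int = 0):
    """Simulate a multi-genotype RFL capture panel with planted families.

    Family ``restorer_specific`` is full-length only in the genotypes
    carrying ``mode`` (and in T. timopheevii); in the other genotypes it
    is absent or C-terminally truncated below 500 codons, per
    ``nonrestorer_state`` ("absent", "truncated" or "mixed").  All other
    (decoy) families are full-length in every genotype.  Optionally one
    decoy family is emitted, in one maintainer genotype, as two partial
    ORFs on a shared contig (a frameshift-split gene).

    Returns (genes, panel, truth): genes is a list of
    :class:`SyntheticGene`; truth records the family partition, the
    planted family id, per-gene motif counts and frameshift coordinates.
    """
    if within_id <= between_id:
        raise ValueError("within_id must exceed between_id")
    rng = np.random.default_rng(seed)
    panel = panel or default_panel()
    model = motif_model or _builtin_models()["P"]
    restorers = set(panel.restorers(mode))
    genes: list[SyntheticGene] = []
    truth_partition: dict[str, int] = {}
    motif_counts: dict[str, int] = {}
    contig_coords: dict[str, tuple] = {}

    # per-member divergence from the founder; pairwise divergence is ~2x
    aa_rate = (1.0 - within_id) / 2.5

    if frameshift_family is not None and frameshift_family == restorer_specific:
        raise ValueError("frameshift family must differ from the planted family")

    for fam in range(n_families):
        n_motifs = int(rng.integers(17, 21))
        total = int(rng.integers(741, 791))
        protein, _ = _founder_protein(rng, model, n_motifs, total)
        founder_dna = _reverse_translate(rng, protein)
        split = frameshift_family is not None and fam == frameshift_family
        for genotype in panel.genotypes:
            specific = fam == restorer_specific
            is_restorer = genotype in restorers
            state = "full"
            if specific and not is_restorer:
                if nonrestorer_state == "mixed":
                    state = "absent" if rng.random() < 0.5 else "truncated"
                else:
                    state = nonrestorer_state
            if state == "absent":
                continue
            n_nonsyn = max(1, int(round(aa_rate * total)))
            n_syn = max(1, int(round(0.01 * total)))
            dna = _mutate_dna(rng, founder_dna, n_nonsyn, n_syn)
            if state == "truncated":
                keep = int(rng.integers(380, 470))
                dna = dna[:keep * 3]
            gid = f"{genotype}.RFL{fam:03d}"
            if split:
                # the gene is ancestrally frameshift-split: every genotype
                # carries it as two sub-500-codon parts on one contig
                cut = total // 2
                d1, d2 = dna[:cut * 3], dna[(cut + 5) * 3:]
                for part, (dpart, offs) in enumerate(
                        [(d1, 0), (d2, (cut + 5) * 3 + 200)]):
                    pid = f"{gid}.fs{part + 1}"
                    genes.append(SyntheticGene(pid, genotype, dpart,
                                               translate_simple(dpart), fam))
                    truth_partition[pid] = fam
                    contig_coords[pid] = (f"contig_{genotype}_{fam}", offs,
                                          offs + len(dpart), "+")
                continue
            genes.append(SyntheticGene(gid, genotype, dna,
                                       translate_simple(dna), fam))
            truth_partition[gid] = fam
            motif_counts[gid] = n_motifs
    truth = SyntheticTruth(seed=seed, planted={
        "partition": truth_partition,
        "restorer_specific_family": restorer_specific,
        "mode": mode,
        "motif_counts": motif_counts,
        "frameshift_family": frameshift_family,
        "frameshift_coords": {k: list(v) for k, v in contig_coords.items()},
    })
    return genes, panel, truth


def simulate_divergent_pair(total_codons: int = 770, n_motifs: int = 20,
                            dna_divergence: float = 0.11,
                            protein_divergence: float = 0.17,
                            pair_diff_motifs: int = 13,
                            motif_model: MotifModel | None = None,
                            table: PprCodeTable | None = None,
                            seed: int = 0):
    """A pair of paralogous RFL-like genes with planted divergence.

    Emulates two restorer paralogs of the same clade: ``n_motifs`` P
    motifs each, overall dna/protein divergence at the given planted
    fractions, and 5th/35th code pairs differing at exactly
    ``pair_diff_motifs`` motif positions.  The first/last 10 codons stay
    identical so a local alignment spans the genes end to end.

    Returns (gene_a, gene_b, truth) as SyntheticGene-like records.
    """
    model = motif_model or _builtin_models()["P"]
    table = table or default_code_table()
    # redraw (deterministically) if a random draw leaves one of the two
    # proteins with an unrecognisable motif, which would break the planted
    # motif-count contract
    for attempt in range(20):
        out = _build_divergent_pair(
            np.random.default_rng([seed, attempt]), total_codons, n_motifs,
            dna_divergence, protein_divergence, pair_diff_motifs, model,
            table, seed)
        a, b = out[0], out[1]
        if _motif_count(a.protein, model) == n_motifs == \
                _motif_count(b.protein, model):
            return out
    raise RuntimeError("could not build a clean divergent pair")


def _motif_count(protein: str, model: MotifModel) -> int:
    from .ppr_annotate import chain_motifs, scan_motifs

    return chain_motifs(scan_motifs(protein, [model]), 2.0).p_count


def _build_divergent_pair(rng, total_codons, n_motifs, dna_divergence,
                          protein_divergence, pair_diff_motifs, model,
                          table, seed):
    pair_pool = sorted(table.scores.keys())

    pairs_a = [pair_pool[i] for i in rng.integers(0, len(pair_pool), n_motifs)]
    pairs_b = list(pairs_a)
    diff_at = rng.choice(n_motifs, size=pair_diff_motifs, replace=False)
    for i in diff_at:
        while True:
            p = pair_pool[rng.integers(0, len(pair_pool))]
            if p != pairs_a[i]:
                pairs_b[i] = p
                break

    protein, arr_start = _founder_protein(rng, model, n_motifs, total_codons)
    protein_a = _plant_pairs(protein, arr_start, model.n_cols, pairs_a)
    dna_a = _reverse_translate(rng, protein_a)

    # plant protein divergence: change residues of gene B (off the code
    # positions and terminal anchors) using minimally different codons,
    # then add synonymous dna changes up to the dna divergence target
    n_aa_diff = int(round(protein_divergence * total_codons))
    code_cols = set()
    for m in range(n_motifs):
        code_cols.add(arr_start + m * model.n_cols + 4)
        code_cols.add(arr_start + m * model.n_cols + 34)
    candidates = np.array(
        [i for i in range(10, total_codons - 10) if i not in code_cols]
    )
    extra = max(0, n_aa_diff - 2 * len(diff_at))
    # repeats stay individually recognisable in real paralog pairs
    # (diversifying selection concentrates at the code positions), so cap
    # the substitutions landing in any single motif body
    max_per_motif = 6

    def _motif_of(pos: int) -> int:
        off = pos - arr_start
        return off // model.n_cols if 0 <= off < n_motifs * model.n_cols else -1

    per_motif: dict[int, int] = {}
    change_pos = []
    for pos in rng.permutation(candidates):
        if len(change_pos) >= extra:
            break
        m = _motif_of(int(pos))
        if m >= 0 and per_motif.get(m, 0) >= max_per_motif:
            continue
        if m >= 0:
            per_motif[m] = per_motif.get(m, 0) + 1
        change_pos.append(int(pos))
    change_pos = np.array(change_pos)

    codons = [dna_a[i:i + 3] for i in range(0, len(dna_a), 3)]
    nt_changed = 0

    def _swap(pos: int, aa: str) -> int:
        old = codons[pos]
        opts = _CODONS_BY_AA[aa]
        best = min(opts, key=lambda c: (sum(x != y for x, y in zip(old, c)), c))
        codons[pos] = best
        return sum(x != y for x, y in zip(old, best))

    for i in diff_at:
        for col, aa in ((4, pairs_b[i][0]), (34, pairs_b[i][1])):
            nt_changed += _swap(arr_start + i * model.n_cols + col, aa)
    for pos in change_pos:
        old_aa = CODON_MAP[codons[pos]]
        while True:
            aa = AA_ORDER[rng.integers(0, 20)]
            if aa != old_aa:
                break
        nt_changed += _swap(int(pos), aa)

    nt_target = int(round(dna_divergence * 3 * total_codons))
    used = set(int(p) for p in change_pos) | code_cols
    syn_candidates = np.array(
        [i for i in range(10, total_codons - 10)
         if i not in used and len(_CODONS_BY_AA[CODON_MAP[codons[i]]]) > 1]
    )
    rng.shuffle(syn_candidates)
    for pos in syn_candidates:
        if nt_changed >= nt_target:
            break
        old = codons[pos]
        opts = [c for c in _CODONS_BY_AA[CODON_MAP[old]] if c != old]
        new = min(opts, key=lambda c: (sum(x != y for x, y in zip(old, c)), c))
        delta = sum(x != y for x, y in zip(old, new))
        if nt_changed + delta <= nt_target:
            codons[pos] = new
            nt_changed += delta
    dna_b = "".join(codons)
    protein_b = translate_simple(dna_b)
    truth = SyntheticTruth(seed=seed, planted={
        "pairs_a": pairs_a,
        "pairs_b": pairs_b,
        "pair_diff_motifs": int(pair_diff_motifs),
        "n_motifs": n_motifs,
        "dna_identity": 1.0 - nt_changed / (3 * total_codons),
        "protein_identity": 1.0 - sum(
            1 for x, y in zip(protein_a, protein_b) if x != y) / total_codons,
    })
    a = SyntheticGene("RFL_A", "synthetic", dna_a, protein_a, 0)
    b = SyntheticGene("RFL_B", "synthetic", dna_b, protein_b, 1)
    return a, b, truth


def _plant_pairs(protein: str, arr_start: int, n_cols: int, pairs) -> str:
    chars = list(protein)
    for m, (a5, a35) in enumerate(pairs):
        chars[arr_start + m * n_cols + 4] = a5
        chars[arr_start + m * n_cols + 34] = a35
    return "".join(chars)


# ---------------------------------------------------------------------------
# chimeric mitochondrial genome pair
# ---------------------------------------------------------------------------

def _alt_frame_ok(cassette: str, max_codons: int = 92) -> bool:
    """No stop-free run of > max_codons codons in any non-coding frame."""
    from .formats import reverse_complement
    for seq in (cassette, reverse_complement(cassette)):
        frames = range(3) if seq is not cassette else range(1, 3)
        for f in frames:
            run = best = 0
            for i in range(f, len(seq) - 2, 3):
                if seq[i:i + 3] in _STOPS:
                    run = 0
                else:
                    run += 1
                    best = max(best, run)
            if best > max_codons:
                return False
    return True


# 12-nt palindrome with a stop codon in every frame of both strands; placed
# at cassette ends it terminates any reading frame crossing the junction
_STOP_BLOCK = "TTAATTAATTAA"


def _orf_cassette(rng, n_codons: int, pool=None, stop: str = "TAA") -> str:
    """stop-block + ATG + (n_codons - 1) sense codons + stop + stop-block."""
    for _ in range(200):
        body = _random_codons(rng, n_codons - 1, pool)
        cassette = _STOP_BLOCK + "ATG" + body + stop + _STOP_BLOCK
        if _alt_frame_ok(cassette):
            return cassette
    raise RuntimeError("could not build a clean ORF cassette")


def simulate_chimeric_genomes(base_len: int = 40_000, donor_codons: int = 150,
                              prefix_codons: int = 96, unique_len_nt: int = 552,
                              n_extra_orfs: int = 9, seed: int = 0):
    """A genome pair differing by a chimeric ORF and extra specific ORFs.

    genome_b carries an atp8-like donor CDS; genome_a replaces everything
    downstream of donor codon ``prefix_codons`` with a unique
    hydrophobic-biased in-frame extension of ``unique_len_nt`` (stop
    included), yielding one chimeric reading frame of
    ``prefix_codons + unique_len_nt/3 - 1`` coding codons.  genome_a
    additionally carries ``n_extra_orfs`` planted lineage-specific ORFs
    of 101-200 codons.  All other sequence is identical, so exactly
    ``1 + n_extra_orfs`` of the >100-codon ORFs are lineage-specific;
    the construction is re-drawn (deterministically from the seed) if an
    incidental reading frame would blur that contract.

    Returns (genome_a, genome_b, donor_cds, truth).
    """
    if unique_len_nt % 3:
        raise ValueError("unique_len_nt must be a multiple of 3")
    if prefix_codons >= donor_codons:
        raise ValueError("prefix must be shorter than the donor CDS")
    last_err: Exception | None = None
    for attempt in range(20):
        rng = np.random.default_rng([seed, attempt])
        try:
            return _build_chimeric_genomes(
                rng, base_len, donor_codons, prefix_codons, unique_len_nt,
                n_extra_orfs, seed,
            )
        except _RetryConstruction as exc:  # incidental ORF: redraw
            last_err = exc
    raise RuntimeError(f"could not build a clean genome pair: {last_err}")


class _RetryConstruction(RuntimeError):
    pass


def _build_chimeric_genomes(rng, base_len, donor_codons, prefix_codons,
                            unique_len_nt, n_extra_orfs, seed):
    backbone = _random_dna(rng, base_len)

    # donor CDS: ATG + sense codons + TAG, preceded by an in-frame TAA
    donor_body = _random_codons(rng, donor_codons - 1)
    donor_cds_seq = "ATG" + donor_body + "TAG"
    while not _alt_frame_ok("TAA" + donor_cds_seq):
        donor_body = _random_codons(rng, donor_codons - 1)
        donor_cds_seq = "ATG" + donor_body + "TAG"
    donor_cassette = "TAA" + donor_cds_seq

    donor_pos = base_len // 3
    b_seq = backbone[:donor_pos] + donor_cassette + backbone[donor_pos:]

    # the chimera: donor prefix + unique extension ending TAA
    unique_codons = unique_len_nt // 3
    prefix_nt = donor_cds_seq[:3 * prefix_codons]
    next_donor_base = donor_cds_seq[3 * prefix_codons]
    for _ in range(200):
        ext_body = _random_codons(rng, unique_codons - 1, _HYDROPHOBIC_CODONS)
        unique_seq = ext_body + "TAA"
        ok = (
            unique_seq[0] != next_donor_base   # exact left anchor boundary
            and unique_seq[-1] != "G"          # donor stop TAG ends in G
            and _alt_frame_ok(prefix_nt + unique_seq)
            and not _shares_kmers(unique_seq, b_seq, 31)
        )
        if ok:
            break
    else:
        raise RuntimeError("could not build a clean unique extension")

    chimera_cassette = "TAA" + prefix_nt + unique_seq
    core = backbone[:donor_pos] + chimera_cassette + backbone[donor_pos:]
    orf_start = donor_pos + 3                       # the ATG
    orf_end = orf_start + 3 * prefix_codons + unique_len_nt - 3
    unique_interval = (orf_start + 3 * prefix_codons,
                       orf_start + 3 * prefix_codons + unique_len_nt)

    # extra lineage-specific ORF cassettes at spaced positions (chosen on
    # `core` coordinates, assembled in one pass)
    lo, hi = orf_end + 500, len(core) - 1000
    if hi - lo < 1600 * max(1, n_extra_orfs):
        raise ValueError("base_len too small for the requested ORF inserts")
    positions: list[int] = []
    draws = 0
    while len(positions) < n_extra_orfs:
        p = int(rng.integers(lo, hi))
        draws += 1
        if draws > 10_000:
            raise _RetryConstruction("could not place ORF inserts")
        if all(abs(p - q) > 800 for q in positions):
            positions.append(p)
    positions.sort()
    cassettes = []
    for _ in positions:
        n_codons = int(rng.integers(101, 201))
        for _ in range(200):
            cassette = _orf_cassette(rng, n_codons, _HYDROPHOBIC_CODONS)
            if not _shares_kmers(cassette[3:-3], core, 31):
                break
        cassettes.append((cassette, n_codons))

    pieces = []
    extra_orfs = []
    prev = 0
    offset = 0
    for p, (cassette, n_codons) in zip(positions, cassettes):
        pieces.append(core[prev:p])
        s = p + offset + len(_STOP_BLOCK)
        extra_orfs.append((s, s + 3 * n_codons))
        pieces.append(cassette)
        offset += len(cassette)
        prev = p
    pieces.append(core[prev:])
    a_seq = "".join(pieces)

    genome_a = SeqRecord(id="mito_A", sequence=a_seq, alphabet="dna",
                         description="synthetic CMS-type mitochondrial genome")
    genome_b = SeqRecord(id="mito_B", sequence=b_seq, alphabet="dna",
                         description="synthetic reference mitochondrial genome")
    donor = SeqRecord(id="atp8_like", sequence=donor_cds_seq, alphabet="dna")

    _check_planted_orfs(genome_a, genome_b, [(orf_start, orf_end)] + extra_orfs)

    truth = SyntheticTruth(seed=seed, planted={
        "prefix_codons": prefix_codons,
        "unique_len_nt": unique_len_nt,
        "unique_interval": list(unique_interval),
        "chimera_orf": [orf_start, orf_end],
        "chimera_codons": prefix_codons + unique_codons - 1,
        "extra_orfs": [list(x) for x in extra_orfs],
        "n_specific_orfs": 1 + n_extra_orfs,
        "donor_id": donor.id,
    })
    return genome_a, genome_b, donor, truth


def _shares_kmers(seq: str, genome: str, k: int) -> bool:
    from .formats import reverse_complement
    g = genome + "#" + reverse_complement(genome)
    return any(seq[i:i + k] in g for i in range(0, max(1, len(seq) - k + 1), k))


def _check_planted_orfs(genome_a: SeqRecord, genome_b: SeqRecord,
                        planted) -> None:
    """The lineage-specific >100-codon ORF set must equal the planted set."""
    from .mito_compare import species_specific_orfs

    # planted ORFs below the >100-codon screen are simply outside its scope
    planted_set = {tuple(p) for p in planted if (p[1] - p[0]) // 3 >= 101}
    orfs = find_orfs(genome_a, OrfParams(min_nt=279, min_codons_filter=101))
    specific = {(o.start, o.end)
                for o in species_specific_orfs(orfs, genome_a, genome_b)}
    if specific != planted_set:
        raise _RetryConstruction(
            f"specific-ORF set {sorted(specific - planted_set)} / missing "
            f"{sorted(planted_set - specific)} does not match the plant"
        )


# ---------------------------------------------------------------------------
# PPR target / binding site
# ---------------------------------------------------------------------------

def simulate_ppr_target(pairs_n: int = 20, transcript_len: int = 1000,
                        table: PprCodeTable | None = None,
                        motif_model: MotifModel | None = None,
                        seed: int = 0):
    """A protein with planted code pairs and a transcript with the
    matching optimal binding site planted at a random position.

    Returns (protein_record, transcript_record, truth) where truth holds
    the planted pairs and the site interval (0-based half-open, 5'->3').
    """
    rng = np.random.default_rng(seed)
    table = table or default_code_table()
    model = motif_model or _builtin_models()["P"]
    pool = sorted(table.scores.keys())
    pairs = [pool[i] for i in rng.integers(0, len(pool), pairs_n)]
    site = "".join(table.argmax_base(p) for p in pairs).replace("U", "T")

    total = 1 + 50 + pairs_n * model.n_cols + 45
    protein, arr_start = _founder_protein(rng, model, pairs_n, total)
    protein = _plant_pairs(protein, arr_start, model.n_cols, pairs)

    pos = int(rng.integers(0, transcript_len - pairs_n + 1))
    flank = _random_dna(rng, transcript_len - pairs_n)
    transcript = flank[:pos] + site + flank[pos:]
    prot_rec = SeqRecord(id="RFL_target", sequence=protein, alphabet="protein")
    tx_rec = SeqRecord(id="orf_tx", sequence=transcript, alphabet="dna")
    truth = SyntheticTruth(seed=seed, planted={
        "pairs": pairs,
        "site": [pos, pos + pairs_n],
    })
    return prot_rec, tx_rec, truth


# ---------------------------------------------------------------------------
# coverage and counts
# ---------------------------------------------------------------------------

def simulate_coverage(ref_len: int = 10_000, cleavage_pos=5000,
                      depth: float = 100.0, fold: float = 5.0,
                      masks=None, strand: str = "+", seed: int = 0,
                      ref_id: str = "mito_A"):
    """Fertile/sterile coverage pairs with a planted cleavage transition.

    ``cleavage_pos`` may be an int or a {genotype: position} mapping (in
    transcript 5'->3' coordinates when strand is '+'; callers planting on
    the '-' strand give genomic positions directly).  Fertile tracks run
    at depth/fold 5' of the transition and depth 3' of it; sterile
    tracks are flat at depth.  Per-base Poisson noise; masked intervals
    are over-covered 20x to emulate undepleted rRNA blocks.

    Returns ({genotype: (fertile, sterile)}, truth) of raw tracks.
    """
    rng = np.random.default_rng(seed)
    masks = list(masks or [])
    if not isinstance(cleavage_pos, dict):
        cleavage_pos = {"restored": int(cleavage_pos)}
    tracks = {}
    for genotype, pos in sorted(cleavage_pos.items()):
        mean_f = np.full(ref_len, depth, dtype=float)
        if strand == "+":
            mean_f[:pos] = depth / fold
        else:
            mean_f[pos:] = depth / fold   # 5' of a reverse-strand transcript
        mean_s = np.full(ref_len, depth, dtype=float)
        for ms, me in masks:
            mean_f[ms:me] = depth * 20
            mean_s[ms:me] = depth * 20
        fertile = CoverageTrack(ref_id=ref_id, strand=strand,
                                depth=rng.poisson(mean_f).astype(float),
                                masks=masks)
        sterile = CoverageTrack(ref_id=ref_id, strand=strand,
                                depth=rng.poisson(mean_s).astype(float),
                                masks=masks)
        tracks[genotype] = (fertile, sterile)
    truth = SyntheticTruth(seed=seed, planted={
        "cleavage_pos": {g: int(p) for g, p in cleavage_pos.items()},
        "depth": depth,
        "fold": fold,
        "strand": strand,
    })
    return tracks, truth


def simulate_counts(n_genes: int = 44, groups=None, effect_size: float = 2.0,
                    dispersion: float = 0.05, up_frac: float = 0.2,
                    down_frac: float = 0.2, seed: int = 0):
    """Negative-binomial count matrix with fertile/sterile block structure.

    ``groups`` maps sample id -> "fertile" or "sterile" (default: three
    fertile and three sterile samples).  The first ``up_frac`` of genes
    are up in fertile samples by ``effect_size``-fold, the next
    ``down_frac`` down by the same factor.  Planted lognormal library-
    size multipliers are recorded in the truth sidecar.

    Returns (CountMatrix, truth).
    """
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = {f"fertile_{i}": "fertile" for i in range(1, 4)}
        groups.update({f"sterile_{i}": "sterile" for i in range(1, 4)})
    samples = list(groups)
    base = np.exp(rng.normal(np.log(500), 1.0, n_genes))
    n_up = int(round(up_frac * n_genes))
    n_down = int(round(down_frac * n_genes))
    lib = np.exp(rng.normal(0.0, 0.3, len(samples)))
    lib /= np.exp(np.mean(np.log(lib)))   # geometric mean 1
    counts = np.zeros((n_genes, len(samples)))
    for j, s in enumerate(samples):
        mu = base.copy()
        if groups[s] == "fertile":
            mu[:n_up] *= effect_size
            mu[n_up:n_up + n_down] /= effect_size
        mu = mu * lib[j]
        if dispersion > 0:
            shape = 1.0 / dispersion
            mu = rng.gamma(shape, mu / shape)
        counts[:, j] = rng.poisson(mu)
    cm = CountMatrix(
        transcript_ids=[f"mt_tx{i + 1:03d}" for i in range(n_genes)],
        sample_ids=samples,
        counts=counts,
        lengths=rng.integers(300, 3000, n_genes).astype(float),
    )
    truth = SyntheticTruth(seed=seed, planted={
        "groups": dict(groups),
        "lib_multipliers": {s: float(x) for s, x in zip(samples, lib)},
        "up_genes": cm.transcript_ids[:n_up],
        "down_genes": cm.transcript_ids[n_up:n_up + n_down],
        "effect_size": effect_size,
    })
    return cm, truth
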