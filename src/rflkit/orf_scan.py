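"""Six-frame ORF discovery and translation (getorf-style screen).

The default mode, ``between_stops``, reports every maximal stop-free
translated stretch between two stop codons (or a sequence end), per frame
and per strand -- the behaviour of EMBOSS getorf with ``-find 0``.  An
``atg_to_stop`` mode restricts each stretch to begin at its first ATG,
which is the convention under which a mitochondrial gene such as a
279-codon chimeric ORF is measured.  ORF sizes are counted in coding
codons, excluding the terminating stop.

Coordinates are always reported on the forward strand (0-based half-open)
with a strand flag; ``frame`` is the 0-2 offset on the reading strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .formats import Feature, ParameterError, SeqRecord, reverse_complement

__all__ = ["Orf", "OrfParams", "translate", "find_orfs", "orfs_to_features"]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_MAP: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_MAP[_stop] = "*"

START_CODON = "ATG"


@dataclass
class OrfParams:
    min_nt: int = 279
    mode: str = "between_stops"
    both_strands: bool = True
    min_codons_filter: int | None = None
    circular: bool = False
    include_open_ended: bool = True

    def __post_init__(self) -> None:
        if self.min_nt < 3:
            raise ParameterError("min_nt must be >= 3")
        if self.mode not in ("between_stops", "atg_to_stop"):
            raise ParameterError(f"unknown ORF mode {self.mode!r}")


@dataclass
class Orf:
    genome_id: str
    start: int           # forward-strand, 0-based half-open, coding only
    end: int
    strand: str
    frame: int           # frame on the reading strand
    protein: str
    open_start: bool = False   # runs into the sequence 5' end (no upstream stop)
    open_end: bool = False     # runs into the sequence 3' end (no stop codon)

    @property
    def nt_len(self) -> int:
        return self.end - self.start

    @property
    def codons(self) -> int:
        return self.nt_len // 3

    @property
    def id(self) -> str:
        return f"{self.genome_id}:{self.start}-{self.end}({self.strand})"


def translate(dna: str, frame: int = 0) -> str:
    """Translate one reading frame with the standard genetic code.

    Stops render as '*'; any codon containing N renders as 'X'; a trailing
    partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ParameterError("frame must be 0, 1 or 2")
    if not set(dna) <= set("ACGTN"):
        raise ParameterError("translate() requires a canonical DNA sequence")
    out = []
    for i in range(frame, len(dna) - 2, 3):
        codon = dna[i:i + 3]
        out.append("X" if "N" in codon else CODON_MAP[codon])
    return "".join(out)


def _segments_one_frame(seq: str, frame: int):
    """Yield (codon_start, codon_end, protein, open5, open3) stop-free runs."""
    aa = translate(seq, frame)
    n = len(aa)
    if n == 0:
        return
    run_start = 0
    for i, c in enumerate(aa):
        if c == "*":
            if i > run_start:
                yield run_start, i, aa[run_start:i], run_start == 0, False
            run_start = i + 1
    if n > run_start:
        yield run_start, n, aa[run_start:n], run_start == 0, True


def find_orfs(seq: SeqRecord, params: OrfParams | None = None) -> list[Orf]:
    """Find ORFs in all reading frames of a DNA record.

    Output is sorted by (start, strand, frame).  In ``between_stops`` mode
    no two reported ORFs on the same frame/strand overlap.
    """
    params = params or OrfParams()
    if seq.alphabet != "dna":
        raise ParameterError("find_orfs requires a dna record")
    L = len(seq.sequence)
    orfs: list[Orf] = []
    strands = ["+", "-"] if params.both_strands else ["+"]
    pad = params.min_nt - 1 if params.circular else 0
    for strand in strands:
        working = seq.sequence if strand == "+" else reverse_complement(seq.sequence)
        if pad:
            working = working + working[:pad]
        for frame in range(3):
            for c0, c1, prot, open5, open3 in _segments_one_frame(working, frame):
                if params.circular:
                    # ends of the padded linearisation are artefacts
                    open5 = open3 = False
                if params.mode == "atg_to_stop":
                    pos = prot.find("M")
                    if pos < 0:
                        continue
                    c0 += pos
                    prot = prot[pos:]
                    open5 = False
                s = frame + 3 * c0
                e = frame + 3 * c1
                if params.circular and s >= L:
                    continue  # duplicate of an unwrapped ORF
                if e - s < params.min_nt:
                    continue
                if params.min_codons_filter is not None and \
                        (e - s) // 3 < params.min_codons_filter:
                    continue
                if not params.include_open_ended and (open5 or open3):
                    continue
                if strand == "+":
                    fs, fe = s, e
                else:
                    Lw = L + pad
                    fs, fe = Lw - e, Lw - s
                    if params.circular:
                        fs %= L
                        fe = fs + (e - s)
                orfs.append(
                    Orf(
                        genome_id=seq.id,
                        start=fs,
                        end=fe,
                        strand=strand,
                        frame=frame,
                        protein=prot,
                        open_start=open5,
                        open_end=open3,
                    )
                )
    if params.circular:
        seen = set()
        unique = []
        for o in orfs:
            key = (o.start % L, o.strand, o.protein)
            if key not in seen:
                seen.add(key)
                unique.append(o)
        orfs = unique
    orfs.sort(key=lambda o: (o.start, o.strand, o.frame))
    return orfs


def orfs_to_features(orfs) -> list[Feature]:
    return [
        Feature(
            seq_id=o.genome_id,
            start=o.start,
            end=o.end,
            strand=o.strand,
            type="ORF",
            attributes={
                "ID": o.id,
                "codons": str(o.codons),
                "frame": str(o.frame),
                "open_start": str(o.open_start).lower(),
                "open_end": str(o.open_end).lower(),
            },
        )
        for o in orfs
    ]
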