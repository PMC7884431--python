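"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
All coordinates inside the package are 0-based half-open, on the forward
strand, with a separate strand flag.  GFF3 is converted from/to 1-based
inclusive at the I/O boundary; bedGraph is already 0-based half-open.
Human-readable report tables emit 1-based inclusive coordinates.

Sequence canonicalisation: DNA is upper-cased with U -> T; N is allowed.
Protein is upper-cased; X (unknown) and * (stop) are allowed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "RflkitError",
    "FormatError",
    "BoundsError",
    "ParameterError",
    "SeqRecord",
    "Feature",
    "CoverageTrack",
    "CountMatrix",
    "parse_fasta",
    "write_fasta",
    "parse_bedgraph",
    "write_bedgraph",
    "parse_feature_table",
    "write_feature_table",
    "reverse_complement",
]


class RflkitError(Exception):
    """Base class for all typed errors raised by this package."""


class FormatError(RflkitError, ValueError):
    """Malformed input file or record."""


class BoundsError(RflkitError, ValueError):
    """Coordinates outside the reference sequence."""


class ParameterError(RflkitError, ValueError):
    """Invalid parameter combination."""


DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _canonicalise_dna(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise FormatError(f"non-DNA symbols in sequence: {sorted(bad)}")
    return s


def _canonicalise_protein(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - PROTEIN_ALPHABET
    if bad:
        raise FormatError(f"non-protein symbols in sequence: {sorted(bad)}")
    return s


@dataclass
class SeqRecord:
    """A named sequence over a declared alphabet ('dna' or 'protein')."""

    id: str
    sequence: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if self.alphabet == "dna":
            self.sequence = _canonicalise_dna(self.sequence)
        elif self.alphabet == "protein":
            self.sequence = _canonicalise_protein(self.sequence)
        else:
            raise ParameterError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """A located annotation in internal 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    type: str
    attributes: dict[str, str] = field(default_factory=dict)
    source: str = "rflkit"
    score: str = "."
    frame: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid feature interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand symbol {self.strand!r}")


@dataclass
class CoverageTrack:
    """Per-base strand-specific depth over one reference sequence."""

    ref_id: str
    strand: str
    depth: np.ndarray
    masks: list[tuple[int, int]] = field(default_factory=list)
    normalised: bool = False
    #: mean unmasked depth used by normalisation (raw-depth scale); set by
    #: rnaseq_mito.normalize_coverage so depth-threshold checks can be made
    #: on the pre-normalisation scale.
    norm_mean: float | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise FormatError("negative coverage depth")
        n = len(self.depth)
        for s, e in self.masks:
            if not (0 <= s < e <= n):
                raise BoundsError(f"mask [{s}, {e}) outside reference of length {n}")

    def unmasked(self) -> np.ndarray:
        """Boolean vector, True where the position is not masked."""
        keep = np.ones(len(self.depth), dtype=bool)
        for s, e in self.masks:
            keep[s:e] = False
        return keep


@dataclass
class CountMatrix:
    """Transcripts x samples raw count matrix with per-transcript lengths."""

    transcript_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.counts.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise FormatError("count matrix dimensions inconsistent with labels")
        if len(self.lengths) != len(self.transcript_ids):
            raise FormatError("length vector inconsistent with transcripts")
        if np.any(self.counts < 0):
            raise FormatError("negative counts")
        if np.any(self.lengths <= 0):
            raise FormatError("non-positive transcript length")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path, alphabet: str = "dna") -> list[SeqRecord]:
    """Parse a (multi-record) FASTA file into canonicalised records.

    Empty files yield an empty list; sequence data before any header is a
    :class:`FormatError`; duplicate ids are a :class:`FormatError`.
    """
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if not stripped:
        return []
    first = stripped.splitlines()[0]
    if not first.startswith((">", ";")):
        raise FormatError("sequence data before any FASTA header")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SeqRecord(id=rec.id, sequence=str(rec.seq), description=desc,
                      alphabet=alphabet)
        )
    return records


def write_fasta(records, path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def parse_bedgraph(path, ref_len: int, strand: str = "+",
                   ref_id: str | None = None) -> CoverageTrack:
    """Parse a 4-column bedGraph into a per-base :class:`CoverageTrack`.

    Positions not covered by any interval get depth 0; overlapping intervals
    are resolved last-wins (with a warning), matching typical bedGraph
    producers that emit disjoint runs.
    """
    depth = np.zeros(ref_len, dtype=float)
    painted = np.zeros(ref_len, dtype=bool)
    name = ref_id
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = parts
            try:
                s, e, v = int(s), int(e), float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if v < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage value")
            if s < 0 or s >= e:
                raise FormatError(f"{path}:{lineno}: invalid interval [{s}, {e})")
            if e > ref_len:
                raise BoundsError(
                    f"{path}:{lineno}: interval end {e} > reference length {ref_len}"
                )
            if name is None:
                name = chrom
            if painted[s:e].any():
                warnings.warn(
                    f"{path}:{lineno}: overlapping bedGraph intervals; last wins",
                    stacklevel=2,
                )
            depth[s:e] = v
            painted[s:e] = True
    return CoverageTrack(ref_id=name or "ref", strand=strand, depth=depth)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as run-length-encoded bedGraph (zero runs included)."""
    d = track.depth
    with open(path, "w") as fh:
        if len(d) == 0:
            return
        boundaries = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(d)]))
        for s, e in zip(starts, ends):
            fh.write(f"{track.ref_id}\t{s}\t{e}\t{d[s]:g}\n")


# ---------------------------------------------------------------------------
# GFF3 subset
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"malformed GFF3 attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        attrs[k] = v
    return attrs


def parse_feature_table(path) -> list[Feature]:
    """Parse a GFF3 subset (9 columns, 1-based inclusive) into Features."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, source, ftype, start, end, score, strand, frame, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start_i > end_i:
                raise FormatError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            feats.append(
                Feature(
                    seq_id=seqid,
                    start=start_i - 1,   # 1-based inclusive -> 0-based half-open
                    end=end_i,
                    strand=strand,
                    type=ftype,
                    attributes=_parse_attributes(attrs),
                    source=source,
                    score=score,
                    frame=frame,
                )
            )
    return feats


def write_feature_table(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        f.source,
                        f.type,
                        str(f.start + 1),  # back to 1-based inclusive
                        str(f.end),
                        f.score,
                        f.strand,
                        f.frame,
                        attrs,
                    ]
                )
                + "\n"
            )
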