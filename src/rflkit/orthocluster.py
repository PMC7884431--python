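"""Greedy identity clustering of RFL paralogs and capture-bait tiling.

Putatively orthologous RFL copies from different genotypes are grouped by
CD-HIT-style greedy clustering: sequences are sorted longest-first and each
joins the first (founding-order) existing cluster whose representative it
matches at >= 96% identity over a sufficiently long, near-full-coverage
local alignment; otherwise it founds a new cluster.  Unlike CD-HIT, every
comparison is a full affine-gap local alignment (no word filter), so the
procedure is deterministic and order-invariant at panel scale.

Bait design tiles capture probes of the maximum length across each target
at a fixed step, with a final probe flush with the target end, trimming or
dropping probes that overlap mask intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._align import local_align
from .formats import ParameterError

__all__ = [
    "ClusteringParams",
    "Orthogroup",
    "CaptureParams",
    "align_identity",
    "greedy_cluster",
    "design_capture_baits",
]


@dataclass
class ClusteringParams:
    identity_c: float = 0.96          # CD-HIT -c
    min_aln_len: int = 105            # CD-HIT -A (aa)
    max_unaligned_short: int = 60     # CD-HIT -AS (aa)
    mode: str = "first"               # first | best matching cluster
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_c <= 1.0):
            raise ParameterError("identity_c must be in (0, 1]")
        if self.mode not in ("first", "best"):
            raise ParameterError("mode must be 'first' or 'best'")


@dataclass
class Orthogroup:
    group_id: str
    representative: str                       # gene id of the longest member
    members: list[tuple[str, str, str]] = field(default_factory=list)
    # members: (genotype, gene_id, status)

    @property
    def genotypes(self) -> set[str]:
        return {g for g, _, _ in self.members}

    def statuses_by_genotype(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, _, s in self.members:
            out.setdefault(g, []).append(s)
        return out


@dataclass
class CaptureParams:
    probe_min: int = 50
    probe_max: int = 95
    step: int = 36

    def __post_init__(self) -> None:
        if self.probe_min > self.probe_max:
            raise ParameterError("probe_min must be <= probe_max")
        if self.step < 1:
            raise ParameterError("step must be >= 1")


def align_identity(a: str, b: str, alphabet: str = "protein"):
    """Local-alignment identity between two sequences.

    Returns (identity, aln_len, unaligned_short): identity is
    matches / alignment columns, aln_len the number of alignment columns,
    and unaligned_short the residues of the shorter sequence left outside
    the aligned span.  Empty input degenerates to (0.0, 0, len(shorter)).
    """
    short_len = min(len(a), len(b))
    if not a or not b:
        return 0.0, 0, short_len
    res = local_align(a, b, alphabet=alphabet)
    span = res["a_span"] if len(a) <= len(b) else res["b_span"]
    unaligned_short = short_len - (span[1] - span[0])
    return res["identity"], res["columns"], unaligned_short


def _cannot_join(a: str, b: str, params: ClusteringParams) -> bool:
    """Exact admissible reject screen via a banded edit-distance bound.

    Any local alignment satisfying the join criterion (identity >= c with
    unaligned_short <= AS) implies an alignment of the full shorter
    sequence inside the longer with at most
    len_short*(1-c)/c + AS edits, so a best infix edit distance above
    that bound proves the pair cannot join.  This is a proven bound, not
    a word-filter heuristic: clustering results are identical with the
    screen on or off.
    """
    import edlib

    if not a or not b:
        return True
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    c = params.identity_c
    bound = int(len(shorter) * (1.0 - c) / c + params.max_unaligned_short)
    res = edlib.align(shorter, longer, mode="HW", task="distance", k=bound)
    return res["editDistance"] == -1


def greedy_cluster(genes, params: ClusteringParams | None = None) -> list[Orthogroup]:
    """Greedy identity clustering of RflGene records into orthogroups.

    The join criterion against a cluster representative is
    identity >= identity_c AND aln_len >= min_aln_len AND
    unaligned_short <= max_unaligned_short (threshold inclusive).
    Deterministic: input order never matters (sorting is internal).
    """
    params = params or ClusteringParams()
    if not genes:
        raise ParameterError("greedy_cluster requires at least one sequence")
    order = sorted(genes, key=lambda g: (-len(g.protein), g.id))
    clusters: list[dict] = []
    for gene in order:
        chosen = None
        best_identity = -1.0
        for cl in clusters:
            if _cannot_join(gene.protein, cl["rep_seq"], params):
                continue
            identity, aln_len, unal = align_identity(
                gene.protein, cl["rep_seq"], alphabet=params.alphabet
            )
            ok = (
                identity >= params.identity_c
                and aln_len >= params.min_aln_len
                and unal <= params.max_unaligned_short
            )
            if not ok:
                continue
            if params.mode == "first":
                chosen = cl
                break
            if identity > best_identity:
                best_identity = identity
                chosen = cl
        if chosen is None:
            clusters.append(
                {"rep_id": gene.id, "rep_seq": gene.protein, "members": [gene]}
            )
        else:
            chosen["members"].append(gene)
    return [
        Orthogroup(
            group_id=f"OG{i + 1:04d}",
            representative=cl["rep_id"],
            members=[(g.genotype, g.id, g.status) for g in cl["members"]],
        )
        for i, cl in enumerate(clusters)
    ]


def design_capture_baits(targets, mask_intervals=None,
                         params: CaptureParams | None = None):
    """Tile capture probes across target sequences.

    Full-length (probe_max) probes are placed at starts 0, step, 2*step, ...
    while they fit; if the tiled probes leave an uncovered tail, a final
    probe flush with the target end is added.  Probes overlapping a mask are
    trimmed to their longest unmasked stretch and kept only if still at
    least probe_min long.  Returns (target_id, start, end) triples.
    """
    params = params or CaptureParams()
    mask_intervals = mask_intervals or {}
    probes: list[tuple[str, int, int]] = []
    for rec in targets:
        L = len(rec.sequence)
        masks = sorted(mask_intervals.get(rec.id, []))
        for s, e in masks:
            if not (0 <= s < e <= L):
                raise ParameterError(
                    f"mask [{s}, {e}) out of bounds for {rec.id} (len {L})"
                )
        if L < params.probe_min:
            warnings.warn(f"target {rec.id} shorter than probe_min; skipped",
                          stacklevel=2)
            continue
        if L <= params.probe_max:
            raw = [(0, L)]
        else:
            raw = []
            s = 0
            while s + params.probe_max <= L:
                raw.append((s, s + params.probe_max))
                s += params.step
            if raw[-1][1] < L:
                raw.append((L - params.probe_max, L))
        for s, e in raw:
            trimmed = _trim_to_unmasked(s, e, masks)
            if trimmed is not None and trimmed[1] - trimmed[0] >= params.probe_min:
                probes.append((rec.id, trimmed[0], trimmed[1]))
    return probes


def _trim_to_unmasked(s: int, e: int, masks) -> tuple[int, int] | None:
    """Longest sub-interval of [s, e) disjoint from all masks."""
    free = [(s, e)]
    for ms, me in masks:
        nxt = []
        for fs, fe in free:
            if me <= fs or ms >= fe:
                nxt.append((fs, fe))
                continue
            if fs < ms:
                nxt.append((fs, ms))
            if me < fe:
                nxt.append((me, fe))
        free = nxt
        if not free:
            return None
    return max(free, key=lambda iv: (iv[1] - iv[0], -iv[0]))
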