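"""P/L/S pentatricopeptide-repeat (PPR) motif annotation.

PPR proteins are built from tandem, fixed-length helical repeats; the
P-class repeat is 35 residues and the residues at repeat positions 5 and
35 (1-based) select the RNA base the repeat binds.  Restorer-of-fertility
-like (RFL) proteins are P-class PPR proteins with long tandem arrays of
these motifs: a protein is called RFL when its chained architecture holds
at least ``rfl_min_p`` (default 10) P motifs, and full-length when it
additionally starts with M, has no internal stop and is at least
``full_length_min_aa`` (default 500) codons long.

Motifs are modelled as ungapped fixed-length log-odds profiles (PSSMs)
built from a consensus plus tolerated-residue sets.  Scanning reports
every window reaching a model's bit threshold; a dynamic program then
chains non-overlapping hits, with a bonus for directly adjacent motifs,
into the most plausible architecture.  Position-5/35 indexing is 1-based
within the motif: a hit starting at ``aa_start`` reads its code residues
at ``aa_start + 4`` and ``aa_start + 34``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .formats import BoundsError, ParameterError

__all__ = [
    "MotifModel",
    "MotifHit",
    "PprArchitecture",
    "RflGene",
    "default_models",
    "load_motif_model",
    "write_motif_model",
    "scan_motifs",
    "chain_motifs",
    "classify_rfl",
    "extract_code_pairs",
    "annotate_protein",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}

# residue similarity groups used to spread profile weight around the consensus
_SIMILAR = {
    "V": "ILM", "I": "VLM", "L": "VIM", "M": "VIL",
    "F": "YW", "Y": "FW", "W": "FY",
    "K": "R", "R": "K",
    "D": "E", "E": "D",
    "S": "T", "T": "S",
    "N": "Q", "Q": "N",
    "A": "G", "G": "A",
    "C": "", "P": "", "H": "",
}

# 35-aa P-class consensus; positions 5 and 35 (1-based) are the variable
# base-specifying positions and are modelled as unconstrained.
_P_CONSENSUS = "VVTYNTLISGLCKAGRLDEALELFEEMKEKGIVPD"
_L_CONSENSUS = "LVSWNSMISGYAQNGEAFEALDLFRRMVAEGVKPNE"
_S_CONSENSUS = "VTFNEMIKGYVQAGLVDDALALFREMQVKGI"
_CODE_COLUMNS = {"P": (4, 34), "L": (4, 35), "S": (4, 30)}


@dataclass
class MotifModel:
    name: str
    n_cols: int
    log_odds: np.ndarray          # 20 x n_cols
    hit_threshold: float

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.n_cols < 15:
            raise ParameterError("motif models must span at least 15 columns")
        if self.log_odds.shape != (20, self.n_cols):
            raise ParameterError("log-odds matrix must be 20 x n_cols")
        if not np.isfinite(self.hit_threshold):
            raise ParameterError("hit threshold must be finite")

    @property
    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in np.argmax(self.log_odds, axis=0))


@dataclass
class MotifHit:
    model: str
    aa_start: int
    aa_end: int
    score: float
    aa5: str
    aa35: str


@dataclass
class PprArchitecture:
    hits: list[MotifHit] = field(default_factory=list)
    total_score: float = 0.0
    adjacency_bonus: float = 0.0

    @property
    def p_count(self) -> int:
        return sum(1 for h in self.hits if h.model == "P")

    @property
    def tandem_max(self) -> int:
        """Longest run of chained P motifs with inter-motif gap <= 2 aa."""
        best = run = 0
        prev_end = None
        for h in self.hits:
            if h.model != "P":
                prev_end = None
                run = 0
                continue
            if prev_end is not None and h.aa_start - prev_end <= 2:
                run += 1
            else:
                run = 1
            prev_end = h.aa_end
            best = max(best, run)
        return best


@dataclass
class RflGene:
    id: str
    genotype: str
    protein: str
    architecture: PprArchitecture
    status: str                      # full_length | truncated | partial | frameshifted
    dna: str | None = None
    mtp: bool | None = None

    @property
    def is_rfl(self) -> bool:
        return self.architecture.p_count >= 10

    @property
    def codons(self) -> int:
        return len(self.protein.rstrip("*"))


def _build_model(name: str, consensus: str, threshold: float,
                 free_cols: tuple[int, ...]) -> MotifModel:
    n = len(consensus)
    m = np.full((20, n), -1.0)
    for j, aa in enumerate(consensus):
        if j in free_cols:
            m[:, j] = 0.25   # variable code position: any residue tolerated
            continue
        m[_AA_INDEX[aa], j] = 1.5
        for s in _SIMILAR[aa]:
            m[_AA_INDEX[s], j] = 0.75
    return MotifModel(name=name, n_cols=n, log_odds=m, hit_threshold=threshold)


def _builtin_models() -> dict[str, MotifModel]:
    return {
        "P": _build_model("P", _P_CONSENSUS, 15.0, _CODE_COLUMNS["P"]),
        "L": _build_model("L", _L_CONSENSUS, 15.0, _CODE_COLUMNS["L"]),
        "S": _build_model("S", _S_CONSENSUS, 13.0, _CODE_COLUMNS["S"]),
    }


def default_models() -> list[MotifModel]:
    """The shipped P/L/S profiles, loaded from the package data TSVs."""
    models = []
    for name in ("P", "L", "S"):
        ref = resources.files("rflkit").joinpath(f"data/motif_{name}.tsv")
        with resources.as_file(ref) as path:
            models.append(load_motif_model(path))
    return models


def write_motif_model(model: MotifModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name={model.name}\n")
        fh.write(f"#threshold={model.hit_threshold:g}\n")
        fh.write("residue\t" + "\t".join(str(j + 1) for j in range(model.n_cols)) + "\n")
        for i, aa in enumerate(AA_ORDER):
            row = "\t".join(f"{v:g}" for v in model.log_odds[i])
            fh.write(f"{aa}\t{row}\n")


def load_motif_model(path) -> MotifModel:
    name = None
    threshold = None
    rows: dict[str, list[float]] = {}
    n_cols = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#name="):
                name = line.split("=", 1)[1]
                continue
            if line.startswith("#threshold="):
                threshold = float(line.split("=", 1)[1])
                continue
            if line.startswith("residue"):
                n_cols = len(line.split("\t")) - 1
                continue
            if not line:
                continue
            parts = line.split("\t")
            rows[parts[0]] = [float(x) for x in parts[1:]]
    if name is None or threshold is None or n_cols is None:
        raise ParameterError(f"{path}: missing model metadata")
    m = np.zeros((20, n_cols))
    for aa, vals in rows.items():
        m[_AA_INDEX[aa]] = vals
    return MotifModel(name=name, n_cols=n_cols, log_odds=m, hit_threshold=threshold)


# ---------------------------------------------------------------------------
# scanning and chaining
# ---------------------------------------------------------------------------

def scan_motifs(protein: str, models) -> list[MotifHit]:
    """All windows of each model scoring at or above its threshold.

    The hit list may contain overlaps; X residues score 0 (neutral).
    Proteins shorter than a model yield no hits for that model.
    """
    if not models:
        raise ParameterError("at least one motif model is required")
    hits: list[MotifHit] = []
    n = len(protein)
    if n == 0:
        return hits
    codes = np.array([_AA_INDEX.get(c, -1) for c in protein], dtype=np.int64)
    for model in models:
        w = model.n_cols
        if n < w:
            continue
        # per-position per-column scores; unknown residues (row -1) score 0
        lo = np.vstack([model.log_odds, np.zeros((1, w))])
        pos = lo[codes]                       # (n, w)
        nwin = n - w + 1
        scores = np.zeros(nwin)
        for j in range(w):
            scores += pos[j:j + nwin, j]
        c5, c35 = _CODE_COLUMNS.get(model.name, (4, w - 1))
        for start in np.flatnonzero(scores >= model.hit_threshold):
            start = int(start)
            hits.append(
                MotifHit(
                    model=model.name,
                    aa_start=start,
                    aa_end=start + w,
                    score=float(scores[start]),
                    aa5=protein[start + c5],
                    aa35=protein[start + c35],
                )
            )
    hits.sort(key=lambda h: (h.aa_start, h.aa_end, h.model))
    return hits


def chain_motifs(hits, adjacency_bonus: float = 2.0) -> PprArchitecture:
    """Select the best-scoring non-overlapping subset of hits.

    Maximises sum(score) + adjacency_bonus * (#consecutive pairs with
    inter-hit gap <= 2 aa) by dynamic programming; ties break toward the
    chain with more hits, then the smaller sum of start coordinates.
    """
    hits = sorted(hits, key=lambda h: (h.aa_start, h.aa_end, h.model))
    n = len(hits)
    if n == 0:
        return PprArchitecture(hits=[], total_score=0.0,
                               adjacency_bonus=adjacency_bonus)
    # best[i]: (total, n_hits, -sum_starts) of the best chain ending at hit i
    best = [None] * n
    prev = [-1] * n
    for i, h in enumerate(hits):
        cand = (h.score, 1, -h.aa_start)
        pr = -1
        for j in range(i):
            g = hits[j]
            if g.aa_end > h.aa_start:
                continue
            bonus = adjacency_bonus if h.aa_start - g.aa_end <= 2 else 0.0
            t = (best[j][0] + h.score + bonus,
                 best[j][1] + 1,
                 best[j][2] - h.aa_start)
            if t > cand:
                cand = t
                pr = j
        best[i] = cand
        prev[i] = pr
    end = max(range(n), key=lambda i: best[i])
    chain = []
    i = end
    while i >= 0:
        chain.append(hits[i])
        i = prev[i]
    chain.reverse()
    return PprArchitecture(hits=chain, total_score=best[end][0],
                           adjacency_bonus=adjacency_bonus)


def classify_rfl(arch: PprArchitecture, protein: str,
                 rfl_min_p: int = 10, full_length_min_aa: int = 500,
                 orthogroup_max_codons: int | None = None) -> tuple[bool, str]:
    """RFL status of one protein: (is_rfl, status).

    A protein is RFL when its chained architecture has >= ``rfl_min_p``
    P motifs.  Status is ``partial`` below ``full_length_min_aa`` codons,
    ``full_length`` for an M-initiated, stop-free RFL of sufficient
    length, else ``truncated`` (e.g. C-terminally shortened relative to
    its orthogroup).  Frameshift calls are made at the selection stage
    from contig context, not here.
    """
    codons = len(protein.rstrip("*"))
    is_rfl = arch.p_count >= rfl_min_p
    internal_stop = "*" in protein.rstrip("*")
    if codons < full_length_min_aa:
        status = "partial"
    elif protein.startswith("M") and not internal_stop and is_rfl:
        if orthogroup_max_codons is not None and \
                codons <= orthogroup_max_codons - 35:
            status = "truncated"
        else:
            status = "full_length"
    else:
        status = "truncated"
    return is_rfl, status


def extract_code_pairs(arch: PprArchitecture, protein: str) -> list[tuple[str, str]]:
    """(position-5, position-35) residue pairs of each P motif, N- to C-terminal."""
    pairs = []
    for h in arch.hits:
        if h.model != "P":
            continue
        if h.aa_end > len(protein):
            raise BoundsError("motif hit extends past the protein end")
        pairs.append((protein[h.aa_start + 4], protein[h.aa_start + 34]))
    return pairs


def annotate_protein(gene_id: str, genotype: str, protein: str,
                     models=None, adjacency_bonus: float = 2.0,
                     rfl_min_p: int = 10, full_length_min_aa: int = 500,
                     dna: str | None = None) -> RflGene:
    """Scan, chain and classify one protein in a single call."""
    models = models if models is not None else default_models()
    arch = chain_motifs(scan_motifs(protein, models), adjacency_bonus)
    _, status = classify_rfl(arch, protein, rfl_min_p, full_length_min_aa)
    return RflGene(id=gene_id, genotype=genotype, protein=protein,
                   architecture=arch, status=status, dna=dna)
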