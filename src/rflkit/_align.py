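"""Shared pairwise-alignment kernels.

Two engines are used behind the public module surfaces:

* an affine-gap local (Smith-Waterman/Gotoh) aligner, compiled with numba,
  for protein/dna identity computations where CD-HIT-style statistics
  (identity over alignment columns, aligned span on the shorter sequence)
  are needed.  The traceback is deterministic: among co-optimal moves the
  order of preference is diagonal, then vertical (gap in the second
  sequence), then horizontal; the alignment endpoint is the first maximal
  cell in row-major order.  A gap of length L costs open + L*extend.
* edlib in infix ("HW") mode for mapping-style questions (where does this
  gene/ORF best fit inside a long reference, and how similar is the best
  full-query placement), where an edit-distance similarity is the right
  statistic and speed matters.

Scoring: BLOSUM62 for protein (X and * score 0 against everything,
neutral); +1 match / -2 mismatch for dna with N neutral.  Default gap
penalties: protein open 10 extend 1, dna open 5 extend 2.
"""

from __future__ import annotations

import numpy as np
from numba import njit

try:  # Bio >= 1.75
    from Bio.Align import substitution_matrices
except ImportError:  # pragma: no cover
    substitution_matrices = None

from .formats import ParameterError

PROTEIN_ORDER = "ACDEFGHIKLMNPQRSTVWYX*"
DNA_ORDER = "ACGTN"

_PROT_INDEX = {c: i for i, c in enumerate(PROTEIN_ORDER)}
_DNA_INDEX = {c: i for i, c in enumerate(DNA_ORDER)}


def _build_protein_matrix() -> np.ndarray:
    m = np.zeros((len(PROTEIN_ORDER), len(PROTEIN_ORDER)), dtype=np.float64)
    blosum = substitution_matrices.load("BLOSUM62")
    for i, a in enumerate(PROTEIN_ORDER):
        for j, b in enumerate(PROTEIN_ORDER):
            if a in "X*" or b in "X*":
                m[i, j] = 0.0  # unknown/stop residues are neutral
            else:
                m[i, j] = float(blosum[a, b])
    return m


def _build_dna_matrix(match: float = 1.0, mismatch: float = -2.0) -> np.ndarray:
    n = len(DNA_ORDER)
    m = np.full((n, n), mismatch, dtype=np.float64)
    np.fill_diagonal(m, match)
    m[_DNA_INDEX["N"], :] = 0.0  # N is neutral
    m[:, _DNA_INDEX["N"]] = 0.0
    return m


PROTEIN_MATRIX = _build_protein_matrix()
DNA_MATRIX = _build_dna_matrix()

# wildcard codes never count as identities
_PROT_WILDCARD = _PROT_INDEX["X"]
_DNA_WILDCARD = _DNA_INDEX["N"]


def encode(seq: str, alphabet: str) -> np.ndarray:
    index = _PROT_INDEX if alphabet == "protein" else _DNA_INDEX
    try:
        return np.array([index[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ParameterError(f"symbol {exc} not valid for {alphabet}") from exc


@njit(cache=True)
def _sw_affine(a, b, score, gap_open, gap_extend, wildcard):
    """Local affine-gap DP with deterministic traceback.

    Returns (score, matches, columns, a_start, a_end, b_start, b_end),
    all coordinates 0-based half-open on the unaligned inputs.
    """
    n, m = len(a), len(b)
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b, horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a, vertical)
    # pointers: for H 0=stop 1=diag 2=fromF 3=fromE; for E/F 0=open 1=extend
    PH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PF = np.zeros((n + 1, m + 1), dtype=np.uint8)

    best = 0.0
    bi, bj = 0, 0
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - first_gap
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 0
            else:
                E[i, j] = e_ext
                PE[i, j] = 1
            f_open = H[i - 1, j] - first_gap
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 0
            else:
                F[i, j] = f_ext
                PF[i, j] = 1
            diag = H[i - 1, j - 1] + score[a[i - 1], b[j - 1]]
            # preference on ties: diag > vertical (F) > horizontal (E); the
            # path never passes through non-positive cells (restart at 0)
            h, p = 0.0, 0
            if E[i, j] > 0.0:
                h, p = E[i, j], 3
            if F[i, j] >= h and F[i, j] > 0.0:
                h, p = F[i, j], 2
            if diag >= h and diag > 0.0:
                h, p = diag, 1
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi, bj = i, j

    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0

    # traceback
    matches = 0
    columns = 0
    i, j = bi, bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != wildcard:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: gap in a, consume b
            columns += 1
            p = PE[i, j]
            j -= 1
            state = 0 if p == 0 else 1
        else:  # F: gap in b, consume a
            columns += 1
            p = PF[i, j]
            i -= 1
            state = 0 if p == 0 else 2
    return best, matches, columns, i, bi, j, bj


def local_align(a: str, b: str, alphabet: str = "protein",
                gap_open: float | None = None,
                gap_extend: float | None = None):
    """Best local alignment of two sequences.

    Returns a dict with score, matches, columns, identity and the aligned
    spans (0-based half-open) on each sequence.
    """
    if alphabet == "protein":
        matrix = PROTEIN_MATRIX
        wildcard = _PROT_WILDCARD
        go = 10.0 if gap_open is None else gap_open
        ge = 1.0 if gap_extend is None else gap_extend
    elif alphabet == "dna":
        matrix = DNA_MATRIX
        wildcard = _DNA_WILDCARD
        go = 5.0 if gap_open is None else gap_open
        ge = 2.0 if gap_extend is None else gap_extend
    else:
        raise ParameterError(f"unknown alphabet {alphabet!r}")
    if not a or not b:
        return {
            "score": 0.0, "matches": 0, "columns": 0, "identity": 0.0,
            "a_span": (0, 0), "b_span": (0, 0),
        }
    sc, matches, columns, ai, aj, bi, bj = _sw_affine(
        encode(a, alphabet), encode(b, alphabet), matrix, go, ge, wildcard
    )
    identity = matches / columns if columns else 0.0
    return {
        "score": float(sc), "matches": int(matches), "columns": int(columns),
        "identity": identity, "a_span": (int(ai), int(aj)),
        "b_span": (int(bi), int(bj)),
    }


def infix_similarity(query: str, target: str):
    """Best full-query placement of `query` inside `target` via edlib.

    Similarity is 1 - edit_distance/len(query); gaps and end-trimming both
    count against it, so it lower-bounds identity*coverage of the best
    single local alignment.  Returns (similarity, target_start, target_end).
    """
    import edlib

    if not query or not target:
        return 0.0, 0, 0
    res = edlib.align(query, target, mode="HW", task="locations")
    dist = res["editDistance"]
    sim = max(0.0, 1.0 - dist / len(query))
    if res["locations"]:
        s, e = res["locations"][0]
        return sim, int(s), int(e) + 1
    return sim, 0, 0
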