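"""Independent reference implementations used as test oracles.

These are deliberately simple, brute-force or textbook implementations,
kept separate from the package code paths they check.
"""

from __future__ import annotations

import math

from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# six-frame ORF enumeration (brute force via Biopython translation)
# ---------------------------------------------------------------------------

def bruteforce_orfs(seq: str, min_nt: int):
    """All maximal stop-free between-stop stretches >= min_nt, as a set of
    (start, end, strand) forward-strand coordinate triples."""
    L = len(seq)
    out = set()
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            trimmed = s[frame:]
            trimmed = trimmed[: len(trimmed) - (len(trimmed) % 3)]
            aa = str(Seq(trimmed).translate())
            start_codon = 0
            for chunk in aa.split("*"):
                if len(chunk) * 3 >= min_nt and chunk:
                    ws = frame + 3 * start_codon
                    we = ws + 3 * len(chunk)
                    if strand == "+":
                        out.add((ws, we, strand))
                    else:
                        out.add((L - we, L - ws, strand))
                start_codon += len(chunk) + 1
    return out


# ---------------------------------------------------------------------------
# exhaustive non-overlapping chain enumeration
# ---------------------------------------------------------------------------

def best_chain_score(hits, bonus: float) -> float:
    """Max over all non-overlapping subsets of sum(score) + bonus*adjacent."""
    n = len(hits)
    hits = sorted(hits, key=lambda h: (h.aa_start, h.aa_end))
    best = 0.0
    for mask in range(1, 1 << n):
        chosen = [hits[i] for i in range(n) if mask >> i & 1]
        ok = all(chosen[i].aa_end <= chosen[i + 1].aa_start
                 for i in range(len(chosen) - 1))
        if not ok:
            continue
        total = sum(h.score for h in chosen)
        total += bonus * sum(
            1 for i in range(len(chosen) - 1)
            if chosen[i + 1].aa_start - chosen[i].aa_end <= 2
        )
        best = max(best, total)
    return best


# ---------------------------------------------------------------------------
# textbook affine-gap local alignment (Gotoh), pure python
# ---------------------------------------------------------------------------

def gotoh_local(a: str, b: str, score_fn, gap_open: float, gap_extend: float):
    """Smith-Waterman with affine gaps; returns (score, matches, columns).

    Tie conventions match the package's documented ones: on equal cell
    scores prefer diagonal over vertical over horizontal, never pass
    through non-positive cells, and end at the first maximal cell in
    row-major order.  gap cost = open + L*extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    PH = [[0] * (m + 1) for _ in range(n + 1)]
    PE = [[0] * (m + 1) for _ in range(n + 1)]
    PF = [[0] * (m + 1) for _ in range(n + 1)]
    first = gap_open + gap_extend
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo, ee = H[i][j - 1] - first, E[i][j - 1] - gap_extend
            E[i][j], PE[i][j] = (eo, 0) if eo >= ee else (ee, 1)
            fo, fe = H[i - 1][j] - first, F[i - 1][j] - gap_extend
            F[i][j], PF[i][j] = (fo, 0) if fo >= fe else (fe, 1)
            diag = H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            h, p = 0.0, 0
            if E[i][j] > 0:
                h, p = E[i][j], 3
            if F[i][j] >= h and F[i][j] > 0:
                h, p = F[i][j], 2
            if diag >= h and diag > 0:
                h, p = diag, 1
            H[i][j], PH[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return 0.0, 0, 0
    i, j, state = bi, bj, 0
    matches = columns = 0
    while True:
        if state == 0:
            p = PH[i][j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if a[i - 1] == b[j - 1] and a[i - 1] not in "X*":
                    matches += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            columns += 1
            p = PE[i][j]
            j -= 1
            state = 0 if p == 0 else 1
        else:
            columns += 1
            p = PF[i][j]
            i -= 1
            state = 0 if p == 0 else 2
    return best, matches, columns


def blosum62_score_fn():
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")

    def fn(x: str, y: str) -> float:
        if x in "X*" or y in "X*":
            return 0.0
        return float(m[x, y])

    return fn


# ---------------------------------------------------------------------------
# naive binding-site scoring
# ---------------------------------------------------------------------------

def naive_window_score(pairs, window: str, table) -> float:
    total = 0.0
    for pair, base in zip(pairs, window):
        if base == "N":
            total += math.log(table.pseudo)
            continue
        base = "U" if base == "T" else base
        vec = table.scores.get(tuple(pair))
        if vec is None:
            total += math.log(table.pseudo)
        else:
            total += math.log(float(vec["ACGU".index(base)]))
    return total


def argmax_window(pairs, transcript: str, table):
    """(best_start, best_total) by exhaustive scan, leftmost on ties."""
    k = len(pairs)
    best_start, best_total = 0, float("-inf")
    for s in range(len(transcript) - k + 1):
        t = naive_window_score(pairs, transcript[s:s + k], table)
        if t > best_total:
            best_total, best_start = t, s
    return best_start, best_total


# ---------------------------------------------------------------------------
# size factors / TPM formula re-implementations
# ---------------------------------------------------------------------------

def size_factors_formula(counts, sample_ids):
    import numpy as np

    keep = (counts > 0).all(axis=1)
    sub = counts[keep]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    return {s: float(np.median(sub[:, j] / geo))
            for j, s in enumerate(sample_ids)}


def tpm_formula(counts, lengths):
    import numpy as np

    rate = counts / lengths[:, None]
    return 1e6 * rate / rate.sum(axis=0, keepdims=True)
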