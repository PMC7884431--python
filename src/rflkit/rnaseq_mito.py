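"""Expression normalisation, fertile/sterile contrasts and coverage-based
cleavage-site localisation.

Counts are normalised with the DESeq2-style pseudoreference (median of
ratios) method and summarised as TPM, PCA of log counts, and hierarchical
clustering of per-stage fertile/sterile log2 ratios.  Strand-specific
coverage is normalised to unit mean over unmasked positions; a
restorer-induced cleavage site appears as a sharp 5'-low / 3'-high step
in the fertile/sterile coverage ratio (the 5' cleavage product is
degraded, the 3' product persists), localised by scanning a two-window
fold statistic along the transcript and calling its argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .formats import CountMatrix, CoverageTrack, ParameterError

__all__ = [
    "CleavageParams",
    "CleavageCall",
    "size_factors",
    "tpm",
    "contrast_cluster",
    "pca_samples",
    "normalize_coverage",
    "detect_cleavage",
]

COUNT_PSEUDO = 0.5        # added to normalised counts before log ratios
COVERAGE_PSEUDO = 0.05    # added to normalised coverage before ratios


@dataclass
class CleavageParams:
    window_w: int = 50
    min_fold: float = 3.0
    min_depth: float = 10.0               # pre-normalisation sterile depth
    search_region: tuple[int, int] | None = None   # genomic, 0-based half-open

    def __post_init__(self) -> None:
        if self.window_w < 5:
            raise ParameterError("window_w must be >= 5")


@dataclass
class CleavageCall:
    ref_id: str
    strand: str
    position: int            # genomic 0-based boundary position
    fold: float              # right-window mean ratio / left-window mean (5'->3')
    passed: bool
    direction: str = "low_to_high"


def size_factors(counts: CountMatrix) -> dict[str, float]:
    """Median-of-ratios (pseudoreference) per-sample size factors.

    The pseudoreference is the per-gene geometric mean across samples
    (genes with any zero count excluded); each sample's factor is the
    median of its count/pseudoreference ratios.
    """
    if len(counts.sample_ids) < 2:
        raise ParameterError("size factors require at least 2 samples")
    c = counts.counts
    all_pos = np.all(c > 0, axis=1)
    if not np.any(all_pos):
        raise ParameterError(
            "no gene has positive counts in every sample; filter the matrix"
        )
    sub = c[all_pos]
    pseudo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    factors = np.median(sub / pseudo, axis=0)
    return dict(zip(counts.sample_ids, factors.tolist()))


def normalized_counts(counts: CountMatrix) -> np.ndarray:
    f = size_factors(counts)
    return counts.counts / np.array([f[s] for s in counts.sample_ids])


def tpm(counts: CountMatrix) -> np.ndarray:
    """Transcripts-per-million; each column sums to 1e6."""
    rate = counts.counts / counts.lengths[:, None]
    colsum = rate.sum(axis=0)
    if np.any(colsum == 0):
        raise ParameterError("sample with zero total counts")
    return 1e6 * rate / colsum


def contrast_cluster(counts: CountMatrix, contrasts):
    """Per-stage fertile/sterile log2 ratios, hierarchically ordered.

    ``contrasts`` is a list of (fertile_sample, sterile_sample, label)
    with matched developmental stages.  Returns (ordered transcript ids,
    ratio matrix in that order, labels).  Gene order comes from
    average-linkage hierarchical clustering on Euclidean distances.
    """
    norm = normalized_counts(counts)
    idx = {s: j for j, s in enumerate(counts.sample_ids)}
    for fert, ster, _ in contrasts:
        if fert not in idx or ster not in idx:
            raise ParameterError(f"contrast samples {fert!r}/{ster!r} not in matrix")
    ratios = np.column_stack([
        np.log2((norm[:, idx[f]] + COUNT_PSEUDO) / (norm[:, idx[s]] + COUNT_PSEUDO))
        for f, s, _ in contrasts
    ])
    labels = [lab for _, _, lab in contrasts]
    if ratios.shape[0] > 2:
        d = pdist(ratios, metric="euclidean")
        if np.all(d == 0):
            order = np.arange(ratios.shape[0])
        else:
            order = leaves_list(linkage(d, method="average"))
    else:
        order = np.arange(ratios.shape[0])
    ids = [counts.transcript_ids[i] for i in order]
    return ids, ratios[order], labels


def pca_samples(counts: CountMatrix):
    """PCA of samples on log2(normalised count + 1), feature-centred SVD.

    Returns (coordinates: samples x components, variance_fractions).
    """
    if len(counts.sample_ids) < 3:
        raise ParameterError("PCA requires at least 3 samples")
    x = np.log2(normalized_counts(counts) + 1.0).T    # samples x genes
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float((s ** 2).sum())
    if total == 0:
        return np.zeros_like(u), np.zeros_like(s)
    return u * s, (s ** 2) / total


def normalize_coverage(track: CoverageTrack) -> CoverageTrack:
    """Scale depth so that the mean over unmasked positions is 1.

    Masks are preserved; idempotent on already-normalised tracks.  The
    pre-normalisation unmasked mean is retained in ``norm_mean`` so later
    depth thresholds can be applied on the raw scale.
    """
    if track.normalised:
        return replace(track, depth=track.depth.copy())
    keep = track.unmasked()
    if not np.any(keep):
        raise ParameterError("cannot normalise an entirely masked track")
    mean = float(track.depth[keep].mean())
    if mean == 0:
        raise ParameterError("cannot normalise a zero-coverage track")
    return CoverageTrack(
        ref_id=track.ref_id,
        strand=track.strand,
        depth=track.depth / mean,
        masks=list(track.masks),
        normalised=True,
        norm_mean=mean,
    )


def detect_cleavage(fertile: CoverageTrack, sterile: CoverageTrack,
                    params: CleavageParams | None = None,
                    transcript_strand: str = "+") -> CleavageCall:
    """Locate the low->high transition of the fertile/sterile ratio.

    The per-base ratio r = (fertile + c) / (sterile + c) is scanned in
    transcript 5'->3' orientation with the statistic
    s(i) = mean r[i, i+w) / mean r[i-w, i); the call is the argmax
    boundary.  It passes when the fold reaches ``min_fold`` and the
    sterile track held at least ``min_depth`` raw coverage in both
    windows.  The returned position is genomic (0-based boundary).
    """
    params = params or CleavageParams()
    if not (fertile.normalised and sterile.normalised):
        raise ParameterError("detect_cleavage expects normalised tracks")
    if len(fertile.depth) != len(sterile.depth):
        raise ParameterError("tracks must cover the same reference")
    if fertile.strand != sterile.strand:
        raise ParameterError("tracks must be from the same strand")
    n = len(fertile.depth)
    w = params.window_w
    f = fertile.depth
    s = sterile.depth
    region = params.search_region or (0, n)
    if transcript_strand == "-":
        f = f[::-1]
        s = s[::-1]
        region = (n - region[1], n - region[0])
    lo = max(region[0], w)
    hi = min(region[1], n - w)
    if hi - lo < 1 or region[1] - region[0] < 2 * w:
        raise ParameterError("search region shorter than two windows")
    r = (f + COVERAGE_PSEUDO) / (s + COVERAGE_PSEUDO)
    cs = np.concatenate(([0.0], np.cumsum(r)))
    bounds = np.arange(lo, hi)
    right = (cs[bounds + w] - cs[bounds]) / w
    left = (cs[bounds] - cs[bounds - w]) / w
    stat = right / left
    k = int(np.argmax(stat))
    pos_t = int(bounds[k])
    fold = float(stat[k])
    raw_scale = sterile.norm_mean if sterile.norm_mean is not None else 1.0
    s_raw = s * raw_scale
    cs_s = np.concatenate(([0.0], np.cumsum(s_raw)))
    depth_left = (cs_s[pos_t] - cs_s[pos_t - w]) / w
    depth_right = (cs_s[pos_t + w] - cs_s[pos_t]) / w
    passed = fold >= params.min_fold and min(depth_left, depth_right) >= params.min_depth
    position = pos_t if transcript_strand == "+" else n - pos_t
    return CleavageCall(
        ref_id=fertile.ref_id,
        strand=fertile.strand,
        position=position,
        fold=fold,
        passed=passed,
    )
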