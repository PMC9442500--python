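"""Pairwise alignment-free similarity and distance metrics on k-mer vectors.

All metrics except the raw D2 statistic are oriented so that *lower* scores
mean *more similar* sequences.  Count-based metrics (D2, cosine/d2,
Bray-Curtis, NGD, d2star, d2s) take :class:`~kmercomp.kmer_core.CountVector`
inputs; the Minkowski family and the normalised Canberra distance operate on
:class:`~kmercomp.kmer_core.FrequencyVector` so that sequences of different
length are compared on the same simplex.

The D2 statistic for a reference *r* and query *q* is

    D2(r, q) = sum_w C_r(w) * C_q(w)

over the word space, where C(w) are k-mer occurrence counts.  Its cosine
normalisation divides by the Euclidean norms of the count vectors, and the
``d2`` distance maps the cosine onto a distance via 0.5 * (1 - cosine).

The Markov-corrected statistics d2star and d2s replace raw counts by centred
counts X~_w = C(w) - n * p_w, with p_w the order-0 background word
probability estimated separately for each sequence; they are defined for DNA
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kmer_core import CountVector, FrequencyVector, MarkovBackground

__all__ = [
    "MetricId",
    "METRICS",
    "get_metric",
    "d2_raw",
    "cosine",
    "d2_distance",
    "minkowski_family",
    "normalised_canberra",
    "bray_curtis",
    "ngd",
    "d2star",
    "d2s",
    "compute_score",
]


@dataclass(frozen=True)
class MetricId:
    """Declared contract of one metric: inputs, score range, orientation."""

    name: str
    input_kind: str  # "counts" | "frequencies" | "counts+background"
    score_range: tuple[float, float]
    lower_is_similar: bool = True
    dna_ok: bool = True
    aa_ok: bool = True


METRICS: dict[str, MetricId] = {
    m.name: m
    for m in (
        MetricId("d2raw", "counts", (0.0, math.inf), lower_is_similar=False),
        MetricId("d2", "counts", (0.0, 1.0)),
        MetricId("euclid", "frequencies", (0.0, math.sqrt(2.0))),
        MetricId("manh", "frequencies", (0.0, 2.0)),
        MetricId("cheby", "frequencies", (0.0, 1.0)),
        MetricId("ncanb", "frequencies", (0.0, 1.0)),
        MetricId("bc", "counts", (0.0, 1.0)),
        MetricId("ngd", "counts", (0.0, 1.0)),
        MetricId("d2star", "counts+background", (0.0, 1.0), aa_ok=False),
        MetricId("d2s", "counts+background", (0.0, 1.0), aa_ok=False),
    )
}

_ALIASES = {"ncamb": "ncanb"}


def get_metric(name: str) -> MetricId:
    """Resolve a metric by name (``ncamb`` accepted as alias of ``ncanb``)."""
    name = _ALIASES.get(name, name)
    try:
        return METRICS[name]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}; expected one of {sorted(METRICS)}") from None


def _check_spec(a, b) -> None:
    if a.spec != b.spec:
        raise ValueError("vectors were built under different KmerSpecs")


def d2_raw(cr: CountVector, cq: CountVector) -> float:
    """Raw D2: sum over the word space of count products (higher = more similar)."""
    _check_spec(cr, cq)
    small, large = (cr.counts, cq.counts) if len(cr.counts) <= len(cq.counts) else (cq.counts, cr.counts)
    return float(sum(c * large[w] for w, c in small.items() if w in large))


def cosine(cr: CountVector, cq: CountVector) -> float:
    """Cosine similarity of count vectors: D2 over the product of Euclidean norms."""
    _check_spec(cr, cq)
    norm_r = math.sqrt(sum(c * c for c in cr.counts.values()))
    norm_q = math.sqrt(sum(c * c for c in cq.counts.values()))
    if norm_r == 0.0 or norm_q == 0.0:
        raise ValueError("cosine is undefined for a zero count vector")
    return d2_raw(cr, cq) / (norm_r * norm_q)


def d2_distance(cr: CountVector, cq: CountVector) -> float:
    """Distance form of D2: 0.5 * (1 - cosine); 0 for identical direction."""
    return 0.5 * (1.0 - cosine(cr, cq))


def minkowski_family(fr: FrequencyVector, fq: FrequencyVector, which: str) -> float:
    """Euclidean / Manhattan / Chebyshev distance between frequency vectors."""
    _check_spec(fr, fq)
    words = set(fr.freqs) | set(fq.freqs)
    diffs = [abs(fr.freqs.get(w, 0.0) - fq.freqs.get(w, 0.0)) for w in words]
    if which == "euclid":
        return math.sqrt(sum(d * d for d in diffs))
    if which == "manh":
        return float(sum(diffs))
    if which == "cheby":
        return max(diffs, default=0.0)
    raise ValueError(f"unknown Minkowski variant {which!r}")


def normalised_canberra(fr: FrequencyVector, fq: FrequencyVector) -> float:
    """Canberra distance averaged over words with non-zero combined frequency.

    Each word with x_w + y_w > 0 contributes |x_w - y_w| / (x_w + y_w); the
    sum is divided by the number of contributing words so the result lies in
    [0, 1] regardless of k.
    """
    _check_spec(fr, fq)
    words = set(fr.freqs) | set(fq.freqs)
    terms = []
    for w in words:
        x, y = fr.freqs.get(w, 0.0), fq.freqs.get(w, 0.0)
        if x + y > 0.0:
            terms.append(abs(x - y) / (x + y))
    if not terms:
        raise ValueError("normalised Canberra is undefined for two all-zero vectors")
    return sum(terms) / len(terms)


def _shared_count(cr: CountVector, cq: CountVector) -> int:
    small, large = (cr.counts, cq.counts) if len(cr.counts) <= len(cq.counts) else (cq.counts, cr.counts)
    return sum(min(c, large[w]) for w, c in small.items() if w in large)


def bray_curtis(cr: CountVector, cq: CountVector) -> float:
    """Bray-Curtis dissimilarity: 1 - 2*C_ij / (S_i + S_j).

    C_ij sums, over words present in both sequences, the lesser of the two
    counts; S_i and S_j are the total counts.  Assumes the two "sites" are of
    comparable size -- with very unequal totals the score saturates.
    """
    _check_spec(cr, cq)
    if cr.total + cq.total == 0:
        raise ValueError("Bray-Curtis is undefined for two empty vectors")
    return 1.0 - 2.0 * _shared_count(cr, cq) / (cr.total + cq.total)


def ngd(cr: CountVector, cq: CountVector) -> float:
    """Normalised Google Distance on k-mer counts.

    NGD = (max(S_i, S_j) - C_ij) / ((S_i + S_j) - min(S_i, S_j)), with C_ij
    the shared-count sum of :func:`bray_curtis`.  When one sequence is much
    longer than the other, NGD >= (S_long - S_short) / S_long, so the score
    is pushed towards 1 regardless of similarity.
    """
    _check_spec(cr, cq)
    s_max, s_min = max(cr.total, cq.total), min(cr.total, cq.total)
    if s_max == 0:
        raise ValueError("NGD is undefined for two empty vectors")
    return (s_max - _shared_count(cr, cq)) / ((cr.total + cq.total) - s_min)


def _centered_dense(
    c: CountVector, bg: MarkovBackground
) -> tuple[np.ndarray, np.ndarray, int]:
    probs = bg.word_probs_dense(c.spec)
    dense = c.dense()
    if np.any((probs == 0.0) & (dense > 0.0)):
        raise ValueError("background probability 0 for an observed word")
    return dense - c.total * probs, probs, c.total


def d2star(
    cr: CountVector, br: MarkovBackground, cq: CountVector, bq: MarkovBackground
) -> float:
    """Markov-standardised D2 distance (DNA only).

    Centred counts are standardised by sqrt(n * p_w) per sequence; the
    correlation-like statistic D2* is mapped onto [0, 1] via
    0.5 * (1 - D2*/ (||X~ / sqrt(n_r p)|| * ||Y~ / sqrt(n_q p)||)).
    Words with zero background probability in either sequence are skipped.
    """
    if cr.spec.alphabet.name != "dna":
        raise ValueError("d2star is defined for DNA only")
    _check_spec(cr, cq)
    if cr.total == 0 or cq.total == 0:
        raise ValueError("d2star is undefined for an empty count vector")
    xt, pr, nr = _centered_dense(cr, br)
    yt, pq, nq = _centered_dense(cq, bq)
    keep = (pr > 0.0) & (pq > 0.0)
    xt, yt, pr, pq = xt[keep], yt[keep], pr[keep], pq[keep]
    num = float(np.sum(xt * yt / (math.sqrt(nr * nq) * np.sqrt(pr * pq))))
    norm_x = math.sqrt(float(np.sum(xt * xt / (nr * pr))))
    norm_y = math.sqrt(float(np.sum(yt * yt / (nq * pq))))
    if norm_x == 0.0 or norm_y == 0.0:
        raise ValueError("d2star is undefined: a centred vector is identically zero")
    return 0.5 * (1.0 - num / (norm_x * norm_y))


def d2s(
    cr: CountVector, br: MarkovBackground, cq: CountVector, bq: MarkovBackground
) -> float:
    """Self-standardised D2 distance (DNA only).

    Each word is scaled by sqrt(X~_w^2 + Y~_w^2); words where both centred
    counts vanish are skipped.  The statistic is mapped onto [0, 1] the same
    way as :func:`d2star`.
    """
    if cr.spec.alphabet.name != "dna":
        raise ValueError("d2s is defined for DNA only")
    _check_spec(cr, cq)
    if cr.total == 0 or cq.total == 0:
        raise ValueError("d2s is undefined for an empty count vector")
    xt, _, _ = _centered_dense(cr, br)
    yt, _, _ = _centered_dense(cq, bq)
    denom = np.sqrt(xt * xt + yt * yt)
    keep = denom > 0.0
    xt, yt, denom = xt[keep], yt[keep], denom[keep]
    num = float(np.sum(xt * yt / denom))
    norm_x = math.sqrt(float(np.sum(xt * xt / denom)))
    norm_y = math.sqrt(float(np.sum(yt * yt / denom)))
    if norm_x == 0.0 or norm_y == 0.0:
        raise ValueError("d2s is undefined: a centred vector is identically zero")
    return 0.5 * (1.0 - num / (norm_x * norm_y))


def compute_score(
    metric: MetricId | str,
    cr: CountVector,
    cq: CountVector,
    fr: FrequencyVector | None = None,
    fq: FrequencyVector | None = None,
    br: MarkovBackground | None = None,
    bq: MarkovBackground | None = None,
) -> float:
    """Dispatch a metric by name on prepared vectors (used by the search engine)."""
    if isinstance(metric, str):
        metric = get_metric(metric)
    name = metric.name
    if name == "d2raw":
        return d2_raw(cr, cq)
    if name == "d2":
        return d2_distance(cr, cq)
    if name in ("euclid", "manh", "cheby"):
        assert fr is not None and fq is not None
        return minkowski_family(fr, fq, name)
    if name == "ncanb":
        assert fr is not None and fq is not None
        return normalised_canberra(fr, fq)
    if name == "bc":
        return bray_curtis(cr, cq)
    if name == "ngd":
        return ngd(cr, cq)
    if name == "d2star":
        assert br is not None and bq is not None
        return d2star(cr, br, cq, bq)
    if name == "d2s":
        assert br is not None and bq is not None
        return d2s(cr, br, cq, bq)
    raise ValueError(f"unknown metric {name!r}")
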