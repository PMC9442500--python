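"""Brute-force reference implementations used only as test oracles.

Everything here is written as straight-line code over plain dicts and
strings, independent of the package internals, so that agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import math
from itertools import product

DNA_SYMBOLS = "ACGT"


def naive_count(seq: str, k: int, masks: tuple[str, ...] = (), ambiguity: str = "N") -> dict[str, int]:
    """O(n*k) substring-scan k-mer counter with ambiguity-window skipping."""
    if not masks:
        masks = ("1" * k,)
    counts: dict[str, int] = {}
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        if any(c in ambiguity for c in window):
            continue
        for mask in masks:
            word = "".join(c for c, bit in zip(window, mask) if bit == "1")
            counts[word] = counts.get(word, 0) + 1
    return counts


def naive_freq(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {w: c / total for w, c in counts.items()} if total else {}


def naive_d2raw(cr: dict, cq: dict) -> float:
    return float(sum(c * cq.get(w, 0) for w, c in cr.items()))


def naive_cosine(cr: dict, cq: dict) -> float:
    nr = math.sqrt(sum(c * c for c in cr.values()))
    nq = math.sqrt(sum(c * c for c in cq.values()))
    return naive_d2raw(cr, cq) / (nr * nq)


def naive_minkowski(fr: dict, fq: dict, which: str) -> float:
    words = set(fr) | set(fq)
    diffs = [abs(fr.get(w, 0.0) - fq.get(w, 0.0)) for w in words]
    if which == "euclid":
        return math.sqrt(sum(d * d for d in diffs))
    if which == "manh":
        return sum(diffs)
    return max(diffs, default=0.0)


def naive_ncanb(fr: dict, fq: dict) -> float:
    words = set(fr) | set(fq)
    terms = [
        abs(fr.get(w, 0.0) - fq.get(w, 0.0)) / (fr.get(w, 0.0) + fq.get(w, 0.0))
        for w in words
        if fr.get(w, 0.0) + fq.get(w, 0.0) > 0
    ]
    return sum(terms) / len(terms)


def naive_shared(cr: dict, cq: dict) -> int:
    return sum(min(c, cq.get(w, 0)) for w, c in cr.items())


def naive_bc(cr: dict, cq: dict) -> float:
    si, sj = sum(cr.values()), sum(cq.values())
    return 1.0 - 2.0 * naive_shared(cr, cq) / (si + sj)


def naive_ngd(cr: dict, cq: dict) -> float:
    si, sj = sum(cr.values()), sum(cq.values())
    return (max(si, sj) - naive_shared(cr, cq)) / ((si + sj) - min(si, sj))


def _letter_probs(seq: str) -> dict[str, float]:
    counts: dict[str, int] = {}
    for c in seq:
        if c in DNA_SYMBOLS:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    return {c: v / total for c, v in counts.items()}


def naive_d2star_d2s(r: str, q: str, k: int) -> tuple[float, float]:
    """Straight-line evaluation of both Markov-corrected distances for DNA."""
    cr, cq = naive_count(r, k), naive_count(q, k)
    nr, nq = sum(cr.values()), sum(cq.values())
    pr, pq = _letter_probs(r), _letter_probs(q)
    num_star = nx = ny = 0.0
    num_s = nxs = nys = 0.0
    for w in map("".join, product(DNA_SYMBOLS, repeat=k)):
        p_r = math.prod(pr.get(c, 0.0) for c in w)
        p_q = math.prod(pq.get(c, 0.0) for c in w)
        x = cr.get(w, 0) - nr * p_r
        y = cq.get(w, 0) - nq * p_q
        if p_r > 0 and p_q > 0:
            num_star += x * y / (math.sqrt(nr * nq) * math.sqrt(p_r * p_q))
            nx += x * x / (nr * p_r)
            ny += y * y / (nq * p_q)
        den = math.hypot(x, y)
        if den > 0:
            num_s += x * y / den
            nxs += x * x / den
            nys += y * y / den
    d2star = 0.5 * (1 - num_star / (math.sqrt(nx) * math.sqrt(ny)))
    d2s = 0.5 * (1 - num_s / (math.sqrt(nxs) * math.sqrt(nys)))
    return d2star, d2s


def naive_spearman(x: list[float], y: list[float]) -> float:
    """Spearman rho via explicit average ranks and Pearson on ranks."""

    def ranks(v: list[float]) -> list[float]:
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    vy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return cov / (vx * vy)
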