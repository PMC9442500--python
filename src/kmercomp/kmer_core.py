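"""K-mer count and frequency vectors, spaced-seed masks, Markov backgrounds.

A sequence of length *n* yields ``n - k + 1`` sliding windows of width *k*;
each window contributes one word per mask (the contiguous case behaves as a
single all-'1' mask).  Windows containing an ambiguity symbol are skipped
entirely, so the realised total can fall below the window count.  Frequencies
divide by the realised total, which keeps them summing to one even when
ambiguous windows were dropped.

The order-0 Markov background models a sequence by its single-letter
composition: the expected probability of a word is the product of its letter
probabilities, and centred counts (observed minus expected) are the raw
material of the D2-family statistics in :mod:`kmercomp.metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sequence_io import Alphabet, SequenceRecord

__all__ = [
    "KmerSpec",
    "CountVector",
    "FrequencyVector",
    "MarkovBackground",
    "word_space_size",
    "count_kmers",
    "to_frequencies",
    "fit_background",
]


@dataclass(frozen=True)
class KmerSpec:
    """Word-space definition: alphabet, k, and optional binary masks.

    Each mask is a string of '0'/'1' of length ``k``; only '1' positions
    contribute letters to the emitted word.  All masks must select the same
    number of positions because their counts share one word space.  An empty
    mask list means contiguous k-mers.
    """

    alphabet: Alphabet
    k: int
    masks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        object.__setattr__(self, "masks", tuple(self.masks))
        widths = set()
        for mask in self.masks:
            if len(mask) != self.k:
                raise ValueError(f"mask {mask!r} length {len(mask)} != k={self.k}")
            if set(mask) - {"0", "1"}:
                raise ValueError(f"mask {mask!r} must be binary")
            ones = mask.count("1")
            if ones == 0:
                raise ValueError(f"mask {mask!r} selects no positions")
            widths.add(ones)
        if len(widths) > 1:
            raise ValueError("all masks must select the same number of positions")

    @property
    def width(self) -> int:
        """Number of letters in an emitted word (mask weight, or k unmasked)."""
        return self.masks[0].count("1") if self.masks else self.k

    @property
    def n_masks(self) -> int:
        return len(self.masks) if self.masks else 1

    def effective_masks(self) -> tuple[str, ...]:
        return self.masks if self.masks else ("1" * self.k,)


def word_space_size(spec: KmerSpec) -> int:
    """Size of the word space: ``|alphabet| ** width`` (e.g. 4**4 = 256 for DNA 4-mers)."""
    return spec.alphabet.size ** spec.width


@dataclass(frozen=True)
class CountVector:
    """Per-word occurrence counts for one sequence under a :class:`KmerSpec`."""

    spec: KmerSpec
    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of counts")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    def dense(self) -> np.ndarray:
        """Counts as a dense array indexed by base-|alphabet| word value."""
        base = self.spec.alphabet.size
        arr = np.zeros(word_space_size(self.spec), dtype=np.float64)
        for word, c in self.counts.items():
            arr[_word_value(word, self.spec.alphabet)] = c
        return arr


@dataclass(frozen=True)
class FrequencyVector:
    """Normalised k-mer frequencies; all-zero when the sequence had no countable window."""

    spec: KmerSpec
    freqs: Mapping[str, float]
    total_kmers: int

    def dense(self) -> np.ndarray:
        base = self.spec.alphabet.size
        arr = np.zeros(word_space_size(self.spec), dtype=np.float64)
        for word, f in self.freqs.items():
            arr[_word_value(word, self.spec.alphabet)] = f
        return arr


def _word_value(word: str, alphabet: Alphabet) -> int:
    value = 0
    for c in word:
        value = value * alphabet.size + alphabet.index(c)
    return value


def _value_word(value: int, width: int, alphabet: Alphabet) -> str:
    letters = []
    for _ in range(width):
        value, r = divmod(value, alphabet.size)
        letters.append(alphabet.symbols[r])
    return "".join(reversed(letters))


def encode(record: SequenceRecord) -> np.ndarray:
    """Residues as integer codes; ambiguity symbols become -1."""
    table = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(record.alphabet.symbols):
        table[ord(c)] = i
    codes = np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8)
    return table[codes]


def count_kmers(record: SequenceRecord, spec: KmerSpec) -> CountVector:
    """Count (possibly spaced) k-mers of a record.

    One window starts at every position ``0..length-k`` per mask; windows
    containing an ambiguity symbol anywhere in their k-long span are skipped.
    A record shorter than k yields an empty vector with total 0.
    """
    if record.alphabet.name != spec.alphabet.name:
        raise ValueError(
            f"record alphabet {record.alphabet.name!r} does not match spec "
            f"{spec.alphabet.name!r}"
        )
    n, k = record.length, spec.k
    base = spec.alphabet.size
    if n < k:
        return CountVector(spec=spec, counts={}, total=0)

    codes = encode(record)
    n_windows = n - k + 1
    # window is valid iff no ambiguity code in its k-long span
    bad = (codes < 0).astype(np.int64)
    badcum = np.concatenate(([0], np.cumsum(bad)))
    valid = (badcum[k:] - badcum[:-k]) == 0

    safe = np.where(codes < 0, 0, codes)
    dense = np.zeros(base ** spec.width, dtype=np.int64)
    for mask in spec.effective_masks():
        positions = [i for i, bit in enumerate(mask) if bit == "1"]
        values = np.zeros(n_windows, dtype=np.int64)
        for pos in positions:
            values = values * base + safe[pos : pos + n_windows]
        dense += np.bincount(values[valid], minlength=dense.size)

    nz = np.flatnonzero(dense)
    counts = {_value_word(int(v), spec.width, spec.alphabet): int(dense[v]) for v in nz}
    return CountVector(spec=spec, counts=counts, total=int(dense.sum()))


def to_frequencies(counts: CountVector) -> FrequencyVector:
    """Normalise counts by the realised total so frequencies sum to one."""
    if counts.total == 0:
        return FrequencyVector(spec=counts.spec, freqs={}, total_kmers=0)
    total = counts.total
    freqs = {w: c / total for w, c in counts.counts.items()}
    return FrequencyVector(spec=counts.spec, freqs=freqs, total_kmers=total)


@dataclass(frozen=True)
class MarkovBackground:
    """Order-0 (single-letter) background composition of one DNA sequence.

    ``word_prob`` multiplies letter probabilities, ``expected_count`` scales
    by the realised k-mer total, and ``centered_counts`` returns the
    observed-minus-expected vector whose entries sum to ~0.
    """

    letter_probs: Mapping[str, float]
    alphabet: Alphabet = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        s = sum(self.letter_probs.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"letter probabilities must sum to 1, got {s}")

    def word_prob(self, word: str) -> float:
        p = 1.0
        for c in word:
            p *= self.letter_probs.get(c, 0.0)
        return p

    def expected_count(self, word: str, total_kmers: int) -> float:
        return total_kmers * self.word_prob(word)

    def word_probs_dense(self, spec: KmerSpec) -> np.ndarray:
        """Word probabilities for the whole word space, base-ary order."""
        base = spec.alphabet.size
        letters = np.array([self.letter_probs.get(c, 0.0) for c in spec.alphabet.symbols])
        probs = np.ones(1)
        for _ in range(spec.width):
            probs = np.outer(probs, letters).ravel()
        return probs

    def centered_counts(self, counts: CountVector) -> dict[str, float]:
        support = set(counts.counts)
        out: dict[str, float] = {}
        for word in support:
            out[word] = counts.counts[word] - counts.total * self.word_prob(word)
        return out


def fit_background(record: SequenceRecord) -> MarkovBackground:
    """Estimate the order-0 background from a DNA record's letter composition.

    Ambiguity symbols are excluded from the composition.  Protein input is
    rejected: the single-letter background is not well defined for the
    D2-family statistics on amino-acid alphabets.
    """
    if record.alphabet.name != "dna":
        raise ValueError("order-0 background is only defined for DNA records")
    if record.length == 0:
        raise ValueError("cannot fit a background to an empty sequence")
    codes = encode(record)
    canonical = codes[codes >= 0]
    if canonical.size == 0:
        raise ValueError("sequence contains no canonical residues")
    freq = np.bincount(canonical, minlength=record.alphabet.size).astype(float)
    freq /= freq.sum()
    probs = {record.alphabet.symbols[i]: float(freq[i]) for i in range(record.alphabet.size)}
    return MarkovBackground(letter_probs=probs, alphabet=record.alphabet)
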