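"""Deterministic synthetic data: genome fragments, signature genomes, ortholog proteins.

Three generators make the whole package testable without any download:

* :func:`make_fragments` applies the alternating-interval fragment-extraction
  protocol used for DNA benchmarks: a genome is split into ~10 equal
  intervals, five query fragments are taken from the even intervals and five
  reference fragments from the odd ones (first L bases of each interval), so
  query and reference material never overlaps and is sampled along the whole
  genome.  Fragment lengths start at 100 bp and double up to 102,400 bp.

* :func:`simulate_signature_genomes` draws order-1 Markov genomes whose
  per-genome transition matrices are perturbed around a shared composition.
  The perturbation plays the role of a genome *signature*: fragments of the
  same genome share k-mer statistics that fragments of different genomes do
  not.  This is an explicit synthetic stand-in for real whole-genome data,
  not a model of real genomes.

* :func:`simulate_ortholog_proteins` builds protein "ortholog" pairs as
  mutated copies of common ancestors (i.i.d. substitutions plus
  geometric-length indels) with unrelated decoys, together with a truth
  table.  Again a stand-in, used for directional and recovery tests only.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .evaluation import LineageRecord, TruthSet
from .sequence_io import DNA, PROTEIN, SequenceRecord

__all__ = [
    "FRAGMENT_LENGTH_SWEEP",
    "FIGURE_LENGTHS",
    "SignatureGenomeModel",
    "make_fragments",
    "make_unequal_reference",
    "simulate_signature_genomes",
    "simulate_ortholog_proteins",
    "write_manifest",
]

#: Doubling sweep of fragment lengths in bp: 100, 200, ..., 102,400 (11 values).
FRAGMENT_LENGTH_SWEEP: tuple[int, ...] = tuple(100 * 2 ** i for i in range(11))

#: The subset of lengths reported in figures: 0.1, 0.4, 1.6, 6.4, 25.6, 102.4 kb.
FIGURE_LENGTHS: tuple[int, ...] = (100, 400, 1600, 6400, 25600, 102400)

N_INTERVALS = 10
FRAGMENTS_PER_SET = 5


def make_fragments(
    genome: SequenceRecord, L: int, n_intervals: int = N_INTERVALS
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Extract alternating query and reference fragments of length ``L``.

    The genome is divided into ``n_intervals`` equal intervals (remainder
    bases dropped); each fragment is the first ``L`` bases of its interval.
    Queries come from even intervals {0,2,4,6,8}, references from odd ones.
    When ``L`` exceeds the interval width, only intervals long enough to
    hold a complete fragment contribute, so fewer (possibly zero) fragments
    are returned, with a warning.
    """
    if L < 1:
        raise ValueError("fragment length must be >= 1")
    width = genome.length // n_intervals
    if L > width:
        warnings.warn(
            f"fragment length {L} exceeds interval width {width} for genome "
            f"{genome.id!r}; emitting only complete fragments"
        )
    queries: list[SequenceRecord] = []
    references: list[SequenceRecord] = []
    for i in range(n_intervals):
        start = i * width
        if start + L > genome.length or L > width:
            continue
        frag = genome.residues[start : start + L]
        dest = queries if i % 2 == 0 else references
        role = "q" if i % 2 == 0 else "r"
        dest.append(
            SequenceRecord(
                id=f"{genome.id}|{role}{i // 2}|L{L}",
                residues=frag,
                description=f"{genome.id}|{role}{i // 2}|L{L} interval={i} start={start}",
                alphabet=genome.alphabet,
            )
        )
    return queries[:FRAGMENTS_PER_SET], references[:FRAGMENTS_PER_SET]


def make_unequal_reference(genome: SequenceRecord, ref_length: int = 250_000) -> SequenceRecord:
    """The single long reference of the L-unequal design: the genome's first 250 kb."""
    n = min(ref_length, genome.length)
    return SequenceRecord(
        id=f"{genome.id}|ref250",
        residues=genome.residues[:n],
        description=f"{genome.id}|ref250 first {n} bp",
        alphabet=genome.alphabet,
    )


@dataclass(frozen=True)
class SignatureGenomeModel:
    """Parameters of the order-1 Markov signature-genome generator.

    ``perturbation`` scales i.i.d. Gaussian noise added to the shared
    transition logits per genome: 0 makes all genomes statistically
    identical (no signature, metrics cannot separate them); around 0.3-0.5
    gives compositional signatures of the strength needed for fragment-level
    recognition at moderate k.  ``genus_size`` groups consecutive genomes
    into shared genera so the taxonomy fixture exercises ranks above
    species.
    """

    seed: int
    n_genomes: int = 20
    genome_length: int = 20_000
    perturbation: float = 0.4
    genus_size: int = 2

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.genome_length < 1:
            raise ValueError("n_genomes and genome_length must be positive")
        if self.perturbation < 0:
            raise ValueError("perturbation must be >= 0")
        if self.genus_size < 1:
            raise ValueError("genus_size must be >= 1")


def _markov_sequence(rng: np.random.Generator, transition: np.ndarray, length: int) -> str:
    """Sample a sequence from an order-1 chain with the given transition matrix."""
    cum = np.cumsum(transition, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    u = rng.random(length)
    states = np.empty(length, dtype=np.int64)
    # start from the uniform distribution over letters
    states[0] = int(rng.integers(4))
    for i in range(1, length):
        states[i] = int(np.searchsorted(cum[states[i - 1]], u[i], side="right"))
    return "".join(DNA.symbols[s] for s in states)


def simulate_signature_genomes(
    model: SignatureGenomeModel,
) -> tuple[list[SequenceRecord], TruthSet]:
    """Draw reproducible signature genomes plus their taxonomy truth set.

    Each genome is one "species"; consecutive genomes share a genus.  The
    returned taxonomy is keyed by genome id, and fragment ids produced by
    :func:`make_fragments` inherit their genome's lineage via
    :func:`fragment_lineages`.
    """
    rng = np.random.default_rng(model.seed)
    base_logits = np.zeros((4, 4))
    genomes: list[SequenceRecord] = []
    lineages: list[LineageRecord] = []
    for g in range(model.n_genomes):
        logits = base_logits + model.perturbation * rng.standard_normal((4, 4))
        transition = np.exp(logits)
        transition /= transition.sum(axis=1, keepdims=True)
        if np.any(transition.sum(axis=1) <= 0):
            raise ValueError("degenerate transition matrix")
        gid = f"genome{g:03d}"
        genomes.append(
            SequenceRecord(
                id=gid,
                residues=_markov_sequence(rng, transition, model.genome_length),
                description=f"{gid} synthetic signature genome",
                alphabet=DNA,
            )
        )
        lineages.append(
            LineageRecord(
                id=gid,
                rank_values={
                    "strain": gid,
                    "species": f"sp{g:03d}",
                    "genus": f"genus{g // model.genus_size:03d}",
                    "family": "famA",
                    "order": "ordA",
                    "class": "claA",
                    "phylum": "phyA",
                },
            )
        )
    return genomes, TruthSet.from_taxonomy(lineages, rank="species")


def fragment_lineages(
    fragments: list[SequenceRecord], truth: TruthSet
) -> list[LineageRecord]:
    """Lineages for fragment ids: the genome's lineage with a fragment-unique strain."""
    out = []
    for frag in fragments:
        genome_id = frag.id.split("|")[0]
        lin = truth.taxonomy.get(genome_id)
        if lin is None:
            raise KeyError(f"fragment {frag.id!r} has no genome lineage {genome_id!r}")
        values = dict(lin.rank_values)
        values["strain"] = frag.id
        out.append(LineageRecord(id=frag.id, rank_values=values))
    return out


_AA = PROTEIN.symbols


def _mutate_protein(
    rng: np.random.Generator, residues: str, substitution_rate: float, indel_rate: float
) -> str:
    """Apply i.i.d. substitutions and geometric-length indels to one sequence."""
    out = []
    i = 0
    n = len(residues)
    while i < n:
        if indel_rate > 0 and rng.random() < indel_rate:
            length = 1 + int(rng.geometric(0.5))
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.extend(rng.choice(list(_AA), size=length))  # insertion
        c = residues[i]
        if rng.random() < substitution_rate:
            choices = [a for a in _AA if a != c]
            c = str(rng.choice(choices))
        out.append(c)
        i += 1
    return "".join(out)


def simulate_ortholog_proteins(
    n_pairs: int,
    seed: int,
    mean_length: float = 450.0,
    substitution_rate: float = 0.3,
    indel_rate: float = 0.02,
    n_decoys: int | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], TruthSet]:
    """Simulate two proteomes related by ortholog pairs, plus the truth table.

    Each true pair is an ancestor (proteome A) and a mutated copy
    (proteome B); ``n_decoys`` unrelated proteins (default: n_pairs) are
    added to proteome B.  Lengths follow a gamma distribution with the given
    mean (shape 3, floor 50 aa), matching the scale of real proteomes.
    """
    if not (0.0 <= substitution_rate < 1.0) or not (0.0 <= indel_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    rng = np.random.default_rng(seed)
    if n_decoys is None:
        n_decoys = n_pairs
    aa = list(_AA)

    def random_protein(tag: str, idx: int) -> SequenceRecord:
        length = max(50, int(rng.gamma(shape=3.0, scale=mean_length / 3.0)))
        seq = "".join(rng.choice(aa, size=length))
        return SequenceRecord(
            id=f"{tag}{idx:04d}", residues=seq, description=f"{tag}{idx:04d}", alphabet=PROTEIN
        )

    proteome_a, proteome_b, pairs = [], [], []
    for i in range(n_pairs):
        anc = random_protein("qA", i)
        mut = _mutate_protein(rng, anc.residues, substitution_rate, indel_rate)
        if len(mut) < 1:  # total deletion is possible at extreme rates
            mut = anc.residues[:1]
        ortho = SequenceRecord(
            id=f"rB{i:04d}", residues=mut, description=f"rB{i:04d} ortholog of qA{i:04d}",
            alphabet=PROTEIN,
        )
        proteome_a.append(anc)
        proteome_b.append(ortho)
        pairs.append((anc.id, ortho.id))
    for j in range(n_decoys):
        proteome_b.append(random_protein("dB", j))
    return proteome_a, proteome_b, TruthSet.from_pairs(pairs)


def write_manifest(path: str | Path, seed: int, **params) -> None:
    """Record the seed and generator parameters next to emitted fixture files."""
    payload = {"seed": seed, **{
        k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v) for k, v in params.items()
    }}
    with open(path, "w") as out:
        json.dump(payload, out, indent=2, sort_keys=True)
        out.write("\n")
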