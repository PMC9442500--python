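"""Objective functions and accuracy statistics.

Alignment-free scores carry no biological meaning by themselves; an
*objective function* restores it by mapping a pair of sequence identifiers
onto external knowledge: either a table of known ortholog pairs, or a
taxonomy assigning each identifier a lineage over the seven-rank hierarchy
strain < species < genus < family < order < class < phylum.

On top of the predicate sit three statistics: top-hit accuracy (fraction of
queries whose rank-1 reference is a true positive), ROC/AUC over all scored
pairs (positives are expected to score LOW), and the Spearman correlation
between mean pair length and score, which diagnoses length-confounded
metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .search import ScoreRecord

__all__ = [
    "RANKS",
    "LineageRecord",
    "TruthSet",
    "unique_positive_pairs",
    "top_hit_accuracy",
    "roc_auc",
    "length_score_correlation",
    "read_pair_table",
    "write_pair_table",
    "read_taxonomy_table",
    "write_taxonomy_table",
]

#: Fixed rank hierarchy, lowest to highest.
RANKS: tuple[str, ...] = ("strain", "species", "genus", "family", "order", "class", "phylum")


@dataclass(frozen=True)
class LineageRecord:
    """Taxonomic lineage of one sequence id; missing ranks never match."""

    id: str
    rank_values: Mapping[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.rank_values) - set(RANKS)
        if unknown:
            raise ValueError(f"unknown ranks {sorted(unknown)}; expected subset of {RANKS}")

    def at(self, rank: str) -> str | None:
        value = self.rank_values.get(rank, "")
        return value if value else None


@dataclass(frozen=True)
class TruthSet:
    """Total predicate over id pairs: ortholog table or taxonomic-rank match."""

    kind: str  # "pair_table" | "taxonomy_rank"
    pair_table: frozenset[tuple[str, str]] = frozenset()
    taxonomy: Mapping[str, LineageRecord] = field(default_factory=dict)
    rank: str = "species"

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[str, str]]) -> "TruthSet":
        canon = frozenset(tuple(sorted(p)) for p in pairs)
        return TruthSet(kind="pair_table", pair_table=canon)

    @staticmethod
    def from_taxonomy(lineages: Iterable[LineageRecord], rank: str) -> "TruthSet":
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return TruthSet(
            kind="taxonomy_rank", taxonomy={lin.id: lin for lin in lineages}, rank=rank
        )

    def at_rank(self, rank: str) -> "TruthSet":
        if self.kind != "taxonomy_rank":
            raise ValueError("at_rank applies to taxonomy truth sets only")
        return TruthSet(kind="taxonomy_rank", taxonomy=self.taxonomy, rank=rank)

    def is_positive(self, id_a: str, id_b: str) -> bool:
        """Order-insensitive truth predicate; unknown ids are false (with warning)."""
        if self.kind == "pair_table":
            return tuple(sorted((id_a, id_b))) in self.pair_table
        lin_a = self.taxonomy.get(id_a)
        lin_b = self.taxonomy.get(id_b)
        if lin_a is None or lin_b is None:
            missing = id_a if lin_a is None else id_b
            warnings.warn(f"id {missing!r} absent from taxonomy; pair counted negative")
            return False
        va, vb = lin_a.at(self.rank), lin_b.at(self.rank)
        return va is not None and va == vb


def unique_positive_pairs(pairs: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Reduce a many-to-many ortholog table to one-to-one first mappings.

    For each left-side id, only its first-listed partner is retained; order
    of first appearance is preserved (used to build the positive-only score
    distribution).
    """
    seen: set[str] = set()
    out = []
    for a, b in pairs:
        if a in seen:
            continue
        seen.add(a)
        out.append((a, b))
    return out


def top_hit_accuracy(top_hits: Sequence[ScoreRecord], truth: TruthSet) -> float:
    """Fraction of queries whose rank-1 reference is a true positive.

    Queries whose best hit is not a positive -- including queries that have
    no possible positive partner in the reference set -- count as failures,
    which is what caps the achievable accuracy below 1 on real data sets.
    """
    if not top_hits:
        raise ValueError("empty top-hit set")
    correct = sum(1 for r in top_hits if truth.is_positive(r.query_id, r.ref_id))
    return correct / len(top_hits)


def roc_auc(records: Sequence[ScoreRecord], truth: TruthSet) -> float:
    """Area under the ROC curve with low scores treated as similar.

    Equals P(score_pos < score_neg) + 0.5 P(tie) via the Mann-Whitney rank
    statistic over all scored pairs.
    """
    scores = np.array([r.score for r in records], dtype=float)
    labels = np.array([truth.is_positive(r.query_id, r.ref_id) for r in records], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC requires at least one positive and one negative pair")
    ranks = stats.rankdata(scores)  # average ranks on ties
    u_pos = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0  # count of pos>neg (+0.5 ties)
    return 1.0 - u_pos / (n_pos * n_neg)


def length_score_correlation(
    records: Sequence[ScoreRecord], lengths: Mapping[str, int]
) -> tuple[float, float]:
    """Spearman rank correlation between mean pair length and score.

    Returns (rho, two-sided p-value).  A strongly negative rho means the
    metric rewards long sequence pairs regardless of biology.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    mean_len = np.array(
        [(lengths[r.query_id] + lengths[r.ref_id]) / 2.0 for r in records], dtype=float
    )
    scores = np.array([r.score for r in records], dtype=float)
    if np.all(mean_len == mean_len[0]) or np.all(scores == scores[0]):
        raise ValueError("rank correlation is undefined for a constant vector")
    rho, p = stats.spearmanr(mean_len, scores)
    return float(rho), float(p)


# --- TSV dialects -----------------------------------------------------------

def read_pair_table(path: str | Path) -> list[tuple[str, str]]:
    """Read an ortholog pair table: two tab-separated ids per line, in order."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed pair-table line: {line!r}")
            pairs.append((fields[0], fields[1]))
    return pairs


def write_pair_table(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as out:
        for a, b in pairs:
            out.write(f"{a}\t{b}\n")


def read_taxonomy_table(path: str | Path) -> list[LineageRecord]:
    """Read a lineage table: id + 7 rank columns (empty field = missing rank)."""
    lineages = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "id" or tuple(header[1:]) != RANKS:
            raise ValueError(f"taxonomy table header must be 'id' + {RANKS}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(RANKS) + 1:
                raise ValueError(f"malformed taxonomy line: {line!r}")
            values = {rank: v for rank, v in zip(RANKS, fields[1:]) if v}
            lineages.append(LineageRecord(id=fields[0], rank_values=values))
    return lineages


def write_taxonomy_table(lineages: Sequence[LineageRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("id\t" + "\t".join(RANKS) + "\n")
        for lin in lineages:
            row = "\t".join(lin.rank_values.get(r, "") for r in RANKS)
            out.write(f"{lin.id}\t{row}\n")
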