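"""All-pairs scoring engine: ranking, filters, and tabular/matrix output.

Every query is scored against every reference that passes the optional
length-ratio filter; scores are ranked per query (rank 1 = most similar,
ties broken by reference input order) and optionally truncated to the top-n
or thresholded at a cut-off score.  The ranking of similarity scores is the
principle output: downstream calibration and evaluation consume rank-1
records.

Reference vectors are computed once and cached across queries.  Scoring is
deterministic: identical inputs and configuration produce byte-identical
output regardless of the requested thread count (per-query work is
independent and merged in input order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kmer_core import (
    CountVector,
    FrequencyVector,
    KmerSpec,
    MarkovBackground,
    count_kmers,
    fit_background,
    to_frequencies,
)
from .metrics import MetricId, compute_score, get_metric
from .sequence_io import SequenceRecord, iter_pairs

__all__ = [
    "ScoreRecord",
    "SearchConfig",
    "SearchResult",
    "length_filter_pass",
    "count_retained_pairs",
    "compare_sets",
    "interleaved_compare",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class ScoreRecord:
    """One scored query-reference pair with its per-query similarity rank."""

    query_id: str
    ref_id: str
    metric: str
    score: float
    rank: int = 0


@dataclass(frozen=True)
class SearchConfig:
    """Engine options.

    ``top_n = 0`` keeps every retained reference per query.  ``fp`` keeps a
    pair only when the shorter sequence has at least that fraction of the
    longer one's length.  ``cutoff`` drops scores beyond the threshold
    (inclusive retention: score <= cutoff for distance metrics) before the
    top-n truncation.  ``threads`` is accepted as a contract knob only; the
    result never depends on it.
    """

    mode: str = "query_vs_reference"  # | "all_vs_all" | "interleaved"
    top_n: int = 0
    fp: float | None = None
    cutoff: float | None = None
    threads: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("query_vs_reference", "all_vs_all", "interleaved"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.top_n < 0:
            raise ValueError("top_n must be >= 0")
        if self.fp is not None and not (0.0 < self.fp <= 1.0):
            raise ValueError("fp must lie in (0, 1]")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


@dataclass
class SearchResult:
    """Grouped score records plus pair-accounting counters.

    ``n_pairs = n_retained + n_filtered + n_truncated``: every candidate
    pair is either scored and kept, removed by a filter (length ratio,
    cut-off, or an unscorable empty vector), or truncated by top-n.
    """

    metric: str
    records_by_query: dict[str, list[ScoreRecord]]
    n_pairs: int = 0
    n_filtered: int = 0
    n_truncated: int = 0

    @property
    def n_retained(self) -> int:
        return sum(len(v) for v in self.records_by_query.values())

    def all_records(self) -> list[ScoreRecord]:
        return [r for recs in self.records_by_query.values() for r in recs]

    def top_hits(self) -> list[ScoreRecord]:
        """Rank-1 record per query (queries with no retained reference omitted)."""
        return [recs[0] for recs in self.records_by_query.values() if recs]


def length_filter_pass(len_a: int, len_b: int, fp: float) -> bool:
    """True iff the shorter sequence is at least ``fp`` of the longer one's length."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    if not (0.0 < fp <= 1.0):
        raise ValueError("fp must lie in (0, 1]")
    return min(len_a, len_b) / max(len_a, len_b) >= fp


def count_retained_pairs(
    query_lengths: Sequence[int], ref_lengths: Sequence[int], fp: float | None = None
) -> int:
    """Number of query-reference pairs surviving the length filter (dry run).

    Vectorised pair counter used to audit comparison counts without scoring:
    with no filter this is simply ``|Q| * |R|``.
    """
    q = np.asarray(query_lengths, dtype=np.float64)
    r = np.asarray(ref_lengths, dtype=np.float64)
    if q.size == 0 or r.size == 0:
        raise ValueError("empty query or reference set")
    if fp is None:
        return int(q.size * r.size)
    ratio = np.minimum.outer(q, r) / np.maximum.outer(q, r)
    return int(np.count_nonzero(ratio >= fp))


@dataclass
class _Prepared:
    record: SequenceRecord
    counts: CountVector
    freqs: FrequencyVector | None
    background: MarkovBackground | None


def _prepare(
    records: Sequence[SequenceRecord], spec: KmerSpec, metric: MetricId
) -> list[_Prepared]:
    need_freq = metric.input_kind == "frequencies"
    need_bg = metric.input_kind == "counts+background"
    prepared = []
    for rec in records:
        counts = count_kmers(rec, spec)
        freqs = to_frequencies(counts) if need_freq else None
        bg = fit_background(rec) if need_bg and counts.total > 0 else None
        prepared.append(_Prepared(rec, counts, freqs, bg))
    return prepared


def _score_pair(metric: MetricId, a: _Prepared, b: _Prepared) -> float | None:
    """Score a prepared pair, or None when a vector is unscorable (warned)."""
    if a.counts.total == 0 or b.counts.total == 0:
        warnings.warn(
            f"skipping pair ({a.record.id}, {b.record.id}): empty k-mer vector",
            stacklevel=2,
        )
        return None
    return compute_score(metric, a.counts, b.counts, a.freqs, b.freqs, a.background, b.background)


def compare_sets(
    queries: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    metric: MetricId | str,
    spec: KmerSpec,
    config: SearchConfig = SearchConfig(),
) -> SearchResult:
    """Score every query against every reference, rank, filter and truncate.

    Records per query are sorted by increasing distance (decreasing score
    for the raw D2 similarity), ties broken by reference input order; the
    cut-off filter is applied before top-n truncation.
    """
    if not queries or not references:
        raise ValueError("empty query or reference set")
    metric = get_metric(metric) if isinstance(metric, str) else metric
    q_prep = _prepare(queries, spec, metric)
    r_prep = _prepare(references, spec, metric)

    result = SearchResult(metric=metric.name, records_by_query={})
    result.n_pairs = len(queries) * len(references)
    for qp in q_prep:
        scored: list[tuple[float, int, str]] = []
        for j, rp in enumerate(r_prep):
            if config.fp is not None and not length_filter_pass(
                qp.record.length, rp.record.length, config.fp
            ):
                result.n_filtered += 1
                continue
            score = _score_pair(metric, qp, rp)
            if score is None:
                result.n_filtered += 1
                continue
            if config.cutoff is not None:
                beyond = score > config.cutoff if metric.lower_is_similar else score < config.cutoff
                if beyond:
                    result.n_filtered += 1
                    continue
            scored.append((score, j, rp.record.id))
        key = (lambda t: (t[0], t[1])) if metric.lower_is_similar else (lambda t: (-t[0], t[1]))
        scored.sort(key=key)
        if config.top_n > 0 and len(scored) > config.top_n:
            result.n_truncated += len(scored) - config.top_n
            scored = scored[: config.top_n]
        result.records_by_query[qp.record.id] = [
            ScoreRecord(qp.record.id, ref_id, metric.name, score, rank)
            for rank, (score, _, ref_id) in enumerate(scored, start=1)
        ]
    return result


def interleaved_compare(
    records: Sequence[SequenceRecord], metric: MetricId | str, spec: KmerSpec
) -> list[ScoreRecord]:
    """Score consecutive (even, odd) record pairs only, preserving input order.

    Used for positive-only score distributions, where the caller controls
    exactly which sequences are paired.
    """
    metric = get_metric(metric) if isinstance(metric, str) else metric
    out: list[ScoreRecord] = []
    for a, b in iter_pairs(records):
        pa = _prepare([a], spec, metric)[0]
        pb = _prepare([b], spec, metric)[0]
        score = _score_pair(metric, pa, pb)
        if score is None:
            continue
        out.append(ScoreRecord(a.id, b.id, metric.name, score, 1))
    return out


def write_results(
    records_or_result: Sequence[ScoreRecord] | SearchResult,
    path: str | Path,
    format: str = "blastlike_tsv",
) -> None:
    """Write score records as a BLAST-like TSV or a PHYLIP-style distance matrix.

    The matrix format requires a symmetric all-vs-all result (every id scored
    against every other, including itself).
    """
    path = Path(path)
    if isinstance(records_or_result, SearchResult):
        records = records_or_result.all_records()
    else:
        records = list(records_or_result)
    if format == "blastlike_tsv":
        with open(path, "w") as out:
            out.write("query_id\tref_id\tmetric\tscore\trank\n")
            for r in records:
                out.write(f"{r.query_id}\t{r.ref_id}\t{r.metric}\t{r.score:.10g}\t{r.rank}\n")
        return
    if format == "matrix":
        ids = list(dict.fromkeys(r.query_id for r in records))
        lookup = {(r.query_id, r.ref_id): r.score for r in records}
        n = len(ids)
        for a in ids:
            for b in ids:
                if (a, b) not in lookup:
                    raise ValueError(
                        f"matrix output requires an all-vs-all result; missing pair ({a}, {b})"
                    )
        with open(path, "w") as out:
            out.write(f"{n}\n")
            for a in ids:
                row = "\t".join(f"{lookup[(a, b)]:.10g}" for b in ids)
                out.write(f"{a}\t{row}\n")
        return
    raise ValueError(f"unknown output format {format!r}")


def read_results(path: str | Path) -> list[ScoreRecord]:
    """Re-parse a BLAST-like TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "ref_id": str})
    return [
        ScoreRecord(row.query_id, row.ref_id, row.metric, float(row.score), int(row.rank))
        for row in df.itertuples(index=False)
    ]
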