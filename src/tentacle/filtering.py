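"""Read pre-processing and hit filtering.

Two concerns live here: (i) quality filtering of FASTQ reads before mapping,
reproducing the classic fastq_quality_filter rule — keep a read iff at least
p% of its bases have Phred quality >= q — and FASTQ->FASTA conversion;
(ii) post-mapping filtering of alignment hits by matching criteria (percent
identity, alignment length) with an optional best-hit policy for ambiguously
mapped reads, where "best" means first listed in mapper output order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Union

from .formats import Hit, SequenceRecord, open_maybe_gzip

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """The requested processing is inconsistent with the input data."""


@dataclass(frozen=True, slots=True)
class QualityFilterParams:
    """Parameters of the keep/discard quality rule.

    ``min_quality``: Phred threshold q. ``min_percent``: minimum percentage
    of bases that must reach q for the read to be kept.
    """

    min_quality: int = 20
    min_percent: float = 90.0

    def __post_init__(self):
        if not 0 <= self.min_quality <= 60:
            raise ValueError(f"min_quality {self.min_quality} outside [0, 60]")
        if not 0 < self.min_percent <= 100:
            raise ValueError(f"min_percent {self.min_percent} outside (0, 100]")


@dataclass(frozen=True, slots=True)
class HitCriteria:
    """Matching criteria applied to alignment hits.

    Hits below ``min_identity_pct`` or shorter than ``min_aln_len`` alignment
    columns are discarded. With ``best_hit_only`` the surviving hit listed
    first in the mapper output is kept per query.
    """

    min_identity_pct: float = 0.0
    min_aln_len: int = 0
    best_hit_only: bool = False

    def __post_init__(self):
        if not 0 <= self.min_identity_pct <= 100:
            raise ValueError(
                f"min_identity_pct {self.min_identity_pct} outside [0, 100]")
        if self.min_aln_len < 0:
            raise ValueError(f"min_aln_len {self.min_aln_len} negative")

    def passes(self, hit: Hit) -> bool:
        return (hit.identity_pct >= self.min_identity_pct
                and hit.aln_len >= self.min_aln_len)


def quality_filter(reads: Iterable[SequenceRecord],
                   params: QualityFilterParams) -> Iterator[SequenceRecord]:
    """Yield reads passing the quality rule, preserving order.

    A read is kept iff (bases with quality >= q) / length * 100 >= p.
    Zero-length reads are kept (the condition is vacuous). Records without
    qualities (FASTA input) raise :class:`ConfigurationError`.
    """
    kept = 0
    total = 0
    q = params.min_quality
    p = params.min_percent
    for rec in reads:
        if rec.qualities is None:
            raise ConfigurationError(
                f"quality filtering requested but record {rec.id!r} carries "
                "no quality scores (FASTA input?)")
        total += 1
        n = len(rec.qualities)
        if n == 0 or sum(1 for b in rec.qualities if b >= q) * 100 >= p * n:
            kept += 1
            yield rec
    logger.info("quality_filter: kept %d of %d reads (q>=%d for >=%.1f%% "
                "of bases)", kept, total, q, p)


def convert_to_fasta(reads: Iterable[SequenceRecord]
                     ) -> Iterator[SequenceRecord]:
    """Drop quality scores, leaving ids and sequences unchanged."""
    for rec in reads:
        if rec.qualities is None:
            yield rec
        else:
            yield SequenceRecord(rec.id, rec.sequence, None)


def load_exclude_ids(path: Union[str, Path]) -> frozenset[str]:
    """Read one read id per line (e.g. host-matching reads to drop)."""
    with open_maybe_gzip(path) as handle:
        return frozenset(line.strip() for line in handle if line.strip())


def exclude_reads(reads: Iterable[SequenceRecord],
                  exclude: frozenset[str]) -> Iterator[SequenceRecord]:
    """Pre-mapping hook dropping reads whose id is in *exclude*.

    This is the attachment point for host-read removal: an external screen
    (e.g. an alignment against a host genome) produces the id set.
    """
    dropped = 0
    for rec in reads:
        if rec.id in exclude:
            dropped += 1
        else:
            yield rec
    if dropped:
        logger.info("exclude_reads: dropped %d host-matching reads", dropped)


def filter_hits(hits: Iterable[Hit], criteria: HitCriteria) -> list[Hit]:
    """Apply matching criteria, then (optionally) the best-hit policy.

    Criteria are applied first, so a failing first-listed hit does not shadow
    a passing later hit for the same query. Under ``best_hit_only`` the
    surviving hit with the smallest ``file_order`` per query is retained.
    Output is sorted by ``file_order``.
    """
    surviving = [h for h in hits if criteria.passes(h)]
    if not criteria.best_hit_only:
        return sorted(surviving, key=lambda h: h.file_order)
    best: dict[str, Hit] = {}
    for h in surviving:
        cur = best.get(h.query_id)
        if cur is None or h.file_order < cur.file_order:
            best[h.query_id] = h
    return sorted(best.values(), key=lambda h: h.file_order)
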