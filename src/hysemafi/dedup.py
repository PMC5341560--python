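"""Containment-based redundancy removal for corrected long reads.

A read B is a duplicate of a longer read A when B aligns to A without
overhangs, without gaps, and with similarity above the threshold (0.99 by
default), similarity being identical nucleotides over the full length of B.
Removing every such B yields the DRCLR set (duplication-removed corrected
long reads) used as the query library downstream and as the quantification
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConsistencyError, UsageError
from .io_formats import AlignmentRecord, IsoformLibrary, SequenceRecord

__all__ = ["DedupParams", "similarity", "is_duplicate", "remove_duplicates", "RemovalLogEntry"]


@dataclass(frozen=True)
class DedupParams:
    """Thresholds of the containment rule.

    min_similarity: similarity must be strictly greater than this.
    max_overhang: allowed unaligned bases at either end of the shorter read
    (0 = the literal "no overhangs").
    max_gap_openings: allowed gap openings of either kind (0 = "no gaps").
    collapse_equal: also remove exact duplicates of identical length (keeps
    the lexicographically smaller id).  Off by default: the rule as stated
    requires the kept read to be strictly longer.
    """

    min_similarity: float = 0.99
    max_overhang: int = 0
    max_gap_openings: int = 0
    collapse_equal: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.min_similarity <= 1.0):
            raise UsageError("min_similarity must be in (0, 1]")
        if self.max_overhang < 0 or self.max_gap_openings < 0:
            raise UsageError("max_overhang and max_gap_openings must be >= 0")


def similarity(aln: AlignmentRecord, query_len: int) -> float:
    """Identical aligned nucleotides over the full query length, in [0, 1]."""
    if query_len != aln.q_size:
        raise ConsistencyError(
            f"query_len={query_len} does not match alignment q_size={aln.q_size} "
            f"for {aln.query_id}"
        )
    return aln.matches / query_len


def is_duplicate(
    aln_b_to_a: AlignmentRecord,
    len_a: int,
    len_b: int,
    params: DedupParams | None = None,
) -> bool:
    """Apply the containment rule to an alignment of read B (query) on read A.

    True iff A is strictly longer, B has no overhangs beyond max_overhang,
    similarity exceeds min_similarity, and the alignment opens at most
    max_gap_openings gaps.
    """
    params = params or DedupParams()
    aln = aln_b_to_a
    if aln.q_size != len_b or aln.t_size != len_a:
        raise ConsistencyError(
            "alignment sizes disagree with the stated read lengths "
            f"({aln.query_id}->{aln.target_id})"
        )
    if not len_a > len_b:
        return False
    if aln.q_start > params.max_overhang or (aln.q_size - aln.q_end) > params.max_overhang:
        return False
    if similarity(aln, len_b) <= params.min_similarity:
        return False
    if aln.q_num_insert + aln.t_num_insert > params.max_gap_openings:
        return False
    return True


@dataclass(frozen=True)
class RemovalLogEntry:
    removed_id: str
    kept_id: str
    similarity: float
    len_removed: int
    len_kept: int


def remove_duplicates(
    reads: IsoformLibrary | Sequence[SequenceRecord],
    alignments: Iterable[AlignmentRecord],
    params: DedupParams | None = None,
) -> tuple[list[SequenceRecord], list[RemovalLogEntry]]:
    """Produce the DRCLR set and a removal log.

    Reads are visited longest first (ties by ascending id); a read is removed
    when the containment rule holds against any longer read that was itself
    retained.  When several alignments exist for one (B, A) pair the one with
    the most matches is used.  Deterministic.
    """
    params = params or DedupParams()
    recs = list(reads)
    by_id = {r.id: r for r in recs}
    best: dict[tuple[str, str], AlignmentRecord] = {}
    for aln in alignments:
        if aln.query_id not in by_id or aln.target_id not in by_id:
            raise ConsistencyError(
                f"alignment references unknown read id "
                f"({aln.query_id} -> {aln.target_id})"
            )
        key = (aln.query_id, aln.target_id)
        cur = best.get(key)
        if cur is None or aln.matches > cur.matches:
            best[key] = aln
    retained: list[SequenceRecord] = []
    log: list[RemovalLogEntry] = []
    for read in sorted(recs, key=lambda r: (-r.length, r.id)):
        hit: RemovalLogEntry | None = None
        for kept in retained:
            aln = best.get((read.id, kept.id))
            if aln is None:
                continue
            dup = is_duplicate(aln, kept.length, read.length, params)
            if not dup and params.collapse_equal and kept.length == read.length:
                eq = DedupParams(
                    min_similarity=params.min_similarity,
                    max_overhang=params.max_overhang,
                    max_gap_openings=params.max_gap_openings,
                )
                # relax strict length: containment both ways, keep smaller id
                dup = (
                    kept.id < read.id
                    and aln.q_start <= params.max_overhang
                    and (aln.q_size - aln.q_end) <= params.max_overhang
                    and similarity(aln, read.length) > eq.min_similarity
                    and aln.q_num_insert + aln.t_num_insert <= eq.max_gap_openings
                )
            if dup:
                hit = RemovalLogEntry(
                    removed_id=read.id, kept_id=kept.id,
                    similarity=similarity(aln, read.length),
                    len_removed=read.length, len_kept=kept.length,
                )
                break
        if hit is None:
            retained.append(read)
        else:
            log.append(hit)
    order = {r.id: i for i, r in enumerate(recs)}
    retained.sort(key=lambda r: order[r.id])
    log.sort(key=lambda e: order[e.removed_id])
    return retained, log
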