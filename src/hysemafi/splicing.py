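"""Alternative-splicing detection from alignment gaps.

A splice is operationally an alignment gap longer than ``min_gap`` (50 bp by
default, strictly greater) between a long read and its gene's longest contig.
Target-side gaps (contig bases the read skips) are *exclusion* events —
skipped exons; query-side gaps (read bases absent from the contig) are
*insertion* events.  The ordered set of a read's gap events is its splice
signature; distinct signatures — different gap sites or lengths — define
distinct isoform classes.

Gap endpoints from error-bearing reads jitter by a few bases, so signatures
are clustered with coordinate rounding: endpoints within ``round_bp`` of each
other collapse to the modal coordinate.  ``round_bp=0`` recovers the literal
exact-coordinate rule.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import UsageError
from .io_formats import AlignmentRecord, SequenceRecord

__all__ = [
    "SpliceEvent",
    "SpliceSignature",
    "IsoformCatalog",
    "extract_gaps",
    "signature",
    "catalog_gene",
    "summarize_catalog",
    "verify_junctions",
]

DEFAULT_MIN_GAP = 50
DEFAULT_ROUND_BP = 5

EXCLUSION = "exclusion"
INSERTION = "insertion"


@dataclass(frozen=True)
class SpliceEvent:
    """One >min_gap alignment gap in longest-contig coordinates.

    exclusion: contig interval [t_start, t_end) skipped by the read.
    insertion: read bases absent from the contig, anchored at t_start == t_end.
    """

    kind: str
    t_start: int
    t_end: int
    length: int

    @property
    def key(self) -> tuple:
        if self.kind == EXCLUSION:
            return (EXCLUSION, self.t_start, self.t_end)
        return (INSERTION, self.t_start, self.length)


@dataclass(frozen=True)
class SpliceSignature:
    """Canonical ordered event tuple of one isoform class, with read support."""

    gene_id: str
    events: tuple[tuple, ...]
    support: tuple[str, ...]

    @property
    def n_support(self) -> int:
        return len(self.support)

    @property
    def is_gapless(self) -> bool:
        return not self.events


@dataclass(frozen=True)
class IsoformCatalog:
    """Per-gene splice signatures; n_isoforms = number of distinct classes."""

    entries: dict[str, tuple[SpliceSignature, ...]]

    def n_isoforms(self, gene_id: str) -> int:
        return len(self.entries[gene_id])

    def genes(self) -> list[str]:
        return sorted(self.entries)


def extract_gaps(
    aln: AlignmentRecord,
    min_gap: int = DEFAULT_MIN_GAP,
    island_merge_bp: int = 0,
) -> list[SpliceEvent]:
    """Emit splice events for each adjacent block pair of one alignment.

    The *net* jump decides the kind: a target-side excess > min_gap is an
    exclusion over the skipped contig interval; a query-side excess > min_gap
    is an insertion anchored where it interrupts the contig.  Gaps <= min_gap
    are ignored (strictly-greater reading of the 50 bp rule).

    ``island_merge_bp``: on noisy reads the optimal alignment occasionally
    splits one long gap around a few spuriously matching bases.  Exclusion
    gaps separated by an aligned island of at most this many bases are fused
    into one event *before* the min_gap filter.  0 (default) keeps the
    literal per-gap rule.
    """
    # (event, net excess) pairs; the net excess is what the 50 bp rule tests
    raw: list[tuple[SpliceEvent, int]] = []
    for prev, nxt in zip(aln.blocks, aln.blocks[1:]):
        dq = nxt.q_start - (prev.q_start + prev.size)
        dt = nxt.t_start - (prev.t_start + prev.size)
        t_gap_start = prev.t_start + prev.size
        if dt - dq > 0:
            raw.append((SpliceEvent(EXCLUSION, t_gap_start, nxt.t_start, dt),
                        dt - dq))
        elif dq - dt > 0:
            raw.append((SpliceEvent(INSERTION, t_gap_start, t_gap_start, dq),
                        dq - dt))
    if island_merge_bp > 0:
        merged: list[tuple[SpliceEvent, int]] = []
        for ev, net in raw:
            if (merged and ev.kind == EXCLUSION
                    and merged[-1][0].kind == EXCLUSION
                    and ev.t_start - merged[-1][0].t_end <= island_merge_bp):
                last, last_net = merged.pop()
                merged.append((
                    SpliceEvent(EXCLUSION, last.t_start, ev.t_end,
                                ev.t_end - last.t_start),
                    last_net + net,
                ))
            else:
                merged.append((ev, net))
        raw = merged
    return [ev for ev, net in raw if net > min_gap]


def signature(aln: AlignmentRecord, min_gap: int = DEFAULT_MIN_GAP) -> tuple[tuple, ...]:
    """Canonical signature key of one read->longest-contig alignment."""
    evs = extract_gaps(aln, min_gap)
    return tuple(ev.key for ev in sorted(evs, key=lambda e: (e.t_start, e.t_end, e.kind)))


def _round_values(values: Iterable[int], round_bp: int) -> dict[int, int]:
    """Cluster integers whose consecutive gaps are <= round_bp; map each to
    the modal value of its cluster (ties to the smallest)."""
    counts = Counter(values)
    if not counts:
        return {}
    mapping: dict[int, int] = {}
    cluster: list[int] = []
    prev = None
    for v in sorted(counts):
        if prev is not None and v - prev > round_bp:
            rep = max(cluster, key=lambda x: (counts[x], -x))
            mapping.update({c: rep for c in cluster})
            cluster = []
        cluster.append(v)
        prev = v
    rep = max(cluster, key=lambda x: (counts[x], -x))
    mapping.update({c: rep for c in cluster})
    return mapping


def catalog_gene(
    gene_id: str,
    alignments_to_longest: Sequence[AlignmentRecord],
    min_gap: int = DEFAULT_MIN_GAP,
    round_bp: int = DEFAULT_ROUND_BP,
) -> tuple[SpliceSignature, ...]:
    """Group one gene's qualifying read alignments into isoform classes.

    Coordinates are first rounded per gene (see module docstring), then reads
    with equal event tuples form one class.  The gapless class is included
    when supported.  Support sets partition the reads; output is sorted by
    descending support then event tuple for determinism.
    """
    raw: dict[str, list[SpliceEvent]] = {}
    for aln in alignments_to_longest:
        raw[aln.query_id] = extract_gaps(aln, min_gap, island_merge_bp=round_bp)
    if round_bp > 0:
        starts = _round_values(
            (e.t_start for evs in raw.values() for e in evs), round_bp)
        ends = _round_values(
            (e.t_end for evs in raw.values() for e in evs), round_bp)
        lengths = _round_values(
            (e.length for evs in raw.values() for e in evs if e.kind == INSERTION),
            round_bp)
        def canon(e: SpliceEvent) -> tuple:
            if e.kind == EXCLUSION:
                return (EXCLUSION, starts[e.t_start], ends[e.t_end])
            return (INSERTION, starts[e.t_start], lengths[e.length])
    else:
        def canon(e: SpliceEvent) -> tuple:
            return e.key
    classes: dict[tuple, list[str]] = {}
    for read_id, evs in raw.items():
        key = tuple(sorted((canon(e) for e in evs), key=lambda k: (k[1], k[2], k[0])))
        classes.setdefault(key, []).append(read_id)
    sigs = [
        SpliceSignature(gene_id=gene_id, events=key, support=tuple(sorted(reads)))
        for key, reads in classes.items()
    ]
    sigs.sort(key=lambda s: (-s.n_support, s.events))
    return tuple(sigs)


def build_catalog(
    alignments_by_gene: Mapping[str, Sequence[AlignmentRecord]],
    min_gap: int = DEFAULT_MIN_GAP,
    round_bp: int = DEFAULT_ROUND_BP,
) -> IsoformCatalog:
    entries = {
        gene: catalog_gene(gene, alns, min_gap, round_bp)
        for gene, alns in alignments_by_gene.items()
        if alns
    }
    return IsoformCatalog(entries=entries)


def summarize_catalog(catalog: IsoformCatalog, thresholds: Sequence[int] = (2, 3, 4)):
    """Histogram of genes by isoform-class count plus gene lists at thresholds.

    Returns (histogram: dict n_isoforms -> n_genes, gene_lists: dict
    threshold -> sorted gene ids with >= threshold classes).  The histogram
    total equals the number of catalogued genes.
    """
    hist: dict[int, int] = {}
    for gene in catalog.genes():
        n = catalog.n_isoforms(gene)
        hist[n] = hist.get(n, 0) + 1
    gene_lists = {
        thr: sorted(g for g in catalog.genes() if catalog.n_isoforms(g) >= thr)
        for thr in thresholds
    }
    return dict(sorted(hist.items())), gene_lists


def verify_junctions(
    signatures: Sequence[SpliceSignature],
    longest_contigs: Mapping[str, SequenceRecord],
    fragments: Sequence[SequenceRecord],
    flank: int = 20,
    max_mismatch_per_flank: int = 0,
) -> dict[tuple[str, tuple], int]:
    """Count merged-fragment support for each exclusion event.

    The junction probe is ``flank`` bases left of the gap start joined to
    ``flank`` bases right of the gap end on the gene's longest contig — the
    sequence an isoform skipping that segment actually contains.  A fragment
    supports the event when it contains the probe exactly (or with at most
    ``max_mismatch_per_flank`` mismatches per flank).  Returns
    {(gene_id, event_key): supporting fragment count}.
    """
    if flank < 1:
        raise UsageError("flank must be >= 1")
    frag_seqs = [f.seq for f in fragments]
    out: dict[tuple[str, tuple], int] = {}
    for sig in signatures:
        contig = longest_contigs.get(sig.gene_id)
        if contig is None:
            continue
        for key in sig.events:
            if key[0] != EXCLUSION:
                continue
            _, t_start, t_end = key
            left_from = t_start - flank
            right_to = t_end + flank
            if left_from < 0 or right_to > contig.length:
                warnings.warn(
                    f"junction flank truncated at contig bounds for "
                    f"{sig.gene_id} event {key}"
                )
                left_from = max(0, left_from)
                right_to = min(contig.length, right_to)
            left = contig.seq[left_from:t_start]
            right = contig.seq[t_end:right_to]
            probe = left + right
            ev_key = (sig.gene_id, key)
            if ev_key in out:
                continue
            if max_mismatch_per_flank == 0:
                count = sum(1 for fs in frag_seqs if probe in fs)
            else:
                count = sum(
                    1 for fs in frag_seqs
                    if _fuzzy_contains(fs, left, right, max_mismatch_per_flank)
                )
            out[ev_key] = count
    return out


def _fuzzy_contains(haystack: str, left: str, right: str, m: int) -> bool:
    probe_len = len(left) + len(right)
    for i in range(len(haystack) - probe_len + 1):
        lm = sum(1 for a, b in zip(haystack[i : i + len(left)], left) if a != b)
        if lm > m:
            continue
        seg = haystack[i + len(left) : i + probe_len]
        rm = sum(1 for a, b in zip(seg, right) if a != b)
        if rm <= m:
            return True
    return False
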