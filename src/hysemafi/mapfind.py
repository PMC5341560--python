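"""Long-read <-> contig map finding, gene grouping and longest-contig selection.

The central selection rule: per gene, a contig is a reference candidate when
(A) it is at least as long as every long read mapped in that gene, and (B) it
carries at least one qualifying alignment — a long read mapping with
similarity >= 0.99 over the read's full length.  Among candidates the longest
one is taken to contain (almost) all exons of the gene and becomes the gene's
entry in the longest-contig reference set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .dedup import similarity
from .errors import ConsistencyError, UsageError
from .io_formats import AlignmentRecord, Role, SequenceRecord

__all__ = [
    "GeneGroup",
    "LongestContigSet",
    "qualifies",
    "group_genes",
    "select_longest_contig",
    "build_reference",
    "mapping_report",
]

DEFAULT_MIN_IDENTITY = 0.99

_TRINITY_ISO_RE = re.compile(r"^(.*)_i\d+$")


@dataclass(frozen=True)
class GeneGroup:
    """Contigs and long reads inferred to come from one gene."""

    gene_id: str
    contig_ids: frozenset[str]
    long_read_ids: frozenset[str]
    alignments: tuple[AlignmentRecord, ...]
    longest_contig_id: str | None = None


@dataclass(frozen=True)
class LongestContigSet:
    """gene_id -> selected longest contig (the reference library)."""

    entries: dict[str, SequenceRecord]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for gene, rec in self.entries.items():
            if rec.id in seen:
                raise ConsistencyError(
                    f"contig {rec.id!r} claimed by genes {seen[rec.id]!r} and {gene!r}"
                )
            seen[rec.id] = gene


def qualifies(aln: AlignmentRecord, min_identity: float = DEFAULT_MIN_IDENTITY) -> bool:
    """A long-read -> contig alignment qualifies at similarity >= min_identity."""
    return similarity(aln, aln.q_size) >= min_identity


def _best_per_pair(alignments: Iterable[AlignmentRecord]) -> dict[tuple[str, str], AlignmentRecord]:
    best: dict[tuple[str, str], AlignmentRecord] = {}
    for aln in alignments:
        key = (aln.query_id, aln.target_id)
        cur = best.get(key)
        if cur is None or aln.matches > cur.matches:
            best[key] = aln
    return best


def trinity_gene_prefix(contig_id: str) -> str:
    """Strip the trailing isoform token (``_i<k>``) from a Trinity-style id."""
    m = _TRINITY_ISO_RE.match(contig_id)
    return m.group(1) if m else contig_id


def group_genes(
    alignments: Sequence[AlignmentRecord],
    contigs: Sequence[SequenceRecord],
    long_reads: Sequence[SequenceRecord],
    mode: str = "components",
) -> list[GeneGroup]:
    """Partition contigs and mapped long reads into gene groups.

    ``alignments`` must already be restricted to qualifying hits.  In
    ``components`` mode genes are the connected components of the bipartite
    read<->contig graph; in ``trinity_names`` mode contigs sharing a Trinity
    gene prefix form a gene and each read joins the gene of its best-identity
    alignment.  Contigs with no alignment become singleton groups (reported
    unmapped downstream); long reads with no qualifying alignment are not
    grouped.  gene_id is the smallest member id; output sorted by gene_id.
    """
    contig_ids = {c.id for c in contigs}
    read_ids = {r.id for r in long_reads}
    for aln in alignments:
        if aln.target_id not in contig_ids or aln.query_id not in read_ids:
            raise ConsistencyError(
                f"alignment {aln.query_id}->{aln.target_id} references an "
                "unknown read or contig"
            )
    best = _best_per_pair(alignments)
    groups: list[GeneGroup] = []
    if mode == "components":
        g = nx.Graph()
        g.add_nodes_from(("C", c) for c in contig_ids)
        for aln in best.values():
            g.add_edge(("R", aln.query_id), ("C", aln.target_id))
        for comp in nx.connected_components(g):
            cids = frozenset(n[1] for n in comp if n[0] == "C")
            rids = frozenset(n[1] for n in comp if n[0] == "R")
            alns = tuple(
                sorted(
                    (a for (q, t), a in best.items() if q in rids and t in cids),
                    key=lambda a: (a.query_id, a.target_id),
                )
            )
            groups.append(GeneGroup(
                gene_id=min(cids | rids), contig_ids=cids,
                long_read_ids=rids, alignments=alns,
            ))
    elif mode == "trinity_names":
        by_prefix: dict[str, set[str]] = {}
        for cid in contig_ids:
            by_prefix.setdefault(trinity_gene_prefix(cid), set()).add(cid)
        prefix_of = {cid: p for p, cs in by_prefix.items() for cid in cs}
        read_gene: dict[str, str] = {}
        read_best: dict[str, tuple[float, str]] = {}
        for aln in best.values():
            ident = similarity(aln, aln.q_size)
            p = prefix_of[aln.target_id]
            cur = read_best.get(aln.query_id)
            if cur is None or (ident, ) > (cur[0], ) or (ident == cur[0] and p < cur[1]):
                read_best[aln.query_id] = (ident, p)
        for rid, (_, p) in read_best.items():
            read_gene[rid] = p
        for p, cids in by_prefix.items():
            rids = frozenset(r for r, g in read_gene.items() if g == p)
            alns = tuple(
                sorted(
                    (a for (q, t), a in best.items() if q in rids and t in cids),
                    key=lambda a: (a.query_id, a.target_id),
                )
            )
            groups.append(GeneGroup(
                gene_id=min(cids | rids), contig_ids=frozenset(cids),
                long_read_ids=rids, alignments=alns,
            ))
    else:
        raise UsageError(f"unknown grouping mode {mode!r}")
    groups.sort(key=lambda gr: gr.gene_id)
    return groups


def select_longest_contig(
    group: GeneGroup, min_identity: float = DEFAULT_MIN_IDENTITY
) -> str | None:
    """Select the gene's reference contig per the A/B selection rule.

    Candidates: contigs with >= 1 qualifying alignment whose length is >= the
    longest mapped read of the group.  Returns the longest candidate (ties by
    ascending contig id), or None when the gene is unresolved.  Invariant
    under permutation of the group's alignment order.
    """
    qual = [a for a in group.alignments if qualifies(a, min_identity)]
    if not qual:
        return None
    max_read_len = max(a.q_size for a in qual)
    cand: dict[str, int] = {}
    for a in qual:
        cand[a.target_id] = a.t_size
    cands = [(length, cid) for cid, length in cand.items() if length >= max_read_len]
    if not cands:
        return None
    cands.sort(key=lambda x: (-x[0], x[1]))
    return cands[0][1]


def build_reference(
    groups: Sequence[GeneGroup],
    contigs: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[LongestContigSet, list[str]]:
    """Resolve every group and assemble the longest-contig reference set.

    Returns (reference, unresolved_gene_ids).  Reference entries keep the
    contig's own sequence; FASTA output written by the pipeline labels them
    ``gene_id|contig_id``.
    """
    if not isinstance(contigs, Mapping):
        contigs = {c.id: c for c in contigs}
    entries: dict[str, SequenceRecord] = {}
    unresolved: list[str] = []
    for group in groups:
        if not group.long_read_ids:
            continue  # contig-only singleton: nothing mapped, not a resolvable gene
        chosen = select_longest_contig(group, min_identity)
        if chosen is None:
            unresolved.append(group.gene_id)
            continue
        entries[group.gene_id] = contigs[chosen]
    return LongestContigSet(entries=entries), sorted(unresolved)


def mapping_report(
    alignments: Sequence[AlignmentRecord],
    reads: Sequence[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    bins: Sequence[float] = (0.95, 0.99),
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> dict:
    """Per-read best-identity histogram plus mapped/unmapped partitions.

    ``alignments`` here should be unfiltered (all identities) so the
    histogram shows the full distribution; the mapped/unmapped contig
    partition still applies the qualifying threshold.
    """
    best_ident: dict[str, float] = {}
    mapped_contigs: set[str] = set()
    for aln in alignments:
        ident = similarity(aln, aln.q_size)
        if ident > best_ident.get(aln.query_id, -1.0):
            best_ident[aln.query_id] = ident
        if qualifies(aln, min_identity):
            mapped_contigs.add(aln.target_id)
    edges = sorted(bins)
    labels = [f"<{edges[0]:g}"]
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f"{lo:g}-{hi:g}")
    labels.append(f">={edges[-1]:g}")
    hist = {lab: 0 for lab in labels}
    for ident in best_ident.values():
        for i, edge in enumerate(edges):
            if ident < edge:
                hist[labels[i]] += 1
                break
        else:
            hist[labels[-1]] += 1
    n_reads = len(reads)
    n_contigs = len(contigs)
    return {
        "identity_histogram": hist,
        "n_reads": n_reads,
        "n_reads_mapped": len(best_ident),
        "n_reads_unmapped": n_reads - len(best_ident),
        "n_contigs": n_contigs,
        "n_contigs_mapped": len(mapped_contigs),
        "n_contigs_unmapped": n_contigs - len(mapped_contigs),
    }


def report_frame(report: dict) -> pd.DataFrame:
    """Flatten a mapping_report dict to a two-column key/value table."""
    rows = [(f"identity_bin:{k}", v) for k, v in report["identity_histogram"].items()]
    rows += [(k, v) for k, v in report.items() if k != "identity_histogram"]
    return pd.DataFrame(rows, columns=["metric", "value"])
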