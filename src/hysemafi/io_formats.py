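"""Sequence and alignment data model plus FASTA / PSL / PAF readers and writers.

Coordinates are 0-based half-open throughout, the native convention of both
PSL (BLAT) and PAF, so no off-by-one conversion happens anywhere downstream.

Minus-strand alignments are normalised at parse time: query coordinates and
block starts are stored in the *reverse-complemented query frame*, the frame
in which blocks ascend in both query and target.  The original strand is kept
as metadata.  This matches how PSL stores its ``qStarts`` list for minus-strand
hits; only the scalar qStart/qEnd columns need converting on read/write.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import FormatError, UnsupportedInputError

__all__ = [
    "Role",
    "LibraryKind",
    "SequenceRecord",
    "Block",
    "AlignmentRecord",
    "IsoformLibrary",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "parse_psl",
    "write_psl",
    "parse_paf",
    "write_paf",
    "reverse_complement",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Role(str, Enum):
    LONG_READ = "long_read"
    CONTIG = "contig"
    SHORT_READ = "short_read"


class LibraryKind(str, Enum):
    """Which side of the hybrid design a library comes from.

    ISO_T: long-read (single-molecule) isoform library — true expressed
    molecules, full length or near full length.
    ISO_S: short-read assembly contig library — candidate isoforms, a mix of
    true and artefactual molecules.
    """

    ISO_T = "Iso_T"
    ISO_S = "Iso_S"


_KIND_ROLE = {LibraryKind.ISO_T: Role.LONG_READ, LibraryKind.ISO_S: Role.CONTIG}


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str
    role: Role = Role.LONG_READ

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record requires a non-empty id")
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r} "
                "(expected A/C/G/T/N, uppercase)"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, seq=reverse_complement(self.seq))


@dataclass(frozen=True)
class Block:
    """One gapless aligned segment: ``size`` bases at ``q_start``/``t_start``."""

    size: int
    q_start: int
    t_start: int


@dataclass(frozen=True)
class AlignmentRecord:
    """One block-structured pairwise alignment with PSL semantics.

    ``matches`` counts identically aligned bases (the identity numerator used
    throughout the pipeline); ``q_num_insert``/``t_num_insert`` count gap
    openings on the query/target side and ``q_base_insert``/``t_base_insert``
    the gapped bases.  All coordinates are 0-based half-open; for strand "-"
    they live in the reverse-complemented query frame (see module docstring).
    """

    query_id: str
    target_id: str
    strand: str
    matches: int
    mismatches: int
    q_num_insert: int
    q_base_insert: int
    t_num_insert: int
    t_base_insert: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    q_size: int
    t_size: int
    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))

    # -- invariants ---------------------------------------------------------

    def validate(self) -> "AlignmentRecord":
        """Check every type invariant; raise FormatError naming the first violated."""
        ctx = f"alignment {self.query_id}->{self.target_id}"
        if self.strand not in ("+", "-"):
            raise FormatError(f"{ctx}: strand must be '+' or '-'")
        if not self.blocks:
            raise FormatError(f"{ctx}: at least one block required")
        prev_q = prev_t = None
        for b in self.blocks:
            if b.size <= 0:
                raise FormatError(f"{ctx}: block sizes must be positive")
            if prev_q is not None and (b.q_start < prev_q or b.t_start < prev_t):
                raise FormatError(
                    f"{ctx}: blocks must be sorted and strictly increasing "
                    "in both query and target coordinates"
                )
            prev_q, prev_t = b.q_start + b.size, b.t_start + b.size
        total = sum(b.size for b in self.blocks)
        if total != self.matches + self.mismatches:
            raise FormatError(
                f"{ctx}: sum(block sizes)={total} != matches+mismatches="
                f"{self.matches + self.mismatches}"
            )
        if self.q_end - self.q_start != total + self.q_base_insert:
            raise FormatError(
                f"{ctx}: q_end-q_start != sum(block sizes)+q_base_insert"
            )
        if self.t_end - self.t_start != total + self.t_base_insert:
            raise FormatError(
                f"{ctx}: t_end-t_start != sum(block sizes)+t_base_insert"
            )
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise FormatError(f"{ctx}: query coordinates out of range")
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise FormatError(f"{ctx}: target coordinates out of range")
        if self.blocks[0].q_start != self.q_start or self.blocks[0].t_start != self.t_start:
            raise FormatError(f"{ctx}: first block must start at q_start/t_start")
        last = self.blocks[-1]
        if last.q_start + last.size != self.q_end or last.t_start + last.size != self.t_end:
            raise FormatError(f"{ctx}: last block must end at q_end/t_end")
        if min(self.matches, self.mismatches, self.q_num_insert, self.q_base_insert,
               self.t_num_insert, self.t_base_insert) < 0:
            raise FormatError(f"{ctx}: counts must be non-negative")
        return self

    @property
    def identity(self) -> float:
        """Identity over the full query: matches / q_size."""
        return self.matches / self.q_size


@dataclass(frozen=True)
class IsoformLibrary:
    """A named collection of sequences from one side of the hybrid design."""

    kind: LibraryKind
    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        want = _KIND_ROLE[self.kind]
        seen: set[str] = set()
        for rec in self.records:
            if rec.role is not want:
                raise FormatError(
                    f"library {self.kind.value}: record {rec.id!r} has role "
                    f"{rec.role.value}, expected {want.value}"
                )
            if rec.id in seen:
                raise FormatError(f"library {self.kind.value}: duplicate id {rec.id!r}")
            seen.add(rec.id)

    def by_id(self) -> dict[str, SequenceRecord]:
        return {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, role: Role = Role.LONG_READ) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, ids checked unique)."""
    path = Path(path)
    text_head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                text_head = line
                break
    if text_head and not text_head.startswith(">"):
        raise FormatError(f"{path}: not FASTA (first non-blank line lacks '>')")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, seq=seq, role=role))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write FASTA with fixed line width (byte-stable output)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path, role: Role = Role.SHORT_READ) -> list[SequenceRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(Path(path)), "fastq"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), role=role))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{quality_char * rec.length}\n")


# ---------------------------------------------------------------------------
# PSL (BLAT dialect, 21 columns)
# ---------------------------------------------------------------------------

_PSL_NCOLS = 21


def _parse_int_list(field: str, path, lineno: int) -> list[int]:
    try:
        return [int(x) for x in field.rstrip(",").split(",") if x != ""]
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: malformed comma list {field!r}") from exc


def parse_psl(path: str | Path, has_header: bool | None = None) -> list[AlignmentRecord]:
    """Parse a 21-column PSL file.

    ``has_header=None`` auto-detects the 5-line psLayout header.  repMatches
    is folded into matches and nCount into mismatches (the identity rate used
    downstream does not distinguish them).  Minus-strand records are
    normalised to the reverse-complemented query frame (see module docstring).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if has_header is None:
        has_header = bool(lines) and lines[0].startswith("psLayout")
    if has_header:
        # psLayout header: title, blank, two column-name lines, dashed rule.
        for i, line in enumerate(lines):
            if line.startswith("---"):
                start = i + 1
                break
        else:
            raise FormatError(f"{path}: header requested but no '---' rule found")
    records: list[AlignmentRecord] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != _PSL_NCOLS:
            raise FormatError(
                f"{path}:{lineno}: expected {_PSL_NCOLS} tab-separated columns, "
                f"got {len(fields)}"
            )
        try:
            (matches, mismatches, rep_matches, n_count, q_num_insert,
             q_base_insert, t_num_insert, t_base_insert) = map(int, fields[:8])
            strand = fields[8]
            q_name, q_size, q_start, q_end = fields[9], int(fields[10]), int(fields[11]), int(fields[12])
            t_name, t_size, t_start, t_end = fields[13], int(fields[14]), int(fields[15]), int(fields[16])
            block_count = int(fields[17])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer numeric column") from exc
        sizes = _parse_int_list(fields[18], path, lineno)
        q_starts = _parse_int_list(fields[19], path, lineno)
        t_starts = _parse_int_list(fields[20], path, lineno)
        if not (len(sizes) == len(q_starts) == len(t_starts) == block_count):
            raise FormatError(
                f"{path}:{lineno}: blockCount={block_count} does not match "
                "block list lengths"
            )
        if strand == "-":
            # scalar qStart/qEnd are plus-strand in PSL; block qStarts already
            # live in the reversed-query frame we store internally.
            q_start, q_end = q_size - q_end, q_size - q_start
        rec = AlignmentRecord(
            query_id=q_name, target_id=t_name, strand=strand,
            matches=matches + rep_matches, mismatches=mismatches + n_count,
            q_num_insert=q_num_insert, q_base_insert=q_base_insert,
            t_num_insert=t_num_insert, t_base_insert=t_base_insert,
            q_start=q_start, q_end=q_end, t_start=t_start, t_end=t_end,
            q_size=q_size, t_size=t_size,
            blocks=tuple(Block(s, q, t) for s, q, t in zip(sizes, q_starts, t_starts)),
        )
        try:
            rec.validate()
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_psl(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write records as 21-column header-less PSL (inverse of parse_psl)."""
    with open(path, "w") as fh:
        for rec in records:
            rec.validate()
            q_start, q_end = rec.q_start, rec.q_end
            if rec.strand == "-":
                q_start, q_end = rec.q_size - rec.q_end, rec.q_size - rec.q_start
            sizes = ",".join(str(b.size) for b in rec.blocks) + ","
            q_starts = ",".join(str(b.q_start) for b in rec.blocks) + ","
            t_starts = ",".join(str(b.t_start) for b in rec.blocks) + ","
            fh.write("\t".join(map(str, [
                rec.matches, rec.mismatches, 0, 0,
                rec.q_num_insert, rec.q_base_insert,
                rec.t_num_insert, rec.t_base_insert,
                rec.strand,
                rec.query_id, rec.q_size, q_start, q_end,
                rec.target_id, rec.t_size, rec.t_start, rec.t_end,
                len(rec.blocks), sizes, q_starts, t_starts,
            ])) + "\n")


# ---------------------------------------------------------------------------
# PAF with cg:Z CIGAR
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse PAF lines carrying a cg:Z CIGAR tag into block structure.

    Matches are taken from the residue-match column (10), reconciled with
    the CIGAR; ``=``/``X`` operators are honoured when present.  Records
    without a CIGAR cannot be reconstructed and raise UnsupportedInputError.
    """
    path = Path(path)
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: PAF needs >= 12 columns")
            q_name, q_size, q_start_c, q_end_c, strand = (
                fields[0], int(fields[1]), int(fields[2]), int(fields[3]), fields[4])
            t_name, t_size, t_start, t_end = (
                fields[5], int(fields[6]), int(fields[7]), int(fields[8]))
            n_match = int(fields[9])
            cigar = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = tag[5:]
                    break
            if cigar is None:
                raise UnsupportedInputError(
                    f"{path}:{lineno}: no cg:Z CIGAR tag; block structure "
                    "cannot be reconstructed"
                )
            if strand == "-":
                q_start, q_end = q_size - q_end_c, q_size - q_start_c
            else:
                q_start, q_end = q_start_c, q_end_c
            blocks: list[Block] = []
            q_pos, t_pos = q_start, t_start
            eq_bases = 0
            has_eq = False
            aligned = 0
            qni = qbi = tni = tbi = 0
            for m in _CIGAR_RE.finditer(cigar):
                n, op = int(m.group(1)), m.group(2)
                if op in "M=X":
                    if blocks and blocks[-1].q_start + blocks[-1].size == q_pos \
                            and blocks[-1].t_start + blocks[-1].size == t_pos:
                        last = blocks.pop()
                        blocks.append(Block(last.size + n, last.q_start, last.t_start))
                    else:
                        blocks.append(Block(n, q_pos, t_pos))
                    if op == "=":
                        eq_bases += n
                        has_eq = True
                    elif op == "X":
                        has_eq = True
                    aligned += n
                    q_pos += n
                    t_pos += n
                elif op == "I":  # extra query bases
                    qni += 1
                    qbi += n
                    q_pos += n
                elif op in "DN":  # extra target bases
                    tni += 1
                    tbi += n
                    t_pos += n
                else:
                    raise UnsupportedInputError(
                        f"{path}:{lineno}: unsupported CIGAR op {op!r}")
            matches = eq_bases if has_eq else min(n_match, aligned)
            rec = AlignmentRecord(
                query_id=q_name, target_id=t_name, strand=strand,
                matches=matches, mismatches=aligned - matches,
                q_num_insert=qni, q_base_insert=qbi,
                t_num_insert=tni, t_base_insert=tbi,
                q_start=q_start, q_end=q_end, t_start=t_start, t_end=t_end,
                q_size=q_size, t_size=t_size, blocks=tuple(blocks),
            )
            try:
                rec.validate()
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write PAF with a cg:Z tag using ``=``/``X``/``I``/``D`` operators."""
    with open(path, "w") as fh:
        for rec in records:
            rec.validate()
            ops: list[str] = []
            # emit per-block aligned runs; identity split unknown per block,
            # so write M ops and rely on column 10 for the match count.
            prev = None
            for b in rec.blocks:
                if prev is not None:
                    dq = b.q_start - (prev.q_start + prev.size)
                    dt = b.t_start - (prev.t_start + prev.size)
                    if dq:
                        ops.append(f"{dq}I")
                    if dt:
                        ops.append(f"{dt}D")
                ops.append(f"{b.size}M")
                prev = b
            q_start, q_end = rec.q_start, rec.q_end
            if rec.strand == "-":
                q_start, q_end = rec.q_size - rec.q_end, rec.q_size - rec.q_start
            aligned = sum(b.size for b in rec.blocks)
            fh.write("\t".join(map(str, [
                rec.query_id, rec.q_size, q_start, q_end, rec.strand,
                rec.target_id, rec.t_size, rec.t_start, rec.t_end,
                rec.matches, aligned + rec.q_base_insert + rec.t_base_insert,
                255, "cg:Z:" + "".join(ops),
            ])) + "\n")
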