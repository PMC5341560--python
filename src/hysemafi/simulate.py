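"""Ground-truthed synthetic data for the hybrid long/short-read design.

The generator emulates the structure the pipeline consumes: exon-structured
genes with alternative isoforms; corrected long reads (full length or 5'
truncated, substitution noise, planted exact-substring duplicates); a contig
library holding the all-exon longest molecule, true isoform contigs and —
optionally — false molecules (chimeras joining two genes, shuffled exon
orders); short reads at known per-tissue abundances; and merged junction
fragments.  Every emission is logged in a machine-readable truth manifest.

Structural guarantees built into the generator (and relied on by tests):

* exon sequences share no k-mer across genes (rejection sampling), so
  component-based gene grouping has a clean ground truth;
* every isoform retains the first and last exon (cap / poly-A reading), and
  false contigs are emitted with their final 40 bp trimmed — consequently no
  read, truncated or not, is contained in a false contig, which is what makes
  chimeras fail the 99 % identity qualification by construction;
* skip-run boundaries are chosen so the flanking bases differ, making the
  optimal gap placement unique — planted splice coordinates are then exactly
  recoverable at zero read error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import UsageError
from .io_formats import Role, SequenceRecord

__all__ = [
    "Isoform",
    "GeneModel",
    "TruthManifest",
    "make_genes",
    "emit_long_reads",
    "emit_contigs",
    "emit_short_reads",
    "emit_junction_fragments",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TISSUES = ("root", "stem", "leaf", "flower")
FALSE_CONTIG_TRIM = 40  # bp removed from the 3' end of every false contig


@dataclass(frozen=True)
class Isoform:
    """An exon-index subset (order preserving) of its gene."""

    name: str
    exon_indices: tuple[int, ...]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    exons: tuple[str, ...]
    isoforms: tuple[Isoform, ...]
    # tissue -> isoform name -> abundance (arbitrary expression units)
    abundances: dict[str, dict[str, float]]

    @property
    def exon_offsets(self) -> tuple[int, ...]:
        """Start of each exon on the all-exon contig."""
        offs, pos = [], 0
        for e in self.exons:
            offs.append(pos)
            pos += len(e)
        return tuple(offs)

    @property
    def all_exon_seq(self) -> str:
        return "".join(self.exons)

    def isoform_seq(self, iso: Isoform | str) -> str:
        if isinstance(iso, str):
            iso = self.isoform(iso)
        return "".join(self.exons[i] for i in iso.exon_indices)

    def isoform(self, name: str) -> Isoform:
        for iso in self.isoforms:
            if iso.name == name:
                return iso
        raise KeyError(name)

    def skipped_runs(self, iso: Isoform | str) -> list[tuple[int, int]]:
        """Maximal skipped-exon runs as [t_start, t_end) on the all-exon contig."""
        if isinstance(iso, str):
            iso = self.isoform(iso)
        included = set(iso.exon_indices)
        offs = self.exon_offsets
        runs: list[tuple[int, int]] = []
        i = 0
        n = len(self.exons)
        while i < n:
            if i in included:
                i += 1
                continue
            j = i
            while j < n and j not in included:
                j += 1
            end = offs[j] if j < n else offs[-1] + len(self.exons[-1])
            runs.append((offs[i], end))
            i = j
        return runs

    def expected_signature(self, iso: Isoform | str, min_gap: int = 50) -> tuple[tuple, ...]:
        """The splice signature an error-free read of this isoform produces."""
        return tuple(
            ("exclusion", a, b) for a, b in self.skipped_runs(iso) if b - a > min_gap
        )


@dataclass
class TruthManifest:
    """Machine-readable ground truth for one simulated dataset."""

    genes: dict = field(default_factory=dict)
    reads: list = field(default_factory=list)
    contigs: list = field(default_factory=list)
    short_reads: dict = field(default_factory=dict)
    fragments: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "genes": self.genes,
                    "reads": self.reads,
                    "contigs": self.contigs,
                    "short_reads": self.short_reads,
                    "fragments": self.fragments,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_genes(
    n: int,
    exon_count_range: tuple[int, int] = (3, 6),
    exon_len_range: tuple[int, int] = (80, 400),
    seed: int = 0,
    isoform_counts: Sequence[int] | None = None,
    isoform_count_probs: Sequence[float] = (0.4, 0.4, 0.2),
    tissues: Sequence[str] = DEFAULT_TISSUES,
    de_prob: float = 0.15,
    de_fold: float = 4.0,
    focal_tissue: str | None = None,
    kmer: int = 20,
) -> list[GeneModel]:
    """Draw ``n`` exon-structured gene models, deterministically from ``seed``.

    Exon sequences are rejection-sampled so no k-mer (forward or reverse
    complement) is shared across exons of any gene.  Each gene carries the
    all-exon isoform plus extra isoforms that skip a run of one or two
    internal exons (first and last exon always retained).  The number of
    isoforms per gene follows ``isoform_count_probs`` (probability of 1, 2,
    3, ... isoforms) unless ``isoform_counts`` pins it per gene.  With
    probability ``de_prob`` an isoform is differentially expressed in the
    focal tissue (first of ``tissues`` by default), up or down by
    ``de_fold``.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    if exon_count_range[0] < 3 or exon_count_range[0] > exon_count_range[1]:
        raise UsageError("exon_count_range must be (lo, hi) with lo >= 3")
    if exon_len_range[0] < 10 or exon_len_range[0] > exon_len_range[1]:
        raise UsageError("exon_len_range must be (lo, hi) with lo >= 10")
    if isoform_counts is not None and len(isoform_counts) != n:
        raise UsageError("isoform_counts must have one entry per gene")
    rng = np.random.default_rng(seed)
    focal = focal_tissue or tissues[0]
    if focal not in tissues:
        raise UsageError(f"focal tissue {focal!r} not in tissues")
    seen_kmers: set[str] = set()
    genes: list[GeneModel] = []
    for gi in range(n):
        gene_id = f"g{gi:03d}"
        if isoform_counts is not None:
            n_iso = int(isoform_counts[gi])
        else:
            probs = np.asarray(isoform_count_probs, dtype=float)
            n_iso = int(rng.choice(np.arange(1, len(probs) + 1), p=probs / probs.sum()))
        # redraw the whole exon set until enough skip runs satisfy the
        # flanking-base uniqueness filter (unique optimal gap placement)
        for _gene_attempt in range(30):
            n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
            exons: list[str] = []
            new_kmers: set[str] = set()
            for _ in range(n_exons):
                length = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
                for _attempt in range(100):
                    cand = _random_seq(rng, length)
                    kms = _kmers(cand, kmer) | _kmers(_rc(cand), kmer)
                    if not (kms & (seen_kmers | new_kmers)):
                        new_kmers |= kms
                        exons.append(cand)
                        break
                else:
                    raise UsageError(
                        "could not draw a k-mer-disjoint exon; enlarge exon_len_range"
                    )
            candidate_runs = []
            for a in range(1, n_exons - 1):
                for b in range(a, min(a + 2, n_exons - 1)):
                    # run skips exons a..b; flanking-base uniqueness:
                    if exons[a][0] != exons[b + 1][0] and exons[a - 1][-1] != exons[b][-1]:
                        candidate_runs.append((a, b))
            if len(candidate_runs) >= n_iso - 1:
                seen_kmers |= new_kmers
                break
        else:
            raise UsageError(
                f"could not build {n_iso} isoform structures for {gene_id}; "
                "increase exon_count_range"
            )
        isoforms = [Isoform(name="iso00", exon_indices=tuple(range(n_exons)))]
        order = rng.permutation(len(candidate_runs))
        for idx in order[: max(0, n_iso - 1)]:
            a, b = candidate_runs[idx]
            kept = tuple(i for i in range(n_exons) if not (a <= i <= b))
            isoforms.append(Isoform(name=f"iso{len(isoforms):02d}", exon_indices=kept))
        abundances: dict[str, dict[str, float]] = {t: {} for t in tissues}
        for iso in isoforms:
            base = float(rng.uniform(50.0, 200.0))
            for t in tissues:
                abundances[t][iso.name] = base
            if rng.random() < de_prob:
                direction = 1 if rng.random() < 0.5 else -1
                abundances[focal][iso.name] = (
                    base * de_fold if direction > 0 else base / de_fold
                )
        genes.append(GeneModel(
            gene_id=gene_id, exons=tuple(exons),
            isoforms=tuple(isoforms), abundances=abundances,
        ))
    return genes


def manifest_genes(genes: Sequence[GeneModel], min_gap: int = 50) -> dict:
    """Truth-manifest entry for a gene list (structures + planted events)."""
    out = {}
    for g in genes:
        out[g.gene_id] = {
            "exon_lengths": [len(e) for e in g.exons],
            "all_exon_length": len(g.all_exon_seq),
            "isoforms": {
                iso.name: {
                    "exon_indices": list(iso.exon_indices),
                    "length": len(g.isoform_seq(iso)),
                    "skipped_runs": [list(r) for r in g.skipped_runs(iso)],
                    "signature": [list(e) for e in g.expected_signature(iso, min_gap)],
                }
                for iso in g.isoforms
            },
            "abundances": g.abundances,
        }
    return out


def _apply_errors(
    seq: str,
    rng: np.random.Generator,
    error_rate: float,
    sub_frac: float = 1.0,
    ins_frac: float = 0.0,
    del_frac: float = 0.0,
) -> str:
    """Per-base noise.  Defaults to substitutions only: corrected long reads
    are modelled with residual substitution error, keeping read length equal
    to the source isoform (length-based selection stays exact)."""
    if error_rate == 0:
        return seq
    tot = sub_frac + ins_frac + del_frac
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = []
    errs = rng.random(len(arr)) < error_rate
    kinds = rng.random(len(arr)) * tot
    for i, b in enumerate(arr):
        if not errs[i]:
            out.append(b)
            continue
        kind = kinds[i]
        if kind < sub_frac:
            choices = _BASES[_BASES != b]
            out.append(choices[rng.integers(0, len(choices))])
        elif kind < sub_frac + ins_frac:
            out.append(b)
            out.append(_BASES[rng.integers(0, 4)])
        else:
            pass  # deletion
    return bytes(out).decode()


def emit_long_reads(
    genes: Sequence[GeneModel],
    per_isoform_depth: int = 4,
    error_rate: float = 0.01,
    full_length_frac: float = 0.9,
    duplicate_rate: float = 0.1,
    seed: int = 0,
    sub_frac: float = 1.0,
    ins_frac: float = 0.0,
    del_frac: float = 0.0,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Corrected-long-read library with planted exact-substring duplicates.

    Each isoform yields ``per_isoform_depth`` reads: full length with
    probability ``full_length_frac``, otherwise 5'-truncated at a uniform
    fraction of the length.  Substitution (and optional indel) noise at
    ``error_rate``.  Afterwards ``duplicate_rate`` x n reads are re-emitted
    as proper substrings of an existing read — the containment-duplicate
    cases the dedup stage must remove.
    """
    if not (0.0 <= error_rate <= 0.05):
        raise UsageError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    rows: list[dict] = []
    for g in genes:
        for iso in g.isoforms:
            src = g.isoform_seq(iso)
            for j in range(per_isoform_depth):
                read_id = f"{g.gene_id}.{iso.name}.r{j:02d}"
                full = bool(rng.random() < full_length_frac)
                seq = src
                cut = 0
                if not full:
                    cut = int(rng.uniform(0.1, 0.5) * len(src))
                    # avoid cutting exactly on an exon boundary: keeps the
                    # truncated read anchored mid-exon
                    seq = src[cut:]
                seq = _apply_errors(seq, rng, error_rate, sub_frac, ins_frac, del_frac)
                reads.append(SequenceRecord(id=read_id, seq=seq, role=Role.LONG_READ))
                rows.append({
                    "read_id": read_id, "gene_id": g.gene_id, "isoform": iso.name,
                    "full_length": full, "truncated_5p": cut,
                    "duplicate_of": None, "length": len(seq),
                })
    n_dups = int(round(duplicate_rate * len(reads)))
    eligible = [i for i, r in enumerate(reads) if r.length >= 100]
    picks = rng.choice(len(eligible), size=min(n_dups, len(eligible)), replace=True)
    for k, pi in enumerate(picks):
        src_rec = reads[eligible[int(pi)]]
        row = rows[eligible[int(pi)]]
        max_trim = max(2, src_rec.length // 8)
        d5 = int(rng.integers(0, max_trim))
        d3 = int(rng.integers(1, max_trim))
        sub = src_rec.seq[d5 : src_rec.length - d3]
        dup_id = f"{src_rec.id}.dup{k:02d}"
        reads.append(SequenceRecord(id=dup_id, seq=sub, role=Role.LONG_READ))
        rows.append({
            "read_id": dup_id, "gene_id": row["gene_id"], "isoform": row["isoform"],
            "full_length": False, "truncated_5p": d5,
            "duplicate_of": src_rec.id, "length": len(sub),
        })
    return reads, rows


def emit_contigs(
    genes: Sequence[GeneModel],
    include_false: bool = True,
    true_contig_prob: float = 0.9,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Contig library: all-exon longest + true isoform contigs + false contigs.

    False contigs are chimeras (5' exons of one gene joined to 3' exons of
    the next) and shuffled exon orders, both trimmed by FALSE_CONTIG_TRIM bp
    at the 3' end so no read is exactly contained in them (they must fail the
    identity qualification, as artefactual assemblies do).
    """
    rng = np.random.default_rng(seed)
    contigs: list[SequenceRecord] = []
    roster: list[dict] = []

    def add(cid: str, seq: str, label: str, gene_ids: list[str]) -> None:
        contigs.append(SequenceRecord(id=cid, seq=seq, role=Role.CONTIG))
        roster.append({
            "contig_id": cid, "label": label, "genes": gene_ids, "length": len(seq),
        })

    for gi, g in enumerate(genes):
        add(f"{g.gene_id}_cL", g.all_exon_seq, "longest", [g.gene_id])
        for iso in g.isoforms:
            if len(iso.exon_indices) == len(g.exons):
                continue  # the all-exon contig already covers the full form
            if rng.random() < true_contig_prob:
                add(f"{g.gene_id}_cT_{iso.name}", g.isoform_seq(iso), "true", [g.gene_id])
        if include_false:
            partner = genes[(gi + 1) % len(genes)]
            if partner.gene_id != g.gene_id:
                h_a = max(1, math.ceil(len(g.exons) / 2))
                h_a = min(h_a, len(g.exons) - 1)  # never include g's last exon
                h_b = max(1, len(partner.exons) // 2)  # never include partner's first
                seq = "".join(g.exons[:h_a]) + "".join(partner.exons[h_b:])
                seq = seq[:-FALSE_CONTIG_TRIM]
                add(f"{g.gene_id}_cFc", seq, "false_chimera",
                    [g.gene_id, partner.gene_id])
            # shuffle the internal order but keep the last exon terminal: the
            # 3' trim then guarantees no (possibly truncated) read, which
            # always ends in the full last exon, is contained
            head = rng.permutation(len(g.exons) - 1)
            if np.all(head == np.arange(len(g.exons) - 1)):
                head = head[::-1]
            perm = list(head) + [len(g.exons) - 1]
            seq = "".join(g.exons[i] for i in perm)[:-FALSE_CONTIG_TRIM]
            add(f"{g.gene_id}_cFs", seq, "false_shuffled", [g.gene_id])
    return contigs, roster


def emit_short_reads(
    genes: Sequence[GeneModel],
    tissue_design: Mapping[str, str],
    read_len: int = 100,
    reads_per_sample: int = 2500,
    seed: int = 0,
) -> tuple[dict[str, list[SequenceRecord]], dict]:
    """Short reads per sample, sampled by planted abundance.

    Read counts per isoform follow a multinomial with probability
    proportional to abundance x (isoform length - read_len + 1); start
    positions are uniform.  Reads are error free (the compatibility stage
    models mismatch tolerance separately).
    """
    iso_list: list[tuple[GeneModel, Isoform, str, int]] = []
    for g in genes:
        for iso in g.isoforms:
            seq = g.isoform_seq(iso)
            if read_len >= len(seq):
                raise UsageError(
                    f"read_len={read_len} must be shorter than the shortest "
                    f"isoform ({g.gene_id}/{iso.name}: {len(seq)} bp)"
                )
            iso_list.append((g, iso, seq, len(seq) - read_len + 1))
    samples: dict[str, list[SequenceRecord]] = {}
    manifest: dict = {}
    for si, (sample, tissue) in enumerate(sorted(tissue_design.items())):
        rng = np.random.default_rng([seed, si])
        weights = np.array([
            g.abundances[tissue][iso.name] * npos for g, iso, _, npos in iso_list
        ], dtype=float)
        probs = weights / weights.sum()
        counts = rng.multinomial(reads_per_sample, probs) if reads_per_sample else np.zeros(len(iso_list), dtype=int)
        recs: list[SequenceRecord] = []
        mrows = {}
        ridx = 0
        for (g, iso, seq, npos), cnt in zip(iso_list, counts):
            if cnt:
                starts = rng.integers(0, npos, size=cnt)
                for st in starts:
                    recs.append(SequenceRecord(
                        id=f"{sample}.s{ridx:06d}",
                        seq=seq[int(st) : int(st) + read_len],
                        role=Role.SHORT_READ,
                    ))
                    ridx += 1
            mrows[f"{g.gene_id}.{iso.name}"] = int(cnt)
        samples[sample] = recs
        manifest[sample] = {"tissue": tissue, "isoform_read_counts": mrows}
    return samples, manifest


def emit_junction_fragments(
    genes: Sequence[GeneModel],
    frag_len_range: tuple[int, int] = (300, 590),
    depth_per_junction: int = 3,
    seed: int = 0,
    min_flank: int = 30,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Merged MiSeq-like fragments spanning each planted skip junction.

    Each fragment is a window of the *isoform* sequence containing the skip
    junction with at least ``min_flank`` bases on each side, so exact
    junction probes of flank <= min_flank are guaranteed to be found.
    """
    rng = np.random.default_rng(seed)
    frags: list[SequenceRecord] = []
    rows: list[dict] = []
    for g in genes:
        offs = g.exon_offsets
        for iso in g.isoforms:
            runs = g.skipped_runs(iso)
            if not runs:
                continue
            seq = g.isoform_seq(iso)
            included = list(iso.exon_indices)
            for k, (t_start, t_end) in enumerate(runs):
                # junction position on the isoform sequence
                jpos = sum(len(g.exons[i]) for i in included if offs[i] < t_start)
                for d in range(depth_per_junction):
                    lo, hi = frag_len_range
                    flen = int(rng.integers(lo, hi + 1))
                    flen = min(flen, len(seq))
                    start_lo = max(0, jpos + min_flank - flen)
                    start_hi = min(jpos - min_flank, len(seq) - flen)
                    if start_hi < start_lo:
                        start = max(0, min(jpos - flen // 2, len(seq) - flen))
                    else:
                        start = int(rng.integers(start_lo, start_hi + 1))
                    fid = f"{g.gene_id}.{iso.name}.j{k}.f{d}"
                    frags.append(SequenceRecord(
                        id=fid, seq=seq[start : start + flen], role=Role.SHORT_READ))
                    rows.append({
                        "fragment_id": fid, "gene_id": g.gene_id,
                        "isoform": iso.name, "junction": [t_start, t_end],
                        "start_on_isoform": start, "length": flen,
                    })
    return frags, rows
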