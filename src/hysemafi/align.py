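"""Small-scale affine-gap pairwise aligner producing block-structured records.

The aligner is global in the query and local in the target (free target end
gaps): a long read should be explained end to end, while a contig may carry
UTR or assembly overhangs on either side.  The affine gap model is tuned so
that a skipped exon surfaces as a single target-side gap rather than a run of
mismatches, *and* so that even a long skip (hundreds of bases, as when two
adjacent exons are absent from a read) stays cheaper than sacrificing a short
flanking exon: with the defaults a 50 bp gap costs 7.125 (vs 100 for 50
mismatches) and an 800 bp gap costs 54, below the 80 bp minimum exon gain.
A steeper gap extension would make the optimal alignment drop short terminal
exons instead of opening splice gaps.

All scores are dyadic rationals, so float32 matrices hold them exactly and
equality comparisons during traceback are exact.

Tie-breaking is deterministic: diagonal state is preferred over a query-side
gap over a target-side gap, and gap extension is preferred over re-opening.
This yields canonical gap placement, which the splice-signature stage relies
on.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ResourceBudgetError, UsageError
from .io_formats import AlignmentRecord, Block, SequenceRecord, reverse_complement

__all__ = ["AlignParams", "align_pair", "align_all"]

_NEG = np.float32(-1e30)


@dataclass(frozen=True)
class AlignParams:
    """Scoring and seeding parameters for the internal aligner.

    match_score / mismatch_penalty / gap_open / gap_extend define the affine
    model (penalties are positive magnitudes).  min_seed_len is the k-mer
    length used by align_all to decide which pairs are worth a full DP.
    free_query_ends additionally leaves query end gaps unpenalised (for
    fragmentary queries); long reads are near full length, so it defaults off.
    """

    match_score: float = 1.0
    mismatch_penalty: float = 2.0
    gap_open: float = 4.0
    gap_extend: float = 0.0625  # dyadic: float32 scores stay exact
    min_seed_len: int = 12
    free_query_ends: bool = False

    def __post_init__(self) -> None:
        if self.mismatch_penalty < 0 or self.gap_open < 0 or self.gap_extend < 0:
            raise UsageError("alignment penalties must be >= 0")
        if self.min_seed_len < 8:
            raise UsageError("min_seed_len must be >= 8")


_ENC_Q = np.zeros(256, dtype=np.uint8)
_ENC_T = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC_Q[_b] = _ENC_T[_b] = _i + 1
_ENC_Q[ord("N")] = 5  # N never equals anything, including another N
_ENC_T[ord("N")] = 6


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_M, _X, _Y = 0, 1, 2  # diagonal, query-side gap (vertical), target-side gap


def _fill_matrices(q: np.ndarray, t: np.ndarray, p: AlignParams):
    """Row-wise Gotoh fill.  Returns (H, M, X, Y) float32 matrices.

    X consumes query only (unaligned query bases -> q_num_insert); Y consumes
    target only (skipped target bases -> t_num_insert).  The horizontal (Y)
    recurrence is vectorised with a prefix running max: opening a new
    target-side gap out of an existing one is never optimal (gap_open > 0),
    so Y[i, j] = max_{k<j} (max(M, X)[i, k] + ge*k) - go - ge*j.
    """
    n, m = len(q), len(t)
    ma, mp = np.float32(p.match_score), np.float32(p.mismatch_penalty)
    go, ge = np.float32(p.gap_open), np.float32(p.gap_extend)
    H = np.empty((n + 1, m + 1), dtype=np.float32)
    M = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    H[0, :] = 0.0  # free target prefix
    col0 = np.float32(0.0) if p.free_query_ends else -(go + ge * np.arange(1, n + 1, dtype=np.float32))
    H[1:, 0] = col0
    jidx = (ge * np.arange(m + 1, dtype=np.float64)).astype(np.float32)
    for i in range(1, n + 1):
        srow = np.where(q[i - 1] == t, ma, -mp)
        M[i, 1:] = H[i - 1, :-1] + srow
        X[i, 1:] = np.maximum(X[i - 1, 1:] - ge, H[i - 1, 1:] - go - ge)
        B = np.maximum(M[i], X[i])
        B[0] = H[i, 0]
        acc = np.maximum.accumulate(B + jidx)
        Y[i, 1:] = acc[:-1] - go - jidx[1:]
        H[i, 1:] = np.maximum(B[1:], Y[i, 1:])
        H[i, 0] = col0 if p.free_query_ends else col0[i - 1]
    return H, M, X, Y


def _traceback(H, M, X, Y, q, t, p: AlignParams, end: tuple[int, int]):
    """Walk back from ``end`` returning the aligned path as (op, length) runs.

    ops: 'D' diagonal, 'X' query-gap, 'Y' target-gap.  Deterministic state
    preference at equal score: M > X > Y; extension preferred over opening.
    """
    ge = np.float32(p.gap_extend)
    go = np.float32(p.gap_open)
    i, j = end
    # choose terminal state
    if M[i, j] == H[i, j]:
        state = _M
    elif X[i, j] == H[i, j]:
        state = _X
    else:
        state = _Y
    path: list[str] = []
    while i > 0 and j > 0:
        if state == _M:
            path.append("D")
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                break
            if M[i, j] == H[i, j]:
                state = _M
            elif X[i, j] == H[i, j]:
                state = _X
            else:
                state = _Y
        elif state == _X:
            path.append("X")
            if X[i, j] == X[i - 1, j] - ge:
                i -= 1
                state = _X
            else:
                i -= 1
                if i == 0 or j == 0:
                    break
                if M[i, j] == H[i, j]:
                    state = _M
                elif X[i, j] == H[i, j]:
                    state = _X
                else:
                    state = _Y
        else:  # _Y
            path.append("Y")
            if Y[i, j] == Y[i, j - 1] - ge:
                j -= 1
                state = _Y
            else:
                j -= 1
                if i == 0 or j == 0:
                    break
                if M[i, j] == H[i, j]:
                    state = _M
                elif X[i, j] == H[i, j]:
                    state = _X
                else:
                    state = _Y
        # boundary handled by loop condition
    path.reverse()
    return path, i, j  # start cell (query bases [0,i) / target [0,j) unaligned)


def align_pair(
    query: SequenceRecord,
    target: SequenceRecord,
    params: AlignParams | None = None,
    dp_budget: int = 100_000_000,
    strand: str = "+",
) -> AlignmentRecord | None:
    """Optimal affine-gap alignment of ``query`` against ``target``.

    Global in query (unless ``params.free_query_ends``), local in target.
    Returns None when the best score is <= 0.  ``strand`` only annotates the
    produced record; callers align the reverse-complemented query themselves.
    """
    params = params or AlignParams()
    if not query.seq or not target.seq:
        raise UsageError("align_pair requires non-empty sequences")
    n, m = query.length, target.length
    # exact containment fast path: a perfect single block is provably optimal
    # for any positive match score.
    pos = target.seq.find(query.seq)
    if pos >= 0 and "N" not in query.seq:
        return AlignmentRecord(
            query_id=query.id, target_id=target.id, strand=strand,
            matches=n, mismatches=0,
            q_num_insert=0, q_base_insert=0, t_num_insert=0, t_base_insert=0,
            q_start=0, q_end=n, t_start=pos, t_end=pos + n,
            q_size=n, t_size=m, blocks=(Block(n, 0, pos),),
        ).validate()
    if (n + 1) * (m + 1) > dp_budget:
        raise ResourceBudgetError(
            f"DP of {n}x{m} exceeds budget of {dp_budget} cells; align "
            "externally (e.g. BLAT/minimap2) and supply PSL/PAF instead"
        )
    qa, ta = _encode(query.seq, _ENC_Q), _encode(target.seq, _ENC_T)
    H, M, X, Y = _fill_matrices(qa, ta, params)
    if params.free_query_ends:
        flat = int(np.argmax(H))
        ei, ej = divmod(flat, m + 1)
    else:
        ei = n
        ej = int(np.argmax(H[n]))
    best = float(H[ei, ej])
    if best <= 0 or ei == 0 or ej == 0:
        return None
    path, si, sj = _traceback(H, M, X, Y, qa, ta, params, (ei, ej))
    # trim terminal gap runs into start/end offsets
    a, b = 0, len(path)
    while a < b and path[a] != "D":
        if path[a] == "X":
            si += 1
        else:
            sj += 1
        a += 1
    while b > a and path[b - 1] != "D":
        if path[b - 1] == "X":
            ei -= 1
        else:
            ej -= 1
        b -= 1
    path = path[a:b]
    if not path:
        return None
    blocks: list[Block] = []
    qi, tj = si, sj
    matches = mismatches = qni = qbi = tni = tbi = 0
    run = 0
    k = 0
    while k < len(path):
        op = path[k]
        run = 1
        while k + run < len(path) and path[k + run] == op:
            run += 1
        if op == "D":
            blocks.append(Block(run, qi, tj))
            seg_q = query.seq[qi : qi + run]
            seg_t = target.seq[tj : tj + run]
            eq = sum(1 for x, y in zip(seg_q, seg_t) if x == y and x != "N")
            matches += eq
            mismatches += run - eq
            qi += run
            tj += run
        elif op == "X":
            qni += 1
            qbi += run
            qi += run
        else:
            tni += 1
            tbi += run
            tj += run
        k += run
    return AlignmentRecord(
        query_id=query.id, target_id=target.id, strand=strand,
        matches=matches, mismatches=mismatches,
        q_num_insert=qni, q_base_insert=qbi, t_num_insert=tni, t_base_insert=tbi,
        q_start=si, q_end=ei, t_start=sj, t_end=ej,
        q_size=n, t_size=m, blocks=tuple(blocks),
    ).validate()


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


def containment_alignments(
    reads: Sequence[SequenceRecord],
    max_mismatch_frac: float = 0.01,
    k: int = 12,
) -> list[AlignmentRecord]:
    """All-vs-all gapless containment alignments among ``reads``.

    Emits a single-block AlignmentRecord for every ordered pair (B, A) with
    len(B) <= len(A) where B matches a window of A with at most
    ``max_mismatch_frac * len(B)`` mismatches — exactly the alignments the
    containment dedup rule can accept (no overhangs, no gaps).  Pairs whose
    best alignment would be gapped or worse than the mismatch budget produce
    nothing, which the dedup rule treats identically to a disqualifying
    alignment.  Much faster than full DP for the dedup stage.
    """
    enc = {r.id: np.frombuffer(r.seq.encode(), dtype=np.uint8) for r in reads}
    index: dict[str, list[tuple[str, int]]] = {}
    for r in reads:
        for i in range(0, r.length - k + 1):
            index.setdefault(r.seq[i : i + k], []).append((r.id, i))
    by_id = {r.id: r for r in reads}
    out: list[AlignmentRecord] = []
    for read in sorted(reads, key=lambda r: r.id):
        m_budget = int(max_mismatch_frac * read.length)
        n_seg = m_budget + 1
        seg = read.length // n_seg
        if seg < k:
            n_seg = max(1, read.length // k)
            seg = read.length // n_seg
        offsets = [i * seg for i in range(n_seg)]
        cand: set[tuple[str, int]] = set()
        for off in offsets:
            for tid, pos in index.get(read.seq[off : off + k], ()):
                start = pos - off
                if tid != read.id and start >= 0 \
                        and start + read.length <= by_id[tid].length:
                    cand.add((tid, start))
        best: dict[str, tuple[int, int]] = {}  # tid -> (mismatches, start)
        qa = enc[read.id]
        for tid, start in cand:
            window = enc[tid][start : start + read.length]
            mm = int(np.count_nonzero(window != qa))
            if mm <= m_budget:
                cur = best.get(tid)
                if cur is None or (mm, start) < cur:
                    best[tid] = (mm, start)
        for tid in sorted(best):
            mm, start = best[tid]
            out.append(AlignmentRecord(
                query_id=read.id, target_id=tid, strand="+",
                matches=read.length - mm, mismatches=mm,
                q_num_insert=0, q_base_insert=0, t_num_insert=0, t_base_insert=0,
                q_start=0, q_end=read.length,
                t_start=start, t_end=start + read.length,
                q_size=read.length, t_size=by_id[tid].length,
                blocks=(Block(read.length, 0, start),),
            ).validate())
    return out


_PREFILTER_K = 20


def _identity_upper_bound(query_seq: str, target_kmers: set[str],
                          target_index: dict[str, list[int]] | None = None,
                          k: int = _PREFILTER_K) -> float:
    """Conservative upper bound on achievable identity (matches / |query|).

    Any run of >= k consecutively matching, gap-free positions implies a
    shared k-mer; a query k-mer start without a *collinearly placeable*
    shared k-mer therefore costs at least 1/k non-matching positions.  With
    ``target_index`` (k-mer -> sorted target positions) the shared k-mers are
    additionally required to chain collinearly (longest increasing
    subsequence over target positions), which catches shuffled-exon targets
    that plain k-mer content cannot.
    """
    L = len(query_seq)
    n_kmers = L - k + 1
    if n_kmers <= 0:
        return 1.0
    if target_index is None:
        covered = sum(
            1 for i in range(n_kmers) if query_seq[i : i + k] in target_kmers)
    else:
        # anchors in query order; LIS over target positions = chainable count
        tails: list[int] = []
        for i in range(n_kmers):
            for pos in target_index.get(query_seq[i : i + k], ()):
                # longest non-decreasing chain
                idx = bisect.bisect_right(tails, pos)
                if idx == len(tails):
                    tails.append(pos)
                else:
                    tails[idx] = pos
        covered = len(tails)
    uncovered = n_kmers - covered
    return 1.0 - uncovered / (k * L)


def align_all(
    queries: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    params: AlignParams | None = None,
    min_identity: float = 0.0,
    both_strands: bool = True,
    dp_budget: int = 100_000_000,
    pair_filter=None,
    prefilter_identity: float | None = None,
) -> list[AlignmentRecord]:
    """Align every query against every target sharing a seed k-mer.

    Alignments with identity (matches / query length) below ``min_identity``
    are dropped.  Self-pairs (same id) are skipped, which makes the function
    directly usable for all-vs-all read dedup.  ``pair_filter(q, t) -> bool``
    can prune pairs before any work (e.g. only shorter-vs-longer for dedup).
    ``prefilter_identity`` skips the full DP for pairs whose collinear
    seed-chain bound proves the identity cannot reach that value (see
    _identity_upper_bound); alignments that would qualify are never lost.
    Output is sorted by (query id, target id) and deterministic.
    """
    params = params or AlignParams()
    if not queries or not targets:
        raise UsageError("align_all requires non-empty query and target sets")
    k = params.min_seed_len
    index: dict[str, set[str]] = {}
    by_id = {t.id: t for t in targets}
    for t in targets:
        for km in _kmers(t.seq, k):
            index.setdefault(km, set()).add(t.id)
    chain_index: dict[str, dict[str, list[int]]] = {}
    if prefilter_identity is not None:
        for t in targets:
            d: dict[str, list[int]] = {}
            for i in range(0, t.length - _PREFILTER_K + 1):
                d.setdefault(t.seq[i : i + _PREFILTER_K], []).append(i)
            chain_index[t.id] = d
    out: list[AlignmentRecord] = []
    for query in sorted(queries, key=lambda r: r.id):
        fwd_hits: set[str] = set()
        for km in _kmers(query.seq, k):
            fwd_hits |= index.get(km, set())
        rev_seq = reverse_complement(query.seq)
        rev_hits: set[str] = set()
        if both_strands:
            for km in _kmers(rev_seq, k):
                rev_hits |= index.get(km, set())
        for tid in sorted(fwd_hits | rev_hits):
            if tid == query.id:
                continue
            target = by_id[tid]
            if pair_filter is not None and not pair_filter(query, target):
                continue
            if prefilter_identity is not None:
                bound = 0.0
                if tid in fwd_hits:
                    bound = _identity_upper_bound(
                        query.seq, set(), chain_index[tid])
                if tid in rev_hits:
                    bound = max(bound, _identity_upper_bound(
                        rev_seq, set(), chain_index[tid]))
                if bound < prefilter_identity:
                    continue
            best: AlignmentRecord | None = None
            if tid in fwd_hits:
                best = align_pair(query, target, params, dp_budget, strand="+")
            if tid in rev_hits:
                rc = SequenceRecord(id=query.id, seq=rev_seq, role=query.role)
                cand = align_pair(rc, target, params, dp_budget, strand="-")
                if cand is not None and (best is None or cand.matches > best.matches):
                    best = cand
            if best is not None and best.identity >= min_identity:
                out.append(best)
    return out
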