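"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from scratch (plain Python loops,
direct arithmetic) and never calls into the package's own implementations of
the operations it checks.
"""

from __future__ import annotations


def oracle_align(q: str, t: str, match=1.0, mismatch=2.0, gap_open=4.0,
                 gap_extend=0.0625, free_query_ends=False):
    """Textbook quadratic-space affine-gap DP: global in query, local in target.

    Returns (score, ops, start_i, start_j) where ops is a list of 'D'
    (diagonal), 'X' (query-consuming gap), 'Y' (target-consuming gap) from
    the alignment start.  State preference at equal score: D > X > Y, gap
    extension preferred over re-opening.
    """
    n, m = len(q), len(t)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        H[0][j] = 0.0
    for i in range(1, n + 1):
        H[i][0] = 0.0 if free_query_ends else -(gap_open + gap_extend * i)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] != "N") else -mismatch
            M[i][j] = H[i - 1][j - 1] + s
            X[i][j] = max(X[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            Y[i][j] = max(Y[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            H[i][j] = max(M[i][j], X[i][j], Y[i][j])
    if free_query_ends:
        best, ei, ej = NEG, 0, 0
        for i in range(n + 1):
            for j in range(m + 1):
                if H[i][j] > best:
                    best, ei, ej = H[i][j], i, j
    else:
        ei = n
        ej = max(range(m + 1), key=lambda j: (H[n][j], -j))
        best = H[n][ej]
    i, j = ei, ej
    if M[i][j] == H[i][j]:
        state = "M"
    elif X[i][j] == H[i][j]:
        state = "X"
    else:
        state = "Y"
    ops = []
    while i > 0 and j > 0:
        if state == "M":
            ops.append("D")
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                break
            state = "M" if M[i][j] == H[i][j] else ("X" if X[i][j] == H[i][j] else "Y")
        elif state == "X":
            ops.append("X")
            ext = X[i][j] == X[i - 1][j] - gap_extend
            i -= 1
            if ext:
                state = "X"
            else:
                if i == 0 or j == 0:
                    break
                state = "M" if M[i][j] == H[i][j] else ("X" if X[i][j] == H[i][j] else "Y")
        else:
            ops.append("Y")
            ext = Y[i][j] == Y[i][j - 1] - gap_extend
            j -= 1
            if ext:
                state = "Y"
            else:
                if i == 0 or j == 0:
                    break
                state = "M" if M[i][j] == H[i][j] else ("X" if X[i][j] == H[i][j] else "Y")
    ops.reverse()
    return best, ops, i, j, (ei, ej)


def oracle_record_fields(q: str, t: str, **kw):
    """Reduce an oracle alignment to the fields an AlignmentRecord carries
    (terminal gap runs trimmed into start/end offsets, as the aligner does)."""
    score, ops, si, sj, (ei, ej) = oracle_align(q, t, **kw)
    a, b = 0, len(ops)
    while a < b and ops[a] != "D":
        if ops[a] == "X":
            si += 1
        else:
            sj += 1
        a += 1
    while b > a and ops[b - 1] != "D":
        if ops[b - 1] == "X":
            ei -= 1
        else:
            ej -= 1
        b -= 1
    ops = ops[a:b]
    blocks = []
    matches = mismatches = qni = qbi = tni = tbi = 0
    qi, tj = si, sj
    k = 0
    while k < len(ops):
        op = ops[k]
        run = 1
        while k + run < len(ops) and ops[k + run] == op:
            run += 1
        if op == "D":
            blocks.append((run, qi, tj))
            for x, y in zip(q[qi : qi + run], t[tj : tj + run]):
                if x == y and x != "N":
                    matches += 1
                else:
                    mismatches += 1
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
    return {
        "score": score, "blocks": tuple(blocks),
        "matches": matches, "mismatches": mismatches,
        "q_num_insert": qni, "q_base_insert": qbi,
        "t_num_insert": tni, "t_base_insert": tbi,
        "q_start": si, "q_end": ei, "t_start": sj, "t_end": ej,
    }


def record_score(rec, match=1.0, mismatch=2.0, gap_open=4.0, gap_extend=0.0625,
                 penalize_query_ends=True):
    """Re-derive the DP score of an alignment record from its counts."""
    score = match * rec.matches - mismatch * rec.mismatches
    prev = None
    for blk in rec.blocks:
        if prev is not None:
            dq = blk.q_start - (prev.q_start + prev.size)
            dt = blk.t_start - (prev.t_start + prev.size)
            if dq:
                score -= gap_open + gap_extend * dq
            if dt:
                score -= gap_open + gap_extend * dt
        prev = blk
    if penalize_query_ends:
        lead = rec.q_start
        tail = rec.q_size - rec.q_end
        if lead:
            score -= gap_open + gap_extend * lead
        if tail:
            score -= gap_open + gap_extend * tail
    return score


def brute_force_dedup(reads, alignments, min_similarity=0.99, max_overhang=0,
                      max_gap_openings=0):
    """Exhaustive O(n^2) application of the containment rule.

    Same retention order as the pipeline (longest first, id ascending), but
    the rule itself is re-evaluated inline from raw alignment fields.
    """
    best = {}
    for a in alignments:
        key = (a.query_id, a.target_id)
        if key not in best or a.matches > best[key].matches:
            best[key] = a
    lengths = {r.id: r.length for r in reads}
    retained = []
    removed = []
    for read in sorted(reads, key=lambda r: (-r.length, r.id)):
        dup_of = None
        for kept in retained:
            a = best.get((read.id, kept.id))
            if a is None:
                continue
            if (
                lengths[kept.id] > lengths[read.id]
                and a.q_start <= max_overhang
                and (a.q_size - a.q_end) <= max_overhang
                and a.matches / lengths[read.id] > min_similarity
                and a.q_num_insert + a.t_num_insert <= max_gap_openings
            ):
                dup_of = kept.id
                break
        if dup_of is None:
            retained.append(read)
        else:
            removed.append((read.id, dup_of))
    return {r.id for r in retained}, removed


def brute_force_longest(alignments, min_identity=0.99):
    """Enumerate the A/B selection rule over every (contig, read) pair."""
    qual = [a for a in alignments if a.matches / a.q_size >= min_identity]
    if not qual:
        return None
    max_read = max(a.q_size for a in qual)
    sizes = {}
    for a in qual:
        sizes[a.target_id] = a.t_size
    cands = [(size, cid) for cid, size in sizes.items() if size >= max_read]
    if not cands:
        return None
    return min(cands, key=lambda x: (-x[0], x[1]))[1]


def brute_force_gap_classes(alignments, min_gap=50):
    """Group reads by the exact tuple of their raw block-jump gaps."""
    classes = {}
    for a in alignments:
        events = []
        for prev, nxt in zip(a.blocks, a.blocks[1:]):
            dq = nxt.q_start - (prev.q_start + prev.size)
            dt = nxt.t_start - (prev.t_start + prev.size)
            if dt - dq > min_gap:
                events.append(("exclusion", prev.t_start + prev.size, nxt.t_start))
            elif dq - dt > min_gap:
                events.append(("insertion", prev.t_start + prev.size, dq))
        key = tuple(sorted(events, key=lambda e: (e[1], e[2], e[0])))
        classes.setdefault(key, set()).add(a.query_id)
    return classes


def bh_adjust(pvals):
    """Direct Benjamini-Hochberg arithmetic."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = n - rank_from_end
        running = min(running, pvals[idx] * n / rank)
        adj[idx] = running
    return adj
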