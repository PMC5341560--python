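"""Isoform abundance estimation and differential-expression screening.

Short reads are reduced to compatibility classes (the set of reference
isoforms a read matches), and abundances come from the standard EM for the
read-generating mixture: a read from isoform i arises with probability
proportional to theta_i / effective_length_i.  Expected counts and TPM are
reported per sample.

Differential expression between two conditions uses a Poisson likelihood-
ratio test on expected counts with library-size offsets, BH adjustment
across isoforms, and the triple screening cutoff: p < 0.05, FDR < 0.01 and
fold change >= 2.  Tissue-specific isoforms are the intersection of the
pairwise screens of a focal condition against every other condition, in a
consistent direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, UsageError
from .io_formats import SequenceRecord

__all__ = [
    "CompatibilityTable",
    "ExpressionTable",
    "build_compatibility",
    "em_abundance",
    "de_screen",
    "tissue_specific",
]


@dataclass(frozen=True)
class CompatibilityTable:
    """Weighted read classes: (compatible isoform ids, number of reads)."""

    classes: tuple[tuple[tuple[str, ...], int], ...]
    n_unmapped: int
    mean_read_len: float

    @property
    def n_mapped(self) -> int:
        return sum(w for _, w in self.classes)


@dataclass
class ExpressionTable:
    """isoform x sample expected counts and TPM plus the sample design."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    design: dict[str, str]  # sample -> condition

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.tpm.columns):
            raise ConsistencyError("counts and tpm must share samples")
        missing = set(self.counts.columns) - set(self.design)
        if missing:
            raise ConsistencyError(f"samples without a condition: {sorted(missing)}")

    def samples_of(self, condition: str) -> list[str]:
        cols = [s for s in self.counts.columns if self.design[s] == condition]
        if not cols:
            raise UsageError(f"unknown condition label {condition!r}")
        return cols

    def conditions(self) -> list[str]:
        return sorted(set(self.design[s] for s in self.counts.columns))


def _seed_offsets(read_len: int, k: int, max_mismatches: int) -> list[int]:
    """Disjoint seed offsets guaranteeing a clean k-mer under <= m mismatches."""
    n_seg = max_mismatches + 1
    seg = read_len // n_seg
    if seg < k:
        raise UsageError(
            f"read length {read_len} too short for {n_seg} disjoint {k}-mers"
        )
    return [i * seg for i in range(n_seg)]


def build_compatibility(
    short_reads: Sequence[SequenceRecord],
    reference: Sequence[SequenceRecord],
    k: int = 20,
    max_mismatches: int = 0,
) -> CompatibilityTable:
    """Assign each read its set of compatible reference isoforms.

    A read is compatible with an isoform when the full read matches at some
    offset with at most ``max_mismatches`` mismatches (exact by default).
    Matching is seeded: the read is cut into ``max_mismatches + 1`` disjoint
    segments so at least one seed k-mer is error free.  Reads matching
    nothing are dropped and counted.  Identical compatibility sets merge into
    weighted classes.
    """
    if not reference:
        raise UsageError("reference must be non-empty")
    index: dict[str, list[tuple[int, int]]] = {}
    ref_seqs = [r.seq for r in reference]
    for ri, seq in enumerate(ref_seqs):
        for i in range(0, len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((ri, i))
    class_counts: dict[tuple[str, ...], int] = {}
    n_unmapped = 0
    total_len = 0
    for read in short_reads:
        total_len += read.length
        offsets = _seed_offsets(read.length, k, max_mismatches)
        hits: set[int] = set()
        cand: set[tuple[int, int]] = set()
        for off in offsets:
            for ri, pos in index.get(read.seq[off : off + k], ()):
                start = pos - off
                if start >= 0 and start + read.length <= len(ref_seqs[ri]):
                    cand.add((ri, start))
        for ri, start in cand:
            if ri in hits:
                continue
            window = ref_seqs[ri][start : start + read.length]
            if max_mismatches == 0:
                ok = window == read.seq
            else:
                mm = sum(1 for a, b in zip(window, read.seq) if a != b)
                ok = mm <= max_mismatches
            if ok:
                hits.add(ri)
        if not hits:
            n_unmapped += 1
            continue
        key = tuple(sorted(reference[ri].id for ri in hits))
        class_counts[key] = class_counts.get(key, 0) + 1
    classes = tuple(sorted(class_counts.items()))
    mean_len = total_len / len(short_reads) if short_reads else 0.0
    return CompatibilityTable(
        classes=classes, n_unmapped=n_unmapped, mean_read_len=mean_len
    )


def effective_length(length: int, mean_fragment_length: float) -> float:
    """Standard effective length, floored at 1."""
    return max(1.0, length - mean_fragment_length + 1.0)


def em_abundance(
    table: CompatibilityTable,
    isoform_lengths: Mapping[str, int],
    mean_fragment_length: float | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[pd.DataFrame, list[float]]:
    """EM abundance estimation over the compatibility classes.

    Returns (DataFrame indexed by isoform with est_counts and tpm, the data
    log-likelihood trace).  The log-likelihood is non-decreasing every
    iteration (asserted).  Uniform initialisation; deterministic.
    """
    if not table.classes:
        raise UsageError("compatibility table is empty")
    isoforms = sorted(isoform_lengths)
    idx = {iso: i for i, iso in enumerate(isoforms)}
    if mean_fragment_length is None:
        mean_fragment_length = table.mean_read_len
    eff = np.array(
        [effective_length(isoform_lengths[i], mean_fragment_length) for i in isoforms]
    )
    if np.any(eff <= 0):
        raise UsageError("zero effective length")
    members: list[np.ndarray] = []
    weights: list[float] = []
    for ids, w in table.classes:
        for i in ids:
            if i not in idx:
                raise ConsistencyError(f"compatibility class references unknown isoform {i!r}")
        members.append(np.array([idx[i] for i in ids], dtype=int))
        weights.append(float(w))
    w_arr = np.array(weights)
    n = len(isoforms)
    theta = np.full(n, 1.0 / n)
    loglik_trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        counts = np.zeros(n)
        ll = 0.0
        for mem, w in zip(members, w_arr):
            rates = theta[mem] / eff[mem]
            tot = rates.sum()
            ll += w * math.log(tot)
            counts[mem] += w * rates / tot
        loglik_trace.append(ll)
        assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
        new_theta = counts / counts.sum()
        delta = np.max(np.abs(new_theta - theta))
        theta = new_theta
        if ll - prev_ll < tol and delta < tol:
            break
        prev_ll = ll
    est_counts = np.zeros(n)
    for mem, w in zip(members, w_arr):
        rates = theta[mem] / eff[mem]
        est_counts[mem] += w * rates / rates.sum()
    tpm = theta / theta.sum() * 1e6
    frame = pd.DataFrame({"est_counts": est_counts, "tpm": tpm}, index=pd.Index(isoforms, name="isoform"))
    return frame, loglik_trace


def _poisson_lrt(ya: np.ndarray, sa: np.ndarray, yb: np.ndarray, sb: np.ndarray) -> float:
    """Two-sample Poisson LRT p-value with library-size offsets (chi2, df=1)."""
    Ya, Sa, Yb, Sb = ya.sum(), sa.sum(), yb.sum(), sb.sum()
    if Ya + Yb == 0:
        return 1.0
    mu_a = Ya / Sa
    mu_b = Yb / Sb
    mu0 = (Ya + Yb) / (Sa + Sb)
    def term(y, mu):
        return y * math.log(mu) if y > 0 else 0.0
    lrt = 2.0 * (term(Ya, mu_a) + term(Yb, mu_b) - term(Ya + Yb, mu0))
    lrt = max(lrt, 0.0)
    return float(stats.chi2.sf(lrt, df=1))


@dataclass(frozen=True)
class DECutoffs:
    p_value: float = 0.05
    fdr: float = 0.01
    min_fold: float = 2.0


def de_screen(
    expr: ExpressionTable,
    cond_a: str,
    cond_b: str,
    cutoffs: DECutoffs | None = None,
) -> pd.DataFrame:
    """Screen isoforms for differential expression between two conditions.

    Per isoform: Poisson LRT on expected counts with per-sample total-count
    offsets; BH-adjusted FDR across isoforms; log2 fold change on
    normalised mean counts with a 0.5 pseudo-count.  ``passed`` requires
    p < cutoffs.p_value, FDR < cutoffs.fdr and |log2FC| >= log2(min_fold).
    With a single replicate per condition the test degrades to the count-
    ratio test; a ``single_replicate`` column flags it.
    """
    cutoffs = cutoffs or DECutoffs()
    sa_cols = expr.samples_of(cond_a)
    sb_cols = expr.samples_of(cond_b)
    counts = expr.counts
    ya = counts[sa_cols].to_numpy(float)
    yb = counts[sb_cols].to_numpy(float)
    sa = ya.sum(axis=0)
    sb = yb.sum(axis=0)
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise UsageError("every sample needs positive total counts")
    sbar = np.concatenate([sa, sb]).mean()
    pvals = np.array([
        _poisson_lrt(ya[i], sa, yb[i], sb) for i in range(counts.shape[0])
    ])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    na = (ya / sa * sbar).mean(axis=1)
    nb = (yb / sb * sbar).mean(axis=1)
    log2_fc = np.log2((na + 0.5) / (nb + 0.5))
    passed = (
        (pvals < cutoffs.p_value)
        & (fdr < cutoffs.fdr)
        & (np.abs(log2_fc) >= math.log2(cutoffs.min_fold))
    )
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": pvals,
            "fdr": fdr,
            "passed": passed,
            "single_replicate": len(sa_cols) == 1 or len(sb_cols) == 1,
        },
        index=counts.index,
    )


def tissue_specific(
    expr: ExpressionTable,
    focal: str,
    others: Sequence[str] | None = None,
    cutoffs: DECutoffs | None = None,
    direction: str = "up",
) -> list[str]:
    """Isoforms passing the screen in ``direction`` against every other condition.

    ``direction`` is "up" (consistently highest in the focal condition) or
    "down".  Intersection semantics: failing against any single other
    condition excludes the isoform.
    """
    if direction not in ("up", "down"):
        raise UsageError("direction must be 'up' or 'down'")
    if others is None:
        others = [c for c in expr.conditions() if c != focal]
    if not others:
        raise UsageError("tissue_specific needs at least one other condition")
    selected: set[str] | None = None
    for other in others:
        res = de_screen(expr, focal, other, cutoffs)
        ok = res["passed"] & ((res["log2_fc"] > 0) if direction == "up" else (res["log2_fc"] < 0))
        ids = set(res.index[ok])
        selected = ids if selected is None else (selected & ids)
    return sorted(selected or [])
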