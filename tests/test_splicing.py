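import numpy as np
import pytest

from hysemafi import simulate
from hysemafi.align import align_pair
from hysemafi.io_formats import AlignmentRecord, Block, SequenceRecord, Role
from hysemafi.splicing import (
    EXCLUSION,
    INSERTION,
    IsoformCatalog,
    build_catalog,
    catalog_gene,
    extract_gaps,
    signature,
    summarize_catalog,
    verify_junctions,
)

from _oracles import brute_force_gap_classes
from conftest import make_contig, make_read, random_seq


def _gapped(q="r", t="c", blocks=((100, 0, 0), (120, 100, 180)),
            q_size=None, t_size=500):
    blocks = tuple(Block(*b) for b in blocks)
    total = sum(b.size for b in blocks)
    q_end = blocks[-1].q_start + blocks[-1].size
    t_end = blocks[-1].t_start + blocks[-1].size
    qbi = q_end - blocks[0].q_start - total
    tbi = t_end - blocks[0].t_start - total
    q_size = q_size or q_end
    return AlignmentRecord(
        query_id=q, target_id=t, strand="+", matches=total, mismatches=0,
        q_num_insert=int(qbi > 0), q_base_insert=qbi,
        t_num_insert=int(tbi > 0), t_base_insert=tbi,
        q_start=blocks[0].q_start, q_end=q_end,
        t_start=blocks[0].t_start, t_end=t_end,
        q_size=q_size, t_size=t_size, blocks=blocks,
    ).validate()


class TestExtractGaps:
    def test_exclusion_coordinates(self):
        (ev,) = extract_gaps(_gapped())
        assert (ev.kind, ev.t_start, ev.t_end, ev.length) == (EXCLUSION, 100, 180, 80)

    def test_single_block_no_events(self):
        assert extract_gaps(_gapped(blocks=((200, 0, 0),))) == []

    def test_fifty_bp_gap_is_not_a_splice(self):
        """'longer than 50 bp' is strict: a 50 bp gap yields no event."""
        aln = _gapped(blocks=((100, 0, 0), (100, 100, 150)))
        assert extract_gaps(aln) == []
        aln51 = _gapped(blocks=((100, 0, 0), (100, 100, 151)))
        assert len(extract_gaps(aln51)) == 1

    def test_query_side_gap_is_insertion(self):
        aln = _gapped(blocks=((100, 0, 0), (100, 180, 100)), q_size=280)
        (ev,) = extract_gaps(aln)
        assert ev.kind == INSERTION and ev.length == 80 and ev.t_start == 100


class TestSignature:
    def test_same_isoform_reads_share_signature(self, small_genes):
        gene = next(g for g in small_genes if len(g.isoforms) > 1)
        contig = make_contig("cL", gene.all_exon_seq)
        iso = gene.isoforms[1]
        r1 = make_read("r1", gene.isoform_seq(iso))
        r2 = make_read("r2", gene.isoform_seq(iso))
        assert signature(align_pair(r1, contig)) == signature(align_pair(r2, contig))

    def test_skip_isoform_differs_from_full(self, small_genes):
        gene = next(g for g in small_genes if len(g.isoforms) > 1)
        contig = make_contig("cL", gene.all_exon_seq)
        full = make_read("rf", gene.isoform_seq(gene.isoforms[0]))
        skip = make_read("rs", gene.isoform_seq(gene.isoforms[1]))
        sig_full = signature(align_pair(full, contig))
        sig_skip = signature(align_pair(skip, contig))
        assert sig_full == ()
        assert sig_skip == gene.expected_signature(gene.isoforms[1])

    def test_same_length_different_site_distinct(self):
        a = _gapped(blocks=((100, 0, 0), (120, 100, 180)))
        b = _gapped(blocks=((150, 0, 0), (70, 150, 230)))
        assert signature(a) != signature(b)
        assert extract_gaps(a)[0].length == extract_gaps(b)[0].length == 80


class TestCatalog:
    def test_recovers_planted_isoform_classes(self, small_genes):
        gene = next(g for g in small_genes if len(g.isoforms) == 3)
        contig = make_contig("cL", gene.all_exon_seq)
        alns = []
        for iso in gene.isoforms:
            for j in range(2):
                alns.append(align_pair(
                    make_read(f"{iso.name}.r{j}", gene.isoform_seq(iso)), contig))
        sigs = catalog_gene(gene.gene_id, alns, round_bp=0)
        assert len(sigs) == 3
        truth = {gene.expected_signature(iso) for iso in gene.isoforms}
        assert {s.events for s in sigs} == truth
        # support partitions the reads
        all_reads = [r for s in sigs for r in s.support]
        assert sorted(all_reads) == sorted(a.query_id for a in alns)

    def test_all_gapless_single_class(self):
        alns = [_gapped(q=f"r{i}", blocks=((200, 0, 0),)) for i in range(4)]
        sigs = catalog_gene("g", alns, round_bp=0)
        assert len(sigs) == 1 and sigs[0].is_gapless and sigs[0].n_support == 4

    def test_matches_bruteforce_grouping(self, small_genes):
        gene = next(g for g in small_genes if len(g.isoforms) == 3)
        contig = make_contig("cL", gene.all_exon_seq)
        alns = [
            align_pair(make_read(f"{iso.name}.r{j}", gene.isoform_seq(iso)), contig)
            for iso in gene.isoforms for j in range(2)
        ]
        sigs = catalog_gene(gene.gene_id, alns, round_bp=0)
        oracle = brute_force_gap_classes(alns)
        assert {frozenset(s.support) for s in sigs} == {
            frozenset(v) for v in oracle.values()}

    def test_rounding_merges_jittered_endpoints(self):
        a = _gapped(q="r1", blocks=((100, 0, 0), (120, 100, 180)))
        b = _gapped(q="r2", blocks=((98, 0, 0), (120, 98, 180)), q_size=218)
        # r2's gap is 98-180 (length 82): within 5 bp of r1's 100-180
        merged = catalog_gene("g", [a, b], round_bp=5)
        assert len(merged) == 1
        exact = catalog_gene("g", [a, b], round_bp=0)
        assert len(exact) == 2

    def test_short_skipped_exon_produces_no_event(self):
        """A skipped segment of <= 50 bp does not create an isoform class."""
        rng = np.random.default_rng(21)
        e1, e2, e3 = random_seq(rng, 150), random_seq(rng, 45), random_seq(rng, 150)
        contig = make_contig("cL", e1 + e2 + e3)
        full = align_pair(make_read("rf", e1 + e2 + e3), contig)
        skip = align_pair(make_read("rs", e1 + e3), contig)
        sigs = catalog_gene("g", [full, skip], round_bp=0)
        assert len(sigs) == 1 and sigs[0].is_gapless


class TestSummary:
    def test_histogram_matches_planted_counts(self):
        genes = simulate.make_genes(
            12, exon_count_range=(4, 5), exon_len_range=(60, 120), seed=17,
            isoform_counts=[1] * 6 + [2] * 4 + [3] * 2)
        by_gene = {}
        for g in genes:
            contig = make_contig("cL", g.all_exon_seq)
            by_gene[g.gene_id] = [
                align_pair(make_read(f"{g.gene_id}.{iso.name}", g.isoform_seq(iso)),
                           contig)
                for iso in g.isoforms
            ]
        catalog = build_catalog(by_gene, round_bp=0)
        hist, gene_lists = summarize_catalog(catalog)
        assert hist == {1: 6, 2: 4, 3: 2}
        assert sum(hist.values()) == len(genes)
        assert len(gene_lists[2]) == 6 and len(gene_lists[3]) == 2

    def test_empty_catalog(self):
        hist, lists = summarize_catalog(IsoformCatalog(entries={}))
        assert hist == {} and lists[2] == []


class TestVerifyJunctions:
    def test_skip_junction_supported_by_its_fragments(self, small_genes):
        gene = next(g for g in small_genes if len(g.isoforms) > 1)
        contig = SequenceRecord(id="cL", seq=gene.all_exon_seq, role=Role.CONTIG)
        iso = gene.isoforms[1]
        aln = align_pair(make_read("r", gene.isoform_seq(iso)), contig)
        sigs = catalog_gene(gene.gene_id, [aln], round_bp=0)
        frags, rows = simulate.emit_junction_fragments([gene], seed=19)
        support = verify_junctions(sigs, {gene.gene_id: contig}, frags, flank=20)
        for key in gene.expected_signature(iso):
            assert support[(gene.gene_id, key)] >= 1

    def test_no_fragments_no_support(self, small_genes):
        gene = next(g for g in small_genes if len(g.isoforms) > 1)
        contig = SequenceRecord(id="cL", seq=gene.all_exon_seq, role=Role.CONTIG)
        aln = align_pair(
            make_read("r", gene.isoform_seq(gene.isoforms[1])), contig)
        sigs = catalog_gene(gene.gene_id, [aln], round_bp=0)
        support = verify_junctions(sigs, {gene.gene_id: contig}, [], flank=20)
        assert all(v == 0 for v in support.values())

    def test_support_monotone_in_depth(self, small_genes):
        gene = next(g for g in small_genes if len(g.isoforms) > 1)
        contig = SequenceRecord(id="cL", seq=gene.all_exon_seq, role=Role.CONTIG)
        aln = align_pair(
            make_read("r", gene.isoform_seq(gene.isoforms[1])), contig)
        sigs = catalog_gene(gene.gene_id, [aln], round_bp=0)
        shallow, _ = simulate.emit_junction_fragments(
            [gene], depth_per_junction=2, seed=19)
        deep, _ = simulate.emit_junction_fragments(
            [gene], depth_per_junction=6, seed=19)
        s1 = verify_junctions(sigs, {gene.gene_id: contig}, shallow, flank=20)
        s2 = verify_junctions(sigs, {gene.gene_id: contig}, deep, flank=20)
        for k in s1:
            assert s2[k] >= s1[k]

    def test_full_isoform_fragments_do_not_support_skip_junction(self, small_genes):
        gene = next(g for g in small_genes if len(g.isoforms) > 1)
        contig = SequenceRecord(id="cL", seq=gene.all_exon_seq, role=Role.CONTIG)
        iso = gene.isoforms[1]
        aln = align_pair(make_read("r", gene.isoform_seq(iso)), contig)
        sigs = catalog_gene(gene.gene_id, [aln], round_bp=0)
        # fragments drawn from the *full* isoform contain the skipped exon, so
        # they cannot contain the skip junction probe
        rng = np.random.default_rng(19)
        full_seq = gene.all_exon_seq
        frags = [
            SequenceRecord(id=f"f{i}", role=Role.SHORT_READ,
                           seq=full_seq[s : s + 300])
            for i, s in enumerate(rng.integers(0, len(full_seq) - 300, size=20))
        ]
        support = verify_junctions(sigs, {gene.gene_id: contig}, frags, flank=20)
        assert all(v == 0 for v in support.values())
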