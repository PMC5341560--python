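import json

import numpy as np
import pytest

from hysemafi import simulate
from hysemafi.errors import UsageError
from hysemafi.simulate import (
    TruthManifest,
    emit_contigs,
    emit_junction_fragments,
    emit_long_reads,
    emit_short_reads,
    make_genes,
    manifest_genes,
)


class TestMakeGenes:
    def test_single_gene_lengths(self):
        (g,) = make_genes(1, exon_count_range=(3, 3),
                          exon_len_range=(100, 100), seed=1)
        assert len(g.exons) == 3
        assert len(g.all_exon_seq) == 300

    def test_deterministic_given_seed(self):
        a = make_genes(4, seed=5)
        b = make_genes(4, seed=5)
        assert a == b
        c = make_genes(4, seed=6)
        assert a != c

    def test_cross_gene_kmers_disjoint(self):
        genes = make_genes(10, exon_count_range=(3, 4),
                           exon_len_range=(60, 120), seed=13)
        seen: dict[str, str] = {}
        for g in genes:
            seq = g.all_exon_seq
            for i in range(len(seq) - 20 + 1):
                km = seq[i : i + 20]
                owner = seen.setdefault(km, g.gene_id)
                assert owner == g.gene_id
        # every k-mer is owned by exactly one gene
        assert len({v for v in seen.values()}) == 10

    def test_isoforms_preserve_exon_order_and_termini(self):
        genes = make_genes(6, seed=2, isoform_counts=[3, 2, 1, 2, 3, 1],
                           exon_count_range=(4, 6))
        for g in genes:
            for iso in g.isoforms:
                assert list(iso.exon_indices) == sorted(iso.exon_indices)
                assert 0 in iso.exon_indices
                assert len(g.exons) - 1 in iso.exon_indices

    def test_impossible_ranges_rejected(self):
        with pytest.raises(UsageError):
            make_genes(1, exon_count_range=(2, 2), seed=1)
        with pytest.raises(UsageError):
            make_genes(0, seed=1)

    def test_function4_isoform_count_invariant(self):
        """Per gene: distinct long-read isoform classes <= emitted contigs."""
        genes = make_genes(8, seed=4, exon_count_range=(4, 6))
        contigs, roster = emit_contigs(genes, include_false=True,
                                       true_contig_prob=1.0, seed=4)
        per_gene_contigs: dict[str, int] = {}
        for row in roster:
            for gid in row["genes"]:
                per_gene_contigs[gid] = per_gene_contigs.get(gid, 0) + 1
        for g in genes:
            n_classes = len({g.expected_signature(i) for i in g.isoforms})
            assert n_classes <= per_gene_contigs[g.gene_id]


class TestLongReads:
    def test_zero_error_reads_match_isoforms(self, small_genes):
        reads, rows = emit_long_reads(
            small_genes, per_isoform_depth=2, error_rate=0.0,
            full_length_frac=1.0, duplicate_rate=0.0, seed=1)
        by_id = {r.id: r for r in reads}
        for row in rows:
            g = next(x for x in small_genes if x.gene_id == row["gene_id"])
            assert by_id[row["read_id"]].seq == g.isoform_seq(row["isoform"])

    def test_truncated_reads_are_suffixes(self, small_genes):
        reads, rows = emit_long_reads(
            small_genes, per_isoform_depth=4, error_rate=0.0,
            full_length_frac=0.3, duplicate_rate=0.0, seed=2)
        by_id = {r.id: r for r in reads}
        truncated = [r for r in rows if not r["full_length"]]
        assert truncated
        for row in truncated:
            g = next(x for x in small_genes if x.gene_id == row["gene_id"])
            src = g.isoform_seq(row["isoform"])
            assert by_id[row["read_id"]].seq == src[row["truncated_5p"]:]

    def test_planted_duplicates_are_proper_substrings(self, small_genes):
        reads, rows = emit_long_reads(
            small_genes, per_isoform_depth=2, error_rate=0.01,
            full_length_frac=1.0, duplicate_rate=0.3, seed=3)
        by_id = {r.id: r for r in reads}
        dups = [r for r in rows if r["duplicate_of"]]
        assert dups
        for row in dups:
            src = by_id[row["duplicate_of"]]
            dup = by_id[row["read_id"]]
            assert dup.length < src.length
            assert dup.seq in src.seq

    def test_error_rate_bounds(self, small_genes):
        with pytest.raises(UsageError):
            emit_long_reads(small_genes, error_rate=0.2, seed=1)


class TestContigs:
    def test_no_false_contigs_when_disabled(self, small_genes):
        _, roster = emit_contigs(small_genes, include_false=False,
                                 true_contig_prob=1.0, seed=1)
        assert {r["label"] for r in roster} <= {"longest", "true"}

    def test_longest_contig_is_exon_sum(self, small_genes):
        contigs, roster = emit_contigs(small_genes, seed=1)
        by_id = {c.id: c for c in contigs}
        for row in roster:
            if row["label"] == "longest":
                g = next(x for x in small_genes if x.gene_id == row["genes"][0])
                assert by_id[row["contig_id"]].length == sum(len(e) for e in g.exons)

    def test_no_read_contained_in_false_contig(self, small_genes):
        """False contigs can never satisfy full-length containment, even for
        truncated reads — the structural basis of the identity qualification."""
        reads, _ = emit_long_reads(
            small_genes, per_isoform_depth=3, error_rate=0.0,
            full_length_frac=0.6, duplicate_rate=0.0, seed=9)
        contigs, roster = emit_contigs(small_genes, include_false=True, seed=9)
        false = [c for c, r in zip(contigs, roster) if r["label"].startswith("false")]
        assert false
        for c in false:
            for r in reads:
                assert r.seq not in c.seq

    def test_chimera_fails_identity_qualification(self, small_genes):
        from hysemafi.align import align_all
        from hysemafi.mapfind import qualifies

        reads, _ = emit_long_reads(
            small_genes, per_isoform_depth=2, error_rate=0.0,
            full_length_frac=1.0, duplicate_rate=0.0, seed=9)
        contigs, roster = emit_contigs(small_genes, include_false=True, seed=9)
        false_ids = {r["contig_id"] for r in roster if r["label"].startswith("false")}
        alns = align_all(reads, contigs, min_identity=0.0)
        for a in alns:
            if a.target_id in false_ids:
                assert not qualifies(a, 0.99)


class TestShortReads:
    def test_zero_depth_empty(self, small_genes):
        samples, _ = emit_short_reads(
            small_genes, {"s1": "root"}, reads_per_sample=0, seed=1)
        assert samples["s1"] == []

    def test_read_length_guard(self, small_genes):
        with pytest.raises(UsageError):
            emit_short_reads(small_genes, {"s1": "root"}, read_len=10_000, seed=1)

    def test_counts_track_planted_abundance(self, small_genes):
        """Observed per-isoform counts within 3 sigma of the multinomial mean."""
        n = 30_000
        samples, manifest = emit_short_reads(
            small_genes, {"s1": "root"}, reads_per_sample=n, seed=23)
        weights = {}
        for g in small_genes:
            for iso in g.isoforms:
                npos = len(g.isoform_seq(iso)) - 100 + 1
                weights[f"{g.gene_id}.{iso.name}"] = (
                    g.abundances["root"][iso.name] * npos)
        total = sum(weights.values())
        counts = manifest["s1"]["isoform_read_counts"]
        assert sum(counts.values()) == n
        for key, w in weights.items():
            p = w / total
            sigma = (n * p * (1 - p)) ** 0.5
            assert abs(counts[key] - n * p) <= 3.5 * sigma

    def test_reads_are_isoform_substrings(self, small_genes):
        samples, _ = emit_short_reads(
            small_genes, {"s1": "root"}, reads_per_sample=200, seed=7)
        iso_seqs = [g.isoform_seq(i) for g in small_genes for i in g.isoforms]
        for read in samples["s1"][:50]:
            assert any(read.seq in s for s in iso_seqs)


class TestJunctionFragments:
    def test_fragments_contain_their_junction(self, small_genes):
        frags, rows = emit_junction_fragments(small_genes, seed=19)
        by_id = {f.id: f for f in frags}
        assert rows
        for row in rows:
            g = next(x for x in small_genes if x.gene_id == row["gene_id"])
            t_start, t_end = row["junction"]
            contig = g.all_exon_seq
            probe = contig[t_start - 20 : t_start] + contig[t_end : t_end + 20]
            assert probe in by_id[row["fragment_id"]].seq

    def test_fragment_lengths_in_range(self, small_genes):
        frags, rows = emit_junction_fragments(
            small_genes, frag_len_range=(200, 300), seed=19)
        for f in frags:
            assert f.length <= 300


class TestManifest:
    def test_manifest_roundtrips_to_json(self, small_genes, tmp_path):
        reads, rows = emit_long_reads(small_genes, seed=1)
        man = TruthManifest(genes=manifest_genes(small_genes), reads=rows)
        p = tmp_path / "m.json"
        man.to_json(p)
        loaded = json.loads(p.read_text())
        assert set(loaded["genes"]) == {g.gene_id for g in small_genes}
        assert loaded["reads"][0]["read_id"] == rows[0]["read_id"]

    def test_signatures_recorded_for_long_skips_only(self):
        genes = make_genes(5, seed=8, exon_count_range=(4, 5),
                           exon_len_range=(60, 120), isoform_counts=[2] * 5)
        man = manifest_genes(genes, min_gap=50)
        for g in genes:
            for iso in g.isoforms:
                recorded = man[g.gene_id]["isoforms"][iso.name]["signature"]
                for ev in recorded:
                    assert ev[2] - ev[1] > 50
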