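"""End-to-end orchestration: simulate -> align -> dedup -> mapfind -> splice
-> quantify -> DE, with one flat config and deterministic, byte-stable
outputs.

Every stage that needs alignments also accepts externally produced PSL/PAF
(see the CLI), so real datasets can be aligned with BLAT/minimap2 while the
internal aligner keeps desk-scale runs self-contained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import align, dedup, io_formats, mapfind, quantify, simulate, splicing
from .errors import UsageError
from .io_formats import Role, SequenceRecord

__all__ = ["PipelineConfig", "run_all", "stage_seed"]

log = logging.getLogger("hysemafi")

FLOAT_FMT = "%.6g"


def stage_seed(seed: int, stage: int) -> int:
    """Derive a per-stage RNG seed below 2**31."""
    return (seed * 7919 + stage) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All thresholds and simulation settings of a run.

    The analysis thresholds default to the method's stated constants:
    qualifying identity 0.99, splice gap 50 bp (strict), dedup similarity
    0.99 with zero overhang and zero gap openings, DE screening p < 0.05,
    FDR < 0.01 and fold change >= 2.
    """

    seed: int = 13
    # simulation
    n_genes: int = 10
    exon_count_range: tuple[int, int] = (3, 6)
    exon_len_range: tuple[int, int] = (80, 400)
    isoform_count_probs: tuple[float, ...] = (0.4, 0.4, 0.2)
    tissues: tuple[str, ...] = simulate.DEFAULT_TISSUES
    replicates: int = 3
    per_isoform_depth: int = 4
    long_read_error: float = 0.01
    full_length_frac: float = 0.9
    duplicate_rate: float = 0.1
    include_false_contigs: bool = True
    true_contig_prob: float = 0.9
    short_read_len: int = 100
    short_reads_per_sample: int = 2000
    fragment_depth_per_junction: int = 2
    # analysis thresholds
    min_identity: float = 0.99
    min_gap: int = 50
    round_bp: int = 5
    dedup_min_similarity: float = 0.99
    dedup_max_overhang: int = 0
    dedup_max_gap_openings: int = 0
    de_p_value: float = 0.05
    de_fdr: float = 0.01
    de_min_fold: float = 2.0
    group_mode: str = "components"
    focal_tissue: str = "root"
    compat_k: int = 20
    compat_mismatches: int = 2
    junction_flank: int = 20

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise UsageError(f"unknown config keys: {sorted(bad)}")
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(getattr(cls, f.name, None), tuple):
                d[f.name] = tuple(d[f.name])
        cfg = cls(**d)
        for name in ("exon_count_range", "exon_len_range", "isoform_count_probs", "tissues"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def dedup_params(self) -> dedup.DedupParams:
        return dedup.DedupParams(
            min_similarity=self.dedup_min_similarity,
            max_overhang=self.dedup_max_overhang,
            max_gap_openings=self.dedup_max_gap_openings,
        )

    def de_cutoffs(self) -> quantify.DECutoffs:
        return quantify.DECutoffs(
            p_value=self.de_p_value, fdr=self.de_fdr, min_fold=self.de_min_fold
        )


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def simulate_dataset(config: PipelineConfig, outdir: Path):
    """Run the generator and write FASTA/FASTQ inputs plus the truth manifest."""
    simdir = outdir / "sim"
    simdir.mkdir(parents=True, exist_ok=True)
    genes = simulate.make_genes(
        config.n_genes,
        exon_count_range=config.exon_count_range,
        exon_len_range=config.exon_len_range,
        isoform_count_probs=config.isoform_count_probs,
        tissues=config.tissues,
        focal_tissue=config.focal_tissue,
        seed=stage_seed(config.seed, 0),
    )
    reads, read_rows = simulate.emit_long_reads(
        genes,
        per_isoform_depth=config.per_isoform_depth,
        error_rate=config.long_read_error,
        full_length_frac=config.full_length_frac,
        duplicate_rate=config.duplicate_rate,
        seed=stage_seed(config.seed, 1),
    )
    contigs, roster = simulate.emit_contigs(
        genes,
        include_false=config.include_false_contigs,
        true_contig_prob=config.true_contig_prob,
        seed=stage_seed(config.seed, 2),
    )
    design = {
        f"{t}_{r + 1}": t for t in config.tissues for r in range(config.replicates)
    }
    short_reads, sr_manifest = simulate.emit_short_reads(
        genes, design,
        read_len=config.short_read_len,
        reads_per_sample=config.short_reads_per_sample,
        seed=stage_seed(config.seed, 3),
    )
    fragments, frag_rows = simulate.emit_junction_fragments(
        genes,
        depth_per_junction=config.fragment_depth_per_junction,
        seed=stage_seed(config.seed, 4),
    )
    manifest = simulate.TruthManifest(
        genes=simulate.manifest_genes(genes, config.min_gap),
        reads=read_rows, contigs=roster,
        short_reads=sr_manifest, fragments=frag_rows,
    )
    io_formats.write_fasta(reads, simdir / "long_reads.fa")
    io_formats.write_fasta(contigs, simdir / "contigs.fa")
    io_formats.write_fasta(fragments, simdir / "fragments.fa")
    for sample, recs in short_reads.items():
        io_formats.write_fastq(recs, simdir / f"{sample}.fq")
    manifest.to_json(simdir / "manifest.json")
    return genes, reads, contigs, short_reads, fragments, design, manifest


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns a summary dict of key objects and paths.

    All outputs are reproducible bit for bit given the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_json(outdir / "config.json")
        log.info("thresholds: min_identity=%g min_gap=%d round_bp=%d "
                 "dedup_similarity=%g de=(p<%g, fdr<%g, fold>=%g)",
                 config.min_identity, config.min_gap, config.round_bp,
                 config.dedup_min_similarity, config.de_p_value,
                 config.de_fdr, config.de_min_fold)
        log.info("stage simulate")
        (genes, reads, contigs, short_reads, fragments, design,
         manifest) = simulate_dataset(config, outdir)

        params = align.AlignParams()
        log.info("stage dedup: %d long reads", len(reads))
        self_alns = align.containment_alignments(
            reads, max_mismatch_frac=1.0 - config.dedup_min_similarity)
        drclr, removal_log = dedup.remove_duplicates(
            reads, self_alns, config.dedup_params())
        io_formats.write_fasta(drclr, outdir / "drclr.fa")
        _write_tsv(pd.DataFrame([dataclasses.asdict(e) for e in removal_log]),
                   outdir / "removed.tsv")
        log.info("dedup removed %d of %d reads", len(removal_log), len(reads))

        log.info("stage mapfind: %d DRCLR vs %d contigs", len(drclr), len(contigs))
        all_alns = align.align_all(
            drclr, contigs, params, min_identity=0.0,
            prefilter_identity=min(0.95, config.min_identity))
        io_formats.write_psl(all_alns, outdir / "drclr_vs_contigs.psl")
        qual = [a for a in all_alns if mapfind.qualifies(a, config.min_identity)]
        groups = mapfind.group_genes(qual, contigs, drclr, mode=config.group_mode)
        reference, unresolved = mapfind.build_reference(
            groups, contigs, config.min_identity)
        ref_records = [
            SequenceRecord(id=f"{gene}|{rec.id}", seq=rec.seq, role=Role.CONTIG)
            for gene, rec in sorted(reference.entries.items())
        ]
        io_formats.write_fasta(ref_records, outdir / "lrd.fa")
        (outdir / "unresolved.txt").write_text("".join(g + "\n" for g in unresolved))
        _write_tsv(pd.DataFrame([
            {"gene_id": gr.gene_id,
             "n_contigs": len(gr.contig_ids),
             "n_long_reads": len(gr.long_read_ids),
             "longest_contig": (reference.entries[gr.gene_id].id
                                if gr.gene_id in reference.entries else "")}
            for gr in groups
        ]), outdir / "groups.tsv")
        report = mapfind.mapping_report(
            all_alns, drclr, contigs, min_identity=config.min_identity)
        _write_tsv(mapfind.report_frame(report), outdir / "map_report.tsv")
        log.info("mapfind: %d groups, %d resolved, %d unresolved",
                 len(groups), len(reference.entries), len(unresolved))

        log.info("stage splice")
        longest_of = {
            gene: rec.id for gene, rec in reference.entries.items()}
        by_gene: dict[str, list] = {}
        gene_of_contig = {rec.id: gene for gene, rec in reference.entries.items()}
        for a in qual:
            gene = gene_of_contig.get(a.target_id)
            if gene is not None:
                by_gene.setdefault(gene, []).append(a)
        catalog = splicing.build_catalog(
            by_gene, min_gap=config.min_gap, round_bp=config.round_bp)
        cat_rows, bed_rows = [], []
        all_sigs: list[splicing.SpliceSignature] = []
        for gene in catalog.genes():
            for si, sig in enumerate(catalog.entries[gene]):
                all_sigs.append(sig)
                cat_rows.append({
                    "gene_id": gene, "class": si,
                    "n_events": len(sig.events),
                    "events": ";".join(
                        f"{k[0]}:{k[1]}-{k[2]}" for k in sig.events) or ".",
                    "support": sig.n_support,
                    "reads": ",".join(sig.support),
                })
                for key in sig.events:
                    if key[0] == splicing.EXCLUSION:
                        bed_rows.append({
                            "contig": longest_of[gene], "start": key[1],
                            "end": key[2], "gene": gene,
                            "kind": key[0], "support": sig.n_support,
                        })
        _write_tsv(pd.DataFrame(cat_rows), outdir / "catalog.tsv")
        pd.DataFrame(bed_rows).to_csv(
            outdir / "events.bed", sep="\t", header=False, index=False)
        hist, gene_lists = splicing.summarize_catalog(catalog)
        _write_tsv(pd.DataFrame(
            [{"n_isoforms": k, "n_genes": v} for k, v in hist.items()]),
            outdir / "isoform_histogram.tsv")
        support = splicing.verify_junctions(
            all_sigs, {g: reference.entries[g] for g in reference.entries},
            fragments, flank=config.junction_flank)
        _write_tsv(pd.DataFrame([
            {"gene_id": g, "event": f"{k[0]}:{k[1]}-{k[2]}", "n_fragments": n}
            for (g, k), n in sorted(support.items())
        ]), outdir / "junction_support.tsv")
        log.info("splice: %d genes catalogued", len(catalog.genes()))

        log.info("stage quantify: reference = %d DRCLR reads", len(drclr))
        iso_lengths = {r.id: r.length for r in drclr}
        counts_cols, tpm_cols = {}, {}
        for sample in sorted(design):
            table = quantify.build_compatibility(
                short_reads[sample], drclr,
                k=config.compat_k, max_mismatches=config.compat_mismatches)
            abundance, _ = quantify.em_abundance(
                table, iso_lengths, mean_fragment_length=config.short_read_len)
            counts_cols[sample] = abundance["est_counts"]
            tpm_cols[sample] = abundance["tpm"]
        counts = pd.DataFrame(counts_cols)
        tpm = pd.DataFrame(tpm_cols)
        expr = quantify.ExpressionTable(counts=counts, tpm=tpm, design=dict(design))
        wide = pd.concat(
            {"est_counts": counts, "tpm": tpm}, axis=1)
        wide.columns = [f"{a}:{b}" for a, b in wide.columns]
        wide.index.name = "isoform"
        _write_tsv(wide, outdir / "expression.tsv", index=True)

        log.info("stage de: focal=%s", config.focal_tissue)
        cutoffs = config.de_cutoffs()
        others = [t for t in config.tissues if t != config.focal_tissue]
        for other in others:
            res = quantify.de_screen(expr, config.focal_tissue, other, cutoffs)
            res.index.name = "isoform"
            _write_tsv(res, outdir / f"de_{config.focal_tissue}_vs_{other}.tsv",
                       index=True)
        up = quantify.tissue_specific(
            expr, config.focal_tissue, others, cutoffs, direction="up")
        down = quantify.tissue_specific(
            expr, config.focal_tissue, others, cutoffs, direction="down")
        (outdir / f"{config.focal_tissue}_up.txt").write_text(
            "".join(i + "\n" for i in up))
        (outdir / f"{config.focal_tissue}_down.txt").write_text(
            "".join(i + "\n" for i in down))
        log.info("de: %d up, %d down in %s", len(up), len(down),
                 config.focal_tissue)
        return {
            "genes": genes, "manifest": manifest, "drclr": drclr,
            "removal_log": removal_log, "groups": groups,
            "reference": reference, "unresolved": unresolved,
            "catalog": catalog, "histogram": hist, "gene_lists": gene_lists,
            "expression": expr, "up": up, "down": down, "outdir": outdir,
        }
    finally:
        log.removeHandler(handler)
        handler.close()
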