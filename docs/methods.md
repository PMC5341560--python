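# Methods

This note documents the models and procedures implemented in `hysemafi`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Data model and coordinates

All coordinates are 0-based half-open, the native convention of PSL and PAF,
so no stage performs off-by-one conversions.  An `AlignmentRecord` stores
the block structure of one pairwise alignment; its invariants (blocks
ascending in both sequences, `sum(blocks) = matches + mismatches`, span
identities) are validated on every parse and before every write.  PSL
`repMatches` is folded into `matches` and `nCount` into `mismatches`: the
similarity statistic used everywhere is identical-base count over query
length and does not distinguish repeat matches.  Minus-strand alignments are
normalised at parse time to the reverse-complemented query frame (the frame
PSL itself uses for its `qStarts` list), with the strand kept as metadata.

## Internal aligner

The built-in aligner exists so the whole pipeline runs without external
binaries at desk scale; real datasets should use BLAT or minimap2 and feed
PSL/PAF in through the same interfaces.

Model: affine-gap Gotoh DP, global in the query (a long read must be
explained end to end; terminal query gaps are penalised and then reported as
unaligned overhangs) and local in the target (contigs may carry assembly
overhangs; target end gaps are free).  Defaults: match +1, mismatch −2,
gap open 4, gap extension 1/16.

The gap extension deserves a note.  The extension must satisfy two
competing constraints: a 50 bp gap has to be far cheaper than 50 mismatches
(so splice gaps surface as gaps — here 7.125 versus 100), while a *long*
skip (two adjacent skipped exons can exceed 700 bp) has to stay cheaper
than what the alignment would gain by discarding a short flanking exon
into a query-side gap instead.  With a steeper extension (e.g. 0.25) the
second constraint fails: on a real simulated gene the optimal alignment of
a skip isoform dropped its 125 bp first exon rather than pay a 739 bp gap,
and the read then failed the 99 % qualification.  Both the implementation
and the independent textbook-DP oracle in the test suite agree on that
optimum, i.e. the failure is a property of the scoring, not of the DP.
With extension 1/16 an 800 bp gap costs 54, below the 80 bp minimum exon
gain, and the correct splice structure is optimal for every generator
configuration.  All scores are dyadic rationals so float32 matrices store
them exactly and traceback equality tests are exact.

Tie-breaking is deterministic and canonical: at equal score the diagonal
state is preferred over a query-side gap over a target-side gap, and gap
extension over re-opening.  The splice-signature stage depends on this
canonicalisation.

`align_all` seeds pairs by shared k-mers (default k = 12, both strands) and
can additionally prune pairs with a *collinear seed-chain bound*: any run of
k gap-free matching positions implies a shared k-mer, so an upper bound on
achievable identity is `1 − uncovered /(k·L)` where `uncovered` counts query
k-mer starts without a collinearly chainable hit (longest increasing
subsequence over target positions).  Pairs whose bound is below the
qualifying threshold — chimeras sharing half a read, shuffled exon orders —
skip the quadratic DP entirely; the bound is conservative, so no qualifying
alignment is lost.  The prefilter is off by default and enabled by the
pipeline.

Budget: the DP refuses instances above `dp_budget` cells (default 1e8) and
advises external alignment.

## Redundancy removal (DRCLR)

Read *B* is a duplicate of read *A* iff *A* is strictly longer, *B* has no
unaligned overhangs (0 bp tolerance by default, configurable), similarity
`matches/|B|` is strictly greater than 0.99, and the alignment opens no gaps
(0 openings by default).  Reads are visited longest-first (ties by id);
a read is removed when the rule holds against any retained longer read.
This order is a determinism choice — the rule itself is asymmetric in
length, so longest-first maximises retained length.  Equal-length exact
copies are *not* removed under the strict rule; `collapse_equal` removes the
lexicographically larger id and is off by default.

In the pipeline the all-vs-all alignments for dedup come from a gapless
containment scan (seed k-mers plus a Hamming check of the implied window)
rather than the full DP: the rule only ever accepts no-overhang no-gap
alignments, and a pair whose best alignment is gapped or below the
similarity floor is indistinguishable from a disqualifying alignment.

## Gene grouping and longest-contig selection

Qualifying alignments (similarity ≥ 0.99; the boundary is included, and the
threshold is configurable) induce a bipartite graph between long reads and
contigs.  In `components` mode genes are its connected components; in
`trinity_names` mode contigs group by the Trinity gene prefix and each read
joins the gene of its best-identity alignment.  Per gene, candidate
reference contigs must have at least one qualifying alignment **and** length
at least the longest mapped read of the group (the length condition is
applied against the group maximum, equivalent to applying it read by read);
the longest candidate wins, ties broken by ascending contig id.  Genes with
no candidate are reported unresolved, not guessed.

## Splice cataloguing

Between adjacent alignment blocks the net target-side excess (`Δt − Δq`)
defines an *exclusion* over the skipped contig interval, and the net
query-side excess an *insertion* anchored at the interruption point.  An
event is a splice only when its net excess is **strictly greater than
50 bp** (`min_gap`, configurable).  A read's signature is its ordered event
tuple; equal signatures — same kinds, sites and lengths — form one isoform
class, and the gapless class is counted when supported.

Noisy reads jitter gap endpoints by a few bases, so cataloguing clusters
endpoint coordinates within `round_bp` (default 5 bp) to the modal value,
and fuses exclusion gaps separated by an aligned island of at most
`round_bp` bases before the 50 bp filter (the optimal alignment of a noisy
read occasionally splits one long gap around a handful of coincidentally
matching bases; under the default scoring a 4 bp island buys +4 matches for
one extra gap opening).  `round_bp = 0` restores the literal
exact-coordinate, per-gap rule, and the zero-error tests run in that mode.

Insertion events cannot be labelled "intron retention" without a genome;
they are reported as insertions.  Junction verification builds, for each
exclusion, the probe `contig[t_start−flank : t_start] + contig[t_end :
t_end+flank]` (flank 20 bp by default) and counts fragments containing it,
exactly or with a configurable per-flank mismatch allowance.

## Quantification and differential expression

Short reads are reduced to weighted compatibility classes by exact full-read
matching against the reference (seeded so that with `m` allowed mismatches
one of `m+1` disjoint segments must hit exactly; the pipeline default allows
2 mismatches per 100 bp read).  The EM treats class counts as draws from a
mixture where isoform *i* generates reads proportionally to
`θᵢ / eff_lenᵢ`, with `eff_len = length − mean fragment length + 1`
floored at 1.  Uniform initialisation, deterministic updates, and the data
log-likelihood is asserted non-decreasing every iteration.  TPM is
`θ · 10⁶`.

The DE statistic is a two-condition Poisson likelihood-ratio test on
expected counts with per-sample total-count offsets (chi-squared, df 1),
BH adjustment across isoforms, and the screening rule p < 0.05 ∧
FDR < 0.01 ∧ |log2FC| ≥ 1, with fold change computed on normalised mean
counts plus a 0.5 pseudo-count.  The upstream method this package follows
specifies the cutoffs but not the test; the Poisson LRT is this package's
documented substitute, and pre-computed count tables (e.g. from RSEM) can be
supplied in its place through the same `ExpressionTable` interface.  With
one replicate per condition the test degrades to a count-ratio test and is
flagged.  Tissue-specific sets are strict intersections of the pairwise
screens of the focal condition against every other condition, split by
direction.

## Synthetic data: what it does and does not emulate

`make_genes` draws exon-structured genes (3–6 exons of 80–400 bp by
default) whose exon sequences share no 20-mer across genes, forward or
reverse complement — component grouping therefore has a clean ground truth
(real paralogs violate this; a stress mode is out of scope).  Every isoform
retains the first and last exon (cap/poly-A reading); alternatives skip a
run of one or two internal exons.  Skip-run boundaries are chosen so the
flanking bases differ, making the optimal gap placement unique — planted
splice coordinates are then *exactly* recoverable at zero read error, which
is what the bijection tests assert.

Long reads are isoform copies, full length with probability 0.9 (else 5'
truncated), with substitution noise at 1 % by default; planted duplicates
are proper substrings of existing reads.  Indel noise is available but off
by default: the length-based selection rule compares read and contig
lengths, and insertion-bearing reads can exceed their source isoform's
length — residual post-correction error is modelled as substitutions.
This also means alignment identity equals 1 − substitution rate, so at the
99 % threshold a 1 % error rate deliberately reproduces the regime where a
large fraction of reads hovers at the qualifying boundary.

Contig libraries contain the all-exon molecule, true isoform contigs (90 %
emission probability each), and false contigs: chimeras (5' exons of one
gene joined to 3' exons of the next) and shuffled exon orders.  False
contigs are emitted with their final 40 bp trimmed and chimeras never
contain a gene's terminal exon pair on the same side, so no read — truncated
or not — is exactly contained in a false contig; this makes "artefacts fail
the 99 % qualification" a structural property of the data, not a tendency.

Short reads are sampled per tissue with multinomial counts proportional to
abundance × (isoform length − read length + 1) and uniform positions, with
constant placeholder qualities and no sequencing error.  Junction fragments
(300–590 bp) always span their planted junction with ≥ 30 bp flanks.
Passing tests on these data demonstrate the pipeline's logic is correct
under its stated assumptions; they do not demonstrate robustness to real
PacBio error profiles, paralogy, incomplete correction, or
coverage-dependent assembly artefacts.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run at desk scale: 50 genes for
reference-recovery and splice-catalog checks, ~230 reads for the dedup
oracle, 20 000 reads for EM recovery, 100 isoforms × 20 runs for DE null
calibration, and a 10-gene default end-to-end run, sizes chosen so each
property is measured on comfortably more instances than it needs while the
whole suite stays fast.  Every random draw flows from an explicit seed (no
global RNG state); `run-all` output is reproducible bit for bit given the
same configuration, and the repository pins golden checksums of a seed-13
run.

## Known limitations

* Grouping by connected components merges genes that share qualifying reads;
  with real paralogous families this over-merges (the generator's k-mer
  disjointness sidesteps it, and `trinity_names` mode is the alternative).
* The 99 % qualification discards genuinely expressed isoforms whose reads
  carry > 1 % residual error; unresolved genes are reported, never imputed.
* Splice classification is contig-relative: without a genome there is no
  A5SS/A3SS/MXE nomenclature and no GT–AG motif check, and insertion events
  cannot be confirmed as intron retention.
* The internal aligner is quadratic and intended for simulation-scale
  verification; the Poisson LRT understates biological overdispersion
  relative to negative-binomial methods when replicate variance is real.
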