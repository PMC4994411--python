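# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind asterion, and what the synthetic-data tests do
and do not establish about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`; lengths are
`end - start` with no off-by-one arithmetic.  GFF3/GTF and BLAST tabular
files are 1-based closed on disk and converted at the I/O boundary.  BED
is 0-based half-open as on disk.  A minus-strand BLAST subject hit is
recognised by `sstart > send` and normalised to an interval with an
explicit strand flag; a reverse-strand hit *on the query* is recognised by
a negative query frame, which requires the
`-outfmt '6 std qframe sframe'` dialect.

Strand is mandatory for transcripts (the whole analysis is strand-aware);
unstranded features are dropped with a warning.  Transcripts whose exons
overlap one another — corrupt assembler output — are repaired by merging
touching/overlapping exons, with a warning.  The GFF3 writer omits a
separate `gene` feature when `gene_id == transcript_id` (assembler-style
annotations), since duplicate feature IDs would corrupt Parent linkage on
re-reading.

## Overlap classification

Opposite-strand overlap requires ≥ 1 shared bp between transcript *spans*
(first exon start to last exon end); abutting half-open intervals do not
overlap.  Classification applies a precedence ladder:

* The directional classes are evaluated for **both orderings** of a pair.
  `intronic` means the AST span sits inside a *single* host intron;
  `nested` means at least one AST exon does while the AST as a whole does
  not.  Both-orderings-nested is geometrically possible (interleaved
  exons) and yields two records; both-orderings-intronic is impossible and
  asserted against.
* If neither ordering embeds, one symmetric class is assigned per
  unordered pair.  With CDS on both transcripts, any CDS–CDS overlap is
  `exonic`.  Otherwise the exon-overlap region is tested against each
  transcript's terminal context: with a CDS, the 5'/3' UTR exonic bases;
  without one, the 5'/3'-terminal exon in transcription direction (the 3'
  terminal exon is the last in genome order on `+`, the first on `-`).
  Overlap touching both 3' contexts is `utr3` (tail-to-tail), both 5'
  contexts `utr5` (head-to-head), anything else falls back to `exonic`.
  For CDS-less transcripts this terminal-exon rule is this package's own
  criterion; assembler output carries no CDS, and single-exon CDS-less
  pairs (where the terminal exon is both 5' and 3') resolve to `utr3` by
  ladder order.

Two symmetries are worth stating precisely.  Classification is invariant
under translation of all coordinates and under the **reverse-complement
view** of a locus (mirrored coordinates with swapped strands) — labels
depend on transcription direction, not on which strand is called `+`.  A
*naive* strand swap without mirroring is not label-preserving for the UTR
classes: it turns a convergent (tail-to-tail) overlap into a divergent
(head-to-head) one, exchanging utr3 and utr5, while the directional and
exonic classes are unaffected.  The test suite checks the classifier
against an independent per-base reimplementation on random annotations.

Counting is dual, matching how such surveys report: per-configuration
counts (each intronic AST counts once per host it embeds in) and
gene-level deduplication for the intronic class (unique ASTs, unique host
genes, unique host–AST gene pairs).

## Protein-evidence resampling test

The statistic is the **number of transcripts with ≥ 1 qualifying hit**
(not total hit count), which is robust to multi-HSP redundancy.  A hit
qualifies if its e-value is strictly below 0.001 (configurable) and its
query frame is positive; reverse-frame hits are artifacts of the opposite
strand in stranded data and are removed first.

The null matches the AST length distribution: interior bin edges at the
1/20 … 19/20 quantiles of AST lengths give 20 equal-frequency bins
(duplicate edges from ties collapse, merging bins); each resample draws,
per bin, a bin-size-matched sample without replacement from *all*
transcripts in that length range, ASTs included.  Because the statistic is
a count and the bin pools partition the universe, the per-bin count under
without-replacement sampling is exactly hypergeometric; null counts are
therefore drawn as sums of independent hypergeometric variates —
distributionally identical to materialising index samples and far
cheaper.  Identical seeds give identical null sequences.

Empirical p-values use the `(r + 1)/(n + 1)` estimator in both tails, so
p is never zero.  One calibration caveat: with a discrete count statistic
the estimator is conservative — ties between the observed and null counts
remove rejection mass.  At small problem sizes (e.g. 2,000 transcripts /
400 ASTs) the measured type-I rate at nominal 0.05 is ≈ 0.028; at the
scale of a real transcriptome survey (≈ 40k transcripts, ≈ 450 ASTs) it is
≈ 0.045.  The calibration test therefore runs at survey scale.

## Expression correlation

Spearman's ρ with midrank ties (Pearson correlation of average ranks) per
antisense gene pair across samples; ≥ 3 samples required,
constant-expression genes yield undefined ρ and the pair is dropped and
counted.  Transcript-level matrices are summed to gene level before
correlating.  The random-pair null draws uniformly among distinct gene
pairs (antisense pairs excludable), with ranks precomputed once so the
draw is vectorised.  Because the underlying survey made this comparison
visually, the quantitative surrogate here is a two-sample KS test plus
5/25/50/75/95 % quantiles of both ρ distributions.

The synthetic generator controls pair correlation through a Gaussian
copula: for target Spearman ρ_S the copula parameter is
`r = 2·sin(π·ρ_S/6)` — the exact inverse of the Spearman ρ of a bivariate
Gaussian — and log-normal marginals preserve ranks, so targeting is exact
up to sampling noise.

## Conservation screen

Per target genome, host-protein hits below e-value 0.001 (strict, as
printed in the protocol this mirrors) define one span per (contig,
strand): leftmost to rightmost hit position; spans on opposite strands
never merge.  A pair is conserved iff at least one passing AST hit lies
*fully* inside such a span on the opposite strand of the same contig —
the existential reading, since partial-hit fragmentation is
alignment-dependent.  The first satisfying contig in lexicographic order
is recorded.  A genome without host hits is reported not-conserved but
flagged `host_detected = false`, keeping the two situations separable; a
missing hit table leaves the matrix cell absent (with a warning), not
false.  The call is monotone: adding a passing hit can only widen a span
or add a witness.

Conserved non-coding element (CNE) candidates are the per-contig
complement of the union of coding and repeat masks, filtered to
≥ 100 bp.  Counting reports distinct query and subject identifiers among
BLASTN hits below the threshold.

## Rank-sum testing

`rank_sum_test` computes Mann–Whitney U from midranks.  For tie-free
samples with n₁ + n₂ ≤ 16 the exact U distribution is enumerated by the
standard two-sample recurrence; otherwise a normal approximation with
tie-corrected variance and a 0.5 continuity correction is used.  The two
branches agree within ~10 % relative p at the crossover size for
non-extreme p; in the far tails the normal approximation is the limiting
factor, which is why exactness is reserved for small samples.  Genes with
no introns are excluded from largest-intron comparisons by default (a
zero-length "largest intron" is not a length); an `--all-introns`-style
toggle reverses this.  Synteny block sizes are taken as the genomic
extents of externally supplied BED records — block computation is out of
scope.

## Synthetic data

The generator plants every configuration in disjoint genomic slots
(500 bp gaps) on one contig, so the only opposite-strand overlaps are the
planted ones and truth labels are exact.  Defaults are the study
conditions of the motivating survey:

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes` | 200 | background genes |
| `planted` | 20/10/8/6/4 | intronic/nested/exonic/utr3/utr5 |
| exon lengths | log-normal(log 200, 0.6) | heavy right tail |
| background introns | log-normal(log 80, 0.8) | short, nematode-like |
| host introns | log-normal(log 1000, 1.0) | ≈ 5 % exceed 5 kb |
| `n_samples` | 30 | developmental expression profiles |
| `rho_target` | 0.0 | host/AST expression independent |
| `evidence_base_rate` | 0.3 | hit rate at the reference length |
| `evidence_enrichment_ratio` | 2.0 | AST multiplier |
| `n_genomes` | 20 | conservation screen width |
| `hit_dropout` | 0.0 | per-witness AST hit loss |

Host genes draw the planted intron from the long-intron model (floored at
AST span + 2×50 bp margin), reproducing the host/non-host largest-intron
contrast.  The default conservation truth makes the first pair conserved
in every genome and the rest in a lineage-specific prefix, mirroring the
one universally conserved pair such surveys find.  Non-conserved cells
realise one of three failure modes (no AST hits, hits outside the span,
hits on the same strand), recorded in the truth bundle.  `hit_dropout`
removes AST witness hits of conserved cells, so recall under dropout *d*
is exactly 1 − *d* per single-witness cell; host-span hits are not
dropped, keeping the recall contract interpretable.  Background synteny
blocks default to a log-normal with median 800 bp, below typical host
spans, so the simulated study reproduces the direction of the real
span-size comparison.

Every generator is a pure function of `(config, seed)` (per-artifact
substreams derived from the seed); rerunning writes byte-identical files.

**What the synthetic data does not emulate:** sequence content (no FASTA),
read-level noise, isoform complexity beyond one transcript per gene,
mis-assembly and fragmented gene models, overlapping same-strand genes,
genome-wide intron-length heterogeneity, or realistic BLAST score/e-value
joint distributions.  Passing tests therefore establish the correctness of
the interval logic, the calibration of the statistics, and the
recoverability of planted signal — not robustness to assembly artifacts
in real annotations.

## Pipeline

Stages run in dependency order (classify → enrich → correlate → conserve
→ introns/spansize); every stage derives its own seed as
`sha256(master_seed, stage_name) mod 2³¹`, so enabling one stage never
perturbs another's draws.  The JSON report contains no timestamps: two
runs with one seed are byte-identical.  The orchestrator reduces the
number of length bins to the AST count when fewer than 20 intronic ASTs
are available (the low-level test errors instead, as an explicit
configuration decision).  Reports are JSON (plus TSV/BED/PNG per stage);
no HTML report is generated.

## Problem sizes used in the checks

The self-checks run at sizes chosen to exercise the contracts while
remaining desk-scale: 500 random annotations of up to 50 genes for
classifier/oracle equivalence, 400 null datasets at survey scale
(42,821 transcripts / 465 ASTs, 200 resamples) for calibration plus 100
power datasets at the 400-AST condition, 1,000 random hit tables for the
conservation oracle, 2,000 simulations for rank-sum null uniformity, and
a 200-host / 2,000-background annotation for the intron-shift contrast.

## Known limitations

* UTR classification without CDS rests on terminal-exon geometry; genes
  with long terminal exons can shadow an internal overlap.
* The conservation call ignores hit scores beyond the e-value gate and
  collapses multi-contig host genes to any-contig satisfaction; a host
  split across contigs with the AST on the far fragment is missed.
* The enrichment statistic ignores hit multiplicity; a totals-based
  variant would need explicit index resampling instead of the
  hypergeometric shortcut.
* Expression input is assumed normalised; no floor is applied by default.
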