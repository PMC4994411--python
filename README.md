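# asterion

Analysis toolkit for **antisense transcription** in compact animal genomes
(originally motivated by nematode transcriptomes).  Given a stranded genome
annotation, asterion finds every pair of transcripts that overlap on
opposite strands, classifies each overlap, and then asks the downstream
questions a strand-specific RNA-seq study raises:

* Do antisense transcripts (ASTs) look protein-coding, or are they
  non-coding RNAs?
* Is host/AST expression correlated, as regulatory interference would
  predict?
* Are antisense gene pairs conserved across related genomes?
* Do host genes carry unusually long introns, and do conserved pairs span
  unusually large syntenic blocks?

It is a library first (plain functions over `pandas`/`numpy` containers),
with a thin `asterion` command-line interface on top, and it ships a
synthetic-data generator that can produce every input with known ground
truth.

## The five overlap classes

For transcripts *t₁*, *t₂* with `strand(t₁) ≠ strand(t₂)` on one contig and
overlapping genomic spans, each **ordered** pair (host, AST) is tested
first:

1. **intronic** — span(AST) ⊆ intronᵢ(host) for a single intron *i*;
2. **nested** — at least one AST exon lies fully inside a host intron, but
   the AST as a whole does not;

and, if neither ordering embeds, one **symmetric** class per pair:

3. **exonic** — the coding parts (CDS where annotated, else exons)
   overlap;
4. **utr3** — exon overlap without shared coding parts at the 3' ends of
   both transcripts (tail-to-tail);
5. **utr5** — the same at the 5' ends (head-to-head).

Precedence is intronic > nested > exonic > utr3 > utr5.  The *(host gene,
intronic AST)* combinations are the **antisense gene pairs** that the rest
of the pipeline studies.

## The statistics

**Protein evidence.**  Whether ASTs carry BLASTX homology to known
proteins is confounded by transcript length, so the null is
length-matched: AST lengths are cut into 20 equal-frequency bins and each
of 1000 resamples draws a bin-size-matched sample (without replacement)
from all transcripts in the same length range.  Reverse-frame hits
(`qframe < 0`) are discarded first — on stranded data they belong to the
opposite strand.  Significance is the empirical p-value
`p = (1 + #{null ≥ observed}) / (reps + 1)`.

**Expression.**  Spearman's ρ (midrank ties) per antisense gene pair
across samples, compared to ρ of uniformly drawn random gene pairs with a
two-sample Kolmogorov–Smirnov test and quantile tables.

**Conservation.**  For each target genome, TBLASTN hits (e-value < 0.001)
of the host protein define, per contig and strand, a span from the
leftmost to the rightmost hit position; a pair is called conserved when at
least one AST hit falls entirely inside that span on the *opposite*
strand.

**Intron and span sizes.**  Mann–Whitney/Wilcoxon rank-sum tests (exact
enumeration for small tie-free samples, tie-corrected normal approximation
otherwise) compare the largest intron per gene between host and non-host
genes, and antisense-pair spans against conserved-synteny block sizes.

## Worked example

Generate a synthetic study (200 background genes plus planted overlaps of
every class) and classify it:

```bash
$ asterion simulate --seed 7 --out demo/bundle
$ asterion classify --gff demo/bundle/annotation.gff3 --out demo/classify
{
 "counts": {
  "exonic": 8,
  "intronic": 20,
  "nested": 10,
  "utr3": 6,
  "utr5": 4
 },
 "n_gene_level_pairs": 20,
 "n_pairs": 48,
 "n_unique_asts": 20,
 "n_unique_hosts": 20
}
```

The classifier recovers exactly the planted configuration: 48 antisense
overlaps, of which 20 are intronic ASTs falling into 20 host genes (one
AST each, so 20 gene-level pairs).  The enrichment test then compares
protein evidence for those ASTs against length-matched random transcripts:

```python
import json
from asterion import EvidenceIndex, read_annotation, read_hit_table, resampling_test

aset = read_annotation("demo/bundle/annotation.gff3")
hits = read_hit_table("demo/bundle/blastx.tsv", format="outfmt6_frames")
idx = EvidenceIndex.build(aset, hits)
truth = json.load(open("demo/bundle/truth.json"))
res = resampling_test(truth["ast_transcripts"], sorted(idx.flags), idx,
                      reps=1000, seed=7)
print(res.observed, res.null_mean, res.empirical_p_high)
# 12 8.753 0.0579
```

12 of the 20 ASTs have a forward-frame hit versus 8.75 expected under the
length-matched null — the planted two-fold enrichment.  With only 20 ASTs
the test sits near its detection boundary (p ≈ 0.06 here); at a 400-AST
condition the same enrichment is rejected in ≥ 95 % of simulations (the
test suite measures this).

The remaining subcommands — `enrich`, `correlate`, `conserve`, `introns`,
`spansize`, `cne`, and `run-all` — follow the same pattern; `run-all`
executes every stage in dependency order and writes a deterministic
`report.json` (same seed ⇒ byte-identical report).

## Layout

| module | contents |
| --- | --- |
| `asterion.intervals` | 0-based half-open `GenomicInterval`, interval algebra |
| `asterion.annotation` | `TranscriptModel`, introns, `AnnotationSet` spatial index |
| `asterion.annotation_io` | GFF3/GTF read-write, BLAST outfmt-6, BED |
| `asterion.classify` | overlap detection and the five-class taxonomy |
| `asterion.evidence` | orientation filter, length bins, resampling test |
| `asterion.expression` | Spearman pair correlations vs random-pair null |
| `asterion.conservation` | hit spans, span-containment calls, CNE regions |
| `asterion.stats` | rank-sum tests, largest-intron tables, empirical p |
| `asterion.simulate` | synthetic data with planted ground truth |
| `asterion.pipeline` / `asterion.cli` | orchestration and the `asterion` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
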