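# Methods

`lncons` implements a coordinate-and-expression pipeline for identifying
long non-coding RNAs (lncRNAs) conserved between two genomes and inferring
their putative functions from three independent evidence streams. This note
documents the models, the parameters that matter, the synthetic study
generator, and the numerical choices made where the design was open.

## The filtering cascade

Assembled transcripts are classified against a reference annotation by
exonic overlap (exon-to-exon, not span containment, mirroring
Cuffcompare-style class codes) with the precedence: same-strand overlap of a
protein-coding exon → `pcg_overlap`; same-strand overlap of an annotated
lncRNA → `known_lncrna_match`; opposite-strand overlap of any annotation →
`antisense_overlap`; otherwise novel single- or multi-exon. A transcript is
kept as a high-confidence lncRNA iff

* spliced length ≥ 200 nt (boundary kept — the removal rule is "< 200"),
* coding-potential score ≤ 0.5 (scores are inputs, e.g. from lncScore;
  the removal rule is "> 0.5", so exactly 0.5 is kept),
* it is expressed (max TPM across samples strictly > 0), and
* its class is `known_lncrna_match` or `multi_exon_novel`.

The removal reason records the first failing rule in the order length →
coding → expression → class; the kept *set* is order-independent.
Multi-exon transcripts with identical intron chains on the same
chromosome/strand are collapsed, preferring annotated ids. "Length" means
spliced length: that is the standard lncRNA definition, and the one
boundary case a genomic-span reading would change (a short-exon,
long-intron transcript) has no biological reading as a ≥200-nt RNA.

Kept isoforms are grouped into **families** by single-linkage span overlap
(≥ 1 base) on the same chromosome and strand. Strand restriction is an
assumption: divergent overlapping loci are biologically distinct
transcriptional units, and merging them would conflate the bidirectional
evidence stream with family identity.

## Chain liftover

Coordinates move between genomes through a UCSC chain file. The parser
validates the format invariants per chain (block sums equal the header
spans, final block gapless, target strand '+'). Lifting maps an interval
per-base through the highest-scoring overlapping chain; the result is the
forward-strand hull of the mapped bases ('−'-strand query coordinates are
converted only at output, `pos_fwd = q_size − 1 − pos_rev`), with the
output strand composed with the chain's query strand. An interval is
`mapped` when one chain carries at least `min_match` of its bases (default
0.95, liftOver's documented default), `ambiguous` when a second chain also
reaches that fraction, `partial` below it, `unmapped` otherwise. Transcript
lifting uses the exon hull (the transcript's "genomic region") rather than
per-exon pieces; a per-block output mode exists for diagnostics. The
implementation is held to exact agreement with a brute-force per-base
mapper in the test suite, and chains can be programmatically inverted,
which the tests use for round-trip checks.

## Orthology pairing and conservation

Every genome-B lncRNA whose span overlaps a lifted genome-A lncRNA region
by ≥ 1 base (configurable) becomes a conserved pair; pairing is
many-to-many (one lifted region over several target isoforms yields one
pair each) and strand-agnostic, since the lifted strand is a property of
chain orientation rather than of the transcript. Cross-species expression
agreement is summarized per transcript (median TPM across each species'
own samples — the sample sets are disjoint, so no sample-wise pairing
exists) and compared by Spearman rank correlation across pairs, reported
separately for lncRNA and protein-coding pairs.

Sequence-level conservation uses a PhastCons-like per-base score track:
a transcript's score is the mean over its scored exonic bases (unscored
bases are excluded from numerator and denominator, since such tracks are
sparse; a "missing = 0" mode exists behind the reader). Group comparisons
(protein-coding vs lncRNA vs length-matched random background) use
one-sided Wilcoxon rank-sum tests; the random background resamples
lengths from the lncRNA length distribution and rejects overlaps with
annotated loci. The background is matched on length only, not GC or
chromatin context.

## Signed co-expression network

The network follows the WGCNA construction. With `cor` the Pearson
correlation across samples:

    a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta,   a_ii = 0

so anticorrelated genes receive near-zero weight (the "signed" network).
`beta` defaults to the smallest integer in 1..20 whose degree distribution
gives a scale-free fit R² ≥ 0.8, falling back to 12 (the signed-network
convention); the pipeline driver pins `beta = 6` for the synthetic study,
where the scale-free criterion is not meaningful (planted-block degree
distributions are bimodal by construction). The topological overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

is the edge similarity; modules are flat clusters of the average-linkage
dendrogram of `1 − TOM`, cut at `cut_height` (default 0.9), discarding
clusters below `min_module_size = 30`. A static cut was chosen over
dynamic tree cut for determinism; labels are ordered by module size with
lexicographic tie-breaks. Note that 0.25 — sometimes quoted as a WGCNA
height — is the module-*eigengene merge* height, not a tree-cut height;
within-module TOM rarely exceeds 0.75, so cutting `1 − TOM` at 0.25 would
shatter every module (verified numerically during design).

Node **connectivity** is the thresholded-TOM degree divided by the summed
degree of the node's module: an edge joins same-module nodes with
TOM > 0.2 (binary degree on the hard cutoff; a weighted `Σ TOM` mode is
available). Connectivities therefore sum to 1 within each module that has
at least one edge. The lncRNA-vs-protein-coding comparison is a one-sided
Wilcoxon rank-sum test on connectivities pooled across modules.

## GO enrichment and annotation transfer

Each module's protein-coding genes are tested for term over-representation
with the upper-tail hypergeometric probability P(X ≥ k); the universe is
the set of protein-coding genes present in the expression matrix
(expressed-gene background, avoiding detection bias). Default significance
is raw p < 0.05 (matching the upstream practice this pipeline reproduces);
Benjamini–Hochberg correction is implemented and recommended for real
data. Significant terms transfer to the module's lncRNAs; when
lncRNA–protein interaction scores are supplied (0–100 scale, e.g. lncPro),
an annotation is flagged interaction-supported if the lncRNA scores > 50
with at least one module gene carrying that term.

## Bidirectional promoter pairs

A divergent (bidirectional) lncRNA–PCG pair requires opposite strands in
head-to-head orientation (the '−' element 5′-ward: tss(−) ≤ tss(+)), a
TSS-to-TSS distance of at most 2000 bp (inclusive; TSS anchoring matches
the shared-promoter rationale — the distance anchor is otherwise
underdetermined), and adjacency (no other transcript's TSS strictly
between the two). Overlapping divergent transcripts (negative distance)
are excluded by default (`allow_overlap` relaxes this). A pair is
*conserved-bidirectional* when a conserved partner of the lncRNA forms a
divergent pair, under the same rule, with the orthologous protein-coding
gene in the second genome; protein-coding orthology is an input table,
not inferred.

## Temporal trends

Stage-labelled samples (defaults: weeks 2, 6, 21, 104 — a rodent lifespan
series) are averaged per stage; a transcript is called `up` iff every
consecutive stage mean increases (`m[t+1] > m[t] · min_ratio`, default
`min_ratio = 1`, i.e. strict monotonicity with ties breaking a trend),
`down` symmetrically, else `none`. Calls are made per isoform. Trends map
back to the first genome through the conserved pairs; partners with
conflicting directions are flagged `mixed`.

## Evidence integration

A conserved family is *annotated* when any member carries any of the three
evidence kinds — a transferred module term, a bidirectional pair, or a
directional (up/down/mixed) partner trend — OR-ed at family level with
member detail preserved. The coverage summary reports the annotated
fraction and the exact 7-way Venn partition of evidence combinations.
Terms from members in different modules are unioned.

## The synthetic study generator

The generator emulates the two-species brain-transcriptome design the
pipeline targets, at desk scale, with every planted structure recorded in
a ground-truth object. Defaults: 2 chromosomes of 1 Mb per genome, 150
protein-coding genes and 40 lncRNAs per genome, 20 conserved lncRNA loci,
66 samples per species (near the motivating study's 80/66), 3 co-expression
modules of 40 genes, 4 temporal stages with 3 replicates, 3 planted
divergent pairs at 500/2000/2001 bp (one deliberately past the threshold),
and fold-10 GO plants in two modules.

* **Genomes and chains.** Loci are laid out sequentially with randomized
  gaps; each conserved locus gets one chain mapping it (±500 bp flank)
  onto its genome-B counterpart, ~30% on the '−' strand; a split mode
  places a gap in the flank to exercise multi-block chains. Non-conserved
  loci lie outside all chains. Distractor transcripts (too short, coding,
  unexpressed, antisense, single-exon) exercise every filter rule.
* **Expression.** One latent factor per module:
  `x_g = s·u_g·f_m + ε`, with lncRNA hubs at loading `u = 1` and
  protein-coding loadings from U(0.5, 0.9). The factor scale `s` is solved
  per module (bisection) so the *expected mean pairwise* within-module
  correlation equals `within_module_cor` under the drawn loadings. Values
  are per-gene standardized on the log scale (sd 0.5), shifted by per-gene
  baselines, and exponentiated to TPM-like positives — a monotone map that
  perturbs Pearson correlations only mildly at this spread. The default
  target correlation is 0.55: a moderate, realistic module strength, and
  the regime in which the hard TOM > 0.2 degree cutoff actually
  discriminates hubs (at within-correlation ≥ 0.8 every within-module pair
  exceeds the cutoff, the module graph is complete, and *no* method could
  exhibit a hub effect on binary degree).
* **Cross-species signal.** Conserved partners share per-gene baselines
  with Gaussian jitter, 1.3 log-units for lncRNA pairs and 0.8 for
  protein-coding orthologs, giving expected summary-expression Spearman
  correlations of ≈ 0.61 and ≈ 0.78 — lncRNAs less conserved in
  expression than protein-coding genes, as in real cross-species brain
  data. Disjoint sample sets make literal factor sharing unobservable by a
  per-gene summary statistic, which is why the signal is planted in the
  baselines.
* **Temporal.** Planted `up`/`down` genes move 1.0 log-unit per stage;
  replicate noise has sd `noise_sd` (default 0.5). At zero noise the trend
  classifier recovers the plant exactly.
* **GO.** Background membership is Bernoulli(0.05) per (gene, term);
  planted (term, module, fold) triples multiply that rate inside the
  module. The 0.05 background (rather than a sparser one) keeps a fold-10
  plant statistically detectable at this universe size — at rate 0.02 a
  "planted" term has ≈ 3 member genes and its detection is a coin flip for
  any test.
* **Conservation track.** Per-bin scores (50 bp bins) with means 0.6 /
  0.4 / 0.2 for protein-coding exons / lncRNA exons / background
  (protein-coding priority on overlap), Gaussian noise sd 0.05, clipped to
  [0, 1].

Everything is a deterministic function of the seed (independent
substreams per component), and two runs of the full pipeline with the same
seed produce byte-identical output trees.

**What passing on synthetic data does not show.** The generator has no
sequence content, no read-level noise, no assembly artifacts beyond the
planted distractors, one isoform per gene (except planted B-side
isoforms), clean block-diagonal correlation structure, and independent
Gaussian noise. Recovery here demonstrates algorithmic correctness — that
each stage finds exactly what its rule defines — not robustness to the
full messiness of real RNA-Seq.

## Numerical and calibration notes

* Hypergeometric p-values use the exact survival function and are checked
  against exhaustive enumeration for universes up to 12. Exact tests are
  conservative under discreteness: with few term genes the achievable
  p-values are coarse and the null rejection rate at α = 0.05 falls below
  5%. The calibration property test therefore uses a dense map (background
  0.3, 300-gene universe, 60-gene modules), where the measured null rate
  is ≈ 0.04.
* The hub-connectivity property test plants all 20 conserved lncRNAs as
  module hubs at 100 samples; the pipeline default plants only 8 so that
  some conserved families legitimately lack co-expression evidence and the
  coverage/Venn outputs stay informative. With 8 hubs the per-seed
  rank-sum test is underpowered, which is a sample-size property, not a
  method property.
* Rank-sum tests on identical samples give p ≈ 0.5 under the one-sided
  alternative (the U statistic sits at its null mean); tests assert
  non-significance, not p = 1.
* Degenerate inputs: constant expression features are dropped (exact
  peak-to-peak test) before correlation; transcripts with no scored
  conservation bases are skipped with a warning in batch mode and raise
  individually; a module with zero edges gives all its nodes connectivity
  0; an empty pairing result is valid, not an error.

## Known limitations

Coordinate-hull liftover can overstate the orthologous region of
transcripts with very long introns; per-exon lifting is not the default.
Family grouping by span overlap merges nested but unrelated same-strand
loci. Module detection by static cut is deterministic but less adaptive
than dynamic tree cut on real dendrograms. The GO map is taken as given —
no ontology-graph propagation. Network construction is dense (O(n²)
memory) and intended for up to a few thousand features, not genome-scale
matrices.
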