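# Methods

## Duplicate-pair classification

The candidate duplicate population is built from protein homology hits
(tabular BLASTP): per query, the top 5 non-self matches with e-value ≤ 1e-10
seed unordered pairs; genes with no qualifying hit in either direction are
singletons.  The e-value ceiling and the top-N are conventional values in
this literature and both are exposed in `ClassifierConfig`.

Pairs are then peeled off in a fixed order.  Syntenic anchor pairs are
authoritative WGD calls: the supplied anchor list is the WGD pair set
verbatim, with no further pruning (collinearity screening is assumed to have
happened upstream, in whatever produced the anchors).  Remaining pairs on
one chromosome are tandem at gene-rank distance 1 and proximal at distance
2–20; the rank of a gene is its 0-based position among *all* annotated genes
of its chromosome ordered by `(start, end, gene_id)` — the window counts
annotated genes, not expressed ones, and the tie-break for identical starts
is lexicographic because annotation formats do not order ties.

A transposed call requires exactly one copy at an *ancestral locus*.  A
locus is ancestral when its resident gene occurs, together with a paralog or
an ortholog, at corresponding positions of a pair of syntenic blocks; the
`AnchorCollection` therefore carries cross-species ortholog anchors next to
the within-species WGD anchors, and the ancestral set is the union of genes
in either.  Only within-species anchors define WGD pairs.  The ancestral
copy is the parent.  A parent with ≥ 3 exons and an intronless copy is a
retrotransposition; two single-exon copies are unclassifiable (the
direction of copying cannot be told); all other one-ancestral cases are
DNA-based transpositions.  Pairs with zero or two ancestral members fall
through to dispersed.

Each gene's unique origin is the highest-priority mode among its pairs:
WGD > tandem > proximal > retrotransposed > DNA-transposed > dispersed.
Unclassifiable pairs rank below dispersed for origin assignment: they carry
no mechanistic information, and a gene whose only relationships are
unclassifiable is labelled accordingly rather than silently dropped.

## Expression divergence

Pair similarity is Pearson's `r` across all individual samples — replicate
samples are never averaged, because averaging would shrink the null
distribution and overstate divergence.  Spearman's rho is available behind
the same interface.  Divergence is `d = 1 − r` (range [0, 2]); the function
is pluggable.  The divergence threshold is empirical: the 95% quantile of
`r` over `n_pairs` distinct unordered random gene pairs (default 10,000),
sampled uniformly without replacement among pairs; true duplicate pairs are
not excluded from the null draw (their density among random pairs is
negligible at genome scale).  For independent Gaussian profiles over `n`
samples the null `r` is approximately N(0, 1/(n−1)), so the 95% quantile is
≈ 1.645/√(n−1) — the analytic check used in the tests.

Dual conservation (the redundancy proxy) calls a pair conserved on both
axes when Ka is below the 25% quantile of all valid Ka and `d` is below a
divergence threshold (default 1 − r-threshold).  The independence
expectation is the product of the pooled marginal proportions.

## Cross-species expression conservation

Given k ortholog pairs and expression matrices A (k × nA) and B (k × nB)
from the two species, each matrix is reduced to its k × k co-expression
(Pearson) matrix.  EC of ortholog i is the correlation of row i of the two
co-expression matrices over the k−1 off-self entries.  The self entry is 1
in both matrices and is excluded by default: including it adds a guaranteed
identical coordinate to both vectors and mechanically inflates EC
(an `include_self` flag exists for sensitivity analysis).  Ortholog classes
are S-S (singleton in both genomes), D-D (duplicate in both) and S-D;
class contrasts use two-sample t-tests on `d = 1 − EC`.

## Sequence divergence

Ka/Ks follows Nei & Gojobori (1986), unweighted pathways.  Synonymous sites
per codon are the sum over positions of the fraction of the three possible
single-nucleotide changes that are synonymous; changes creating a stop codon
count as nonsynonymous.  S and N are averaged over the two sequences.
Codon pairs differing at 2–3 positions average their (Sd, Nd) over all
substitution orderings; orderings through a stop codon are discarded, and a
codon pair whose every ordering hits a stop is excluded from both the
difference and the site totals (keeping its sites while discarding its
differences would bias p downward).  Codon pairs containing a gap, an
ambiguous base, or a stop in either sequence are likewise excluded and
counted.  pS = Sd/S and pN = Nd/N receive the Jukes–Cantor correction
`K = −(3/4)·ln(1 − 4p/3)`; `p ≥ 3/4` (or differences observed on a zero
site count) sets an invalid flag rather than raising, mirroring how
downstream analyses drop such pairs.  The implementation is cross-checked
in the tests against an exhaustive pathway-enumeration oracle over the
whole codon table and against an independent NG86 implementation
(Biopython's); computation imposes no cap on Ka/Ks — any display trimming
is presentation-layer only.

Noncoding μ is the same Jukes–Cantor transform of the mismatch proportion
over ungapped alignment columns; `p = 0` gives μ = 0 (valid), `p ≥ 3/4`
flags invalid.

Promoters: up to 1,000 bp upstream of the TSS, truncated at the nearest
annotated upstream gene boundary, clipped at chromosome edges, strand-aware
(the TSS is the annotated start on `+`, the end on `−`; minus-strand
promoters are reverse-complemented).  With a minimal GFF3 no UTR-aware TSS
is available, so the gene boundary stands in for the TSS.  Promoter
duplication calls use a global alignment (match 1, mismatch 0, gap −1;
Biopython's PairwiseAligner) with identity = matches / all alignment
columns including gap columns; *duplicated* means identity strictly
greater than 0.45.

## Methylation and enrichment

A promoter is methylated when two probes, consecutive in the genome-ordered
probe track and both inside the promoter region, are both methylated.
"Adjacent" carries no distance cap — array probe spacing is roughly uniform,
and a cap would add a parameter the call does not need; genes with fewer
than two in-region probes are callable and unmethylated.

Term and family enrichment uses the one-sided (over-representation) Fisher
exact test on the 2×2 table of subset × term membership over the gene
universe — here the genes with an origin assignment, matching the duplicate
populations being contrasted.  Bonferroni correction multiplies by the
number of *tested* terms (terms with at least one universe gene); a flag
switches the denominator to all annotated terms.  Families with fewer than
10 members in the universe are excluded from the family-by-mode scan.

## Regression, power, splines

Regressions of `d` on Ks and the WGD code W (α, β, γ → 1, 2, 3; ρ, σ → 1, 2
— the count of whole-genome duplications the pair has lived through) are
ordinary least squares.  AIC uses the full Gaussian log-likelihood with
σ̂² = RSS/n and counts σ as a parameter, AIC = −2 logL + 2(k+2) for k
slopes — the convention of standard statistical packages; model *orderings*
are insensitive to the additive constant this choice fixes.

Correlation power uses Fisher's z with the finite-sample mean
`zm = atanh(r) + r/(2(n−1))`:
`power = Φ(√(n−3)·zm − z₁₋α/₂) + Φ(−√(n−3)·zm − z₁₋α/₂)`.
The bias term matters at moderate n (without it the approximation misses
exact power by ~0.014 at r = 0.5, n = 30; with it, by ~0.002, verified
against Monte-Carlo simulation of the correlation t-test in the tests).
At r = 0 power reduces to α exactly.

"Smoothing spline with df degrees of freedom" means: the natural cubic
smoothing spline whose smoother-matrix trace equals df.  The penalized
criterion Σ wᵢ(yᵢ − s(xᵢ))² + λ∫s″² is solved in the Demmler–Reinsch basis
(eigendecomposition of the weighted roughness penalty), where
trace(S_λ) = Σ 1/(1 + λγᵢ) is monotone and numerically stable for any λ;
λ is root-found so the trace hits df within 0.1.  Duplicate x values are
weight-averaged.  The fit agrees with scipy's `make_smoothing_spline` at
matched λ to ~1e-11 (a test asserts this); df = 2 recovers the OLS line and
any df reproduces exactly linear data, since linear functions span the
penalty's null space.

## The synthetic corpus

The generator emulates the statistical structure of a two-species plant
study — it is not a molecular-evolution simulator (no indels, no rate
heterogeneity, no transposon sequence models, no array-normalization
artifacts).  Defaults, chosen once as the study conditions:

* **Genome**: 2 chromosomes × 500 genes (1,000 bp gene spacing), 50 planted
  events per mode.  WGD events emit collinear anchor blocks of 5 pairs
  across two chromosomes with event labels cycling α/β/γ; tandem copies sit
  at adjacent ranks, proximal at rank distance uniform in [2, 20]; retro
  and DNA-transposed parents acquire ancestral status through cross-species
  ortholog anchors and their copies land on another chromosome (retro
  copies intronless, DNA copies with ≥ 2 exons); dispersed pairs join
  non-ancestral loci on different chromosomes.  Every planted pair emits
  qualifying homology hits in both directions; 50 decoy hits with e-values
  above the threshold exercise the filter.  Planted events are mutually
  non-interfering by default so recovery is exact; `interference=True`
  additionally plants tandem partners beside WGD anchor genes to exercise
  the priority rule.
* **Expression**: 200 samples; pair profiles built as z and
  r·z + √(1−r²)·ε so the population correlation equals the per-mode target
  (WGD 0.45, tandem 0.50, proximal 0.35, dispersed 0.20, DNA 0.15, retro
  0.12 — echoing the reported ordering that tandem/WGD duplicates conserve
  expression best and transposed duplicates least).
* **Sequences**: 200-codon ancestors of uniform sense codons; synonymous
  pressure applied only at 4-fold third positions (so synonymous-only
  corpora have Ka ≡ 0 by construction), nonsynonymous pressure at first
  positions constrained to sense, amino-acid-changing codons; per-mode
  pressures follow the age ordering tandem < proximal < WGD <
  transposed < dispersed.  Promoters are 1,000 bp with per-site mutation
  probability 0.1.
* **Methylation**: probes every 150 bp, methylated i.i.d. Bernoulli(0.2) —
  the scale of promoter-methylation rates reported for plant genomes.
* **Families**: 12 families of 10–30 genes; two of three receive an origin
  bias (80% of members drawn from one mode), the rest are null.
* **Two-species panel**: 200 orthologs per class (S-S, S-D, D-D), 100
  samples, an 8-factor latent model so co-expression is informative;
  species 2 adds class-specific perturbation noise σ = 1, 2, 4 so the true
  mean d orders S-S < S-D < D-D.  With all σ = 0 the matrices are
  identical and EC ≡ 1.  The two species share sample count by
  construction; EC itself never compares samples across species, only
  co-expression rows.

What passing tests show — and do not show.  Exact classifier recovery holds
because planted events are non-interfering and anchors are noiseless; real
corpora have missing anchors, fragmented annotations and promiscuous
homology, so real precision/recall will be lower.  The expression generator
plants exchangeable Gaussian profiles; array data have heavy tails,
batch structure and probe effects that widen the null.  The sequence
generator draws codons uniformly; real codon usage and transition bias
shift S/N site counts.  The tests therefore validate the *statistics and
the procedure*, not field performance.

Problem sizes in the test and acceptance runs (one CPU, a few seconds to a
few tens of seconds per block) were chosen so Monte-Carlo error sits well
inside each check's tolerance: 100-replicate recovery checks, 10,000-pair
null thresholds, 20,000-draw power simulations, n = 5,000 regressions with
100 replicates.

## Known limitations

* The classifier consumes anchors; it cannot detect synteny de novo, date
  events, or identify the mediating transposon families.
* Ka/Ks is the 1986 equal-rate method: no transition/transversion bias, no
  codon-frequency weighting; for saturated pairs the invalid flag is the
  honest answer.
* The promoter TSS is the annotated gene boundary; with UTR-annotated
  genomes the true TSS may sit downstream, shifting promoters.
* EC depends on the shared ortholog panel; with few orthologs (k small) the
  k−1-vector correlation is noisy, and the implementation refuses k < 4.
* Gene-family enrichment treats families as flat labels; no GO-graph
  propagation is performed.
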