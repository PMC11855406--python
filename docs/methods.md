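# Methods

This note documents the statistical definitions, conventions and design
choices behind `cubkit`, and what the synthetic test bed does and does not
establish about real data.

## Gene set definition

Codon statistics are only meaningful on clean, in-frame coding sequences, so
extraction applies the field's standard filter: a CDS is retained when it is
longer than 300 nt (strictly greater), a multiple of 3, starts with ATG, ends
with exactly one stop (TAA/TAG/TGA), contains no internal stop and no
ambiguity characters. Plastome inverted repeats duplicate several genes
(e.g. *ndhB*, *rps12*); duplicates of a gene name are collapsed to the first
occurrence in genomic order so no gene is double-counted. Every rejected
feature is written to the exclusion report with its reason, making the
retained set auditable — annotated plastomes typically carry ~80+ CDS
features of which ~50 survive this filter. Multi-exon and minus-strand
features are spliced and strand-corrected from their GenBank locations;
*trans*-spliced genes whose location cannot be extracted are excluded with a
reason rather than guessed at.

All statistics use the sense-codon → amino-acid mapping of NCBI translation
table 11 (identical to the standard code for sense codons). Stop codons are
carried in count vectors but excluded from every statistic; the initial ATG
is an ordinary Met codon and is counted. The sense-codon total of a valid
CDS is therefore length/3 − 1.

## Statistics

**RSCU.** For codon *j* of an amino acid with *k* synonyms and family total
*x*: RSCU = x_j·k/x. Families with zero occurrences are flagged unobserved
and their codons carry RSCU 0 (read as missing, not as bias). Within every
observed family the values sum to *k* by construction.

**Positional GC.** GC1/GC2/GC3 are G+C fractions at the three positions over
sense codons; GC12 is the mean of the first two; GCall the mean of all three
(equal to the base-level GC fraction of the concatenated sense codons). GC3s
restricts the third-position tally to codons of amino acids with at least two
synonyms (59 codons' worth; Met, Trp, stops excluded) — the denominator on
which synonymous choice actually operates, and the argument of the
expected-ENC curve. A3/T3/G3/C3 are third-position base counts over all
sense codons, the inputs of the PR2 plot.

**ENC.** Wright's statistic. Per amino-acid family with observed total
n ≥ 2, the codon homozygosity is F = (nΣp² − 1)/(n − 1), the finite-sample
estimator; families with n ≤ 1 or F ≤ 0 are dropped. Class means F̄_k
average F over families of degeneracy k (2-fold ×9, 3-fold ×1 = Ile,
4-fold ×5, 6-fold ×3), and ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. When no
Ile codons are observed, F̄₃ is imputed as (F̄₂ + F̄₄)/2 (the CodonW
convention); when a 2-, 4- or 6-fold mean cannot be formed the gene's ENC is
undefined (NaN) rather than extrapolated. Values are capped at 61; values
below 20 cannot arise. The expected curve ENC_exp(s) = 2 + s + 29/[s² +
(1−s)²] is evaluated exactly for s ∈ [0, 1].

**Species aggregation.** Per-species rows recompute composition on pooled
counts (not means of per-gene fractions). Because "the species ENC" is
ambiguous — the statistic can be taken on pooled counts or averaged over
genes, and published tables do not always say which — both are emitted
(`enc_pooled`, `enc_mean`). On strongly heterogeneous gene sets they differ
substantially; readers should state which they quote.

**Diagnostics.** The neutrality fit is ordinary least squares of GC12 on GC3
(scipy's `linregress`), requiring ≥ 3 genes and non-degenerate GC3; the slope
is conventionally read as the mutation share and 1 − slope as the selection
share, a reading reported as-is without endorsement of its causal
interpretation. The ENC ratio is (ENC_exp − ENC_obs)/ENC_exp with ENC_exp
evaluated at the gene's GC3s; the histogram uses width-0.05 bins with edges
at multiples of 0.05, closed on the left, and the mutation-consistent class
is |ratio| ≤ 0.05. PR2 coordinates use third positions of all sense codons
(matching the A3/T3/G3/C3 definition above), not only 4-fold families; a zero
denominator flags the point undefined. Correlations are Pearson r with
two-sided p from the t distribution (n − 2 df), starred at p < 0.05 (*) and
p < 0.01 (**); no multiple-testing correction is applied, matching how such
tables are conventionally reported. Zero-variance variables are flagged, not
silently dropped.

**Optimal codons.** Genes are ranked by observed ENC; the lowest-ENC
round(0.10·n) genes (round half up, minimum 1) form the high-expression pool
— low ENC ⇔ strong bias ⇔ putatively high expression, the convention this
threshold scheme comes from — and the highest-ENC genes the low-expression
pool. Ties at a pool boundary are resolved by gene id with a warning. Pool
RSCU is computed on pooled codon counts, not as a mean of per-gene RSCU. A
codon is optimal when RSCU_high > 1 and ΔRSCU ≥ 0.08; Met, Trp and stops are
never optimal. The ΔRSCU threshold is a parameter (`--delta-min`) because
both 0.08 and 0.8 circulate in the literature; 0.08 is the default, as 0.8
admits almost nothing. Per-species sets are intersected for the shared set;
a genus-wide pooled mode (`--pooled`) covers the alternative reading in
which all species' genes form one ranking.

## Synthetic data

The generator emulates a filtered plastid gene set: ~51 genes, lengths
300–1500 nt (multiples of 3), ATG start, sampled terminal stop, no internal
stops. Defaults mirror that scale; tests override sizes where an asymptotic
claim needs more codons. Four regimes:

* **uniform** — amino acids i.i.d. from `aa_freqs` (default uniform over the
  20 amino acids), codons i.i.d. uniform within each family. Calibration
  regime: RSCU → 1, per-gene ENC → 61 with length.
* **mutation** — one per-gene pressure g, spread evenly across
  `gc3_gradient` (default 0.2–0.8), sets P(G) = P(C) = g/2 at every codon
  position; codons are drawn from the resulting stop-free categorical over
  sense codons, which is exactly i.i.d. mutational base sampling with
  stop-prone draws resampled. All three positions track g, so the neutrality
  slope approaches 1, attenuated only by per-gene sampling noise in GC3
  (≈ 0.95 at the default sizes).
* **selection** — amino-acid composition fixed; within each family codons
  are reweighted by third base (weight t for G/C-ending, 1 − t otherwise,
  t swept over 0.1–0.9). The 6-fold families' first-position composition is
  invariant under this reweighting, so expected GC12 is constant across genes
  and the slope is ≈ 0.
* **planted-optimal** — genes share one fixed length and identical
  largest-remainder quota allocations of amino acids and synonymous codons;
  the designated tenth of genes replaces each planted codon's family
  entirely with the planted codon. Planted genes are therefore strictly the
  lowest-ENC genes, non-planted codons have ΔRSCU exactly 0 between pools,
  and the optimal-codon procedure must recover exactly the planted set —
  a sharp parameter-recovery check with no sampling slack. The quota
  construction is what makes the recovery exact; i.i.d. sampling at these
  sizes would leave ~0.03–0.06 RSCU noise against an 0.08 threshold.

Ground truth records each gene's regime, pressure parameter and realized
sense-codon distribution. The same spec and seed give byte-identical output.

What passing synthetic tests shows: the formulas, conventions and decision
rules are implemented correctly and recover planted structure. What it does
not show: real plastomes have correlated amino-acid usage across genes,
length–function correlations, intron/edit artefacts and annotation
idiosyncrasies that the generator deliberately omits; agreement with a
published multi-genome analysis additionally depends on selecting the same
gene set, which is why the exclusion report exists and why the real-genome
reproduction test runs on the downloaded records themselves.

## Numerical and reproducibility choices

Problem sizes in tests and in `scripts/acceptance.py` are chosen so each
check's sampling error is well inside its assertion band (e.g. the uniform
RSCU calibration uses ~6×10⁵ codons, putting 4.5 binomial standard deviations
inside the ±0.05 band for 6-fold families). Regression/correlation checks
use closed-form references at 1e-10; count-statistic checks use an
independently coded brute-force oracle at 1e-9. Tables are written sorted by
(species, gene) with fixed decimals (3 for fractions and RSCU, 2 for ENC, 4
for slopes, correlations and ratios), so identical configurations reproduce
byte-identical TSVs. All stochastic steps take explicit integer seeds; the
acceptance script derives every stream from its `--seed`.

## Known limitations

* Codon adaptation index, tAI and Fop are out of scope, as are phylogenetic
  reconstruction and genome drawing.
* ENC is undefined (NaN, flagged) for genes too short or too skewed to
  populate the 2-, 4- and 6-fold classes; such genes drop out of ENC-based
  diagnostics but remain in composition tables.
* The expression proxy behind the optimal-codon pools is ENC rank, not
  measured expression; results are a usage contrast between bias extremes,
  not a validated expression analysis.
* GenBank parsing trusts the annotation; it does not re-predict genes or
  repair frame errors.
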