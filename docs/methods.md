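# Methods

`gwasbench` implements a wave-based evaluation framework for methods that
nominate trait-associated genomic loci from GWAS summary statistics. This
note describes the model, its parameters, the synthetic data used to test
it, and the numerical choices made where the procedure left room.

## The evaluation model

### Locus definition

All coordinates are 1-based and closed at both ends; interval overlap is
`min(end_a, end_b) − max(start_a, start_b) + 1` bases. Significant loci are
built from summary statistics by a stepwise window procedure:

1. Collect all variants with p < 5 × 10⁻⁸ (configurable via
   `LocusConfig.sig_threshold`).
2. While any remain: take the variant with the smallest p-value (ties broken
   by ascending chromosome, then position), emit the window
   [pos − flank, pos + flank] with flank = 500 kb, and absorb every
   remaining significant variant inside it.
3. Merge emitted windows on the same chromosome that share at least one
   base.
4. Union any chromosome-6 locus touching the extended HLA/MHC region
   (chr6:25,000,000–35,000,000, a region of extreme linkage disequilibrium)
   with that fixed interval and collapse the results into a single `is_hla`
   locus. The union preserves any extension beyond 25–35 Mb, and the
   expanded interval is re-merged against its neighbours, so no captured
   variant is dropped.

The output partitions the significant variants: each belongs to exactly one
locus, and loci on one chromosome never overlap. Windows are deliberately
not clipped at chromosome ends or centromeres; starts may run below 1
internally, and only the BED writer clamps them (flagging how many).

### Gold standard and exclusion

Given two waves of the same trait, the gold standard is the wave-2
significant loci with *any* degree of overlap against wave-1 significant
loci removed — a nomination method earns no credit for rediscovering what
the earlier wave already found. Variant-level nominations are likewise
filtered by dropping points inside any wave-1 locus interval before
windows are opened around them; the same exclusion applies to every method
so all are judged identically.

### Classification and metrics

At locus level, a nominated locus is a true positive when it overlaps at
least one gold locus by ≥ 250 kb (`EvalConfig.min_overlap_locus`; the
sensitivity grid is 1 b / 250 kb / 500 kb / 750 kb) and a false positive
otherwise; a gold locus is covered when some nominated locus reaches the
same overlap and a false negative otherwise. Sensitivity (SN) is the
covered fraction of gold loci; positive predictive value (PPV) is the
confirmed fraction of nominated loci; F1 is their harmonic mean. The two
TP counts (nominated-side and gold-side) are carried separately because a
single broad nomination can cover two gold loci: it then counts once
toward PPV while both gold loci count toward SN, keeping each metric a
true proportion of its own denominator. No metric involving true negatives
is computed — a variant non-significant in the earlier wave may simply be
underpowered, so a TN is undefined in this design.

Variant-level classification matches exact (chromosome, position) pairs.
Gene-level classification judges nominations against the genes whose
gene-based p-values pass a Bonferroni correction on the count of genes
with a valid p-value; matching is by Ensembl ID or symbol (`id_match`), or
by converting genes to loci — annotated boundaries with a 2,500 b minimum
overlap, or ±500 kb around the midpoint `floor((start+end)/2)` with the
250 kb overlap — after merging overlapping gene loci to avoid double
counting. In the locus modes the gold side defaults to loci built from the
significant gold genes the same way; a precomputed variant-based gold
locus list can be supplied instead.

### Nomination procedures

- **Suggestive band**: 5 × 10⁻⁸ ≤ p < 1 × 10⁻⁵. Together with the
  genome-wide significant set this partitions {p < 1e-5} disjointly.
- **Annotation thresholds** (Sveinbjornsson scheme): per-category cutoffs
  loss-of-function p < 5.5 × 10⁻⁷, moderate impact p < 1.1 × 10⁻⁷, low
  impact p < 1.0 × 10⁻⁸, other p < 1.7 × 10⁻⁹. Unannotated variants fall
  in "other", the stringent catch-all — the conservative choice.
- **Weighted-Bonferroni eQTL** (Li scheme): raw weight
  √(−log₁₀ p_eQTL) for eSNPs and 1 otherwise (general mode), or a
  configurable two-level ratio (binary mode); weights are normalized to
  mean 1 over all M included variants and the weighted p-value is
  p/w (capped at 1), thresholded at 5 × 10⁻⁸. Mean-one normalization
  preserves the family-wise error rate: under the null the expected
  nomination count is Σ w_i · 5 × 10⁻⁸ = M · 5 × 10⁻⁸ regardless of the
  eSNP fraction. Dividing p by w is equivalent to multiplying each
  variant's threshold by w, and mean-one normalization is numerically
  identical to sum-M normalization. The closed-form optimal binary ratio
  (a function of α = 0.05, power = 0.6, M, and the eSNP fraction ε) is
  kept explicit as `binary_ratio` rather than baked in; the default of 2
  favours eSNPs without overwhelming the unweighted majority.
- **Generic rules** for external score tables: a fixed threshold, a
  Bonferroni correction on the number of valid p-values, or
  Benjamini–Hochberg FDR at q < 0.05. The FDR procedure is the standard
  step-up with monotone-adjusted q-values, chosen over local-FDR density
  estimation, which would introduce smoothing parameters the framework has
  no basis to set; BH's q-values are a deterministic function of the
  p-values alone.

P-values parse as given, with a floor of 7.41 × 10⁻³²³ applied to anything
smaller (including exact zeros from underflow) — the smallest positive
value a double-precision reader preserves reliably. Rows with missing,
negative, or > 1 p-values are dropped with a logged count rather than
aborting a run, since real summary-statistics files are dirty. Duplicate
(chromosome, position) records keep the smallest p-value, with exact ties
broken by lexicographically smallest rsid and then first occurrence, so
deduplication is deterministic and idempotent; multi-allelic rows at one
position are treated as duplicates by position.

### Ranking and ensembles

Per trait, each method's best PPV (across its database options) is ranked
by the Olympic worst-tie rule: a method's rank is the number of methods
whose PPV is ≥ its own, so tied methods share the lowest rank of their
group, and methods that nominated nothing rank 18 (`n_methods_total`),
below a PPV of 0. Cross-trait aggregation takes the median rank, defined
as the lower middle order statistic for even counts (for the odd trait
counts used here the convention is immaterial). Methods with zero
nominations are omitted from SN-vs-PPV scatter reports but keep rank 18 in
ranking tables. Scatter quadrants use strict boundaries: quadrant I is
SN > 0.5 and PPV > 0.5, II high-PPV/low-SN, IV high-SN/low-PPV, III
otherwise, with (0.5, 0.5) itself in III.

`gwasbench.benchmark` carries a published 18-method × 5-trait best-PPV
table as a fixed reference input for this arithmetic. Recomputing ranks
from its PPV columns reproduces 88 of the 90 printed rank cells and 17 of
18 printed medians; the two failing cells (and the one median they drive)
are an internal inconsistency of the printed source — two methods' ranks
are swapped relative to their printed PPVs — documented in that module's
docstring. A printed "median rank excluding one trait" column of the same
source is not carried at all, as no single median convention reproduces it.

The ensemble membership matrix is built stepwise: methods ordered by
descending nominated-locus count (ties by name), the largest first
contributing all its loci, each later method contributing only loci that
do not already overlap a matrix locus by ≥ 250 kb. Every contributed locus
is tested against *all* methods' nominations to fill its row at insertion,
so rows never need retroactive updates; the contributing method always
owns its locus even when the locus is narrower than the overlap
requirement. PPV by method support is reported both cumulatively (loci
nominated by ≥ k methods — the reading under which a "minimum number of
methods" achieves a target PPV) and exactly at each k, since support-PPV
need not be monotone.

## The synthetic generator

`simulate_two_wave_gwas` emulates the two-wave structure the framework
consumes. Defaults, chosen once as a realistic desk-scale configuration:

| parameter | default | meaning |
|---|---|---|
| `chrom_lengths` | 2 × 50 Mb | two synthetic autosomes |
| `n_variants` | 20,000 | total shared variant set |
| `n_causal_loci` | 6 | planted leads, ≥ 5 Mb apart |
| `effect_scale` | 4.5 | lead noncentrality (E\|z\|) at n₁ |
| `n1`, `n2` | 25,000 / 100,000 | wave sample sizes (n₂ = 4·n₁) |
| `decay_bp` | 50,000 | exponential signal decay scale |

Variant positions are uniform per chromosome (leads are always variants);
null z-scores are independent standard normals per wave; within 3·decay_bp
of a lead the z-score gains a shared signal
`effect_scale · √(n_wave/n1) · exp(−d/decay_bp)` plus unit noise. P-values
are two-sided normal tails, hence exactly uniform under the null. With the
defaults a wave-1 lead has E|z| ≈ 4.5 (detected ~17% of the time at
5 × 10⁻⁸) while wave 2's E|z| = 9 makes detection near-certain, so the
larger wave reaches significance at a superset of the planted loci — some
loci are "novel in wave 2", which is precisely what the gold standard
measures. All randomness derives from one root seed through named
substreams, so adding a stage never perturbs earlier draws and output is
byte-identical across reruns.

What the generator does *not* model: linkage disequilibrium (distance
decay stands in for it only to exercise locus collapsing), realistic
allele-frequency spectra, population structure, or binary-trait liability.
Passing tests therefore demonstrate the correctness of the evaluation
arithmetic and its calibration under the stated model — not that any
nomination method performs well on real GWAS data.

`make_nominations` builds nomination sets of exact planted composition:
true-positive points sit at gold-locus leads, and decoys are
rejection-sampled at least 2·flank + min_overlap away from every gold and
wave-1 locus and from each other, which guarantees decoy windows neither
merge with each other nor graze a gold locus. Infeasible requests (genome
too crowded) raise an error rather than silently degrading the planted
counts. `simulate_annotations` draws impact categories from a 4-vector of
probabilities (default heavily weighted to "other", mirroring how rare
coding consequences are) and gives eSNPs eQTL p-values log-uniform on
[10⁻²⁰, 10⁻⁴]. `simulate_gene_table` plants an exact count of
Bonferroni-significant genes and draws the rest uniformly above the
threshold, so the significant gold gene set equals the planted set by
construction.

## Verification strategy and problem sizes

The test suite checks the interval algorithms against brute-force oracles
that represent intervals as explicit sets of base coordinates, making
overlap literal set intersection — exact, obviously correct, and entirely
independent of the implementation. Randomized cross-checks run on
small-coordinate instances (positions ≤ a few thousand, flanks of tens of
bases) so the base sets stay cheap: 400 instances each for locus
definition and classification and 200 multi-method instances for the
ensemble matrix, alongside 100 full-pipeline planted-recovery cases at
3,000 variants and null calibration at 10⁶ variants × 20 seeds. These
sizes keep the default suite and the acceptance script at a few minutes
while the statistical checks retain 3-standard-error resolution around
the binomial expectation of 0.05 significant hits per million null
variants.

## Known limitations

- The framework consumes p-values only; effect directions, allele
  harmonization, VCF input, LD-based clumping, conditional analysis, and
  genome-build liftover are out of scope (inputs are assumed on one build).
- Gene-level evaluation trusts the supplied gene-based p-values; it never
  computes them.
- The 14 external functional-weighting tools whose outputs the framework
  evaluates are consumed as nomination files, never re-implemented.
- Whether a nominated locus covering two gold loci should count once or
  twice toward TP is not uniquely determined by the procedure's
  description; the implementation counts it once on each side's own
  denominator (see above), and the dual counts are exposed so either
  convention can be recovered.
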