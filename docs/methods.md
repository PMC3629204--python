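# Methods

## Design overview

`asepipe` analyses allele-specific gene expression (ASE) in an F1 hybrid
of two inbred lines from aligned RNA-seq reads. Because the parents are
inbred, every transcribed position is expected to be homozygous within a
parent; an inter-parental SNP is therefore detectable as two different
fixed bases, and every hybrid read covering it can be assigned a parent
of origin. All internal coordinates are 0-based half-open; serialized
output (VCF, TSVs) is 1-based.

## Read and base filtering

A read is discarded when strictly more than 30% of its bases have phred
quality below 20. Surviving reads have Q<20 bases trimmed from the 5′
and 3′ ends (trimmed positions contribute to no pileup); internal Q<20
or non-ACGT bases are tallied per column as `other_count` and never used
for calling. Secondary, supplementary and unmapped alignments are
skipped; duplicates are kept (conventional for RNA-seq quantification,
where high coverage of short transcripts produces legitimate duplicate
read starts). Biological replicates of a library are pooled before
pileup; per-replicate read totals are retained for the
replicate-agreement report.

## SNP discovery

At each exonic position covered in both parents:

- **Consensus.** Each parent must produce a consensus base among its
  Q≥20 bases. The default is strict unanimity (`max_minor_fraction=0`).
  Real data contain sequencing errors that break unanimity at high
  depth, so the knob admits a minor fraction up to the given value; the
  default stays at the strict reading because the simulator's default
  error model is clean and the knob's effect is exercised separately.
- **Depth.** The consensus allele needs ≥10 supporting reads in each
  parent, at each stage.
- **Stage concordance.** The identical allele pair must be observed
  independently at both developmental stages; sites with conflicting
  alleles between stages (or more than two alleles overall) are dropped.
  A SNP is a genomic property, so stage discordance indicates error.
- **Site quality.** The paper trail for this analysis style uses a
  caller-reported quality with a ≥20 cutoff without defining the score,
  so the package defines one: the phred-scaled probability that a truly
  heterogeneous site (minor fraction 0.5) would show at most the
  observed number of minor bases, taken per parent and minimized over
  parents, `q = min_p −10·log10(BinomCDF(minor_p; depth_p, 0.5))`. The
  score is monotone in depth, decreases with discordant reads, and any
  unanimous column of depth ≥10 scores ≥30, so the ≥20 gate binds only
  for shallow or heterogeneous columns (e.g. 3 minor in 15 scores 17.6
  and fails). Any monotone score with these properties would serve; this
  one has no tunable constants.

## Substitution spectrum

A directed substitution X→Y (parent-1 allele → parent-2 allele) is the
same molecular event as comp(X)→comp(Y) read from the opposite strand,
giving six complement-collapsed classes, labelled by the member whose
origin base is A or C: A:C, A:G, A:T, C:A, C:G, C:T. The headline
`ct_ga_fraction` is the strand-agnostic transition share — the combined
mass of the C:T class (C→T, G→A) and the A:G class (A→G, T→C), i.e. all
C↔T/G↔A events regardless of which parent carries which base. Under a
uniform spectrum (12 equiprobable directed substitutions) this baseline
is 1/3; methylated plant genomes show roughly double that, which is what
the simulator's default spectrum (0.68 transition mass, split evenly
between the two transition classes, remainder uniform over the four
transversion classes) emulates.

## Allelic-bias test

At each SNP the hybrid's Q≥20 bases are split into `n_p1` (parent-1
allele), `n_p2` (parent-2 allele) and `n_other` (neither; sequencing
error or a third allele — excluded from the test as uninformative about
parental origin). The test is the exact two-sided binomial test of
H0: p = 0.5 by the minimum-likelihood rule: the p-value sums P(k) over
all outcomes no more probable than the observation. Because the null
pmf is symmetric and strictly unimodal this equals the doubled smaller
tail; the implementation computes it in exact integer arithmetic
(sum of binomial coefficients over 2^n), so the returned double is the
correctly rounded exact value for any n. Reference points:
p(16,4) ≈ 0.0118 and p(17,3) ≈ 0.0026, straddling the P < 0.01 gate.

SNP-level p-values are used raw at alpha = 0.01 (no multiple-testing
correction, matching the analysis style this pipeline reproduces; a BH
option exists in `expression_metrics.bh_adjust` for callers who want
it). Transcripts with fewer than 20 SNP-supporting hybrid reads at a
stage are discarded for that stage (the support filter is per stage;
applying it across stages would be a one-line change). A transcript's
direction is decided on its significant SNPs only: all toward parent 1
→ `p1_biased`, all toward parent 2 → `p2_biased`, disagreement →
`contradictory` (excluded downstream), none significant → `balanced`.

Stage patterns compare the two per-stage calls (both stages, one stage,
none). Strong mono-allelic expression uses the read-weighted pooled
parent-1 fraction per stage, Σn_p1/Σ(n_p1+n_p2), with strict cutoffs
(< 0.3 or > 0.7); a transcript strongly skewed toward opposite parents
at the two stages is `switching`.

## Expression metrics and cis/trans logic

RPKM = count / (exon_kb) / (mapped_millions); fold coverage =
count × 100 / summed exon length. Parental differential expression uses
a two-sided Fisher exact test on the 2×2 table (transcript count vs
rest of library, parent 1 vs parent 2, replicates pooled) with BH FDR;
significance requires FDR ≤ 0.05 and |log₂FC| ≥ 1, with the fold change
computed on RPKM after adding a pseudocount of 0.5 to both sides. This
Fisher+BH gate deliberately stands in for negative-binomial dispersion
modelling: with replicates pooled there is no within-condition
dispersion to estimate, and the DE call only feeds the regulatory
classification. It is a pragmatic, anti-conservative stand-in on real
overdispersed data — a caveat for anyone applying the pipeline beyond
simulated inputs.

Regulatory mode per transcript and stage, given the parental ratio
r = RPKM₁/RPKM₂ (pseudocounted) and pooled hybrid allele counts:

| parental DE | allelic bias | ratio compatibility | mode |
|---|---|---|---|
| no | no | — | conserved |
| no | yes | — | ambiguous |
| yes | no | — | trans |
| yes | yes | binomial p ≥ 0.05 | cis |
| yes | yes | binomial p < 0.05 | cis_plus_trans |

Compatibility tests the parent-1 allele count against the expected
fraction r/(1+r) (exact binomial, two-sided). The 0.05 floor is a knob;
with it, a true cis transcript is mislabelled cis_plus_trans at roughly
the test's type-I rate, which bounds attainable cis recovery near 95%.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the full messiness of real RNA-seq. Defaults (chosen once, as the
study conditions for all tests): 40 transcripts of 2–4 exons of 150–300
bp on one chromosome; 3 planted SNPs per exonic kb with the 68%
transition spectrum; parent coverage 40×, hybrid 60×, split over 2
replicates per condition; 100 bp single-end reads emitted as aligned
SAM (M/N CIGARs over exons); per-transcript expression levels drawn
log-normal(0, 1) and shared across samples and replicates (this is the
biological signal behind replicate R² ≈ 0.95–0.98); 17% of transcripts
biased with parent-1 fractions drawn from {0.20, 0.35, 0.65, 0.80}
(mass 0.10/0.20/0.30/0.40 — skewed toward parent 1 and including
strong mono-allelic mass); 70% of biased transcripts biased at one
stage only and 3% switching between stages; 2% of bases assigned Q=11
and 1% junk reads (>40% low-quality bases) to exercise the filters;
sequencing error off by default. Hybrid reads draw a parent of origin
per read, so all SNPs on one read share an origin, as in a real
molecule. cis/trans divergence can be planted read-level
(`frac_cis`/`frac_trans` with a 4-fold expression ratio) or, for
calibration cohorts, counts-level via `simulate_regulation_counts`
(Poisson parental counts, binomial hybrid allele counts), which is the
exact generative model the classifier assumes.

Not emulated: mapping bias toward the reference allele, positional
quality decay, indels, spliced reads crossing exon boundaries of
*other* transcripts, overdispersed biological replication, paired-end
structure (immaterial to per-base pileups). Passing tests therefore
demonstrate correctness of the statistical machinery and filters, not
robustness to alignment artefacts.

## Numerical and degenerate-input choices

- Binomial p-values in exact integer arithmetic; ties at the observed
  pmf value are included by construction (no floating-point fudge
  factor).
- Strict inequalities throughout where the rules say "more than 30%",
  "P < 0.01", "less than 0.3 or greater than 0.7"; depth and support
  thresholds are inclusive (≥10, ≥20).
- Consensus ties (two bases at equal top count) never yield a consensus.
- Zero-depth columns: consensus none, site quality 0.
- Uncovered SNPs in the hybrid produce zero-count records that are kept
  but never tested; empty spectra report `ct_ga_fraction = 0` by
  convention.
- Replicate R² uses log10(RPKM+1); the +1 keeps zero-count transcripts
  finite at the cost of exact scale invariance.
- `generate_dataset` uses a single seeded generator stream, so output
  is byte-identical across runs of the same configuration.

## Problem sizes used in verification

The shipped verification suite uses: the full n ≤ 200 support sweep for
binomial exactness; 10,000 null SNPs at depth 100 for type-I error
(expected rate ≈ 0.0065 at alpha 0.01 — below nominal because the
discrete support is conservative); 2,000 SNPs at fraction 0.75, depth
100 for power (analytic ≈ 0.995); ~10,000 planted SNPs for spectrum
recovery (±0.02); 150 transcripts per class for cis/trans recovery
(≥90%); and the 40-transcript read-level dataset for end-to-end SNP
recall (≥95% of planted SNPs meeting the depth criteria) and
allelic-fraction recovery. These sizes keep each study's sampling error
comfortably inside its acceptance band while running in seconds.

## Known limitations

- The consensus rule at `max_minor_fraction=0` is unrealistically
  strict for deep real data; open the knob (0.05–0.1) for real inputs.
- No mapping-bias correction: on real data, reference-allele alignment
  bias inflates the reference parent's counts; allele-aware alignment
  or simulation-based correction is out of scope.
- Fisher-on-pooled-counts DE is anti-conservative under biological
  overdispersion (see above).
- The ≥20-support filter and the binomial test treat SNPs within a
  transcript as independent reads pools; overlapping reads covering two
  SNPs of the same transcript are counted at both, which mildly
  overstates the effective sample size — a shared limitation of
  count-pooling ASE designs.
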