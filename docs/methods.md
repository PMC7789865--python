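# Methods

This note records the statistical model behind `cubkit`, the numerical and
design choices that were genuinely open, what the synthetic data generator
does and does not emulate, and the known limitations.

## Quality control

A CDS passes iff its length is a multiple of 3, it begins with ATG, ends
with TAA/TAG/TGA, contains no internal stop and no ambiguous base, and has
at least `min_aa` (default 100) non-stop codons.  Checks are applied in
that order and the first failure is reported, so each rejected record
carries exactly one reason.  "Longer than 100 amino acids" is read
inclusively (≥ 100); the threshold is a parameter, so the strict reading is
one flag away.  ATG is the only accepted initiation codon.  Sequences with
ambiguity codes are rejected rather than codon-masked because every
downstream index assumes unambiguous codons.  All composition and usage
metrics exclude the terminal stop codon; the stop family is tabulated (and
chi-square tested) only in the pooled report tables.

## Indices

**RSCU.**  RSCU(c) = k·n_c/Σ_family n.  Amino-acid families follow the
standard genetic code with Leu, Ser and Arg as single six-fold families and
Ile as the only three-fold family; Met and Trp are uninformative singletons
(RSCU ≡ 1 when present).  Families absent from a gene yield missing values,
not zeros.  Report tables round half-up to 2 decimals.

**ENc.**  Wright's estimator: per family with total count n ≥ 2, the codon
homozygosity is F = (nΣp̂² − 1)/(n − 1); F values are averaged within each
degeneracy class and combined as ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.
Families with n ≤ 1 carry no information and are skipped (F is undefined at
n = 1).  If the three-fold class (Ile alone) is missing, F̄₃ is imputed as
(F̄₂ + F̄₄)/2; any other missing class is omitted from the sum — its amino
acids were not observed, so it cannot contribute.  Genes of ≥ 100 codons
essentially never trigger either path.  The estimate is clamped into
[20, 61]: 20 means one codon per amino acid, 61 no preference; the raw
estimator can exceed 61 (or dip below 20) by sampling noise.

**Expected ENc.**  ENc_exp(s) = 2 + s + 29/(s² + (1 − s)²), the ENc of a
gene whose only source of bias is third-position composition s = GC3s.  The
per-gene relative deviation (ENc_exp − ENc_obs)/ENc_exp is reported with a
0.05-width histogram.

**CAI.**  Relative adaptiveness w(c) = n_c/max_family n over a pooled
reference; a gene's CAI is the geometric mean of w over its codons with
Met, Trp and stops excluded (computed as a mean of logs).  Zero-count
codons in an observed reference family are floored at 0.5 occurrences
before weighting so that using them is penalised without annihilating the
geometric mean; families wholly absent from the reference get w ≡ 1 with a
logged warning.

**Choice of internal CAI reference.**  With no expression data, the
reference must be a proxy for highly expressed genes.  Ranking genes by raw
ENc is the traditional proxy but it conflates selective bias with
compositional extremity: in a set whose GC3 spans 0.2–0.9, the lowest-ENc
genes include GC3-extreme genes whose usage is concentrated by composition
alone.  A reference contaminated this way tilts the weights toward the
AT-rich end, and the downstream high/low partition then contrasts
composition rather than expression.  `cubkit` therefore ranks genes by the
*residual* ENc_obs − ENc_exp(GC3s) — how much more biased a gene is than
its own composition predicts — and pools the most deficient 5%
(`reference_method="enc_residual"`, the default; `"enc"` restores the raw
ranking, and an explicit weight table can be supplied instead).  On
synthetic data with an expression gradient, the residual reference recovers
all planted preferred codons where the raw-ENc reference recovers barely
half with many compositional false flags.

## Gene-set diagnostics

**Neutrality regression.**  OLS of GC12 on GC3 with the Pearson r of the
pair; the x-axis is GC3 over all third positions (not GC3s).  A slope near
1 means positions 1–2 track third-position composition (mutational
pressure); near 0, selective constraint.

**PR2 bias.**  x = G3/(G3 + C3), y = A3/(A3 + U3) per gene, by default over
the five strictly four-fold degenerate families (Ala, Gly, Pro, Thr, Val —
Sueoka's convention, where third-position composition is free of amino-acid
effects); an `all_synonymous` scope is computed alongside.  Quadrants are
numbered counter-clockwise from the upper-right (Q1: x > 0.5, y > 0.5);
points exactly on a 0.5 boundary are assigned to the lowest consistent
quadrant index and counted separately, so quadrant totals are reproducible.
The report also counts points inside the central [0.2, 0.8]² box.

**Correlation matrix.**  Pairwise Pearson (default; Spearman by flag)
correlations and unadjusted two-sided p-values over GC12, GC3, GC, ENc,
CAI and CA Axis 1, on the genes complete for all six parameters.

## Correspondence analysis

The gene × 59-codon RSCU matrix is decomposed under the chi-square metric:
P = X/ΣX, standardized residuals S = (P − rcᵀ)/√(rcᵀ), SVD, principal
coordinates; axis k carries inertia σₖ²/Σσ², and the total inertia equals
the chi-square statistic of the table divided by its grand total.  RSCU is
used rather than raw counts so genes are compared by usage profile, not
length.  Missing families are imputed at the family-uniform value 1.0 —
neutral, inducing no direction.  Rows are divided by their sums before
decomposition; for complete RSCU rows this is a no-op (every row sums to
59) but it makes gene coordinates exactly invariant to rescaling a single
gene's RSCU vector.  Axis 1's sign is fixed by requiring a non-negative
correlation with GC3 (the dominant compositional trend); later axes get the
largest-|coordinate|-positive convention.  Four axes are retained by
default, and each gene carries a GC-content class (< 45%, 45–60%, > 60%)
for plotting.

## Optimal codons

Genes are ranked by CAI (ties broken by id); the top and bottom
max(1, round(0.05·n)) genes form the high and low pools, codon counts are
summed *within* each pool, and pool RSCU is computed from the summed counts
(pooling before RSCU — not averaging per-gene RSCU — keeps every codon's
table entry an integer count).  Each codon of a multi-codon sense family is
tested with a 2×2 Pearson chi-square — this codon vs the rest of its family,
high vs low pool — without continuity correction (pool counts are in the
hundreds to thousands, where Yates over-corrects).  A codon is optimal when
p < 0.01 and its RSCU is higher in the high pool; no RSCU > 1 requirement
is imposed, so a codon can be optimal while still a minority choice within
its family.  Stop codons are tabulated and tested but never flagged; Met
and Trp are excluded.  A pre-pooled counts table can be supplied directly
(`optimal_codons_from_counts`, CLI `optimal --counts`), which is how the
bundled *R. palmatum* high/low table runs without sequence data.  In that
bundled table, the few codons whose counts were not tabulated at source are
back-calculated from their family's RSCU and a sibling codon's count
(flagged `reconstructed`; they preserve family totals but their individual
entries are placeholders), and the Glu family is absent because no member
was tabulated — its two codons are skipped with a logged warning.

## Synthetic data generator

The generator emulates the statistical structure of a QC'd plant
transcriptome CDS set: n = 500 genes by default (10²–10³ is the intended
regime), lengths lognormal between 100 and 800 aa (median ≈ 283, sigma
0.45), synonymous third-position GC (GC3s) targets spread over 0.21–0.89
with mean 0.466 (a Beta(1.1, ·) profile laid down as stratified quantiles,
so the configured range and mean are hit deterministically), a GC12–GC3
coupling with nominal neutrality slope 0.171, and an expression gradient:
gene i draws a latent expression rank e_i ~ U(0,1) and a bias level
b_i = bias_strength · (coupling·e_i + (1 − coupling)·u_i) with
bias_strength 2.0 and coupling 0.8 by default, which puts the most biased
genes near ENc ≈ 31 and unbiased genes near 61.

Codons are sampled per amino acid from a tilted multinomial with weight
exp(b_i·[c = preferred]) × t₃(c), where t₃ is τ_i for G/C-ending codons and
1 − τ_i otherwise.  The gene-level tilt τ_i is solved by a monotone 1-D
root so that the *expected* GC3s equals the gene's target exactly, whatever
its bias level and whichever codons are planted as preferred — without this
correction the planted-bias term and the fixed third positions of Met/Trp/
Ile shift realized GC3 off target by several points.  The GC12 coupling is
a linear tilt of the amino-acid distribution along each amino acid's mean
positional GC, calibrated against the damping from invariant Met/Trp third
positions; the six-fold families were checked to contribute no spurious
slope (their sub-family split is independent of τ).  Amino acids are
otherwise uniform — realistic plant protein composition is deliberately not
emulated.  The stop codon is uniform over TAA/TAG/TGA and outside the bias
machinery.  Each gene's randomness comes from a substream keyed by
(seed, gene_index), so datasets are byte-reproducible under partial
regeneration.

What passing tests on this generator do **not** show about real data: real
transcriptomes have non-uniform amino-acid usage, length-dependent
composition, assembly and annotation artifacts, and expression proxies far
noisier than the generator's latent rank; recovery rates here are
upper bounds on what CAI-based partitioning achieves in practice.

## Calibration caveat for the null

Under a true null (no preferred usage anywhere), partitioning by CAI is
circular: the internal reference is itself chosen from the bias extremes of
the same data, so the top/bottom CAI pools are noise-selected in the
direction of the reference weights and the chi-square flags far more
codons than its nominal level (a winner's-curse effect measured at 7–30
flags on 300-gene null sets).  The calibration test therefore partitions
null data by the generator's latent expression — the quantity CAI proxies —
where the procedure is honest (0–4 flags, within the upper 99.9% binomial
bound for 59 tests at the 1% level, allowing for the mild overdispersion
that pool-level GC3 heterogeneity adds).  Consumers should treat
optimal-codon lists obtained from CAI partitions without external
expression data as conditional on the reference choice.

## Numerical conventions

Fractions are kept in [0, 1] internally and scaled to percentages only in
summaries; report tables round half-up to 2 decimals.  TSV outputs are
sorted (amino acid name, codon, or gene id) and written with fixed float
formats, so re-running a fit with the same inputs produces byte-identical
files (checksummed in the run manifest).  Genes whose GC3s or ENc is
undefined (no synonymous codons; no family with n ≥ 2) carry missing
values and are dropped per-analysis, never imputed.  Problem sizes used by
the test suite — 200–500 genes of ~100–800 codons — are the package's
desk-scale defaults; the full pipeline on 500 genes runs in a few seconds.
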