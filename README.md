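# cubkit

Codon usage bias analysis for coding-sequence (CDS) collections — built for
transcriptome-scale studies of non-model organisms (the motivating case is a
medicinal-plant transcriptome of a few thousand predicted CDSs, such as
*Rheum palmatum*), where the questions are: how biased is synonymous codon
usage, is the bias driven by mutation pressure or by selection, and which
codons are "optimal" (preferentially used by highly expressed genes)?

`cubkit` takes a nucleotide FASTA of CDSs and runs the complete standard
analysis as one fitted model:

1. **QC** — keep sequences that start with ATG, end with a stop, have no
   internal stop or ambiguous base, and code for ≥ 100 amino acids.
2. **Composition** — per-gene base fractions, GC1/GC2/GC3/GC12/GC, GC3s
   (third positions of synonymous codons only), third-position base counts.
3. **Usage indices** —
   * RSCU(c) = k·n_c / Σ_family n (family sums equal the degeneracy k;
     Leu/Ser/Arg are six-fold families, Ile three-fold);
   * ENc by Wright's estimator,
     ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with
     F = (nΣp̂² − 1)/(n − 1) per family, capped into [20, 61];
   * CAI = geometric mean of relative adaptiveness w(c) = n_c/max_family n
     from a reference pool of (proxy) highly expressed genes.
4. **Diagnostics** — neutrality regression (GC12 on GC3), the ENc–GC3s plot
   against the null curve ENc_exp = 2 + s + 29/(s² + (1−s)²), the relative
   deviation (ENc_exp − ENc_obs)/ENc_exp, and the PR2-bias plot
   A3/(A3+U3) vs G3/(G3+C3) with quadrant counts about (0.5, 0.5).
5. **Correspondence analysis** of the gene × 59-codon RSCU matrix
   (chi-square metric, SVD), with Axis 1 oriented to correlate positively
   with GC3, plus the six-parameter correlation matrix
   (GC12, GC3, GC, ENc, CAI, Axis 1).
6. **Optimal codons** — pool codon counts of the top and bottom 5% of genes
   by CAI, per-codon 2×2 Pearson chi-square (codon vs rest of family ×
   high vs low pool, no continuity correction); optimal = p < 0.01 with
   higher RSCU in the high pool.

A seeded synthetic-CDS generator with known ground truth (planted preferred
codons, GC3 targets, expression gradient) makes every stage testable without
external data.

## Worked example

```python
from cubkit import CodonUsageAnalysis, GeneratorConfig, generate_dataset

dataset = generate_dataset(GeneratorConfig(n_genes=500, seed=7))
results = CodonUsageAnalysis(dataset.genes).fit()
print(results.summary())
```

```
Codon usage bias analysis
==========================================================
Genes analysed:        500 (of 500 input; 0 rejected by QC)
Mean GC / GC1 / GC2 / GC3 (%): 46.53 / 47.29 / 39.99 / 52.30
ENc: mean 46.97, range 30.45-61.00; 24 genes < 35
CAI: mean 0.482 (reference: most ENc-deficient 5% pool (n=25))
Neutrality plot: GC12 = 0.180 * GC3 + 0.342  (r = 0.760, p = 3.68e-95, n = 500)
ENc-GC3s: 401/500 genes below the expected curve
PR2 (fourfold_only): quadrants Q1=28, Q2=251, Q3=209, Q4=12; 442 in [0.2,0.8]^2
COA: Axis1 33.00% and Axis2 10.59% of total inertia
Axis1-GC3 correlation: r = 0.986
Optimal codons (p < 0.01, high-pool biased): 18 of 62 tested (25 genes per pool)
```

Reading it: the synthetic transcriptome is mildly AT-rich (GC 46.5%) with a
broad ENc spread (30.5–61); the neutrality slope of 0.180 says third-position
composition explains only ~18% of the variation at positions 1–2 (selection
constrains the rest); most genes sit below the expected ENc curve, and the
18 flagged optimal codons are exactly the generator's planted preferred
codons recovered from the expression gradient. `results.save("outdir")`
writes the full TSV report bundle (per-gene metrics, pooled RSCU, neutrality
fit, ENc–GC3s and PR2 tables, CA coordinates and inertia, correlations,
optimal-codon table, manifest with checksums).

The same run from the shell:

```bash
cubkit simulate -o sim --n-genes 500 --seed 7
cubkit all sim/synthetic.fasta -o report --plots
cubkit optimal counts.tsv --counts -o out   # pre-pooled high/low counts mode
```

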