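# nampop

Simulation and analysis of **nested association mapping (NAM) populations**
of recombinant inbred lines (RILs), as used in crop genetics: many
biparental families that share one recurrent founder (RF), advanced by
single-seed descent (SSD) to near-homozygosity, genotyped on a SNP array and
phenotyped in multi-environment field trials.

The package is aimed at quantitative geneticists and breeders who want a
tested, scriptable desk pipeline for such populations:

- **Forward simulator** — founder panels, Haldane meiosis, literal
  one-seed-per-line SSD (residual heterozygosity and drift are emergent),
  optional viability selection creating localized segregation distortion,
  array-like measurement artifacts (missingness, spurious heterozygotes,
  ascertainment masking), and alpha-lattice trial phenotypes. Every run is
  reproducible from a single seed and carries its ground truth.
- **Genotype QC** — sample filter (call rate ≥ 80%, heterozygosity ≤ 20%)
  then marker filter at the same thresholds; per-family polymorphism,
  heterozygosity and failure statistics; MAF spectra; exclusive (UpSet-style)
  intersections of family polymorphic sets; SNP density in 10 Mb bins.
- **Marker placement** — physical map from SAM alignments of marker flanking
  reads, rejecting MAPQ < 10, secondary/supplementary records and
  multiple-hit evidence (XA/SA tags or duplicate primaries).
- **Distortion scan** — within each family, founder-polarized calls tested
  per locus against the Mendelian 50:50 with a 1-df chi-squared; p-values
  averaged in 5 Mb bins, −log-transformed and signed by the over-represented
  founder; Bonferroni threshold −log(α/n_markers).
- **LD** — pairwise dosage r², Hill–Weir decay fits with the decay distance
  at r² = 0.2, and a two-stage (0.5 Mb neighborhood, 30-marker rolling)
  LD-evolution profile along chromosomes.
- **Diversity** — allele-sharing distances, Saitou–Nei neighbor joining with
  deterministic tie-breaking, PCA with explained-variance fractions, and a
  reproducible misassigned-sample screen.
- **Trials and GWAS** — REML (average-information, mixed-model-equation
  space) for the row-column alpha-lattice model
  `Y = μ + G + L + G×L + rep + col(rep) + row(rep) + ε`, genotype BLUPs,
  entry-mean broad-sense heritability
  `h² = σ²G / (σ²G + σ²GL/l + σ²ε/(l·r))`, VanRaden kinship, an EMMA-style
  single-marker mixed-model scan with 3 PC covariates, Bonferroni QTN
  calling, and ±500 kb candidate-gene lookup from GFF3.

## The core statistics

Per-locus founder distortion in a family with `n_rf` RF-homozygous and
`n_alt` alternative-homozygous RILs:

    χ² = (n_rf − n/2)²/(n/2) + (n_alt − n/2)²/(n/2),  n = n_rf + n_alt

LD decay with recombination-scale parameter `C = a·d` and sample size `n`
(Hill–Weir expectation):

    E[r²] = (10+C)/((2+C)(11+C)) · [1 + (3+C)(12+12C+C²) / (n(2+C)(11+C))]

The association scan estimates `δ = σ²e/σ²g` once under the null by REML on
the spectral decomposition of the kinship matrix, then tests each marker by
generalized least squares; with an identity kinship it reduces exactly to
ordinary least squares.

## Worked example

`examples/06_trial_blups_gwas.py` simulates a 6-family NAM in which one
marker carries a 3-day allele-class effect on days to booting (DB), runs the
trial model and the GWAS:

```
variance components: {'genotype': 1.7, 'gl': 0.27, 'rep': 0.08, 'col': 0.09, 'row': 0.15, 'resid': 1.02}
broad-sense heritability (entry-mean): 86.8%

1 QTNs at the Bonferroni 0.1 cutoff (causal marker: chr1_m0021):
    marker chromosome  position traits        min_p
chr1_m0021       chr1  51219512     DB 8.721883e-13
```

The REML fit recovers the simulated variance structure, the heritability is
in the range typical of phenology traits, and the single called QTN is the
causal marker itself. The other scripts in `examples/` each exercise one
capability; `examples/04_ld_decay.py`, for instance, prints the
multiparental LD contrast:

```
family fam01 (n=100):  decay to r2=0.2 at 42.3 Mb
pooled NAM  (n=1200): decay to r2=0.2 at 1.8 Mb
```

pooled families accumulate recombination events, so the NAM as a whole
decays more than an order of magnitude faster than a biparental family —
the reason multiparental populations map QTL at higher resolution.

A thin CLI wraps only the simulator:

```bash
nampop simulate -c examples/simulate_config.yaml -o out/ --seed 1
```

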