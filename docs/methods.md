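# Methods

## The population model

A NAM population is a star of biparental crosses: a recurrent founder (RF)
crossed to each of several alternative founders, each F1 advanced by
single-seed descent (SSD). The simulator implements this generative model
literally rather than sampling from closed-form genotype distributions:

- **Founders** are fully homozygous, so one haplotype per founder suffices.
  `simulate_founders` draws the RF haplotype uniformly and flips each other
  founder's allele per marker with probability `divergence`. A scalar
  divergence of 0.5 means half the markers segregate in a given cross —
  about what a diverse landrace-by-elite cross shows on a fixed array — and
  is the default used throughout the examples and validation studies.
- **Meiosis** follows the Haldane model: crossover counts per chromosome are
  Poisson(genetic length/100), breakpoint positions uniform on the genetic
  map, no interference, start phase fair. Haldane was chosen as the simplest
  map-function-consistent model; interference would slightly reduce
  double-crossover classes but none of the downstream statistics are
  sensitive to it at the marker densities involved. Physical and genetic
  coordinates are linked by piecewise-linear interpolation between anchor
  points (default: chromosome ends, i.e. a uniform landscape; tied cM
  positions encode recombination-suppressed stretches).
- **SSD** advances exactly one offspring per line per generation for
  `generations_of_selfing` generations (default 5: F1 → F6). Residual
  heterozygosity (expected (1/2)^k per segregating locus) and within-family
  drift are emergent from this one-seed bottleneck, not imposed.
- **Viability selection** rejects an offspring of the targeted genotype
  class with probability `s` and redraws a sibling seed (cap 100 tries per
  generation); a line whose descent dies is restarted from the F1 (cap 20,
  counted as lines lost). This conditions each parent's offspring
  distribution on survival, so the matching analytic oracle is the 3-state
  selfing transition matrix with row-wise (per-parent) renormalization —
  not population-level truncation. Selection loci snap to the nearest marker
  on their chromosome, because markers are the only loci tracked.
- **Array artifacts** are overlaid on clean calls in a separate, logged
  step: calls go missing at `missing_rate`, true homozygotes flip to
  heterozygous at `het_error_rate`, and a fraction
  `ascertainment_fraction` of "FV-private" markers is masked to the RF
  homozygote across all samples. FV-private is operationalized as: markers
  polymorphic in the founder panel at which the RF carries the panel-majority
  allele — the variation contributed by the exotic (farmer-variety) side,
  which an internationally ascertained array is most likely to miss.
  Defaults (1% missing, 0.2% heterozygote error, 10% ascertainment loss) are
  of the order reported for fixed wheat arrays on landrace material.
- **Trial phenotypes** are drawn exactly from the row-column alpha-lattice
  model below, with rows and columns nested in replication and an
  independent randomization per location-rep.

All randomness flows from a single master seed through named substreams
(`substream(seed, *keys)`), so results are byte-identical across runs and
independent of unrelated code paths.

## QC conventions

Thresholds are applied strictly as stated: a sample is removed when its call
rate is *below* 0.8 or its heterozygosity *above* 0.2; boundary values stay.
The sample filter runs before the marker filter, and marker rates are
computed on retained samples. Heterozygosity is always a fraction of
non-missing calls, to avoid conflating missingness with heterozygosity.
A marker counts as polymorphic within a family when a homozygote class plus
a different call class is observed; founder rows never enter family counts.
Filtering is idempotent in practice (re-applying it removes nothing) as long
as no sample or marker sits exactly at a threshold after the first pass; the
test suite checks this at realistic artifact rates.

The removal of visually misassigned samples is replaced by a reproducible
rule: a sample is flagged when its mean allele-sharing distance to its own
family exceeds its distance to some other family by a margin (default 0.05).
Flagged samples are reported, never silently dropped.

## Distortion scan

Within a family, calls are polarized by founder origin; markers with a
missing or heterozygous founder call, or monomorphic between the founders,
are dropped, and heterozygous RIL calls are treated as failed. Each locus is
tested against 50:50 with a 1-df chi-squared; per-marker p-values are
averaged within 5 Mb bins (half-open, anchored at 0), −log-transformed
(natural log) and signed by the bin's majority founder direction weighted by
informative calls. Bins with fewer than three markers are suppressed.
Signing is applied per bin to the unsigned mean-p score — signing raw
p-values before averaging would mix signs incoherently. The genome-wide
threshold is −log(α/n_markers) with α = 0.05 and the marker count (not the
bin count) in the denominator, a deliberately conservative choice given bins
are what is reported. With natural logs and ~12 000 markers this threshold
is ≈ 12.4; the module always computes it rather than quoting a constant.

## LD

r² is the squared Pearson correlation of allele dosages over
pairwise-complete samples — the composite genotype measure, which for
near-inbred RILs essentially equals the haplotype measure. Pairs with fewer
than 10 complete samples or a conditionally monomorphic marker are missing,
never zero, and missing pairs are excluded from fitting rather than imputed.
The decay fit uses the Hill–Weir expectation with `C = a·d` and one free
coefficient `a ≥ 0` (sample size fixed, not fitted), by Levenberg–Marquardt
least squares on log a from a coarse-grid start; flat data pin `a` at the
zero boundary with a warning. Decay distance is found by bracketing and
Brent root-finding on the monotone fitted curve; a curve that never crosses
the threshold reports +inf with a warning. The LD-evolution profile is
two-stage: a distance-based stage (mean r² to all markers within ±0.5 Mb,
self excluded; markers with no neighbor stay missing) followed by a
count-based centered 30-marker rolling mean, truncated at chromosome edges.

## Trial model and heritability

The plot model is

    Y = μ + G_a + L_b + GL_ab + b_i + c_j(i) + r_k(i) + ε

with location fixed and genotype, genotype-by-location, replication,
column-in-rep and row-in-rep random. Genotype is treated as random so that
BLUPs are defined (BLUPs do not exist for fixed effects); its variance
doubles as the numerator of heritability. REML is fitted by
average-information steps taken on log-variances (multiplicative updates
stay positive and tame flat directions of near-degenerate fits), with all
per-iteration quantities computed in mixed-model-equation space via the
Woodbury identity — no n×n matrix is ever formed, so a 1 800-plot design
fits in a few seconds. Convergence is a relative log-likelihood change
below 1e-6; variances are floored at 1e-10 of the phenotypic variance. The
implementation is verified against an explicit dense-V REML oracle and
against lme4 in the test suite.

Broad-sense heritability is on an entry-mean basis across `l` locations and
`r` replications: `h² = σ²G / (σ²G + σ²GL/l + σ²ε/(l·r))`, with `l` and `r`
taken from the realized design.

## Association scan

Kinship is the VanRaden-type centered-dosage cross-product scaled by marker
count, with ≤ 1e-6 diagonal jitter for numerical positive semidefiniteness.
The scan follows the EMMA strategy: the variance ratio δ = σ²e/σ²g is
estimated once under the null by REML profiled over the spectral
decomposition of K (grid on log δ in [−10, 10] plus bounded refinement);
each marker is then tested by generalized least squares with intercept and
three PC covariates computed from the same filtered genotype matrix used for
K, the residual scale re-estimated per marker, and a Wald t-test on the
allele-substitution coefficient. Re-estimating the scale per marker makes
the scan reduce *exactly* to OLS when K = I, which the tests check to 1e-8.
Markers below 1% MAF are skipped and logged. A deliberate design choice is
the single-pass scan: iterative pseudo-QTN conditioning (FarmCPU-style)
would sharpen signals near linked QTL but is a separate algorithm; the
single-pass mixed model keeps the scan transparent and testable against OLS
and power simulations. QTNs are markers below α/n_markers with α = 0.1,
reported once per marker with the joint trait list; traits are scanned
independently with no cross-trait multiplicity correction. Candidate genes
are protein-coding gene models from a GFF3 annotation overlapping the closed
±500 kb window around each QTN.

## Validation studies and their scope

`nampop.validation` fixes the simulation conditions used to characterize the
pipeline: 1 000 RILs for heterozygosity; 10 000 meioses per map distance;
200 replicate families of 200 RILs on a 2×100 Mb genome (80 markers per
chromosome, four per 5 Mb bin) for scan calibration; a 12×100-RIL NAM on a
60-marker chromosome for the LD contrast; 50 replicates of a 12×100-RIL NAM
(80 markers) for QTN power with an allele-substitution effect of 1.5
(a 3-unit homozygote-class difference, e.g. 3 days of flowering time), a
polygenic background and broad-sense heritability 0.9; and 20 replicates of
a 300-genotype, 3-location × 2-rep trial for variance-component recovery.
These sizes make each study run in seconds to a couple of minutes while
keeping Monte-Carlo error well inside the tolerances tested.

What passing these studies does and does not show: the generator emulates
biallelic array genotypes on an idealized genome — equal chromosome sizes,
evenly spaced markers, a uniform (or piecewise-linear) recombination
landscape, independent founder divergence per marker, no genotype-calling
cluster artifacts, no population structure beyond the NAM design itself, and
single-trait phenotypes with Gaussian effects. Results on real array data
additionally face marker clustering near genes, pericentromeric marker
deserts, shared ancestry among founders, and non-Gaussian trait
distributions; the pipeline's statistics are defined for those inputs, but
the power and calibration numbers here should be read as properties under
the simulator's conditions, not guarantees for any particular field dataset.

## Known limitations

- Backcross/MAGIC designs, outcrossing, epistatic selection and
  sequence-level simulation are out of scope; markers are the only loci.
- The NJ implementation is O(n³)–O(n⁴) with exhaustive tie-scanning;
  fine for the few-hundred-sample trees it is meant for, not for thousands.
- The scan's PC covariates and kinship derive from the same genotype matrix;
  with very small marker panels this double use can overcorrect.
- `fit_trial_model` assumes a single trait per record table and drops no
  outliers; plot-level data cleaning is the caller's responsibility.
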