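# Methods

## Model and assumptions

The pipeline operates entirely on GWAS summary statistics: per variant and
trait, an effect estimate β, its standard error, the Z-score z = β/se, the
effect-allele frequency and a sample size. The core modeling assumptions
are:

* Under the null, the vector of a variant's Z-scores across traits is
  multivariate normal with unit variances and a correlation matrix R
  driven by phenotypic correlation and sample overlap. R is estimated as
  the genome-wide Pearson correlation of the per-trait Z columns over all
  shared variants. A null-restricted estimate (|z| < cutoff in every
  trait) is available by configuration, since genuine signals inflate the
  raw estimate; the raw estimate is the default because at genome scale
  the significant fraction of variants is negligible.
* The N-weighted combination z_multi = Σ √Nᵢ zᵢ / √(wᵀRw) is the optimal
  fixed-effect combination when true effects are proportional across
  traits on the standardized scale; under the null it is standard normal
  by construction whatever R.
* Colocalization assumes at most one causal variant per trait per window.
  Violations (allelic heterogeneity) are handled by the approximate
  conditional adjustment, which assumes the conditioning variant's LD with
  every window variant is known and that two signals are approximately
  additive on the z scale.

For case-control traits the sample size used in the weights is the
effective size 4/(1/N_cases + 1/N_controls); a per-variant N column
overrides the study-level value when present.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| nominal_p | 5×10⁻³ | every scanned trait must beat this at the sentinel |
| gw_p | 5×10⁻⁸ | no single trait may beat this (novelty vs single-trait GWAS); also the discovery threshold for sentinels |
| locus window | 1 Mb | distance rule for locus membership and independent-locus merging |
| locus r² | 0.2 | LD rule for locus membership and catalog screening |
| novelty radius | 500 kb | proximity rule against the known-association catalog |
| coloc window | 500 kb | ±250 kb around the sentinel for colocalization |
| resampling | S=10⁴ sets × M=10⁶ draws, 95th percentile | experiment-wide threshold (tests use scaled-down sizes) |
| pairwise priors | p1=p2=10⁻⁴, p12=10⁻⁵ | per-variant causal-configuration priors |
| trivariate priors | 10⁻⁴/10⁻⁶/10⁻⁷ | per-variant priors for a variant causal for 1/2/3 traits |
| prior SD | 0.15 (quantitative), 0.2 (log-odds) | Wakefield effect-scale prior |
| verdict bands | ≥0.8 / 0.5–0.8 | colocalized / borderline on PP4/(PP3+PP4) |
| secondary signal | p < 10⁻⁵ and r² < 0.1 | automated trigger for the conditional rescue |

All inequalities are strict exactly as conventionally quoted (p < 5×10⁻³,
p > 5×10⁻⁸, r² > 0.2). The HLA exclusion uses the extended-MHC bounds
chr6:25–34 Mb (GRCh37) unless a BED interval is supplied.

## Numerical choices

* Normal tails via `scipy.stats.norm.sf`, so large |z| keep full relative
  accuracy; two-sided convention throughout (the "most extreme Z" in the
  resampling is max |Z|).
* The resampling quantile uses linear interpolation between order
  statistics; any convention differs by less than Monte-Carlo noise, but
  one must be fixed for determinism. Sampling is chunked (bounded memory)
  and the chunking provably does not alter the drawn stream.
* Correlation matrices are repaired to the nearest positive semi-definite
  correlation by eigenvalue clipping and diagonal rescaling; MVN sampling
  uses an eigendecomposition factor so singular (perfectly correlated)
  matrices are valid.
* All colocalization hypothesis sums are computed with log-sum-exp,
  including the signed inclusion–exclusion terms for distinct-variant
  configurations (Σ_{i≠j} and Σ_{i≠j≠k}); |z| up to 40 is safe. A
  mathematically non-negative term that rounds negative is treated as
  log(0).
* Sentinel ties at equal p_multi break on (chromosome, position);
  single-linkage merging collapses identical sentinel IDs first, then
  chains sentinels within 1 Mb along each chromosome.
* Strand-ambiguous variants (A/T, C/G) are always dropped at
  harmonization rather than frequency-resolved: conservative, and avoids
  silent sign errors. The variant key is (chromosome, position, unordered
  allele pair); rsIDs are labels only.
* When z and p are both present but inconsistent beyond 0.1% relative,
  z wins and p is recomputed (logged).

## The synthetic generator

`pleioscan.simulate` emulates the structure the analysis assumes: AR(1) LD
blocks (rho^|i−j| within a block, independence across blocks), separable
(Kronecker) noise covariance of LD × cross-trait null correlation, planted
per-trait non-centralities at causal variants smeared over neighbors by
LD, MAF uniform on (0.05, 0.5), and β/se back-filled from z via
se = 1/√(2·N·MAF·(1−MAF)). Case-control traits are simulated on the z
scale with effective-N back-fill; there is no liability-scale modelling,
no MAF–LD coupling, and no realistic human LD map. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to real-data pathologies such as unmodelled
stratification, mis-specified LD reference panels or variant-level QC
artifacts.

## Validation design and problem sizes

* The resampling threshold is checked against the Šidák closed form
  1 − 0.95^(1/(M·K)) at M=10⁴, S=2000. A single run's 95th-percentile
  estimate carries roughly 10% Monte-Carlo noise on the p scale, so the
  check compares the *median* over independent same-sized replicates
  (11 at K=1, 9 at K=15), which estimates the same quantity with ~3×
  smaller noise while leaving the experiment's size and quantile
  definition untouched.
* The family-wise error calibration study simulates LD-free null genomes
  (rho = 0, 3000 variants, three traits, three scans, 400 replicates).
  With LD the resampled threshold is conservative by construction —
  resampling models independent variants — so an LD-free genome is the
  condition under which the 5% target is the correct expectation rather
  than an upper bound.
* The planted-locus recovery study uses three shared PAD+CAD loci, one
  PAD-only and one CAD-only locus, and one catalog-known shared locus, on
  2400-variant panels (60 blocks, rho 0.6), 100 panels per run. These
  sizes keep the whole suite and the reproduction script within a few
  minutes on one CPU.

## Known limitations

* The novelty cascade requires every single-trait p at the sentinel to lie
  strictly inside (5×10⁻⁸, 5×10⁻³), i.e. |z| inside a window only ~2.6
  standard deviations wide. Since a summary-statistic z carries unit
  noise, even a locus whose true per-trait non-centrality sits exactly at
  the window's center passes with probability ≈0.81 per trait; a strong
  shared signal (non-centrality 5.5) passes with probability ≈0.48 per
  trait because it frequently crosses single-trait genome-wide
  significance. Exact recovery of *all* planted pleiotropic loci in one
  run is therefore intrinsically improbable, and the recovery study
  reports the honest rate rather than a tuned one. This is a property of
  the filter definition itself, worth keeping in mind when interpreting
  "novel pleiotropic" counts on real data too: the filter trades
  sensitivity near both boundaries for a clean novelty claim.
* The trivariate conditional probability of colocalization is defined
  here as P(all three traits share one causal variant) / P(every trait
  has an associated variant) — the natural three-trait analogue of
  PP4/(PP3+PP4); other conventions (e.g. pairwise within the triple)
  exist.
* Direction-of-effect concordance between GWAS and QTL signals is
  computed on signs only; effect magnitudes across studies are not placed
  on a common scale.
* No multi-signal (SuSiE-style) colocalization and no fine-mapping
  credible sets; the conditional rescue handles one secondary signal per
  window.
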