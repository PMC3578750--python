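# Methods

This note documents the statistical models implemented in `replitime`,
the defaults and conventions chosen where more than one reasonable option
exists, what the synthetic-data generator does and does not emulate, and
the package's known limitations.

## Promoter construction

Coordinates are 0-based, half-open (BED convention) throughout.

- **Unique TSS.** A TSS is kept iff no other annotated TSS on the same
  chromosome lies within 1000 bp (a 2 kb window centered on the TSS). The
  boundary is inclusive: a neighbor at exactly 1000 bp disqualifies both.
  Two transcripts annotated at the same base disqualify each other. The
  filter is idempotent and independent of input row order; output order is
  (chrom, position, gene id).
- **Promoter window.** `[tss − 500, tss + 500)` regardless of strand
  (strand only determines which transcript coordinate is the TSS). A TSS
  closer than 500 bp to the chromosome start would leave the coordinate
  space; such promoters are skipped with a warning rather than truncated,
  so every window has exactly 1000 bp.
- **Timing summary.** The median value of probes mapping *entirely* within
  the window (partial overlaps excluded; non-finite probe values dropped
  before counting). An even probe count averages the two central values.
  Promoters with fewer than `min_probes = 10` contained probes are flagged
  discarded and excluded from all downstream sets; the cutoff trades
  genome coverage for robustness of the median.

## Mixture model and enrichment calls

Probe-level M-values are modelled genome-wide as
`pi1 N(mu1, sigma1^2) + pi2 N(mu2, sigma2^2)` and fitted by EM.

- **Initialization.** Deterministic start at the 25th/75th percentiles of
  the data with pooled standard deviation and equal weights, plus two
  seeded random restarts (means drawn from the data); the best
  log-likelihood wins. In practice the deterministic start dominates; the
  restarts guard against rare saddle behavior.
- **Convergence.** `|Δ log-likelihood| < 1e-8` or 500 iterations. The
  per-iteration log-likelihood path is retained and is non-decreasing (EM
  guarantee; validated to 1e-9 slack).
- **Variance floor** of 1e-6 (signal units squared) prevents a component
  from collapsing onto a single point.
- **Label convention.** Components are relabeled after fitting so the
  enriched component has the larger mean; enrichment means higher
  M-values.
- **Posteriors and MAP.** Responsibilities are computed in log space (a
  stable logistic of the log-density difference); they sum to 1 to 1e-12.
  A probe exactly on the decision boundary (p2 = 0.5) goes to the
  background class — ties break conservatively.
- **Promoter rule.** Enriched iff ≥ 80% of the probes entirely contained
  in the window (the same containment rule used for timing) are
  MAP-assigned to the enriched class; a promoter with zero contained
  probes is never enriched. The rule is monotone in its threshold.
- **Separation guard.** The genome-wide caller checks Ashman's
  `D = |mu2 − mu1| / sqrt((sigma1^2 + sigma2^2)/2)` of the fitted
  components. When `D < 2` the fit is effectively unimodal — there is no
  distinct enriched population, and MAP classes would merely split one
  Gaussian around an arbitrary crossing point — so no probe is assigned to
  the enriched class and a warning is emitted. `D = 2` is the classical
  bimodality boundary for a two-Gaussian mixture. The guard can be
  disabled (`min_separation = 0`); the per-promoter rule itself is
  untouched.
- The mixture is fitted genome-wide on the (assumed pre-smoothed) track;
  an optional running-mean smoother is provided for raw tracks. Fitting
  per chromosome can be achieved by subsetting the track, but is not a
  separate mode.

Joint binding across features (e.g. PRC1 from PC, Ph, Psc calls) is a
logical AND over boolean per-feature columns.

## Activity classes

Class 0 holds promoters with expression ≤ `zero_threshold` (default
exactly 0; raise it for noisy expression estimates). Transcribed promoters
get `class = ceil(4 · rank / n)` over the transcribed subset, so classes
1–4 are expression quartiles balanced to within one promoter when values
are distinct. Ranks use the minimum-rank convention for ties, so a tie
group spanning a quartile boundary takes the lower class. Classification
is rank-based and therefore invariant under strictly monotone transforms
of expression. OFF = classes 0–1, ON = classes 2–4.

## Bootstrap, weighted bootstrap, rank-sum test

- **Percentile CI.** `B = 10^4` resamples of size n with replacement; the
  interval is the (α, 1−α) pair of empirical quantiles of the resample
  means with linear interpolation between order statistics. α = 0.025 is
  *per tail*, i.e. the default interval is 95%.
- **Importance weights.** With k represented ON/OFF classes, a promoter in
  a class of size m is drawn with probability `1/(k·m)`: weights sum to 1
  and each class carries equal total weight. Class sizes are taken within
  the group being resampled (within-group equalization); explicit weights
  can be passed instead to equalize against a pooled reference
  composition.
- **Sampling path.** Both bootstrap variants draw indices by inverse-CDF
  sampling of the cumulative weight vector, so the unweighted bootstrap is
  exactly the weighted bootstrap with uniform weights and the two are
  stream-identical under the same seed. One root seed per comparison
  spawns independent per-group streams via `numpy.random.SeedSequence`;
  seeds are recorded in the output.
- **Wilcoxon rank-sum.** Two-sided; delegated to
  `scipy.stats.mannwhitneyu` — exact when the pooled sample has ≤ 12
  untied observations, otherwise the normal approximation with tie and
  continuity correction. An independent full-enumeration implementation
  lives in the package (`exact_ranksum_p`) and serves as the oracle in the
  test suite. Raw p-values are reported; no multiple-testing correction is
  applied because comparisons are few and pre-specified.

## Locus-level qPCR and 3C

- Replicate Ct values are averaged arithmetically *before*
  exponentiation, then `abundance_i = E^-(Ct_i − Ctmit_i)` per fraction
  with amplification efficiency E = 2 by default (exposed as a
  parameter). Percent-of-total normalizes across the assayed fractions.
  The mitochondrial reference is matched per fraction (with the same
  fraction labels); the early/late ratio uses the same ΔCt construction
  in two fractions.
- 3C crosslinking frequency is a two-step convention: within-sample
  normalization to an internal control region
  (`2^-(Ct_product − Ct_control region)`), then a ratio to the control
  sample. Frequencies are invariant to adding a constant to all Cts of a
  sample.

## Synthetic-data generator

The generator emulates the *statistical* structure the analysis assumes,
not the physics of arrays or sequencing:

- A genome (default 20 Mb over two chromosomes) tiled by 25 bp probes
  every 36 bp, with non-overlapping enriched domains (exponential lengths,
  mean 10 kb, floored at 2 kb) covering an exact target fraction (default
  30%) of each chromosome.
- ChIP M-values drawn from N(0, 1) over background and N(3, 0.5) over
  domains — a cleanly separated mixture (Ashman's D ≈ 3.8) so recovery is
  a test of correctness rather than of identifiability.
- A timing track in a larger-is-earlier convention (sign configurable):
  flat baseline, minus `timing_shift_delta = 0.5` over enriched domains,
  plus i.i.d. N(0, 0.5) probe noise. The shift equals one probe-noise
  standard deviation. **No spatial autocorrelation by default**: an
  optional sinusoidal baseline (`timing_baseline_amplitude`, period
  2 Mb) and a moving-average noise smoother are available to emulate the
  smoothness of real timing tracks, but they make nearby promoters
  correlated, which visibly inflates the type-I error of rank-based group
  comparisons when groups are defined by spatial domains (observed ~9%
  at nominal 5% with amplitude 1.0). That inflation is a property of real
  spatially structured genomes too — a caveat for interpreting the
  pipeline's p-values on real data, where promoters are not exchangeable.
- 2,000 genes placed uniformly (1 kb margins), with 5% of genes arranged
  in sub-1 kb pairs so the uniqueness filter is always exercised; at this
  density random proximity removes additional TSSs, as in real annotations.
- Expression is log-normal with a point mass at zero: background genes
  `p0 = 0.2, LN(1, 1)`; enriched genes `p0 = 0.7, LN(0, 1)` — enriched
  promoters are mostly silent or lowly expressed, mirroring repressive
  chromatin, while leaving both ON and OFF promoters in both groups so
  the weighted bootstrap has composition to equalize.
- qPCR tables use canonical per-class abundance profiles across S-phase
  fractions (e.g. late = 7/13/25/55% across f1–f4; two-fraction variants
  75/25 and 25/75), converted to Ct values around a constant mitochondrial
  reference (Ct 20), with N(0, noise) replicate noise on the target and a
  third of that on the reference; 6 replicates by default for BrdU-IP
  timing and 4 for 3C. 3C tables are constructed so the within-sample
  frequency equals `base_frequency × interaction_strength` exactly when
  noiseless.

Everything is driven by one `numpy.random.default_rng(seed)`; a fixed
seed gives byte-identical output.

What passing tests therefore show: the estimators and decision rules are
correct on data satisfying their assumptions (independent promoters,
Gaussian mixture signal, known ground truth). What they do not show:
robustness to spatial autocorrelation, to non-Gaussian signal tails, to
annotation errors, or to array-specific artifacts in real data.

## Validation problem sizes

The test suite validates mixture recovery on 50,000 draws (tolerances
0.05 on means and weights, 0.1 on standard deviations), EM monotonicity on
100 random datasets, bootstrap coverage on 1,000 simulated N(0, 1) samples
of n = 100 at resampling depth 2,000 (depth is reduced from the 10^4
default because coverage depends on the quantiles, not the depth, and
1,000 × 10^4 resamples adds nothing but runtime), full-pipeline shift
recovery at the default 2,000-gene scale, and null calibration over 200
replicates of a 2 Mb, 200-gene genome with zero timing shift. Locus-assay
recovery uses 1,000 simulated Ct tables at 0.3 cycles of noise.

## Limitations

- Two components only; broad "weak enrichment" populations would be
  absorbed into whichever component is nearer, and no HMM-style spatial
  segmentation is attempted.
- The separation guard makes genome-wide calls conservative on nearly
  unimodal tracks; per-promoter calls via the low-level API are not
  guarded.
- Wilcoxon p-values and bootstrap CIs treat promoters as independent;
  on spatially structured data they are anti-conservative (see above).
- ChIP-seq-derived binding calls (e.g. for PRC1 components) are consumed
  as boolean inputs; no peak calling is implemented.
- qPCR quantification assumes a fixed amplification efficiency per run
  and no primer-specific calibration.
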