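# replitime

Genome-wide analysis of the relationship between Polycomb-type chromatin
enrichment at promoters and DNA replication timing, with the locus-level
qPCR quantifications used to validate timing calls at individual loci.

Repressed chromatin — marked, for example, by H3K27me3 and bound by
Polycomb-group complexes (PRC1, PRC2, PhoRC) — tends to replicate late in
S phase. Testing that association genome-wide requires a chain of careful
statistics: defining promoters free of neighbor interference, deciding
which promoters are *significantly* enriched for a chromatin feature given
noisy tiling-array signal, and comparing replication-timing distributions
between promoter groups while controlling for their different
transcriptional activity. `replitime` implements that chain as a tested,
scriptable pipeline for computational epigenomics work, together with a
synthetic-genome generator carrying ground-truth labels so every stage can
be validated end to end.

## What it computes

**Promoter construction.** A TSS is *unique* if no other TSS lies within a
2 kb window centered on it; the promoter is the 1 kb window centered on a
unique TSS. Promoter replication timing is the median timing score of the
probes mapping entirely within the window; promoters with fewer than 10
such probes are discarded.

**Enrichment calling.** Genome-wide smoothed M-values $X$ are modelled as a
two-component Gaussian mixture

$$f(x) = \pi_1\, \mathcal{N}(x;\mu_1,\sigma_1^2) + \pi_2\, \mathcal{N}(x;\mu_2,\sigma_2^2),$$

with $\mathcal{N}_1$ the background and $\mathcal{N}_2$ the enriched
component ($\mu_2 > \mu_1$). Parameters are estimated by EM; each probe
gets the posterior responsibility

$$p_2(x) = \frac{\pi_2 \mathcal{N}(x;\mu_2,\sigma_2^2)}{\pi_1 \mathcal{N}(x;\mu_1,\sigma_1^2) + \pi_2 \mathcal{N}(x;\mu_2,\sigma_2^2)}$$

and a MAP class. A promoter is called significantly enriched when at least
80% of its contained probes are MAP-assigned to the enriched class — a
deliberately conservative rule. Boolean per-factor calls combine into
joint binding (e.g. PRC1 = PC ∧ Ph ∧ Psc).

**Activity classes.** Promoters with zero expression form class 0;
transcribed promoters are split into expression quartiles (classes 1–4).
Classes 0–1 are OFF, classes 2–4 are ON.

**Group comparisons.** For two promoter groups the pipeline reports
five-number summaries, a two-sided Wilcoxon rank-sum p-value, and
percentile bootstrap confidence intervals of the mean timing (resampling
depth $10^4$, interval endpoints at the $\alpha$ and $1-\alpha$ empirical
quantiles, $\alpha = 0.025$ per tail). The *weighted* bootstrap resamples
promoter $i$ with probability inversely proportional to the size of its
ON/OFF class, so both classes contribute equal total weight — asking
whether a timing difference survives equalizing transcriptional
composition.

**Locus assays.** From qPCR threshold-cycle tables: per-fraction BrdU-IP
abundance $2^{-(Ct_i - Ct_{mit,i})}$ (normalized to a mitochondrial
internal control), the early/late ratio
$2^{-(Ct_{early}-Ct_{mit})} / 2^{-(Ct_{late}-Ct_{mit})}$, and 3C
crosslinking frequencies $2^{-(Ct_{product} - Ct_{control\ region})}$
expressed relative to a control sample.

## Worked example

```python
from replitime import RunConfig, run_genomewide_analysis

report = run_genomewide_analysis(RunConfig(seed=1))
c = report["counts"]
print(f"unique TSSs: {c['unique_tss']} / {c['tss_in']}")
print(f"enriched promoters: {c['enriched']}")
g = report["gmm"]
print(f"mixture: pi2={g['pi2']:.3f} mu=({g['mu1']:.3f}, {g['mu2']:.3f})")
comp = report["comparison"]
for label, b in comp["bootstrap"].items():
    print(f"{label}: mean {b['mean_estimate']:.3f} "
          f"95% CI [{b['ci_low']:.3f}, {b['ci_high']:.3f}]")
print(f"wilcoxon p = {comp['wilcoxon_p']:.3g}; CI overlap: {comp['ci_overlap']}")
```

prints

```
unique TSSs: 1539 / 2000
enriched promoters: 413
mixture: pi2=0.300 mu=(-0.002, 3.000)
enriched: mean -0.490 95% CI [-0.501, -0.478]
non-enriched: mean -0.022 95% CI [-0.031, -0.014]
wilcoxon p = 2.48e-189; CI overlap: False
```

The simulated genome places 30% of its sequence in enriched domains whose
M-values come from N(3, 0.5) against an N(0, 1) background, and delays
their replication by 0.5 timing-score units (larger score = earlier
replication). The run recovers the mixture (weight 0.300, means −0.002 and
3.000), and the enriched promoter group replicates later by ≈ 0.47 units
with clearly separated 95% bootstrap intervals — the qualitative behavior
expected when repressive chromatin delays replication. 461 of 2,000 TSSs
were dropped by the 2 kb uniqueness filter (clustered genes plus random
proximity).

The same stages are available as a CLI (`replitime simulate | promoters |
call-enrichment | classify-activity | compare | qpcr-timing | c3 |
run-all`); each subcommand reads and writes plain BED/bedGraph/TSV/JSON so
stages can be run and inspected independently.

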