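"""Synthetic genomes with ground truth for the replication-timing analysis.

The generator emulates the statistical structure that the genome-wide
analysis assumes: a tiling-array ChIP track whose probe-level M-values are a
mixture of two Gaussians (background vs. enriched domains), a smooth
replication-timing track that is shifted *later* over enriched domains, an
expression table in which enriched promoters tend to be lowly expressed or
silent, and qPCR threshold-cycle (Ct) tables for the locus-level BrdU-IP
replication-timing and 3C assays.  Every gene carries a ground-truth label so
each downstream stage can be validated without external data.

Timing-score convention: larger values mean *earlier* replication (an
early/late log-ratio style score), so enriched (repressed) domains have their
timing lowered by ``timing_shift_delta``.  Setting
``earlier_is_larger=False`` flips the sign.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .errors import InvalidConfigError

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "simulate_qpcr_ct",
    "simulate_3c_ct",
    "QPCR_ABUNDANCE_PROFILES",
]


def _default_expression_model() -> dict:
    # Log-normal expression; enriched (repressed) promoters are mostly
    # silent and otherwise draw from a lower-mean component.
    return {
        "background": {"p_zero": 0.2, "meanlog": 1.0, "sdlog": 1.0},
        "enriched": {"p_zero": 0.7, "meanlog": 0.0, "sdlog": 1.0},
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic genome.

    Defaults emulate a fly-sized tiling-array experiment at desk scale:
    a 20 Mb genome over two chromosomes, 2,000 genes, 36 bp probe spacing
    (25 bp probes), 30% of the genome in enriched domains with mean length
    10 kb, M-value mixture N(0,1) vs. N(3,0.5), and a timing shift equal to
    one probe-level noise standard deviation.

    Timing noise is i.i.d. Gaussian per probe with no spatial
    autocorrelation by default: the baseline is flat
    (``timing_baseline_amplitude = 0``) and the moving-average smoother is
    off (``timing_smooth_window = 1``).  Real timing tracks are spatially
    smooth; set a positive baseline amplitude (sinusoid with
    ``timing_baseline_period``) and/or a smoothing window to emulate that,
    at the cost of promoters no longer being exchangeable under the null
    (neighboring promoters then share baseline timing).
    """

    genome_length: int = 20_000_000
    n_chromosomes: int = 2
    n_genes: int = 2000
    probe_spacing: int = 36
    probe_length: int = 25
    frac_enriched_domains: float = 0.3
    mix_background: tuple[float, float] = (0.0, 1.0)
    mix_enriched: tuple[float, float] = (3.0, 0.5)
    timing_shift_delta: float = 0.5
    timing_noise_sd: float = 0.5
    timing_baseline_amplitude: float = 0.0
    timing_baseline_period: float = 2_000_000.0
    timing_smooth_window: int = 1
    earlier_is_larger: bool = True
    domain_length_mean: float = 10_000.0
    min_domain_length: float = 2_000.0
    clustered_pair_frac: float = 0.05
    expression_model: dict = field(default_factory=_default_expression_model)
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise InvalidConfigError("genome_length must be positive")
        if self.n_genes <= 0:
            raise InvalidConfigError("n_genes must be positive")
        if self.n_chromosomes <= 0:
            raise InvalidConfigError("n_chromosomes must be positive")
        if self.probe_spacing < 1:
            raise InvalidConfigError("probe_spacing must be >= 1")
        if not 0.0 <= self.frac_enriched_domains <= 1.0:
            raise InvalidConfigError("frac_enriched_domains must be in [0, 1]")
        for name, (_, sd) in (
            ("mix_background", self.mix_background),
            ("mix_enriched", self.mix_enriched),
        ):
            if sd <= 0:
                raise InvalidConfigError(f"{name} sd must be > 0")
        if self.timing_noise_sd <= 0:
            raise InvalidConfigError("timing_noise_sd must be > 0")
        if not 0.0 <= self.clustered_pair_frac <= 1.0:
            raise InvalidConfigError("clustered_pair_frac must be in [0, 1]")
        if self.timing_smooth_window < 1:
            raise InvalidConfigError("timing_smooth_window must be >= 1")


@dataclass
class SyntheticDataset:
    """A simulated genome with ground-truth labels.

    Attributes
    ----------
    annotation : DataFrame (gene_id, chrom, strand, tss)
    chip_track : DataFrame (chrom, start, end, value) — probe M-values
    timing_track : DataFrame (chrom, start, end, value) — timing scores
    expression : DataFrame (gene_id, expression)
    truth : DataFrame (promoter_id, enriched, timing_class)
    domains : DataFrame (chrom, start, end) — the enriched intervals
    """

    annotation: pd.DataFrame
    chip_track: pd.DataFrame
    timing_track: pd.DataFrame
    expression: pd.DataFrame
    truth: pd.DataFrame
    domains: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all components as plain-text files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.bed",
            "chip_track": outdir / "chip.bedGraph",
            "timing_track": outdir / "timing.bedGraph",
            "expression": outdir / "expression.tsv",
            "truth": outdir / "truth.tsv",
            "domains": outdir / "domains.tsv",
        }
        rio.write_annotation_bed6(self.annotation, paths["annotation"])
        rio.write_bedgraph(self.chip_track, paths["chip_track"])
        rio.write_bedgraph(self.timing_track, paths["timing_track"])
        rio.write_table(self.expression, paths["expression"])
        rio.write_table(self.truth, paths["truth"])
        rio.write_table(self.domains, paths["domains"])
        return paths


def _chrom_lengths(config: SimulationConfig) -> dict[str, int]:
    base = config.genome_length // config.n_chromosomes
    lengths = {}
    for i in range(config.n_chromosomes):
        extra = config.genome_length % config.n_chromosomes if i == 0 else 0
        lengths[f"chr{i + 1}"] = base + extra
    return lengths


def _place_domains(
    rng: np.random.Generator, length: int, config: SimulationConfig
) -> np.ndarray:
    """Place non-overlapping enriched domains covering ~frac of a chromosome.

    Domain lengths are exponential with the configured mean (floored at
    ``min_domain_length``); the final domain is trimmed so that the total
    covered length matches the target exactly.
    """
    target = config.frac_enriched_domains * length
    if target <= 0:
        return np.empty((0, 2), dtype=np.int64)
    starts: list[int] = []
    ends: list[int] = []
    covered = 0.0
    attempts = 0
    max_attempts = 200_000
    while covered < target and attempts < max_attempts:
        attempts += 1
        dlen = max(
            config.min_domain_length, rng.exponential(config.domain_length_mean)
        )
        dlen = min(dlen, target - covered) if covered + dlen > target else dlen
        dlen = int(round(dlen))
        if dlen < 100:
            break
        s = int(rng.integers(0, max(1, length - dlen)))
        e = s + dlen
        # reject overlap with already placed domains
        overlap = any(s < pe and e > ps for ps, pe in zip(starts, ends))
        if overlap:
            continue
        starts.append(s)
        ends.append(e)
        covered += dlen
    order = np.argsort(starts)
    return np.column_stack(
        [np.asarray(starts)[order], np.asarray(ends)[order]]
    ).astype(np.int64)


def _in_domains(positions: np.ndarray, domains: np.ndarray) -> np.ndarray:
    """Boolean mask: is each position inside any [start, end) domain."""
    if len(domains) == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(domains[:, 0], positions, side="right") - 1
    inside = idx >= 0
    inside[inside] &= positions[inside] < domains[idx[inside], 1]
    return inside


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a genome, tracks, expression and truth labels.

    Deterministic: a fixed ``config.seed`` yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = _chrom_lengths(config)
    chroms = list(lengths)

    # --- enriched domains per chromosome ---
    domain_rows = []
    domains_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chroms:
        doms = _place_domains(rng, lengths[chrom], config)
        domains_by_chrom[chrom] = doms
        for s, e in doms:
            domain_rows.append((chrom, int(s), int(e)))
    domains = pd.DataFrame(domain_rows, columns=["chrom", "start", "end"])

    # --- probe tracks ---
    chip_parts, timing_parts = [], []
    mu_bg, sd_bg = config.mix_background
    mu_en, sd_en = config.mix_enriched
    sign = 1.0 if config.earlier_is_larger else -1.0
    for chrom in chroms:
        L = lengths[chrom]
        starts = np.arange(0, L - config.probe_length, config.probe_spacing)
        mid = starts + config.probe_length // 2
        enr = _in_domains(mid, domains_by_chrom[chrom])
        chip = rng.normal(mu_bg, sd_bg, size=len(starts))
        chip[enr] = rng.normal(mu_en, sd_en, size=int(enr.sum()))
        phase = rng.uniform(0, 2 * math.pi)
        baseline = config.timing_baseline_amplitude * np.sin(
            2 * math.pi * mid / config.timing_baseline_period + phase
        )
        noise = rng.normal(0.0, config.timing_noise_sd, size=len(starts))
        if config.timing_smooth_window > 1:
            w = config.timing_smooth_window
            kernel = np.ones(w) / w
            noise = np.convolve(noise, kernel, mode="same")
        timing = baseline - sign * config.timing_shift_delta * enr + noise
        frame = {
            "chrom": chrom,
            "start": starts,
            "end": starts + config.probe_length,
        }
        chip_parts.append(pd.DataFrame({**frame, "value": chip}))
        timing_parts.append(pd.DataFrame({**frame, "value": timing}))
    chip_track = pd.concat(chip_parts, ignore_index=True)
    timing_track = pd.concat(timing_parts, ignore_index=True)

    # --- genes: uniform placement plus clustered pairs to exercise the
    # uniqueness filter (both members of a pair sit < 1 kb apart) ---
    n_pairs = int(round(config.clustered_pair_frac * config.n_genes / 2))
    n_base = config.n_genes - n_pairs
    chrom_lengths_arr = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(
        len(chroms), size=n_base, p=chrom_lengths_arr / chrom_lengths_arr.sum()
    )
    margin = 1000
    positions = np.array(
        [
            rng.integers(margin, lengths[chroms[ci]] - margin)
            for ci in chrom_idx
        ],
        dtype=np.int64,
    )
    pair_parents = rng.choice(n_base, size=n_pairs, replace=False) if n_pairs else []
    gene_chrom = [chroms[ci] for ci in chrom_idx]
    gene_pos = list(positions)
    for parent in pair_parents:
        offset = int(rng.integers(100, 1001)) * (1 if rng.random() < 0.5 else -1)
        pos = int(
            np.clip(positions[parent] + offset, margin,
                    lengths[gene_chrom[parent]] - margin)
        )
        gene_chrom.append(gene_chrom[parent])
        gene_pos.append(pos)
    strands = rng.choice(["+", "-"], size=len(gene_pos))
    annotation = pd.DataFrame(
        {
            "chrom": gene_chrom,
            "strand": strands,
            "tss": np.asarray(gene_pos, dtype=np.int64),
        }
    )
    annotation = annotation.sort_values(
        ["chrom", "tss"], kind="mergesort"
    ).reset_index(drop=True)
    annotation.insert(
        0, "gene_id", [f"g{i + 1:05d}" for i in range(len(annotation))]
    )

    # --- truth and expression ---
    enr_gene = np.zeros(len(annotation), dtype=bool)
    for chrom in chroms:
        mask = (annotation["chrom"] == chrom).to_numpy()
        enr_gene[mask] = _in_domains(
            annotation.loc[mask, "tss"].to_numpy(), domains_by_chrom[chrom]
        )
    truth = pd.DataFrame(
        {
            "promoter_id": annotation["gene_id"],
            "enriched": enr_gene,
            "timing_class": np.where(enr_gene, "late", "early"),
        }
    )
    model = config.expression_model
    expr = np.empty(len(annotation))
    for label, mask in (("enriched", enr_gene), ("background", ~enr_gene)):
        params = model[label]
        k = int(mask.sum())
        vals = rng.lognormal(params["meanlog"], params["sdlog"], size=k)
        zero = rng.random(k) < params["p_zero"]
        vals[zero] = 0.0
        expr[mask] = vals
    expression = pd.DataFrame(
        {"gene_id": annotation["gene_id"], "expression": expr}
    )

    return SyntheticDataset(
        annotation=annotation,
        chip_track=chip_track,
        timing_track=timing_track,
        expression=expression,
        truth=truth,
        domains=domains,
        config=dataclasses.replace(config),
    )


# Canonical relative-abundance profiles across S-phase fractions for each
# replication-timing class.  Rows sum to 1; the class's characteristic
# fraction carries the largest share of newly replicated DNA.
QPCR_ABUNDANCE_PROFILES: dict[int, dict[str, tuple[float, ...]]] = {
    4: {
        "early": (0.55, 0.25, 0.13, 0.07),
        "mid-early": (0.20, 0.45, 0.25, 0.10),
        "mid-late": (0.10, 0.25, 0.45, 0.20),
        "late": (0.07, 0.13, 0.25, 0.55),
    },
    2: {
        "early": (0.75, 0.25),
        "late": (0.25, 0.75),
    },
}

_FRACTION_NAMES = {4: ("f1", "f2", "f3", "f4"), 2: ("early", "late")}


def simulate_qpcr_ct(
    timing_class: str,
    n_fractions: int = 4,
    replicates: int = 6,
    noise_sd: float = 0.3,
    seed: int = 0,
    target: str = "locus",
    mit_ref: str = "mito",
    ct_mit: float = 20.0,
    sample: str = "control",
) -> pd.DataFrame:
    """Simulate a BrdU-IP qPCR Ct table for a locus of known timing class.

    The target Ct in fraction *i* is ``ct_mit - log2(p_i)`` plus replicate
    noise, where ``p_i`` is the class's canonical abundance share, so the
    fraction matching ``timing_class`` has the smallest target-minus-
    mitochondrial delta-Ct.  The mitochondrial reference is roughly constant
    across fractions (noise at a third of ``noise_sd``).
    """
    if n_fractions not in QPCR_ABUNDANCE_PROFILES:
        raise InvalidConfigError("n_fractions must be 2 or 4")
    if replicates < 1:
        raise InvalidConfigError("replicates must be >= 1")
    profiles = QPCR_ABUNDANCE_PROFILES[n_fractions]
    if timing_class not in profiles:
        raise InvalidConfigError(
            f"unknown timing_class {timing_class!r}; "
            f"expected one of {sorted(profiles)}"
        )
    rng = np.random.default_rng(seed)
    fractions = _FRACTION_NAMES[n_fractions]
    rows = []
    for frac, p in zip(fractions, profiles[timing_class]):
        delta_ct = -math.log2(p)
        for rep in range(1, replicates + 1):
            rows.append(
                (
                    sample,
                    target,
                    frac,
                    rep,
                    ct_mit + delta_ct + rng.normal(0.0, noise_sd),
                )
            )
            rows.append(
                (
                    sample,
                    mit_ref,
                    frac,
                    rep,
                    ct_mit + rng.normal(0.0, noise_sd / 3.0),
                )
            )
    return pd.DataFrame(rows, columns=rio.CT_COLUMNS)


def simulate_3c_ct(
    interaction_strength: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    replicates: int = 4,
    sample: str = "test",
    anchor: str = "anchor",
    target_fragment: str = "PRE",
    control_region: str = "int2",
    base_frequency: float = 0.1,
    ct_control: float = 24.0,
) -> pd.DataFrame:
    """Simulate a 3C qPCR Ct table for one anchor/target ligation product.

    The ligation-product Ct is set so that the within-sample crosslinking
    frequency ``2^-(Ct_product - Ct_control_region)`` equals
    ``base_frequency * interaction_strength``: stronger interactions give
    more product, hence lower Ct.  The internal-control region is measured
    for every replicate.  Noiseless by default so closed-form relations hold
    exactly.
    """
    if not 0.0 < interaction_strength <= 1.0:
        raise InvalidConfigError("interaction_strength must be in (0, 1]")
    if replicates < 1:
        raise InvalidConfigError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    product = f"{anchor}:{target_fragment}"
    ct_product = ct_control - math.log2(base_frequency * interaction_strength)
    rows = []
    for rep in range(1, replicates + 1):
        rows.append(
            (sample, product, "na", rep, ct_product + rng.normal(0, noise_sd))
        )
        rows.append(
            (
                sample,
                control_region,
                "na",
                rep,
                ct_control + rng.normal(0, noise_sd),
            )
        )
    return pd.DataFrame(rows, columns=rio.CT_COLUMNS)
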