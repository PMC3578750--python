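"""Locus-level qPCR quantification for replication timing and 3C.

BrdU-IP replication timing: the relative abundance of a locus in S-phase
fraction i is ``2^-(Ct_i - Ctmit_i)``, where Ct values are first averaged
arithmetically over replicates and Ctmit is the threshold cycle of a
mitochondrial reference sequence measured in the same fraction (mitochondrial
DNA replicates throughout the cell cycle, so it serves as an internal
control).  Per-target abundances are also reported as the percent of their
total across the assayed fractions.  The early/late ratio
``2^-(CtEarly - Ctmit,early) / 2^-(CtLate - Ctmit,late)`` exceeds 1 for
early-replicating loci.

3C: within a sample, the crosslinking frequency of a ligation product is
``2^-(Ct_product - Ct_control_region)`` (normalization to an internal
control region); frequencies are then expressed relative to a control
sample (e.g. mock-depleted cells).

The amplification efficiency per cycle defaults to 2 (perfect doubling)
and is exposed as a parameter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import MissingMeasurementError

__all__ = ["fraction_abundance", "early_late_ratio", "crosslink_frequency"]


def _mean_ct(
    ct_table: pd.DataFrame, target: str, sample: str | None
) -> pd.Series:
    """Replicate-averaged Ct per fraction for one target (one sample)."""
    rows = ct_table[ct_table["target"] == target]
    if sample is not None:
        rows = rows[rows["sample"] == sample]
    if rows.empty:
        raise MissingMeasurementError(
            f"no Ct measurements for target {target!r}"
            + (f" in sample {sample!r}" if sample else "")
        )
    return rows.groupby("fraction")["ct"].mean()


def _single_sample(ct_table: pd.DataFrame, sample: str | None) -> str:
    if sample is not None:
        return sample
    samples = ct_table["sample"].unique()
    if len(samples) != 1:
        raise ValueError(
            f"table holds {len(samples)} samples; pass sample= explicitly"
        )
    return samples[0]


def fraction_abundance(
    ct_table: pd.DataFrame,
    target: str,
    mit_ref: str = "mito",
    sample: str | None = None,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative abundance of a locus in each S-phase fraction.

    Returns a DataFrame (sample, target, fraction, abundance,
    percent_of_total) with one row per assayed fraction, where abundance is
    ``efficiency^-(Ct_i - Ctmit_i)`` on replicate-averaged Ct values and
    percent_of_total normalizes across fractions to sum to 1.

    Raises :class:`MissingMeasurementError` when the mitochondrial
    reference is absent from a fraction in which the target was measured.
    """
    sample = _single_sample(ct_table, sample)
    ct_target = _mean_ct(ct_table, target, sample)
    ct_mit = _mean_ct(ct_table, mit_ref, sample)
    missing = [f for f in ct_target.index if f not in ct_mit.index]
    if missing:
        raise MissingMeasurementError(
            f"mitochondrial reference {mit_ref!r} not measured in "
            f"fraction(s) {missing}"
        )
    delta = ct_target - ct_mit.reindex(ct_target.index)
    abundance = np.power(float(efficiency), -delta)
    out = pd.DataFrame(
        {
            "sample": sample,
            "target": target,
            "fraction": ct_target.index,
            "abundance": abundance.to_numpy(),
        }
    )
    out["percent_of_total"] = out["abundance"] / out["abundance"].sum()
    return out.reset_index(drop=True)


def early_late_ratio(
    ct_table: pd.DataFrame,
    target: str,
    mit_ref: str = "mito",
    early_fraction: str = "early",
    late_fraction: str = "late",
    sample: str | None = None,
    efficiency: float = 2.0,
) -> float:
    """Early/late replication ratio of a locus.

    ``efficiency^-(CtEarly - Ctmit,early) / efficiency^-(CtLate -
    Ctmit,late)``; values above 1 indicate earlier replication.  For
    four-fraction tables pass ``early_fraction='f1', late_fraction='f4'``.
    """
    sample = _single_sample(ct_table, sample)
    ct_target = _mean_ct(ct_table, target, sample)
    ct_mit = _mean_ct(ct_table, mit_ref, sample)
    for frac in (early_fraction, late_fraction):
        if frac not in ct_target.index:
            raise MissingMeasurementError(
                f"target {target!r} not measured in fraction {frac!r}"
            )
        if frac not in ct_mit.index:
            raise MissingMeasurementError(
                f"reference {mit_ref!r} not measured in fraction {frac!r}"
            )
    d_early = ct_target[early_fraction] - ct_mit[early_fraction]
    d_late = ct_target[late_fraction] - ct_mit[late_fraction]
    eff = float(efficiency)
    return float(eff ** (-d_early) / eff ** (-d_late))


def crosslink_frequency(
    ct_table: pd.DataFrame,
    anchor: str,
    target_fragment: str,
    control_region: str,
    control_sample: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Normalized 3C crosslinking frequencies for one anchor/target pair.

    The ligation product is the target named ``"{anchor}:{target_fragment}"``.
    Within each sample, frequency = ``efficiency^-(Ct_product -
    Ct_control_region)`` on replicate-averaged Cts; ``relative_to_control``
    divides by the control sample's frequency.  Returns one row per sample
    (sample, anchor, target_fragment, frequency, relative_to_control).
    """
    product = f"{anchor}:{target_fragment}"
    eff = float(efficiency)
    samples = list(ct_table["sample"].unique())
    if control_sample not in samples:
        raise MissingMeasurementError(
            f"control sample {control_sample!r} not present"
        )
    freqs = {}
    for sample in samples:
        sub = ct_table[ct_table["sample"] == sample]
        ct_prod = sub[sub["target"] == product]["ct"]
        ct_ctrl = sub[sub["target"] == control_region]["ct"]
        if ct_prod.empty:
            raise MissingMeasurementError(
                f"ligation product {product!r} not measured in sample "
                f"{sample!r}"
            )
        if ct_ctrl.empty:
            raise MissingMeasurementError(
                f"control region {control_region!r} not measured in sample "
                f"{sample!r}"
            )
        freqs[sample] = eff ** -(ct_prod.mean() - ct_ctrl.mean())
    control_freq = freqs[control_sample]
    return pd.DataFrame(
        {
            "sample": samples,
            "anchor": anchor,
            "target_fragment": target_fragment,
            "frequency": [freqs[s] for s in samples],
            "relative_to_control": [freqs[s] / control_freq for s in samples],
        }
    )
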