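"""Two-genotype droplet digital PCR quantification.

The assay partitions template molecules into ~20,000 droplets and reads two
competing hydrolysis probes: FAM reports the unedited allele, HEX the edited
one. Under Poisson loading the mean copies per partition for a channel is
recovered from its negative-droplet fraction, lambda = -ln(n_neg / n_total),
and the edited fraction is lambda_HEX / (lambda_FAM + lambda_HEX). Channels
are treated independently: each genotype loads its own Poisson stream, so
double-positive droplets need no special handling.

The 95% confidence interval uses the delta method on the log negative
fraction of each channel, Var(lambda_hat) ~= (1 - p) / (n * p) with
p = n_neg / n_total, propagated to the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

_Z95 = 1.959963984540054


class SaturationError(ValueError):
    """All droplets positive: lambda is unbounded above."""


@dataclass(frozen=True)
class DropletCounts:
    """Positive-droplet counts for one two-channel reaction."""

    n_total: int
    n_pos_fam: int
    n_pos_hex: int
    partition_volume_ul: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        for name, n in (("n_pos_fam", self.n_pos_fam), ("n_pos_hex", self.n_pos_hex)):
            if not 0 <= n <= self.n_total:
                raise ValueError(f"{name}={n} outside [0, n_total]")


@dataclass(frozen=True)
class GenotypeQuant:
    """Mean copies/partition per genotype and the edited-fraction estimate."""

    lambda_fam: float
    lambda_hex: float
    edited_fraction: float
    ci95: tuple[float, float]
    copies_per_ul_fam: Optional[float] = None
    copies_per_ul_hex: Optional[float] = None


def lambda_from_droplets(n_neg: int, n_total: int) -> float:
    """Poisson-corrected mean copies per partition from negative droplets."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_neg > n_total:
        raise ValueError(f"n_neg={n_neg} exceeds n_total={n_total}")
    if n_neg == 0:
        raise SaturationError(
            "no negative droplets: the channel is saturated and lambda "
            "cannot be estimated"
        )
    return -math.log(n_neg / n_total)


def _lambda_variance(n_neg: int, n_total: int) -> float:
    p = n_neg / n_total
    return (1.0 - p) / (n_total * p)


def quantify_genotypes(counts: DropletCounts) -> GenotypeQuant:
    """Estimate both genotype concentrations and the edited fraction.

    Each channel's lambda comes from its own negative count; the edited
    fraction is the HEX share of total lambda with a delta-method 95% CI
    clipped to [0, 1].
    """
    n = counts.n_total
    neg_fam = n - counts.n_pos_fam
    neg_hex = n - counts.n_pos_hex
    if neg_fam == 0 and neg_hex == 0:
        raise SaturationError("both channels saturated; dilute and re-run")
    lam_f = lambda_from_droplets(neg_fam, n) if neg_fam else float("inf")
    lam_h = lambda_from_droplets(neg_hex, n) if neg_hex else float("inf")
    if math.isinf(lam_f) or math.isinf(lam_h):
        raise SaturationError(
            "one channel saturated; edited fraction is not estimable"
        )
    total = lam_f + lam_h
    if total == 0:
        raise ValueError("no template detected in either channel")
    frac = lam_h / total
    var_f = _lambda_variance(neg_fam, n)
    var_h = _lambda_variance(neg_hex, n)
    # d(frac)/d(lam_h) = lam_f/total^2 ; d(frac)/d(lam_f) = -lam_h/total^2
    var_frac = (lam_f**2 * var_h + lam_h**2 * var_f) / total**4
    half = _Z95 * math.sqrt(var_frac)
    ci = (max(0.0, frac - half), min(1.0, frac + half))
    cp_f = cp_h = None
    if counts.partition_volume_ul:
        cp_f = lam_f / counts.partition_volume_ul
        cp_h = lam_h / counts.partition_volume_ul
    return GenotypeQuant(
        lambda_fam=lam_f,
        lambda_hex=lam_h,
        edited_fraction=frac,
        ci95=ci,
        copies_per_ul_fam=cp_f,
        copies_per_ul_hex=cp_h,
    )


def quantify_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Quantify every row of a droplet-count table.

    Expects columns sample, n_total, n_pos_fam, n_pos_hex and optionally
    partition_volume_ul; returns the input plus lambda_fam, lambda_hex,
    edited_fraction, ci_low, ci_high (and copies/µl when volume is given).
    """
    required = {"sample", "n_total", "n_pos_fam", "n_pos_hex"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"droplet table missing columns: {sorted(missing)}")
    out = frame.copy()
    results = []
    for _, row in frame.iterrows():
        counts = DropletCounts(
            n_total=int(row["n_total"]),
            n_pos_fam=int(row["n_pos_fam"]),
            n_pos_hex=int(row["n_pos_hex"]),
            partition_volume_ul=(
                float(row["partition_volume_ul"])
                if "partition_volume_ul" in frame.columns
                and pd.notna(row.get("partition_volume_ul"))
                else None
            ),
        )
        results.append(quantify_genotypes(counts))
    out["lambda_fam"] = [r.lambda_fam for r in results]
    out["lambda_hex"] = [r.lambda_hex for r in results]
    out["edited_fraction"] = [r.edited_fraction for r in results]
    out["ci_low"] = [r.ci95[0] for r in results]
    out["ci_high"] = [r.ci95[1] for r in results]
    if any(r.copies_per_ul_fam is not None for r in results):
        out["copies_per_ul_fam"] = [r.copies_per_ul_fam for r in results]
        out["copies_per_ul_hex"] = [r.copies_per_ul_hex for r in results]
    return out
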