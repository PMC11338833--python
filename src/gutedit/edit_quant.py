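"""Editing-outcome quantification.

Builds on :mod:`gutedit.pileup` to answer the questions a base-editing
experiment asks of deep sequencing and plating data:

* how often is the target base edited, and which bystander positions in the
  protospacer also carry edits (``window_profile`` / ``call_bystanders``);
* do candidate off-target sites show elevated mismatch frequencies in the
  treated sample relative to an untreated control (``offtarget_compare``);
* does the whole genome show a mutation-rate excess in the treated sample,
  e.g. from constitutive deaminase activity (``genome_scan_compare``);
* what edited fraction does a fold-reduction in selective plating imply
  (``edited_fraction_from_fold_reduction``), and what per-particle delivery
  probability explains a dose–response curve (``fit_delivery_model``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .guide_design import SPACER_LENGTH, GuideSpec, ProtospacerSite
from .offtarget import CandidateSite
from .pileup import PileupTable

#: absolute frequency-difference threshold for calling a position elevated;
#: roughly 3x the 0.1–0.3% Illumina substitution-error scale
DEFAULT_ELEVATION_THRESHOLD = 0.005
DEFAULT_MIN_COV = 100
DEFAULT_BYSTANDER_MIN_FRACTION = 0.05

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class CoverageError(ValueError):
    """Raised when required positions lack coverage."""


@dataclass(frozen=True)
class EditProfile:
    """Per-protospacer-position edit fractions for one site in one sample.

    ``per_position`` maps positions 1–20 to the fraction of covering reads
    carrying the product base, oriented to the protospacer strand; positions
    whose reference base is not the editable base map to None (not 0).
    """

    site: ProtospacerSite
    sample_label: str
    per_position: dict[int, Optional[float]]
    coverage_per_position: dict[int, int]
    target_position: Optional[int] = None

    @property
    def target_fraction(self) -> Optional[float]:
        if self.target_position is None:
            return None
        return self.per_position[self.target_position]

    def editable_positions(self) -> list[int]:
        return [p for p, f in sorted(self.per_position.items()) if f is not None]

    def any_window_edit_estimate(self, spec: GuideSpec) -> float:
        """Fraction of molecules with >=1 in-window edit, assuming positions
        edit independently (column-wise data cannot resolve linkage)."""
        fracs = [
            f for p, f in self.per_position.items()
            if f is not None and spec.in_window(p)
        ]
        unedited = float(np.prod([1.0 - f for f in fracs])) if fracs else 1.0
        return 1.0 - unedited


def window_profile(
    pileup: PileupTable,
    site: ProtospacerSite,
    spec: GuideSpec,
    target_position: Optional[int] = None,
) -> EditProfile:
    """Edit fraction at every editable protospacer position of ``site``.

    For each position whose protospacer-strand reference base equals the
    editor's substrate base, the fraction of covering reads carrying the
    product base is computed, with counts complemented for minus-strand
    sites. Raises :class:`CoverageError` on zero coverage at the designated
    target position.
    """
    contig = site.interval.contig
    per_position: dict[int, Optional[float]] = {}
    coverage: dict[int, int] = {}
    for p in range(1, SPACER_LENGTH + 1):
        if site.base_at(p) != spec.edited_base:
            per_position[p] = None
            continue
        g = site.genomic_position(p)
        col = pileup.column(contig, g)
        coverage[p] = col.coverage
        if col.coverage == 0:
            if p == target_position:
                raise CoverageError(
                    f"zero coverage at target position {p} "
                    f"({contig}:{g + 1})"
                )
            per_position[p] = None
            continue
        product = (
            spec.product_base if site.strand == "+" else _COMP[spec.product_base]
        )
        per_position[p] = col.counts[product] / col.coverage
    if target_position is not None and per_position.get(target_position) is None:
        raise CoverageError(
            f"target position {target_position} is not an editable "
            f"{spec.edited_base} with coverage at this site"
        )
    return EditProfile(
        site=site,
        sample_label=pileup.sample_label,
        per_position=per_position,
        coverage_per_position=coverage,
        target_position=target_position,
    )


def call_bystanders(
    profile: EditProfile,
    min_fraction: float = DEFAULT_BYSTANDER_MIN_FRACTION,
) -> list[int]:
    """Editable positions other than the target with fraction >= threshold."""
    return sorted(
        p
        for p, f in profile.per_position.items()
        if f is not None and p != profile.target_position and f >= min_fraction
    )


@dataclass(frozen=True)
class OffTargetReport:
    """Treated-vs-control max-base mismatch frequencies per candidate site.

    One row per candidate: the highest per-base non-reference frequency
    across the 20 protospacer positions in each sample (the quantity plotted
    per off-target in treated/control bar charts), the difference, and a
    flag when the treated excess exceeds the decision threshold.
    """

    table: pd.DataFrame
    threshold: float
    min_cov: int

    @property
    def n_flagged(self) -> int:
        return int(self.table["elevated"].sum())

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["elevated"]]


def _candidate_max_base(
    pileup: PileupTable, cand: CandidateSite
) -> tuple[float, str, int]:
    """(max non-ref per-base frequency, argmax base, min coverage) over the
    candidate's 20 positions. Ties between bases resolve alphabetically."""
    iv = cand.site.interval
    maxfreq = pileup.max_base_frequency(iv.contig)[iv.start : iv.end]
    cov = pileup.coverage(iv.contig)[iv.start : iv.end]
    min_coverage = int(cov.min()) if len(cov) else 0
    if np.all(np.isnan(maxfreq)):
        return float("nan"), "", min_coverage
    best_pos = int(np.nanargmax(maxfreq))
    col = pileup.column(iv.contig, iv.start + best_pos)
    non_ref = {
        b: c for b, c in col.counts.items() if b != col.ref_base
    }
    best_base = min(non_ref, key=lambda b: (-non_ref[b], b)) if non_ref else ""
    return float(maxfreq[best_pos]), best_base, min_coverage


def offtarget_compare(
    treated: PileupTable,
    control: PileupTable,
    candidates: Sequence[CandidateSite],
    min_cov: int = DEFAULT_MIN_COV,
    threshold: float = DEFAULT_ELEVATION_THRESHOLD,
) -> OffTargetReport:
    """Compare candidate off-target sites between treated and control.

    Candidates with coverage below ``min_cov`` at any of their positions in
    either sample are reported with status ``insufficient_coverage`` rather
    than silently dropped; their elevation flag is never set.
    """
    rows = []
    for cand in candidates:
        ft, bt, ct = _candidate_max_base(treated, cand)
        fc, _, cc = _candidate_max_base(control, cand)
        status = "ok" if ct >= min_cov and cc >= min_cov else "insufficient_coverage"
        diff = ft - fc if status == "ok" else float("nan")
        s1, e1 = cand.site.interval.as_1based()
        rows.append(
            {
                "contig": cand.site.interval.contig,
                "start": s1,
                "end": e1,
                "strand": cand.site.strand,
                "protospacer": cand.site.protospacer_seq,
                "mm_total": cand.mismatches_total,
                "mm_proximal": cand.mismatches_proximal,
                "is_on_target": cand.is_on_target,
                "max_base_freq_treated": ft,
                "max_base_freq_control": fc,
                "max_base_treated": bt,
                "difference": diff,
                "status": status,
                "elevated": bool(status == "ok" and diff > threshold),
            }
        )
    return OffTargetReport(
        table=pd.DataFrame(rows), threshold=threshold, min_cov=min_cov
    )


@dataclass(frozen=True)
class GenomeScanResult:
    """Symmetric count of elevated positions in each direction plus a
    sign-test verdict on whether the treated sample shows a genuine excess."""

    n_elevated_treated: int
    n_elevated_control: int
    n_positions_compared: int
    threshold: float
    min_cov: int
    base_restrict: Optional[str]
    p_value: float
    verdict: str  # "elevated" | "no_elevation"


def genome_scan_compare(
    treated: PileupTable,
    control: PileupTable,
    threshold: float = DEFAULT_ELEVATION_THRESHOLD,
    min_cov: int = DEFAULT_MIN_COV,
    base_restrict: Optional[str] = None,
) -> GenomeScanResult:
    """Genome-wide mutation-rate comparison between two samples.

    Counts positions exceeding ``threshold`` in each direction over all
    positions covered at >= ``min_cov`` in both samples (optionally
    restricted to one reference base, e.g. adenines for an ABE). The verdict
    is a two-sided exact binomial sign test on the direction of exceedances
    at level 0.05: "elevated" only when significant and the treated count is
    larger.
    """
    if set(treated.contigs) != set(control.contigs):
        raise ValueError("treated and control pileups cover different contigs")
    n_t = n_c = n_compared = 0
    for contig in treated.contigs:
        ft = treated.mismatch_frequency(contig)
        fc = control.mismatch_frequency(contig)
        usable = (
            (treated.coverage(contig) >= min_cov)
            & (control.coverage(contig) >= min_cov)
            & ~np.isnan(ft)
            & ~np.isnan(fc)
        )
        if base_restrict is not None:
            ref = np.frombuffer(
                treated.refs[contig].seq.encode("ascii"), dtype=np.uint8
            )
            usable &= ref == ord(base_restrict)
        n_compared += int(usable.sum())
        diff = ft[usable] - fc[usable]
        n_t += int((diff > threshold).sum())
        n_c += int((diff < -threshold).sum())
    if n_compared == 0:
        raise CoverageError("no positions covered in both samples")
    n_exceed = n_t + n_c
    p_value = (
        stats.binomtest(n_t, n=n_exceed, p=0.5).pvalue if n_exceed else 1.0
    )
    verdict = "elevated" if (p_value < 0.05 and n_t > n_c) else "no_elevation"
    return GenomeScanResult(
        n_elevated_treated=n_t,
        n_elevated_control=n_c,
        n_positions_compared=n_compared,
        threshold=threshold,
        min_cov=min_cov,
        base_restrict=base_restrict,
        p_value=float(p_value),
        verdict=verdict,
    )


@dataclass(frozen=True)
class PlateCounts:
    """Colony counts from one plating condition (CFU per µl)."""

    cfu_selective: float
    cfu_nonselective: float
    fold_reduction: Optional[float] = None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.cfu_selective < 0 or self.cfu_nonselective < 0:
            raise ValueError("colony counts must be non-negative")


def compute_fold_reduction(
    treated: PlateCounts,
    control: PlateCounts,
    normalize_nonselective: bool = False,
) -> PlateCounts:
    """Fold reduction in selective growth of treated vs untreated control.

    Defined as CFU_selective(control) / CFU_selective(treated); with
    ``normalize_nonselective`` each selective count is first divided by its
    non-selective count to correct for plating-input differences. When the
    treated selective count is zero the fold is censored at the control
    count (a lower bound).
    """
    num = control.cfu_selective
    den = treated.cfu_selective
    if normalize_nonselective:
        if control.cfu_nonselective == 0 or treated.cfu_nonselective == 0:
            raise ValueError("non-selective counts must be positive to normalize")
        num /= control.cfu_nonselective
        den /= treated.cfu_nonselective
    if den == 0:
        return replace(treated, fold_reduction=num if num > 0 else None,
                       censored=True)
    return replace(treated, fold_reduction=num / den, censored=False)


def edited_fraction_from_fold_reduction(fold: float) -> float:
    """Edited fraction implied by a fold-reduction on selective plates.

    A 10^4-fold drop in selectively growing (unedited) cells means
    1 - 1/10^4 = 99.99% of the population carries the inactivating edit.
    """
    if fold < 1:
        raise ValueError(f"fold reduction must be >= 1, got {fold}")
    return 1.0 - 1.0 / fold


@dataclass(frozen=True)
class DeliveryModel:
    """Single-hit Poisson delivery: f(MOI) = 1 - exp(-a * MOI).

    ``a`` is the per-particle effective delivery probability; at MOI m each
    cell receives Poisson(a*m) payloads and is delivered-to when it receives
    at least one.
    """

    a: float

    def __post_init__(self) -> None:
        if not 0 < self.a <= 1:
            raise ValueError(f"delivery probability a must be in (0, 1], got {self.a}")

    def predict(self, moi) -> np.ndarray:
        return 1.0 - np.exp(-self.a * np.asarray(moi, dtype=float))


class FitError(RuntimeError):
    """Raised when the delivery model cannot be fitted."""


def fit_delivery_model(
    moi: Sequence[float], delivered_fraction: Sequence[float]
) -> DeliveryModel:
    """Least-squares fit of the single-hit model; f(0)=0 is structural.

    A single (MOI, fraction) point is solved in closed form,
    a = -ln(1-f)/MOI.
    """
    m = np.asarray(moi, dtype=float)
    f = np.asarray(delivered_fraction, dtype=float)
    if m.size == 0 or m.size != f.size:
        raise ValueError("need matching, non-empty MOI and fraction arrays")
    if np.any(m < 0):
        raise ValueError("MOIs must be non-negative")
    if np.any((f < 0) | (f >= 1)):
        raise ValueError("delivered fractions must lie in [0, 1)")
    positive = (m > 0) & (f > 0)
    if not positive.any():
        raise FitError("all delivered fractions are zero; a is unidentifiable")
    closed_form = -np.log1p(-f[positive]) / m[positive]
    x0 = float(np.clip(np.median(closed_form), 1e-9, 1.0))
    if positive.sum() == 1 and m.size == positive.sum():
        return DeliveryModel(a=x0)
    res = optimize.least_squares(
        lambda a: 1.0 - np.exp(-a[0] * m) - f,
        x0=[x0],
        bounds=([1e-12], [1.0]),
    )
    if not res.success:
        raise FitError(f"delivery-model fit failed: {res.message}")
    return DeliveryModel(a=float(res.x[0]))
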