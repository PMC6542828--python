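"""Genotype-level quality resets and sample-level cohort QC.

Two layers of quality control precede panel filtering:

* **Genotype resets** — calls with genotype quality below Phred 13
  (≈95% confidence), depth below 5, alt-allele fraction below 0.2, or
  mapping quality below Phred 13 are reset to no-calls.  Absent fields
  never trigger their rule (some cohorts, e.g. combined gVCF merges,
  carry no per-call MQ).
* **Sample exclusion** — per sample, the number of extreme heterozygous
  calls (alt fraction outside [0.15, 0.8]) and of rare homozygous calls
  (reference-panel AF < 0.01) are computed; samples beyond mean + 3 SD
  extreme hets, or below mean − 3 SD rare homozygotes, are excluded as
  poor quality or potentially contaminated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .vocab import Zygosity

__all__ = [
    "GenotypeCall",
    "QualityThresholds",
    "SampleQcMetrics",
    "phred_to_confidence",
    "reset_low_quality_calls",
    "compute_sample_qc",
    "exclude_outlier_samples",
]


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site, with its quality fields.

    Any quality field may be absent (``None``); ``ad_alt`` is the
    alt-allele read depth (records are decomposed upstream, so there is a
    single alt allele per record).
    """

    sample_id: str
    gt: Zygosity
    gq: float | None = None
    dp: int | None = None
    ad_alt: int | None = None
    mq: float | None = None

    def __post_init__(self):
        for name in ("gq", "dp", "ad_alt", "mq"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.ad_alt is not None and self.dp is not None and self.ad_alt > self.dp:
            raise ValidationError(f"ad_alt ({self.ad_alt}) exceeds dp ({self.dp})")

    @property
    def alt_fraction(self) -> float | None:
        if self.ad_alt is None or self.dp is None or self.dp == 0:
            return None
        return self.ad_alt / self.dp


@dataclass(frozen=True)
class QualityThresholds:
    """Genotype reset thresholds; defaults are the diagnostic-pipeline values."""

    min_gq: float = 13.0  # Phred 13 ~= 95% confidence
    min_dp: int = 5
    min_alt_fraction: float = 0.2
    min_mq: float = 13.0


def phred_to_confidence(q: float) -> float:
    """Confidence (1 − error probability) of a Phred-scaled quality.

    ``phred_to_confidence(13)`` ≈ 0.95, the rationale for the GQ/MQ < 13
    reset thresholds.
    """
    if q < 0:
        raise ValidationError(f"Phred score must be >= 0, got {q}")
    return 1.0 - 10.0 ** (-q / 10.0)


def reset_low_quality_calls(
    call: GenotypeCall, thresholds: QualityThresholds = QualityThresholds()
) -> GenotypeCall:
    """Reset a low-quality call to no-call; pass everything else through.

    A call is reset when GQ < min_gq, DP < min_dp, alt fraction < the
    minimum, or (MQ present and MQ < min_mq).  Absent fields do not
    trigger their rule.  Homozygous-reference calls and existing no-calls
    are returned unchanged; the operation is idempotent and never changes
    a genotype except to no-call.
    """
    if call.gt in (Zygosity.HOM_REF, Zygosity.NO_CALL):
        return call
    frac = call.alt_fraction
    reset = (
        (call.gq is not None and call.gq < thresholds.min_gq)
        or (call.dp is not None and call.dp < thresholds.min_dp)
        or (frac is not None and frac < thresholds.min_alt_fraction)
        or (call.mq is not None and call.mq < thresholds.min_mq)
    )
    return replace(call, gt=Zygosity.NO_CALL) if reset else call


@dataclass(frozen=True)
class SampleQcMetrics:
    """Per-sample contamination/quality indicators."""

    sample_id: str
    n_extreme_het: int  # het calls with alt fraction outside [0.15, 0.8]
    n_rare_hom: int  # hom-alt calls at reference AF < 0.01

    def __post_init__(self):
        if self.n_extreme_het < 0 or self.n_rare_hom < 0:
            raise ValidationError("QC counts must be >= 0")


def compute_sample_qc(
    cohort_calls: Mapping[str, Iterable[tuple[str, GenotypeCall]]],
    reference_afs: Mapping[str, float],
    extreme_het_range: tuple[float, float] = (0.15, 0.8),
    rare_hom_af: float = 0.01,
) -> list[SampleQcMetrics]:
    """Compute per-sample QC metrics over (site-key, call) collections.

    ``reference_afs`` maps site keys to a reference-panel allele
    frequency; sites without an AF are excluded from the rare-homozygote
    count (the metric needs rarity evidence, not its absence).
    """
    lo, hi = extreme_het_range
    out = []
    for sample_id, calls in cohort_calls.items():
        n_extreme = 0
        n_rare_hom = 0
        for site, call in calls:
            if call.gt is Zygosity.HET:
                frac = call.alt_fraction
                if frac is not None and (frac < lo or frac > hi):
                    n_extreme += 1
            elif call.gt is Zygosity.HOM_ALT:
                af = reference_afs.get(site)
                if af is not None and af < rare_hom_af:
                    n_rare_hom += 1
        out.append(SampleQcMetrics(sample_id, n_extreme, n_rare_hom))
    return out


def exclude_outlier_samples(
    metrics: Sequence[SampleQcMetrics],
    n_sd: float = 3.0,
    population_sd: bool = True,
) -> set[str]:
    """Samples failing the cohort-level mean ± 3 SD screens.

    Excluded iff n_extreme_het > mean + ``n_sd``·SD of n_extreme_het, or
    n_rare_hom < mean − ``n_sd``·SD of n_rare_hom.  Statistics are taken
    over all samples; ``population_sd`` selects the divide-by-n SD
    (default) versus the n−1 sample SD.  A zero-variance metric excludes
    nobody.  The result is invariant under sample reordering.
    """
    if len(metrics) < 2:
        raise ValidationError("outlier exclusion needs at least 2 samples")
    ddof = 0 if population_sd else 1
    het = np.array([m.n_extreme_het for m in metrics], dtype=float)
    hom = np.array([m.n_rare_hom for m in metrics], dtype=float)
    het_hi = het.mean() + n_sd * het.std(ddof=ddof)
    hom_lo = hom.mean() - n_sd * hom.std(ddof=ddof)
    excluded = set()
    for m in metrics:
        if het.std(ddof=ddof) > 0 and m.n_extreme_het > het_hi:
            excluded.add(m.sample_id)
        if hom.std(ddof=ddof) > 0 and m.n_rare_hom < hom_lo:
            excluded.add(m.sample_id)
    return excluded


def qc_report(metrics: Sequence[SampleQcMetrics], excluded: set[str]) -> pd.DataFrame:
    """QC report table: one row per sample with metrics and exclusion reason."""
    rows = []
    for m in metrics:
        reasons = []
        if m.sample_id in excluded:
            reasons.append("outlier")
        rows.append(
            {
                "sample_id": m.sample_id,
                "n_extreme_het": m.n_extreme_het,
                "n_rare_hom": m.n_rare_hom,
                "excluded": m.sample_id in excluded,
                "reason": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)
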