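"""Case:control background statistics for panel-filter output.

Any diagnostic gene-panel filter should show a clear difference between a
disease cohort and a population unselected for the disease; the surviving
variants in the control arm estimate the *background noise* of the panel.
This module provides the comparisons used for that assessment: per-stratum
carrier burden with Fisher exact odds ratios, per-gene carrier
proportions, the fraction of unique missense variants with high CADD,
per-sample qualifying-variant distributions and mean-MAF ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import GeneFinding, QualifiedVariant, VariantKey
from .errors import ValidationError
from .vocab import ConsequenceClass, Zygosity

__all__ = [
    "BurdenTable",
    "OddsRatioResult",
    "burden_tables",
    "fisher_odds_ratio",
    "per_gene_proportions",
    "cadd_high_fraction",
    "findings_per_sample_distribution",
    "maf_ratio",
]


@dataclass(frozen=True)
class BurdenTable:
    """Carrier counts for one stratum in each cohort arm."""

    stratum: tuple[str, ...]
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int

    def __post_init__(self):
        if self.case_carriers > self.case_total or self.control_carriers > self.control_total:
            raise ValidationError("carriers cannot exceed cohort totals")

    def as_2x2(self) -> list[list[int]]:
        return [
            [self.case_carriers, self.case_total - self.case_carriers],
            [self.control_carriers, self.control_total - self.control_carriers],
        ]


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float  # may be inf
    p_value: float
    ci95: tuple[float, float]
    undefined: bool = False


def _sample_ids(findings: Iterable[GeneFinding]) -> set[str]:
    return {f.sample_id for f in findings}


def _default_stratifier(v: QualifiedVariant) -> tuple[str, ...]:
    return (v.lgmdet.allelic_requirement.value, v.consequence_class.value)


def burden_tables(
    case_findings: Sequence[GeneFinding],
    control_findings: Sequence[GeneFinding],
    case_total: int | None = None,
    control_total: int | None = None,
    stratify: Callable[[QualifiedVariant], tuple[str, ...]] = _default_stratifier,
) -> list[BurdenTable]:
    """Per-stratum carrier counts: samples with >= 1 valid variant in the stratum.

    A sample counts once per stratum regardless of how many variants it
    carries there (set semantics — duplicated variant rows cannot inflate
    a count).  ``case_total``/``control_total`` default to the number of
    distinct samples appearing in each finding set; pass the true cohort
    sizes to include samples with no findings in the denominators.
    """
    case_samples, control_samples = _sample_ids(case_findings), _sample_ids(control_findings)
    if case_samples & control_samples:
        raise ValidationError(
            f"cohort arms share sample ids: {sorted(case_samples & control_samples)[:5]}"
        )
    case_total = case_total if case_total is not None else len(case_samples)
    control_total = control_total if control_total is not None else len(control_samples)

    def carriers(findings: Sequence[GeneFinding]) -> dict[tuple[str, ...], set[str]]:
        out: dict[tuple[str, ...], set[str]] = {}
        for f in findings:
            for v in f.qualifying_variants:
                out.setdefault(stratify(v), set()).add(f.sample_id)
        return out

    case_c, control_c = carriers(case_findings), carriers(control_findings)
    tables = []
    for stratum in sorted(set(case_c) | set(control_c)):
        tables.append(
            BurdenTable(
                stratum,
                len(case_c.get(stratum, ())),
                case_total,
                len(control_c.get(stratum, ())),
                control_total,
            )
        )
    return tables


def fisher_odds_ratio(table: Sequence[Sequence[int]] | BurdenTable) -> OddsRatioResult:
    """Two-tailed Fisher exact test with a 95% CI on the odds ratio.

    The odds ratio is the cross-product ratio ad/bc (infinite when b·c is
    zero and a·d is not).  The p-value is the exact conditional two-tailed
    probability (sum of hypergeometric probabilities no larger than the
    observed table's).  The CI uses the normal approximation on log OR
    with the Haldane–Anscombe +0.5 correction applied when any cell is
    zero; it is approximate, not an exact conditional interval.
    """
    if isinstance(table, BurdenTable):
        table = table.as_2x2()
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValidationError("2x2 table cells must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return OddsRatioResult(math.nan, math.nan, (math.nan, math.nan), undefined=True)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    _, p = sps.fisher_exact(table, alternative="two-sided")
    # Haldane-Anscombe correction for the CI when any cell is empty
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    log_or = math.log((a2 * d2) / (b2 * c2))
    se = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    ci = (math.exp(log_or - 1.959963984540054 * se), math.exp(log_or + 1.959963984540054 * se))
    return OddsRatioResult(odds, float(p), ci)


def per_gene_proportions(
    case_findings: Sequence[GeneFinding],
    control_findings: Sequence[GeneFinding],
    case_total: int | None = None,
    control_total: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene carrier fractions in each arm, plus control-excess summaries.

    Returns the per-gene table and a summary with ``n_genes``,
    ``higher_in_control`` (control carrier fraction strictly above the
    case fraction) and ``absent_in_control`` (genes with no control
    carriers at all).
    """
    case_samples, control_samples = _sample_ids(case_findings), _sample_ids(control_findings)
    case_total = case_total if case_total is not None else len(case_samples)
    control_total = control_total if control_total is not None else len(control_samples)

    def per_gene(findings: Sequence[GeneFinding]) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for f in findings:
            if f.qualifying_variants:
                out.setdefault(f.gene_symbol, set()).add(f.sample_id)
        return out

    case_g, control_g = per_gene(case_findings), per_gene(control_findings)
    rows = []
    for gene in sorted(set(case_g) | set(control_g)):
        cf = len(case_g.get(gene, ())) / case_total if case_total else math.nan
        gf = len(control_g.get(gene, ())) / control_total if control_total else math.nan
        rows.append(
            {
                "gene_symbol": gene,
                "case_carriers": len(case_g.get(gene, ())),
                "case_fraction": cf,
                "control_carriers": len(control_g.get(gene, ())),
                "control_fraction": gf,
            }
        )
    df = pd.DataFrame(rows, columns=["gene_symbol", "case_carriers", "case_fraction",
                                     "control_carriers", "control_fraction"])
    summary = {
        "n_genes": len(df),
        "higher_in_control": int((df["control_fraction"] > df["case_fraction"]).sum()) if len(df) else 0,
        "absent_in_control": int((df["control_carriers"] == 0).sum()) if len(df) else 0,
    }
    return df, summary


def cadd_high_fraction(
    findings: Sequence[GeneFinding], cadd_cutoff: float = 30.0
) -> tuple[float, int, int]:
    """Fraction of unique missense variants with CADD above the cutoff.

    Uniqueness is keyed on (chrom, pos, ref, alt) across the whole
    cohort; variants without a CADD annotation are excluded from both the
    numerator and the denominator.  Returns ``(fraction, n_high, n_scored)``;
    the fraction is NaN (not 0) when no missense variant carries a CADD
    score.
    """
    best_cadd: dict[VariantKey, float] = {}
    for f in findings:
        for v in f.qualifying_variants:
            if v.consequence_class is not ConsequenceClass.MISSENSE:
                continue
            if v.annotation.cadd_phred is None:
                best_cadd.setdefault(v.key, math.nan)
            else:
                prev = best_cadd.get(v.key)
                if prev is None or math.isnan(prev) or v.annotation.cadd_phred > prev:
                    best_cadd[v.key] = v.annotation.cadd_phred
    scored = [c for c in best_cadd.values() if not math.isnan(c)]
    if not scored:
        return math.nan, 0, 0
    n_high = sum(c > cadd_cutoff for c in scored)
    return n_high / len(scored), n_high, len(scored)


def findings_per_sample_distribution(
    findings: Sequence[GeneFinding], cohort_samples: Sequence[str]
) -> dict:
    """Histogram and moments of per-sample qualifying-variant counts.

    ``cohort_samples`` must list every cohort member so zero-finding
    samples enter the denominator.  SNVs and indels are counted
    separately (unique sites per sample), plus a combined count; the
    histogram is over the combined counts, as proportions of samples.
    """
    per_sample: dict[str, set[VariantKey]] = {s: set() for s in cohort_samples}
    for f in findings:
        if f.sample_id in per_sample:
            per_sample[f.sample_id].update(v.key for v in f.qualifying_variants)
    snv = np.array([sum(k.is_snv for k in ks) for ks in per_sample.values()], dtype=float)
    indel = np.array([sum(not k.is_snv for k in ks) for ks in per_sample.values()], dtype=float)
    total = snv + indel
    counts = pd.Series(total).value_counts().sort_index()
    hist = {int(k): float(v) / len(cohort_samples) for k, v in counts.items()}
    return {
        "histogram": hist,
        "mean": float(total.mean()),
        "sd": float(total.std(ddof=0)),
        "snv_mean": float(snv.mean()),
        "snv_sd": float(snv.std(ddof=0)),
        "indel_mean": float(indel.mean()),
        "indel_sd": float(indel.std(ddof=0)),
        "n_samples": len(cohort_samples),
    }


def maf_ratio(
    case_findings: Sequence[GeneFinding],
    control_findings: Sequence[GeneFinding],
    stratify: Callable[[QualifiedVariant], bool] | None = None,
) -> float:
    """Ratio of mean max-AF over qualifying variants: control / case.

    ``stratify`` optionally restricts both arms to a variant subset (e.g.
    missense in monoallelic threads).  NaN when either stratum is empty.
    """

    def mean_af(findings: Sequence[GeneFinding]) -> float:
        afs = [
            v.max_af
            for f in findings
            for v in f.qualifying_variants
            if stratify is None or stratify(v)
        ]
        return float(np.mean(afs)) if afs else math.nan

    case_mean, control_mean = mean_af(case_findings), mean_af(control_findings)
    if math.isnan(case_mean) or math.isnan(control_mean) or case_mean == 0:
        return math.nan
    return control_mean / case_mean
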