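"""Accuracy of the filter against a truth set: confusion counts, MAF
sweeps in ROC space, consequence-stratified precision-recall, AUC lower
bound, and causative-gene ranking.

The truth set lists known causative variants as (sample, chrom, pos, ref,
alt, gene).  Scoring is variant-level: a true positive is a truth variant
found among the qualifying variants of requirement-satisfied findings; a
false positive is any other surviving variant.  True negatives exist only
relative to a caller-supplied negative universe, so specificity (and the
ROC x-axis) is computed only when one is given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .engine import (
    REASON_MAF,
    Candidate,
    CandidateSet,
    FilterConfig,
    FilterResult,
    GeneFinding,
    VariantKey,
    collect_candidates,
    findings_from_candidates,
)
from .errors import ValidationError
from .panel import Panel
from .vocab import ConsequenceClass, Sex

__all__ = [
    "TruthSet",
    "ConfusionCounts",
    "score_findings",
    "maf_sweep",
    "consequence_strata_pr",
    "auc_lower_bound",
    "rank_causative_gene",
    "explain_misses",
]

#: Default MAF ladder for sweeps; 0 encodes "not seen in any control database".
DEFAULT_SWEEP_CUTOFFS = (0.0, 1e-5, 2e-5, 4e-5, 1e-4)


@dataclass(frozen=True)
class TruthEntry:
    sample_id: str
    key: VariantKey
    gene_symbol: str
    expected_requirement: str = ""


@dataclass
class TruthSet:
    """Known causative variants, unique on (sample, variant)."""

    entries: list[TruthEntry]

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            k = (e.sample_id, e.key)
            if k in seen:
                raise ValidationError(f"duplicate truth entry for {e.sample_id} {e.key}")
            seen.add(k)

    def __len__(self):
        return len(self.entries)

    def pairs(self) -> set[tuple[str, VariantKey]]:
        return {(e.sample_id, e.key) for e in self.entries}

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthSet":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        entries = [
            TruthEntry(
                r["sample_id"],
                VariantKey(r["chrom"], int(r["pos"]), r["ref"], r["alt"]),
                r["gene_symbol"],
                r.get("expected_requirement", ""),
            )
            for r in df.to_dict("records")
        ]
        return cls(entries)

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "sample_id": e.sample_id,
                "chrom": e.key.chrom,
                "pos": e.key.pos,
                "ref": e.key.ref,
                "alt": e.key.alt,
                "gene_symbol": e.gene_symbol,
                "expected_requirement": e.expected_requirement,
            }
            for e in self.entries
        ]
        pd.DataFrame(
            rows,
            columns=["sample_id", "chrom", "pos", "ref", "alt", "gene_symbol", "expected_requirement"],
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN(/TN) with the derived diagnostic rates.

    sensitivity = TP/(TP+FN); precision = TP/(TP+FP);
    F1 = 2·precision·sensitivity/(precision+sensitivity).  Specificity and
    the false-positive rate require TN, i.e. a negative universe.
    """

    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0 or (self.tn is not None and self.tn < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    recall = sensitivity

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def false_positive_fraction(self) -> float:
        """Complement of precision: the fraction of survivors that are not true."""
        return 1.0 - self.precision

    @property
    def specificity(self) -> float:
        if self.tn is None:
            return math.nan
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan

    @property
    def fpr(self) -> float:
        s = self.specificity
        return 1.0 - s if not math.isnan(s) else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.sensitivity
        if math.isnan(p) or math.isnan(r) or (p + r) == 0:
            return math.nan
        return 2 * p * r / (p + r)


def _predicted_pairs(findings: Sequence[GeneFinding]) -> set[tuple[str, VariantKey]]:
    return {
        (f.sample_id, v.key)
        for f in findings
        if f.requirement_satisfied
        for v in f.qualifying_variants
    }


def score_findings(
    findings: Sequence[GeneFinding],
    truth: TruthSet,
    universe: set[tuple[str, VariantKey]] | None = None,
) -> ConfusionCounts:
    """Variant-level confusion counts of findings against the truth set.

    ``universe`` optionally supplies the negative universe — every
    (sample, variant) pair considered testable — enabling TN and
    specificity.  Without it specificity is undefined (NaN), never
    silently approximated.
    """
    predicted = _predicted_pairs(findings)
    truth_pairs = truth.pairs()
    tp = len(predicted & truth_pairs)
    fp = len(predicted - truth_pairs)
    fn = len(truth_pairs - predicted)
    tn = None
    if universe is not None:
        negatives = universe - truth_pairs
        tn = len(negatives - predicted)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def maf_sweep(
    vcf_path,
    panel: Panel,
    cfg: FilterConfig,
    truth: TruthSet,
    cutoffs: Sequence[float] = DEFAULT_SWEEP_CUTOFFS,
    sex_table: Mapping[str, Sex] | None = None,
    universe: set[tuple[str, VariantKey]] | None = None,
) -> list[tuple[float, ConfusionCounts]]:
    """Confusion counts across a ladder of MAF cut-offs.

    One collection pass over the VCF is reused for every cutoff (valid
    because the MAF rule is the only criterion swept); each cutoff
    replaces both per-requirement thresholds.  Cutoff 0 admits only
    alleles unseen in every reference source.  Unsorted cutoffs are
    sorted internally.
    """
    cset = collect_candidates(vcf_path, panel, cfg, sex_table)
    return sweep_candidates(cset, cfg, truth, cutoffs, sex_table, universe)


def sweep_candidates(
    cset: CandidateSet,
    cfg: FilterConfig,
    truth: TruthSet,
    cutoffs: Sequence[float] = DEFAULT_SWEEP_CUTOFFS,
    sex_table: Mapping[str, Sex] | None = None,
    universe: set[tuple[str, VariantKey]] | None = None,
) -> list[tuple[float, ConfusionCounts]]:
    out = []
    for cutoff in sorted(cutoffs):
        cfg_i = FilterConfig(
            maf_monoallelic=cutoff,
            maf_biallelic=cutoff,
            canonical_only=cfg.canonical_only,
            require_sift_polyphen_concordance=cfg.require_sift_polyphen_concordance,
            allowed_class_overrides=cfg.allowed_class_overrides,
            quality=cfg.quality,
        )
        result = findings_from_candidates(cset, cfg_i, sex_table)
        out.append((cutoff, score_findings(result.findings, truth, universe)))
    return out


def consequence_strata_pr(
    vcf_path,
    panel: Panel,
    cfg: FilterConfig,
    truth: TruthSet,
    cutoffs: Sequence[float] = DEFAULT_SWEEP_CUTOFFS,
    sex_table: Mapping[str, Sex] | None = None,
) -> pd.DataFrame:
    """Precision/recall per consequence stratum across the MAF ladder.

    Strata: ``lof_only``, ``missense_cadd20``, ``missense_cadd30`` (CADD
    at or above the number) and ``all``.  Predictions are restricted to
    the stratum; recall keeps the full truth set as denominator, so a
    stratum that cannot contain some truth variants pays for them in
    recall — matching how consequence-restricted filters trade recall for
    precision.
    """

    def in_stratum(v, stratum: str) -> bool:
        if stratum == "all":
            return True
        if stratum == "lof_only":
            return v.consequence_class is ConsequenceClass.LOF
        cadd_min = {"missense_cadd20": 20.0, "missense_cadd30": 30.0}[stratum]
        return (
            v.consequence_class is ConsequenceClass.MISSENSE
            and v.annotation.cadd_phred is not None
            and v.annotation.cadd_phred >= cadd_min
        )

    cset = collect_candidates(vcf_path, panel, cfg, sex_table)
    truth_pairs = truth.pairs()
    rows = []
    for cutoff in sorted(cutoffs):
        cfg_i = FilterConfig(maf_monoallelic=cutoff, maf_biallelic=cutoff,
                             canonical_only=cfg.canonical_only,
                             require_sift_polyphen_concordance=cfg.require_sift_polyphen_concordance,
                             allowed_class_overrides=cfg.allowed_class_overrides,
                             quality=cfg.quality)
        result = findings_from_candidates(cset, cfg_i, sex_table)
        for stratum in ("lof_only", "missense_cadd20", "missense_cadd30", "all"):
            predicted = {
                (f.sample_id, v.key)
                for f in result.findings
                if f.requirement_satisfied
                for v in f.qualifying_variants
                if in_stratum(v, stratum)
            }
            tp = len(predicted & truth_pairs)
            fp = len(predicted - truth_pairs)
            precision = tp / (tp + fp) if (tp + fp) else math.nan
            recall = tp / len(truth_pairs) if truth_pairs else math.nan
            rows.append(
                {
                    "stratum": stratum,
                    "maf_cutoff": cutoff,
                    "tp": tp,
                    "fp": fp,
                    "precision": precision,
                    "recall": recall,
                }
            )
    return pd.DataFrame(rows)


def auc_lower_bound(sensitivity: float, specificity: float) -> float:
    """Lower bound on the ROC AUC of a binary test: (sensitivity + specificity)/2."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    return (sensitivity + specificity) / 2.0


_PATTERN_RANK = {"hom_alt": 0, "hemizygous_alt": 0, "two_or_more_hets": 0, "single_het": 0,
                 "not_satisfied": 1}


def _finding_sort_key(f: GeneFinding) -> tuple:
    severities = [v.consequence_class for v in f.qualifying_variants]
    best = min((ConsequenceClass.parse(s) for s in severities), key=lambda c: _SEVERITY[c]) if severities else ConsequenceClass.OTHER
    min_af = min((v.max_af for v in f.qualifying_variants), default=1.0)
    return (not f.requirement_satisfied, _SEVERITY[best], min_af, f.gene_symbol)


_SEVERITY = {
    ConsequenceClass.LOF: 0,
    ConsequenceClass.MISSENSE: 1,
    ConsequenceClass.INFRAME: 2,
    ConsequenceClass.SPLICE_REGION: 3,
    ConsequenceClass.OTHER: 4,
}


def rank_causative_gene(findings: Sequence[GeneFinding], truth_gene: str) -> int | None:
    """1-based rank of the truth gene in one sample's ordered finding list.

    Findings are ordered satisfied-first, then by consequence severity,
    then ascending minimum AF, then gene symbol (a documented convention
    — the ordering of diagnostic reports is not standardised).  Returns
    ``None`` when the gene is absent (counted as a miss by callers).
    """
    ordered = sorted(findings, key=_finding_sort_key)
    for i, f in enumerate(ordered, start=1):
        if f.gene_symbol == truth_gene:
            return i
    return None


def explain_misses(result: FilterResult, truth: TruthSet) -> pd.DataFrame:
    """Attribute each missed truth variant to the rule that dropped it.

    For every truth entry absent from the surviving predictions, the drop
    log is searched for that (variant[, sample]); the first matching
    reason code is reported (e.g. ``maf_above_threshold``, the dominant
    cause of missed diagnoses under strict rarity filtering).
    """
    predicted = _predicted_pairs(result.findings)
    rows = []
    for e in truth.entries:
        if (e.sample_id, e.key) in predicted:
            continue
        reason = "not_observed_in_vcf"
        for rej in result.rejections:
            if rej.key == e.key and rej.sample_id in (None, e.sample_id):
                reason = rej.reason
                break
        rows.append(
            {
                "sample_id": e.sample_id,
                "variant": str(e.key),
                "gene_symbol": e.gene_symbol,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "variant", "gene_symbol", "reason"])
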