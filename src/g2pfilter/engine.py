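"""The core panel filter: variant validity, genotype aggregation, cohort runs.

For every record of a decomposed, normalised, CSQ-annotated multi-sample
VCF the engine (a) parses the transcript annotations, (b) quality-resets
each sample's genotype, (c) tests the variant against every reportable
panel thread for its gene — transcript choice, consequence class, minor
allele frequency — and (d) aggregates the surviving (sample, thread)
variants into gene findings by allelic requirement:

* monoallelic-like threads: one altered allele suffices;
* biallelic threads: a homozygote, or two different heterozygous sites
  (a *possible* compound heterozygote — phase is not resolved);
* hemizygous threads: a hemizygous or homozygous-alt call; a heterozygous
  call on X counts only for female or unknown-sex samples;
* digenic / mitochondrial / uncertain threads are reported but never
  satisfied by this engine.

MAF thresholds are strict less-than, with the stricter cut-off (default
1:10,000) for single-allele requirements and a looser one (default 0.005)
for biallelic threads.  Every drop is logged with a reason code so missed
diagnoses can be traced to the rule responsible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .annotation import (
    TranscriptConsequence,
    allowed_classes,
    classify_consequence,
    max_population_af,
    parse_csq,
    parse_csq_format,
    severity_rank,
)
from .errors import FormatError, ValidationError
from .panel import LGMDET, Panel, reportable_entries
from .quality import GenotypeCall, QualityThresholds, reset_low_quality_calls
from .vocab import (
    MONOALLELIC_LIKE,
    UNSUPPORTED_REQUIREMENTS,
    AllelicRequirement,
    Confidence,
    ConsequenceClass,
    MutationConsequence,
    Sex,
    Zygosity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "VariantKey",
    "QualifiedVariant",
    "GeneFinding",
    "FilterResult",
    "variant_is_valid",
    "aggregate_gene_findings",
    "filter_cohort",
    "collect_candidates",
    "findings_to_frame",
    "write_findings_tsv",
    "read_findings_tsv",
    "read_sex_table",
]

# Reason codes attached to rejected variants/genotypes.
REASON_NOT_CANONICAL = "not_canonical_transcript"
REASON_CLASS_NOT_ALLOWED = "consequence_class_not_allowed"
REASON_MAF = "maf_above_threshold"
REASON_DISCORDANT = "sift_polyphen_not_concordant"
REASON_MECHANISM_UNSUPPORTED = "mechanism_not_detectable_from_coding_consequences"
REASON_REQUIREMENT_UNSUPPORTED = "allelic_requirement_not_supported"
REASON_LOW_QUALITY = "genotype_reset_low_quality"
REASON_NOT_CARRIER = "genotype_not_alt_carrier"
REASON_GENE_NOT_IN_PANEL = "gene_not_in_reportable_panel"
REASON_REQUIREMENT_NOT_MET = "allelic_requirement_not_met"


@dataclass(frozen=True)
class FilterConfig:
    """Tunable filter parameters.

    ``maf_monoallelic`` (default 1e-4, i.e. 1:10,000) applies to threads
    where one altered allele suffices; ``maf_biallelic`` (default 5e-3)
    to biallelic threads.  ``canonical_only`` restricts to canonical
    transcripts.  ``require_sift_polyphen_concordance`` optionally demands
    SIFT-deleterious *and* PolyPhen-damaging agreement for missense.
    """

    maf_monoallelic: float = 1e-4
    maf_biallelic: float = 5e-3
    canonical_only: bool = True
    require_sift_polyphen_concordance: bool = False
    allowed_class_overrides: Mapping[MutationConsequence, frozenset[ConsequenceClass]] | None = None
    quality: QualityThresholds = field(default_factory=QualityThresholds)

    def __post_init__(self):
        if not 0.0 <= self.maf_monoallelic <= self.maf_biallelic <= 1.0:
            raise ValidationError(
                "need 0 <= maf_monoallelic <= maf_biallelic <= 1, got "
                f"{self.maf_monoallelic} / {self.maf_biallelic}"
            )

    def maf_threshold(self, requirement: AllelicRequirement) -> float:
        return (
            self.maf_biallelic
            if requirement is AllelicRequirement.BIALLELIC
            else self.maf_monoallelic
        )


@dataclass(frozen=True, order=True)
class VariantKey:
    """Variant identity in VCF convention (1-based, decomposed)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class QualifiedVariant:
    """A variant that passed all thread-level filters for one sample."""

    key: VariantKey
    lgmdet: LGMDET
    annotation: TranscriptConsequence
    consequence_class: ConsequenceClass
    max_af: float
    zygosity: Zygosity

    def __post_init__(self):
        if self.zygosity in (Zygosity.HOM_REF, Zygosity.NO_CALL):
            raise ValidationError("a qualified variant must carry an alternate allele")


@dataclass
class GeneFinding:
    """Per (sample, panel-thread) result: qualifying variants and the verdict."""

    sample_id: str
    lgmdet: LGMDET
    qualifying_variants: list[QualifiedVariant]
    requirement_satisfied: bool
    genotype_pattern: str  # single_het | hom_alt | two_or_more_hets | hemizygous_alt | not_satisfied
    reason: str = ""

    @property
    def incidental_flag(self) -> bool:
        return self.lgmdet.incidental_flag

    @property
    def gene_symbol(self) -> str:
        return self.lgmdet.gene_symbol


def variant_is_valid(
    tc: TranscriptConsequence, lgmdet: LGMDET, cfg: FilterConfig = FilterConfig()
) -> tuple[bool, str]:
    """Is this transcript annotation a valid candidate for this panel thread?

    Checks, in order: canonical transcript (if required), consequence
    class allowed for the thread's mechanism, maximum population AF
    strictly below the requirement's threshold, and (optionally)
    SIFT/PolyPhen concordance for missense.  Returns ``(verdict, reason)``
    where the reason names the first failing criterion (empty on pass).
    """
    if tc.gene_symbol != lgmdet.gene_symbol:
        raise ValidationError(
            f"annotation gene {tc.gene_symbol!r} does not match thread gene {lgmdet.gene_symbol!r}"
        )
    allowed = allowed_classes(lgmdet.mutation_consequence, cfg.allowed_class_overrides)
    if not allowed:
        return False, REASON_MECHANISM_UNSUPPORTED
    if cfg.canonical_only and not tc.is_canonical:
        return False, REASON_NOT_CANONICAL
    cls = classify_consequence(tc.so_terms)
    if cls not in allowed:
        return False, REASON_CLASS_NOT_ALLOWED
    threshold = cfg.maf_threshold(lgmdet.allelic_requirement)
    if not _af_passes(max_population_af(tc), threshold):
        return False, REASON_MAF
    if (
        cfg.require_sift_polyphen_concordance
        and cls is ConsequenceClass.MISSENSE
        and not (tc.sift_deleterious and tc.polyphen_damaging)
    ):
        return False, REASON_DISCORDANT
    return True, ""


def _af_passes(max_af: float, threshold: float) -> bool:
    """Strict less-than; threshold 0 admits only alleles unseen everywhere."""
    if threshold == 0.0:
        return max_af == 0.0
    return max_af < threshold


def aggregate_gene_findings(
    sample_id: str,
    lgmdet: LGMDET,
    variants: Sequence[QualifiedVariant],
    sex: Sex = Sex.UNKNOWN,
) -> GeneFinding:
    """Decide whether a sample's qualifying variants satisfy the allelic requirement."""
    req = lgmdet.allelic_requirement
    vs = list(variants)
    hets = [v for v in vs if v.zygosity is Zygosity.HET]
    homs = [v for v in vs if v.zygosity is Zygosity.HOM_ALT]
    hemis = [v for v in vs if v.zygosity is Zygosity.HEMI]
    n_het_sites = len({v.key for v in hets})

    satisfied, pattern, reason = False, "not_satisfied", ""
    if req in UNSUPPORTED_REQUIREMENTS:
        reason = REASON_REQUIREMENT_UNSUPPORTED
    elif req is AllelicRequirement.BIALLELIC:
        if homs:
            satisfied, pattern = True, "hom_alt"
        elif n_het_sites >= 2:
            satisfied, pattern = True, "two_or_more_hets"
        else:
            reason = REASON_REQUIREMENT_NOT_MET
    elif req is AllelicRequirement.HEMIZYGOUS:
        if hemis:
            satisfied, pattern = True, "hemizygous_alt"
        elif homs:
            satisfied, pattern = True, "hom_alt"
        elif hets and sex in (Sex.FEMALE, Sex.UNKNOWN):
            satisfied, pattern = True, "single_het"
        else:
            reason = REASON_REQUIREMENT_NOT_MET
    elif req in MONOALLELIC_LIKE:
        # one altered allele suffices; pattern records the strongest genotype seen
        if homs:
            satisfied, pattern = True, "hom_alt"
        elif hemis:
            satisfied, pattern = True, "hemizygous_alt"
        elif hets:
            satisfied, pattern = True, "single_het"
        else:
            reason = REASON_REQUIREMENT_NOT_MET
    else:  # pragma: no cover - vocabulary is closed
        reason = REASON_REQUIREMENT_UNSUPPORTED
    return GeneFinding(sample_id, lgmdet, vs, satisfied, pattern, reason)


@dataclass(frozen=True)
class Rejection:
    """One dropped (variant, thread[, sample]) with the rule that dropped it."""

    key: VariantKey
    gene_symbol: str
    sample_id: str | None
    reason: str


@dataclass(frozen=True)
class Candidate:
    """A per-(sample, thread, site) variant that passed every rule except MAF.

    Candidates carry their max population AF so MAF thresholds can be
    applied (and swept) after a single collection pass.
    """

    sample_id: str
    lgmdet: LGMDET
    key: VariantKey
    annotation: TranscriptConsequence
    consequence_class: ConsequenceClass
    max_af: float
    zygosity: Zygosity

    def qualify(self) -> QualifiedVariant:
        return QualifiedVariant(
            self.key, self.lgmdet, self.annotation, self.consequence_class, self.max_af, self.zygosity
        )


@dataclass
class CandidateSet:
    """Output of one VCF collection pass, before MAF thresholding."""

    candidates: list[Candidate]
    rejections: list[Rejection]
    samples: list[str]
    n_records: int


@dataclass
class FilterResult:
    """Findings plus the per-sample summary and the drop log."""

    findings: list[GeneFinding]
    per_sample: pd.DataFrame
    rejections: list[Rejection]
    samples: list[str]

    @property
    def satisfied(self) -> list[GeneFinding]:
        return [f for f in self.findings if f.requirement_satisfied]


def read_sex_table(path: str | Path) -> dict[str, Sex]:
    """Read sample sex from a 6-column PED-style table (sex: 1=male, 2=female)."""
    out: dict[str, Sex] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"PED line has {len(parts)} columns, expected >= 5: {line!r}")
            out[parts[1]] = Sex.parse(parts[4])
    return out


def _zygosity_from_gt(alleles: tuple) -> Zygosity:
    """Map a pysam GT tuple to zygosity (single-alt records only)."""
    if alleles is None or all(a is None for a in alleles):
        return Zygosity.NO_CALL
    observed = [a for a in alleles if a is not None]
    if len(observed) < len(alleles):
        return Zygosity.NO_CALL
    if len(observed) == 1:
        return Zygosity.HEMI if observed[0] == 1 else Zygosity.HOM_REF
    if all(a == 0 for a in observed):
        return Zygosity.HOM_REF
    if all(a == 1 for a in observed):
        return Zygosity.HOM_ALT
    return Zygosity.HET


def _call_from_record(rec, sample: str) -> GenotypeCall:
    fmt = rec.samples[sample]
    gt = _zygosity_from_gt(fmt.get("GT"))
    ad = fmt.get("AD")
    ad_alt = None
    if ad is not None and len(ad) >= 2 and ad[1] is not None:
        ad_alt = int(ad[1])
    mq = rec.info.get("MQ")
    if isinstance(mq, tuple):
        mq = mq[0] if mq else None
    gq = fmt.get("GQ")
    dp = fmt.get("DP")
    return GenotypeCall(
        sample_id=sample,
        gt=gt,
        gq=float(gq) if gq is not None else None,
        dp=int(dp) if dp is not None else None,
        ad_alt=ad_alt,
        mq=float(mq) if mq is not None else None,
    )


def _choose_annotation(
    tcs: Sequence[TranscriptConsequence], allowed: frozenset[ConsequenceClass], cfg: FilterConfig
) -> tuple[TranscriptConsequence | None, str]:
    """Pick the winning transcript annotation for one (variant, thread).

    Among annotations whose class is allowed (and concordant, when that
    sub-filter is on): the canonical one wins, else the most severe
    class, ties broken by transcript identifier for determinism.  Returns
    (None, reason) when nothing is eligible.
    """
    eligible = []
    saw_class_pass = False
    for tc in tcs:
        if cfg.canonical_only and not tc.is_canonical:
            continue
        cls = classify_consequence(tc.so_terms)
        if cls not in allowed:
            continue
        saw_class_pass = True
        if (
            cfg.require_sift_polyphen_concordance
            and cls is ConsequenceClass.MISSENSE
            and not (tc.sift_deleterious and tc.polyphen_damaging)
        ):
            continue
        eligible.append((tc, cls))
    if not eligible:
        if cfg.canonical_only and not any(tc.is_canonical for tc in tcs):
            return None, REASON_NOT_CANONICAL
        if not saw_class_pass:
            return None, REASON_CLASS_NOT_ALLOWED
        return None, REASON_DISCORDANT
    eligible.sort(
        key=lambda e: (not e[0].is_canonical, severity_rank(e[1]), e[0].transcript_id)
    )
    return eligible[0][0], ""


def collect_candidates(
    vcf_path: str | Path,
    panel: Panel,
    cfg: FilterConfig = FilterConfig(),
    sex_table: Mapping[str, Sex] | None = None,
) -> CandidateSet:
    """Single pass over the VCF collecting pre-MAF candidates and rejections.

    Raises :class:`~g2pfilter.errors.FormatError` for a missing CSQ header
    declaration or an un-decomposed multi-allelic record.
    """
    panel = reportable_entries(panel)
    vcf = pysam.VariantFile(str(vcf_path))
    if "CSQ" not in vcf.header.info:
        raise FormatError(f"{vcf_path}: no CSQ INFO declaration in header")
    csq_fields = parse_csq_format(vcf.header.info["CSQ"].description)
    samples = list(vcf.header.samples)

    candidates: list[Candidate] = []
    rejections: list[Rejection] = []
    n_records = 0
    for rec in vcf:
        n_records += 1
        where = f"{rec.chrom}:{rec.pos}"
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(
                f"{where}: record is not decomposed (found {0 if rec.alts is None else len(rec.alts)} alts)"
            )
        key = VariantKey(rec.chrom, rec.pos, rec.ref, rec.alts[0])
        tcs = parse_csq(csq_fields, rec.info.get("CSQ"), where=where)
        by_gene: dict[str, list[TranscriptConsequence]] = {}
        for tc in tcs:
            by_gene.setdefault(tc.gene_symbol, []).append(tc)

        # thread-level decisions are sample-independent: do them once
        per_thread: list[tuple[LGMDET, TranscriptConsequence, ConsequenceClass, float]] = []
        for gene, gene_tcs in by_gene.items():
            threads = panel.entries_for_gene(gene)
            if not threads:
                rejections.append(Rejection(key, gene, None, REASON_GENE_NOT_IN_PANEL))
                continue
            for lgmdet in threads:
                allowed = allowed_classes(lgmdet.mutation_consequence, cfg.allowed_class_overrides)
                if not allowed:
                    rejections.append(
                        Rejection(key, gene, None, REASON_MECHANISM_UNSUPPORTED)
                    )
                    continue
                tc, reason = _choose_annotation(gene_tcs, allowed, cfg)
                if tc is None:
                    rejections.append(Rejection(key, gene, None, reason))
                    continue
                per_thread.append((lgmdet, tc, classify_consequence(tc.so_terms), max_population_af(tc)))

        if not per_thread:
            continue
        for sample in samples:
            call = _call_from_record(rec, sample)
            reset = reset_low_quality_calls(call, cfg.quality)
            if reset.gt is Zygosity.NO_CALL and call.gt is not Zygosity.NO_CALL:
                rejections.append(Rejection(key, "", sample, REASON_LOW_QUALITY))
                continue
            if not reset.gt.carries_alt:
                continue
            for lgmdet, tc, cls, af in per_thread:
                candidates.append(
                    Candidate(sample, lgmdet, key, tc, cls, af, reset.gt)
                )
    return CandidateSet(candidates, rejections, samples, n_records)


def _thread_key(lgmdet: LGMDET) -> tuple:
    return (
        lgmdet.gene_symbol,
        lgmdet.disease_name,
        lgmdet.allelic_requirement.value,
        lgmdet.mutation_consequence.value,
        lgmdet.confidence.value,
    )


def findings_from_candidates(
    cset: CandidateSet,
    cfg: FilterConfig = FilterConfig(),
    sex_table: Mapping[str, Sex] | None = None,
) -> FilterResult:
    """Apply MAF thresholds to a candidate set and aggregate gene findings."""
    sex_table = sex_table or {}
    grouped: dict[tuple, list[Candidate]] = {}
    rejections = list(cset.rejections)
    for c in cset.candidates:
        threshold = cfg.maf_threshold(c.lgmdet.allelic_requirement)
        if not _af_passes(c.max_af, threshold):
            rejections.append(Rejection(c.key, c.lgmdet.gene_symbol, c.sample_id, REASON_MAF))
            continue
        grouped.setdefault((c.sample_id,) + _thread_key(c.lgmdet), []).append(c)

    findings = []
    for key in sorted(grouped):
        group = grouped[key]
        sample_id = group[0].sample_id
        lgmdet = group[0].lgmdet
        variants = sorted((c.qualify() for c in group), key=lambda v: v.key)
        findings.append(
            aggregate_gene_findings(
                sample_id, lgmdet, variants, sex_table.get(sample_id, Sex.UNKNOWN)
            )
        )
    per_sample = _per_sample_summary(findings, cset.samples)
    return FilterResult(findings, per_sample, rejections, cset.samples)


def filter_cohort(
    vcf_path: str | Path,
    panel: Panel,
    cfg: FilterConfig = FilterConfig(),
    sex_table: Mapping[str, Sex] | None = None,
) -> FilterResult:
    """Run the full filter over an annotated multi-sample VCF.

    Equivalent to :func:`collect_candidates` followed by
    :func:`findings_from_candidates`; the two-stage form exists so that
    MAF sweeps can reuse one collection pass.
    """
    cset = collect_candidates(vcf_path, panel, cfg, sex_table)
    return findings_from_candidates(cset, cfg, sex_table)


def _per_sample_summary(findings: Sequence[GeneFinding], samples: Sequence[str]) -> pd.DataFrame:
    """Per-sample counts of qualifying SNVs and indels (unique sites) and findings."""
    rows = []
    by_sample: dict[str, list[GeneFinding]] = {s: [] for s in samples}
    for f in findings:
        by_sample.setdefault(f.sample_id, []).append(f)
    for s in samples:
        fs = by_sample[s]
        keys = {v.key for f in fs for v in f.qualifying_variants}
        rows.append(
            {
                "sample_id": s,
                "n_findings": len(fs),
                "n_findings_satisfied": sum(f.requirement_satisfied for f in fs),
                "n_snvs": sum(k.is_snv for k in keys),
                "n_indels": sum(not k.is_snv for k in keys),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Findings serialisation (TSV long format: one row per finding-variant;
# findings without qualifying variants keep one row with empty variant cells)
# ---------------------------------------------------------------------------

_FINDING_COLS = [
    "sample_id",
    "gene_symbol",
    "disease_name",
    "confidence",
    "allelic_requirement",
    "mutation_consequence",
    "requirement_satisfied",
    "genotype_pattern",
    "incidental_flag",
    "reason",
    "chrom",
    "pos",
    "ref",
    "alt",
    "zygosity",
    "consequence_class",
    "max_af",
    "cadd_phred",
    "transcript_id",
    "is_canonical",
]


def findings_to_frame(findings: Sequence[GeneFinding]) -> pd.DataFrame:
    rows = []
    for f in findings:
        base = {
            "sample_id": f.sample_id,
            "gene_symbol": f.gene_symbol,
            "disease_name": f.lgmdet.disease_name,
            "confidence": f.lgmdet.confidence.value,
            "allelic_requirement": f.lgmdet.allelic_requirement.value,
            "mutation_consequence": f.lgmdet.mutation_consequence.value,
            "requirement_satisfied": f.requirement_satisfied,
            "genotype_pattern": f.genotype_pattern,
            "incidental_flag": f.incidental_flag,
            "reason": f.reason,
        }
        if not f.qualifying_variants:
            rows.append({**base, "chrom": "", "pos": "", "ref": "", "alt": "", "zygosity": "",
                         "consequence_class": "", "max_af": "", "cadd_phred": "",
                         "transcript_id": "", "is_canonical": ""})
        for v in f.qualifying_variants:
            rows.append(
                {
                    **base,
                    "chrom": v.key.chrom,
                    "pos": v.key.pos,
                    "ref": v.key.ref,
                    "alt": v.key.alt,
                    "zygosity": v.zygosity.value,
                    "consequence_class": v.consequence_class.value,
                    "max_af": repr(v.max_af),
                    "cadd_phred": "" if v.annotation.cadd_phred is None else repr(v.annotation.cadd_phred),
                    "transcript_id": v.annotation.transcript_id,
                    "is_canonical": v.annotation.is_canonical,
                }
            )
    return pd.DataFrame(rows, columns=_FINDING_COLS)


def write_findings_tsv(findings: Sequence[GeneFinding], path: str | Path) -> None:
    findings_to_frame(findings).to_csv(path, sep="\t", index=False)


def write_findings_json(findings: Sequence[GeneFinding], path: str | Path) -> None:
    findings_to_frame(findings).to_json(path, orient="records", indent=2)


def read_findings_tsv(path: str | Path) -> list[GeneFinding]:
    """Rebuild findings from the TSV written by :func:`write_findings_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    findings: dict[tuple, GeneFinding] = {}
    for _, row in df.iterrows():
        lgmdet = LGMDET(
            gene_symbol=row["gene_symbol"],
            disease_name=row["disease_name"],
            confidence=Confidence.parse(row["confidence"]),
            allelic_requirement=AllelicRequirement.parse(row["allelic_requirement"]),
            mutation_consequence=MutationConsequence.parse(row["mutation_consequence"]),
        )
        fkey = (row["sample_id"],) + _thread_key(lgmdet)
        if fkey not in findings:
            findings[fkey] = GeneFinding(
                sample_id=row["sample_id"],
                lgmdet=lgmdet,
                qualifying_variants=[],
                requirement_satisfied=row["requirement_satisfied"] == "True",
                genotype_pattern=row["genotype_pattern"],
                reason=row["reason"],
            )
        if row["chrom"]:
            tc = TranscriptConsequence(
                allele=row["alt"],
                gene_symbol=row["gene_symbol"],
                transcript_id=row["transcript_id"],
                so_terms=("unavailable_from_tsv",),
                is_canonical=row["is_canonical"] == "True",
                cadd_phred=float(row["cadd_phred"]) if row["cadd_phred"] else None,
            )
            findings[fkey].qualifying_variants.append(
                QualifiedVariant(
                    key=VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                    lgmdet=lgmdet,
                    annotation=tc,
                    consequence_class=ConsequenceClass.parse(row["consequence_class"]),
                    max_af=float(row["max_af"]),
                    zygosity=Zygosity.parse(row["zygosity"]),
                )
            )
    return list(findings.values())
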