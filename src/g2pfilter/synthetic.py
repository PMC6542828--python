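"""Synthetic panels, annotated cohort VCFs and truth sets.

The generator emulates the inputs of a panel-filtering study without any
managed-access data: a curated gene panel, a decomposed/normalised
multi-sample VCF annotated with per-transcript CSQ blocks (consequence
terms, canonical flag, SIFT/PolyPhen, CADD, population AFs), a PED-style
sex table, and the truth set of planted causative variants.

Case samples receive planted causative genotypes that respect their
target thread's allelic requirement (het for monoallelic; hom-alt or two
het sites for biallelic; hemizygous-male for X threads).  All samples
additionally receive background variation whose allele-frequency spectrum
straddles the filter thresholds and whose quality fields sometimes fail
the genotype resets — so a configurable expected number of *qualifying*
background variants per sample survives filtering, emulating the
background noise a control cohort reveals.

Everything is deterministic under the seed: the same configuration
produces byte-identical VCF/PED/panel/truth files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .engine import GeneFinding, QualifiedVariant, VariantKey, aggregate_gene_findings
from .annotation import TranscriptConsequence
from .errors import ValidationError
from .evaluation import TruthEntry, TruthSet
from .panel import LGMDET, Panel, write_g2p_csv
from .vocab import (
    MONOALLELIC_LIKE,
    AllelicRequirement,
    Confidence,
    ConsequenceClass,
    MutationConsequence,
    Zygosity,
)

__all__ = [
    "AFSpectrum",
    "QualityModel",
    "SimulationConfig",
    "generate_panel",
    "generate_cohort",
    "generate_worked_confusion",
    "CSQ_FIELDS",
]

CSQ_FIELDS = (
    "Allele|Consequence|SYMBOL|Gene|Feature|CANONICAL|SIFT|PolyPhen|"
    "CADD_PHRED|AF|gnomAD_AF|UK10K_AF|TOPMed_AF"
)

_AF_SOURCES = ("AF", "gnomAD_AF", "UK10K_AF", "TOPMed_AF")

_CONTIGS = {"1": 50_000_000, "2": 50_000_000, "X": 50_000_000}


@dataclass(frozen=True)
class AFSpectrum:
    """Population-AF distribution for background alleles.

    A point mass at 0 models alleles unseen in every reference cohort;
    the remainder is log-uniform across a range that straddles both MAF
    thresholds, so every cut-off has variants on both sides.
    """

    p_unseen: float = 0.6
    log10_min: float = -6.0
    log10_max: float = -3.0

    def draw(self, rng: np.random.Generator) -> float:
        if rng.random() < self.p_unseen:
            return 0.0
        return float(10.0 ** rng.uniform(self.log10_min, self.log10_max))

    def p_below(self, threshold: float) -> float:
        """P(AF passes a strict < threshold filter; threshold 0 = unseen only)."""
        if threshold <= 0.0:
            return self.p_unseen
        span = self.log10_max - self.log10_min
        frac = (math.log10(threshold) - self.log10_min) / span
        return self.p_unseen + (1.0 - self.p_unseen) * min(1.0, max(0.0, frac))


@dataclass(frozen=True)
class QualityModel:
    """Genotype-quality distribution for background calls.

    With probability ``p_low_quality`` a call is given exactly one
    failing quality field (GQ, DP, alt-fraction or MQ below its reset
    threshold); otherwise all fields comfortably pass.
    """

    p_low_quality: float = 0.1

    @property
    def p_pass(self) -> float:
        return 1.0 - self.p_low_quality


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``background_rate`` is the expected number of background variants per
    sample that *survive* filtering (the generator inflates the raw event
    rate by the analytic acceptance probability of the AF spectrum and
    quality model).  ``planted_fraction`` of case samples receive one
    causative genotype; ``n_high_af_planted`` of those are deliberately
    given a population AF of 2e-4 — above the 1:10,000 monoallelic
    cut-off — to model causative variants lost to the rarity filter.
    """

    seed: int = 0
    n_case_samples: int = 50
    n_control_samples: int = 50
    panel_spec: Mapping[tuple[str, str], int] | None = None
    planted_fraction: float = 1.0
    background_rate: float = 2.0
    compound_het_fraction: float = 0.5
    n_high_af_planted: int = 0
    indel_fraction: float = 0.12
    offpanel_rate: float = 0.5
    af_spectrum: AFSpectrum = field(default_factory=AFSpectrum)
    quality_model: QualityModel = field(default_factory=QualityModel)
    maf_threshold_for_calibration: float = 1e-4

    def __post_init__(self):
        for name in ("planted_fraction", "compound_het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.background_rate < 0 or self.offpanel_rate < 0:
            raise ValidationError("rates must be >= 0")

    def acceptance_probability(self) -> float:
        """Analytic P(a background event survives AF + quality filtering)."""
        return (
            self.af_spectrum.p_below(self.maf_threshold_for_calibration)
            * self.quality_model.p_pass
        )


DEFAULT_PANEL_SPEC: dict[tuple[str, str], int] = {
    ("monoallelic", "loss_of_function"): 6,
    ("monoallelic", "all_missense_in_frame"): 2,
    ("monoallelic", "activating"): 1,
    ("biallelic", "loss_of_function"): 4,
    ("biallelic", "all_missense_in_frame"): 2,
    ("hemizygous", "loss_of_function"): 2,
    ("digenic", "uncertain"): 1,
}


def generate_panel(cfg: SimulationConfig) -> Panel:
    """Generate a panel matching ``cfg.panel_spec`` (counts per cell).

    Deterministic under the seed.  Confidences are drawn mostly
    confirmed/probable; the output always contains at least one
    possible-confidence entry (exercising reportability) and one entry
    relevant both to the referred disease and incidentally.
    """
    spec = dict(DEFAULT_PANEL_SPEC if cfg.panel_spec is None else cfg.panel_spec)
    if not spec:
        raise ValidationError("panel_spec must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    entries: list[LGMDET] = []
    gene_no = 0
    for (req, mc), count in sorted(spec.items()):
        for _ in range(count):
            gene_no += 1
            confidence = Confidence.CONFIRMED if rng.random() < 0.8 else Confidence.PROBABLE
            entries.append(
                LGMDET(
                    gene_symbol=f"GENE{gene_no:04d}",
                    disease_name=f"SYNTHETIC DISORDER {gene_no}",
                    confidence=confidence,
                    allelic_requirement=AllelicRequirement.parse(req),
                    mutation_consequence=MutationConsequence.parse(mc),
                    hpo_terms=(f"HP:{rng.integers(1, 9999):07d}",),
                    pmids=(str(rng.integers(10_000_000, 30_000_000)),),
                )
            )
    # guarantee vocabulary coverage needed downstream
    gene_no += 1
    entries.append(
        LGMDET(
            gene_symbol=f"GENE{gene_no:04d}",
            disease_name=f"SYNTHETIC DISORDER {gene_no}",
            confidence=Confidence.POSSIBLE,
            allelic_requirement=AllelicRequirement.MONOALLELIC,
            mutation_consequence=MutationConsequence.LOSS_OF_FUNCTION,
        )
    )
    gene_no += 1
    entries.append(
        LGMDET(
            gene_symbol=f"GENE{gene_no:04d}",
            disease_name=f"SYNTHETIC DISORDER {gene_no} (incidental)",
            confidence=Confidence.BOTH_RD_AND_IF,
            allelic_requirement=AllelicRequirement.BIALLELIC,
            mutation_consequence=MutationConsequence.LOSS_OF_FUNCTION,
        )
    )
    return Panel(name=f"synthetic-panel-seed{cfg.seed}", entries=entries)


class _GeneMap:
    """Assign genes to contigs/base positions and allocate unique sites."""

    def __init__(self, panel: Panel):
        self.base: dict[str, tuple[str, int]] = {}
        self._next_offset: dict[str, int] = {}
        autosome_toggle = 0
        for i, gene in enumerate(sorted({e.gene_symbol for e in panel})):
            reqs = {e.allelic_requirement for e in panel.entries_for_gene(gene)}
            x_linked = reqs & {
                AllelicRequirement.HEMIZYGOUS,
                AllelicRequirement.X_LINKED_DOMINANT,
                AllelicRequirement.X_LINKED_OVER_DOMINANCE,
            }
            if x_linked:
                chrom = "X"
            else:
                chrom = "1" if autosome_toggle % 2 == 0 else "2"
                autosome_toggle += 1
            self.base[gene] = (chrom, 1_000_000 + i * 100_000)
            self._next_offset[gene] = 0

    def register(self, gene: str, chrom: str = "1") -> None:
        if gene not in self.base:
            i = len(self.base)
            self.base[gene] = (chrom, 1_000_000 + i * 100_000)
            self._next_offset[gene] = 0

    def new_site(self, gene: str) -> tuple[str, int]:
        chrom, base = self.base[gene]
        off = self._next_offset[gene]
        self._next_offset[gene] = off + 10
        return chrom, base + off


def _csq_block(
    gene: str,
    transcript: str,
    consequence: str,
    canonical: bool,
    sift: str,
    polyphen: str,
    cadd: str,
    afs: Mapping[str, float],
    alt: str,
) -> str:
    af_cells = {s: (_format_af(afs[s]) if s in afs else "") for s in _AF_SOURCES}
    return "|".join(
        [
            alt,
            consequence,
            gene,
            f"ENSG_{gene}",
            transcript,
            "YES" if canonical else "",
            sift,
            polyphen,
            cadd,
            af_cells["AF"],
            af_cells["gnomAD_AF"],
            af_cells["UK10K_AF"],
            af_cells["TOPMed_AF"],
        ]
    )


def _format_af(af: float) -> str:
    return np.format_float_positional(af, trim="-")


@dataclass
class _Record:
    chrom: str
    pos: int
    ref: str
    alt: str
    mq: float | None
    csq: list[str]
    genotypes: dict[str, str]  # sample -> GT:GQ:DP:AD string


def _good_format(zyg: str, rng: np.random.Generator) -> str:
    dp = int(rng.integers(20, 41))
    if zyg == "het":
        ad_alt = dp // 2
        gt = "0/1"
    elif zyg == "hom_alt":
        ad_alt = dp
        gt = "1/1"
    elif zyg == "hemi_alt":
        ad_alt = dp
        gt = "1"
    else:
        raise ValueError(zyg)
    gq = int(rng.integers(40, 100))
    return f"{gt}:{gq}:{dp}:{dp - ad_alt},{ad_alt}"


def _low_quality_format(rng: np.random.Generator) -> tuple[str, float | None]:
    """A het call failing exactly one quality rule; returns (FORMAT, record MQ)."""
    mode = rng.integers(0, 4)
    if mode == 0:  # GQ below 13
        return "0/1:8:30:15,15", None
    if mode == 1:  # DP below 5
        return "0/1:60:3:2,1", None
    if mode == 2:  # alt fraction below 0.2
        return "0/1:60:30:27,3", None
    return "0/1:60:30:15,15", 9.0  # MQ below 13


def _hom_ref_format(x_male: bool) -> str:
    return "0:50:30:30,0" if x_male else "0/0:50:30:30,0"


def _draw_af_sources(af: float, rng: np.random.Generator) -> dict[str, float]:
    if af <= 0:
        return {}
    n = int(rng.integers(1, 3))
    sources = rng.choice(len(_AF_SOURCES), size=n, replace=False)
    return {_AF_SOURCES[int(s)]: af for s in sources}


def _variant_alleles(indel: bool, rng: np.random.Generator) -> tuple[str, str]:
    bases = "ACGT"
    ref = bases[int(rng.integers(0, 4))]
    if indel:
        ins = bases[int(rng.integers(0, 4))]
        return ref, ref + ins
    alt = bases[int((rng.integers(1, 4) + bases.index(ref)) % 4)]
    return ref, alt


def _consequence_for(mc: MutationConsequence, indel: bool) -> str:
    if mc is MutationConsequence.LOSS_OF_FUNCTION:
        return "frameshift_variant" if indel else "stop_gained"
    return "inframe_insertion" if indel else "missense_variant"


def _annotation_cells(consequence: str, rng: np.random.Generator) -> tuple[str, str, str]:
    """SIFT / PolyPhen / CADD cells appropriate to the consequence term."""
    if consequence == "missense_variant":
        sift = f"deleterious({rng.uniform(0, 0.05):.3f})"
        polyphen = f"probably_damaging({rng.uniform(0.9, 1.0):.3f})"
        cadd = f"{rng.uniform(15.0, 45.0):.1f}"
        if rng.random() < 0.2:  # discordant predictions occur in real data
            sift = f"tolerated({rng.uniform(0.2, 1.0):.3f})"
        return sift, polyphen, cadd
    if consequence in ("stop_gained", "frameshift_variant"):
        return "", "", f"{rng.uniform(25.0, 50.0):.1f}"
    return "", "", ""


def generate_cohort(
    cfg: SimulationConfig, panel: Panel, out_dir: str | Path
) -> tuple[Path, Path, TruthSet]:
    """Write the cohort VCF and PED under ``out_dir``; return their paths
    and the truth set of planted causative variants.

    Case samples are named ``CASE####``, controls ``CTRL####``.  Samples
    planted with an X-linked hemizygous genotype are forced male in the
    PED so the genotype is written as a true single-allele call.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    cases = [f"CASE{i:04d}" for i in range(1, cfg.n_case_samples + 1)]
    controls = [f"CTRL{i:04d}" for i in range(1, cfg.n_control_samples + 1)]
    samples = cases + controls
    sex = {s: ("male" if rng.random() < 0.5 else "female") for s in samples}

    gmap = _GeneMap(panel)
    reportable = [e for e in panel if e.reportable]
    plantable = [
        e
        for e in reportable
        if e.allelic_requirement
        in (
            AllelicRequirement.MONOALLELIC,
            AllelicRequirement.BIALLELIC,
            AllelicRequirement.HEMIZYGOUS,
        )
    ]
    if not plantable:
        raise ValidationError("panel has no plantable reportable entries")
    mono_plantable = [
        e for e in plantable if e.allelic_requirement is AllelicRequirement.MONOALLELIC
    ]
    background_pool = [
        e
        for e in reportable
        if e.allelic_requirement in MONOALLELIC_LIKE
        and e.allelic_requirement is AllelicRequirement.MONOALLELIC
    ]

    records: list[_Record] = []
    truth_entries: list[TruthEntry] = []

    def make_record(
        gene: str,
        lgmdet_mc: MutationConsequence,
        sample: str,
        zyg: str,
        af: float,
        low_quality: bool,
        extra_noncanonical: bool,
    ) -> _Record:
        indel = rng.random() < cfg.indel_fraction
        chrom, pos = gmap.new_site(gene)
        ref, alt = _variant_alleles(indel, rng)
        consequence = _consequence_for(lgmdet_mc, indel)
        sift, polyphen, cadd = _annotation_cells(consequence, rng)
        csq = [
            _csq_block(
                gene, f"ENST_{gene}_1", consequence, True, sift, polyphen, cadd,
                _draw_af_sources(af, rng), alt,
            )
        ]
        if extra_noncanonical:
            csq.append(
                _csq_block(
                    gene, f"ENST_{gene}_2", "intron_variant", False, "", "", "",
                    {}, alt,
                )
            )
        mq: float | None = float(rng.integers(40, 70))
        if low_quality:
            fmt, mq_override = _low_quality_format(rng)
            if mq_override is not None:
                mq = mq_override
        else:
            fmt = _good_format(zyg, rng)
        return _Record(chrom, pos, ref, alt, mq, csq, {sample: fmt})

    # --- planted causative genotypes -------------------------------------
    n_planted = round(cfg.planted_fraction * len(cases))
    n_high_af_assigned = 0
    for i, sample in enumerate(cases[:n_planted]):
        if n_high_af_assigned < cfg.n_high_af_planted and mono_plantable:
            target = mono_plantable[i % len(mono_plantable)]
            af: float = 2e-4  # above the 1:10,000 monoallelic cut-off
            n_high_af_assigned += 1
        else:
            target = plantable[i % len(plantable)]
            af = 0.0
        req = target.allelic_requirement
        if req is AllelicRequirement.MONOALLELIC:
            rec = make_record(target.gene_symbol, target.mutation_consequence, sample,
                              "het", af, False, rng.random() < 0.3)
            records.append(rec)
            truth_entries.append(
                TruthEntry(sample, VariantKey(rec.chrom, rec.pos, rec.ref, rec.alt),
                           target.gene_symbol, req.value)
            )
        elif req is AllelicRequirement.BIALLELIC:
            if rng.random() < cfg.compound_het_fraction:
                for _ in range(2):
                    rec = make_record(target.gene_symbol, target.mutation_consequence,
                                      sample, "het", af, False, rng.random() < 0.3)
                    records.append(rec)
                    truth_entries.append(
                        TruthEntry(sample, VariantKey(rec.chrom, rec.pos, rec.ref, rec.alt),
                                   target.gene_symbol, req.value)
                    )
            else:
                rec = make_record(target.gene_symbol, target.mutation_consequence, sample,
                                  "hom_alt", af, False, rng.random() < 0.3)
                records.append(rec)
                truth_entries.append(
                    TruthEntry(sample, VariantKey(rec.chrom, rec.pos, rec.ref, rec.alt),
                               target.gene_symbol, req.value)
                )
        else:  # hemizygous on X
            sex[sample] = "male"
            rec = make_record(target.gene_symbol, target.mutation_consequence, sample,
                              "hemi_alt", af, False, rng.random() < 0.3)
            records.append(rec)
            truth_entries.append(
                TruthEntry(sample, VariantKey(rec.chrom, rec.pos, rec.ref, rec.alt),
                           target.gene_symbol, req.value)
            )

    # --- background variation --------------------------------------------
    p_accept = cfg.acceptance_probability()
    raw_rate = cfg.background_rate / p_accept if p_accept > 0 else 0.0
    for sample in samples:
        n_events = int(rng.poisson(raw_rate)) if raw_rate > 0 else 0
        for _ in range(n_events):
            target = background_pool[int(rng.integers(0, len(background_pool)))]
            af = cfg.af_spectrum.draw(rng)
            low_q = rng.random() < cfg.quality_model.p_low_quality
            records.append(
                make_record(target.gene_symbol, target.mutation_consequence, sample,
                            "het", af, low_q, rng.random() < 0.3)
            )
        n_off = int(rng.poisson(cfg.offpanel_rate)) if cfg.offpanel_rate > 0 else 0
        for _ in range(n_off):
            gene = "OFFPANEL1"
            gmap.register(gene, "2")
            records.append(
                make_record(gene, MutationConsequence.LOSS_OF_FUNCTION, sample,
                            "het", cfg.af_spectrum.draw(rng), False, False)
            )

    # --- serialise ---------------------------------------------------------
    contig_order = {c: i for i, c in enumerate(_CONTIGS)}
    records.sort(key=lambda r: (contig_order[r.chrom], r.pos, r.ref, r.alt))

    vcf_path = out_dir / "cohort.vcf"
    with open(vcf_path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in _CONTIGS.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write(
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations '
            f'from variant annotation. Format: {CSQ_FIELDS}">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for rec in records:
            info = (f"MQ={rec.mq:.1f};" if rec.mq is not None else "") + "CSQ=" + ",".join(rec.csq)
            cells = []
            for s in samples:
                if s in rec.genotypes:
                    cells.append(rec.genotypes[s])
                else:
                    cells.append(_hom_ref_format(rec.chrom == "X" and sex[s] == "male"))
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t100\tPASS\t{info}\tGT:GQ:DP:AD\t"
                + "\t".join(cells)
                + "\n"
            )

    ped_path = out_dir / "cohort.ped"
    with open(ped_path, "w", encoding="utf-8") as fh:
        for s in samples:
            code = "1" if sex[s] == "male" else "2"
            phenotype = "2" if s.startswith("CASE") else "1"
            fh.write(f"FAM_{s}\t{s}\t0\t0\t{code}\t{phenotype}\n")

    truth = TruthSet(truth_entries)
    truth.write_tsv(out_dir / "truth.tsv")
    return vcf_path, ped_path, truth


def write_panel_csv(cfg: SimulationConfig, out_dir: str | Path) -> Path:
    """Generate a panel and write it to ``out_dir/panel.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "panel.csv"
    write_g2p_csv(generate_panel(cfg), path)
    return path


def generate_worked_confusion(
    truth_size: int, recovered: int, surviving: int
) -> tuple[list[GeneFinding], TruthSet]:
    """A minimal findings/truth pair with a prescribed confusion matrix.

    ``truth_size`` causative variants of which ``recovered`` are found,
    among ``surviving`` total variants passing the filter — so scoring
    yields tp=recovered, fn=truth_size−recovered, tp+fp=surviving.
    """
    if not 0 <= recovered <= truth_size:
        raise ValidationError("need 0 <= recovered <= truth_size")
    if surviving < recovered:
        raise ValidationError("surviving predictions cannot be fewer than recovered truths")
    lgmdet = LGMDET(
        gene_symbol="GENE_T",
        disease_name="SYNTHETIC WORKED EXAMPLE",
        confidence=Confidence.CONFIRMED,
        allelic_requirement=AllelicRequirement.MONOALLELIC,
        mutation_consequence=MutationConsequence.LOSS_OF_FUNCTION,
    )
    findings: list[GeneFinding] = []
    truth_entries: list[TruthEntry] = []

    def variant(pos: int) -> QualifiedVariant:
        key = VariantKey("1", pos, "A", "T")
        tc = TranscriptConsequence(
            allele="T", gene_symbol="GENE_T", transcript_id="ENST_T_1",
            so_terms=("stop_gained",), is_canonical=True,
        )
        return QualifiedVariant(key, lgmdet, tc, ConsequenceClass.LOF, 0.0, Zygosity.HET)

    for i in range(truth_size):
        sample = f"S{i + 1:05d}"
        key = VariantKey("1", 1000 + i, "A", "T")
        truth_entries.append(TruthEntry(sample, key, "GENE_T", "monoallelic"))
        if i < recovered:
            findings.append(
                aggregate_gene_findings(sample, lgmdet, [variant(1000 + i)])
            )
    for j in range(surviving - recovered):
        sample = f"X{j + 1:05d}"
        findings.append(
            aggregate_gene_findings(sample, lgmdet, [variant(500_000 + j)])
        )
    return findings, TruthSet(truth_entries)
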