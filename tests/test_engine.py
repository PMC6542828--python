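from __future__ import annotations

import itertools

import numpy as np
import pytest

from g2pfilter.annotation import TranscriptConsequence
from g2pfilter.engine import (
    REASON_CLASS_NOT_ALLOWED,
    REASON_MAF,
    REASON_NOT_CANONICAL,
    FilterConfig,
    GeneFinding,
    QualifiedVariant,
    VariantKey,
    aggregate_gene_findings,
    filter_cohort,
    findings_from_candidates,
    collect_candidates,
    read_findings_tsv,
    variant_is_valid,
    write_findings_tsv,
)
from g2pfilter.errors import FormatError, ValidationError
from g2pfilter.panel import LGMDET, Panel, reportable_entries
from g2pfilter.vocab import (
    AllelicRequirement,
    Confidence,
    ConsequenceClass,
    MutationConsequence,
    Sex,
    Zygosity,
)

from . import oracles


def thread(req=AllelicRequirement.MONOALLELIC, mc=MutationConsequence.LOSS_OF_FUNCTION,
           gene="G1"):
    return LGMDET(gene_symbol=gene, disease_name="D", confidence=Confidence.CONFIRMED,
                  allelic_requirement=req, mutation_consequence=mc)


def tc(gene="G1", terms=("stop_gained",), canonical=True, afs=None, transcript="ENST1",
       sift=None, polyphen=None):
    return TranscriptConsequence(
        allele="T", gene_symbol=gene, transcript_id=transcript, so_terms=tuple(terms),
        is_canonical=canonical, population_afs=afs or {},
        sift_prediction=sift, polyphen_prediction=polyphen,
    )


def qv(lgmdet, zyg=Zygosity.HET, pos=100, af=0.0, terms=("stop_gained",)):
    annotation = tc(gene=lgmdet.gene_symbol, terms=terms)
    cls = ConsequenceClass.LOF if "stop_gained" in terms else ConsequenceClass.MISSENSE
    return QualifiedVariant(VariantKey("1", pos, "A", "T"), lgmdet, annotation, cls, af, zyg)


class TestVariantIsValid:
    def test_common_allele_fails_monoallelic_rarity(self):
        ok, reason = variant_is_valid(tc(afs={"gnomAD_AF": 2e-4}), thread())
        assert not ok and reason == REASON_MAF

    def test_unseen_allele_passes_frequency(self):
        ok, reason = variant_is_valid(tc(terms=("missense_variant",)), thread())
        assert ok and reason == ""

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            variant_is_valid(tc(gene="OTHER"), thread())

    def test_noncanonical_rejected_when_canonical_only(self):
        ok, reason = variant_is_valid(tc(canonical=False), thread())
        assert not ok and reason == REASON_NOT_CANONICAL
        ok, _ = variant_is_valid(tc(canonical=False), thread(),
                                 FilterConfig(canonical_only=False))
        assert ok

    def test_grid_matches_independent_rule_evaluation(self):
        """Exhaustive small grid: canonical x class x AF x requirement."""
        cfg = FilterConfig()
        classes = [("stop_gained",), ("missense_variant",), ("inframe_deletion",),
                   ("splice_region_variant",), ("synonymous_variant",)]
        afs = [0.0, 5e-5, 2e-4, 1e-3, 6e-3]
        for canonical, terms, af, req, mc in itertools.product(
            [True, False], classes, afs, list(AllelicRequirement),
            [MutationConsequence.LOSS_OF_FUNCTION,
             MutationConsequence.ALL_MISSENSE_IN_FRAME,
             MutationConsequence.UTR_MUTATION],
        ):
            annotation = tc(terms=terms, canonical=canonical,
                            afs={"gnomAD_AF": af} if af else {})
            got, _ = variant_is_valid(annotation, thread(req=req, mc=mc), cfg)
            # independent re-evaluation via the oracle's tables
            cls = oracles.classify(terms)
            threshold = 5e-3 if req is AllelicRequirement.BIALLELIC else 1e-4
            expect = (
                canonical
                and cls in oracles._ALLOWED[mc.value]
                and af < threshold
            )
            assert got == expect, (canonical, terms, af, req, mc)

    def test_concordance_subfilter_only_hits_missense(self):
        cfg = FilterConfig(require_sift_polyphen_concordance=True)
        discordant = tc(terms=("missense_variant",), sift="tolerated",
                        polyphen="probably_damaging")
        concordant = tc(terms=("missense_variant",), sift="deleterious",
                        polyphen="probably_damaging")
        lof = tc(terms=("stop_gained",))
        assert not variant_is_valid(discordant, thread(), cfg)[0]
        assert variant_is_valid(concordant, thread(), cfg)[0]
        assert variant_is_valid(lof, thread(), cfg)[0]


class TestAggregate:
    def test_biallelic_single_het_not_satisfied(self):
        t = thread(req=AllelicRequirement.BIALLELIC)
        f = aggregate_gene_findings("S", t, [qv(t)])
        assert not f.requirement_satisfied and f.genotype_pattern == "not_satisfied"

    def test_biallelic_hom_alt_satisfied(self):
        t = thread(req=AllelicRequirement.BIALLELIC)
        f = aggregate_gene_findings("S", t, [qv(t, Zygosity.HOM_ALT)])
        assert f.requirement_satisfied and f.genotype_pattern == "hom_alt"

    def test_biallelic_two_het_sites_is_possible_compound_het(self):
        t = thread(req=AllelicRequirement.BIALLELIC)
        f = aggregate_gene_findings("S", t, [qv(t, pos=100), qv(t, pos=200)])
        assert f.requirement_satisfied and f.genotype_pattern == "two_or_more_hets"

    def test_biallelic_duplicated_het_site_not_satisfied(self):
        t = thread(req=AllelicRequirement.BIALLELIC)
        f = aggregate_gene_findings("S", t, [qv(t, pos=100), qv(t, pos=100)])
        assert not f.requirement_satisfied

    def test_hemizygous_het_needs_female_or_unknown(self):
        t = thread(req=AllelicRequirement.HEMIZYGOUS)
        assert aggregate_gene_findings("S", t, [qv(t)], Sex.FEMALE).requirement_satisfied
        assert aggregate_gene_findings("S", t, [qv(t)], Sex.UNKNOWN).requirement_satisfied
        assert not aggregate_gene_findings("S", t, [qv(t)], Sex.MALE).requirement_satisfied
        assert aggregate_gene_findings("S", t, [qv(t, Zygosity.HEMI)],
                                       Sex.MALE).requirement_satisfied

    def test_unsupported_requirements_never_satisfied(self):
        for req in (AllelicRequirement.DIGENIC, AllelicRequirement.MITOCHONDRIAL,
                    AllelicRequirement.UNCERTAIN):
            t = thread(req=req)
            f = aggregate_gene_findings("S", t, [qv(t), qv(t, pos=200)])
            assert not f.requirement_satisfied and f.reason

    def test_random_zygosity_multisets_match_truth_table(self):
        rng = np.random.default_rng(61)
        zygs = [Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HEMI]
        sexes = [Sex.MALE, Sex.FEMALE, Sex.UNKNOWN]
        for _ in range(400):
            req = list(AllelicRequirement)[rng.integers(0, len(AllelicRequirement))]
            t = thread(req=req)
            n = int(rng.integers(1, 5))
            variants = [qv(t, zygs[rng.integers(0, 3)], pos=int(rng.integers(1, 4)) * 100)
                        for _ in range(n)]
            sex = sexes[rng.integers(0, 3)]
            got = aggregate_gene_findings("S", t, variants, sex).requirement_satisfied
            # independent truth-table evaluation
            zs = [v.zygosity for v in variants]
            het_sites = {v.key for v in variants if v.zygosity is Zygosity.HET}
            if req.value in oracles._UNSUPPORTED:
                expect = False
            elif req is AllelicRequirement.BIALLELIC:
                expect = Zygosity.HOM_ALT in zs or len(het_sites) >= 2
            elif req is AllelicRequirement.HEMIZYGOUS:
                expect = (Zygosity.HEMI in zs or Zygosity.HOM_ALT in zs
                          or (Zygosity.HET in zs and sex in (Sex.FEMALE, Sex.UNKNOWN)))
            else:
                expect = any(z.carries_alt for z in zs)
            assert got == expect, (req, zs, sex)

    def test_biallelic_satisfaction_implies_valid_pattern(self):
        rng = np.random.default_rng(67)
        t = thread(req=AllelicRequirement.BIALLELIC)
        zygs = [Zygosity.HET, Zygosity.HOM_ALT]
        for _ in range(100):
            variants = [qv(t, zygs[rng.integers(0, 2)], pos=int(rng.integers(1, 5)) * 50)
                        for _ in range(int(rng.integers(1, 4)))]
            f = aggregate_gene_findings("S", t, variants)
            if f.requirement_satisfied:
                assert f.genotype_pattern in ("hom_alt", "two_or_more_hets")


class TestCohortFilter:
    def test_noiseless_recovery_one_finding_per_case(self, noiseless):
        result = noiseless["result"]
        truth = noiseless["truth"]
        satisfied = result.satisfied
        case_ids = {e.sample_id for e in truth.entries}
        assert {f.sample_id for f in satisfied} == case_ids
        assert all(not f.sample_id.startswith("CTRL") for f in satisfied)

    def test_planted_compound_het_reported_as_two_or_more_hets(self, noiseless):
        patterns = {f.genotype_pattern for f in noiseless["result"].satisfied
                    if f.lgmdet.allelic_requirement is AllelicRequirement.BIALLELIC}
        assert "two_or_more_hets" in patterns and "hom_alt" in patterns

    def test_cohort_matches_brute_force_oracle(self, sim):
        """End-to-end: engine findings equal an independent per-(sample, thread)
        re-evaluation of every rule from the raw VCF text."""
        result = sim["result"]
        vcf_text = sim["vcf"].read_text()
        panel_rows = [
            {"gene": e.gene_symbol, "disease": e.disease_name,
             "requirement": e.allelic_requirement.value,
             "consequence": e.mutation_consequence.value}
            for e in reportable_entries(sim["panel"])
        ]
        sex = {s: v.value for s, v in sim["sex"].items()}
        expected = oracles.oracle_filter(vcf_text, panel_rows, sex)
        got = {
            (f.sample_id, f.gene_symbol, f.lgmdet.disease_name,
             f.lgmdet.allelic_requirement.value, f.lgmdet.mutation_consequence.value): {
                "satisfied": f.requirement_satisfied,
                "variants": frozenset(
                    (v.key.chrom, v.key.pos, v.key.ref, v.key.alt)
                    for v in f.qualifying_variants
                ),
            }
            for f in result.findings
        }
        assert got == expected

    def test_off_panel_genes_never_in_output(self, sim):
        genes = {f.gene_symbol for f in sim["result"].findings}
        reportable = {e.gene_symbol for e in reportable_entries(sim["panel"])}
        assert genes <= reportable
        assert "OFFPANEL1" not in genes

    def test_maf_monotonicity_on_findings(self, sim):
        """Raising a MAF threshold never removes a qualifying variant."""
        cset = collect_candidates(sim["vcf"], reportable_entries(sim["panel"]),
                                  sim["filter_cfg"], sim["sex"])
        previous = None
        for cutoff in (0.0, 1e-5, 2e-5, 4e-5, 1e-4):
            cfg = FilterConfig(maf_monoallelic=cutoff, maf_biallelic=cutoff)
            res = findings_from_candidates(cset, cfg, sim["sex"])
            current = {(f.sample_id, f.gene_symbol, v.key)
                       for f in res.findings for v in f.qualifying_variants}
            if previous is not None:
                assert previous <= current
            previous = current

    def test_undecomposed_record_rejected(self, tmp_path, sim):
        text = sim["vcf"].read_text().splitlines()
        body = next(i for i, l in enumerate(text) if not l.startswith("#"))
        fields = text[body].split("\t")
        fields[4] = fields[4] + ",G"  # forge a multi-allelic ALT
        bad = tmp_path / "bad.vcf"
        bad.write_text("\n".join(text[:body] + ["\t".join(fields)]) + "\n")
        with pytest.raises(FormatError, match="decomposed"):
            filter_cohort(bad, reportable_entries(sim["panel"]))

    def test_missing_csq_header_rejected(self, tmp_path):
        bad = tmp_path / "nocsq.vcf"
        bad.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        with pytest.raises(FormatError, match="CSQ"):
            filter_cohort(bad, Panel(entries=[thread()]))

    def test_findings_tsv_round_trip(self, sim, tmp_path):
        path = tmp_path / "f.tsv"
        write_findings_tsv(sim["result"].findings, path)
        again = read_findings_tsv(path)
        orig = {
            (f.sample_id, f.gene_symbol, f.requirement_satisfied, f.genotype_pattern,
             frozenset((v.key, v.zygosity, v.consequence_class, v.max_af)
                       for v in f.qualifying_variants))
            for f in sim["result"].findings
        }
        back = {
            (f.sample_id, f.gene_symbol, f.requirement_satisfied, f.genotype_pattern,
             frozenset((v.key, v.zygosity, v.consequence_class, v.max_af)
                       for v in f.qualifying_variants))
            for f in again
        }
        assert orig == back

    def test_determinism_byte_identical_reports(self, sim, tmp_path):
        cfg = sim["filter_cfg"]
        panel = reportable_entries(sim["panel"])
        a = filter_cohort(sim["vcf"], panel, cfg, sim["sex"])
        b = filter_cohort(sim["vcf"], panel, cfg, sim["sex"])
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_findings_tsv(a.findings, pa)
        write_findings_tsv(b.findings, pb)
        assert pa.read_bytes() == pb.read_bytes()
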