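from __future__ import annotations

import math

import numpy as np
import pytest

from g2pfilter.errors import ValidationError
from g2pfilter.stats import (
    BurdenTable,
    burden_tables,
    cadd_high_fraction,
    findings_per_sample_distribution,
    fisher_odds_ratio,
    maf_ratio,
    per_gene_proportions,
)
from g2pfilter.engine import QualifiedVariant, VariantKey, aggregate_gene_findings
from g2pfilter.annotation import TranscriptConsequence
from g2pfilter.panel import LGMDET
from g2pfilter.vocab import (
    AllelicRequirement,
    Confidence,
    ConsequenceClass,
    MutationConsequence,
    Zygosity,
)

from . import oracles


def thread(gene="G1", req=AllelicRequirement.MONOALLELIC):
    return LGMDET(gene_symbol=gene, disease_name="D", confidence=Confidence.CONFIRMED,
                  allelic_requirement=req,
                  mutation_consequence=MutationConsequence.LOSS_OF_FUNCTION)


def finding(sample, gene="G1", positions=(100,), cls=ConsequenceClass.MISSENSE,
            cadd=None, af=0.0):
    t = thread(gene)
    variants = []
    for pos in positions:
        tc = TranscriptConsequence(
            allele="T", gene_symbol=gene, transcript_id="ENST1",
            so_terms=("missense_variant",) if cls is ConsequenceClass.MISSENSE
            else ("stop_gained",),
            is_canonical=True, cadd_phred=cadd,
        )
        variants.append(QualifiedVariant(VariantKey("1", pos, "A", "T"), t, tc, cls,
                                         af, Zygosity.HET))
    return aggregate_gene_findings(sample, t, variants)


class TestBurden:
    def test_constructed_counts(self):
        cases = [finding(f"C{i}") for i in range(3)]
        controls = [finding("K1")]
        (table,) = burden_tables(cases, controls, case_total=10, control_total=10)
        assert (table.case_carriers, table.case_total,
                table.control_carriers, table.control_total) == (3, 10, 1, 10)

    def test_empty_controls(self):
        tables = burden_tables([finding("C1")], [], control_total=5)
        assert all(t.control_carriers == 0 for t in tables)

    def test_overlapping_sample_ids_rejected(self):
        with pytest.raises(ValidationError):
            burden_tables([finding("S1")], [finding("S1")])

    def test_duplicated_variant_rows_do_not_inflate_carriers(self):
        doubled = [finding("C1"), finding("C1")]  # same sample twice
        (table,) = burden_tables(doubled, [finding("K1")])
        assert table.case_carriers == 1

    def test_random_sets_match_membership_scan(self):
        rng = np.random.default_rng(71)
        genes = [f"G{i}" for i in range(5)]
        cases = [finding(f"C{rng.integers(0, 20)}", genes[rng.integers(0, 5)],
                         positions=(int(rng.integers(1, 1000)),))
                 for _ in range(60)]
        controls = [finding(f"K{rng.integers(0, 20)}", genes[rng.integers(0, 5)],
                            positions=(int(rng.integers(1, 1000)),))
                    for _ in range(40)]
        tables = burden_tables(cases, controls)
        for t in tables:
            req, cls = t.stratum
            expect_case = {
                f.sample_id for f in cases for v in f.qualifying_variants
                if (v.lgmdet.allelic_requirement.value, v.consequence_class.value) == (req, cls)
            }
            assert t.case_carriers == len(expect_case)


class TestFisher:
    def test_or_20_and_exact_p_match_enumeration(self):
        res = fisher_odds_ratio([[10, 5], [2, 20]])
        assert res.odds_ratio == pytest.approx(20.0)
        assert res.p_value == pytest.approx(oracles.fisher_p_two_sided(10, 5, 2, 20),
                                            rel=1e-9)

    def test_balanced_table(self):
        res = fisher_odds_ratio([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_table_infinite_or_finite_ci(self):
        res = fisher_odds_ratio([[10, 0], [0, 10]])
        assert math.isinf(res.odds_ratio)
        assert all(math.isfinite(x) for x in res.ci95)

    def test_zero_margin_flagged_undefined(self):
        assert fisher_odds_ratio([[0, 0], [3, 4]]).undefined

    def test_ci_brackets_or_when_finite(self):
        res = fisher_odds_ratio([[12, 8], [5, 15]])
        lo, hi = res.ci95
        assert lo <= res.odds_ratio <= hi

    def test_p_matches_enumeration_for_all_small_tables(self):
        """Exhaustive check over all 2x2 tables with total <= 14, plus a random
        sample of larger tables up to total 60."""
        for n in range(1, 15):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                            continue
                        res = fisher_odds_ratio([[a, b], [c, d]])
                        expect = oracles.fisher_p_two_sided(a, b, c, d)
                        assert res.p_value == pytest.approx(expect, rel=1e-8), (a, b, c, d)
        rng = np.random.default_rng(73)
        checked = 0
        while checked < 300:
            cells = rng.multinomial(int(rng.integers(4, 61)), [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            res = fisher_odds_ratio([[a, b], [c, d]])
            assert res.p_value == pytest.approx(
                oracles.fisher_p_two_sided(a, b, c, d), rel=1e-8), (a, b, c, d)
            checked += 1

    def test_null_calibration_or_centres_on_one(self):
        """Two arms drawn from the same carrier probability: the average
        log-OR across replicates is near zero."""
        rng = np.random.default_rng(79)
        log_ors = []
        for _ in range(200):
            a = rng.binomial(50, 0.3)
            c = rng.binomial(50, 0.3)
            res = fisher_odds_ratio([[a + 1, 50 - a + 1], [c + 1, 50 - c + 1]])
            log_ors.append(math.log(res.odds_ratio))
        assert abs(np.mean(log_ors)) < 0.1


class TestPerGene:
    def test_higher_in_control_and_absent_in_control(self):
        cases = [finding("C1", "GA"), finding("C2", "GB")]
        controls = [finding("K1", "GA"), finding("K2", "GA")]
        df, summary = per_gene_proportions(cases, controls, case_total=100,
                                           control_total=10)
        assert summary["higher_in_control"] == 1  # GA: 2/10 > 1/100
        assert summary["absent_in_control"] == 1  # GB
        assert summary["n_genes"] == 2

    def test_random_cohorts_match_direct_loop(self):
        rng = np.random.default_rng(83)
        cases = [finding(f"C{rng.integers(0, 30)}", f"G{rng.integers(0, 8)}",
                         positions=(int(rng.integers(1, 500)),)) for _ in range(80)]
        controls = [finding(f"K{rng.integers(0, 30)}", f"G{rng.integers(0, 8)}",
                            positions=(int(rng.integers(1, 500)),)) for _ in range(50)]
        df, summary = per_gene_proportions(cases, controls)
        nc = len({f.sample_id for f in cases})
        nk = len({f.sample_id for f in controls})
        higher = absent = 0
        for gene in {f.gene_symbol for f in cases} | {f.gene_symbol for f in controls}:
            cs = {f.sample_id for f in cases if f.gene_symbol == gene}
            ks = {f.sample_id for f in controls if f.gene_symbol == gene}
            if len(ks) / nk > len(cs) / nc:
                higher += 1
            if not ks:
                absent += 1
        assert summary["higher_in_control"] == higher
        assert summary["absent_in_control"] == absent


class TestCadd:
    def test_fraction_above_cutoff(self):
        findings = [finding("S1", positions=(i,), cadd=c)
                    for i, c in enumerate([31, 35, 40, 10, 12, 15, 20, 22, 25, 28])]
        frac, n_high, n_scored = cadd_high_fraction(findings)
        assert (frac, n_high, n_scored) == (pytest.approx(0.30), 3, 10)

    def test_no_cadd_flagged_undefined_not_zero(self):
        frac, _, n = cadd_high_fraction([finding("S1", cadd=None)])
        assert math.isnan(frac) and n == 0

    def test_duplicated_variant_across_samples_counted_once(self):
        findings = [finding("S1", positions=(100,), cadd=35.0),
                    finding("S2", positions=(100,), cadd=35.0),
                    finding("S3", positions=(200,), cadd=10.0)]
        frac, n_high, n_scored = cadd_high_fraction(findings)
        # set-based recount: unique sites {100, 200}
        assert (n_high, n_scored) == (1, 2)
        assert frac == pytest.approx(0.5)

    def test_lof_variants_not_in_missense_denominator(self):
        findings = [finding("S1", cls=ConsequenceClass.LOF, cadd=45.0),
                    finding("S2", positions=(300,), cadd=35.0)]
        _, n_high, n_scored = cadd_high_fraction(findings)
        assert (n_high, n_scored) == (1, 1)


class TestDistribution:
    def test_worked_histogram(self):
        findings = [finding("S3", positions=(1,)),
                    finding("S4", positions=(2, 3, 4))]
        d = findings_per_sample_distribution(findings, ["S1", "S2", "S3", "S4"])
        assert d["mean"] == pytest.approx(1.0)
        assert d["histogram"] == {0: 0.5, 1: 0.25, 3: 0.25}

    def test_all_zero_cohort(self):
        d = findings_per_sample_distribution([], ["S1", "S2"])
        assert d["mean"] == 0.0 and d["sd"] == 0.0

    def test_random_cohort_matches_direct_tally(self):
        rng = np.random.default_rng(89)
        samples = [f"S{i}" for i in range(20)]
        findings = [finding(samples[rng.integers(0, 20)],
                            positions=tuple(int(p) for p in
                                            rng.choice(1000, size=rng.integers(1, 4),
                                                       replace=False)))
                    for _ in range(40)]
        d = findings_per_sample_distribution(findings, samples)
        tally = {s: set() for s in samples}
        for f in findings:
            tally[f.sample_id].update(v.key for v in f.qualifying_variants)
        counts = [len(v) for v in tally.values()]
        assert d["mean"] == pytest.approx(np.mean(counts))
        assert d["sd"] == pytest.approx(np.std(counts))


class TestMafRatio:
    def test_worked_ratio(self):
        cases = [finding("C1", af=1e-5)]
        controls = [finding("K1", af=2e-5)]
        assert maf_ratio(cases, controls) == pytest.approx(2.0)

    def test_identical_cohort_distributions_give_one(self):
        fs = [finding(f"C{i}", af=af) for i, af in enumerate([1e-5, 3e-5, 5e-5])]
        gs = [finding(f"K{i}", af=af) for i, af in enumerate([1e-5, 3e-5, 5e-5])]
        assert maf_ratio(fs, gs) == pytest.approx(1.0)

    def test_empty_stratum_undefined(self):
        assert math.isnan(maf_ratio([], [finding("K1")]))

    def test_random_sets_match_direct_arithmetic(self):
        rng = np.random.default_rng(97)
        cases = [finding(f"C{i}", af=float(rng.random() * 1e-4)) for i in range(20)]
        controls = [finding(f"K{i}", af=float(rng.random() * 1e-4)) for i in range(20)]
        expect = (np.mean([v.max_af for f in controls for v in f.qualifying_variants])
                  / np.mean([v.max_af for f in cases for v in f.qualifying_variants]))
        assert maf_ratio(cases, controls) == pytest.approx(expect)
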