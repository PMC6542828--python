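# g2pfilter

Panel-driven, genotype-aware filtering of annotated VCFs for rare-disease
diagnosis — plus the quality control, case:control background statistics
and accuracy evaluation that a diagnostic panel should undergo before
clinical or research use.

## The problem

Diagnostic sequence analysis of genetically heterogeneous presentations
(developmental disorders, familial cancer, ...) starts from tens of
thousands of called variants per exome and must end with a handful of
loci a clinician can review.  Curated gene panels make this tractable:
each panel entry links a gene, via a disease mechanism, to a disease,
and carries

* an **allelic requirement** — the genotype configuration needed at the
  locus (monoallelic, biallelic, hemizygous, ...),
* a **mutation consequence** — the mechanism class of pathogenic
  variants (loss of function, activating, all missense/in-frame, ...),
* a curation **confidence** (confirmed and probable entries are
  reportable; possible entries are not).

`g2pfilter` consumes a multi-sample VCF that has been decomposed,
normalised and annotated with VEP-style per-transcript `CSQ` blocks
(Sequence Ontology terms, canonical flag, SIFT/PolyPhen, CADD,
population allele frequencies) and reports, per sample and panel entry,
the genotypes that plausibly cause disease:

1. genotype calls failing quality rules (GQ < 13 ≈ 95% confidence,
   DP < 5, alt fraction < 0.2, MQ < 13) are reset to no-calls;
2. a variant is valid for a panel entry when a canonical-transcript
   consequence falls in the classes allowed by the entry's mechanism and
   its maximum allele frequency across reference cohorts is strictly
   below the threshold for its allelic requirement (default 1:10,000 for
   single-allele requirements, 0.005 for biallelic);
3. valid variants are aggregated into **gene findings** by allelic
   requirement — one altered allele suffices for monoallelic entries;
   biallelic entries need a homozygote or two different heterozygous
   sites (a *possible* compound heterozygote: phase is not resolved);
   hemizygous entries use the sample's sex from an optional PED table.

Genotype-aware reporting matters: reporting only genotypes that satisfy
the requirement both shortens the review list and masks incidental
single-carrier findings in recessive genes.

The accuracy vocabulary is the usual confusion-matrix one: over a truth
set of causative variants, sensitivity = TP/(TP+FN), precision =
TP/(TP+FP), F1 = 2·precision·recall/(precision+recall), and
(sensitivity+specificity)/2 lower-bounds the ROC AUC of the binary test.
A cohort *unselected* for the disease run through the same filter
estimates the panel's background noise; the `stats` module compares the
two arms (Fisher exact carrier burden, per-gene proportions, CADD>30
enrichment among unique missense variants, per-sample count
distributions, mean-MAF ratios).

Because real diagnostic cohorts are managed-access, the package ships a
synthetic generator (`g2pfilter.synthetic`) that produces panels,
annotated cohort VCFs with planted causative genotypes plus calibrated
background noise, PED sex tables and truth sets — every analysis here is
runnable end to end from nothing.

## Worked example

```sh
$ printf 'n_case_samples: 8\nn_control_samples: 4\nbackground_rate: 0.0\noffpanel_rate: 0.0\n' > sim.yaml
$ g2p simulate --config sim.yaml --seed 3 --out sim
wrote sim/cohort.vcf, sim/cohort.ped, sim/truth.tsv, sim/panel.csv (20 panel entries, 12 truth variants)
$ g2p filter --vcf sim/cohort.vcf --panel sim/panel.csv --ped sim/cohort.ped --out flt
8 findings (8 satisfied) across 12 samples -> flt/findings.tsv
$ g2p evaluate --findings flt/findings.tsv --truth sim/truth.tsv --out ev
{"f1": 1.0, "fn": 0, "fp": 0, "precision": 1.0, "sensitivity": 1.0, "tp": 12}
```

The simulation plants one causative genotype per case sample (8 samples,
12 truth variants — compound-heterozygous plants contribute two sites)
and, with `background_rate: 0`, nothing else.  The filter emits 8
satisfied findings, one per planted (sample, panel-entry) pair; scoring
them against the truth set recovers every planted variant with no false
positives, hence sensitivity, precision and F1 of 1.0.  The first rows of
`flt/findings.tsv` show a biallelic finding reported as
`two_or_more_hets` — a possible compound heterozygote:

```
sample_id  gene_symbol  ...  allelic_requirement  requirement_satisfied  genotype_pattern  ...  pos      zygosity
CASE0001   GENE0001     ...  biallelic            True                   two_or_more_hets  ...  1000000  het
CASE0001   GENE0001     ...  biallelic            True                   two_or_more_hets  ...  1000010  het
```

Raising `background_rate` adds filter-surviving noise to every sample;
`g2p compare` then contrasts the case and control arms, and
`g2p qc` screens samples for contamination indicators (extreme-het and
rare-homozygote counts beyond mean ± 3 SD).

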