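# Methods

## Filtering model

The filter treats a curated panel entry (gene → disease, with an allelic
requirement, a mutation consequence and a curation confidence) as a
contract: a sample is flagged for that entry only when its surviving
genotypes could satisfy the contract.  The pipeline per VCF record is

1. parse the per-transcript `CSQ` annotation blocks (field order taken
   from the VCF header declaration, never assumed);
2. reset each sample's genotype to a no-call when any quality rule
   fires: genotype quality < 13, depth < 5, alt-allele fraction < 0.2,
   or mapping quality < 13 when an MQ value is present.  Absent fields
   never fire their rule — cohorts merged from gVCFs may carry no
   per-record MQ, and resetting on missing evidence would silently
   discard data;
3. per overlapping reportable entry, test the variant: canonical
   transcript (configurable), consequence class allowed by the entry's
   mechanism, and maximum population allele frequency strictly below the
   requirement's threshold;
4. aggregate the surviving (sample, entry) variants into a gene finding
   and decide the allelic requirement.

Assumptions inherited from this design: the VCF is decomposed and
normalised upstream (one alt allele per record — the engine rejects
anything else); consequence prediction is consumed, not recomputed;
phase is unknown, so two heterozygous sites in a biallelic gene are only
a *possible* compound heterozygote; proband-only analysis, so de
novo/inheritance status is out of scope.

### Consequence classes

Sequence Ontology terms collapse onto five classes with
most-severe-wins precedence: `lof` (stop_gained, frameshift_variant,
splice_acceptor/donor_variant, start_lost, transcript_ablation), then
`missense`, then `inframe` (inframe_insertion/deletion, stop_lost),
then `splice_region`, else `other`.  The per-mechanism allowed sets are:
loss-of-function genes admit {lof, missense, inframe, splice_region}
(predicted-deleterious missense in LOF genes is diagnostically
informative and is analysed as such in the stats module);
all-missense/in-frame, activating and dominant-negative mechanisms admit
{missense, inframe}; uncertain admits the LOF set; UTR, cis-regulatory
and increased-dosage mechanisms are not detectable from coding
consequences and map to the empty set — findings for them are emitted as
unsupported rather than silently dropped.  Both the LOF term set and the
allowed-class table are config-overridable: neither is standardised, and
in particular whether splice_region belongs in the LOF-gene set is a
judgement call (kept in by default, removable).

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `maf_monoallelic` | 1e-4 | allele frequency | 1:10,000 — a dominant high-penetrance allele more common than this is implausible |
| `maf_biallelic` | 5e-3 | allele frequency | recessive carriers can be common; 0.005 is the conventional recessive screen |
| `min_gq`, `min_mq` | 13 | Phred | 1 − 10^(−1.3) ≈ 0.95: 95% genotype/mapping confidence |
| `min_dp` | 5 | reads | below this a diploid genotype is unreliable |
| `min_alt_fraction` | 0.2 | fraction | hets below this look like artefact/contamination |
| `canonical_only` | true | — | one representative transcript standardises reporting |
| `require_sift_polyphen_concordance` | false | — | optional missense sub-filter; the burden analysis can enable it per stratum |

Comparisons are strict (`AF < cutoff`, quality `< threshold`); a cutoff
of exactly 0 in a MAF sweep means "unseen in every reference source".

### Numerical and tie-break choices

* When several transcript annotations of a gene are eligible, the
  canonical one wins, else the most severe class, ties broken by
  transcript identifier — output is therefore byte-deterministic.
* MAF thresholds are applied *after* winner selection, which lets a MAF
  sweep reuse one VCF collection pass; the sweep replaces both
  per-requirement thresholds with each ladder value.
* Sample-QC outlier screens use the population SD (divide by n,
  configurable); at realistic cohort sizes the n−1 difference is
  negligible.  The screen is a single pass, not iterated.
* Fisher's exact test: two-tailed conditional p-value (scipy); the
  reported odds ratio is the cross-product ratio ad/bc (infinite over a
  zero denominator with non-zero numerator).  The 95% CI is the normal
  approximation on log OR with the Haldane–Anscombe +0.5 correction on
  zero cells — approximate, documented as such, not an exact conditional
  interval.  Degenerate tables (a zero margin) return an undefined
  result explicitly flagged.
* Rates with empty denominators (precision with no predictions,
  specificity with no negative universe, CADD fraction with no scored
  variants) are NaN with a flag, never silently 0.
* Finding order for causative-gene ranking: satisfied first, then
  consequence severity, then ascending minimum AF, then gene symbol — a
  documented convention, since diagnostic report ordering is not
  standardised.

### Genotype aggregation details

Hemizygous entries need sample sex, which the VCF lacks; an optional
PED-style table supplies it, defaulting to unknown.  The default is
permissive — a heterozygous call on X counts for female or unknown-sex
samples — and the genotype pattern is recorded so reviewers can see what
the verdict rests on.  Digenic, mitochondrial and uncertain requirements
are never satisfied by this engine; findings for them carry a reason
code.  True negatives require a caller-supplied negative universe; the
package never invents one.

## The synthetic generator

`g2pfilter.synthetic` emulates the study inputs: a panel with a
configurable composition over (requirement, consequence) cells
(defaulting to a majority of monoallelic/biallelic loss-of-function
entries, plus coverage entries for the possible and RD+IF confidence
categories); a multi-sample VCF on a toy contig set (two autosomes and
X — no reference genome is needed because consequences are asserted via
CSQ, not computed); a PED sex table; and a truth set.

Planted causative genotypes respect their entry's requirement (het for
monoallelic; hom-alt or two het sites for biallelic, split by
`compound_het_fraction` = 0.5; hemizygous-male on X) with unseen alleles
and comfortable quality, so they survive filtering by construction.
`n_high_af_planted` deliberately gives that many planted variants an AF
of 2e-4 — above the monoallelic cut-off — to model causative variants
lost to the rarity filter, the dominant cause of missed diagnoses under
strict MAF screening.

Background variants model panel noise: heterozygous calls in monoallelic
panel genes, with AFs from a spectrum putting 60% mass at 0 (unseen) and
the rest log-uniform over 1e-6..1e-3, so both sides of every MAF ladder
value are populated, and with 10% of calls given exactly one failing
quality field.  `background_rate` is the expected number of background
variants per sample *after* filtering: the generator inflates the raw
Poisson rate by the analytic acceptance probability
P(AF passes)·P(quality passes), which the calibration test checks to
within three standard errors.  Off-panel variants (`offpanel_rate`) are
added for realism and must never reach the output.

What the generator does **not** emulate: linkage/haplotype structure
(every site is independent, so compound-heterozygote false positives
from cis configurations cannot arise here), shared recurrent variants
across samples, indel-specific error modes, population stratification,
and annotation disagreement between transcript sets beyond a token
non-canonical block.  Passing tests on this generator therefore
demonstrate the *logic* of the filter — rule correctness, monotonicity,
determinism, calibration — not its clinical yield on real cohorts, which
depends on panel curation quality and real AF spectra.

## Evaluation framework

Scoring is variant-level: predictions are the qualifying variants of
requirement-satisfied findings; a truth entry found there is a TP, an
extra surviving variant an FP.  The MAF sweep ladder is {unseen, 1e-5,
2e-5, 4e-5, 1e-4}; ROC/PR points along it are monotone by construction,
which the tests assert.  Consequence-stratified precision-recall
restricts predictions to a stratum (LOF-only; missense with CADD ≥ 20 or
≥ 30; all) while keeping the full truth set in the recall denominator,
so class restriction visibly trades recall for precision.

## Problem sizes

The test suite and acceptance script run cohorts of 30–200 samples with
~20-entry panels and background rate 2.0/sample — sizes chosen so every
requirement type, both MAF thresholds, every quality rule and the
case:control machinery are exercised many times over while the whole
suite stays interactive.  All randomness flows from explicit seeds; two
runs under one seed produce byte-identical artefacts.

## Known limitations

* No phase: biallelic findings from two het sites overcall compound
  heterozygotes; trio or long-read phasing is out of scope.
* Non-coding mechanisms (UTR, cis-regulatory, dosage) and structural
  variants are flagged unsupported, not analysed.
* PanelApp conversion maps ratings and inheritance modes; mutation
  consequence is not inferable from that format and defaults to
  uncertain, which admits a broad class set.
* The exact-test CI is a normal approximation; p-values are exact.
* Multiple-testing correction across genes is deliberately not applied
  in the burden tables (single-panel screening context); callers doing
  gene discovery should adjust.
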