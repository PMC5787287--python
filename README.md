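# couplescreen

Carrier screening for couples at increased risk of severe autosomal-recessive
childhood disorders. Given annotated variant calls from the two healthy
partners — typically a gene-panel or exome screen performed after the loss of
one or more affected children — the package finds genes in which the couple's
genotypes predict a recessive risk genotype in future offspring, classifies
the variants, and decides whether the finding supports prenatal or
preimplantation genetic diagnosis (PGD).

## Who this is for

Clinical-genetics analysts and method developers who want a tested,
scriptable implementation of the couple-based screening logic: the variant
filter cascade, the gene-level partner intersection, ACMG/AMP classification,
cosegregation confirmation in affected children, and Mendelian recurrence
risk — plus a synthetic-data layer so the whole pipeline can be exercised and
validated without any protected data.

## The method

Per parent, a variant is retained when it is

- **heterozygous** (parents are unaffected carriers),
- **rare** — every listed population frequency (dbSNP / ESP / ExAC fields)
  is below the MAF threshold (default 1%), or the variant carries a
  disease-causing assertion in HGMD or ClinVar; absence from all databases
  counts as rare,
- of **qualifying consequence** — non-synonymous coding or splice-site,
  including small indels and whole-exon CNVs,
- **predicted deleterious** — nonsense/frameshift/exon-CNV qualify outright;
  otherwise CADD ≥ 20 (configurable) or agreement of ≥ 2 of the binary
  predictors (SIFT, PolyPhen, splice prediction).

For every gene retained in *both* partners, candidates are emitted:

- **shared_hom** — both partners carry the identical heterozygous variant;
  offspring can be homozygous (25% per pregnancy);
- **compound_het** — the partners carry different heterozygous variants in
  the same gene; offspring can be compound heterozygous (trans phase holds
  by construction, one allele per parent).

Each parental allele is classified 1–5 with the ACMG/AMP combining rules;
prenatal diagnosis / PGD eligibility requires Class ≥ 4 on **both** alleles,
and Class 3–5 findings are reportable. Candidates are confirmed by
cosegregation where DNA from an affected child or fetus exists (homozygous or
compound-het risk genotype in an affected child).

The synthetic layer provides (a) a reconstructed 13-couple demonstration
cohort with known expected outcomes at every pipeline stage, and (b) a
consanguinity-aware couple simulator in which a partner shares each rare
variant with probability φ + (1 − φ)·2p(1 − p) for kinship φ (1/16 for first
cousins) and population frequency p, with a closed-form expectation for the
number of incidentally shared genes.

## Worked example

```
$ couplescreen fixtures --out cohort_fixture
wrote 13-couple cohort to cohort_fixture
$ couplescreen cohort --fixtures cohort_fixture --out cohort_report
couples: 13
class45_match: 5
class3_candidate: 2
no_finding: 6
confirmed_in_child: 4
```

Five couples have a candidate with Class-4/5 variants on both alleles and
are eligible for prenatal diagnostics/PGD, two couples have a Class-3
candidate in a gene without an established disease entry (reportable, not
actionable), six couples have no finding, and four families have the risk
genotype confirmed in an affected child or fetus. Per-couple detail lands in
`cohort_report.tsv`, e.g. the second family:

```
couple_id  gene  mode          maternal_variant            paternal_variant          class_m  class_f  eligible  coseg_status  tier
family02   COQ2  compound_het  1:4001197CT>C c.1197delT    1:4000764C>T c.764C>T     5        4        1         unavailable   class45_match
```

A single couple can be screened directly from VCFs (`couplescreen screen
--mother M.vcf --father F.vcf --panel genes.txt --out prefix`, with `--wes`
skipping the panel restriction), and `couplescreen simulate --config
cfg.yaml --out dir` writes simulated couple VCFs plus the ground-truth table
of engineered shared genes.

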