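# Methods

## Screening model

The package implements couple-based carrier screening for autosomal-recessive
(AR) disease: both partners are phenotypically healthy, so the signal is a
gene in which *each* partner carries one rare, plausibly deleterious
heterozygous variant. Two offspring risk configurations exist and are kept
as distinct candidate modes, because they imply different confirmation
genotypes in affected children:

- *shared_hom*: identical variant in both partners → offspring may be
  homozygous;
- *compound_het*: different variants in the same gene → offspring may be
  compound heterozygous. Phase is trans by construction (one allele per
  parent), so the pipeline contains no phasing step.

De novo dominant disease is invisible to a parents-only design and is
explicitly out of scope, as are digenic hypotheses.

## Variant identity and normalization

All matching keys on the normalized `(chrom, pos, ref, alt)` tuple
(1-based, anchor-base convention); whole-exon CNV events key on
`(gene, exon label)` and enter the same VCF stream as symbolic `<DEL>`
records. HGVS strings are carried for display only — they are
transcript-dependent and unsafe as match keys. Indel normalization follows
the standard left-align-and-trim algorithm: trim shared trailing bases
(extending left from the reference when the anchor would be consumed), then
trim shared leading bases while both alleles keep one base. The operation
is idempotent and haplotype-preserving; tests check it against a
brute-force left-shift oracle.

Annotation floats (population frequencies, CADD) are canonicalized to six
significant digits at construction so that values survive the htslib
float32 round trip exactly; missing annotation values are encoded by
absence of the INFO key, never by sentinel numbers, because "not listed in
any database" must be treated as rare rather than as frequency 0.

## Filter cascade

Three per-variant predicates plus the heterozygosity requirement:

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.01 | rarity cutoff applied to every *present* frequency |
| `cadd_cutoff` | 20 | CADD phred cutoff (conventional "top 1%" rank) |
| `min_tool_votes` | 2 | binary predictors that must agree when CADD does not decide |

Design choices where the rule wording was open:

- Rarity is *conjunctive over present sources*: a variant common in any
  database that lists it is not rare. The disjunctive reading would retain
  variants common in one database merely because another omits them.
- A disease-causing database assertion (HGMD/ClinVar) overrides frequency.
- Loss-of-function classes (nonsense, frameshift, exon CNV) bypass the
  prediction scores: a truncating allele with no CADD score must not be
  discarded for missing annotation.
- Both partners' variants must pass the filter independently before a gene
  can match (the stricter reading).
- Homozygous parental calls are excluded from matching but logged: the
  screen is for heterozygous carriers, and a homozygous "carrier" of a
  severe recessive allele is more likely an annotation or calling artifact.

## Classification and actionability

Evidence codes (PVS/PS/PM/PP vs BA/BS/BP, 28 criteria) are combined with
the published ACMG/AMP rule table into classes 1–5; contradictory
pathogenic + benign evidence yields Class 3. The engine does not derive
evidence from annotations — codes are inputs (VCF `ACMG` key or sidecar
TSV), because evidence assignment is clinical judgment, not pipeline logic.
Eligibility for prenatal diagnosis/PGD requires Class ≥ 4 on both parental
alleles; Class 3–5 candidates are reportable. Couples are tiered by their
best candidate: `class45_match` (≥ 1 eligible candidate), `class3_candidate`
(≥ 1 reportable candidate), else `no_finding`. Within a report, candidates
rank by eligibility, then joint class, then CADD, then symbol — a
presentation policy, not a clinical claim.

## Cosegregation and risk

An affected child with the candidate's risk genotype confirms the gene; one
such child suffices, matching practice where a single archived sample is
often all that exists. An affected child carrying a single allele demotes
the gene (carrier_only); an unaffected child with the risk genotype is
inconsistent. Eligibility is class-based only; phenotype overlap between a
deceased child and a candidate gene is free-text clinical reasoning and is
deliberately not modeled.

Recurrence risk is Mendelian-exact, ignoring de novo and mosaic terms: AR
with two carrier parents → 0.25 independent of fetal sex; X-linked maternal
with a carrier mother → 0.5 for a male fetus, 0 for a female fetus under
full recessivity, and 0.25 for unknown sex (marginal over an equal sex
ratio). A simulation test draws 1000 children by Mendelian transmission and
checks the affected-genotype rate against the closed form within 3 binomial
standard errors.

## Synthetic data

The demonstration cohort encodes 13 couples (8 consanguineous) with the
variants, genotypes, CADD scores, classes and child genotypes of a
published carrier-screening case series, on synthetic coordinates (one
contig, gene-indexed 1 Mb spacing) since the source prints HGVS rather than
genomic positions. Evidence-code sets are reconstructed so the classifier
reproduces each printed class, and are labeled as such. Six unsolved
families carry only decoys, each engineered to fail exactly one filter
predicate (common / synonymous / benign-predicted), plus a single-partner
candidate and a homozygous call, making per-predicate attribution testable.
One known inconsistency in the source's variant description (two different
transcript-level descriptions of the ACADVL allele) is preserved in the
manifest rather than reconciled.

The couple simulator models incidental sharing between related partners:
each of n maternal rare variants (frequency p drawn from a weighted
spectrum) is carried identically by the father with probability
φ + (1 − φ)·2p(1 − p), i.e. identity by descent plus chance sharing; the
father receives n further independent variants. Variants are independent —
no linkage blocks — because the quantity of interest is the expected count
of incidentally shared genes, which the closed form
`Σ [φ + (1 − φ)·2p(1 − p)] + planted` gives exactly under independence.
Defaults (n = 64, φ = 1/16, strongly rare spectrum) put the expectation
near 4 shared genes, the regime reported for exome-wide screening of
first-cousin couples. Monte-Carlo agreement is tested at 2000 replicates
within 3 standard errors; planted candidates are recovered by the full
pipeline in 100/100 seeded runs.

What the generator does *not* emulate: realistic exome-wide mutation
spectra, linkage/haplotype structure, population-specific frequency panels,
sequencing error, or coverage gaps. Passing tests therefore demonstrate the
correctness of the screening logic and the sharing model's first moment,
not performance on real exomes.

## Numerical and degenerate-input choices

- Shared-variant sets: when both partners share ≥ 2 identical variants in
  one gene and carry nothing private, the compound-het candidate splits the
  shared variants deterministically (lowest key maternal); any deterministic
  split of a fully symmetric configuration cannot also be mother/father
  swap-symmetric, so the symmetry property is stated on unordered side-sets.
- Candidate equality for the matcher oracle is at the (gene, mode) level,
  keeping the oracle independent of the side-assignment policy.
- VCF writing uses a fixed INFO key order and `%g` float formatting for
  byte-stable, diffable fixtures; identical simulator seeds produce
  byte-identical files.
- X-linked panel genes are excluded from couple matching and reported as
  maternal carrier findings — the couple-intersection logic is AR-specific.
- The cohort fixture and its expected 5/2/6 tier partition and 4 confirmed
  families run in seconds; problem sizes throughout the suite (200-record
  filter fixtures, ≤ 100-variant matcher fixtures, 2000 simulator
  replicates) were chosen as the smallest sizes at which the statistical
  checks have power.

## Known limitations

Gene-symbol aliasing is not resolved; panel membership is exact-match on
uppercase symbols. CNV support is limited to whole-exon deletion/duplication
labels. Bayesian risk updates from negative prenatal tests, mosaicism, and
non-paternity are out of scope.
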