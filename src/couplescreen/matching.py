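"""Couple-level gene matching: nominate autosomal-recessive risk genes.

For each gene carried by *both* partners after filtering, two offspring risk
genotypes are possible: the partners share the identical heterozygous
variant (offspring could be homozygous — one ``shared_hom`` candidate per
shared variant), or they carry different heterozygous variants in the same
gene (offspring could be compound heterozygous — one ``compound_het``
candidate per gene).  Trans phase of a compound-het candidate holds by
construction: one allele comes from each parent, so no phasing step exists.

Whole-exon CNV records flow through the same logic keyed by (gene, exon);
two *different* exon deletions in one gene form a compound-het candidate
flagged low-confidence.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from .variants import AnnotatedRecord, VariantKind

__all__ = ["MatchMode", "CandidateGene", "match_couple", "match_cnv", "match_all"]


class MatchMode(str, enum.Enum):
    SHARED_HOM = "shared_hom"
    COMPOUND_HET = "compound_het"


_RISK_GENOTYPE = {MatchMode.SHARED_HOM: "homozygous",
                  MatchMode.COMPOUND_HET: "compound_heterozygous"}


@dataclass(frozen=True)
class CandidateGene:
    """A gene nominated for a couple, with the variants on each parental side."""

    gene: str
    mode: MatchMode
    maternal_variants: tuple[AnnotatedRecord, ...]
    paternal_variants: tuple[AnnotatedRecord, ...]
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.maternal_variants or not self.paternal_variants:
            raise ValueError("candidate requires variants on both parental sides")
        for r in self.maternal_variants + self.paternal_variants:
            if r.variant.gene != self.gene:
                raise ValueError("all member variants must share the candidate gene")
        mk = {r.variant.identity_key for r in self.maternal_variants}
        pk = {r.variant.identity_key for r in self.paternal_variants}
        if self.mode is MatchMode.SHARED_HOM:
            if not (mk & pk):
                raise ValueError("shared_hom requires an identity-equal variant pair")
        else:
            if mk & pk:
                raise ValueError("compound_het lists must hold no identity-equal pair")

    @property
    def offspring_risk_genotype(self) -> str:
        return _RISK_GENOTYPE[self.mode]

    @property
    def variant_keys(self) -> frozenset:
        return frozenset(r.variant.identity_key
                         for r in self.maternal_variants + self.paternal_variants)


def _by_gene(records: Sequence[AnnotatedRecord]) -> dict[str, list[AnnotatedRecord]]:
    out: dict[str, list[AnnotatedRecord]] = defaultdict(list)
    for r in records:
        out[r.variant.gene].append(r)
    return out


def _match_gene(gene: str, mom: list[AnnotatedRecord],
                dad: list[AnnotatedRecord]) -> list[CandidateGene]:
    mkeys = {r.variant.identity_key for r in mom}
    pkeys = {r.variant.identity_key for r in dad}
    shared = sorted(mkeys & pkeys, key=str)
    out: list[CandidateGene] = []
    is_cnv = any(r.variant.kind is VariantKind.EXON_CNV for r in mom + dad)

    for key in shared:
        out.append(CandidateGene(
            gene=gene, mode=MatchMode.SHARED_HOM,
            maternal_variants=tuple(r for r in mom if r.variant.identity_key == key),
            paternal_variants=tuple(r for r in dad if r.variant.identity_key == key),
        ))

    # compound het: at least one non-identical cross-parent pair must exist
    if not (mkeys == pkeys == set(shared) and len(shared) <= 1):
        m_side = [r for r in mom if r.variant.identity_key not in pkeys]
        p_side = [r for r in dad if r.variant.identity_key not in mkeys]
        if not m_side and not p_side:
            # both parents carry the same >=2 shared variants: split them,
            # lowest key maternal, the rest paternal
            k0 = shared[0]
            m_side = [r for r in mom if r.variant.identity_key == k0]
            p_side = [r for r in dad if r.variant.identity_key != k0]
        elif not m_side:
            m_side = [r for r in mom if r.variant.identity_key in shared]
        elif not p_side:
            p_side = [r for r in dad if r.variant.identity_key in shared]
        if m_side and p_side:
            out.append(CandidateGene(
                gene=gene, mode=MatchMode.COMPOUND_HET,
                maternal_variants=tuple(m_side), paternal_variants=tuple(p_side),
                low_confidence=is_cnv,
            ))
    return out


def match_couple(mother: Sequence[AnnotatedRecord],
                 father: Sequence[AnnotatedRecord]) -> list[CandidateGene]:
    """Match the couple's retained SNV/indel records gene by gene.

    Returns candidates sorted by gene symbol (shared_hom before compound_het
    within a gene).  Genes carried by only one parent are never emitted.
    """
    mom = [r for r in mother if r.variant.kind is not VariantKind.EXON_CNV]
    dad = [r for r in father if r.variant.kind is not VariantKind.EXON_CNV]
    return _match_records(mom, dad)


def match_cnv(mother: Sequence[AnnotatedRecord],
              father: Sequence[AnnotatedRecord]) -> list[CandidateGene]:
    """Match whole-exon CNV records by (gene, exon label) identity."""
    mom = [r for r in mother if r.variant.kind is VariantKind.EXON_CNV]
    dad = [r for r in father if r.variant.kind is VariantKind.EXON_CNV]
    return _match_records(mom, dad)


def _match_records(mom: Sequence[AnnotatedRecord],
                   dad: Sequence[AnnotatedRecord]) -> list[CandidateGene]:
    mg, dg = _by_gene(mom), _by_gene(dad)
    out: list[CandidateGene] = []
    for gene in sorted(set(mg) & set(dg)):
        out.extend(_match_gene(gene, mg[gene], dg[gene]))
    return out


def match_all(mother: Sequence[AnnotatedRecord],
              father: Sequence[AnnotatedRecord]) -> list[CandidateGene]:
    """SNV/indel and CNV matching merged into one candidate stream."""
    merged = match_couple(mother, father) + match_cnv(mother, father)
    return sorted(merged, key=lambda c: (c.gene, c.mode.value))
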