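"""Per-parent variant filter cascade: rare, qualifying consequence, predicted deleterious.

The screen keeps a parental variant when it is

1. *rare* — every population frequency that is actually listed (dbSNP, ESP,
   ExAC) is below the MAF threshold, or the variant carries a
   disease-causing assertion in HGMD or ClinVar (which overrides frequency);
   a variant absent from all databases counts as rare;
2. of *qualifying consequence* — non-synonymous coding or splice-site,
   including small indels and whole-exon CNVs;
3. *predicted deleterious* — loss-of-function classes (nonsense, frameshift,
   exon CNV) qualify outright; otherwise a CADD phred score at or above the
   cutoff, or agreement of at least ``min_tool_votes`` of the binary
   predictors (SIFT / PolyPhen / splice prediction), is required;

and the parent is a heterozygous carrier.  Homozygous parental calls are
excluded from couple matching (parents are unaffected carriers) but logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import yaml

from .variants import (AnnotatedRecord, AnnotationBundle, Consequence, SeqVariant,
                       VariantKind, Zygosity)

__all__ = ["FilterParams", "is_rare", "is_candidate_consequence",
           "is_predicted_deleterious", "filter_parent_variants"]

log = logging.getLogger(__name__)

_QUALIFYING = frozenset({
    Consequence.MISSENSE, Consequence.NONSENSE, Consequence.FRAMESHIFT,
    Consequence.INFRAME_INDEL, Consequence.SPLICE_SITE,
})
_LOF = frozenset({Consequence.NONSENSE, Consequence.FRAMESHIFT})


@dataclass(frozen=True)
class FilterParams:
    """Filter thresholds.

    maf_threshold : population-frequency cutoff (default 0.01, i.e. MAF < 1%).
    cadd_cutoff : CADD phred cutoff (default 20, the conventional "top 1%"
        deleteriousness rank).
    min_tool_votes : number of binary prediction tools that must agree when
        the CADD score is below the cutoff or missing (default 2 of 3).
    """

    maf_threshold: float = 0.01
    cadd_cutoff: float = 20.0
    min_tool_votes: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold < 1.0:
            raise ValueError("maf_threshold must lie in (0,1)")
        if self.cadd_cutoff <= 0:
            raise ValueError("cadd_cutoff must be positive")
        if self.min_tool_votes not in (1, 2, 3):
            raise ValueError("min_tool_votes must be 1, 2 or 3")

    @classmethod
    def from_yaml(cls, path: str) -> "FilterParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"filter config {path} must be a mapping")
        allowed = {"maf_threshold", "cadd_cutoff", "min_tool_votes"}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        return cls(**data)


def is_rare(a: AnnotationBundle, p: FilterParams | None = None) -> bool:
    p = p or FilterParams()
    if a.hgmd_disease_causing or a.clinvar_disease_causing:
        return True
    return all(m < p.maf_threshold for m in a.present_mafs())


def is_candidate_consequence(v: SeqVariant) -> bool:
    return v.kind is VariantKind.EXON_CNV or v.consequence in _QUALIFYING


def is_predicted_deleterious(v: SeqVariant, a: AnnotationBundle,
                             p: FilterParams | None = None) -> bool:
    p = p or FilterParams()
    if v.kind is VariantKind.EXON_CNV or v.consequence in _LOF:
        return True
    if a.cadd_phred is not None and a.cadd_phred >= p.cadd_cutoff:
        return True
    votes = sum(bool(t) for t in (a.sift_deleterious, a.polyphen_damaging,
                                  a.splice_predicted_damaging) if t is not None)
    return votes >= p.min_tool_votes


def filter_parent_variants(records: Sequence[AnnotatedRecord],
                           p: FilterParams | None = None) -> list[AnnotatedRecord]:
    """Retain heterozygous records passing all three predicates, order preserved."""
    p = p or FilterParams()
    kept: list[AnnotatedRecord] = []
    for r in records:
        if r.genotype.zygosity is Zygosity.HOM:
            log.warning("homozygous parental call at %s in %s excluded from couple matching",
                        r.variant.label, r.genotype.sample_id)
            continue
        if r.genotype.zygosity is not Zygosity.HET:
            continue
        if (is_rare(r.annotation, p) and is_candidate_consequence(r.variant)
                and is_predicted_deleterious(r.variant, r.annotation, p)):
            kept.append(r)
    return kept
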