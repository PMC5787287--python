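"""Cosegregation checks against affected offspring and Mendelian recurrence risk.

A candidate gene is *confirmed* when at least one affected child (or fetus)
with available DNA carries the predicted risk genotype: homozygous for a
shared parental variant, or both alleles of a compound-het candidate.  An
affected child carrying only one allele demotes the gene to carrier-only
for that child; an *unaffected* child with the full risk genotype is
inconsistent with causality.  Without material from any affected child the
status is unavailable.

Recurrence risk is Mendelian-exact (no de novo or mosaic terms): 25% per
pregnancy for an autosomal-recessive candidate with two carrier parents,
50% for male pregnancies of a carrier mother under maternally inherited
X-linked recessive inheritance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .matching import CandidateGene, MatchMode
from .variants import GenotypeCall, Zygosity

__all__ = ["CosegStatus", "ChildObservation", "CosegregationResult", "RiskQuery",
           "check_cosegregation", "recurrence_risk", "fetal_genotype_interpretation"]


class CosegStatus(str, enum.Enum):
    CONFIRMED = "confirmed"
    CARRIER_ONLY = "carrier_only"
    INCONSISTENT = "inconsistent"
    UNAVAILABLE = "unavailable"


# per-child annotations also allow "uninformative" (unaffected non-risk child)
ChildStatus = Literal["confirmed", "carrier_only", "inconsistent",
                      "unavailable", "uninformative"]


@dataclass(frozen=True)
class ChildObservation:
    child_id: str
    affected: bool
    genotypes: tuple[GenotypeCall, ...] = ()
    material_available: bool = True

    def __post_init__(self) -> None:
        if not self.material_available and self.genotypes:
            raise ValueError("no material implies no genotypes")


@dataclass(frozen=True)
class CosegregationResult:
    candidate: CandidateGene
    status: CosegStatus
    per_child: dict = field(default_factory=dict)  # child_id -> ChildStatus


@dataclass(frozen=True)
class RiskQuery:
    inheritance: Literal["AR", "XL_maternal"]
    fetus_sex: Literal["male", "female", "unknown"] = "unknown"
    both_parents_carriers: bool = False
    mother_carrier: bool = False

    def __post_init__(self) -> None:
        if self.inheritance not in ("AR", "XL_maternal"):
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if self.fetus_sex not in ("male", "female", "unknown"):
            raise ValueError(f"unknown fetus sex {self.fetus_sex!r}")


def _allele_pattern(c: CandidateGene, child: ChildObservation) -> tuple[bool, bool, int]:
    """(has maternal-side allele, has paternal-side allele, any-hom flag).

    Raises ``ValueError`` when the child is genotyped at a variant that is
    not part of the candidate.
    """
    mkeys = {r.variant.identity_key for r in c.maternal_variants}
    pkeys = {r.variant.identity_key for r in c.paternal_variants}
    has_m = has_p = False
    hom = 0
    for g in child.genotypes:
        key = g.variant.identity_key
        if key not in mkeys and key not in pkeys:
            raise ValueError(
                f"child {child.child_id} genotyped at {g.variant.label}, "
                f"absent from candidate {c.gene}")
        if g.zygosity is Zygosity.ABSENT:
            continue
        if key in mkeys:
            has_m = True
        if key in pkeys:
            has_p = True
        if g.zygosity is Zygosity.HOM:
            hom += 1
    return has_m, has_p, hom


def _risk_genotype(c: CandidateGene, child: ChildObservation) -> bool:
    has_m, has_p, hom = _allele_pattern(c, child)
    if c.mode is MatchMode.SHARED_HOM:
        return hom >= 1
    return has_m and has_p


def _carries_any(c: CandidateGene, child: ChildObservation) -> bool:
    has_m, has_p, _ = _allele_pattern(c, child)
    return has_m or has_p


def check_cosegregation(c: CandidateGene,
                        children: Sequence[ChildObservation]) -> CosegregationResult:
    """Evaluate a candidate against the family's children.

    Overall status: confirmed if any affected child has the risk genotype;
    else inconsistent if any child contradicts the candidate (affected
    non-carrier, or unaffected with the risk genotype); else carrier_only if
    an affected child carries a single allele; else unavailable.
    """
    per_child: dict[str, str] = {}
    for child in children:
        if not child.material_available:
            per_child[child.child_id] = "unavailable"
            continue
        risk = _risk_genotype(c, child)
        if child.affected:
            if risk:
                per_child[child.child_id] = "confirmed"
            elif _carries_any(c, child):
                per_child[child.child_id] = "carrier_only"
            else:
                per_child[child.child_id] = "inconsistent"
        else:
            per_child[child.child_id] = "inconsistent" if risk else "uninformative"

    statuses = set(per_child.values())
    if "confirmed" in statuses:
        status = CosegStatus.CONFIRMED
    elif "inconsistent" in statuses:
        status = CosegStatus.INCONSISTENT
    elif "carrier_only" in statuses:
        status = CosegStatus.CARRIER_ONLY
    else:
        status = CosegStatus.UNAVAILABLE
    return CosegregationResult(candidate=c, status=status, per_child=per_child)


def recurrence_risk(q: RiskQuery) -> float:
    """Mendelian recurrence risk for a future pregnancy.

    AR with both parents carriers: 1/4 regardless of fetus sex.  Maternally
    inherited X-linked recessive with a carrier mother: 1/2 for a male
    fetus, 0 for a female fetus (affected-status risk under full
    recessivity), 1/4 when the sex is unknown (marginal over sex).  Any
    non-carrier configuration: 0.
    """
    if q.inheritance == "AR":
        return 0.25 if q.both_parents_carriers else 0.0
    if not q.mother_carrier:
        return 0.0
    return {"male": 0.5, "female": 0.0, "unknown": 0.25}[q.fetus_sex]


def fetal_genotype_interpretation(
        c: CandidateGene, fetus: ChildObservation
) -> Literal["unaffected_noncarrier", "carrier", "affected_genotype"]:
    """Classify a prenatally tested fetus at the candidate's variants."""
    if _risk_genotype(c, fetus):
        return "affected_genotype"
    if _carries_any(c, fetus):
        return "carrier"
    return "unaffected_noncarrier"
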