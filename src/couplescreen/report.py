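"""Couple-level screening driver and cohort reporting.

``screen_couple`` runs the full analysis for one couple: optional panel
restriction, the per-parent filter cascade, gene-level matching, ACMG
classification of each candidate's parental alleles, the prenatal/PGD
eligibility rule (both alleles Class >= 4), and cosegregation against any
genotyped children.  ``summarize_cohort`` tallies couples into the three
outcome tiers (eligible Class-4/5 match, Class-3 candidate, no finding) and
counts families with a child-confirmed genotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from . import acmg
from .cosegregation import ChildObservation, CosegStatus, CosegregationResult, check_cosegregation
from .filters import FilterParams, filter_parent_variants
from .fixture import evidence_key
from .matching import CandidateGene, match_all
from .panel import GenePanel, restrict_to_panel
from .variants import (AnnotatedRecord, GenotypeCall, Zygosity, read_annotated_vcf)

__all__ = ["ClassifiedCandidate", "CoupleReport", "CohortSummary",
           "screen_couple", "summarize_cohort", "load_pedigree", "load_evidence",
           "load_children", "write_report_tsv", "write_report_json",
           "REPORT_COLUMNS"]

REPORT_COLUMNS = ("couple_id", "gene", "mode", "maternal_variant",
                  "paternal_variant", "class_m", "class_f", "eligible",
                  "coseg_status", "tier")


@dataclass(frozen=True)
class ClassifiedCandidate:
    candidate: CandidateGene
    class_maternal: int
    class_paternal: int
    eligible: bool
    coseg: CosegregationResult | None = None

    @property
    def reportable(self) -> bool:
        return (acmg.reportable(self.class_maternal)
                and acmg.reportable(self.class_paternal))

    @property
    def max_cadd(self) -> float:
        cadds = [r.annotation.cadd_phred
                 for r in self.candidate.maternal_variants + self.candidate.paternal_variants
                 if r.annotation.cadd_phred is not None]
        return max(cadds, default=0.0)


@dataclass(frozen=True)
class CoupleReport:
    couple_id: str
    consanguinity: str = "none"
    mode_flags: str = "panel"        # panel | wes
    candidates: tuple[ClassifiedCandidate, ...] = ()
    xl_maternal_carriers: tuple[AnnotatedRecord, ...] = ()
    summary_tier: str = "no_finding"  # class45_match | class3_candidate | no_finding


@dataclass(frozen=True)
class CohortSummary:
    n_couples: int
    n_class45_match: int
    n_class3_candidate: int
    n_no_finding: int
    n_confirmed_in_child: int

    def __post_init__(self) -> None:
        if self.n_class45_match + self.n_class3_candidate + self.n_no_finding != self.n_couples:
            raise ValueError("tier counts must partition the cohort")


def _codes_for(rec: AnnotatedRecord, evidence: dict | None) -> frozenset[str]:
    if rec.evidence:
        return frozenset(rec.evidence)
    if evidence:
        return frozenset(evidence.get(evidence_key(rec.variant), ()))
    return frozenset()


def _classify_side(records, evidence) -> int:
    return max(acmg.combine_evidence(_codes_for(r, evidence)) for r in records)


def screen_couple(couple_id: str,
                  mother: Sequence[AnnotatedRecord],
                  father: Sequence[AnnotatedRecord],
                  *,
                  panel: GenePanel | None = None,
                  params: FilterParams | None = None,
                  evidence: dict | None = None,
                  children: Sequence[ChildObservation] | None = None,
                  consanguinity: str = "none") -> CoupleReport:
    """Run filter -> match -> classify -> cosegregation for one couple.

    ``panel=None`` is WES mode (no gene restriction).  ``evidence`` maps
    variant keys to ACMG code collections; explicit per-record codes take
    precedence.  ``children`` may be genotyped at any of the couple's
    variants; calls are subset to each candidate before cosegregation.
    """
    params = params or FilterParams()
    mode = "panel" if panel is not None else "wes"
    if panel is not None:
        mother = restrict_to_panel(mother, panel)
        father = restrict_to_panel(father, panel)

    xl_carriers: tuple[AnnotatedRecord, ...] = ()
    if panel is not None and panel.xl_genes():
        xl = panel.xl_genes()
        xl_carriers = tuple(r for r in filter_parent_variants(
            [r for r in mother if r.variant.gene in xl], params))
        mother = [r for r in mother if r.variant.gene not in xl]
        father = [r for r in father if r.variant.gene not in xl]

    mom_kept = filter_parent_variants(mother, params)
    dad_kept = filter_parent_variants(father, params)
    candidates = match_all(mom_kept, dad_kept)

    classified: list[ClassifiedCandidate] = []
    for cand in candidates:
        cm = _classify_side(cand.maternal_variants, evidence)
        cf = _classify_side(cand.paternal_variants, evidence)
        coseg = None
        if children:
            coseg = check_cosegregation(cand, _subset_children(cand, children))
        classified.append(ClassifiedCandidate(
            candidate=cand, class_maternal=cm, class_paternal=cf,
            eligible=acmg.eligible_for_action(cm, cf), coseg=coseg))

    # rank: eligible first, then joint class, then CADD, then gene symbol
    classified.sort(key=lambda c: (not c.eligible,
                                   -min(c.class_maternal, c.class_paternal),
                                   -c.max_cadd, c.candidate.gene))

    if any(c.eligible for c in classified):
        tier = "class45_match"
    elif any(c.reportable for c in classified):
        tier = "class3_candidate"
    else:
        tier = "no_finding"

    return CoupleReport(couple_id=couple_id, consanguinity=consanguinity,
                        mode_flags=mode, candidates=tuple(classified),
                        xl_maternal_carriers=xl_carriers, summary_tier=tier)


def _subset_children(cand: CandidateGene,
                     children: Sequence[ChildObservation]) -> list[ChildObservation]:
    keys = cand.variant_keys
    out = []
    for c in children:
        gts = tuple(g for g in c.genotypes if g.variant.identity_key in keys)
        out.append(ChildObservation(child_id=c.child_id, affected=c.affected,
                                    genotypes=gts,
                                    material_available=c.material_available))
    return out


def summarize_cohort(reports: Sequence[CoupleReport]) -> CohortSummary:
    """Tally couple tiers and child-confirmed families across the cohort."""
    ids = [r.couple_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate couple_id in cohort")
    tiers = [r.summary_tier for r in reports]
    confirmed = sum(
        1 for r in reports
        if any(c.coseg is not None and c.coseg.status is CosegStatus.CONFIRMED
               for c in r.candidates))
    return CohortSummary(
        n_couples=len(reports),
        n_class45_match=tiers.count("class45_match"),
        n_class3_candidate=tiers.count("class3_candidate"),
        n_no_finding=tiers.count("no_finding"),
        n_confirmed_in_child=confirmed)


# --- sidecar loaders -------------------------------------------------------

def load_pedigree(path: str) -> list[dict]:
    """Read the pedigree sidecar: sample_id, role, affected, sex, material."""
    entries: list[dict] = []
    with open(path) as fh:
        header = None
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["sample_id", "role", "affected", "sex", "material"]
                if header != expected:
                    raise ValueError(f"pedigree header must be {expected} (line {line_no})")
                continue
            if len(fields) != 5:
                raise ValueError(f"pedigree line {line_no} has {len(fields)} fields")
            sample_id, role, affected, sex, material = fields
            if role not in ("mother", "father", "child", "fetus"):
                raise ValueError(f"unknown role {role!r} at line {line_no}")
            if sex not in ("M", "F", "U"):
                raise ValueError(f"unknown sex {sex!r} at line {line_no}")
            entries.append({"sample_id": sample_id, "role": role,
                            "affected": affected == "1", "sex": sex,
                            "material": material == "1"})
    if header is None:
        raise ValueError(f"pedigree file {path} is empty")
    return entries


def load_evidence(path: str) -> dict[str, frozenset[str]]:
    """Read the evidence sidecar TSV: variant_key -> comma-separated codes."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("variant_key\t"):
                continue
            key, codes = line.split("\t")
            out[key] = frozenset(codes.split(","))
    return out


def load_children(children_vcf: str, pedigree: Sequence[dict]) -> list[ChildObservation]:
    """Assemble child observations from a multi-sample VCF plus the pedigree.

    Children flagged without material appear with empty genotypes even if
    the VCF carries a column for them.
    """
    out: list[ChildObservation] = []
    for entry in pedigree:
        if entry["role"] not in ("child", "fetus"):
            continue
        gts: tuple[GenotypeCall, ...] = ()
        if entry["material"] and children_vcf is not None:
            try:
                recs = read_annotated_vcf(children_vcf, entry["sample_id"])
            except KeyError:
                recs = []
            gts = tuple(r.genotype for r in recs)
        out.append(ChildObservation(child_id=entry["sample_id"],
                                    affected=entry["affected"], genotypes=gts,
                                    material_available=bool(gts) or entry["material"]))
    return out


# --- report serialization --------------------------------------------------

def _variant_labels(records) -> str:
    return ";".join(r.variant.label for r in records)


def report_rows(report: CoupleReport) -> list[dict]:
    rows = []
    if not report.candidates:
        rows.append(dict(zip(REPORT_COLUMNS, (
            report.couple_id, "", "", "", "", "", "", "", "",
            report.summary_tier))))
    for c in report.candidates:
        rows.append(dict(zip(REPORT_COLUMNS, (
            report.couple_id, c.candidate.gene, c.candidate.mode.value,
            _variant_labels(c.candidate.maternal_variants),
            _variant_labels(c.candidate.paternal_variants),
            str(c.class_maternal), str(c.class_paternal),
            "1" if c.eligible else "0",
            c.coseg.status.value if c.coseg else "unavailable",
            report.summary_tier))))
    return rows


def write_report_tsv(path: str, reports: Sequence[CoupleReport]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for rep in reports:
            for row in report_rows(rep):
                fh.write("\t".join(row[c] for c in REPORT_COLUMNS) + "\n")


def write_report_json(path: str, reports: Sequence[CoupleReport],
                      summary: CohortSummary | None = None) -> None:
    payload: dict = {"reports": [report_rows(r) for r in reports]}
    if summary is not None:
        payload["summary"] = {
            "n_couples": summary.n_couples,
            "n_class45_match": summary.n_class45_match,
            "n_class3_candidate": summary.n_class3_candidate,
            "n_no_finding": summary.n_no_finding,
            "n_confirmed_in_child": summary.n_confirmed_in_child,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
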