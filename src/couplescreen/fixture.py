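"""Reconstructed 13-couple demonstration cohort with known expected outcomes.

The cohort encodes, family by family, the variants a carrier screen of 13
couples (8 consanguineous, 5 not) would see: five couples with Class-4/5
candidates in established disease genes (CTSD+FTCD+NAGA, COQ2, ACADVL,
UNC13D, BRAT1), two couples with Class-3 candidates in genes without an
established disease entry (a shared PALLD exon-1 deletion; APAF1 compound
het), and six couples whose variants all fail a filter or the couple
overlap.  Affected-child genotypes (homozygous / compound het) are encoded
where the family had material, so cosegregation can confirm four families.

Genomic coordinates are synthetic placeholders (gene-indexed spacing on one
contig) because the source material is HGVS-based; the manifest maps HGVS to
the synthetic coordinate.  ACMG evidence codes are reconstructed fixture
metadata chosen so that the rule engine reproduces each variant's class;
they are not clinically asserted code sets.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from .synthetic import decoy_records
from .variants import (AnnotatedRecord, AnnotationBundle, Consequence, GenotypeCall,
                       SeqVariant, VariantKind, Zygosity, write_annotated_vcf)

__all__ = ["FamilyFixture", "CohortFixture", "build_table1_fixture",
           "write_fixture", "evidence_key"]

# gene-indexed synthetic coordinates on contig 1
_GENE_ORDER = ("ACADVL", "APAF1", "BRAT1", "COQ2", "CTSD", "FTCD", "NAGA",
               "PALLD", "UNC13D")


def _gpos(gene: str, offset: int = 0) -> int:
    return (_GENE_ORDER.index(gene) + 1) * 1_000_000 + offset


def evidence_key(v: SeqVariant) -> str:
    if v.kind is VariantKind.EXON_CNV:
        return f"CNV:{v.gene}:{v.exon}"
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


@dataclass(frozen=True)
class ChildSpec:
    child_id: str
    affected: bool
    sex: str = "U"              # M / F / U
    material: bool = False
    genotypes: tuple[tuple[SeqVariant, Zygosity], ...] = ()


@dataclass(frozen=True)
class FamilyFixture:
    family_id: int
    consanguinity: str          # none | first_cousins | other
    mode: str                   # panel | wes
    mother: tuple[AnnotatedRecord, ...]
    father: tuple[AnnotatedRecord, ...]
    children: tuple[ChildSpec, ...] = ()
    evidence: dict = field(default_factory=dict)   # evidence key -> tuple of codes
    expected: dict = field(default_factory=dict)

    @property
    def couple_id(self) -> str:
        return f"family{self.family_id:02d}"

    @property
    def is_consanguineous(self) -> bool:
        return self.consanguinity != "none"


@dataclass(frozen=True)
class CohortFixture:
    families: tuple[FamilyFixture, ...]
    panel_genes: tuple[str, ...]
    manifest: dict


def _var(gene: str, offset: int, ref: str, alt: str, transcript: str,
         hgvs_c: str, hgvs_p: str, csq: Consequence) -> SeqVariant:
    kind = VariantKind.SNV if len(ref) == 1 and len(alt) == 1 else VariantKind.INDEL
    return SeqVariant(chrom="1", pos=_gpos(gene, offset), ref=ref, alt=alt,
                      gene=gene, transcript=transcript, hgvs_c=hgvs_c,
                      hgvs_p=hgvs_p, consequence=csq, kind=kind)


def _rec(sample: str, v: SeqVariant, ann: AnnotationBundle,
         zyg: Zygosity = Zygosity.HET) -> AnnotatedRecord:
    return AnnotatedRecord(variant=v,
                           genotype=GenotypeCall(sample, v, zyg), annotation=ann)


# --- the candidate variants, as printed (transcripts, HGVS, CADD, classes) ---

CTSD = _var("CTSD", 268, "T", "TC", "NM_001909",
            "c.268_269insC", "p.(Gln90Profs*50)", Consequence.FRAMESHIFT)
CTSD_ANN = AnnotationBundle(cadd_phred=None)            # CADD n.a.; Class 4

FTCD = _var("FTCD", 530, "G", "A", "NM_001320412",
            "c.530G>A", "p.(Gly177Glu)", Consequence.MISSENSE)
FTCD_ANN = AnnotationBundle(cadd_phred=25.8)            # Class 4

NAGA = _var("NAGA", 973, "G", "A", "NM_000262",
            "c.973G>A", "p.(Glu325Lys)", Consequence.MISSENSE)
NAGA_ANN = AnnotationBundle(sift_deleterious=True, polyphen_damaging=True)  # Class 3

COQ2_M = _var("COQ2", 1197, "CT", "C", "NM_015697",
              "c.1197delT", "p.(Asn401Ilefs*15)", Consequence.FRAMESHIFT)
COQ2_M_ANN = AnnotationBundle(cadd_phred=23.7)          # Class 5
COQ2_F = _var("COQ2", 764, "C", "T", "NM_015697",
              "c.764C>T", "p.(Pro255Leu)", Consequence.MISSENSE)
COQ2_F_ANN = AnnotationBundle(cadd_phred=29.0)          # Class 4

# Table form of the variant (the running text prints a different
# transcript-level description; see manifest notes)
ACADVL = _var("ACADVL", 1274, "T", "C", "NM_001033859",
              "c.1274T>C", "p.(L425P)", Consequence.MISSENSE)
ACADVL_ANN = AnnotationBundle(cadd_phred=27.4)          # Class 4

UNC13D = _var("UNC13D", 2447, "G", "T", "NM_199242",
              "c.2447+1G>T", "p.?", Consequence.SPLICE_SITE)
UNC13D_ANN = AnnotationBundle(cadd_phred=27.4, splice_predicted_damaging=True)  # Class 4

BRAT1 = _var("BRAT1", 1280, "G", "A", "NM_152743",
             "c.1280G>A", "p.(Arg427Gln)", Consequence.MISSENSE)
BRAT1_ANN = AnnotationBundle(cadd_phred=32.0)           # Class 4

PALLD = SeqVariant(chrom="1", pos=_gpos("PALLD"), ref="", alt="", gene="PALLD",
                   transcript="NM_001166108", hgvs_c="", hgvs_p="",
                   consequence=Consequence.OTHER_NONCODING,
                   kind=VariantKind.EXON_CNV, exon="1")
PALLD_ANN = AnnotationBundle()                          # CADD n.a.; Class 3

APAF1_M = _var("APAF1", 1350, "C", "G", "NM_181861",
               "c.1350C>G", "p.(Cys450Trp)", Consequence.MISSENSE)
APAF1_M_ANN = AnnotationBundle(cadd_phred=23.1)         # Class 3
APAF1_F = _var("APAF1", 3127, "C", "G", "NM_181861",
               "c.3127C>G", "p.(His1043Asp)", Consequence.MISSENSE)
APAF1_F_ANN = AnnotationBundle(cadd_phred=25.7)         # Class 3

# reconstructed evidence codes reproducing the printed classes
_EVIDENCE = {
    evidence_key(CTSD): ("PVS1", "PM2"),                 # -> 4
    evidence_key(FTCD): ("PS1", "PM2"),                  # -> 4
    evidence_key(NAGA): ("PM2", "PP3"),                  # -> 3
    evidence_key(COQ2_M): ("PVS1", "PS3", "PM2"),        # -> 5
    evidence_key(COQ2_F): ("PS1", "PM2"),                # -> 4
    evidence_key(ACADVL): ("PM2", "PM3", "PP3", "PP4"),  # -> 4
    evidence_key(UNC13D): ("PVS1", "PM2"),               # -> 4
    evidence_key(BRAT1): ("PM1", "PM2", "PP3", "PP4"),   # -> 4
    evidence_key(PALLD): ("PM2",),                       # -> 3
    evidence_key(APAF1_M): ("PM2", "PP3"),               # -> 3
    evidence_key(APAF1_F): ("PM2", "PP3"),               # -> 3
}


def _overlap_decoy(sample: str, fam: int) -> AnnotatedRecord:
    """Rare deleterious missense carried by one partner only (fails overlap)."""
    v = SeqVariant(chrom="1", pos=60_000_000 + fam * 1000, ref="C", alt="T",
                   gene=f"OVL{fam:02d}", consequence=Consequence.MISSENSE)
    return _rec(sample, v, AnnotationBundle(cadd_phred=26.0))


def _hom_decoy(sample: str, fam: int) -> AnnotatedRecord:
    """Homozygous rare deleterious call (excluded: parents must be het carriers)."""
    v = SeqVariant(chrom="1", pos=61_000_000 + fam * 1000, ref="G", alt="A",
                   gene=f"HOM{fam:02d}", consequence=Consequence.MISSENSE)
    return _rec(sample, v, AnnotationBundle(cadd_phred=24.0), zyg=Zygosity.HOM)


def _background(sample: str, fam: int) -> list[AnnotatedRecord]:
    """Per-family background: 3 shared predicate-failing decoys + an
    overlap-failing and (father) a homozygous decoy."""
    recs = decoy_records(sample, 3, seed=fam)
    if sample == "MOTHER":
        recs.append(_overlap_decoy(sample, fam))
    else:
        recs.append(_hom_decoy(sample, fam))
    return recs


def _family(fid: int, consang: str, mode: str,
            mother_core: list[tuple[SeqVariant, AnnotationBundle]],
            father_core: list[tuple[SeqVariant, AnnotationBundle]],
            children: tuple[ChildSpec, ...],
            expected: dict) -> FamilyFixture:
    mother = tuple(_rec("MOTHER", v, a) for v, a in mother_core) + tuple(_background("MOTHER", fid))
    father = tuple(_rec("FATHER", v, a) for v, a in father_core) + tuple(_background("FATHER", fid))
    keys = {evidence_key(v) for v, _ in mother_core + father_core}
    evidence = {k: _EVIDENCE[k] for k in sorted(keys) if k in _EVIDENCE}
    return FamilyFixture(family_id=fid, consanguinity=consang, mode=mode,
                         mother=mother, father=father, children=children,
                         evidence=evidence, expected=expected)


def build_table1_fixture() -> CohortFixture:
    """Construct the full 13-couple cohort with expected pipeline outcomes."""
    fams: list[FamilyFixture] = []

    fams.append(_family(
        1, "first_cousins", "wes",
        [(CTSD, CTSD_ANN), (FTCD, FTCD_ANN), (NAGA, NAGA_ANN)],
        [(CTSD, CTSD_ANN), (FTCD, FTCD_ANN), (NAGA, NAGA_ANN)],
        (
            ChildSpec("F01_C1", affected=True, sex="F", material=False),
            ChildSpec("F01_C2", affected=True, sex="M", material=False),
            ChildSpec("F01_C3", affected=True, sex="M", material=True,
                      genotypes=((CTSD, Zygosity.HOM), (FTCD, Zygosity.HET),
                                 (NAGA, Zygosity.HET))),
        ),
        {"tier": "class45_match", "candidates": [["CTSD", "shared_hom"],
                                                 ["FTCD", "shared_hom"],
                                                 ["NAGA", "shared_hom"]],
         "eligible_genes": ["CTSD", "FTCD"], "confirmed_genes": ["CTSD"]},
    ))

    fams.append(_family(
        2, "none", "panel",
        [(COQ2_M, COQ2_M_ANN)], [(COQ2_F, COQ2_F_ANN)],
        (ChildSpec("F02_C1", affected=True, sex="F", material=False),),
        {"tier": "class45_match", "candidates": [["COQ2", "compound_het"]],
         "eligible_genes": ["COQ2"], "confirmed_genes": []},
    ))

    fams.append(_family(
        3, "first_cousins", "panel",
        [(ACADVL, ACADVL_ANN)], [(ACADVL, ACADVL_ANN)],
        (ChildSpec("F03_C1", affected=True, sex="M", material=True,
                   genotypes=((ACADVL, Zygosity.HOM),)),),
        {"tier": "class45_match", "candidates": [["ACADVL", "shared_hom"]],
         "eligible_genes": ["ACADVL"], "confirmed_genes": ["ACADVL"]},
    ))

    fams.append(_family(
        4, "first_cousins", "panel",
        [(UNC13D, UNC13D_ANN)], [(UNC13D, UNC13D_ANN)],
        (
            ChildSpec("F04_C1", affected=True, sex="F", material=False),
            ChildSpec("F04_C2", affected=False, sex="M", material=True,
                      genotypes=((UNC13D, Zygosity.ABSENT),)),
        ),
        {"tier": "class45_match", "candidates": [["UNC13D", "shared_hom"]],
         "eligible_genes": ["UNC13D"], "confirmed_genes": []},
    ))

    fams.append(_family(
        5, "other", "panel",       # multiple consanguinity: first cousins whose
        [(BRAT1, BRAT1_ANN)],      # parents are also first cousins
        [(BRAT1, BRAT1_ANN)],
        (ChildSpec("F05_C1", affected=True, sex="M", material=False),),
        {"tier": "class45_match", "candidates": [["BRAT1", "shared_hom"]],
         "eligible_genes": ["BRAT1"], "confirmed_genes": []},
    ))

    _none = {"tier": "no_finding", "candidates": [], "eligible_genes": [],
             "confirmed_genes": []}
    fams.append(_family(6, "none", "panel", [], [],
                        (ChildSpec("F06_C1", affected=True, sex="F", material=False),),
                        dict(_none)))

    fams.append(_family(
        7, "first_cousins", "wes",
        [(PALLD, PALLD_ANN)], [(PALLD, PALLD_ANN)],
        (
            ChildSpec("F07_C1", affected=True, sex="F", material=True,
                      genotypes=((PALLD, Zygosity.HOM),)),
            ChildSpec("F07_C2", affected=True, sex="M", material=False),
            ChildSpec("F07_C3", affected=True, sex="M", material=False),
            ChildSpec("F07_C4", affected=False, sex="U", material=True,
                      genotypes=((PALLD, Zygosity.ABSENT),)),
        ),
        {"tier": "class3_candidate", "candidates": [["PALLD", "shared_hom"]],
         "eligible_genes": [], "confirmed_genes": ["PALLD"]},
    ))

    fams.append(_family(8, "other", "panel", [], [],
                        (ChildSpec("F08_C1", affected=True, sex="F", material=False),),
                        dict(_none)))
    fams.append(_family(9, "none", "panel", [], [],
                        (ChildSpec("F09_C1", affected=True, sex="M", material=False),
                         ChildSpec("F09_C2", affected=True, sex="F", material=False)),
                        dict(_none)))
    fams.append(_family(10, "other", "panel", [], [], (), dict(_none)))
    fams.append(_family(11, "none", "panel", [], [],
                        (ChildSpec("F11_C1", affected=True, sex="F", material=False),
                         ChildSpec("F11_C2", affected=True, sex="M", material=False),
                         ChildSpec("F11_C3", affected=True, sex="M", material=False)),
                        dict(_none)))
    fams.append(_family(12, "other", "panel", [], [],
                        (ChildSpec("F12_C1", affected=True, sex="F", material=False),),
                        dict(_none)))

    fams.append(_family(
        13, "none", "wes",
        [(APAF1_M, APAF1_M_ANN)], [(APAF1_F, APAF1_F_ANN)],
        (
            ChildSpec("F13_F1", affected=True, sex="U", material=True,
                      genotypes=((APAF1_M, Zygosity.HET), (APAF1_F, Zygosity.HET))),
            ChildSpec("F13_F2", affected=True, sex="U", material=True,
                      genotypes=((APAF1_M, Zygosity.HET), (APAF1_F, Zygosity.HET))),
        ),
        {"tier": "class3_candidate", "candidates": [["APAF1", "compound_het"]],
         "eligible_genes": [], "confirmed_genes": ["APAF1"]},
    ))

    panel = _demo_panel_genes(fams)
    manifest = {
        "cohort": "reconstructed 13-couple carrier-screening demonstration cohort",
        "n_couples": len(fams),
        "n_consanguineous": sum(f.is_consanguineous for f in fams),
        "families": {
            f.couple_id: {
                "consanguinity": f.consanguinity,
                "mode": f.mode,
                "expected": f.expected,
                "children": [
                    {"child_id": c.child_id, "affected": c.affected, "sex": c.sex,
                     "material": c.material} for c in f.children],
            } for f in fams
        },
        "expected_summary": {"n_class45_match": 5, "n_class3_candidate": 2,
                             "n_no_finding": 6, "n_confirmed_in_child": 4},
        "coordinates": "synthetic placeholders: contig 1, gene-indexed 1 Mb "
                       "spacing; HGVS strings identify the real variants",
        "hgvs_map": {evidence_key(v): f"{v.gene} {v.transcript}:{v.hgvs_c or 'exon'+v.exon+'del'}"
                     for v in (CTSD, FTCD, NAGA, COQ2_M, COQ2_F, ACADVL, UNC13D,
                               BRAT1, PALLD, APAF1_M, APAF1_F)},
        "notes": [
            "The ACADVL variant is described inconsistently in the source "
            "material (c.1274T>C p.(L425P) in the overview table vs "
            "c.1436T>C p.(Pro479Leu) in the running text); this fixture "
            "encodes the table form and does not reconcile the two.",
            "ACMG evidence codes are reconstructed to reproduce the printed "
            "classes; the source prints classes only.",
            "The NAGA variant's class is not printed; Class 3 is assigned "
            "because the variant was deemed not eligible for prenatal testing.",
        ],
    }
    return CohortFixture(families=tuple(fams), panel_genes=panel, manifest=manifest)


def _demo_panel_genes(fams: list[FamilyFixture]) -> tuple[str, ...]:
    # panel-discoverable disease genes + every decoy symbol, so that decoys
    # are removed by the filter cascade rather than by panel restriction;
    # FTCD/NAGA/APAF1/PALLD are deliberately absent (exome/array-tier finds)
    genes = {"CTSD", "COQ2", "ACADVL", "UNC13D", "BRAT1"}
    for f in fams:
        for r in f.mother + f.father:
            g = r.variant.gene
            if g.startswith(("DCY", "OVL", "HOM")):
                genes.add(g)
    return tuple(sorted(genes))


def write_fixture(fixture: CohortFixture, out_dir: str) -> None:
    """Emit the cohort as familyNN/{mother,father,children}.vcf + sidecars,
    panel.txt and manifest.json.  Fully deterministic."""
    os.makedirs(out_dir, exist_ok=True)
    for fam in fixture.families:
        fdir = os.path.join(out_dir, fam.couple_id)
        os.makedirs(fdir, exist_ok=True)
        write_annotated_vcf(os.path.join(fdir, "mother.vcf"), list(fam.mother),
                            sample_ids=["MOTHER"])
        write_annotated_vcf(os.path.join(fdir, "father.vcf"), list(fam.father),
                            sample_ids=["FATHER"])

        child_records: list[AnnotatedRecord] = []
        genotyped = [c for c in fam.children if c.material and c.genotypes]
        ann_by_key = {r.variant.identity_key: r.annotation
                      for r in fam.mother + fam.father}
        for c in genotyped:
            for v, zyg in c.genotypes:
                child_records.append(AnnotatedRecord(
                    variant=v, genotype=GenotypeCall(c.child_id, v, zyg),
                    annotation=ann_by_key.get(v.identity_key, AnnotationBundle())))
        if child_records:
            write_annotated_vcf(os.path.join(fdir, "children.vcf"), child_records,
                                sample_ids=[c.child_id for c in genotyped])

        with open(os.path.join(fdir, "pedigree.tsv"), "w") as fh:
            fh.write("sample_id\trole\taffected\tsex\tmaterial\n")
            fh.write("MOTHER\tmother\t0\tF\t1\nFATHER\tfather\t0\tM\t1\n")
            for c in fam.children:
                fh.write(f"{c.child_id}\tchild\t{int(c.affected)}\t{c.sex}\t"
                         f"{int(c.material)}\n")

        with open(os.path.join(fdir, "evidence.tsv"), "w") as fh:
            fh.write("# reconstructed evidence codes (fixture metadata)\n")
            fh.write("variant_key\tcodes\n")
            for key, codes in sorted(fam.evidence.items()):
                fh.write(f"{key}\t{','.join(codes)}\n")

    with open(os.path.join(out_dir, "panel.txt"), "w") as fh:
        fh.write("# demonstration virtual panel (disease genes + decoys)\n")
        for g in fixture.panel_genes:
            fh.write(g + "\tAR\n")

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(fixture.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
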