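"""Domain types for sequence variants and the annotated-VCF dialect.

The pipeline exchanges all variant data through a small VCF 4.2 dialect in
which per-variant annotation (gene symbol, consequence class, population
allele frequencies, database assertions, prediction scores) travels in INFO
keys with a fixed vocabulary.  Whole-exon copy-number events enter the same
stream as symbolic ``<DEL>`` records keyed by gene + exon label, so that a
shared exon deletion can flow through the same couple matcher as a shared
SNV.

Coordinates are 1-based VCF-style throughout; indels carry the anchor base.
Variant identity for all downstream matching is the normalized
``(chrom, pos, ref, alt)`` tuple for SNVs/indels and ``(gene, exon)`` for
exon CNVs.  HGVS strings are display metadata only, never match keys.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

__all__ = [
    "Consequence",
    "VariantKind",
    "Zygosity",
    "SeqVariant",
    "GenotypeCall",
    "AnnotationBundle",
    "AnnotatedRecord",
    "VcfFormatError",
    "read_annotated_vcf",
    "write_annotated_vcf",
    "normalize_variant",
]


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER_NONCODING = "other_noncoding"


class VariantKind(str, enum.Enum):
    SNV = "snv"
    INDEL = "indel"
    EXON_CNV = "exon_cnv"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    ABSENT = "absent"


@dataclass(frozen=True)
class SeqVariant:
    """One normalized variant: SNV, small indel, or whole-exon CNV.

    For ``exon_cnv`` records ``ref``/``alt`` are empty and the event is
    identified by ``(gene, exon)``; for SNVs/indels identity is
    ``(chrom, pos, ref, alt)``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.OTHER_NONCODING
    kind: VariantKind = VariantKind.SNV
    exon: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.kind is VariantKind.EXON_CNV:
            if not self.gene or not self.exon:
                raise ValueError("exon_cnv requires gene and exon label")
        else:
            if not self.ref or not self.alt:
                raise ValueError(f"{self.kind.value} requires ref and alt")
            if self.ref == self.alt:
                raise ValueError("ref must differ from alt")

    @property
    def identity_key(self) -> tuple:
        if self.kind is VariantKind.EXON_CNV:
            return ("cnv", self.gene, self.exon)
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        """Human-readable variant label used in reports."""
        if self.kind is VariantKind.EXON_CNV:
            return f"{self.gene}:exon{self.exon}del"
        hgvs = f" {self.hgvs_c}" if self.hgvs_c else ""
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}{hgvs}"


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    variant: SeqVariant
    zygosity: Zygosity


def _f6(x: float) -> float:
    # Annotation floats are carried at 6 significant digits; canonicalizing
    # at construction makes the htslib float32 round trip exact.
    return float(f"{float(x):.6g}")


@dataclass(frozen=True)
class AnnotationBundle:
    """Population frequencies, database assertions and prediction scores.

    ``None`` means *not listed in the available databases* — distinct from
    an observed frequency of 0, and treated as rare by the filter cascade.
    Numeric values are canonicalized to 6 significant digits.
    """

    maf_dbsnp: float | None = None
    maf_esp: float | None = None
    maf_exac: float | None = None
    hgmd_disease_causing: bool = False
    clinvar_disease_causing: bool = False
    cadd_phred: float | None = None
    sift_deleterious: bool | None = None
    polyphen_damaging: bool | None = None
    splice_predicted_damaging: bool | None = None

    def __post_init__(self) -> None:
        for name in ("maf_dbsnp", "maf_esp", "maf_exac", "cadd_phred"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _f6(v))
        for name in ("maf_dbsnp", "maf_esp", "maf_exac"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")

    def present_mafs(self) -> list[float]:
        return [m for m in (self.maf_dbsnp, self.maf_esp, self.maf_exac) if m is not None]


@dataclass(frozen=True)
class AnnotatedRecord:
    variant: SeqVariant
    genotype: GenotypeCall
    annotation: AnnotationBundle = field(default_factory=AnnotationBundle)
    evidence: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.genotype.variant is not self.variant and self.genotype.variant != self.variant:
            raise ValueError("genotype.variant must be the record's variant")


class VcfFormatError(ValueError):
    """Raised on a malformed line of the annotated-VCF dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)


# Fixed INFO key order: the writer always emits keys in this order so that
# fixtures are byte-stable across runs.
_INFO_KEYS = (
    "GENE", "TRANSCRIPT", "HGVSC", "HGVSP", "CSQ",
    "MAF_DBSNP", "MAF_ESP", "MAF_EXAC",
    "HGMD_DM", "CLNSIG_PATHO",
    "CADD", "SIFT_DEL", "PPH2_DAM", "SPLICE_DAM",
    "EXON", "ACMG",
)

_INFO_HEADER = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC gene symbol">',
    '##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript accession">',
    '##INFO=<ID=HGVSC,Number=1,Type=String,Description="Coding HGVS">',
    '##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein HGVS">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=MAF_DBSNP,Number=1,Type=Float,Description="dbSNP allele frequency">',
    '##INFO=<ID=MAF_ESP,Number=1,Type=Float,Description="ESP allele frequency">',
    '##INFO=<ID=MAF_EXAC,Number=1,Type=Float,Description="ExAC allele frequency">',
    '##INFO=<ID=HGMD_DM,Number=0,Type=Flag,Description="HGMD disease-causing assertion">',
    '##INFO=<ID=CLNSIG_PATHO,Number=0,Type=Flag,Description="ClinVar pathogenic assertion">',
    '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">',
    '##INFO=<ID=SIFT_DEL,Number=1,Type=Integer,Description="SIFT deleterious (0/1)">',
    '##INFO=<ID=PPH2_DAM,Number=1,Type=Integer,Description="PolyPhen-2 damaging (0/1)">',
    '##INFO=<ID=SPLICE_DAM,Number=1,Type=Integer,Description="Splice prediction damaging (0/1)">',
    '##INFO=<ID=EXON,Number=1,Type=String,Description="Affected exon label for CNV records">',
    '##INFO=<ID=ACMG,Number=1,Type=String,Description="Comma-separated ACMG/AMP evidence codes">',
]


def _fmt_float(x: float) -> str:
    return f"{_f6(x):g}"


def read_annotated_vcf(path: str, sample_id: str) -> list[AnnotatedRecord]:
    """Read one sample's records from an annotated VCF.

    Multi-allelic sites are split into one record per alternate allele.
    Genotypes ``0/0`` and ``./.`` are returned with ``zygosity=absent``.

    Raises
    ------
    VcfFormatError
        If the mandatory ``GENE`` INFO key is missing or the ``CSQ`` value is
        not a recognized consequence class; the error names the offending
        line number.
    KeyError
        If ``sample_id`` is not a sample of the file.
    """
    try:
        vcf = VCF(str(path))
    except OSError as exc:
        raise VcfFormatError(f"{path}: {exc}") from exc
    if sample_id not in vcf.samples:
        raise KeyError(f"sample {sample_id!r} not in {path} (has {vcf.samples})")
    sidx = vcf.samples.index(sample_id)
    with open(path) as fh:
        header_lines = 0
        for raw in fh:
            if not raw.startswith("#"):
                break
            header_lines += 1

    records: list[AnnotatedRecord] = []
    for i, v in enumerate(vcf):
        line_no = header_lines + i + 1
        info = v.INFO
        gene = info.get("GENE")
        if gene is None:
            raise VcfFormatError("missing mandatory INFO key GENE", line=line_no)
        csq_raw = info.get("CSQ")
        consequence = Consequence.OTHER_NONCODING
        if csq_raw is not None:
            try:
                consequence = Consequence(csq_raw)
            except ValueError:
                raise VcfFormatError(f"unknown consequence {csq_raw!r}", line=line_no) from None

        annotation = AnnotationBundle(
            maf_dbsnp=_opt_f6(info.get("MAF_DBSNP")),
            maf_esp=_opt_f6(info.get("MAF_ESP")),
            maf_exac=_opt_f6(info.get("MAF_EXAC")),
            hgmd_disease_causing=bool(info.get("HGMD_DM")),
            clinvar_disease_causing=bool(info.get("CLNSIG_PATHO")),
            cadd_phred=_opt_f6(info.get("CADD")),
            sift_deleterious=_opt_bool(info.get("SIFT_DEL")),
            polyphen_damaging=_opt_bool(info.get("PPH2_DAM")),
            splice_predicted_damaging=_opt_bool(info.get("SPLICE_DAM")),
        )
        acmg_raw = info.get("ACMG")
        evidence = frozenset(acmg_raw.split(",")) if acmg_raw else None

        gt = v.genotypes[sidx]
        alleles = [a for a in gt[:-1] if a is not None]

        for ai, alt in enumerate(v.ALT, start=1):
            if alt == "<DEL>":
                exon = info.get("EXON")
                if exon is None:
                    raise VcfFormatError("CNV record lacks INFO key EXON", line=line_no)
                variant = SeqVariant(
                    chrom=v.CHROM, pos=v.POS, ref="", alt="", gene=gene,
                    transcript=info.get("TRANSCRIPT") or "",
                    hgvs_c=info.get("HGVSC") or "", hgvs_p=info.get("HGVSP") or "",
                    consequence=consequence, kind=VariantKind.EXON_CNV, exon=str(exon),
                )
            else:
                kind = VariantKind.SNV if len(v.REF) == 1 and len(alt) == 1 else VariantKind.INDEL
                variant = SeqVariant(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt, gene=gene,
                    transcript=info.get("TRANSCRIPT") or "",
                    hgvs_c=info.get("HGVSC") or "", hgvs_p=info.get("HGVSP") or "",
                    consequence=consequence, kind=kind,
                )
            n_alt = sum(1 for a in alleles if a == ai)
            if not alleles or all(a < 0 for a in alleles) or n_alt == 0:
                zyg = Zygosity.ABSENT
            elif n_alt >= 2:
                zyg = Zygosity.HOM
            else:
                zyg = Zygosity.HET
            records.append(AnnotatedRecord(
                variant=variant,
                genotype=GenotypeCall(sample_id=sample_id, variant=variant, zygosity=zyg),
                annotation=annotation,
                evidence=evidence,
            ))
    return records


def _opt_f6(x) -> float | None:
    return None if x is None else _f6(x)


def _opt_bool(x) -> bool | None:
    return None if x is None else bool(int(x))


def _info_string(rec: AnnotatedRecord) -> str:
    v, a = rec.variant, rec.annotation
    vals: dict[str, str | None] = {
        "GENE": v.gene,
        "TRANSCRIPT": v.transcript or None,
        "HGVSC": v.hgvs_c or None,
        "HGVSP": v.hgvs_p or None,
        "CSQ": v.consequence.value,
        "MAF_DBSNP": None if a.maf_dbsnp is None else _fmt_float(a.maf_dbsnp),
        "MAF_ESP": None if a.maf_esp is None else _fmt_float(a.maf_esp),
        "MAF_EXAC": None if a.maf_exac is None else _fmt_float(a.maf_exac),
        "HGMD_DM": "" if a.hgmd_disease_causing else None,
        "CLNSIG_PATHO": "" if a.clinvar_disease_causing else None,
        "CADD": None if a.cadd_phred is None else _fmt_float(a.cadd_phred),
        "SIFT_DEL": None if a.sift_deleterious is None else str(int(a.sift_deleterious)),
        "PPH2_DAM": None if a.polyphen_damaging is None else str(int(a.polyphen_damaging)),
        "SPLICE_DAM": None if a.splice_predicted_damaging is None else str(int(a.splice_predicted_damaging)),
        "EXON": v.exon or None,
        "ACMG": ",".join(sorted(rec.evidence)) if rec.evidence else None,
    }
    parts = []
    for key in _INFO_KEYS:
        val = vals[key]
        if val is None:
            continue
        parts.append(key if val == "" else f"{key}={val}")
    return ";".join(parts)


_GT = {Zygosity.HET: "0/1", Zygosity.HOM: "1/1", Zygosity.ABSENT: "0/0"}


def write_annotated_vcf(path: str, records: Sequence[AnnotatedRecord],
                        sample_ids: Sequence[str] | None = None) -> None:
    """Write records as an annotated VCF with byte-stable key order.

    Records may come from several samples (one column per sample, grouped by
    variant identity in first-seen order); a sample without a call at a
    variant is written ``./.``.
    """
    if sample_ids is None:
        seen: list[str] = []
        for r in records:
            if r.genotype.sample_id not in seen:
                seen.append(r.genotype.sample_id)
        sample_ids = seen or ["SAMPLE"]

    by_variant: dict[tuple, dict] = {}
    for r in records:
        entry = by_variant.setdefault(r.variant.identity_key, {"rec": r, "gt": {}})
        entry["gt"][r.genotype.sample_id] = _GT[r.genotype.zygosity]

    chroms = sorted({e["rec"].variant.chrom for e in by_variant.values()})
    lines = ["##fileformat=VCFv4.2", "##source=couplescreen"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += _INFO_HEADER
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))

    for entry in by_variant.values():
        rec: AnnotatedRecord = entry["rec"]
        v = rec.variant
        if v.kind is VariantKind.EXON_CNV:
            ref, alt = "N", "<DEL>"
        else:
            ref, alt = v.ref, v.alt
        gts = [entry["gt"].get(s, "./.") for s in sample_ids]
        lines.append("\t".join([v.chrom, str(v.pos), ".", ref, alt, ".", ".",
                                _info_string(rec), "GT"] + gts))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def normalize_variant(v: SeqVariant, reference: Mapping[str, str] | None = None) -> SeqVariant:
    """Left-align and minimalize an SNV/indel representation.

    Shared trailing bases are trimmed (extending to the left from
    ``reference`` — a mapping chrom → full 1-based contig sequence — when a
    trim would consume the anchor base), then shared leading bases are
    trimmed while both alleles keep at least one base.  SNVs already minimal
    and exon CNVs pass through unchanged.  Idempotent.
    """
    if v.kind is VariantKind.EXON_CNV:
        return v
    ref, alt, pos = v.ref, v.alt, v.pos
    seq = reference.get(v.chrom) if reference else None
    while ref and alt and ref[-1] == alt[-1]:
        if len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        elif seq is not None and pos > 1:
            base = seq[pos - 2]
            ref, alt, pos = base + ref[:-1], base + alt[:-1], pos - 1
        else:
            break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    kind = VariantKind.SNV if len(ref) == 1 and len(alt) == 1 else VariantKind.INDEL
    if (ref, alt, pos, kind) == (v.ref, v.alt, v.pos, v.kind):
        return v
    return replace(v, ref=ref, alt=alt, pos=pos, kind=kind)
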