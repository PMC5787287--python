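"""Annotated-VCF dialect I/O and variant normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from couplescreen.variants import (AnnotatedRecord, AnnotationBundle, Consequence,
                                   GenotypeCall, SeqVariant, VariantKind,
                                   VcfFormatError, Zygosity, normalize_variant,
                                   read_annotated_vcf, write_annotated_vcf)
from conftest import random_records


def _het_record(gene, pos, ref="A", alt="T"):
    v = SeqVariant(chrom="1", pos=pos, ref=ref, alt=alt, gene=gene,
                   consequence=Consequence.MISSENSE)
    return AnnotatedRecord(variant=v, genotype=GenotypeCall("S1", v, Zygosity.HET),
                           annotation=AnnotationBundle(cadd_phred=21.5, maf_exac=5e-4))


def test_simple_parse_three_het_records(tmp_path):
    recs = [_het_record("CTSD", 100), _het_record("COQ2", 200, "G", "C"),
            _het_record("BRAT1", 300, "C", "A")]
    path = tmp_path / "t.vcf"
    write_annotated_vcf(str(path), recs, sample_ids=["S1"])
    got = read_annotated_vcf(str(path), "S1")
    assert len(got) == 3
    assert all(r.genotype.zygosity is Zygosity.HET for r in got)


def test_write_read_round_trip_is_identity(tmp_path):
    rng = np.random.default_rng(7)
    recs = random_records(rng, 40, sample="S1")
    path = tmp_path / "rt.vcf"
    write_annotated_vcf(str(path), recs, sample_ids=["S1"])
    assert read_annotated_vcf(str(path), "S1") == recs


def test_multiallelic_line_splits_per_alt_allele(tmp_path):
    # a 1/2 genotype decomposes into one het record per alternate allele
    path = tmp_path / "ma.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="c">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "1\t100\t.\tA\tT,C\t.\t.\tGENE=CTSD;CSQ=missense\tGT\t1/2\n")
    got = read_annotated_vcf(str(path), "S1")
    assert [(r.variant.alt, r.genotype.zygosity) for r in got] == [
        ("T", Zygosity.HET), ("C", Zygosity.HET)]
    # allele-count conservation: two alt alleles on the line, two records
    assert len(got) == 2


def test_absent_genotypes_returned_as_absent(tmp_path):
    recs = [_het_record("CTSD", 100)]
    path = tmp_path / "a.vcf"
    write_annotated_vcf(str(path), recs, sample_ids=["S1", "S2"])
    got = read_annotated_vcf(str(path), "S2")
    assert got[0].genotype.zygosity is Zygosity.ABSENT


def test_missing_gene_key_is_format_error_with_line(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="c">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "1\t100\t.\tA\tT\t.\t.\tCSQ=missense\tGT\t0/1\n")
    with pytest.raises(VcfFormatError, match="line 6"):
        read_annotated_vcf(str(path), "S1")


def test_unknown_consequence_is_format_error(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="c">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "1\t100\t.\tA\tT\t.\t.\tGENE=CTSD;CSQ=stopgain\tGT\t0/1\n")
    with pytest.raises(VcfFormatError, match="stopgain"):
        read_annotated_vcf(str(path), "S1")


# --- normalization ---------------------------------------------------------

def _hap(seq: str, pos: int, ref: str, alt: str) -> str:
    return seq[:pos - 1] + alt + seq[pos - 1 + len(ref):]


def _leftmost_deletion(seq: str, pos: int, ref: str, alt: str):
    """Brute-force oracle: shift an anchored deletion left over all valid
    placements and return the leftmost minimal representation."""
    target = _hap(seq, pos, ref, alt)
    d = len(ref) - len(alt)
    for p in range(1, len(seq) + 1):
        r, a = seq[p - 1:p + d], seq[p - 1]
        if len(r) == d + 1 and _hap(seq, p, r, a) == target:
            return p, r, a
    raise AssertionError("no placement found")


def test_snv_passes_through_unchanged():
    v = SeqVariant(chrom="chr4", pos=100, ref="A", alt="T", gene="X")
    assert normalize_variant(v) is v


def test_exon_cnv_passes_through():
    v = SeqVariant(chrom="1", pos=1, ref="", alt="", gene="PALLD",
                   kind=VariantKind.EXON_CNV, exon="1")
    assert normalize_variant(v) is v


def test_homopolymer_deletion_matches_left_shift_oracle():
    seq = "A" * 94 + "CTTTT" + "A" * 21
    reference = {"1": seq}
    # mid-run anchored representation of deleting one T
    v = SeqVariant(chrom="1", pos=97, ref="TT", alt="T", gene="X",
                   kind=VariantKind.INDEL)
    got = normalize_variant(v, reference)
    exp_pos, exp_ref, exp_alt = _leftmost_deletion(seq, 97, "TT", "T")
    assert (got.pos, got.ref, got.alt) == (exp_pos, exp_ref, exp_alt) == (95, "CT", "C")
    # the spec form CTT>CT trims to the same representation
    v2 = SeqVariant(chrom="1", pos=95, ref="CTT", alt="CT", gene="X",
                    kind=VariantKind.INDEL)
    assert normalize_variant(v2, reference).identity_key == got.identity_key


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.data())
def test_deletion_normalization_agrees_with_oracle_and_preserves_haplotype(data):
    seq = data.draw(st.text(alphabet="ACGT", min_size=12, max_size=40))
    d = data.draw(st.integers(1, 3))
    pos = data.draw(st.integers(2, len(seq) - d))
    ref, alt = seq[pos - 1:pos + d], seq[pos - 1]
    v = SeqVariant(chrom="1", pos=pos, ref=ref, alt=alt, gene="X",
                   kind=VariantKind.INDEL)
    got = normalize_variant(v, {"1": seq})
    p, r, a = _leftmost_deletion(seq, pos, ref, alt)
    assert (got.pos, got.ref, got.alt) == (p, r, a)
    assert _hap(seq, got.pos, got.ref, got.alt) == _hap(seq, pos, ref, alt)
    assert normalize_variant(got, {"1": seq}) == got  # idempotent


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.data())
def test_normalization_idempotent_on_insertions(data):
    seq = data.draw(st.text(alphabet="ACGT", min_size=12, max_size=40))
    pos = data.draw(st.integers(2, len(seq) - 2))
    ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
    ref = seq[pos - 1]
    v = SeqVariant(chrom="1", pos=pos, ref=ref, alt=ref + ins, gene="X",
                   kind=VariantKind.INDEL)
    once = normalize_variant(v, {"1": seq})
    assert normalize_variant(once, {"1": seq}) == once
    assert _hap(seq, once.pos, once.ref, once.alt) == _hap(seq, pos, ref, ref + ins)
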