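"""Consanguinity-aware couple-genotype simulator with known ground truth.

The simulator emulates the background of incidentally shared rare variants
between two partners related with kinship coefficient phi.  Each maternal
background variant (population frequency p drawn from a weighted spectrum)
is carried identically by the father with probability

    phi + (1 - phi) * 2 p (1 - p)

i.e. identity-by-descent sharing plus chance sharing at the population
frequency.  The father additionally receives his own independent background
variants.  Each background variant lives in its own synthetic gene, so a
shared variant is a shared gene; variants are independent (no linkage
blocks).  Known candidates can be planted on top, and the truth table lists
every engineered shared gene, which downstream filtering + matching must
recover.

Defaults (n=64 rare background variants per parent, phi=1/16 as for a
first-cousin couple, strongly rare frequency spectrum) put the expected
shared-gene count near 4, the regime reported for exome-wide carrier
screening of consanguineous couples (3-4 shared genes on average).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .variants import (AnnotatedRecord, AnnotationBundle, Consequence, GenotypeCall,
                       SeqVariant, VariantKind, Zygosity)

__all__ = ["PedigreeRelation", "SimulationConfig", "kinship_coefficient",
           "simulate_couple", "expected_shared_genes", "decoy_records"]


@dataclass(frozen=True)
class PedigreeRelation:
    """Relationship between the two partners.

    ``custom_paths`` lists, for each loop connecting the partners through a
    common ancestor, its meiosis count L; the loop contributes (1/2)^(L+1)
    to the kinship coefficient.
    """

    relation: str  # unrelated | first_cousins | double_first_cousins | custom
    custom_paths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.relation not in ("unrelated", "first_cousins",
                                 "double_first_cousins", "custom"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.relation == "custom":
            if not self.custom_paths:
                raise ValueError("custom relation requires loop paths")
            if any(l < 2 for l in self.custom_paths):
                raise ValueError("loop path lengths must be >= 2 meioses")


def kinship_coefficient(r: PedigreeRelation) -> float:
    """Kinship phi between the partners; offspring inbreeding F equals phi.

    First cousins: two loops of 4 meioses -> 2 * (1/2)^5 = 1/16.
    Double first cousins: four such loops -> 1/8.
    """
    if r.relation == "unrelated":
        return 0.0
    if r.relation == "first_cousins":
        paths: Sequence[int] = (4, 4)
    elif r.relation == "double_first_cousins":
        paths = (4, 4, 4, 4)
    else:
        paths = r.custom_paths
    return float(sum(0.5 ** (l + 1) for l in paths))


_DEFAULT_SPECTRUM = ((1e-4, 0.4), (1e-3, 0.4), (5e-3, 0.2))


@dataclass(frozen=True)
class SimulationConfig:
    n_background_variants: int = 64
    maf_spectrum: tuple[tuple[float, float], ...] = _DEFAULT_SPECTRUM
    kinship: float = 1 / 16
    planted_candidates: tuple[tuple[str, str], ...] = ()  # (gene, shared_hom|compound_het)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_variants < 0:
            raise ValueError("n_background_variants must be >= 0")
        if not 0.0 <= self.kinship <= 0.25:
            raise ValueError("kinship must lie in [0, 0.25]")
        w = sum(w for _, w in self.maf_spectrum)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"maf_spectrum weights must sum to 1, got {w}")
        for gene, mode in self.planted_candidates:
            if mode not in ("shared_hom", "compound_het"):
                raise ValueError(f"unknown planted mode {mode!r} for {gene}")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"simulator config {path} must be a mapping")
        allowed = {"n_background_variants", "maf_spectrum", "kinship",
                   "planted_candidates", "seed"}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown simulator config keys: {sorted(unknown)}")
        if "maf_spectrum" in data:
            data["maf_spectrum"] = tuple((float(p), float(w)) for p, w in data["maf_spectrum"])
        if "planted_candidates" in data:
            data["planted_candidates"] = tuple((g, m) for g, m in data["planted_candidates"])
        return cls(**data)


_BASES = ("A", "C", "G", "T")


def _mk_record(sample: str, gene: str, pos: int, p: float | None, rng_alt: int,
               consequence: Consequence = Consequence.MISSENSE) -> AnnotatedRecord:
    ref = _BASES[rng_alt % 4]
    alt = _BASES[(rng_alt + 1 + rng_alt % 3) % 4]
    if alt == ref:
        alt = _BASES[(rng_alt + 2) % 4]
    variant = SeqVariant(chrom="1", pos=pos, ref=ref, alt=alt, gene=gene,
                         consequence=consequence,
                         kind=VariantKind.SNV)
    annotation = AnnotationBundle(maf_exac=None if p is None or p == 0 else float(f"{p:.6g}"),
                                  cadd_phred=25.0)
    return AnnotatedRecord(
        variant=variant,
        genotype=GenotypeCall(sample_id=sample, variant=variant, zygosity=Zygosity.HET),
        annotation=annotation)


@dataclass(frozen=True)
class SharedTruth:
    gene: str
    mode: str           # shared_hom | compound_het
    origin: str         # background | planted


def simulate_couple(cfg: SimulationConfig) -> tuple[list[AnnotatedRecord],
                                                    list[AnnotatedRecord],
                                                    list[SharedTruth]]:
    """Simulate one couple's retained-variant lists plus the truth table.

    Deterministic for a fixed config (seed included): identical seeds give
    identical record lists and, through the dialect writer, byte-identical
    VCFs.
    """
    rng = np.random.default_rng(cfg.seed)
    phi = cfg.kinship
    freqs = np.array([p for p, _ in cfg.maf_spectrum])
    weights = np.array([w for _, w in cfg.maf_spectrum])

    mother: list[AnnotatedRecord] = []
    father: list[AnnotatedRecord] = []
    truth: list[SharedTruth] = []

    n = cfg.n_background_variants
    if n:
        p_idx = rng.choice(len(freqs), size=n, p=weights)
        share_u = rng.random(n)
        alt_codes = rng.integers(0, 4, size=n)
    pos = 1000
    for i in range(n):
        p = float(freqs[p_idx[i]])
        gene = f"BG{i + 1:04d}"
        rec_m = _mk_record("MOTHER", gene, pos, p, int(alt_codes[i]))
        mother.append(rec_m)
        p_share = phi + (1 - phi) * 2 * p * (1 - p)
        if share_u[i] < p_share:
            father.append(AnnotatedRecord(
                variant=rec_m.variant,
                genotype=GenotypeCall("FATHER", rec_m.variant, Zygosity.HET),
                annotation=rec_m.annotation))
            truth.append(SharedTruth(gene=gene, mode="shared_hom", origin="background"))
        pos += 1000

    if n:
        fp_idx = rng.choice(len(freqs), size=n, p=weights)
        falt = rng.integers(0, 4, size=n)
    for i in range(n):
        gene = f"BF{i + 1:04d}"
        father.append(_mk_record("FATHER", gene, pos, float(freqs[fp_idx[i]]), int(falt[i])))
        pos += 1000

    for gene, mode in cfg.planted_candidates:
        if mode == "shared_hom":
            rec = _mk_record("MOTHER", gene, pos, None, 0)
            mother.append(rec)
            father.append(AnnotatedRecord(
                variant=rec.variant,
                genotype=GenotypeCall("FATHER", rec.variant, Zygosity.HET),
                annotation=rec.annotation))
            pos += 1000
        else:
            mother.append(_mk_record("MOTHER", gene, pos, None, 0))
            father.append(_mk_record("FATHER", gene, pos + 500, None, 1))
            pos += 1000
        truth.append(SharedTruth(gene=gene, mode=mode, origin="planted"))

    return mother, father, truth


def expected_shared_genes(cfg: SimulationConfig) -> float:
    """Closed-form expectation of the truth-table size.

    Sum over background variants of phi + (1-phi)*2p(1-p), with p averaged
    over the frequency spectrum, plus the planted-candidate count.
    """
    phi = cfg.kinship
    per_variant = sum(w * (phi + (1 - phi) * 2 * p * (1 - p))
                      for p, w in cfg.maf_spectrum)
    return cfg.n_background_variants * per_variant + len(cfg.planted_candidates)


def decoy_records(sample: str, n: int, seed: int = 0,
                  start_pos: int = 50_000_000) -> list[AnnotatedRecord]:
    """Deterministic decoy records that each fail exactly one filter predicate.

    Decoys cycle through: common missense (fails rarity), synonymous rare
    (fails consequence class), benign-predicted rare missense with low CADD
    (fails deleteriousness prediction).
    """
    rng = np.random.default_rng(seed)
    out: list[AnnotatedRecord] = []
    for i in range(n):
        gene = f"DCY{i + 1:04d}"
        pos = start_pos + i * 1000
        code = int(rng.integers(0, 4))
        flavor = i % 3
        if flavor == 0:
            rec = _mk_record(sample, gene, pos, 0.05, code)
        elif flavor == 1:
            rec = _mk_record(sample, gene, pos, 1e-4, code,
                             consequence=Consequence.SYNONYMOUS)
        else:
            base = _mk_record(sample, gene, pos, 1e-4, code)
            rec = AnnotatedRecord(
                variant=base.variant, genotype=base.genotype,
                annotation=AnnotationBundle(maf_exac=1e-4, cadd_phred=3.0,
                                            sift_deleterious=False,
                                            polyphen_damaging=False))
        out.append(rec)
    return out
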