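import numpy as np
import pytest

from couplescreen.cosegregation import ChildObservation
from couplescreen.fixture import build_table1_fixture
from couplescreen.report import screen_couple
from couplescreen.variants import (AnnotatedRecord, AnnotationBundle, Consequence,
                                   GenotypeCall, SeqVariant, VariantKind, Zygosity)

GENE_POOL = [f"G{i:02d}" for i in range(12)]
_CSQS = list(Consequence)
_ZYGS = [Zygosity.HET, Zygosity.HOM, Zygosity.ABSENT]


def random_records(rng: np.random.Generator, n: int, sample: str = "MOTHER",
                   het_only: bool = False) -> list[AnnotatedRecord]:
    """Random annotated records over a small gene pool, unique identity keys."""
    recs: list[AnnotatedRecord] = []
    used: set = set()
    while len(recs) < n:
        gene = GENE_POOL[int(rng.integers(len(GENE_POOL)))]
        pos = int(rng.integers(1, 5000)) * 10 + GENE_POOL.index(gene) * 100_000 + 1
        ref = "ACGT"[int(rng.integers(4))]
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        v = SeqVariant(chrom="1", pos=pos, ref=ref, alt=alt, gene=gene,
                       consequence=_CSQS[int(rng.integers(len(_CSQS)))])
        if v.identity_key in used:
            continue
        used.add(v.identity_key)

        def maybe(p, draw):
            return draw() if rng.random() < p else None

        ann = AnnotationBundle(
            maf_dbsnp=maybe(0.5, lambda: float(10 ** rng.uniform(-5, -0.5))),
            maf_esp=maybe(0.5, lambda: float(10 ** rng.uniform(-5, -0.5))),
            maf_exac=maybe(0.5, lambda: float(10 ** rng.uniform(-5, -0.5))),
            hgmd_disease_causing=bool(rng.random() < 0.1),
            clinvar_disease_causing=bool(rng.random() < 0.1),
            cadd_phred=maybe(0.7, lambda: float(rng.uniform(0, 40))),
            sift_deleterious=maybe(0.5, lambda: bool(rng.random() < 0.5)),
            polyphen_damaging=maybe(0.5, lambda: bool(rng.random() < 0.5)),
            splice_predicted_damaging=maybe(0.3, lambda: bool(rng.random() < 0.5)),
        )
        zyg = Zygosity.HET if het_only else _ZYGS[int(rng.choice(3, p=[0.8, 0.1, 0.1]))]
        recs.append(AnnotatedRecord(variant=v,
                                    genotype=GenotypeCall(sample, v, zyg),
                                    annotation=ann))
    return recs


def children_of(fam) -> list[ChildObservation]:
    out = []
    for c in fam.children:
        gts = tuple(GenotypeCall(c.child_id, v, z) for v, z in c.genotypes)
        out.append(ChildObservation(c.child_id, c.affected, gts, c.material))
    return out


def screen_family(fam):
    return screen_couple(fam.couple_id, list(fam.mother), list(fam.father),
                         evidence=dict(fam.evidence), children=children_of(fam),
                         consanguinity=fam.consanguinity)


@pytest.fixture(scope="session")
def cohort():
    return build_table1_fixture()


@pytest.fixture(scope="session")
def cohort_reports(cohort):
    return [screen_family(f) for f in cohort.families]


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, cohort):
    from couplescreen.fixture import write_fixture
    out = tmp_path_factory.mktemp("cohort_fixture")
    write_fixture(cohort, str(out))
    return out
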