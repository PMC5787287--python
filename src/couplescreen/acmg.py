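"""ACMG/AMP five-tier variant classification by evidence-combining rules.

Evidence codes (PVS1, PS1-4, PM1-6, PP1-5 on the pathogenic side; BA1,
BS1-4, BP1-7 on the benign side) are combined with the published rule table
into classes 1 (benign) to 5 (pathogenic); insufficient or contradictory
evidence yields Class 3 (uncertain significance).  The actionability policy
is class-based: prenatal diagnosis / PGD eligibility requires Class 4 or 5
on both parental alleles; Class 3-5 variants are reportable to the couple.
"""

from __future__ import annotations

from typing import Iterable

__all__ = ["VALID_CODES", "CLASS_NAMES", "combine_evidence",
           "eligible_for_action", "reportable"]

VALID_CODES: frozenset[str] = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

CLASS_NAMES = {1: "benign", 2: "likely benign", 3: "uncertain significance",
               4: "likely pathogenic", 5: "pathogenic"}


def _counts(codes: frozenset[str]) -> tuple[int, int, int, int, int, int, int]:
    pvs = sum(1 for c in codes if c.startswith("PVS"))
    ps = sum(1 for c in codes if c.startswith("PS"))
    pm = sum(1 for c in codes if c.startswith("PM"))
    pp = sum(1 for c in codes if c.startswith("PP"))
    ba = sum(1 for c in codes if c.startswith("BA"))
    bs = sum(1 for c in codes if c.startswith("BS"))
    bp = sum(1 for c in codes if c.startswith("BP"))
    return pvs, ps, pm, pp, ba, bs, bp


def combine_evidence(codes: Iterable[str]) -> int:
    """Combine evidence codes into a class 1-5.

    Raises ``ValueError`` on a code outside the declared vocabulary.
    """
    codeset = frozenset(codes)
    unknown = codeset - VALID_CODES
    if unknown:
        raise ValueError(f"unknown evidence codes: {sorted(unknown)}")
    pvs, ps, pm, pp, ba, bs, bp = _counts(codeset)

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs == 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp == 1) or bp >= 2

    patho_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if patho_side and benign_side:
        return 3
    if pathogenic:
        return 5
    if likely_pathogenic:
        return 4
    if benign:
        return 1
    if likely_benign:
        return 2
    return 3


def eligible_for_action(class_maternal: int, class_paternal: int) -> bool:
    """Prenatal diagnosis / PGD eligibility: both parental alleles Class >= 4."""
    return class_maternal >= 4 and class_paternal >= 4


def reportable(c: int) -> bool:
    """Classes 3-5 are reported to the couple."""
    return c >= 3
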