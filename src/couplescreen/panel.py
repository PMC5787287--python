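"""Virtual gene panel loading and record restriction.

A panel is a plain-text list of HGNC symbols, optionally with a
tab-separated inheritance column (``AR`` or ``XL``), standing in for a
curated virtual panel of genes for severe recessive and X-linked childhood
disorders.  Screening can run in panel mode (records restricted to the
panel) or WES mode (no restriction), mirroring a two-tier strategy of panel
diagnostics first and exome sequencing for unsolved couples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .variants import AnnotatedRecord

__all__ = ["GenePanel", "PanelFormatError", "load_panel", "restrict_to_panel"]


class PanelFormatError(ValueError):
    pass


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: frozenset[str]
    inheritance: dict = field(default_factory=dict)  # gene -> "AR" | "XL"

    def __post_init__(self) -> None:
        if not self.genes:
            raise PanelFormatError("panel has no genes")
        bad = [g for g in self.genes if g != g.upper()]
        if bad:
            raise PanelFormatError(f"panel symbols must be uppercase: {bad}")

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def xl_genes(self) -> frozenset[str]:
        return frozenset(g for g, m in self.inheritance.items() if m == "XL")


def load_panel(path: str, name: str | None = None) -> GenePanel:
    """Load a panel file: one ``SYMBOL[\\tAR|XL]`` per line, '#' comments."""
    genes: set[str] = set()
    inheritance: dict[str, str] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            symbol = fields[0].strip().upper()
            if not symbol:
                raise PanelFormatError(f"empty gene symbol at line {line_no}")
            genes.add(symbol)
            if len(fields) > 1 and fields[1].strip():
                token = fields[1].strip().upper()
                if token not in ("AR", "XL"):
                    raise PanelFormatError(
                        f"malformed inheritance token {token!r} at line {line_no}")
                inheritance[symbol] = token
    if not genes:
        raise PanelFormatError(f"panel file {path} lists no genes")
    return GenePanel(name=name or str(path), genes=frozenset(genes), inheritance=inheritance)


def restrict_to_panel(records: Sequence[AnnotatedRecord], panel: GenePanel) -> list[AnnotatedRecord]:
    """Keep exactly the records whose gene is on the panel, order preserved."""
    return [r for r in records if r.variant.gene.upper() in panel.genes]
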