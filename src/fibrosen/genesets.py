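"""Gene sets and GMT input/output.

A gene set is a named, ordered collection of unique gene symbols. GMT is the
tab-separated line format used throughout: ``name<TAB>description<TAB>gene1
<TAB>gene2...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (unique, order-preserving)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        deduped = tuple(dict.fromkeys(self.genes))
        if len(deduped) != len(self.genes):
            object.__setattr__(self, "genes", deduped)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def intersect(self, universe: Iterable[str]) -> list[str]:
        """Members present in ``universe``, in universe order."""
        members = set(self.genes)
        return [g for g in universe if g in members]


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
        sets.append(GeneSet(name=fields[0], genes=tuple(fields[2:]), description=fields[1]))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([gs.name, gs.description or gs.name, *gs.genes]) for gs in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
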