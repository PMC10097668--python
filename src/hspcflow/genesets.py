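"""Named gene sets, set algebra, and the GMT file format.

Gene sets are the pathway signatures scored per cell (IFN-alpha, IFN-gamma,
IL-6/JAK/STAT3, TNF-alpha responses in the default simulation) and the
inputs to preranked GSEA. The plain-text GMT format is the MSigDB
convention: one tab-separated line per set, ``name<TAB>description<TAB>
gene1<TAB>gene2...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

__all__ = ["GeneSet", "GeneSetCollection", "read_gmt", "write_gmt"]


@dataclass(frozen=True)
class GeneSet:
    """An ordered, duplicate-free list of gene names under one name."""

    name: str
    genes: tuple
    description: str = ""

    def __post_init__(self):
        genes = tuple(self.genes)
        if not genes:
            raise ConfigError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ConfigError(f"gene set {self.name!r} contains duplicate genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in set(self.genes)

    def intersection(self, other: "GeneSet") -> set:
        return set(self.genes) & set(other.genes)


class GeneSetCollection:
    """Ordered mapping of set name -> :class:`GeneSet`."""

    def __init__(self, sets=()):
        self._sets = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise DataError(f"duplicate gene set name {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __getitem__(self, name: str) -> GeneSet:
        if name not in self._sets:
            raise DataError(f"unknown gene set {name!r}")
        return self._sets[name]

    def __contains__(self, name) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list:
        return list(self._sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file.

    Duplicate genes within a line are kept once (logged); a line with fewer
    than three fields or a repeated set name is an error.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}: line {lineno}: expected name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name, description, raw_genes = fields[0], fields[1], fields[2:]
            genes, seen = [], set()
            for g in raw_genes:
                if not g:
                    continue
                if g in seen:
                    log.warning("%s: line %d: duplicate gene %r in set %r kept once",
                                path, lineno, g, name)
                    continue
                seen.add(g)
                genes.append(g)
            if not genes:
                raise DataError(f"{path}: line {lineno}: set {name!r} has no genes")
            collection.add(GeneSet(name=name, genes=tuple(genes), description=description))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
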