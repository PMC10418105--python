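"""Minimal rooted taxonomy with lowest-common-ancestor queries.

Taxa live on fixed-depth paths root -> domain -> genus -> genome; ranks are
assigned by depth. This is deliberately tiny — genome headers carry their
own paths, no external taxonomy files are parsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .containers import GenomeRecord

__all__ = ["TaxonomyTree", "build_taxonomy", "lca", "RANKS"]

RANKS = ("root", "domain", "genus", "genome")


@dataclass
class TaxonomyTree:
    """Rooted tree as a child -> parent map; the root's parent is None."""

    parent: dict[str, str | None] = field(default_factory=lambda: {"root": None})

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def add_path(self, path: Sequence[str]) -> None:
        if not path or path[0] != "root":
            raise ValueError(f"taxon path must start at 'root': {list(path)}")
        for parent, child in zip(path, path[1:]):
            known = self.parent.get(child)
            if known is not None and known != parent:
                raise ValueError(
                    f"conflicting parent for taxon {child!r}: {known!r} vs {parent!r}"
                )
            self.parent[child] = parent

    def ancestors(self, taxon: str) -> list[str]:
        """Path from ``taxon`` up to the root, inclusive."""
        if taxon not in self.parent:
            raise KeyError(f"unknown taxon {taxon!r}")
        chain = [taxon]
        while (up := self.parent[chain[-1]]) is not None:
            chain.append(up)
        return chain

    def depth(self, taxon: str) -> int:
        return len(self.ancestors(taxon)) - 1

    def rank(self, taxon: str) -> str:
        d = self.depth(taxon)
        if d >= len(RANKS):
            raise ValueError(f"taxon {taxon!r} deeper than supported ranks")
        return RANKS[d]

    def children(self, taxon: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == taxon]

    def leaves(self) -> list[str]:
        parents = {p for p in self.parent.values() if p is not None}
        return [t for t in self.parent if t not in parents]

    def at_rank(self, taxon: str, rank: str) -> str | None:
        """Ancestor of ``taxon`` at the given rank (or None if above it)."""
        target = RANKS.index(rank)
        chain = self.ancestors(taxon)  # taxon .. root
        d = len(chain) - 1
        if d < target:
            return None
        return chain[d - target]


def build_taxonomy(genomes: Iterable[GenomeRecord]) -> TaxonomyTree:
    """Tree containing every taxon on every genome's claimed path."""
    tree = TaxonomyTree()
    for g in genomes:
        tree.add_path(g.taxon_path)
    return tree


def lca(tree: TaxonomyTree, taxon_a: str, taxon_b: str) -> str:
    """Deepest node ancestral to (or equal to) both taxa."""
    chain_a = tree.ancestors(taxon_a)
    seen = set(chain_a)
    for t in tree.ancestors(taxon_b):
        if t in seen:
            return t
    raise AssertionError("disjoint ancestor chains in a rooted tree")  # pragma: no cover


def lca_many(tree: TaxonomyTree, taxa: Iterable[str]) -> str:
    """LCA of an arbitrary non-empty collection of taxa."""
    it = iter(taxa)
    try:
        acc = next(it)
    except StopIteration:
        raise ValueError("lca of an empty collection") from None
    for t in it:
        acc = lca(tree, acc, t)
    return acc
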