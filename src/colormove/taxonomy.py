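"""Parent-pointer taxonomy with LCA and rank-lifting queries.

The taxonomy is a rooted tree given as one row per node:
``node_id <TAB> parent_id <TAB> rank <TAB> name``, where the root points to
itself.  This is the minimal structure needed for LCA assignment of
reported documents and for rank-level evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class Taxonomy:
    parents: dict[int, int]
    ranks: dict[int, str] = field(default_factory=dict)
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parents.items() if p == n]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for n, p in self.parents.items():
            if p not in self.parents:
                raise ValueError(f"parent {p} of node {n} is not a node")

    def __contains__(self, node: int) -> bool:
        return node in self.parents

    def path_to_root(self, node: int) -> list[int]:
        """Node and all its ancestors, ending at the root."""
        path = [node]
        while self.parents[path[-1]] != path[-1]:
            path.append(self.parents[path[-1]])
        return path

    def lca(self, nodes: list[int]) -> int:
        """Lowest common ancestor of a non-empty set of nodes."""
        if not nodes:
            raise ValueError("LCA of an empty node set")
        common: list[int] | None = None
        for node in nodes:
            path = self.path_to_root(node)
            if common is None:
                common = path
            else:
                anc = set(path)
                common = [x for x in common if x in anc]
        return common[0]

    def is_ancestor(self, ancestor: int, node: int, strict: bool = True) -> bool:
        path = self.path_to_root(node)
        if strict:
            path = path[1:]
        return ancestor in path

    def ancestor_at_rank(self, node: int, rank: str) -> int | None:
        """The (unique) ancestor-or-self of ``node`` at ``rank``, else None."""
        for anc in self.path_to_root(node):
            if self.ranks.get(anc) == rank:
                return anc
        return None

    def rank_of(self, node: int) -> str:
        return self.ranks.get(node, "")

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        parents: dict[int, int] = {}
        ranks: dict[int, str] = {}
        names: dict[int, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            node, parent, rank, name = line.rstrip("\n").split("\t")
            parents[int(node)] = int(parent)
            ranks[int(node)] = rank
            names[int(node)] = name
        if not parents:
            raise ValueError(f"empty taxonomy file: {path}")
        return cls(parents, ranks, names)

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"{node}\t{self.parents[node]}\t{self.ranks.get(node, '')}\t{self.names.get(node, '')}"
            for node in sorted(self.parents)
        ]
        Path(path).write_text("\n".join(lines) + "\n")
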