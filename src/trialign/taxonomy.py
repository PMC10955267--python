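"""Taxonomic annotation: parent-pointer trees and lowest-common-ancestor
binning of per-query match sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = ["TaxTree", "TaxonomyError", "load_taxonomy", "lca", "UNASSIGNED"]

logger = logging.getLogger(__name__)

#: sentinel taxid for subjects without an annotation
UNASSIGNED = 0


class TaxonomyError(ValueError):
    pass


@dataclass
class TaxTree:
    """Rooted tree as a taxid -> parent map (root is its own parent)."""

    parent: dict[int, int]
    rank: dict[int, str] = field(default_factory=dict)
    name: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [t for t, p in self.parent.items() if t == p]
        if len(roots) != 1:
            raise TaxonomyError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        ok: set[int] = {self.root}
        for start in self.parent:
            path = []
            node = start
            while node not in ok:
                path.append(node)
                node = self.parent.get(node)
                if node is None:
                    raise TaxonomyError(f"taxid {path[-1]} has no parent entry")
                if node in path:
                    raise TaxonomyError(f"cycle in taxonomy at taxid {node}")
            ok.update(path)

    def path_to_root(self, taxid: int) -> list[int]:
        if taxid not in self.parent:
            raise TaxonomyError(f"unknown taxid {taxid}")
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path


def _split_row(line: str) -> list[str]:
    # NCBI nodes.dmp dialect uses "<TAB>|<TAB>" separators (auto-detected)
    if "\t|" in line:
        return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
    return line.rstrip("\n").split("\t")


def load_taxonomy(nodes_path, seq2taxid_path) -> tuple[TaxTree, dict[str, int]]:
    """Load a nodes table (taxid, parent[, rank[, name]]) and a seqid->taxid
    table.  Malformed rows are skipped with a logged count; cyclic parent
    tables raise :class:`TaxonomyError`."""
    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    name: dict[int, str] = {}
    skipped = 0
    with open(nodes_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_row(line)
            try:
                taxid, par = int(fields[0]), int(fields[1])
            except (ValueError, IndexError):
                skipped += 1
                continue
            parent[taxid] = par
            if len(fields) > 2 and fields[2]:
                rank[taxid] = fields[2]
            if len(fields) > 3 and fields[3]:
                name[taxid] = fields[3]
    if skipped:
        logger.warning("skipped %d malformed taxonomy rows", skipped)
    tree = TaxTree(parent, rank, name)
    seq2taxid: dict[str, int] = {}
    skipped = 0
    with open(seq2taxid_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_row(line)
            try:
                seq2taxid[fields[0]] = int(fields[1])
            except (ValueError, IndexError):
                skipped += 1
    if skipped:
        logger.warning("skipped %d malformed seq2taxid rows", skipped)
    return tree, seq2taxid


def lca(tree: TaxTree, taxids) -> int:
    """Lowest common ancestor of a non-empty taxid set.

    Unassigned members (taxid 0) are ignored; an all-unassigned set yields
    :data:`UNASSIGNED`.  Unknown taxids raise an error naming them.
    """
    ids = [t for t in taxids if t != UNASSIGNED]
    if not ids:
        return UNASSIGNED
    common: list[int] | None = None
    for t in ids:
        path = tree.path_to_root(t)[::-1]  # root first
        if common is None:
            common = path
        else:
            limit = min(len(common), len(path))
            k = 0
            while k < limit and common[k] == path[k]:
                k += 1
            common = common[:k]
    assert common  # root is always shared
    return common[-1]
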