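"""File formats: Newick trees, PHYLIP square distance matrices, TSV colour maps."""

from __future__ import annotations

import io as _io
from typing import Optional, Union

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .trees import PlantedTree, TreeNode

__all__ = ["read_newick", "write_newick", "read_phylip_square",
           "write_phylip_square", "read_color_map", "write_color_map"]


def read_newick(source: str, is_path: bool = True) -> PlantedTree:
    """Parse a Newick tree into a :class:`PlantedTree`.

    The Newick string describes the unplanted part of the tree; a planted
    root is added above it.  A length on the outermost group is kept as the
    planted-edge length.  Inner-node labels (e.g. support values) are
    accepted and ignored.
    """
    try:
        if is_path:
            dtree = dendropy.Tree.get(path=source, schema="newick",
                                      suppress_internal_node_taxa=True)
        else:
            dtree = dendropy.Tree.get(data=source, schema="newick",
                                      suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"malformed Newick input: {exc}") from None

    counter = [0]

    def conv(dnode) -> TreeNode:
        counter[0] += 1
        label = dnode.taxon.label if dnode.taxon is not None else None
        node = TreeNode(counter[0], label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(conv(dchild))
        return node

    planted = TreeNode(0)
    planted.add_child(conv(dtree.seed_node))
    return PlantedTree(planted)


def write_newick(tree: PlantedTree, path: Optional[str] = None) -> str:
    """Serialise the unplanted part of a tree to Newick (lengths after ':')."""
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def conv(node: TreeNode, dnode) -> None:
        for child in node.children:
            dchild = dnode.new_child()
            dchild.edge.length = child.length
            if child.is_leaf:
                dchild.taxon = taxa.new_taxon(child.label)
            conv(child, dchild)

    dtree.seed_node.edge.length = tree.root.length
    conv(tree.root, dtree.seed_node)
    text = dtree.as_string(schema="newick", suppress_rooting=True,
                           real_value_format_specifier=".12g")
    text = text.strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_phylip_square(D: DistanceMatrix, path_or_handle) -> None:
    """Write a square PHYLIP distance matrix (count line, then label + row)."""
    own = isinstance(path_or_handle, str)
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write(f"{len(D)}\n")
        for label, row in zip(D.labels, D.data):
            fh.write(label + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")
    finally:
        if own:
            fh.close()


def read_phylip_square(path_or_handle) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix; errors report the line number."""
    own = isinstance(path_or_handle, str)
    fh = open(path_or_handle) if own else path_or_handle
    try:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    finally:
        if own:
            fh.close()
    if not lines:
        raise ValueError("empty PHYLIP input (line 1)")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise ValueError("line 1: expected leaf count") from None
    if len(lines) - 1 < n:
        raise ValueError(f"expected {n} rows, found {len(lines) - 1}")
    labels, rows = [], []
    for lineno, line in enumerate(lines[1:n + 1], start=2):
        parts = line.split()
        if len(parts) != n + 1:
            raise ValueError(
                f"line {lineno}: expected label + {n} values, got "
                f"{len(parts)} fields")
        labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    return DistanceMatrix(labels, np.array(rows))


def read_color_map(path_or_handle) -> dict[str, str]:
    """Read a gene<TAB>species map."""
    own = isinstance(path_or_handle, str)
    fh = open(path_or_handle) if own else path_or_handle
    try:
        out = {}
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated fields")
            out[parts[0]] = parts[1]
        return out
    finally:
        if own:
            fh.close()


def write_color_map(color: dict[str, str], path_or_handle) -> None:
    own = isinstance(path_or_handle, str)
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        for gene, species in color.items():
            fh.write(f"{gene}\t{species}\n")
    finally:
        if own:
            fh.close()
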