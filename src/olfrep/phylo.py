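"""Tree-based computations: rooting, cophenetic distances, clade extraction.

Trees arrive as newick with branch lengths in substitutions/site and
bootstrap supports (0-100 integers) on internal nodes. The two scientific
operations are:

* ``extract_clades`` — the bootstrap-gated clade rule used to partition a
  receptor repertoire into major clades: a clade qualifies when it contains
  at least ``min_size`` focal genes (and focal genes only) with bootstrap
  support >= ``min_support``; the *maximal* such nodes are reported, so the
  partition uses the largest defendable clades. Genes in no selected clade
  are labelled ``Else``.
* ``classify_by_reference_clade`` — family assignment by the smallest
  reference-defined clade (e.g. typical V2R vs. CaSR vs. V2R-like panels)
  containing each focal gene.

Supports are expected on the 0-100 scale; trees whose supports all lie in
[0, 1] are rejected unless ``fractional_supports=True`` is passed at read
time, which rescales them by 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SupportTree",
    "CladeNotFoundError",
    "root_with_outgroup",
    "cophenetic_distances",
    "extract_clades",
    "classify_by_reference_clade",
    "read_clade_table",
    "write_clade_table",
]

ELSE_LABEL = "Else"


class CladeNotFoundError(ValueError):
    """A required clade (outgroup or reference panel) is absent or broken."""


class SupportTree:
    """A rooted tree with branch lengths and 0-100 internal-node supports.

    Thin wrapper over a :class:`dendropy.Tree`; supports are parsed from
    internal-node labels (``...)95:0.1``) and kept as ``node.support``
    (``None`` when absent).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            seen, dup = set(), set()
            for l in labels:
                (dup if l in seen else seen).add(l)
            raise ValueError(f"duplicate leaf labels: {sorted(dup)}")
        for nd in tree.preorder_node_iter():
            if not hasattr(nd, "support"):
                nd.support = None

    # -- construction -------------------------------------------------------

    @classmethod
    def read_newick(cls, source: str, fractional_supports: bool = False) -> "SupportTree":
        """Parse newick text or a file path; internal labels become supports."""
        try:
            if "(" in source:
                tree = dendropy.Tree.get(
                    data=source, schema="newick", preserve_underscores=True
                )
            else:
                tree = dendropy.Tree.get(
                    path=source, schema="newick", preserve_underscores=True
                )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate leaf labels in newick: {exc}") from exc
        tree.is_rooted = True
        supports = []
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                nd.support = None
                continue
            nd.support = None
            if nd.label is not None:
                try:
                    nd.support = float(nd.label)
                except ValueError:
                    pass
            if nd.support is not None:
                supports.append(nd.support)
        if supports:
            if any(s < 0 or s > 100 for s in supports):
                raise ValueError("supports outside [0, 100]")
            if max(supports) <= 1.0:
                if not fractional_supports:
                    raise ValueError(
                        "all supports lie in [0, 1]; pass fractional_supports=True "
                        "if they are fractions of 1 (they will be rescaled by 100)"
                    )
                for nd in tree.preorder_node_iter():
                    if nd.support is not None:
                        nd.support = nd.support * 100.0
        for e in tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValueError("negative branch length")
        return cls(tree)

    def write_newick(self, path=None) -> str:
        """Emit newick with supports as plain internal-node labels."""
        for nd in self._tree.preorder_node_iter():
            if not nd.is_leaf() and nd.support is not None:
                nd.label = (
                    str(int(nd.support)) if float(nd.support).is_integer()
                    else repr(nd.support)
                )
        text = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip() + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    # -- basic queries ------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def __len__(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def clade_leafsets(self) -> list[tuple[frozenset[str], float | None]]:
        """(leaf set, support) for every internal node, preorder."""
        out = []
        for nd in self._tree.preorder_internal_node_iter():
            leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            out.append((leaves, nd.support))
        return out


def root_with_outgroup(tree: SupportTree, outgroup: Iterable[str]) -> SupportTree:
    """Root on the edge separating a monophyletic outgroup from the ingroup.

    Supports stay attached to the bipartitions they describe: they are
    carried on edges through the rerooting, so no support jumps across the
    new root.
    """
    outgroup = set(outgroup)
    t = tree.dendropy_tree.clone(depth=1)
    all_leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
    missing = outgroup - all_leaves
    if missing:
        raise CladeNotFoundError(f"outgroup leaves not in tree: {sorted(missing)}")

    # supports describe bipartitions, i.e. edges: pin them there for the move
    for nd in t.preorder_node_iter():
        nd.edge.support = getattr(nd, "support", None)

    ingroup = all_leaves - outgroup
    if not ingroup:
        raise CladeNotFoundError("outgroup covers the entire tree")

    target = None
    for nd in t.preorder_node_iter():
        leaves = {lf.taxon.label for lf in nd.leaf_iter()}
        # an edge separates outgroup from ingroup iff its leafset equals
        # the outgroup or its complement (unrooted monophyly)
        if leaves == outgroup or leaves == ingroup:
            target = nd
            break
    if target is None:
        mrca = t.mrca(taxon_labels=sorted(outgroup))
        inside = sorted(
            {lf.taxon.label for lf in mrca.leaf_iter()} - outgroup
        )
        raise CladeNotFoundError(
            f"outgroup is not monophyletic; intruding leaves: {inside}"
        )

    edge = target.edge
    if edge.tail_node is not None:
        lg = (edge.length or 0.0) / 2.0
        t.reroot_at_edge(edge, length1=lg, length2=lg, update_bipartitions=False)
    t.suppress_unifurcations()

    for nd in t.preorder_node_iter():
        nd.support = getattr(nd.edge, "support", None)
    root = t.seed_node
    root.support = None
    return SupportTree(t)


def cophenetic_distances(tree: SupportTree) -> pd.DataFrame:
    """All-pairs leaf path-length (cophenetic) distance matrix.

    d(i, j) is the sum of branch lengths on the unique path between leaves
    i and j — the quantity ``cophenetic.phylo`` returns in ape. Computed
    from root-to-leaf depths: d(i, j) = depth(i) + depth(j) − 2·depth(mrca).
    """
    t = tree.dendropy_tree
    leaves = []
    for lf in t.leaf_node_iter():
        leaves.append(lf)
        if lf.edge.tail_node is not None and lf.edge.length is None:
            raise ValueError(f"missing branch length above leaf {lf.taxon.label}")
    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    index = {lf: i for i, lf in enumerate(leaves)}

    depth: dict = {t.seed_node: 0.0}
    for nd in t.preorder_node_iter():
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise ValueError("missing branch length on an internal edge")
            depth[nd] = depth[nd.parent_node] + nd.edge.length

    dmat = np.zeros((n, n))
    # postorder accumulation: for each internal node, pairs of leaves whose
    # mrca is that node are pairs drawn from different child subtrees
    below: dict = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = [nd]
            continue
        kids = [below[c] for c in nd.child_nodes()]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for la in kids[a]:
                    ia = index[la]
                    da = depth[la] - 2.0 * depth[nd]
                    for lb in kids[b]:
                        ib = index[lb]
                        d = da + depth[lb]
                        dmat[ia, ib] = d
                        dmat[ib, ia] = d
        merged = [lf for k in kids for lf in k]
        below[nd] = merged
    return pd.DataFrame(dmat, index=labels, columns=labels)


@dataclass(frozen=True)
class Clade:
    label: str
    leaves: frozenset[str]
    support: float


def extract_clades(
    tree: SupportTree,
    focal: Iterable[str],
    min_size: int = 5,
    min_support: float = 85.0,
) -> dict[str, str]:
    """Partition focal genes into bootstrap-supported major clades.

    A node qualifies when its leaf set lies entirely within ``focal``, has
    >= ``min_size`` leaves, and support >= ``min_support``. The maximal
    qualifying nodes (those with no qualifying ancestor) become the clades,
    labelled ``Clade1..K`` by decreasing size then alphabetically by first
    leaf; remaining focal genes map to ``Else``. A warning is emitted if
    fewer than three clades are found, since repertoire partitions of fewer
    clades rarely separate the genomic clusters.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    focal = set(focal)
    t = tree.dendropy_tree

    def qualifies(nd) -> bool:
        if nd.is_leaf():
            return False
        leaves = {lf.taxon.label for lf in nd.leaf_iter()}
        return (
            leaves <= focal
            and len(leaves) >= min_size
            and nd.support is not None
            and nd.support >= min_support
        )

    selected: list[frozenset[str]] = []
    stack = [t.seed_node]
    while stack:
        nd = stack.pop()
        if qualifies(nd):
            selected.append(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
        else:
            stack.extend(nd.child_nodes())

    selected.sort(key=lambda s: (-len(s), min(s)))
    assignment = {g: ELSE_LABEL for g in focal}
    for i, leaves in enumerate(selected, start=1):
        for g in leaves:
            assignment[g] = f"Clade{i}"
    if len(selected) < 3:
        warnings.warn(
            f"only {len(selected)} clade(s) met min_size={min_size}, "
            f"min_support={min_support}; three or more were aimed for",
            stacklevel=2,
        )
    return assignment


def classify_by_reference_clade(
    tree: SupportTree,
    refs: Mapping[str, Iterable[str]],
    focal: Iterable[str],
) -> dict[str, str]:
    """Assign focal genes to reference groups by smallest containing clade.

    Each reference group (e.g. gnathostome V2Rs, CaSRs, V2R-like) defines a
    clade: the smallest clade containing all its reference leaves (MRCA
    leaf set, on the rooted tree). A focal gene takes the group whose
    defining clade is the smallest one containing it; genes inside no
    defining clade are ``unclassified``.
    """
    focal = set(focal)
    t = tree.dendropy_tree
    all_leaves = set(tree.leaf_labels)
    defining: dict[str, frozenset[str]] = {}
    for group, leaves in refs.items():
        leaves = set(leaves)
        missing = leaves - all_leaves
        if missing:
            raise CladeNotFoundError(
                f"reference group {group!r} leaves absent from tree: {sorted(missing)}"
            )
        mrca = t.mrca(taxon_labels=sorted(leaves))
        defining[group] = frozenset(lf.taxon.label for lf in mrca.leaf_iter())

    out: dict[str, str] = {}
    for g in sorted(focal):
        containing = [(len(s), grp) for grp, s in defining.items() if g in s]
        out[g] = min(containing)[1] if containing else "unclassified"
    return out


def read_clade_table(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"].astype(str), df["clade"].astype(str)))


def write_clade_table(assignment: Mapping[str, str], path) -> None:
    pd.DataFrame(
        sorted(assignment.items()), columns=["gene_id", "clade"]
    ).to_csv(path, sep="\t", index=False)
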