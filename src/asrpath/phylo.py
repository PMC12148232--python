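"""Rooted phylogenies, phylogenetic covariance, and independent contrasts.

The tree is the source of the error-covariance structure used throughout the
package: under Brownian motion, trait covariance between two species equals
the shared root-to-MRCA path length.  This module provides newick I/O (parsed
and validated through dendropy), construction of that covariance matrix,
Pagel's-lambda rescaling of either the matrix or the tree itself, Nee's-method
branch lengths for composite supertrees, and Felsenstein's phylogenetically
independent contrasts.

Conventions
-----------
* Branch lengths are kept in the tree's native units; nothing is rescaled to
  unit height unless a caller asks for it.
* Polytomies are resolved deterministically left-to-right with zero-length
  internal branches before contrasts are computed.
* Missing branch lengths are preserved as ``None`` and rejected (with the
  offending edges named) by operations that need them; they are never
  silently set to zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

try:
    import dendropy
except ImportError as _exc:  # pragma: no cover
    raise ImportError("asrpath requires dendropy for newick parsing") from _exc


class PhyloError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


class Node:
    """A node in a rooted tree; tips carry labels, edges carry lengths."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node(label={self.label!r}, length={self.length!r}, nchild={len(self.children)})"


class Phylogeny:
    """A rooted phylogeny with unique tip labels and non-negative branch lengths."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self._validate()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        """Parse a newick string.  Underscores and quoted labels are accepted;
        internal node labels are ignored; a ``.phy`` file containing plain
        newick parses identically."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise PhyloError(f"newick parse error: {exc}") from exc

        def convert(dnode) -> Node:
            label = None
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        root = convert(dtree.seed_node)
        root.length = None  # the root has no branch
        return cls(root)

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                core = _quote_label(node.label)
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.length is not None and node.parent is not None:
                core += ":%.17g" % node.length
            return core

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------ traversal

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    # ----------------------------------------------------------- validation

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            seen, dups = set(), set()
            for lab in labels:
                (dups if lab in seen else seen).add(lab)
            raise PhyloError(f"duplicate tip labels: {sorted(dups)}")
        if any(lab is None for lab in labels):
            raise PhyloError("unlabeled tip in tree")
        for node in self.preorder():
            if node.parent is not None and node.length is not None:
                if not math.isfinite(node.length) or node.length < 0:
                    raise PhyloError(
                        f"invalid branch length {node.length!r} above "
                        f"{node.label or 'internal node'}"
                    )

    @property
    def has_branch_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.preorder() if n.parent is not None
        )

    def missing_length_edges(self) -> list[str]:
        out = []
        for node in self.preorder():
            if node.parent is not None and node.length is None:
                out.append(node.label or f"internal:{id(node) & 0xffff}")
        return out

    # ----------------------------------------------------------- structure

    def copy(self) -> "Phylogeny":
        def dup(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(dup(child))
            return new

        return Phylogeny(dup(self.root), validate=False)

    def node_depths(self) -> dict[int, float]:
        """Root-to-node path lengths keyed by ``id(node)``."""
        self._require_lengths()
        depths = {id(self.root): 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depths[id(node)] = depths[id(node.parent)] + node.length
        return depths

    def _require_lengths(self) -> None:
        missing = self.missing_length_edges()
        if missing:
            raise PhyloError(f"missing branch lengths above: {missing}")

    def total_length(self) -> float:
        self._require_lengths()
        return sum(n.length for n in self.preorder() if n.parent is not None)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self.node_depths()
        tip_depths = [depths[id(t)] for t in self.tips()]
        return max(tip_depths) - min(tip_depths) <= tol

    def height(self) -> float:
        depths = self.node_depths()
        return max(depths[id(t)] for t in self.tips())

    def prune(self, labels: Iterable[str]) -> "Phylogeny":
        """Restrict to a subset of tips; unifurcations are collapsed by summing
        branch lengths, so tip-to-tip path lengths are preserved."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise PhyloError(f"labels not in tree: {sorted(missing)}")
        if not keep:
            raise PhyloError("cannot prune to an empty label set")

        def rebuild(node: Node) -> Node | None:
            if node.is_tip:
                if node.label in keep:
                    return Node(node.label, node.length)
                return None
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if node.length is not None and child.length is not None:
                    child.length = child.length + node.length
                elif node.parent is None:
                    pass  # becoming the new root; its edge is dropped
                return child
            new = Node(node.label, node.length)
            for k in kids:
                new.add_child(k)
            return new

        root = rebuild(self.root)
        if root is None:  # pragma: no cover - guarded above
            raise PhyloError("pruning removed every tip")
        root.parent = None
        if root.is_tip:
            raise PhyloError("pruning left a single tip; need >= 2")
        root.length = None
        return Phylogeny(root)

    def resolve_polytomies(self) -> "Phylogeny":
        """Binary tree via deterministic left-to-right resolution; the new
        internal branches have length zero."""
        tree = self.copy()
        for node in list(tree.postorder()):
            while len(node.children) > 2:
                left, second = node.children[0], node.children[1]
                merged = Node(None, 0.0)
                merged.add_child(left)
                merged.add_child(second)
                merged.parent = node
                node.children = [merged] + node.children[2:]
        return Phylogeny(tree.root, validate=False)

    def rescale_lambda(self, lam: float) -> "Phylogeny":
        """Pagel's-lambda tree rescaling: every branch is multiplied by
        ``lam`` and each terminal branch receives ``(1-lam)`` times the tip's
        original root-to-tip depth, so tip variances (matrix diagonal) are
        preserved while shared history shrinks."""
        _check_lambda(lam)
        depths = self.node_depths()
        tree = self.copy()
        orig = {t.label: depths[id(t)] for t in self.tips()}
        for node in tree.preorder():
            if node.parent is None:
                continue
            node.length = node.length * lam
            if node.is_tip:
                node.length += (1.0 - lam) * orig[node.label]
        return tree

    def covariance(self) -> "PhyloCovariance":
        return phylo_covariance(self)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _check_lambda(lam: float) -> None:
    if not (0.0 <= lam <= 1.0):
        raise PhyloError(f"lambda must lie in [0, 1]; got {lam!r}")


# --------------------------------------------------------------------------
# Covariance
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion covariance implied by a tree: C[i, j] is the shared
    root-to-MRCA path length, C[i, i] the root-to-tip length.  ``lam`` records
    the Pagel's-lambda scaling already applied to the off-diagonals."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise PhyloError("covariance shape does not match labels")
        object.__setattr__(self, "matrix", m)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def align(self, labels: Sequence[str]) -> "PhyloCovariance":
        """Reorder/subset to the given labels."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            idx = [index[lab] for lab in labels]
        except KeyError as exc:
            raise PhyloError(f"label {exc} not in covariance") from exc
        sub = self.matrix[np.ix_(idx, idx)]
        return PhyloCovariance(tuple(labels), sub, self.lam)


def read_newick(path) -> Phylogeny:
    """Read a newick (or plain-newick ``.phy``) file."""
    return Phylogeny.read(path)


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """Shared-path-length matrix over the tips, in tip (preorder) order."""
    tree._require_lengths()
    tips = tree.tips()
    labels = tuple(t.label for t in tips)
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    depths = tree.node_depths()

    def collect(node: Node) -> list[int]:
        if node.is_tip:
            return [index[id(node)]]
        groups = [collect(c) for c in node.children]
        depth = depths[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        C[i, j] = C[j, i] = depth
        merged = [i for g in groups for i in g]
        return merged

    collect(tree.root)
    for tip in tips:
        i = index[id(tip)]
        C[i, i] = depths[id(tip)]
    return PhyloCovariance(labels, C, 1.0)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by ``lam`` (diagonal unchanged)."""
    _check_lambda(lam)
    m = cov.matrix * lam
    np.fill_diagonal(m, np.diag(cov.matrix))
    return PhyloCovariance(cov.labels, m, cov.lam * lam)


def nee_branch_lengths(tree: Phylogeny) -> Phylogeny:
    """Assign branch lengths to a (composite) topology by Nee's method:
    each node sits at height ``ln(number of descendant tips)`` above the tips,
    so a branch's length is the difference of the log tip counts of its ends.
    The result is ultrametric with total depth ``ln(n_tips)``."""
    new = tree.copy()
    counts: dict[int, int] = {}
    for node in new.postorder():
        counts[id(node)] = 1 if node.is_tip else sum(
            counts[id(c)] for c in node.children
        )
    for node in new.preorder():
        if node.parent is None:
            node.length = None
            continue
        length = math.log(counts[id(node.parent)]) - math.log(counts[id(node)])
        if length == 0.0:
            warnings.warn(
                "Nee's method produced a zero-length branch (unifurcation or "
                "equal descendant counts)",
                stacklevel=2,
            )
        node.length = length
    return Phylogeny(new.root)


# --------------------------------------------------------------------------
# Independent contrasts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastSet:
    """Standardized independent contrasts: one per internal node of the
    (polytomy-resolved) tree, so ``n_tips - 1`` in total."""

    contrasts: np.ndarray
    expected_variances: np.ndarray
    node_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.contrasts)


def independent_contrasts(
    tree: Phylogeny, values: Mapping[str, float] | pd.Series
) -> ContrastSet:
    """Felsenstein's standardized contrasts for one trait.

    The tree is pruned to the valued tips and polytomies are resolved
    (deterministically) first.  Contrasts follow the convention
    ``(left - right) / sqrt(vL + vR)``; ancestral values are the
    branch-length-weighted averages and parent branches are lengthened by
    ``vL*vR/(vL+vR)`` as usual.  A zero-variance contrast (both adjusted
    branches of length zero) is an error unless the two descendant values are
    equal, in which case the contrast is 0 and the variance is imputed as the
    smallest positive branch-length sum in the tree times 1e-6.
    """
    if isinstance(values, pd.Series):
        values = values.dropna().to_dict()
    values = {k: float(v) for k, v in values.items() if np.isfinite(v)}
    labels = [lab for lab in tree.tip_labels if lab in values]
    if len(labels) < 2:
        raise PhyloError("need at least two valued tips for contrasts")
    work = tree if set(labels) == set(tree.tip_labels) else tree.prune(labels)
    work = work.resolve_polytomies()
    work._require_lengths()

    positive_sums = [
        c1.length + c2.length
        for node in work.postorder()
        if len(node.children) == 2
        for c1, c2 in [node.children]
        if c1.length + c2.length > 0
    ]
    floor = (min(positive_sums) * 1e-6) if positive_sums else 1e-6

    x: dict[int, float] = {}
    v: dict[int, float] = {}
    contrasts, variances, node_ids = [], [], []
    internal_index = 0
    for node in work.postorder():
        if node.is_tip:
            x[id(node)] = values[node.label]
            v[id(node)] = node.length
            continue
        c1, c2 = node.children
        v1, v2 = v[id(c1)], v[id(c2)]
        total = v1 + v2
        diff = x[id(c1)] - x[id(c2)]
        if total <= 0:
            if diff != 0.0:
                raise PhyloError(
                    "zero expected variance with unequal descendant values"
                )
            total = floor
        contrasts.append(diff / math.sqrt(total))
        variances.append(total)
        node_ids.append(internal_index)
        internal_index += 1
        x[id(node)] = (x[id(c1)] / v1 + x[id(c2)] / v2) / (1 / v1 + 1 / v2) if (
            v1 > 0 and v2 > 0
        ) else (x[id(c1)] + x[id(c2)]) / 2.0
        extra = (v1 * v2 / (v1 + v2)) if (v1 + v2) > 0 else 0.0
        v[id(node)] = (node.length or 0.0) + extra
    return ContrastSet(
        np.asarray(contrasts), np.asarray(variances), tuple(node_ids)
    )
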