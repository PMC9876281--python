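"""Phylogenetic tree container and Newick serialization.

Trees carry non-negative branch lengths in substitutions per site. An
unrooted tree is represented with a trifurcating root node; a rooted tree
(e.g. after midpoint rooting) has a bifurcating root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


class NewickError(ValueError):
    """Raised on malformed Newick text; carries the character offset."""


@dataclass
class TreeNode:
    label: Optional[str] = None
    branch_length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, bl={self.branch_length:g}, n={len(self.children)})"


@dataclass
class Tree:
    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label or "" for n in self.leaves()]

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def n_edges(self) -> int:
        return sum(1 for n in self.preorder() if n.parent is not None)

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Patristic distance between every unordered pair of leaves."""
        dists: dict[tuple[str, str], float] = {}
        # distances from each node down to the leaves beneath it
        below: dict[int, list[tuple[str, float]]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = [(node.label or "", 0.0)]
                continue
            merged: list[tuple[str, float]] = []
            kid_lists = []
            for child in node.children:
                lst = [(lab, d + child.branch_length) for lab, d in below[id(child)]]
                kid_lists.append(lst)
            for i in range(len(kid_lists)):
                for j in range(i + 1, len(kid_lists)):
                    for la, da in kid_lists[i]:
                        for lb, db in kid_lists[j]:
                            key = (la, lb) if la < lb else (lb, la)
                            dists[key] = da + db
                merged.extend(kid_lists[i])
            below[id(node)] = merged
        return dists

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the smaller-or-canonical leaf set.

        Used to compare topologies of trees over the same leaf set
        irrespective of rooting.
        """
        all_leaves = frozenset(self.leaf_labels())
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label or ""])
                continue
            clade = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = clade
            if node.parent is None:
                continue
            other = all_leaves - clade
            if len(clade) < 2 or len(other) < 2:
                continue
            splits.add(min(clade, other, key=lambda s: (len(s), sorted(s))))
        return splits


def _format_length(value: float) -> str:
    """Six significant digits, no exponent notation for typical lengths."""
    return f"{value:.6g}"


def write_newick(tree: Tree) -> str:
    def render(node: TreeNode, with_length: bool) -> str:
        if node.is_leaf:
            body = node.label or ""
        else:
            body = "(" + ",".join(render(c, True) for c in node.children) + ")"
        if with_length:
            body += f":{_format_length(node.branch_length)}"
        return body

    return render(tree.root, False) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement (must end in ';').

    Branch lengths default to 0 when absent. Raises :class:`NewickError`
    with the character offset on unbalanced parentheses or stray input,
    and on duplicate leaf labels.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError(f"Newick statement must end in ';' (offset {len(text)})")
    body = text[:-1]
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(f"{msg} (offset {pos})")

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(body) and body[pos] not in "(),:;":
            pos += 1
        return body[start:pos].strip()

    def parse_length() -> float:
        nonlocal pos
        if pos < len(body) and body[pos] == ":":
            pos += 1
            start = pos
            while pos < len(body) and body[pos] not in "(),;":
                pos += 1
            try:
                return float(body[start:pos])
            except ValueError:
                raise error(f"bad branch length {body[start:pos]!r}") from None
        return 0.0

    def parse_clade() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(body) and body[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_clade())
                if pos >= len(body):
                    raise error("unbalanced parentheses")
                if body[pos] == ",":
                    pos += 1
                    continue
                if body[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {body[pos]!r}")
            label = parse_label()
            node.label = label or None
        else:
            label = parse_label()
            if not label:
                raise error("expected a leaf label")
            node.label = label
        node.branch_length = parse_length()
        return node

    root = parse_clade()
    if pos != len(body):
        raise NewickError(f"trailing characters after tree (offset {pos})")
    tree = Tree(root)
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate leaf labels: {dupes}")
    return tree
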