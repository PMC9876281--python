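"""Pairwise and progressive alignment, distances, and neighbor-joining trees.

The alignment stage is an explicit, fully specified stand-in for the
black-box aligner typically used in published surveys: affine-gap global
alignment (Gotoh three-state recurrence) under BLOSUM62 with gap open 10
and gap extend 1, a p-distance matrix, Saitou–Nei neighbor joining with the
Studier–Keppler Q criterion, midpoint rooting, and a guide-tree progressive
profile aligner. Every choice (tie-breaks included) is deterministic so
identical inputs give byte-identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from rbh3kit.formats import AMINO_ACIDS, GAP, UNKNOWN, Alignment, ProteinSequence
from rbh3kit.tree import Tree, TreeNode

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


class ScoringMatrix:
    """Symmetric residue substitution scores (BLOSUM62 by default).

    ``X`` (unknown residue) scores 0 against everything: ambiguity codes
    neither support nor penalize a homologous-substitution call.
    """

    def __init__(self, name: str = "BLOSUM62"):
        self.name = name
        raw = substitution_matrices.load(name)
        self._alphabet = AMINO_ACIDS + UNKNOWN
        n = len(self._alphabet)
        self._index = {aa: i for i, aa in enumerate(self._alphabet)}
        mat = np.zeros((n, n), dtype=float)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                mat[i, j] = raw[a][b]
        # X row/column forced to 0 regardless of the published matrix
        self._matrix = mat

    def score(self, a: str, b: str) -> float:
        try:
            return self._matrix[self._index[a], self._index[b]]
        except KeyError as exc:
            raise ValueError(f"unknown residue {exc.args[0]!r}") from None

    def as_array(self) -> np.ndarray:
        """Scores over the alphabet ``ACDEFGHIKLMNPQRSTVWYX`` (X row = 0)."""
        return self._matrix.copy()

    @property
    def alphabet(self) -> str:
        return self._alphabet


def score(matrix: ScoringMatrix, a: str, b: str) -> float:
    return matrix.score(a, b)


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned1: str
    aligned2: str
    score: float
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if len(self.aligned1) != len(self.aligned2):
            raise ValueError("aligned rows differ in length")


def global_align(
    s1: str,
    s2: str,
    matrix: ScoringMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gap cost ``open + k * extend``.

    Three-state (match / gap-in-s2 / gap-in-s1) dynamic program with a
    deterministic traceback (match preferred, then a gap consuming ``s1``,
    then a gap consuming ``s2``).
    """
    if not s1 or not s2:
        raise ValueError("global_align requires two non-empty sequences")
    if GAP in s1 or GAP in s2:
        raise ValueError("input sequences must be gap-free")
    matrix = matrix or get_blosum62()

    n, m = len(s1), len(s2)
    NEG = float("-inf")
    # state 0 = M (aligned pair), 1 = Ix (gap in s2, consumes s1), 2 = Iy
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + j * gap_extend)

    for i in range(1, n + 1):
        si = s1[i - 1]
        for j in range(1, m + 1):
            sub = matrix.score(si, s2[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + sub
            Ix[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend,
                Ix[i - 1, j] - gap_extend,
                Iy[i - 1, j] - gap_open - gap_extend,
            )
            Iy[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend,
                Iy[i, j - 1] - gap_extend,
                Ix[i, j - 1] - gap_open - gap_extend,
            )

    # deterministic traceback, state preference M > Ix > Iy
    scores = (M, Ix, Iy)
    i, j = n, m
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    best = scores[state][n, m]
    out1: list[str] = []
    out2: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            sub = matrix.score(s1[i - 1], s2[j - 1])
            target = M[i, j] - sub
            cands = [(M, 0), (Ix, 1), (Iy, 2)]
            state = next(s for arr, s in cands if arr[i - 1, j - 1] == target)
            out1.append(s1[i - 1])
            out2.append(s2[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            out1.append(s1[i - 1])
            out2.append(GAP)
            val = Ix[i, j]
            if M[i - 1, j] - gap_open - gap_extend == val:
                state = 0
            elif Ix[i - 1, j] - gap_extend == val:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            out1.append(GAP)
            out2.append(s2[j - 1])
            val = Iy[i, j]
            if M[i, j - 1] - gap_open - gap_extend == val:
                state = 0
            elif Iy[i, j - 1] - gap_extend == val:
                state = 2
            else:
                state = 1
            j -= 1
    return PairwiseAlignment(
        "".join(reversed(out1)), "".join(reversed(out2)), float(best),
        gap_open, gap_extend,
    )


_BLOSUM62: ScoringMatrix | None = None


def get_blosum62() -> ScoringMatrix:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = ScoringMatrix("BLOSUM62")
    return _BLOSUM62


def p_distance(row1: str, row2: str) -> float:
    """Fraction of mismatches over columns where neither row is gapped.

    Degenerate pairs with no comparable column return 1.0.
    """
    if len(row1) != len(row2):
        raise ValueError("rows differ in length")
    comparable = 0
    identical = 0
    for a, b in zip(row1, row2):
        if a == GAP or b == GAP:
            continue
        comparable += 1
        if a == b:
            identical += 1
    if comparable == 0:
        return 1.0
    return 1.0 - identical / comparable


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def validate(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.matrix < 0):
            raise ValueError("distance matrix has negative entries")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix diagonal is not zero")


def distance_matrix(
    data: Alignment | Sequence[ProteinSequence],
    matrix: ScoringMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> DistanceMatrix:
    """p-distance matrix from an alignment, or from unaligned sequences by
    aligning each pair globally first. Requires at least three sequences."""
    if isinstance(data, Alignment):
        rows = [(r.id, r.residues) for r in data.rows]
        aligned = True
    else:
        rows = [(r.id, r.residues) for r in data]
        aligned = False
    if len(rows) < 3:
        raise ValueError("need at least 3 sequences for a usable distance matrix")
    n = len(rows)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if aligned:
                d = p_distance(rows[i][1], rows[j][1])
            else:
                pw = global_align(rows[i][1], rows[j][1], matrix, gap_open, gap_extend)
                d = p_distance(pw.aligned1, pw.aligned2)
            out[i, j] = out[j, i] = d
    return DistanceMatrix([r[0] for r in rows], out)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining (Studier–Keppler Q criterion).

    Ties in Q are broken by the lowest (i, j) pair in the current node
    order, which follows the input id order; negative branch-length
    estimates are clamped to zero. The result is unrooted, represented
    with a trifurcating root.
    """
    dm.validate()
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(label=i) for i in dm.ids]
    D = dm.matrix.astype(float).copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(k, 1)
        # row-major argmin gives the lowest (i, j) pair on exact ties
        best = int(np.argmin(Q[iu]))
        i, j = int(iu[0][best]), int(iu[1][best])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode()
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        new.add_child(child_i)
        new.add_child(child_j)
        newdist = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        D2 = np.zeros((k - 1, k - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = newdist[keep]
        D2[:-1, -1] = newdist[keep]
        nodes = [nodes[x] for x in keep] + [new]
        D = D2

    # resolve the final three nodes around a trifurcating root
    a = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    b = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    c = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    root = TreeNode()
    for node, length in zip(nodes, (a, b, c)):
        node.branch_length = max(length, 0.0)
        root.add_child(node)
    return Tree(root)


def _reroot_at(child: TreeNode, dist_below: float) -> Tree:
    """Insert a root on the edge above ``child``, ``dist_below`` from it."""
    parent = child.parent
    assert parent is not None
    edge_len = child.branch_length
    root = TreeNode()
    parent.children.remove(child)
    root.add_child(child)
    child.branch_length = dist_below

    # reverse the parent chain so `parent` hangs off the new root
    carry = edge_len - dist_below
    node = parent
    prev: TreeNode = root
    while node is not None:
        upper = node.parent
        upper_len = node.branch_length
        if upper is not None:
            upper.children.remove(node)
        prev.add_child(node)
        node.branch_length = carry
        carry = upper_len
        prev = node
        node = upper
    # collapse any passthrough node left with a single child
    for n in list(Tree(root).preorder()):
        if n is not root and not n.is_leaf and len(n.children) == 1:
            only = n.children[0]
            only.branch_length += n.branch_length
            gp = n.parent
            idx = gp.children.index(n)
            gp.children[idx] = only
            only.parent = gp
    return Tree(root)


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties on the diameter pair break lexicographically by leaf labels; a
    tree whose branch lengths are all zero is rooted on the edge above the
    lexicographically smallest leaf.
    """
    leaves = {n.label: n for n in tree.leaves()}
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    dists = tree.leaf_distances()
    (u_lab, v_lab), diameter = min(
        dists.items(), key=lambda kv: (-kv[1], kv[0])
    )
    if diameter == 0.0:
        u_lab = min(leaves)
        return _reroot_at(leaves[u_lab], 0.0)

    # edge path from u to v through their junction
    def ancestors(node: TreeNode) -> list[TreeNode]:
        chain = [node]
        while chain[-1].parent is not None:
            chain.append(chain[-1].parent)
        return chain

    u, v = leaves[u_lab], leaves[v_lab]
    anc_u, anc_v = ancestors(u), ancestors(v)
    common = {id(n) for n in anc_u} & {id(n) for n in anc_v}
    up = []  # edges (node, length) walking u -> junction
    node = u
    while id(node) not in common:
        up.append(node)
        node = node.parent
    down = []
    node = v
    while id(node) not in common:
        down.append(node)
        node = node.parent
    path = up + list(reversed(down))  # each entry: edge above that node
    # walking from u, the first len(up) edges ascend; the rest descend to v
    half = diameter / 2.0
    walked = 0.0
    for idx, edge_node in enumerate(path):
        L = edge_node.branch_length
        if walked + L >= half or idx == len(path) - 1:
            from_u_side = half - walked
            if idx < len(up):
                # ascending: edge_node is nearer u; distance below = remainder
                return _reroot_at(edge_node, min(from_u_side, L))
            # descending: edge_node is nearer v
            below = L - min(from_u_side, L)
            return _reroot_at(edge_node, below)
        walked += L
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _profile_columns(rows: list[str], matrix: ScoringMatrix) -> np.ndarray:
    """Residue count vectors per column over the 21-letter alphabet."""
    idx = {aa: i for i, aa in enumerate(matrix.alphabet)}
    width = len(rows[0])
    counts = np.zeros((width, len(matrix.alphabet)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != GAP:
                counts[c, idx[ch]] += 1
    return counts


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    matrix: ScoringMatrix,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two gapped profiles.

    The substitution term between two columns is the mean pairwise
    substitution score over non-gap residue pairs; gap-against-residue
    contributes through the affine gap states only.
    """
    S = matrix.as_array()
    ca = _profile_columns(rows_a, matrix)
    cb = _profile_columns(rows_b, matrix)
    na = ca.sum(axis=1)
    nb = cb.sum(axis=1)
    cross = ca @ S @ cb.T
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        sub = np.where(denom > 0, cross / np.maximum(denom, 1e-300), 0.0)

    n, m = len(ca), len(cb)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        prevM, prevIx, prevIy = M[i - 1], Ix[i - 1], Iy[i - 1]
        subrow = sub[i - 1]
        for j in range(1, m + 1):
            M[i, j] = max(prevM[j - 1], prevIx[j - 1], prevIy[j - 1]) + subrow[j - 1]
            Ix[i, j] = max(
                prevM[j] - gap_open - gap_extend,
                prevIx[j] - gap_extend,
                prevIy[j] - gap_open - gap_extend,
            )
            Iy[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend,
                Iy[i, j - 1] - gap_extend,
                Ix[i, j - 1] - gap_open - gap_extend,
            )
    i, j = n, m
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    cols_a: list[int] = []  # -1 means gap column
    cols_b: list[int] = []
    while i > 0 or j > 0:
        if state == 0:
            target = M[i, j] - sub[i - 1, j - 1]
            for arr, s in ((M, 0), (Ix, 1), (Iy, 2)):
                if arr[i - 1, j - 1] == target:
                    state = s
                    break
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            i, j = i - 1, j - 1
        elif state == 1:
            cols_a.append(i - 1)
            cols_b.append(-1)
            val = Ix[i, j]
            if M[i - 1, j] - gap_open - gap_extend == val:
                state = 0
            elif Ix[i - 1, j] - gap_extend == val:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            cols_a.append(-1)
            cols_b.append(j - 1)
            val = Iy[i, j]
            if M[i, j - 1] - gap_open - gap_extend == val:
                state = 0
            elif Iy[i, j - 1] - gap_extend == val:
                state = 2
            else:
                state = 1
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    out_a = [
        "".join(row[c] if c >= 0 else GAP for c in cols_a) for row in rows_a
    ]
    out_b = [
        "".join(row[c] if c >= 0 else GAP for c in cols_b) for row in rows_b
    ]
    return out_a, out_b


def progressive_msa(
    sequences: Sequence[ProteinSequence],
    guide: Tree,
    matrix: ScoringMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Guide-tree progressive alignment with profile-profile merges.

    Profiles are merged in post-order; column scores are sum-of-pairs
    BLOSUM62 means and gaps use the same affine parameters as the pairwise
    aligner. Degapping any output row recovers the corresponding input.
    """
    matrix = matrix or get_blosum62()
    by_id = {s.id: s for s in sequences}
    leaf_ids = set(guide.leaf_labels())
    if leaf_ids != set(by_id):
        raise ValueError(
            f"guide tree leaves do not match sequences: "
            f"missing={sorted(leaf_ids - set(by_id))}, "
            f"extra={sorted(set(by_id) - leaf_ids)}"
        )
    profiles: dict[int, tuple[list[str], list[str]]] = {}  # ids, rows
    for node in guide.postorder():
        if node.is_leaf:
            seq = by_id[node.label]
            profiles[id(node)] = ([seq.id], [seq.residues.replace(GAP, "")])
            continue
        ids, rows = profiles[id(node.children[0])]
        for child in node.children[1:]:
            ids_b, rows_b = profiles[id(child)]
            rows, rows_b = _align_profiles(rows, rows_b, matrix, gap_open, gap_extend)
            ids = ids + ids_b
            rows = rows + rows_b
        profiles[id(node)] = (ids, rows)
    ids, rows = profiles[id(guide.root)]
    order = {s.id: k for k, s in enumerate(sequences)}
    merged = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    return Alignment(
        [ProteinSequence(i, r, by_id[i].description) for i, r in merged]
    )
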