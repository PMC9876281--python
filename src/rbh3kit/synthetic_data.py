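"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the data shape of a cross-species rBH3 survey: a
family of homologous protein sequences evolved along a known tree, carrying
an 18-residue motif window whose fate differs by clade — intact in some,
ablated by the binding-abolishing E→A substitution in others, displaced by
one position, or replaced by a forward BH3-like pattern. The defaults
mirror the clade patterns reported for the INK4/p53 families (mammals
intact, a reptilian intact/lost split, amphibians shifted, birds carrying
only a forward BH3-like motif).

The evolutionary model is deliberately simple: site-independent
substitution with per-branch probability 1 - exp(-t * scale) and
replacements drawn from the 19 alternatives weighted by exp(BLOSUM62/2),
so substitutions are biased toward homologous exchanges. There are no
indels; the true alignment is the simulated matrix itself. Designated
columns (the motif window and a set of frozen columns) are copied
verbatim, giving exact downstream ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rbh3kit.align_phylo import get_blosum62
from rbh3kit.formats import AMINO_ACIDS, GAP, Alignment, ProteinSequence
from rbh3kit.motifs import WINDOW_LENGTH, MotifStatus
from rbh3kit.tree import Tree, TreeNode

#: 18-column window templates implanted per clade action. The intact
#: template embeds a genuine reverse-BH3: window positions 6-17 read
#: backwards ("ISTNLRQLGEKV") satisfy Φ-X(3)-L-X(2)-Φ-G-[DE]-X-Φ, which
#: places the acid at window position 8 and hydrophobics at 10 and 13 —
#: the key-position geometry of the human motif. The other templates
#: derive from it: the E→A ablation, the one-column shift, replacement by
#: a forward BH3-like segment (LKRIDE matches Φ-X(2)-Φ-X-E), or deletion.
WINDOW_TEMPLATES: dict[str, str] = {
    "intact": "SGNTAVKEGLQRLNTSIN",
    "ablate_E_to_A": "SGNTAVKAGLQRLNTSIN",
    "shift_minus_1": "SGNTVKEGLQRLNTSINN",
    "replace_with_forward_bh3_like": "SGLKRIDEGSRTDTSKNG",
    "delete_window": GAP * WINDOW_LENGTH,
}

#: Status the assessor is expected to call for each implanted action.
ACTION_STATUS: dict[str, MotifStatus] = {
    "intact": MotifStatus.INTACT,
    "ablate_E_to_A": MotifStatus.LOST,
    "shift_minus_1": MotifStatus.SHIFTED,
    "replace_with_forward_bh3_like": MotifStatus.BH3_LIKE,
    "delete_window": MotifStatus.ABSENT,
}

#: Packaged default clade plan (24 taxa) mirroring the observed family
#: patterns: mammals intact, reptiles split intact/lost, amphibians
#: shifted by one position, birds with a forward BH3-like motif only.
DEFAULT_CLADE_PLAN: dict[str, list[str]] = {
    "Mammalia": ["intact"] * 6,
    "Reptilia": ["intact"] * 3 + ["ablate_E_to_A"] * 4,
    "Amphibia": ["shift_minus_1"] * 5,
    "Aves": ["replace_with_forward_bh3_like"] * 6,
}


#: Family-scale plans at the published per-class sequence counts.
#: The p18-like family carries the full set of observed fates: intact in
#: chondrichthyans/osteichthyans/mammals, shifted in amphibians, a 9/12
#: intact/lost split in reptiles, and a forward BH3-like motif in birds.
P18_LIKE_PLAN: dict[str, list[str]] = {
    "Chondrichthyes": ["intact"] * 5,
    "Osteichthyes": ["intact"] * 26,
    "Amphibia": ["shift_minus_1"] * 7,
    "Aves": ["replace_with_forward_bh3_like"] * 24,
    "Reptilia": ["intact"] * 9 + ["ablate_E_to_A"] * 12,
    "Mammalia": ["intact"] * 67,
}

#: The p73-like family keeps the motif intact in every class.
P73_LIKE_PLAN: dict[str, list[str]] = {
    "Chondrichthyes": ["intact"] * 4,
    "Osteichthyes": ["intact"] * 34,
    "Amphibia": ["intact"] * 7,
    "Aves": ["intact"] * 97,
    "Reptilia": ["intact"] * 8,
    "Mammalia": ["intact"] * 67,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic family.

    ``scale`` multiplies branch lengths to give the per-site substitution
    probability 1 - exp(-t * scale); 0.3 with exponential(0.1) branch
    lengths yields realistically divergent but alignable families.
    """

    n_taxa: int = 24
    root_length: int = 120
    scale: float = 0.3
    motif_locus: int = 60  # 0-based start column of the 18-residue window
    clade_plan: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CLADE_PLAN.items()}
    )
    n_extra_frozen: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.motif_locus < 0 or self.motif_locus + WINDOW_LENGTH > self.root_length:
            raise ValueError("motif window must fit inside the root sequence")
        planned = sum(len(v) for v in self.clade_plan.values())
        if planned != self.n_taxa:
            raise ValueError(
                f"clade plan covers {planned} leaves but n_taxa={self.n_taxa}"
            )
        for clade, actions in self.clade_plan.items():
            for action in actions:
                if action not in WINDOW_TEMPLATES:
                    raise ValueError(f"unknown action {action!r} for clade {clade!r}")

    @property
    def anchor_column(self) -> int:
        """Alignment column on which window extraction should be anchored."""
        return self.motif_locus + 8


@dataclass
class SyntheticTruth:
    tree: Tree
    statuses: dict[str, MotifStatus]
    frozen_columns: list[int]
    clade_labels: dict[str, str]
    anchor_column: int


def simulate_tree(n_taxa: int, seed: int) -> Tree:
    """Random bifurcating topology by sequential attachment to a random
    edge, with exponential(mean 0.1) branch lengths; unrooted form with a
    trifurcating root. Deterministic given the seed."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1:03d}" for i in range(n_taxa)]
    root = TreeNode()
    for lab in labels[:3]:
        root.add_child(TreeNode(label=lab))
    # every non-root node stands for the edge above it
    edges: list[TreeNode] = list(root.children)
    for lab in labels[3:]:
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = TreeNode()
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(target)
        leaf = TreeNode(label=lab)
        mid.add_child(leaf)
        edges.extend([mid, leaf])
    tree = Tree(root)
    for node in tree.preorder():
        if node.parent is not None:
            node.branch_length = float(rng.exponential(0.1))
    return tree


def substitution_kernel(temperature: float = 2.0) -> np.ndarray:
    """Row-stochastic 20x20 replacement kernel, zero diagonal, with
    P(a -> b) ∝ exp(BLOSUM62(a, b) / temperature)."""
    matrix = get_blosum62()
    n = len(AMINO_ACIDS)
    K = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                K[i, j] = math.exp(matrix.score(a, b) / temperature)
    K /= K.sum(axis=1, keepdims=True)
    return K


def evolve_sequences(
    tree: Tree, config: SimulationConfig
) -> tuple[Alignment, SyntheticTruth]:
    """Evolve a family along ``tree`` and implant the per-clade motif fates.

    Returns the true (gap-free except deleted windows) alignment with clade
    labels attached, and the ground truth needed to score downstream
    recovery.
    """
    rng = np.random.default_rng(config.seed)
    kernel = substitution_kernel()
    aa_idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    L = config.root_length

    window_cols = list(range(config.motif_locus, config.motif_locus + WINDOW_LENGTH))
    non_window = [c for c in range(L) if c not in set(window_cols)]
    k_extra = min(config.n_extra_frozen, len(non_window))
    extra_frozen = sorted(
        int(c) for c in rng.choice(non_window, size=k_extra, replace=False)
    )
    frozen = set(window_cols) | set(extra_frozen)
    mutable = np.array([c for c in range(L) if c not in frozen], dtype=int)

    root_seq = rng.integers(0, len(AMINO_ACIDS), size=L)
    template = WINDOW_TEMPLATES["intact"]
    for k, col in enumerate(window_cols):
        root_seq[col] = aa_idx[template[k]]

    leaf_seqs: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            p = 1.0 - math.exp(-child.branch_length * config.scale)
            out = seq.copy()
            if p > 0 and len(mutable):
                hit = rng.random(len(mutable)) < p
                sites = mutable[hit]
                for site in sites:
                    out[site] = rng.choice(
                        len(AMINO_ACIDS), p=kernel[out[site]]
                    )
            if child.is_leaf:
                leaf_seqs[child.label] = out
            else:
                descend(child, out)

    descend(tree.root, root_seq)

    # clades are assigned as contiguous blocks in tree (postorder) leaf
    # order, approximating the monophyletic classes of real family data
    tree_order = [n.label for n in tree.postorder() if n.is_leaf]
    clade_labels: dict[str, str] = {}
    actions: dict[str, str] = {}
    cursor = 0
    for clade in sorted(config.clade_plan):
        for action in config.clade_plan[clade]:
            leaf = tree_order[cursor]
            clade_labels[leaf] = clade
            actions[leaf] = action
            cursor += 1
    leaf_order = sorted(leaf_seqs)

    rows = []
    statuses: dict[str, MotifStatus] = {}
    for leaf in leaf_order:
        chars = [AMINO_ACIDS[i] for i in leaf_seqs[leaf]]
        action = actions[leaf]
        implant = WINDOW_TEMPLATES[action]
        for k, col in enumerate(window_cols):
            chars[col] = implant[k]
        rows.append(ProteinSequence(leaf, "".join(chars)))
        statuses[leaf] = ACTION_STATUS[action]

    alignment = Alignment(rows, dict(clade_labels))
    truth = SyntheticTruth(
        tree=tree,
        statuses=statuses,
        frozen_columns=sorted(frozen),
        clade_labels=clade_labels,
        anchor_column=config.anchor_column,
    )
    return alignment, truth


def simulate_family(config: SimulationConfig) -> tuple[Alignment, SyntheticTruth]:
    """Tree + evolved family in one call (tree seeded from the config)."""
    tree = simulate_tree(config.n_taxa, config.seed)
    return evolve_sequences(tree, config)


def _pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    element: str,
) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def make_fixture_structure(
    n_contact_residues: int,
    n_noncontact: int,
    cutoff: float = 4.0,
    seed: int = 0,
) -> str:
    """Two-chain toy PDB text with an exactly known contact census.

    Chain B is a peptide of CA atoms spaced 3.8 Å along x. Chain A holds
    ``n_contact_residues`` residues whose nearest heavy atom sits within
    cutoff - 0.1 Å of a peptide atom, and ``n_noncontact`` residues beyond
    cutoff + 0.5 Å. Offsets are perpendicular to the peptide axis so the
    anchoring atom is always the nearest one.
    """
    rng = np.random.default_rng(seed)
    n_pep = max(4, n_contact_residues // 2 + 2)
    lines = ["MODEL        1"]
    serial = 1
    for i in range(n_pep):
        lines.append(
            _pdb_line(serial, " CA ", "GLY", "B", i + 1, 3.8 * i, 0.0, 0.0, "C")
        )
        serial += 1

    def receptor_residue(resnum: int, distance: float) -> None:
        nonlocal serial
        anchor = int(rng.integers(n_pep))
        angle = float(rng.uniform(0, 2 * math.pi))
        dy, dz = distance * math.cos(angle), distance * math.sin(angle)
        x0 = 3.8 * anchor
        lines.append(
            _pdb_line(serial, " CA ", "ALA", "A", resnum, x0, dy, dz, "C")
        )
        serial += 1
        # a second heavy atom strictly farther from the peptide
        lines.append(
            _pdb_line(
                serial, " CB ", "ALA", "A", resnum,
                x0, dy * (1 + 1.5 / distance), dz * (1 + 1.5 / distance), "C",
            )
        )
        serial += 1

    resnum = 1
    for _ in range(n_contact_residues):
        receptor_residue(resnum, float(rng.uniform(max(1.5, cutoff - 2.0), cutoff - 0.1)))
        resnum += 1
    for _ in range(n_noncontact):
        receptor_residue(resnum, float(rng.uniform(cutoff + 0.6, cutoff + 6.0)))
        resnum += 1
    lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
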