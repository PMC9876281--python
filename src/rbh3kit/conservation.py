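"""Column-wise conservation analysis of a protein alignment.

Implements the consensus-centric conservation scheme used in comparative
surveys of the MCL1 BH3-binding groove: per column, the modal residue is
the consensus, a row counts as *conserved* if its residue is the consensus
or substitutes for it with a positive BLOSUM62 score, and the conserved
fraction is binned into five classes (100% identical; 100% conserved;
75-99%; 50-74%; <50%). Sequence-logo information content follows the
standard Schneider-Stephens formulation: R = log2(20) - H, optionally
minus the small-sample correction e_n = (s - 1) / (2 ln2 n).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from rbh3kit.align_phylo import ScoringMatrix, get_blosum62
from rbh3kit.formats import GAP, Alignment

MAX_BITS = math.log2(20.0)
N_RESIDUE_TYPES = 20


class ConservationClass(Enum):
    """Five-way conservation bin for an alignment column.

    Listed in priority order; the first class whose condition holds wins.
    """

    IDENTICAL_100 = "identical_100"
    CONSERVED_100 = "conserved_100"
    BIN_75_99 = "75-99"
    BIN_50_74 = "50-74"
    BIN_LT_50 = "<50"


@dataclass(frozen=True)
class ColumnProfile:
    column: int
    counts: dict[str, int]
    gap_count: int
    n: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) + self.gap_count != self.n:
            raise ValueError("column profile counts do not sum to n")

    @property
    def n_residues(self) -> int:
        return self.n - self.gap_count


def column_profile(alignment: Alignment, col: int) -> ColumnProfile:
    column = alignment.column(col)  # raises IndexError when out of range
    counts = Counter(ch for ch in column if ch != GAP)
    return ColumnProfile(
        column=col,
        counts=dict(counts),
        gap_count=column.count(GAP),
        n=len(column),
    )


def consensus_residue(profile: ColumnProfile) -> str:
    """Modal non-gap residue; alphabetical tie-break; '-' for all-gap."""
    if not profile.counts:
        return GAP
    return min(profile.counts, key=lambda aa: (-profile.counts[aa], aa))


def conserved_fraction(
    profile: ColumnProfile, matrix: ScoringMatrix | None = None
) -> float:
    """Fraction of rows matching the consensus residue or homologously
    substituting for it (positive BLOSUM62 score). Gaps never conserve."""
    matrix = matrix or get_blosum62()
    cons = consensus_residue(profile)
    if cons == GAP:
        return 0.0
    conserved = 0
    for aa, count in profile.counts.items():
        if aa == cons or matrix.score(aa, cons) > 0:
            conserved += count
    return conserved / profile.n


def classify_column(
    profile: ColumnProfile, matrix: ScoringMatrix | None = None
) -> ConservationClass:
    if profile.n < 1:
        raise ValueError("empty column profile")
    cons = consensus_residue(profile)
    if cons != GAP and profile.counts.get(cons, 0) == profile.n:
        return ConservationClass.IDENTICAL_100
    f = conserved_fraction(profile, matrix)
    if f == 1.0:
        return ConservationClass.CONSERVED_100
    if f >= 0.75:
        return ConservationClass.BIN_75_99
    if f >= 0.5:
        return ConservationClass.BIN_50_74
    return ConservationClass.BIN_LT_50


@dataclass(frozen=True)
class LogoColumn:
    """Information content of one logo column, in bits."""

    content: float
    letter_heights: dict[str, float]
    correction_applied: bool
    n: int


def information_content(
    profile: ColumnProfile, correction: bool = False
) -> LogoColumn:
    """Bits of information at a column: ``log2(20) - H`` (- e_n if corrected).

    Frequencies are over non-gap residues; an all-gap column carries zero
    information. The small-sample correction e_n = 19 / (2 ln2 n_res)
    reproduces the reduced stack heights seen for clades with few
    sequences; content is clamped at zero.
    """
    n_res = profile.n_residues
    if n_res == 0:
        return LogoColumn(0.0, {}, correction, profile.n)
    freqs = {aa: c / n_res for aa, c in profile.counts.items()}
    entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
    content = MAX_BITS - entropy
    if correction:
        content -= (N_RESIDUE_TYPES - 1) / (2 * math.log(2) * n_res)
    content = max(content, 0.0)
    heights = {aa: f * content for aa, f in freqs.items()}
    return LogoColumn(content, heights, correction, profile.n)


@dataclass
class ConsensusProfile:
    """Consensus residue, conservation class, and numbering map per column."""

    alignment: Alignment
    consensus: str
    classes: list[ConservationClass]
    fractions: list[float]
    _maps: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def position_map(self, seq_id: str) -> list[int]:
        """Per column: 1-based residue number in ``seq_id``, or 0 at gaps."""
        if seq_id not in self._maps:
            row = self.alignment.row(seq_id).residues
            out = []
            count = 0
            for ch in row:
                if ch == GAP:
                    out.append(0)
                else:
                    count += 1
                    out.append(count)
            self._maps[seq_id] = out
        return self._maps[seq_id]


def consensus_sequence(
    alignment: Alignment, matrix: ScoringMatrix | None = None
) -> ConsensusProfile:
    """Consensus (modal residue per column) with conservation classes."""
    matrix = matrix or get_blosum62()
    residues = []
    classes = []
    fractions = []
    for col in range(alignment.n_columns):
        prof = column_profile(alignment, col)
        residues.append(consensus_residue(prof))
        classes.append(classify_column(prof, matrix))
        fractions.append(conserved_fraction(prof, matrix))
    return ConsensusProfile(alignment, "".join(residues), classes, fractions)


def map_position(profile: ConsensusProfile, seq_id: str, column: int) -> int:
    """1-based residue number of ``column`` (0-based) in sequence ``seq_id``.

    Counts non-gap characters of that row up to and including the column;
    raises ValueError if the row is gapped there.
    """
    if not 0 <= column < profile.alignment.n_columns:
        raise IndexError(f"column {column} out of range")
    number = profile.position_map(seq_id)[column]
    if number == 0:
        raise ValueError(f"sequence {seq_id!r} has a gap at column {column}")
    return number
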