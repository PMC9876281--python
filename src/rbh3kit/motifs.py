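"""Residue-class motif patterns and the rBH3 status decision rules.

The BH3 consensus is written Φ-X(3)-L-X(2)-Φ-G-D-X-Φ, where Φ is any
hydrophobic residue and X any residue. A reverse-BH3 (rBH3) is a segment
matching such a pattern when read backwards. Within the 18-residue window
used for cross-species comparison, the three residues known to drive MCL1
binding sit at window positions 8 (acidic), 10 and 13 (hydrophobic); the
status rules below encode the observed evolutionary outcomes: the intact
triple, the one-position shift, the E→A ablation that abolishes binding,
and replacement by a forward BH3-like pattern (Φ-X(2)-[LΦ]-X-E).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from rbh3kit.formats import AMINO_ACIDS, GAP, Alignment, ProteinSequence

#: Hydrophobic residue class (Φ) as used in the logo coloring convention.
HYDROPHOBIC = frozenset("AVLIPWFM")

WINDOW_LENGTH = 18
DEFAULT_KEY_POSITIONS = (8, 10, 13)
ACIDIC = frozenset("DE")


class MotifGrammarError(ValueError):
    """Raised when a motif pattern string cannot be compiled."""


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    tokens: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("motif must have at least one token")
        for tok in self.tokens:
            if not tok or not tok <= set(AMINO_ACIDS):
                raise ValueError("every token must be a non-empty residue subset")

    def __len__(self) -> int:
        return len(self.tokens)


_TOKEN_RE = re.compile(
    r"^(?P<base>[A-Z]|Φ|h|\[[A-ZΦ]+\])(?:\((?P<rep>\d+)\))?$"
)


def compile_motif(
    pattern: str, name: str | None = None, phi: frozenset[str] = HYDROPHOBIC
) -> MotifDefinition:
    """Compile a dash-separated pattern into a token-set motif.

    Grammar per token: a residue letter, ``X`` (any residue), ``Φ`` (alias
    ``h``, the hydrophobic class), or ``[ABC]`` alternatives; any token may
    carry a repeat count ``(k)`` with k >= 1.
    """
    tokens: list[frozenset[str]] = []
    for index, raw in enumerate(pattern.split("-")):
        m = _TOKEN_RE.match(raw.strip())
        if not m:
            raise MotifGrammarError(f"malformed token {raw!r} at index {index}")
        base = m.group("base")
        if base in ("Φ", "h"):
            allowed = phi
        elif base == "X":
            allowed = frozenset(AMINO_ACIDS)
        elif base.startswith("["):
            inner = base[1:-1]
            allowed = frozenset()
            for ch in inner:
                allowed |= phi if ch == "Φ" else frozenset(ch)
        else:
            allowed = frozenset(base)
        if not allowed <= set(AMINO_ACIDS):
            raise MotifGrammarError(f"token {raw!r} at index {index} is not a residue set")
        rep = int(m.group("rep")) if m.group("rep") else 1
        if rep < 1:
            raise MotifGrammarError(f"zero repetition in token {raw!r} at index {index}")
        tokens.extend([frozenset(allowed)] * rep)
    return MotifDefinition(name or pattern, tuple(tokens))


#: The canonical BH3 consensus and the BH3-like degenerate patterns.
BH3_PATTERN = "Φ-X(3)-L-X(2)-Φ-G-D-X-Φ"
#: rBH3 scanning pattern: the BH3 consensus with the salt-bridge acid
#: relaxed to [DE] — reverse-BH3 sequences carry a glutamate where the
#: canonical BH3 has its aspartate. Scanned in reverse orientation.
RBH3_PATTERN = "Φ-X(3)-L-X(2)-Φ-G-[DE]-X-Φ"
BH3_LIKE_L_PATTERN = "Φ-X(2)-L-X-E"
BH3_LIKE_PHI_PATTERN = "Φ-X(2)-Φ-X-E"

NAMED_PATTERNS: dict[str, str] = {
    "BH3": BH3_PATTERN,
    "rBH3": RBH3_PATTERN,  # scanned in reverse orientation
    "BH3_LIKE_L": BH3_LIKE_L_PATTERN,
    "BH3_LIKE_PHI": BH3_LIKE_PHI_PATTERN,
}


class Orientation(Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int
    end: int
    orientation: Orientation
    matched: str
    motif_name: str


def _matches_at(seq: str, pos: int, motif: MotifDefinition) -> bool:
    return all(seq[pos + k] in tok for k, tok in enumerate(motif.tokens))


def scan_forward(seq: ProteinSequence, motif: MotifDefinition) -> list[MotifHit]:
    """All (possibly overlapping) forward matches, sorted by start.

    Gaps are stripped before scanning; coordinates refer to the degapped
    sequence.
    """
    text = seq.residues.replace(GAP, "")
    L = len(motif)
    hits = []
    for i in range(len(text) - L + 1):
        if _matches_at(text, i, motif):
            hits.append(
                MotifHit(seq.id, i, i + L, Orientation.FORWARD, text[i:i + L], motif.name)
            )
    return hits


def scan_reverse(seq: ProteinSequence, motif: MotifDefinition) -> list[MotifHit]:
    """Matches of the motif against the reversed sequence, reported in the
    original orientation: a hit at [i, i+L) means seq[i:i+L] reversed
    satisfies the token sequence."""
    text = seq.residues.replace(GAP, "")
    L = len(motif)
    rev = text[::-1]
    hits = []
    for i in range(len(text) - L + 1):
        # window [i, i+L) of text is window [n-i-L, n-i) of rev
        j = len(text) - i - L
        if _matches_at(rev, j, motif):
            hits.append(
                MotifHit(seq.id, i, i + L, Orientation.REVERSE, text[i:i + L], motif.name)
            )
    return hits


class MotifStatus(Enum):
    INTACT = "intact"
    SHIFTED = "shifted"
    LOST = "lost"
    BH3_LIKE = "bh3_like"
    ABSENT = "absent"


@dataclass(frozen=True)
class MotifWindow:
    """An 18-column window centered on the rBH3 anchor for one sequence."""

    sequence_id: str
    residues: str  # length 18, '-' padded at alignment boundaries
    anchor_column: int
    key_positions: tuple[int, int, int] = DEFAULT_KEY_POSITIONS

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW_LENGTH:
            raise ValueError(
                f"window must have {WINDOW_LENGTH} columns, got {len(self.residues)}"
            )
        for p in self.key_positions:
            if not 1 <= p <= WINDOW_LENGTH:
                raise ValueError(f"key position {p} outside 1..{WINDOW_LENGTH}")


def extract_window(
    alignment: Alignment,
    anchor_column: int,
    seq_id: str,
    key_positions: tuple[int, int, int] = DEFAULT_KEY_POSITIONS,
) -> MotifWindow:
    """Columns anchor-8 .. anchor+9 for one row, '-'-padded at the edges."""
    if not 0 <= anchor_column < alignment.n_columns:
        raise IndexError(f"anchor column {anchor_column} out of range")
    row = alignment.row(seq_id).residues  # raises KeyError for unknown id
    start = anchor_column - 8
    chars = []
    for col in range(start, start + WINDOW_LENGTH):
        chars.append(row[col] if 0 <= col < len(row) else GAP)
    return MotifWindow(seq_id, "".join(chars), anchor_column, key_positions)


def _triple_present(
    window: str, key_positions: Sequence[int], offset: int, phi: frozenset[str]
) -> bool:
    acid, hyd1, hyd2 = key_positions
    try:
        return (
            window[acid - 1 + offset] in ACIDIC
            and window[hyd1 - 1 + offset] in phi
            and window[hyd2 - 1 + offset] in phi
        )
    except IndexError:
        return False


_BH3_LIKE = compile_motif(BH3_LIKE_PHI_PATTERN, "BH3_LIKE_PHI")


def assess_rbh3_status(
    window: MotifWindow,
    key_positions: tuple[int, int, int] | None = None,
    phi: frozenset[str] = HYDROPHOBIC,
) -> MotifStatus:
    """Status call for one window; precedence intact > shifted > lost >
    bh3_like > absent.

    * intact — acidic (E or D) at the acid position, hydrophobic at both
      hydrophobic positions (canonically 8/10/13);
    * shifted — the same triple displaced one position left (7/9/12);
    * lost — alanine at the acid position (the E→A ablation known to
      abolish MCL1 binding);
    * bh3_like — a forward Φ-X(2)-Φ-X-E match anywhere in the window;
    * absent — none of the above.
    """
    keys = key_positions or window.key_positions
    w = window.residues
    if _triple_present(w, keys, 0, phi):
        return MotifStatus.INTACT
    if _triple_present(w, keys, -1, phi):
        return MotifStatus.SHIFTED
    if w[keys[0] - 1] == "A":
        return MotifStatus.LOST
    degapped = w.replace(GAP, "")
    if len(degapped) >= len(_BH3_LIKE):
        probe = ProteinSequence(window.sequence_id, degapped)
        if scan_forward(probe, _BH3_LIKE):
            return MotifStatus.BH3_LIKE
    return MotifStatus.ABSENT


def window_annotations(
    window: MotifWindow, phi: frozenset[str] = HYDROPHOBIC
) -> list[str]:
    """Flags worth reporting alongside a status call.

    ``E->D`` marks the homologous aspartate at the acid position (seen in
    osteichthyan p73 and in p19); ``H16`` marks the histidine replacing the
    hydrophobic residue at window position 16 in mammalian p19.
    """
    notes = []
    acid = window.key_positions[0]
    if window.residues[acid - 1] == "D":
        notes.append("E->D")
    if window.residues[15] == "H":
        notes.append("H16")
    return notes


def survey_windows(
    alignment: Alignment,
    anchor_column: int,
    key_positions: tuple[int, int, int] = DEFAULT_KEY_POSITIONS,
    phi: frozenset[str] = HYDROPHOBIC,
) -> pd.DataFrame:
    """Per-sequence window, status, and annotations as a DataFrame."""
    records = []
    for row in alignment.rows:
        win = extract_window(alignment, anchor_column, row.id, key_positions)
        status = assess_rbh3_status(win, phi=phi)
        records.append(
            {
                "id": row.id,
                "clade": alignment.clade_labels.get(row.id, ""),
                "window": win.residues,
                "status": status.value,
                "annotations": ";".join(window_annotations(win, phi)),
            }
        )
    return pd.DataFrame.from_records(records)


def clade_motif_summary(
    alignment: Alignment,
    clade_labels: Mapping[str, str] | None = None,
    anchor_column: int = 0,
    key_positions: tuple[int, int, int] = DEFAULT_KEY_POSITIONS,
    phi: frozenset[str] = HYDROPHOBIC,
    clades: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Clade × status count table for the windows at ``anchor_column``.

    Every row must carry a clade label; ``clades`` may add empty clades
    (reported as all-zero rows). Counts partition each clade.
    """
    labels = dict(clade_labels) if clade_labels is not None else dict(alignment.clade_labels)
    unlabeled = [r.id for r in alignment.rows if r.id not in labels]
    if unlabeled:
        raise ValueError(f"rows without clade labels: {unlabeled}")
    work = Alignment(alignment.rows, dict(labels))
    table = survey_windows(work, anchor_column, key_positions, phi)
    statuses = [s.value for s in MotifStatus]
    counts = (
        table.groupby(["clade", "status"]).size().unstack(fill_value=0)
    )
    all_clades = sorted(set(labels.values()) | set(clades or []))
    counts = counts.reindex(index=all_clades, columns=statuses, fill_value=0)
    counts.index.name = "clade"
    return counts.astype(int)
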