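# Methods

This note records the models, numerical conventions, and design choices
behind rbh3kit, and what the synthetic-data checks do and do not
establish about behavior on real family data.

## Alignment and distances

Pairwise alignment is global (end-to-end) with affine gap cost: a gap of
length *k* costs `gap_open + k·gap_extend`, defaults 10 and 1, under
BLOSUM62 (loaded from Biopython's published matrix). The dynamic program
is the three-state Gotoh recurrence; state transitions between the two
gap states are permitted (with a fresh gap-open charge), so the optimum
equals a maximum over *all* gapped alignments without gap–gap columns —
the property the exhaustive-enumeration oracle in the tests checks.
Traceback preference is fixed (substitution, then gap in the second
sequence, then gap in the first), making the reported alignment, not
just its score, deterministic.

The unknown-residue code `X` scores 0 against everything: ambiguity
evidence neither supports nor penalizes homology. Gap characters `.`
are normalized to `-` on input.

Multiple alignment is progressive: an NJ guide tree built from
p-distances of pairwise global alignments, then post-order
profile–profile merges. The substitution term between two profile
columns is the mean pairwise BLOSUM62 score over non-gap residue pairs;
gap-versus-residue contributes only through the affine gap states. This
is a desk-scale, fully specified stand-in for production aligners
(Clustal Omega, MAFFT): it is deterministic and exact on the small
families used here, but it has no iterative refinement and its gap
placement will differ from those tools on hard cases. Nothing downstream
depends on matching any particular aligner's output.

Distances are uncorrected p-distances — the fraction of mismatches over
columns where neither row is gapped; a pair with no comparable columns
degenerates to 1.0. No Poisson/Kimura correction is applied by default:
at the divergences the surveys target (≲ 40%) the correction changes NJ
topologies rarely, and an uncorrected distance is the simplest contract
to test.

## Trees

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q
criterion. Ties in Q break toward the lowest (i, j) pair in input order;
negative branch-length estimates are clamped to zero (standard practice,
and required downstream by midpoint rooting). The result is unrooted,
held as a trifurcating root; with exactly three taxa the closed-form
star resolution is used.

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path; ties on the diameter pair break lexicographically by leaf label,
and an all-zero-length tree roots deterministically above the smallest
label. Newick output carries branch lengths at six significant digits —
enough for exact round-trips of the quantities used here without false
precision.

## Conservation and logos

The consensus residue of a column is the modal non-gap residue, ties
broken alphabetically, `-` for all-gap columns. A row counts as
*conserved* at a column if its residue equals the consensus or scores
> 0 against it in BLOSUM62; gaps never conserve. The conserved fraction
is binned into five classes with closed lower bounds — 100% identical,
100% conserved, 75–99%, 50–74%, <50% — with identity taking priority
over the conserved-100% class. Conservation is measured against the
consensus, not all-pairs and not a designated reference row; the
reference-based variant can be obtained by passing a single-row
"alignment" of interest, but the consensus convention is the one used
throughout.

Logo information content is `R = log2(20) − H` bits, with `H` the
Shannon entropy of the residue frequencies after excluding gaps, clamped
at zero. The ceiling is log2(20) ≈ 4.32 bits. The small-sample
correction `e_n = (s − 1)/(2 ln2 · n)` with `s = 20` and `n` the non-gap
count is applied by default in the per-clade logo tables of the family
workflow (so a fully conserved column in a 4-sequence clade reports
≈ 0.90 bits, reproducing the reduced stacks seen for small clades) and
is off by default in the `conserve` subcommand, where the raw
conservation signal is usually wanted. Letter heights are frequency ×
content, so they sum to the column content.

Consensus-to-sequence numbering uses the position map: the 1-based count
of non-gap characters of a row up to a column. Asking for a residue
number at a gapped position is an error rather than a nearest-residue
guess.

## Motifs and the rBH3 status rules

Motif patterns are dash-separated tokens: a fixed residue, `X` (any),
`Φ`/`h` (hydrophobic: A, V, L, I, P, W, F, M — the logo coloring
convention; proline's membership is debatable in helical context, so the
class is a parameter), bracketed alternatives, and `(k)` repeats.
Scanning is over degapped sequences; a reverse hit at [i, i+L) means the
reversal of that substring satisfies the tokens, with coordinates
reported in the original orientation. The shipped patterns are the BH3
consensus `Φ-X(3)-L-X(2)-Φ-G-D-X-Φ`, the rBH3 variant with the acid
relaxed to `[DE]` (reverse-BH3 sequences carry a glutamate at the
position where canonical BH3 has its aspartate), and the degenerate
forward patterns `Φ-X(2)-L-X-E` and `Φ-X(2)-Φ-X-E`.

Survey windows are 18 alignment columns (anchor−8 … anchor+9), padded
with gaps at alignment edges. Status calls use the key-position triple —
acidic at window position 8 (E or D; the aspartate variant is reported
with an `E->D` annotation, not a status change), hydrophobic at 10 and
13 — with fixed precedence:

1. **intact** — triple holds at 8/10/13;
2. **shifted** — triple holds at 7/9/12 (only the one-column shift is
   recognized; larger offsets report *absent* since nothing larger is
   attested);
3. **lost** — alanine at position 8, the substitution known to abolish
   MCL1 binding, regardless of what else the window contains;
4. **bh3_like** — a forward `Φ-X(2)-Φ-X-E` match anywhere in the
   degapped window;
5. **absent** — none of the above.

A histidine at window position 16 is likewise an annotation (`H16`), not
a status change — its effect on binding is unresolved, so it must not
move counts between categories.

Auto-anchoring takes the lowest-start reverse rBH3 hit in a named
reference sequence and anchors one column right of the motif's acidic
residue, which lands the acid at window position 8 and reproduces the
8/10/13 geometry. On real alignments whose reference lacks a clean
reverse hit the anchor must be supplied explicitly.

## Structure stage

A receptor residue is a contact if any of its heavy atoms lies within
the cutoff (default 4.0 Å, boundary inclusive) of any heavy atom of the
peptide chain. Only `ATOM` records of the first model are read;
hydrogens/deuteriums and alternate locations other than blank/`A` are
dropped — the reproducible convention for crystal structures solved
without hydrogens. Distances are computed with a dense all-pairs
evaluation (the structures involved are small enough that spatial
indexing would buy nothing), which the tests verify against an
independent brute-force oracle and under random rigid motions. Receptor
and peptide chain identifiers are always user-supplied; nothing is
guessed from header records. Mapping contact residues onto alignment
columns uses the position map of a named row, with an optional constant
offset for structures whose numbering differs from the mature sequence;
contacts outside the aligned region are reported `unmapped` rather than
dropped.

## Synthetic data: what it emulates and what it does not

The generator produces the data shape of a cross-species motif survey.
Topologies come from sequential random attachment (each new leaf splits
a uniformly chosen edge) with branch lengths drawn Exp(mean 0.1).
Sequences evolve site-independently: along a branch of length *t* each
unfrozen site substitutes with probability `1 − exp(−t·scale)` (default
scale 0.3), replacements drawn from the 19 alternatives with probability
∝ `exp(BLOSUM62/2)`, biasing toward homologous exchanges. The 18-column
motif window plus eight additional columns are frozen; after evolution,
the window of each leaf is overwritten with the template for its clade's
planned fate (intact / E→A ablation / one-column shift / forward
BH3-like replacement / deletion). The intact template embeds a genuine
reverse-BH3 instance, so auto-anchoring works on synthetic references
exactly as on real ones. Clades are contiguous blocks in tree postorder,
approximating the near-monophyletic vertebrate classes of real family
data. The packaged default plan (24 taxa) mirrors the observed family
patterns — mammals intact, reptiles split intact/lost, amphibians
shifted, birds forward-BH3-like — and two family-scale plans reproduce
the published per-class sequence counts: a 150-sequence p18-like family
(with the 9/12 reptilian split) and a 217-sequence p73-like family
(motif intact in every class).

Deliberately missing: indels (the true alignment is the simulated
matrix; columns never shift), rate heterogeneity across sites or
lineages, and any calibrated empirical substitution model (WAG/LG).
Passing the recovery checks therefore shows the *survey logic* is
correct — statuses, clade summaries, frozen-column classes, and census
counts are read back exactly as implanted — not that the aligner or tree
builder would match a production tool on real, indel-rich families.

One recovery property deserves its number: over 20 replicates of the
default configuration, NJ on the simulated alignments recovers ~63% of
true bipartitions (~76% under an all-intact plan). This is a property of
the simulation regime, not of the tree builder: with Exp(0.1) branches,
120 sites, and scale 0.3, about 26% of internal branches are expected to
carry zero substitutions and are unrecoverable in principle; restricted
to branches almost certain to carry at least one substitution, recovery
is > 99%, and NJ is exact on additive matrices. The conditions are kept
as designed rather than inflated to flatter the statistic.

## Determinism

Every stage is deterministic given its inputs: fixed tie-breaks in NJ,
consensus, and traceback; integer-seeded NumPy generators with no
dependence on hash ordering; workflow outputs hashed (SHA-256) into a
run-metadata JSON so byte-identical re-runs can be verified. The
acceptance script derives all of its randomness from its `--seed`
argument.

## Problem sizes

The test suite and acceptance script run at sizes chosen to exercise
every code path while staying desk-scale: oracle comparisons at 200
alignment pairs (length ≤ 8), 200 random 4–8-leaf trees, 1000 scanned
sequences, 50 toy complexes; surveys at 24, 150, and 217 taxa with
120-column sequences. The library itself has no hard-coded limits; the
NJ selection step is vectorized and handles the few-hundred-taxon
families of published surveys directly.
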