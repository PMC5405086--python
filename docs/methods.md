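# Methods

## The block model

The unit of analysis is a *block*: a gap-free multiple alignment of
orthologous protein sequences in which every column is a fixed
homologous position. The input contract is strict — at least two
sequences, equal lengths, upper-case normalisation, the 20 standard
one-letter codes only — and every violation raises a distinct named
error rather than being silently repaired. Alignment construction and
block trimming are upstream of this package; it consumes a ready
block. Ambiguity codes (X, B, Z, U, O, J) are rejected by default
because there is no principled way to assign them to a physicochemical
class; the `--drop-bad-columns` option instead removes (and logs)
every column containing one, preserving the remaining columns'
statistics exactly.

## Pair counting

Each column of a depth-*n* block contributes one residue pair per
unordered sequence pair — the counting convention of the BLOSUM
construction — so a width-*w* block yields exactly `w·C(n,2)`
observations split over 20 homo-pair and 190 hetero-pair types. Counts
are kept as exact integers in a symmetric 20×20 matrix; every derived
percentage is computed from those integers at reporting time, so no
intermediate rounding can drift. No sequence weighting or
%-identity clustering is applied: the statistics deliberately describe
the block as given. The implementation computes per-column residue
multiplicities and uses `C(c_a,2)` / `c_a·c_b` closed forms; the test
suite holds it against an independent quadratic enumeration oracle on
random blocks.

## The residue class scheme

All conservative/non-conservative labelling runs through a pluggable
`ClassScheme`. The default partitions the alphabet into 9 hydrophobic
residues {A,V,L,I,P,F,M,W,C} and 11 hydrophilic {G,S,T,Y,N,Q,D,E,K,R,H},
with sub-classes acidic {D,E}, basic {K,R,H} (histidine counted basic),
polar-uncharged {G,S,T,Y,N,Q}, Ser/Thr {S,T}, and non-polar = HB ∪ {G}
(a class-diversity grouping distinct from hydrophobic). The 9/11 sizes
are forced by the pair-type combinatorics (36/55/99); the *membership*
follows common hydropathy groupings and is a design choice — published
family tables fix the sizes but not the memberships, which is why the
scheme is constructor-injectable and overridable from a config file,
validated against the partition invariants (sides partition the
alphabet at sizes 9/11; sub-classes partition the hydrophilic side).

"Conservative" is defined as within-side (HB-HB or HL-HL) and
"non-conservative" as cross-side (HB-HL). This definition is the one
under which the R↔CD identity below reproduces published family tables,
which is the strongest available evidence for it.

## Derived parameters

All parameters are occurrence-weighted (frequency shares), not
type-count shares, with the single exception of E:

- `E = 100 · (observed hetero types) / 190`; type usage, monotone
  under adding new types, 0 for an invariant block, 100 at full usage.
- `R = 100 · f(HB-HL) / (f(HB-HB) + f(HL-HL))`. Degenerate cases: a
  block with hetero-pairs but zero conservative frequency raises
  (R is undefined); a fully invariant block reports R = 0 with a
  `no_hetero` flag.
- `D`: argmax over the 190 folded cells; share of the hetero total.
- `RD(x) = 100 · (hetero occurrences involving x) / total`; ΣRD = 200
  since each occurrence has two members. MDR = argmax, RDmin = argmin.
- `CD(c) = 100 · (hetero occurrences with ≥1 member in c) / total` for
  c ∈ {acidic, basic, non-polar, hydrophobic, hydrophilic}.

Ties in D, MDR and RDmin break alphabetically (by two-letter pair
label, respectively by residue) — deterministic and documented.

Because a cross-side occurrence is counted by both CD_HB and CD_HL,
`CD_HB + CD_HL − 100` equals the cross-side share and
`200 − CD_HB − CD_HL` the within-side share, giving

    R = 100 · (CD_HB + CD_HL − 100) / (200 − CD_HB − CD_HL).

The occurrence-weighted definitions were chosen precisely because this
identity then holds exactly on any block (it is asserted on random
blocks in the suite). Applied to the published table of eight protein
families (`blocksub.reference`), the identity recovers the printed R
within ±1 for seven of the eight rows (e.g. LDH: CD 69.4/66.1 → 55.0;
ribonucleases: 58.2/81.8 → 66.7). The kappa-casein row (printed R = 92,
identity gives ≈41.4) cannot be reconciled and is treated as a
suspected inconsistency in the published table; it is excluded from
the identity audit and flagged here rather than papered over. The
ubiquitin row rounds to 41 against a printed 42 but is within the ±1
band.

One published "ratio parameter" column (N) has no recoverable
definition; `blocksub` does not guess. `summarize()` accepts a
`plugins` mapping of extra column names to callables so a user with a
definition can add it; no default is shipped.

## Positional analysis

Per-column Shannon entropy is computed in bits, `H = −Σ pᵢ log₂ pᵢ`
(scipy's entropy with base 2). The log base is a choice; bits make the
conserved-position threshold of 1.0 read naturally as "effectively at
most two equiprobable residues". The threshold is a parameter
(`entropy_threshold`, default 1.0 bit).

Column categories use an ordered decision list — INV (single residue
type), HB (all hydrophobic), Ac (⊆ {D,E}), Bs (⊆ {K,R,H}), PC
(polar-charged with both acidic and basic present), ST (⊆ {S,T}),
HB+HL (both sides present), PU+PC (any remaining hydrophilic-only
mix) — with first-match precedence, which makes the categories
exclusive so their percentages partition to 100 up to rounding.
Folding every leftover hydrophilic-only mix into PU+PC is a design
choice: published positional tables print no separate label for such
columns, and their row sums are consistent with this folding. A
glycine-only column is INV; glycine in a mixed hydrophilic column
lands in PU+PC under the default scheme. %CONV (conserved columns)
overlaps the categories and is reported separately.

## Synthetic blocks

The generator simulates a star phylogeny: one ancestral sequence with
residues uniform over the 20 amino acids, from which each of `depth`
sequences derives independently. Every non-locked position of every
sequence mutates with probability `p_sub`; a mutation crosses the
HB/HL boundary with probability `p_cross` (uniform over the opposite
side) and otherwise draws a uniform *different* residue of the same
side. `invariant_fraction` locks a random subset of columns. All
randomness comes from one `numpy` generator seeded from the spec, so
identical specs give identical blocks.

Defaults (`p_sub = 0.2`, `p_cross = 0.25`) represent a moderately
diverged family: roughly the mid-range of the block statistics the
tool reports, with a clearly non-zero but not saturating hetero-pair
usage. Parameter-recovery checks run at width 200, depth 20 over 50
seeds — large enough that mean R orders strictly with `p_cross` while
keeping the whole suite fast on one CPU; that recovery (plus
`p_cross = 0 ⇒ R = 0` exactly) is the desk-scale analogue of the
R-vs-divergence-rate correlation observed on real families.

What the generator does *not* emulate: tree-structured relatedness
(substitutions are independent per lineage), realistic amino-acid
composition, rate heterogeneity across sites beyond the binary
locked/free distinction, and back-substitution dynamics. Passing
recovery tests therefore demonstrate the statistics' correctness and
sensitivity, not that real families satisfy the star-phylogeny
assumptions.

## Report and comparison

The itemized report writes Items A–F as TSV with fixed ordering and
1-decimal formatting (matching published table conventions), so
identical inputs give byte-identical output and every percentage is
re-derivable from the Item B integer counts. The cross-block
comparison computes a plain Pearson product–moment correlation of R
against user-supplied literature divergence rates (scipy); it requires
at least three blocks and non-degenerate variance, and no significance
testing is attempted. On the published eight-family table the
correlation is ≥ 0.93 (the suite recomputes it).

## Known limitations

- Class-based conservativeness only; no substitution-matrix (BLOSUM
  score) notion of similarity.
- No sequence weighting: heavily sampled clades dominate counts by
  design.
- The hetero-pair probability table uses 10 equal-width bins on
  [0, max probability] (half-open, last closed); the binning of the
  original figures is unstated, so bin contents — not edges — are the
  stable quantity. No distribution fitting is performed.
- Published per-family values are used only as printed-constant
  oracles; the original alignments are not redistributed, so the
  family tables themselves are not recomputed from sequence data.
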