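# Methods

This note records the models, conventions and numerical choices behind
`pfvmkit`, in the order the method runs.

## 1. The folding-shape descriptor space

A 5-residue Cα fragment is summarized by three internal coordinates:

| descriptor | definition | units |
|---|---|---|
| δ₁ | signed virtual dihedral over Cα1–Cα2–Cα3–Cα4 | degrees, (−180, 180] |
| δ₂ | signed virtual dihedral over Cα2–Cα3–Cα4–Cα5 | degrees, (−180, 180] |
| κ  | Cα1–Cα5 distance (compactness / bend) | Å |

The dihedral sign convention makes a right-handed α-helix positive
(≈ +50°).  Because consecutive windows share four atoms, δ₂ of window *i*
**equals** δ₁ of window *i* + 1 exactly; this overlap identity is what
makes the encoding a connected description of the chain rather than a set
of independent fragments, and it is asserted to 10⁻⁶ degrees in tests.

Each descriptor is trichotomized into the states `alpha` / `beta` /
`other` with half-open bins:

* dihedrals — `alpha`: [20°, 80°); `beta`: |δ| ≥ 150° (one circular bin
  wrapping the ±180° branch cut, since extended-chain torsions straddle
  it); `other`: the rest;
* κ — `alpha` (compact): [0, 8 Å); `beta` (extended): ≥ 11 Å; `other`:
  [8, 11 Å).

The bin anchors are the ideal secondary-structure values, computed in
closed form from the generator geometries before any classification code
existed: an ideal α-helix Cα trace (rise 1.5 Å, radius 2.3 Å,
100°/residue, right-handed) has δ₁ = δ₂ = +50.04° and κ = 6.20 Å; an
ideal extended strand (planar zigzag, 3.8 Å virtual bonds, 120° virtual
bond angle) has δ = 180° and κ = 13.16 Å.  Bin edges sit near the
midpoints between those anchors; the exact widths are free calibration
parameters exposed in `pfvmkit.config.Calibration` and overridable from a
`key = value` file.  All geometric comparisons use a 10⁻⁶ tolerance
(degrees/Å).

The 3×3×3 = 27 cells of the descriptor cube are the folding shapes.  The
cell → letter table is frozen in `pfvmkit.geometry.CELL_TO_SYMBOL`:

* `A` = (α, α, α), the typical helix; `B` = (β, β, β), the typical strand;
* partial helix Y, P, D, H = {(α,α,o), (α,α,β), (α,o,α), (o,α,α)} —
  either both dihedrals helical with non-helical compactness, or one
  helical dihedral with helical compactness;
* partial strand E, G, S, M = the mirrored cells around β;
* mixed V = (α, β, o) and J = (β, α, o) — one helical and one strand
  dihedral (these letters carry both partial-helix and partial-strand
  character);
* the remaining 15 cells are irregular and take the letters
  X, U, R, I, F, L, O, C, Z, W, T, K, $, N, Q in lexicographic cell
  order.

Only the class-level semantics of this table (which letters are
helix-like, strand-like, mixed, irregular) are externally meaningful; the
letter-to-cell choice inside a class is a package convention, so
letter-for-letter agreement with other implementations of 27-letter
folding alphabets is not claimed.  Cube adjacency orders the states
`alpha < other < beta` on every axis — geometrically, `other` separates
the helix and strand ranges of each descriptor — and neighbors differ by
one step on one axis; corner cells (such as A and B) have exactly three
neighbors.

Representative geometry: every code owns a canonical 5-Cα fragment built
by internal-coordinate chaining with 3.8 Å virtual bonds, torsions at the
code's bin centers (α → 50°, β → 180°, other → −60°) and one uniform
virtual bond angle solved by bracketed root finding (Brent) so that κ
hits the cell-center value (6.2 / 9.5 / 13.0 Å), preferring the root
nearest the protein-like 110° regime.  Re-classifying the representative
returns its own code for all 27 letters (tested exhaustively).

## 2. Encoding structures and building the lookup library

`encode_structure` slides the 5-residue window along a Cα trace and emits
one letter per window — length L − 4, no gaps.  Windows containing a
chain break (consecutive Cα–Cα distance outside [2.8, 4.3] Å; the ideal
virtual bond is 3.8 Å) or a residue outside the 20-letter alphabet yield
the marker `?` so string positions stay aligned to windows; such windows
are also skipped during library building.

`build_from_structures` tallies (5-mer, code) observations over a
collection of traces.  Entries are ranked by descending count with
lexicographic tie-break (`$` sorts last) — a deterministic frequency
ranking.  Energy-based ranking of simulated fragments is out of scope:
5-mers never observed simply answer an empty query.  An optional
`query(..., fallback=True)` pools the codes of stored keys sharing a
4-mer with the query; it is an explicitly labelled extension, off by
default, and never fabricates counts silently.

## 3. The folding variation matrix and disorder profile

`assemble_pfvm` produces one column per window, aligned to the window's
center residue (1-based position *window* + 2); column contents are the
library's ranked answer, verbatim.  Reports use 1-based inclusive residue
intervals throughout ([672, 713] has length 42).

Disorder profiling: D(i) = number of codes in column *i* (0–27); S(i) =
arithmetic mean of D over the 5-column window centered at *i*, truncated
at the matrix edges (no padding — the simplest defensible edge rule).
Region labels segment the S curve by tertiles into high / medium / low
disorder; this is a reporting convention, not a calibrated threshold —
the method's point is precisely that the full matrix carries more
information than any binary order/disorder call.  The terminal two
residues at each end have no centered window; region reports extend the
nearest column's values to the termini.  The curve is reported in code
counts (no normalization by 27).

Secondary-structure tendency pools the classes of the top-ranked codes
(default 2 rows): helix + partial helix vs strand + partial strand vs
irregular, with mixed-class codes contributing half a vote to each of
the helix and strand pools; exact ties are `ambiguous`, empty columns
`unknown`.  In text renderings, helix codes are red, partial helix pink,
strand blue, partial strand light blue, irregular unstyled, and mixed
codes carry a dual pink/underline tag; the plain-text rendering contains
identical symbols with the styling stripped.  Empty columns render as
`·`.

`diff_pfvm` compares column code *sets* between equal-length sequences;
a single substitution can touch at most the five windows covering it.

## 4. Rebuilding Cα traces from shape strings

A shape string prescribes, window by window, the descriptor cell of five
consecutive Cα atoms.  The builder is greedy and never revises earlier
geometry: the first window is the first code's representative fragment;
each further residue is appended by internal-coordinate placement with a
3.8 Å virtual bond, choosing the new virtual torsion from a grid inside
the code's δ₂ bin and the free virtual bond angle from 45–178° so that
the completed window's κ lands inside the code's κ bin, as close to the
cell center as possible.  Because windows share four atoms, δ₁ of each
new window is pinned by the previous placement and — for any string that
was produced by encoding a real trace — automatically lies in the correct
bin.  Only κ can be geometrically over-constrained by the frozen prefix,
so a one-step lookahead prefers candidates that keep the next window's κ
bin reachable (the new point becomes Cα2 of the next window, so its
distance to the current Cα3 brackets the next achievable κ).  When no
candidate reaches the κ bin, the nearest miss is taken.

An earlier design glued each code's representative fragment onto the
chain by least-squares superposition of its first four atoms; it
reproduced uniform strings but only ~64% of positions for coil-derived
strings, because bin-center snapping at the joints drifts κ across bin
edges.  The descriptor-targeted placement above was adopted instead and
reaches ~93% aggregate agreement on coil-derived strings; the test suite
asserts ≥ 90%.  Exact round trips hold for uniform strings of
self-consistent codes (equal dihedral states — e.g. all-A, all-B), for
which chained placement reproduces congruent windows; arbitrary mixed
strings are generally not exactly realizable because adjacent windows
constrain each other — the alphabet quantizes a continuous space, and the
builder projects onto one realizable geometry.

All candidate grids are fixed, so the builder is deterministic.  Built
traces have virtual bonds of exactly the calibrated 3.8 Å.

Ensembles: `enumerate_strings` yields the top string, all single-column
substitutions (capped at 10,000 by default — the full column product is
astronomically large), or `k` column-independent samples with probability
proportional to counts under one NumPy seed; empty columns restrict
strings to the longest contiguous covered span.  `ensemble_spread`
reports pairwise RMSD after least-squares rigid superposition
(Kabsch, via `scipy.spatial.transform.Rotation.align_vectors`).

## 5. Synthetic data

The fixture generators define the test conditions:

* ideal helix / strand — the calibration standards above; they encode to
  uniform `A`/`B` strings by construction of the bins, not by tuning;
* random coils — 3.8 Å virtual bonds, bond angles uniform on [80°, 140°],
  torsions uniform on (−180°, 180°], seeded; they exercise the irregular
  sector of the alphabet;
* `worked_example_table` — eight curated 5-mer → ranked-code mappings
  (e.g. MEDSQ → A,D; EKKKG → 14 codes).  Ranks are encoded as strictly
  decreasing synthetic counts because the curated source gives order,
  not frequencies.  The curated list for GEGNG contains one letter
  twice; the duplicate is collapsed (11 distinct codes) and logged.
* `random_library` — seeded random tables (distinct keys, 1–`max_codes`
  codes each, counts uniform on 1–100) for property tests.

What synthetic data do **not** emulate: real PDB composition statistics,
sequence-dependent fragment preferences, side-chain sterics, or the
MD-derived entries a full 5-mer library would need for 5-mers absent from
structural databases.  Tests passing on these fixtures validate the
machinery (alphabet completeness, overlap identities, tally bookkeeping,
round trips), not biological prediction accuracy; a production library
must be built from a curated structure collection with
`build_from_structures` / `pfvm build-lib`.

## 6. Problem sizes and determinism

Default verification sizes: 1,000 random library × sequence pairs for
the column-bound audit (libraries of 8 keys, up to 27 codes; sequences of
20–200 residues composed from library keys so columns are populated);
200 planted traces for library recovery; uniform-string round trips to
30 windows; 20 seeded coils of 30 residues for the quantization round
trip.  Every stochastic step takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds give bit-identical fixtures,
samples and CLI outputs.

## Known limitations

* The bin boundaries are a calibration, not a derivation; alternative
  partitions of the descriptor space would relabel borderline fragments.
* Letter-level output is comparable only within this calibration/table
  version (tagged `pfsc27-v1` in tables and configs).
* The builder produces Cα-only geometry with no clash relief or energy
  model; conformers are shape-faithful sketches, not refined models.
* Disorder-degree profiles are only as informative as the lookup
  library's coverage: unknown 5-mers give empty columns, which read as
  "no information", not "ordered".
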