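# Methods

## Library model

The unit of analysis is the *unique mature miRNA sequence*: a string over
{A,C,G,U}, 1 nt or longer, obtained from FASTA input by uppercasing and
mapping T→U.  Records whose sequence contains anything else abort the run
with the offending id — silent drops would corrupt every downstream
census.  Deduplication collapses identical sequences annotated under
different names, keeping the first-seen id and recording all names in an
alias map; it is idempotent, and the alias merge is designed so that
re-deduplicating an already-deduplicated library preserves aliases.
Species filtering is by id prefix on the first header token (human
miRBase ids begin `hsa-`), the only definition of "human subset" the
`mature.fa` dialect supports.

## Composition and richness

Pooled base content counts every nucleotide of every sequence.
Positional occupancy matrices are 1-based and anchored at either the 5′
or the 3′ end; position *p* of the 3′-anchored matrix is the *p*-th base
counting backwards, and sequences shorter than *p* simply do not cover
it, so per-position coverage is non-increasing.  Two identities tie these
together and are enforced by tests: both matrices pool to the same base
totals as the library-wide content, and reversing every sequence swaps
the two anchors exactly.

Purine/pyrimidine richness is called per whole sequence: purine-rich iff
the A+G fraction strictly exceeds the threshold (default 0.70 — "over
70%" is a strict inequality), pyrimidine-rich symmetrically, otherwise
neither.  A `highly_rich` flag marks the dominant fraction reaching 0.90;
this bound is inclusive (≥) because the highly-rich report band is
defined by printed integer percentages of 90 and above.  Printed
percentages use half-away-from-zero integer rounding; this convention
reproduces all eleven reference-set rows (e.g. 18/19 → 95, 19/21 → 90),
which banker's rounding does not.  The reference fixture preserves one
printed inconsistency — hsa-miR-4271's sequence is a 19-mer although its
length column says 22 — and flags it in metadata rather than correcting
either value; the percentage verifies on the printed 19-mer regardless.

## SSR detection

A valid SSR tract is ≥ `min_repeats` (default 3, for all unit sizes)
complete copies of a *primitive* unit of 1–5 nt.  Primitivity (the unit
is not itself a repetition of a shorter string) prevents phantom tracts:
(AA)₃ is never reported inside (A)₆.  Tracts are maximal in complete
units — no full unit immediately before or after — and a trailing partial
unit does not extend them (repeat counts are integers: `GUGUGUG` is
(GU)₃).  Each unit length is censused independently, so a mono run and a
di tract may overlap; within one unit length, scanning is leftmost-greedy
and non-overlapping, which resolves phase ambiguity deterministically
(`UGUGUGU…` is read in the UG phase if that comes first).  The scanner is
verified against a brute-force oracle (enumerate every start × unit
length, keep maximal primitive tracts, greedy-select) on every embedded
reference sequence and 1000 seeded random sequences.

The *relative count* is tracts per miRNA: total tracts divided by library
size, reported to two decimals (three when the value would print as
0.00, as very rare repeat classes do).  Dinucleotide classes group as
unordered pairs (GU/UG); longer units group by lexicographically smallest
rotation.  `longest_mono_run` ignores the `min_repeats` floor so maxima
of 1–2 are well-defined on degenerate libraries.

The published library-wide di- through penta-nucleotide totals came from
a third-party SSR tool whose overlap and normalization conventions are
not recorded, so those exact totals are not reproduction targets; the
oracle-equivalence and planted-recovery properties stand in for them.

## Motif scanning and GU tracts

Motif scanning is exact-string matching over {A,C,G,U}; overlapping
occurrences are the default because UGUGU copies inside GU repeats
overlap, and the non-overlapping mode is leftmost-greedy.  Coordinates
are 1-based inclusive throughout the package.  Only the given strand is
scanned — mature miRNAs are single-stranded.

A GU tract is a maximal run of strictly alternating G and U (either
phase).  No formal GU-richness criterion accompanies the published
GU-rich list; the classifier adopts the weakest rule every listed
sequence satisfies — presence of a tract ≥ 5 nt — and exposes the
threshold.  This makes GU-richness a necessary-condition membership test,
not an exclusive definition; set-equality against the published list is
deliberately not asserted.

## Hairpin enumeration

For every loop window (default 3–8 nt) the stem grows outward from the
closing pair while bases pair — Watson-Crick A:U and G:C plus the G:U
wobble (toggleable; wobble pairing is standard in RNA stems).  Stems are
contiguous: no bulges or internal loops.  With molecules of ≤ 27 nt this
restriction is mild, and it makes the enumerator exactly checkable
against a brute-force oracle that tests every (loop placement, stem
length) combination — verified on 1000 seeded random sequences.  It also
means the enumerator is *not* a thermodynamic folder: sequences a
free-energy model folds via bulged stems may be reported as non-folding
here, so published folder-dependent counts (foldable/unfoldable splits,
ΔG ranges, per-motif loop frequencies) are out of scope, replaced by the
structural properties above.

One hairpin is reported per viable loop placement (the maximal stem for
that loop); ranking is stem length (desc), then loop length, then loop
start, and `best_hairpin` takes the top.  The stability score is a
stacked-pair surrogate — GC = 3, AU = 2, GU = 1, minus 0.5 per loop
nucleotide beyond 3 — intended only to order hairpins; it is documented
as not a free energy in kcal/mol.

The tetraloop cascade classifies loops against the stable-tetraloop set
{UUCG, GAAA, GCAA, GAGA, GUGA, GGAA, CUUG, UUUG} plus UUUU (tabulated
alongside them in the source's cascade table): stage 1 = motif loop,
stage 2 = + stem ≥ 3 bp, stage 3 = + C-G closing pair.  "C-G closing
pair" defaults to the unordered pair {C,G} with a strict-orientation
(5′-C, 3′-G) mode available, since orientation is unspecified in the
source.  By default each sequence counts once, by the qualifying hairpin
that survives deepest in the cascade (`count_mode="all"` counts every
qualifying hairpin instead).  Cascade counts are non-increasing across
stages by construction, and tests enforce it.

## Synthetic generator

`SyntheticSpec` draws lengths from a distribution over 16–27 nt (defaults:
22 nt at 47%, 21 at 12%, 23 at 14%, the remainder spread over the range)
and background bases i.i.d. at G 0.29 / U 0.26 / A 0.23 / C 0.22 — the
pooled composition of the real deduplicated human library.  Exactly
`round(fraction·n)` records receive each planted-feature directive; a
record carries at most one directive (fractions must sum to ≤ 1), which
keeps plantings from interfering inside one sequence.

Planting overwrites background positions at a uniformly drawn admissible
placement, redrawing the length if the feature cannot fit.  SSR flanks
are resampled so the planted boundaries are the maximal tract (the base
before may not complete a unit copy, the base after may not begin one);
hairpin flanks are resampled so the planted stem cannot extend outward.
Records not assigned a feature are resampled until the package's own
scanners certify them free of every planted feature type (motif absent,
no SSR tract at all); records carrying one feature type are excluded from
the certified-free sets of other types (a planted (GU)ₙ tract contains
UGUGU, for example).  Tracts nested *inside* a planted SSR span (e.g. the
(A)₃ runs inside (AAAG)₃) are tolerated and reported.  Using the
package's scanners for certification is a deliberate economy: ground-truth
coordinates are recorded independently at planting time, so the recovery
tests still exercise coordinate bookkeeping end to end.

What the generator does *not* emulate: sequence relatedness (miRNA
families, paralogues), positional composition gradients (e.g. the real
5′-U enrichment, unless planted via a terminal-base directive), and any
dependence between features.  Passing recovery tests therefore
demonstrates scanner correctness on realistic length/composition
profiles, not distributional fidelity to miRBase.

## Determinism and problem sizes

All analysis stages are deterministic; randomness exists only in the
generator, which takes a mandatory integer seed (numpy `default_rng`) and
produces byte-identical FASTA on identical spec + seed.  The run manifest
hashes every analysis-relevant config field (output location excluded),
so bundles are comparable across runs.

Test-suite scales, chosen to exercise every code path while keeping the
suite fast: oracle equivalence on all 84 embedded reference sequences
plus 1000 seeded random sequences per scanner (lengths ≤ 30 nt, where
brute force is exact and cheap); planted-feature recovery on a 500-record
library carrying five directive types; composition calibration on a
~10⁵-nt corpus (3-standard-error band).  The analysis scripts use a
2042-record synthetic library mirroring the real library's size.

## Known limitations

* The hairpin enumerator's no-bulge restriction understates folding
  propensity relative to thermodynamic folders (and the surrogate score
  is ordinal only).
* GU-richness and tetraloop-cascade counting ("per sequence by best
  hairpin") are reasonable conventions where the source leaves the rule
  unstated; both are configurable but defaults are a choice.
* Reproducing full-library census numbers requires the actual miRBase
  release-19 human `mature.fa`; the package reads it directly
  (`read_fasta(path, species_prefix="hsa-")`) but does not download it,
  and the synthetic stand-in makes no claim of matching its exact
  contents.
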