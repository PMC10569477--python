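# Methods

## Problem setting

A degenerate primer is an oligonucleotide containing IUPAC ambiguity codes
(R, Y, W, …) and is synthesized as the equimolar mixture of all its
concrete expansions; its *degeneracy* is the product of per-position code
sizes. When a gene family is too divergent for a single primer, several
degenerate variants targeting the same binding region can be pooled into an
equimolar *mix* that jointly covers the panel. The package designs such
mixes from an alignment of orthologs and validates them in silico. Gaps
(`-`) are permitted only in alignment rows; windows containing a gap in any
row are ineligible as binding regions. All user-facing coordinates are
1-based inclusive; storage is 0-based half-open.

## Binding-region guidelines

A candidate window must satisfy, on its majority-base consensus:

| parameter | default | meaning |
|---|---|---|
| `primer_len_min/max` | 17 / 22 bp | binding-region length |
| `tm_min/max` | 50 / 65 °C | melting-temperature window |
| `gc_max` | 0.50 | GC fraction must stay **below** this |
| `conservation_threshold` | 0.75 | per-column majority-base fraction, averaged over the window |
| `polyN_max_run` | 4 | longest allowed homopolymer (runs of 5+ fail) |
| `hairpin_stem_min`, `hairpin_loop_min` | 4, 3 bp | smallest self-complementary fold that disqualifies |
| `dimer_run_max` | 4 | 3′-anchored complementary run length that disqualifies |
| `pair_tm_delta_max` | 4 °C | max consensus-Tm difference within a pair |
| `max_degenerate` | 4 | degenerate positions per primer, never consecutive |

Column conservation is the fraction of rows carrying the most frequent
non-gap base (ties broken alphabetically); "conserved" is operationalized
as a window whose mean majority fraction reaches the threshold, since the
per-window aggregation rule behind the usual 75 %-colour convention is not
standardized. Forward/reverse windows are paired only when the forward one
lies entirely upstream, the spanned product reaches `min_product` (default
400 columns, configurable) and the consensus Tm difference is within
tolerance; pairs are ranked by product span, largest first, because a
longer fragment carries more phylogenetic signal.

## Melting temperature and structure screening

Tm uses composition formulas only — the Wallace rule
`2(A+T) + 4(G+C)` below 14 nt and `64.9 + 41(GC − 16.4)/L` from 14 nt —
with no salt or nearest-neighbour corrections; both are monotone in GC
count, so the extremes over a degenerate pool are computed analytically
from the per-position GC bounds. Sequences shorter than 8 nt are rejected
as unreliable. A consequence worth knowing: with these formulas, a primer
can satisfy both Tm ≥ 50 °C and GC < 50 % only at lengths 21–22 with 9–10
G/C, so the scan effectively emits 21–22-column windows. Hairpin and dimer
screening is alignment-free complementary-run counting (the string check of
classic oligo calculators), not ΔG folding: hairpins are upstream/downstream
reverse-complementary stems separated by a loop, dimers the longest
contiguous Watson–Crick run over all ungapped offsets of one oligo against
the reverse of the other; the QC verdict uses the 3′-anchored self-dimer
run, the form that actually primes extension artefacts. For degenerate
oligos every structure statistic is the worst case any expansion (or pair
of pool members) can realize, and the Tm guideline is applied to the
extremes of the expansion pool — an equimolar mix anneals reliably only if
all its members do.

## Variant design

A target group is *feasible* when its minimal degenerate consensus (per
column, the unique IUPAC code expanding exactly to the observed bases —
never wider than the data) satisfies the degeneracy rules (≤ 4 positions,
none adjacent) and keeps length, Tm extremes and GC inside the guideline
box. Feasibility deliberately includes the thermodynamic box so that every
emitted variant is usable as-is; hairpin/dimer statistics are attached to
the variant's QC report but do not gate grouping, because the scan already
rejected structure-prone regions. Targets whose window alone is infeasible
are reported as uncoverable rather than failing the design.

Partitioning minimizes the number of groups. Up to 12 targets the optimum
is found exactly by dynamic programming over target subsets (the canonical
submask recursion); beyond that a deterministic greedy set-cover repeatedly
grows the feasible group covering the most uncovered targets, breaking ties
toward fewer degeneracies, then the lexicographically smallest variant.
The cutoff reflects the 2^n cost of the exact table; both paths are
exposed (`exact_limit`). Groups are named G1..Gk by decreasing coverage.

*Relaxation* (the mix-B strategy) adds exactly one degenerate position to a
variant: every concrete position not adjacent to an existing degenerate one
is considered, widened only to bases observed among targets that mismatch
the variant there and nowhere else; the widening maximizing the coverage
gain wins (ties: fewer added bases, then leftmost position). If the full
widening breaks the Tm/GC box, single-base widenings are tried instead.
Coverage can only grow, since the new code contains the old one. A variant
"covers" a target iff some expansion matches the target window with zero
mismatches; PCR's real-world tolerance is modelled separately in the
matching policy, not in the design-time coverage count.

`spacing_score` reports the minimal distance between degenerate positions
(sequence length as the sentinel when fewer than two), for ranking variants
that are equal otherwise.

## In-silico PCR

Matching slides the degenerate primer over both strands of a linear
template; a position matches when the template base is in the code's
expansion set. Default policy is strict: zero mismatches, full length, `N`
in the template matches nothing (configurable). The permissive mode allows
up to 2 mismatches with the 3′-terminal bases exact, reflecting that
annealing tolerates internal mismatches far better than 3′ ones. Amplicons
form between a plus-strand forward hit and a downstream minus-strand
reverse hit with product length (both footprints included) inside
[100, 3000] by default — bounds that suppress spurious pairings on long
templates. Products with identical coordinates are collapsed keeping the
fewest-mismatch primer pair. The coverage matrix marks a template covered
by a variant when at least one hit exists anywhere on it under the active
policy.

## Marker resolution

Phylogenetic usefulness of the amplified fragment is assessed at desk
scale: p-distances (fraction of differing sites, columns with a gap in
either sequence excluded pairwise), neighbor joining with deterministic
tie-breaking (smallest id pair at equal Q; negative branch estimates
clamped to zero), and unrooted Robinson–Foulds distance over non-trivial
bipartitions. NJ and RF are implemented in-package because the contracts
require order-independent determinism and unrooted split semantics;
external reference implementations (scikit-bio's NJ, dendropy's RF) serve
as independent cross-checks in the test suite. Maximum-likelihood
inference, support values and model selection are intentionally out of
scope — alignments, distance matrices (TSV) and trees (newick) are written
so external ML tools can take over.

## Synthetic data

`simulate_gene_family` evolves taxa from a (random or supplied) root:
background sites substitute independently per taxon with probability
`background_divergence` (uniform over the three alternative bases — a
Jukes–Cantor-like choice, the simplest model that exercises the design
logic); an optional clade structure shares half the divergence within
clades. Conserved blocks keep the root base in at least
`1 − max_minor_fraction` of taxa at every column. No indels are simulated,
so the alignment is trivially known; gap handling is tested by injecting
gaps post hoc. Generators are pure functions of (spec, seed) and
self-validate after generation.

`benchmark_panel` constructs a fully synthetic 24-taxon, 1100-bp panel
whose two binding regions (columns 112..133 and 949..970) are built from
planted variant groups, reproducing the structure of the published *hglT*
validation conditions: seven forward groups of sizes 8/4/3/3/2/2/2 and five
reverse groups of sizes 6/5/5/4/4; within group 1, six of eight members
match the 3-degeneracy variant Fw1_G1 and all eight match its one-position
relaxation Fw1_G1n; mix B (7 oligos) and Rv1 (5 oligos) span 859 columns on
the Anabaena-like reference, inside the ~850 ± 25 bp design target. Group
identity is enforced by even-weight A/T "codeword" positions so members of
different groups differ at ≥ 2 fixed positions and can never be matched by
another group's variant; variable positions are A/T (code W) so every
expansion keeps 10 G/C in 22 nt — Tm 52.97 °C, safely inside the box.
Background divergence is 0.15 from a random root (typical of within-genus
marker-gene identity); coverage counts, mix sizes and product length are
measured by the matcher at run time, never tabulated. What passing on this
panel does *not* show: robustness to indels, to sequencing error, to
paralogs, or to real templates whose binding sites deviate from the design
alignment — those need real data.

`plant_primer_sites` embeds one expansion of each primer in a random
template and rejection-samples the background until neither primer has any
off-target strict match, giving exact amplicon truth.

`recovery_family` (24 taxa, 1050 columns, blocks at 112..131 and 970..989,
background divergence 0.30, block minority ≤ 8 %) is the seed-fixed
end-to-end fixture: at that divergence background windows fall below the
conservation threshold, so the scan's top-ranked windows are the planted
blocks and the best admissible pair spans ≈ 900 columns.

## Problem sizes and numerics

The test suite and the acceptance script run entirely on generated data:
the 24-taxon panel, 1.1-kb templates, oracle checks on ≥ 1000 random
instances of ≤ 40 bp, exhaustive partition search up to 8 targets, and 100
random 6–10-leaf trees — a few minutes end to end on one CPU. Ties are
broken deterministically everywhere (alphabetical majority base, leftmost
window, lexicographically smallest variant, smallest id pair in NJ), so
identical inputs and seeds give byte-identical outputs.

## Known limitations

- Composition-formula Tm only; no nearest-neighbour ΔG, salt or Mg²⁺
  corrections. Absolute Tm values differ from thermodynamic estimators;
  the guideline box is calibrated to the formulas above.
- Dimer/hairpin screening is string complementarity, not folding energy.
- The greedy partition is not guaranteed minimal beyond the exact-search
  cutoff (it matched the optimum in all tested panels).
- Linear templates only; no circular wrap-around amplicons.
- The published variant groupings of the original assay were partly
  phylogeny-informed; the designer reproduces coverage-equivalent mixes,
  not necessarily identical oligo sequences.
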