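# Methods

## Problem and model

CRISPR imaging labels a genomic locus by recruiting fluorescent dCas9
probes via sgRNAs. Signal requires many bound probes clustered in the
target window; specificity requires that no comparable cluster of binding
activity exists anywhere else in the genome. `guideset` formalizes this as:
choose a set of spacers maximizing (or budgeting) the *expected number of
bound probes* in the target, then verify that the best off-target window's
expected activity is a small fraction of the on-target activity.

The expected-probe interpretation comes from the scoring model: each
binding site *i* carries a binding-probability-like score `s_i ∈ [0, 1]`
(1 for a perfect protospacer match), so the sum over counted sites is the
expected number of occupied sites.

## Candidate enumeration and site mapping

Sites are spacer+PAM layouts fully contained in the sequence, on both
strands; a site's coordinate is always the leftmost forward-strand base of
the full layout, which makes strand-symmetric enumeration testable by
mirroring. Candidates are the distinct N-free spacers with at least one
exact occurrence in the target. Binding sites of a candidate are all
PAM-anchored target loci with spacer-region Hamming distance ≤ `max_mm`
(inclusive; default 3). Decisions fixed here:

* Mismatches are counted over the spacer only; the PAM must match its
  IUPAC pattern exactly. No PAM-relaxed (e.g. NAG) sites are considered.
* A genomic N matches nothing: it disqualifies a PAM position and counts
  as a spacer mismatch; spacers containing N are discarded. Lowercase
  (soft-masked) input is treated as ordinary sequence; IUPAC ambiguity
  codes other than N are normalized to N on input.
* Indels/bulges are not modeled; matching is pure Hamming at fixed offsets.
* "sgRNA length" means spacer length (default 20), so the default site is
  20 + 3 = 23 bp.

## Scoring

`site_score` multiplies, over mismatched positions *p* (1 = PAM-distal,
20 = PAM-proximal), a penalty `pen(p, rna_base, dna_base) ∈ [0, 1]`. The
model applies only to the 20 nt + NGG geometry; any other geometry
dispatches to uniform scoring (every site counts 1.0), as does a missing
penalty table (with a logged warning). An N in a site at a mismatched
position scores 0.

The bundled table is **synthetic**: the published mismatch-activity
supplementary data cannot be redistributed here, so a stand-in is generated
(`scripts/make_cfd_table.py`) from a monotone position profile
(`0.08 + 0.92·(1 − (p−1)/19)^1.6`, i.e. distal mismatches tolerated,
proximal ones ~12× worse) times a base-pair weight that favors wobble-like
pairings (rG:dT, rU:dG). It preserves every property the package's logic
and tests rely on — range, multiplicativity, monotonicity, position
asymmetry — but its numeric values are not measurements, so absolute
activity scores on real guides should be interpreted only after loading a
measured table.

## ILP selection

Variables: binary `x_j` per candidate spacer, binary `y_i` per site.
Constraints: `y_i ≤ x_owner(i)`; `y_i + y_k ≤ 1` for every pair with
`|start_i − start_k| < g` on the same contig (g = 30 bp default — bound
probes need physical separation); and additionally for every pair of sites
at the identical `(start, strand)` locus owned by different spacers, so a
physical locus is never counted twice even at g = 0 (the solver then keeps
the max-scoring owner). Formulation 1 adds `Σ x_j ≤ K` and maximizes
`Σ s_i y_i`; formulation 2 adds `Σ s_i y_i ≥ T` and minimizes `Σ x_j`.
Distance is measured between site starts, strand-blind, across all counted
sites of the whole set.

The backend is HiGHS through `scipy.optimize.milp` with `mip_rel_gap = 0`
(proven optimality). HiGHS is deterministic and exposes no seed; the
config's `seed` field is recorded in outputs and would be forwarded to a
backend that accepts one. Among tied optima any solution is valid;
outputs are post-sorted (spacers lexicographically, sites by coordinate) so
files are reproducible for a given solver build. All internal checks and
the test oracles compare objective values, never the identity of the
selected set. An unreachable formulation-2 floor returns a distinct
`infeasible` status carrying the best achievable activity.

The brute-force oracle enumerates spacer subsets and solves the site layer
exactly: conflicts depend only on start-coordinate proximity, so a sorted
dynamic program with a prefix-max lookup gives the max-weight independent
set in O(n log n) per subset (per-locus max at g = 0). It refuses instances
above 15 candidates / 30 sites.

## Off-target evaluation and the removal loop

The off-target search is a built-in exhaustive scanner (identical machinery
to on-target mapping, applied genome-wide, excluding any site overlapping
the target region by ≥ 1 bp). A pluggable engine interface accepts external
search tools returning the same site records, but only the exhaustive
scanner is implemented and tested.

Off-target activity is the maximum over all windows of width `W` (default:
the target length) of the summed scores of sites whose start lies in the
window; windows never span contigs. Because shifting a window's left edge
to the next site start never loses sites, the per-base sliding maximum is
attained at a site-start-anchored window, so only those are evaluated —
exactness against the every-integer-start scan is property-tested.

**Ratio convention.** The tested quantity is `off/on`, and a set passes
when `off/on < r` (strict; default r = 0.2). The describing text this
design follows words the division the other way round, which would prefer
designs whose off-target activity dwarfs the target's; the off/on reading
is the one consistent with the stated goal, and the CLI help states it.

On failure the sgRNA whose *own* sites give the largest window score (ties
broken lexicographically) is removed from the candidate pool — not merely
from the current set — so re-solving can restructure freely. The pool
strictly shrinks, bounding iterations by the candidate count. Terminal
statuses: `ok` (report's recomputed ratio passes), `exhausted`,
`infeasible`, `no_candidates`. This greedy removal can discard a spacer
that belonged to some passing optimum; that is a known limitation of the
two-stage heuristic (a joint on/off ILP is intractable because each spacer
can have thousands of off-target sites).

## Accessibility survey

`accessibility_survey` partitions each contig into consecutive
non-overlapping windows (a trailing partial window is ignored), solves
formulation 1 with `K = set_size` per window, and reports the fraction of
windows whose optimal activity reaches `site_floor`. Defaults (floor 25,
window 50 kb) encode the empirical high-density-cluster criterion for a
usable imaging signal. It is intended for toy genomes at desk scale;
genome-wide runs are possible offline but scale linearly in windows.

## Synthetic fixtures

`make_genome` builds i.i.d.-uniform background with planted clusters:
copies of a prototype spacer at fixed spacing, each with an exact number
of seeded random substitutions, ending in a concrete PAM. After planting,
accidental exact background copies of any prototype (either strand) are
rewritten so the ground-truth table stays exact; near-matches within the
mismatch cap may remain in the background, which is realistic and only
adds off-target noise, never corrupts planted truth. Fixtures are
byte-reproducible from (seed, spec). What passing fixture tests shows:
correctness of enumeration, scoring, optimization and the removal loop.
What it does not show: behavior on repeat families, GC skew, assembly
gaps, or chromatin context — uniform background has none of these, and
the scoring model explicitly ignores chromatin.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale problems chosen to keep
the oracles honest: enumeration equality on 100 seeded sequences of
150–600 bp across PAMs NGG/NG/TTTN and mismatch caps 0–3; ILP-vs-brute-force
equality on 100 seeded instances with 3–9 candidates and ≤ 25 sites
(gap ∈ {0, 5, 30, 60}); window-maximum equality on 100 layouts over 50 kb
coordinates; the end-to-end decoy fixture uses a 30 kb genome with a 3 kb
(design) or 2 kb (tests) target. Floating-point comparisons use 1e-9
absolute slack against the solver; scores are plain float64 products and
sums. Degenerate inputs are defined, not special-cased: empty site lists
score 0, a candidate-free target returns `no_candidates`, an all-N target
has no sites, and a zero on-target activity refuses to form a ratio.
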