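# Methods

This note documents the models, rules and numerical choices behind
`pcfkit`, what the simulator does and does not emulate, and the known
limitations. Coordinates are 0-based half-open throughout; all
randomness flows through one explicitly passed `numpy` generator per
run, so identical seeds give byte-identical outputs.

## The adjacency model behind PCF construction

PCF building is a deliberately transparent re-implementation of
reference-assisted scaffolding. Raw pairwise alignment blocks are
chained into syntenic fragments (SFs) when consecutive blocks share
target sequence, reference chromosome and orientation, are colinear on
both genomes, and both inter-block gaps fall below the resolution
(default 150 kb). The dual-gap rule is intentional: testing only one
genome's gap admits spurious merges across insertions on the other.
Blocks under `min_block_bp` (default 5 kb, a free parameter) are
dropped before chaining; target-overlapping blocks keep the longer.

An intra-scaffold SF adjacency is **retained** iff

    spanning physical coverage >= threshold_c
    OR (reference AND outgroup both support the adjacency),

otherwise the scaffold is cut there and the cut becomes a split joint.
Physical coverage at a position is the number of mate-pair fragments
(the interval from the leftmost read start to the rightmost read end)
containing it; only same-scaffold, inward-oriented pairs count. The
coverage attributed to a joint is the **minimum over the gap** between
the flanking SFs. The gap-midpoint alternative (available via
`coverage_mode="midpoint"`) is unsafe whenever alignment dropout widens
the gap beyond the insert size: the midpoint can then sit more than one
insert away from the true junction and read normal coverage across a
genuine chimera.

Retained runs are chained across scaffolds with the indicator score
`w_ref*I_ref + w_out*I_out + w_read*cov_norm >= join_min` (defaults
1/1/1 and 2). Read pairs never span two scaffolds, so `cov_norm` is 0
at chain junctions and chaining effectively requires both comparative
supports. Chains are assembled greedily by score along the reference
with a union-find cycle guard; PCFs inherit reference orientation.
This imposes reference order on inter-scaffold joins — the classic
reference bias of this family of methods. It is precisely the error
class that downstream verification (split-joint testing) and
cytogenetic conflict splitting are designed to catch; inversions that
span scaffold boundaries can still be scrambled when probe resolution
is too coarse to flag them, which inflates intrachromosomal EBR counts
measured on assembled (rather than true) chromosomes.

## Verification and threshold calibration

Split joints are narrowed using finer alignment blocks colinear with
either flanking SF; a joint is *testable* when the narrowed gap is
under 6 kb (the practical PCR amplicon bound). Verification outcomes
drive two things:

* **Calibration** — the retained/split coverage threshold is the
  smallest integer `c` maximizing
  `A(c) = #(confirmed with cov >= c) + #(refuted with cov < c)`,
  found by exhaustive scan (coverages are small integers). The
  agreement-maximization objective is this package's formalization of
  choosing the threshold "most consistent" with verification outcomes;
  ties break toward smaller `c` (keeping more scaffolds intact). With
  no refuted joints the rule degenerates to the minimum confirmed
  coverage.
* **Refinement** — confirmed joints are welded back permanently,
  `alternative_confirmed` joints are welded in the swapped order,
  refuted joints stay split, and PCFs conflicting with the cytogenetic
  map are split at their lowest-coverage internal junction. Map
  evidence outranks a confirmed PCR when the two collide (cytogenetics
  is terminal in this workflow).

## Probe rule and panel

The universality rule is applied exactly as printed: alignable fraction
>= 0.93 AND (longest conserved element >= 300 bp OR (total repeats
< 1290 bp AND a CE >= 3 bp present)). The >= 93 % gate applies to both
branches. The "CE of at least 3 bp" clause is implemented as a presence
flag. Placement concordance is insert length within the library mean
± 3 SD with end sequences on opposite strands. Panel selection is a
greedy per-chromosome sweep accepting the next candidate at least
`target_spacing_bp` past the last accepted; the first candidate of each
chromosome is always accepted, so all inter-probe gaps except possibly
the terminal one reach the spacing.

## Anchoring

A PCF is assigned to the chromosome holding the majority of its mapped
probes; any PCF touching two chromosomes is flagged as a candidate
mis-join (and split when it has more than one member). Along a
chromosome, PCFs are ordered by the mean map position of their probes
(ties broken by length, longer first, logged) and oriented by the sign
of the Kendall rank correlation between in-PCF probe coordinates and
map order — more robust to a single noisy probe than endpoint
comparison. Single-probe or exactly tied PCFs stay `?`, and `?` PCFs
contribute to placed but not oriented bp. Interleaved probe ranges
(map reads A, B, A) are a hard error from the library function; the
pipeline resolves them by dropping the PCF with the weaker probe
support from the build, mirroring how ambiguous placements are excluded
in practice.

## EBR detection and classification

On a homeology map (HSBs at a stated resolution, built with the same
chaining as SFs, with reference-side overlaps trimmed), every
reference-adjacent HSB pair whose target continuity breaks —
different target chromosome, order jump, or orientation flip — yields
one EBR spanning the inter-HSB reference gap. Intervals under 1 kb are
extended by 1 kb per side (before the size filter); intervals over
100 kb are flagged excluded and skipped by the CNE analysis, as are
records whose flanks are unoriented (`well_defined = false`).

Typing treats the reference as the ancestral proxy: same target
chromosome on both sides → intrachromosomal; different target
chromosomes → fission (the reference chromosome was split). Each
target-side junction joining blocks of two reference chromosomes emits
one fusion record per reference flank, the flank being the gap to the
next HSB outward or, at a reference chromosome end, the terminal 10 kb
inward from the block edge (a default for the case the source material
leaves open). The two ends of one inversion are recognized by the
single orientation-discordant block between them and share an event
group; a fusion flank coinciding with a fission gap likewise shares its
group, so one biological event is never double-counted. Lineage
assignment labels an EBR species-specific when no other species' map is
disrupted within a resolution slack, otherwise with the smallest clade
(MRCA on a user tree) containing all disrupted species.

## Window statistics

Chromosomes are cut into non-overlapping 1-kb windows; windows with
more than half their bases uncovered are unusable, terminal short
windows are dropped. Labels: msHSB (only intervals > 1.5 Mb),
intra/fusion/fission EBR (well-defined, <= 100 kb records only), rest;
an EBR label wins over msHSB on overlap since EBRs are the analysis
target. For every usable zero-CNE window, the reported distance is the
bidirectional minimum number of windows to the nearest usable window
whose density reaches the mean msHSB density (computed on usable msHSB
windows of the same track); chromosomes with no qualifying window have
their zero-windows excluded and tallied. Distances and densities are
computed per-window.

Group comparison is Kruskal–Wallis followed by all pairwise two-sided
Mann–Whitney tests, run only when the omnibus p is below alpha. For
group sizes up to 8 the pairwise p is exact by complete enumeration of
all C(n+m, n) label assignments, defining the two-sided p as the
probability of a U deviating from nm/2 at least as much as observed
(valid under ties); larger groups use the normal approximation with tie
correction. Raw and Benjamini–Hochberg-adjusted p values are both
reported. TE enrichment compares per-family densities in 10-kb
EBR-containing vs other windows with Welch's t-test (the unequal-
variance form, a deliberate choice where the variant was unspecified),
for families whose elements average more than 100 bp. Five-slot EBR
flank profiles use windows of the EBR's own size, labeled by genomic
coordinate (negative = lower coordinates); out-of-chromosome flanks
are reported unavailable rather than clipped.

## The simulator: what it emulates, and what it does not

The simulator is coordinate-level interval bookkeeping — downstream
mathematics never reads a nucleotide. An ancestor (the reference
proxy) carries designated msHSB intervals; a replayable plan applies
fusions first (joining whole chromosomes end-to-end, emulating the
observed absence of reciprocal translocations), then fissions, then
inversions confined to single current segments, all with margins and a
minimum breakpoint separation so each planted event leaves a resolvable
signature. Translocation is implemented but off by default. Breakpoints
can be kept out of supplied intervals (e.g. msHSBs), mirroring the
observation that breakpoints avoid conserved synteny blocks.

Shredding cuts descendant chromosomes at exponential spacing (default
mean 1 Mb; scaffold-length and insert-size distributions are free
parameters) and, at the chimera rate, concatenates two unrelated
fragments, registering the joint. A chimeric joint receives zero
spanning pairs with probability `p_chim_zero` (default 0.9), else its
spanning pairs are thinned to half rate — the coverage signature of a
mis-join is not documented in the source material, so it is an explicit
model here. Mate pairs are uniform with Gaussian inserts (default
3 kb ± 300 bp), giving Lander–Waterman expected physical coverage
`n_pairs * insert_mean / genome_length`.

CNE tracks drop one fixed 200-bp element per 1-kb cell with Bernoulli
probability `density * 1000 / 200`, so the expected base fraction per
region equals the configured density (msHSB 0.11, background 0.02) and
realized densities follow the element-draw binomial. Fission sites are
surrounded by hard deserts (zero CNE within ± 50 kb); fusion flanks
carry background/12 density over ± 50 kb — the order-of-magnitude
deficit reported for interchromosomal versus intrachromosomal
breakpoints — which is what makes the median zero-window distance
ordering msHSB < intra < fusion < fission an emergent property rather
than a coin flip. TE families are placed per-cell with a configurable
density multiplier near intrachromosomal breakpoints (default: one
enriched, one neutral family).

Alignment-block emission erodes block ends adjacent to breakpoints and
scaffold ends by U(0, E): E defaults to 5 kb for scaffold-level blocks
(raw pairwise alignments localize well) and 25 kb for chromosome-level
blocks (synteny blocks at 100–500 kb resolutions localize edges only
coarsely). The erosion gives EBR intervals realistic nonzero width;
detected breakpoints are therefore localized only to within the
resolution, and simulated chimeric joints inside wholly unaligned
fragments (< `min_block_bp`) are undetectable by construction — the
chimera benchmarks count only joints with aligned material on both
sides.

Not modeled: sequencing error, base-level mutation, repeat-family
sequence content, diploidy, assembly gaps, probe hybridization
chemistry. Passing tests on simulated data therefore demonstrate the
correctness of the interval logic and the statistical machinery under
the stated generative model, not performance on real alignments with
paralogy, missing data, or assembly-specific artifacts.

## Problem sizes and defaults

The shipped demo profile is a 20-Mb, 5-chromosome genome with 10
inversions, 3 fusions, 2 fissions, 10 % chimera rate and ~27x physical
coverage (60,000 pairs x 3 kb / 20 Mb ≈ 9 fragments deep at any
position), chosen so the full pipeline completes in about one second.
The CNE-desert statistics scenario uses 12 chromosomes x 4 Mb with 20
inversions, 11 fusions and 10 fissions so that every window class
yields at least 200 zero-CNE windows for the distance comparison. The
anchoring benchmark uses 50 chromosomes of 3–4 PCFs each with 2–4
noise-free probes per PCF plus planted single-probe PCFs.

## Known limitations

* Inter-scaffold chaining is reference-ordered; species-specific
  junctions spanning scaffold boundaries survive only where read
  coverage keeps the scaffold intact or the map catches the error.
* Event grouping assumes isolated, non-nested inversions (guaranteed by
  the default plan generator); overlapping or nested events would be
  counted as multiple events.
* The `ebr` counts reported by the pipeline are measured on the
  assembled chromosomes and include assembly-artifact records; exact
  recovery holds on chromosome-level alignments of the true karyotype.
* Fusion flank intervals at reference chromosome ends use a fixed 10-kb
  inward default.
* `real-input` mode expects externally produced block tables, pair
  placements, tracks, and probe maps in the documented TSV/BED formats;
  it skips simulation-only conveniences such as in-silico PCR.
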