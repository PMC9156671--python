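# Methods

This note documents the models, algorithms and design choices behind
`pansv`, in the order the pipeline runs them.

## Graph model and coordinates

A pangenome graph is a set of segments with reference-origin tags (sample,
offset, rank; rank 0 is the backbone) plus oriented links, as in rGFA.
Rank-0 segments of one chromosome must tile it contiguously; this
invariant is checked on every read and is what makes backbone projection
of bubbles well defined. All intervals are 0-based half-open internally
(BED convention); conversion of GFF3's 1-based closed coordinates on read
is the only coordinate shift in the codebase. Deletion length is therefore
always `end − start`.

The haplotype-walk dialect is a 6-column BED: chromosome, backbone start,
backbone end, source segment, sink segment, and an oriented path string
(`>`/`<`-prefixed segment ids) or `.` for a missing walk. Real
`minigraph --call` output with extra trailing columns can be read with the
permissive flag.

## Superbubble detection

Detection runs on the oriented-copy digraph: each segment contributes a
`+` and a `−` node and every link induces its edge and the reverse
complement, so graphs with reverse-orientation links are handled (inversion
*calling* is out of scope). A candidate bubble is an ordered pair of
rank-0 forward nodes `(s, t)` with `pos(s) < pos(t)` on one chromosome
such that:

1. `t` is reachable from `s`;
2. the node set reachable from `s` without passing `t` equals the set
   that reaches `t` without passing `s` (no escapes, no external entries);
3. the induced subgraph is acyclic (not expanding past `t`);
4. at least two distinct `s → t` allele paths exist;
5. every rank-0 interior node lies strictly between the endpoints on the
   backbone.

Minimality removes candidates that contain another candidate's sink (same
source) or source (same sink) in their interior; an outermost pass then
removes any bubble whose node set is strictly contained in another's, so
reported bubbles are flat with pairwise-disjoint interiors — matching the
per-bubble granularity of minigraph/gfatools calls. Nested variation inside
a reported bubble is intentionally not re-decomposed. Overlapping
candidates are ordered by leftmost source, then longest span. The detector
is validated against an exhaustive-path brute-force oracle on hundreds of
random 12-segment graphs.

The reference allele is the path whose interior tiles the backbone
interval exactly; when present it is always allele 0. Allele length is the
sum of interior segment lengths, and typing reuses the 50 bp graph
divergence threshold (no separate SV-typing cutoff is introduced):
INS when `ref_len < 50 ≤ alt_len`, DEL when `alt_len < 50 ≤ ref_len`,
COMPLEX otherwise (including bubbles without a reference path, which are
flagged `no-ref`).

## Allele matrix and discordance

Path identity is exact oriented segment-sequence equality; alternative
traversals of equal length are distinct alleles. An assembly with zero or
multiple records at a site is missing there (ambiguous walks are lumped
with incomplete ones). `filter_complete` drops sites missing in any
assembly and reports the count — it counts matrix rows, i.e. bubbles.

The pairwise distance is the number of bubbles at which two assemblies
took different paths; multi-allelic differences count one per bubble.
Missing entries are handled pairwise-complete so partially phased
assemblies remain comparable, and a normalized mode (divide by the
per-pair jointly observed site count) is available since raw counts scale
with coverage; raw is the default.

## UPGMA and topology classification

UPGMA is size-weighted average linkage: the pair at minimum distance
merges at half that distance and the new cluster's distances are the
member-count-weighted means. Ties break deterministically toward the
lexicographically smallest pair of cluster minimum labels. Ultrametric
inputs are reproduced exactly (cophenetic fixed point), and the
implementation is cross-checked against scipy's average-linkage on
tie-free inputs in the test suite.

Topology classification takes the two ordered outgroups (gaur outermost,
then indicine) and three ingroup (taurine) labels: if the clades
{ingroup ∪ second outgroup} and {ingroup} both exist, the ingroup member
whose two siblings form a clade is the one that "splits first" and names
the arrangement (`O_OUT` / `P_OUT` / `B_OUT`); any other shape is `OTHER`.
This agrees with a direct clade-membership check on all 105 labeled
rooted 5-leaf topologies.

## Consensus matching

Two SV records are one site when they share chromosome and type, their
starts differ by ≤100 bp and their lengths (max of ref/alt) agree within a
ratio of 0.9 — standard SV-benchmarking practice at this scale; both knobs
are configurable and echoed in every report. Matching is greedy
left-to-right (each test record takes the earliest unmatched compatible
truth record), which is deterministic; a test bounds its cost against
optimal bipartite matching (≥99% cardinality agreement on random sets).
Precision, recall and F1 are reported as percentages; an empty test set
scores 0 by convention and an empty truth set is an error. Shared
fractions across ≥2 call sets union-find cross-set matches into sites and
classify each site by the exact label subset containing it; fractions are
per site.

## Permutation test for CDS-overlap depletion

The observed statistic is the number of overlapping (bubble, CDS-interval)
pairs (≥1 bp, half-open). Each permutation replicate relocates every
bubble uniformly on the 1-based start interval `[1, C − L]` of its own
chromosome, preserving the per-chromosome length multiset exactly;
permuted bubbles may overlap each other — no rejection or avoidance is
applied, which differs from common interval-shuffling tools and follows
plain uniform placement.

The signed-rank test pairs the observed total with each replicate total
(replicate pairing, the default); per-chromosome pairing against the
per-chromosome null means is available behind a flag. Zero differences are
dropped, the exact null distribution is used for ≤25 non-zero pairs and a
normal approximation with continuity correction above. **Caveat:** under
replicate pairing every difference shares the single observed total, so
the pairs are perfectly correlated and the signed-rank independence
assumption fails; simulation shows this p rejects ~49% of null datasets at
α = 0.05. It is reported for fidelity to the published procedure, but the
empirical permutation p, `(1 + #{replicate ≤ observed}) / (n + 1)`, is the
calibrated decision rule (measured 3–7% null rejection at α = 0.05 at the
problem sizes the acceptance suite uses: ~400 bubbles and 300 CDS
intervals over two 500 kb chromosomes, 200 replicates) and is what every
report carries alongside. With few bubbles the integer-valued statistic is
heavily tied and the empirical p becomes conservative; published
genome-scale depletion p-values obtained from replicate-paired signed-rank
statistics should be read with the same caveat.

## Coding consequences

The coding length change of an SV is `alt_len − ref_len` restricted to the
CDS-overlapping portion: a deletion counts only the removed bases inside
CDS, an insertion counts its full net gain when its anchor interval
touches CDS, and intronic ends are ignored — the only reading under which
"36 bp deletion contained in a CDS → 12 residues" generalizes to
partially overlapping variants. A change divisible by 3 is in-frame with
`aa_change = change / 3` (sign included); otherwise frameshift. A deletion
containing a gene's whole span is GENE_SPANNING_DEL regardless of frame
arithmetic. Magnitudes are strand-independent. A gene whose CDS total is
not a multiple of 3 triggers a warning but is processed.

VNTR copy-number changes multiply out the same arithmetic per motif copy;
domain-unit accounting (e.g. 84 bp per zinc finger) is expressed by
calling `vntr_extension` with the domain length rather than hard-coding
any gene's biology.

Depth-based copy number is `round(mean window depth over the region /
baseline) − 1`, ties away from zero, floored at 0, using only windows
fully inside the region; the raw ratio is exposed because ±1 copy is
inherent to depth ratios (read technologies disagree at that resolution).

## Assembly QC

NG50 is the largest length `L` such that contigs ≥ `L` sum to at least
half the expected genome size (0 with a warning if the assembly is
smaller); PG50 is the same statistic on haplotype-phased block lengths and
can only decrease under splitting. QV is `−10·log10(errors/total)` on an
externally estimated error count, capped at 99 when zero errors are
observed (the estimator saturates, not the assembly). Telomere content is
counted inside a terminal 10 kb window, clipped per base; satellite
content inside the proximal 5 Mb — the proximal window is a package choice
(no window is standard for acrocentric chromosomes) and configurable. A
chromosome is end-to-end when proximal satellite ≥ 50 kb *and* distal
telomere ≥ 500 bp, both inclusive. Both TTAGGG-strand classes count
(classification is by annotation class, not sequence scan). Dropout
regions are maximal runs of consecutive same-chromosome windows below 1×.
Gap counts are whatever the gap track annotates.

## Synthetic pangenome generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Tree**: `((((P:1,B:1):2,O:3):5,N:8):12,G:20)` — ultrametric, gaur far
  out, indicine next, three close taurines — plus a root edge of length 2
  whose events are carried by all five haplotypes (divergence from the
  backbone reference). Planted arrangement: `O_OUT`.
* **SV process**: per-branch event counts are
  Poisson(`sv_rate × branch_length × genome_size`); carrier sets are
  exactly clades (infinite-sites on branches; an optional homoplasy rate
  plants non-clade carriers to stress the discordance statistic). The
  default rate 6 × 10⁻⁷ events/bp/unit over 2 × 5 Mb gives ≈310 SVs,
  enough for reliable topology recovery. Event lengths are geometric,
  shifted to a 50 bp minimum with mean 500 bp (matching the heavy tail of
  real bubble sizes at desk scale). VNTR events (15%) draw a motif of
  6–90 bp, divisible by 3 with probability 0.5 so both in-frame and
  frameshift consequences occur, and enough extra copies to clear 50 bp.
* **Graph construction** emulates iterative augmentation by splitting the
  backbone at SV breakpoints: deletions get a direct source→sink edge;
  insertions attach a rank-1 allele node and keep a 1 bp rank-0 anchor as
  the reference allele so every bubble projects to a non-empty backbone
  interval. Footprints keep ≥2 bp separation so each SV is its own bubble.
* **Annotation**: genes are a fixed exon/intron template (4 × 150 bp CDS,
  300 bp introns, in frame); by default they are placed avoiding bubble
  footprints (planted depletion signal), with an independent-placement
  mode for null calibration.
* **Repeats/QC tracks**: per chromosome, a proximal satellite block is
  "complete" (uniform 50 kb–3 Mb) with probability 0.8 else short
  (uniform < 50 kb); a distal telomere block is complete (uniform
  0.5–3 kb) with probability 0.6 else short (< 500 bp), so the expected
  end-to-end rate is `p_sat × p_tel`. Contigs arise from Poisson(1.5)
  breaks per chromosome and phase blocks from further Poisson splits.
* **Depth**: 10 kb windows with multiplicative Gaussian noise (CV 5%,
  appropriate for long-read window means), scaled by `1 + extra_copies`
  inside planted CNV regions for carriers, plus an exponentially rare
  dropout process `p = 0.012·exp(−0.1·depth_mean)` that reproduces the
  qualitative decline of dropout regions with coverage.
* **Replicates**: each bubble is independently perturbed with the given
  noise probability — dropped (50%) or split into two half-size events
  2 bp apart (events too small to split into two ≥50 bp pieces are
  dropped). This abstracts construction-order sensitivity; the real
  mechanism (alignment of palindromic sequence) is not modeled. Expected
  replicate-vs-truth recall is exactly `1 − noise`.

What passing tests on this generator do **not** show: behavior on
nucleotide-level alignment artifacts, nested or overlapping real bubbles,
repeat-dense regions where minigraph's own calls degrade, or read-level
noise — the generator plants clean node-level truth by construction.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng` seeded from the
config; the pipeline derives per-stage seeds from one global seed by a
fixed counter, so reruns are byte-identical. Permutation replicate `r`
uses seed `(seed + r) mod 2³¹`, making nulls extensible without
recomputation. UPGMA tie-breaks, record orderings in every writer, and
greedy matching order are all deterministic. Exact integer arithmetic is
used wherever the quantity is integral (overlap counts, coding-bp changes,
NG50); the only floating tolerances are in UPGMA height comparisons
(1e-9) and test assertions.

## Problem sizes

The test and acceptance suites run at desk scale: 2 × 5 Mb default
genomes (~300 SVs), 500 random 12-segment graphs for the detector oracle,
100 seeds for topology recovery, 500 null datasets × 200 permutations for
calibration, and 20 replicates × 4 noise levels for consensus scoring.
These sizes were chosen so each statistical check has the power its
acceptance band requires.
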