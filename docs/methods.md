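# Methods

This note records the models behind each finishkit stage, the parameters
that matter, the numerical choices, and what the simulation-based tests do
and do not demonstrate.

## BAC fingerprint physical mapping

**Model.** A clone's fingerprint is its multi-channel restriction fragment
size list.  Two clones that overlap physically share bands; the Sulston
score is the binomial tail probability of sharing at least the observed
band count by chance (n_lo trials, per-band chance-match probability
p = 1 − (1 − 2·tol/G)^n_hi).  Bands are matched greedily one-to-one within
`tolerance` gel units, per dye channel — the channel-offset encoding (0
blue, 10,000 green, 20,000 yellow, 30,000 red) exists precisely to keep
channels separate.

**Calibration.** `tolerance` and `gel_bins` (G) are platform parameters.
For the synthetic SNapShot-style data (five enzymes, four dyes, sizes
100–1200 gel units, multiplicative sizing noise) we use tolerance 2 (≈ 3×
the median absolute sizing error at 0.5% noise) and G = 2500, chosen so the
model's expected chance matches equal the empirical rate measured on
non-overlapping clone pairs.  With these, genuinely overlapping clone pairs
score 1e−15…1e−45 while unrelated pairs stay above ≈ 1e−8.

**Assembly.** The overlap network uses the conventional cutoff 1e−10 and
five stringency iterations at cutoff × 1e−5 per step (read as
multiplicative).  At each step:

* *Q-clone flagging.* A clone is questionable when its neighbour set splits
  into ≥ 2 groups (largest ≥ 2) that cannot reach each other within 4 hops
  once the clone is removed.  Articulation clones are the
  unreachable-at-any-distance case; the finite radius additionally catches
  chimeras that short-circuit one connected tiling.  The test is repeated
  with each single neighbour withheld, because two chimeras bridging
  similar region pairs mask each other.  Clones whose band count exceeds
  1.5× the library median are pre-flagged: co-ligation of two inserts
  doubles the fingerprint, and such outliers also distort the binomial
  model (their inflated n_hi masks their own overlaps).
* *Thin-junction splitting.* Sub-cutoff components are contracted; two
  groups separate only when ≤ 2 weak edges bridge them and both sides keep
  ≥ `min_clones` members.  Many sub-threshold edges across a cut are
  stringency attrition inside a genuine contig, not a weak join.

**Ordering.** Contig order comes from spectral seriation (Fiedler vector of
the excess-shared-band Laplacian) — chosen over a greedy Hamiltonian-path
heuristic for robustness on noisy band counts — polished by (a) adjacent
swap hill-climbing on the seriation stress, (b) witness votes: sub-cutoff
pairs (score ≤ 1e−2) carry long-baseline order evidence and every clone
votes on adjacent pairs by its excess-band difference, and (c) a deep-stack
estimator: within runs of mutually nested clones, midpoints are estimated
from averaged witness profiles (right-side witnesses track clone ends,
left-side the negated starts; two-sided averaging cancels the clone-length
confound).  All tie-breaks are by clone id; the result is deterministic.

**Order convention and the information bound.** Reported order targets
clone *midpoints*: overlap evidence is symmetric about clone centers, and
for stacked/nested clones start- and end-order are not well defined.  Under
the default study conditions (150 uniformly placed 160 kb clones on 2 Mb,
0.5% sizing noise), small contigs occasionally contain three or more clones
whose centers differ by < 3 kb — below the fingerprint resolution (an
oracle that orders true centers blurred by only 1 kb of noise already
misorders such stacks).  Passing order-recovery tests therefore demonstrate
correct ordering *up to sub-resolution ties*; per-contig rank correlations
can dip below 0.95 on unlucky draws at other seeds.

**MTP.** Greedy furthest-reach interval covering over the inferred
coordinates, requiring consecutive clones to share a significant edge; this
greedy is provably minimal for interval covers and matches exhaustive
search on all small instances.

## Optical mapping

**Alignment model.** Maps and molecules are ordered label-site coordinate
lists (0-based bp).  Digestion reports motif occurrences on both strands
(default `GCTCTTC`); windows containing N never match.  Alignment is a DP
over monotone site correspondences with per-pair score
`bonus − ((g_q − g_t)/(σ·max(g_q, g_t, 1000)))²` and fixed penalties (2.0)
per skipped label on either side.  σ defaults to 0.03 (3% interval sizing
error).  The bonus is 6.0 ≈ 3× the skip penalty, so a true matched interval
nets +4 on average (the squared standardized difference has expectation ≈ 2
under this standardization).  With unlimited lookback the DP equals
exhaustive enumeration of monotone chains; assembly uses lookback 4–6 for
speed.

**Significance.** p ≈ n_q·n_t·q^(k−1): the expected number of chance
monotone chains of the observed length k, with q the empirical probability
that two unrelated intervals agree (estimated from interval pairs drawn
across molecules, seeded).  This statistic reaches the very small
magnitudes optical assembly thresholds are conventionally quoted on
(defaults: pairwise 1e−10, final refinement 1e−15), unlike a raw
permutation null whose resolution is bounded by the permutation count.
Uniformly spaced labels make q → 1 and are correctly reported as
unalignable.

**Assembly.** Candidate molecule pairs share a quantized interval 3-mer
(quantum 400–500 bp, ±1 neighbourhood probing); accepted overlaps
(p ≤ p_pairwise, ≥ 5 matched sites) feed an orientation/offset union-find,
then molecule offsets are re-estimated by joint weighted least squares over
all accepted constraints.  The LS is made robust by residual trimming
(3 iterations, drop |residual| > max(20 kb, 6× median)): a single spurious
long-range overlap otherwise folds the whole layout.  Consensus sites come
from EM registration: each molecule's residual shift is the median signed
offset to the nearest well-supported site cluster (shrinking capture
windows, no long-range search — that would let molecules jump to
self-similar registrations), observations are pooled and clustered at a
1 kb gap; a cluster where many molecules contribute two observations is
split at its widest internal gap (those molecules resolve two close
labels), and adjacent clusters with disjoint molecule sets merge (they are
registration islands of one label).  A final DP realignment pass
(refinement then final threshold; label-sparse molecules accepted when half
their sites match, since membership is already established) recomputes
support and drops unsupported sites (< 2 molecules).

**Accuracy measurement.** Per-molecule registration leaves a slowly varying
kb-scale warp along a long consensus — exactly as in real optical maps,
which are always evaluated after alignment.  Site recovery is therefore
measured after piecewise-linear projection of the true digest through a map
alignment; at the default study conditions (2 Mb, 50×, 3% sizing noise, 10%
missed labels, 1 false label/100 kb) ≥ 95% of true sites are recovered
within 1 kb.

**Islands.** Scaffold–map alignment components become islands.  Map frames
are grown by the strongest spanning evidence first (weak spurious cross-map
alignments never anchor a frame); a scaffold keeps its strongest placement
plus all agreeing ones, discards weak disagreeing alignments, and is left
unplaced (logged) only when a disagreeing alignment of comparable strength
(≥ 2/3 the matched pairs) exists.  Inter-scaffold gaps are optical
distances between projected scaffold ends; negative gaps are preserved as
overlaps, and a gap is flagged unsized when a flanking scaffold end has no
label within 50 kb.

## Assembly reconciliation

The stringent mapper seeds on exact 13-mers and extends to maximal ungapped
HSPs in which every 50 bp window has ≤ 1 mismatch and the HSP spans ≥ 50 bp
(≈ 98% identity).  All tied best locations are reported with a uniqueness
flag; binned density counts unique reads at their location and multireads
once at a tied location drawn uniformly under the seed.

Contig classification: *exact* means the donor contig is a full-length
perfect substring of the target (either strand); *partial* means stringent
HSPs on the dominant target/strand cover > 90% of the contig; everything
else is *unmatched*.  The three classes partition the donor.

Gap filling is deliberately conservative: an N-run is replaced only when
both gap-adjacent flanks (up to 1 kb, truncated at neighbouring N-runs)
occur exactly once in the donor (both strands searched; palindromic flanks
deduplicated by physical locus), on the same contig and strand, in order.
Overlapping flank images are reported as bridged-overlap; nothing else is
touched — the patched assembly is byte-identical to the draft outside
filled runs.  Declared N counts and filled lengths both appear in the
report (they routinely differ).  Bridging applies the same logic to
terminal flanks of adjacent scaffolds; a bridge is *clean* iff both flanks
match exactly.  Super-scaffold reduction merges adjacent super-scaffolds
when an island's scaffolds span the junction without interleaving, and
orients previously unoriented scaffolds through the island's oriented
members (majority vote fixes the island's direction).

## Region analyses

Crossovers are placed at inter-marker midpoints (unbiased under uniform
position uncertainty within the interval) and binned at 10 Mb.  Double
crossovers within one interval are invisible by construction.  The
suppressed interval is the longest run of bins with count ≤ f × the
genome-wide mean (f = 0.1 default) — an operational stand-in recorded as
such in the profile metadata, since no standard numeric rule exists for
delimiting a recombination-suppressed centromeric region.

Two-locus haplotype frequencies come from EM over unphased genotypes
(linkage-equilibrium initialization, only the double heterozygote is
ambiguous, convergence 1e−9 or 1000 iterations); LOD is the base-10
genotype likelihood ratio of the EM solution against independence at the
same allele frequencies; D′ = |D|/D_max with the sign-dependent D_max.  The
colour classes follow the familiar convention: D′ = 1 (within 1e−9) and
LOD > 2 → high; LOD < 2 → none; else low-medium.  Missing genotypes are
dropped pairwise.

## Simulators

Background sequence is i.i.d. at a configurable GC content (no Markov
structure — sufficient for the algorithms under test; real genomes add
repeat-induced ambiguity beyond the planted tandem arrays).  Defaults
mirror the target data regime: 2 Mb regions; 150 BACs of 160 ± 15 kb
(realistic insert sizes; also what gives the 1e−10 Sulston cutoff usable
sensitivity at half-insert overlaps); five enzymes with 0.5% multiplicative
sizing noise and a 100–1200 size window; optical molecules at 50× coverage,
200 ± 35 kb, 3% interval noise, 10% missed labels, 1 false label/100 kb,
random orientation; drafts with 200 N-gaps biased toward planted GC-rich
tracts and homopolymers, declared sizes distorted ± 30%; 8 founders × 500
progeny with ~2 crossovers each and a zero-recombination interval; LD
panels with two-pattern blocks (within-block D′ = 1 by construction).
Chimeric BACs are co-ligations of two full inserts drawn from the library's
own clone pool at > 4 insert-lengths separation — the actual mechanism of
BAC chimerism (half-insert chimeras are statistically invisible at the
1e−10 cutoff in this regime).  The five enzymes map to four dyes via a
configurable table (blunt-cutting HaeIII is unlabelled, as in the SNapShot
chemistry).  Every simulator is byte-deterministic under its seed and
writes machine-readable truth.

**What passing tests show.** Recovery on these synthetics demonstrates the
algorithms' correctness and calibration under the modelled noise; they do
not capture repeat-induced mapping ambiguity beyond the planted arrays,
context-dependent label/nicking biases, cloning bias, or segregation
distortion in real populations.

## Known limitations

* Fingerprint ordering is resolution-limited to ≈ 3 kb clone-center
  separation; sub-resolution stacks are ordered arbitrarily.
* The optical chance-chain p-value is a first-order expected-count bound,
  not an exact null; thresholds are comparable across runs but not
  calibrated tail probabilities.
* Gap filling requires exact flank matches; a donor with even one
  mismatch in a flank leaves the gap unfilled (by design — the bridging
  report, which tolerates mismatches, covers the rest).
* Super-scaffold reduction consumes island placements as evidence and does
  not re-examine the underlying alignments.
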