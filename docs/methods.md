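# Methods

This note documents the models implemented by `rtquant`, the assumptions
behind them, the synthetic data used to validate them, and the numerical
choices made where the design was genuinely open.

## 1. Single-cycle processivity from densitometry

### Assay and signal model

A single-turnover primer-extension reaction (excess trap duplex prevents a
dissociated polymerase from rebinding) produces a cDNA length distribution.
Products carry a 5′-end-labeled primer, so lane intensity is proportional to
*molecule count*, not to product mass; intensities are therefore never
length-normalized (a normalization switch exists for body-labeled designs
but defaults off).

### Background subtraction

The rolling-ball background of a 1-D lane trace is the upper envelope of a
disc of radius *r* rolled beneath the curve — equivalently, grayscale
opening with the semicircular structuring element b(u) = √(r² − u²),
|u| ≤ r, with r in pixels = radius_µm / pixel_pitch_µm. It is computed with
`scipy.ndimage.grey_opening` (edge-extended borders, `mode="nearest"`) and
asserted in tests against an independently written brute-force
erosion/dilation oracle. Guaranteed properties: background ≤ profile and
corrected ≥ 0 pointwise; adding a constant offset moves the background, not
the corrected signal; the operator is idempotent on its own background.

The radius must be at least one pixel pitch (the scanner's resolution
floor, default 100 µm). For a clean separation the radius should also be
well above the band width: opening removes only features narrower than the
element, so a radius comparable to the band width lets the ball climb into
the bands themselves. A linear background (constant + ramp) is preserved
exactly by the opening at any radius, which is what makes the round-trip
recovery in the tests exact to well under a pixel.

### Ladder calibration and the median

Electrophoretic mobility is modeled as log-linear: log10(length) =
a·pixel + c, fitted by ordinary least squares over the ladder band table
(≥ 2 distinct pixels required; R² reported). The macroscopic processivity is
the pixel where cumulative corrected intensity crosses 50% of the regional
total, interpolated linearly within the crossing pixel (a pixel *i* spans
[i − ½, i + ½] with uniform density; an exact-boundary crossing followed by
a zero-weight plateau resolves to the plateau midpoint), then mapped through
the calibration. Sub-pixel interpolation is the default; it makes the
median of a symmetric band exactly its center.

### Dissociation model

With expected full-length product L and measured median m:

    f  = (L − m) / L          incomplete fraction
    p  = f / L                per-nucleotide dissociation probability
    1 − p                     per-nucleotide processivity
    N50 = 0.5 / p             uniform ("evenly distributed") approximation
    N50* = ln 2 / (−ln(1−p))  exact geometric survival

The link from the median to the incomplete fraction via (L − m)/L is a
modeling heuristic, not a derived statistic: it treats the shortfall of the
median from full length as the fraction of early-terminating extensions.
The package reproduces it as the canonical chain because it is
self-consistent with the uniform model downstream, and reports the
geometric-survival N50 alongside (always ≥ the uniform value; the two agree
to first order in p). m = L yields p = 0 and flagged-undefined N50s.
`N50_uniform · p = 0.5` holds exactly for every p > 0. When calibration
noise pushes a measured median marginally past L, the reported median keeps
the raw value while the model chain clamps at L (f ≥ 0).

Lane-level ratios follow directly from corrected intensities: full-length
fraction = signal in the full-length band window / total product signal
(window defaulting to µ ± 3σ of a Gaussian fitted to the terminal band,
overridable by explicit pixel bounds), and primer incorporation efficiency =
extended / (extended + unincorporated primer), with fold changes taken
against a reference efficiency. Replicate aggregation reports per-statistic
mean and sample standard deviation (n − 1; omitted for n = 1).

## 2. Dual-UMI consensus misincorporation analysis

### Library design assumed

Each RT product carries a 15-nt random UMI at both ends plus condition
barcodes (4 nt on the R1 side, 3 nt on the R2 side). The combined 30-nt key
space, 4³⁰ ≈ 1.15 × 10¹⁸, dwarfs any library size (a lab-scale 0.2 pmol of
template is ~1.2 × 10¹¹ molecules), so distinct molecules essentially never
collide. R1 reads barcode → UMI → template-proximal sequence from the
reference start; R2 reads the opposite strand from the reference end. The
read-out order (barcode before UMI) is configurable; both mates' analysis
windows are disjoint reference intervals given in the configuration, since
the trimming arithmetic of any particular sequencing layout is a property
of that run, not of the method.

### Pipeline order and rules

1. barcode/UMI extraction (optional whitelist; short reads routed out);
2. trimming to the configured windows (read-coordinate slices, R2
   reverse-complemented onto the reference);
3. whole-read quality filter: a pair is discarded if **any retained base**
   of either mate has Q < 20 (Q = 20 itself is kept — the rule is strictly
   "lower than"); never per-base masking;
4. grouping by exact combined-UMI identity (no error-tolerant clustering;
   reads whose UMI was miscalled by the sequencer found spurious singleton
   groups, which the next step removes);
5. groups with ≥ 3 read pairs qualify; unique products (pre-filter) and
   qualifying products (post-filter) are both reported;
6. every member window is globally aligned to its reference window
   (Needleman–Wunsch with affine gaps: match +1, mismatch −2, gap open −4,
   gap extend −1; deterministic tie-breaks; indels left-normalized);
7. a call is emitted only when the identical change — same position, type
   and alternative allele — appears in every member; PCR and sequencer
   errors, private to a subset of reads, are rejected by construction.

Substitution frequency = substituted nt / (qualifying products × nt per
product); indel frequency = indel events / qualifying products, reported as
not-determinable when zero events are observed. A "naive" comparator — the
bulk per-read mismatch frequency over all surviving window reads, with no
UMI collapsing — is computed alongside to quantify the bias the consensus
removes.

### Window-edge artifacts

Because trimming is by read coordinates, a true indel inside a window
shifts the remainder of that fixed-length slice. A global end-to-end
alignment must absorb the shift at the window edge away from the read's
anchored end: typically a spurious indel at that edge, or — when the indel
sits within a few nt of the edge — one or two shifted substitutions there.
Indel calls whose placement (under repeat equivalence) can reach the
unanchored edge are suppressed as unresolvable artifacts; edge-adjacent
shifted substitutions are rare (they require an indel within ~2 nt of the
edge) and are left in, as suppressing genuine substitutions at those
positions would bias the estimator. At realistic indel rates (≤ 10⁻⁵ per
nt) the residual effect on the substitution frequency is orders of
magnitude below its sampling error.

### Estimator properties (verified in tests)

- group sizes always partition the surviving pairs;
- the consensus estimate with min_reads = 3 is ≤ the min_reads = 1 estimate
  on libraries containing sequencing errors (singleton groups pass the
  all-reads-agree rule vacuously and absorb sequencer noise);
- over seeded replicates at a true substitution rate of 1 × 10⁻⁴ with
  sequencing errors at 1 × 10⁻³, the pooled consensus estimate stays within
  3 binomial SE of the truth while the naive estimate does not;
- a mild downward bias exists because a sequencing miscall at the site of a
  true RT error in any single member breaks unanimity; with group size g it
  is ≈ g × seq_error_rate relative (≈ 2–3% at the default study scale),
  well inside the sampling tolerance.

## 3. Synthetic data: what it emulates, what it does not

The generator reproduces the features the analyses are sensitive to:

- **RT errors**: per-position Bernoulli substitutions (wrong base uniform
  over the three alternatives) and indels (event rate split evenly between
  single-base insertion and deletion), recorded as ground truth per
  molecule. Defaults: substitutions 1 × 10⁻⁴, indels 1 × 10⁻⁵ (an order of
  magnitude below, consistent with indels being unobserved at these depths).
- **PCR subclonal structure**: the first `explicit_tree_depth` cycles
  (default 6) are simulated as an explicit branching lineage — duplication
  with probability `pcr_efficiency` per cycle, per-copy substitution errors
  at `pcr_error_rate`, inherited by exactly the copy's descendants. An
  error at cycle c under full efficiency reaches a 2⁻ᶜ fraction of the
  molecule's final amplicons, which is precisely the structure the
  consensus rule must reject. Later cycles (to the default 23 = 10 + 13)
  are folded into read-private errors applied per sampled pair: an error
  from cycle c > depth is carried by ≤ 2⁻⁷ of reads, so its chance of
  surviving a ≥3-read consensus is negligible and full 2²³-leaf simulation
  is unnecessary. Efficiency (0.9) and per-cycle error rate (5 × 10⁻⁷,
  a proofreading-polymerase scale) are package defaults, configurable.
- **Sequencing**: pairs sampled with replacement from the leaf pool
  (PCR-jackpot overdispersion of family sizes arises naturally), per-base
  miscalls at 1 × 10⁻³, and a two-level quality mixture: with probability
  0.02 a read is low-quality (all bases Q15), otherwise Q40. Only the
  below/above-Q20 split matters to the pipeline, so the mixture is applied
  per read; a per-base mixture at any appreciable rate would interact with
  the whole-read filter to discard nearly all long reads, which is not the
  attrition pattern the assay design anticipates.
- **Gel lanes**: bands as Gaussians centered at pixel
  (log10(L) − c)/a under a known log-linear calibration, constant + ramp
  background, additive Gaussian noise, plus a 10-band ladder lane and band
  table. Termination lengths follow the truncated geometric law
  P(k = j) = p(1 − p)ʲ for j < E, P(k = E) = (1 − p)ᴱ.

Not modeled (out of scope): adapter chemistry, GC- or position-dependent
error profiles, insert-size variation, polymerase context effects, lane
smiling or 2-D gel geometry. Passing recovery tests therefore demonstrate
correctness of the estimators under their stated error model, not
robustness to instrument-specific systematics of real data.

All randomness derives from one seed; per-molecule sub-streams come from
(seed, molecule_id), so identical configurations give byte-identical FASTQ
and profiles.

### Problem sizes used in the checks

The full-scale recovery check runs the generator's default study scale:
2,000 molecules and 60,000 read pairs over a 260-nt window (≈ 520,000
consensus nucleotides, ≈ 52 expected true substitutions). The replicate
invariant uses 12 seeded replicates at 300 molecules / 6,000 pairs. The
termination-law check draws 10⁶ lengths; the densitometry round trip uses
10⁵ molecules on a 1,200-pixel lane. These sizes put 3-SE assertions well
inside detectable-effect territory while keeping the suite fast.

## 4. Alignment details

The aligner is a three-state Gotoh dynamic program (match/mismatch, gap in
reference, gap in query) with gap(k) = open + (k − 1)·extend. Tie-breaks:
prefer a (mis)match column over a gap, a deletion over an insertion, and
extending an open gap over opening a new one; after traceback, indels are
shifted to their upstream-most equivalent position, so repeat-embedded
indels have canonical coordinates across reads. `N` never matches (scored
as mismatch) and N-containing alternatives are never called. Scores are
verified against an independent plain dynamic program, exhaustive
enumeration of all alignments at tiny lengths, and Biopython's
`PairwiseAligner` under the same scheme.

For the equal-length read/window pairs that dominate real libraries, the
diagonal (gap-free) alignment is provably optimal whenever there are at
most two mismatches under the default scores — regaining two mismatches is
worth at most 6 while the cheapest gap pair costs 8 — so such pairs skip
the dynamic program entirely; a property test asserts the fast path is
output-identical to the full alignment. Within a UMI group, one exact-match
member empties the consensus set immediately, so alignment effort
concentrates on the rare groups that can actually produce calls.

## 5. Known limitations

- The (L − m)/L incomplete-fraction heuristic is reproduced, not derived;
  median-based estimation of p is coarse when p is small relative to the
  gel's length resolution (a sub-pixel shift of the median moves p
  substantially), so per-nucleotide processivity figures close to 100%
  should be read as order-of-magnitude statements.
- Consensus calling trusts exact UMI identity; template switching or UMI
  collisions (negligible at 4³⁰) are not modeled. An optional Hamming-1 UMI
  collapse exists but defaults off.
- Indel frequency is reported per product, so it is not directly comparable
  across configurations with different window sizes.
- Fixed-length trimming produces the window-edge effects described above;
  window coordinates are configuration, and analyses comparing enzymes
  should hold them fixed.
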