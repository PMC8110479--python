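# Methods

This note documents the models, algorithms and parameter choices behind
each module, what the synthetic-data generator does and does not emulate,
and the numerical decisions a user should know before trusting a result.

## Data model and conventions

All internal coordinates are 0-based half-open.  GFF3 and pairs files
(1-based) are converted at the I/O boundary and restored on write.  A
`ContactMatrix` stores raw symmetric counts plus one multiplicative
balancing weight per bin (NaN = masked); balanced values are produced
lazily as `counts[i,j]·w[i]·w[j]`, so raw and corrected views coexist.
Binned matrices round-trip through a single-resolution cooler-schema HDF5
container (written with h5py) and through a plain-text triplet dialect
(`bin1_id  bin2_id  count` with a bin-table sidecar) so no test requires a
binary file.

## Iterative correction

`ice_balance` equalises bin marginals by repeated division with the
normalised marginal vector, declaring convergence when the coefficient of
variation of unmasked marginals falls below `tol` (default 1e-5; typical
desk-scale matrices converge in 200–400 sparse matrix–vector products).
Masking is one-sided: bins with zero marginal, or marginals more than
`mad_filter` (default 5) median absolute deviations *below* the median,
are excluded.  High-coverage bins are deliberately kept — in this genome
elevated coverage is signal (terminal-domain compaction, high-copy
repeats), and a two-sided filter was observed to mask entire telomeric
regions.  Weights are scaled so the mean balanced marginal is 1; masked
bins surface as NaN in every dense view and are ignored downstream.

## Insulation and boundary calling

The insulation score of bin *i* with window *W* (default 500 kb at 10-kb
bins) is the mean balanced contact over the square `[i−w, i) × (i, i+w]`,
computed with extended-precision (80-bit) integral images — plain float64
prefix sums lose ~1e-11 relative accuracy to cancellation on large
windows.  Windows more than half masked, and bins within one window of a
chromosome end, are undefined; chromosomes shorter than `2W + resolution`
yield empty profiles.  Scores are log2-normalised by the chromosome mean
(not genome mean), so profiles from chromosomes of different overall
contact level are comparable.

Boundaries are called on the delta vector — mean score over
`(i, i+delta_span]` minus mean over `[i−delta_span, i)`, span default
100 kb — at downward-to-upward zero crossings; of the two crossing bins
the more insulated one is reported.  Strength is the delta height between
the nearest flanking local extrema; candidates below `strength_min`
(default 0.2) are dropped.  Refinement snaps each call to the insulation
minimum within ±2 bins, keeping the original position on ties.  The
contiguity flag extends each 10-kb boundary by 10 kb on each side and
requires no run of 24 or more consecutive Ns in that 30-kb window;
missing sequence leaves the flag undefined rather than dropping the call.

On expectation-level single-boundary matrices, balancing induces broad
shallow bowls near the defined-profile edges whose candidate strengths sit
right at ~0.2; the default floor keeps them out of sampled-data call sets,
but users lowering `strength_min` should expect such edge candidates.

## Contact-probability scaling

`ps_from_pairs` bins cis separations geometrically (factor 2^(1/8)) and
normalises each bin's count by the number of possible locus pairs at that
separation, `Σ_chrom ∫(L−s) ds`, which prevents long chromosomes from
dominating.  The exponent is the log–log regression slope over a stated
fit range (default 50 kb to 2 Mb; analyses at a scaled-down cutoff use
50 kb to 0.8·d_max).  `segment_regimes` fits a continuous piecewise-linear
model in log–log space by exhaustive knot search, collapsing to a single
slope when two knots improve the fit by less than 5%.  The rod cutoff is
located separately by `detect_drop`, the midpoint of the adjacent bins
with the steepest discrete slope: the geometric bin containing a hard
truncation mixes suppressed and unsuppressed separations, which biases
piecewise-fit knots one to two bins off the cutoff, while the derivative
extremum stays within a bin.  The short-range regime (a few kb, dominated
in real libraries by uninformative ligation products) is reported but
excluded from regime-II fitting.

Per-domain-square curves are per-diagonal means of balanced entries over
the grid of squares defined by the boundary set at 50-kb bins; squares off
the main diagonal lose their single-cell extreme diagonals, and squares
smaller than 3×3 bins are skipped.  The inter-domain gap shift is a grid
search (default step 50 kb up to 2 Mb) minimising the squared difference
of log10 P against the log-interpolated reference; an optimum at the grid
limit is flagged censored.

`terminal_vs_internal` compares mean per-diagonal contact (s up to 1 Mb)
of each chromosome's first and last domains against its internal domains,
averaging the ratio over chromosomes with at least three domains.  It uses
raw counts by default: iterative correction equalises per-bin coverage and
therefore removes most of a genuine uniform compaction difference between
regions; on the generator (which has no technical coverage bias) raw
per-diagonal means are the unbiased estimator.  With real data the flag
`use_balanced=True` is available but will understate the ratio.

## Karyotyping and scaffolding

The pair statistic is the mean balanced trans contact per bin pair (mean,
not sum, so scaffold length does not dominate).  Because contacts vanish
beyond one rod length, chromosomes are contact *chains*: two scaffolds of
the same chromosome more than d_max apart share almost no direct contact,
and clustering the raw pair statistic fails.  Scaffolds are therefore
clustered by the Pearson correlation of their log mean-contact profiles
(average linkage), which propagates membership transitively along the
chain; k is taken from the largest merge-height gap or given explicitly
(the realistic usage when the chromosome count is known).  A scaffold
whose second-best cluster affinity exceeds `ambiguity_ratio` (default
0.35) of its best, or whose best affinity is below 5% of the cohort
median (no informative linkage — typical when a scaffold's chromosomal
neighbours were themselves set aside), moves to the ambiguous set.
Scaffolds under 40 kb are excluded up front and reported separately.

Misjoin splitting assigns every bin of every scaffold to its
most-contacted cluster (own scaffold excluded), absorbs label runs
shorter than 3 bins, and cuts at the remaining change points; a change
point inside the terminal 3 bins produces no cut but flags the scaffold.
Ordering members are the resulting subscaffolds of one cluster, excluding
pieces under 5 bins (200 kb at 40-kb bins): junction slivers from the
±1-bin split uncertainty carry mixed signal and misplace easily.  The
order maximises `Σ log(contact(i,j) + ε) / |rank_i − rank_j|` by greedy
chaining from the strongest pair followed by 2-opt segment reversals and
single-element relocations; orientation compares each member's half-scaffold
contacts towards its neighbours, with confidence the normalised margin.
A whole-chromosome reversal is an unavoidable equivalence class — Hi-C
carries no global handedness — and a coverage gap longer than one rod
length splits a chromosome into components whose mutual arrangement is
likewise unidentifiable.

High-copy clusters are assigned to the chromosome with maximal mean
balanced contact (margin = best over runner-up), and relative copy number
is the median per-bin coverage of cluster bins over the median across
placed chromosomes (invariant under global rescaling of coverage).

## Gene architecture

Blocks are maximal runs of same-strand genes after deterministic sorting
(chromosome, start, end, id).  Orientation-change statistics count
opposite-strand adjacencies in sliding 10-gene windows against the exact
Binomial(9, ½) independent-orientation null (validated by enumeration).
Junction sites sit at the midpoint of the inter-block interval, flagged
when blocks overlap; with stranded expression supplied, a block qualifies
when its own strand carries at least half of the expressed base pairs in
its span (a strand-share test — transcribed gene bodies cover only ~15%
of a block's span at realistic spacing, so an absolute span-coverage
threshold would reject everything), and consecutive qualifying same-strand
blocks merge into expression blocks before junctions are called.

Track machinery: GC fraction over fixed windows ignoring Ns (undefined
when over half N); feature-centred profiles sample interval tracks in
100-bp (configurable) windows, mirror minus-oriented anchors and, for
stranded data, swap the two strands on mirrored anchors; telomere
profiles average both chromosome ends (right end mirrored) over
chromosomes of at least 5 Mb; correlations are Pearson over 100-kb bins
where all tracks are defined.

## Aggregate maps

The expected model is the per-chromosome per-diagonal mean of balanced
entries, smoothed by a 3-bin running mean in log space (a genome-pooled
variant exists; per-chromosome is the default).  Pileups stack obs/exp
submatrices (±500 kb at 10-kb bins) over anchors, dropping anchors whose
window leaves the chromosome, mirroring minus-oriented anchors, and
averaging obs/exp *linearly* across anchors per cell before taking log10
(floored at 1e-4, cells with under 10 contributing anchors undefined).
Linear averaging is deliberate: at desk-scale depth individual cells hold
Poisson counts with mean near 1, and averaging logs of floored per-anchor
ratios is dominated by empty cells, whereas the mean ratio is unbiased.
Condition contrasts are elementwise log2 ratios of the linear pileups.

The cross-boundary quadrant of a boundary pileup is *not* expected to
equal the planted attenuation exactly: the distance-expected denominator
already contains the attenuated crossing pairs (raising obs/exp by
~1/(1 − (1−β)·s̄/D) for boundary spacing D), and balancing lifts
boundary-adjacent bins whose marginals the attenuation depressed.  At the
default geometry these biases total ≈ +0.08 in log10.  Tests therefore
score the sampled pileup against the expectation-level pileup — the same
truth pushed through the identical pipeline via
`simulate.expected_contact_matrix`, which isolates estimator behaviour
from sampling noise — and the two agree to ~0.03 log10.

## The synthetic-data generator

`SyntheticSpec` defaults define the desk-scale study conditions used
throughout the tests: 4 chromosomes of 8–12 Mb (40 Mb total), planted
boundary spacing ~2.5 Mb (so each chromosome holds at least three domains
and ±500-kb pileups rarely span two boundaries), decay exponent −0.4,
rod cutoff d_max 1 Mb (3 Mb at full scale), boundary attenuation β = 0.5,
terminal compaction τ = 2, divergent stripe factor 3, 2% trans pairs, and
10⁶ pairs.  One full desk run (genome, contacts, binning, balancing,
insulation) takes under 10 s on one CPU; every generator is byte-stable
under its seed.

Contact sampling is vectorised thinning: separations are drawn by inverse
CDF from the truncated power law (hard suppression ×0.01 beyond d_max,
matching a nonzero long-range plateau rather than zero), plus a steep
short-range component standing in for uninformative ligation products;
candidates are then accepted with probability proportional to
`(L−s)/L · β^crossings · compaction · stripe`.  The `(L−s)/L` factor
makes the density per locus pair exactly `s^α` (sampling s first and
placing uniformly would otherwise leave `s^α/(L−s)` and bias the fitted
exponent by ≈ +0.03).  Three modelling choices matter for realism:

* **Telomeric compaction is a smooth ramp**, a logistic of position
  centred on the outermost boundaries (scale 50 kb), applied as
  √(c(x₁)c(x₂)) at separations up to 1 Mb.  A hard per-domain factor is
  itself a contact step — i.e. an insulation boundary — and would survive
  the transcription-blocked condition; the ramp leaves the treated maps
  boundary-free while the terminal/internal ratio still recovers ≈ τ
  (1.97 measured for τ = 2, the edge of the ramp costing a few percent).
* **Divergent-anchored stripes act only beyond 100 kb.**  A stripe
  multiplying all separations is a rank-one per-bin factor that iterative
  correction removes exactly; restricted to longer range, the corrected
  map shows the intended phenotype — enriched stripe arms plus a
  short-range depletion at the anchor — though the post-correction
  enrichment is necessarily smaller than the generating factor.
* **Gene layout is junction-aware.**  Blocks alternate strand with
  geometric sizes (mean 9), never straddle a boundary or bidirectional
  locus, and a block ending against a junction on the antisense strand is
  flipped to sense, so expressed transcription converges exactly at
  boundaries and diverges exactly at bidirectional loci.  Genes are sense
  (expressible) when their strand matches their domain half; expression
  levels are log-normal with a silent fraction.

Fragmentation cuts chromosomes into scaffolds of 0.5–1.5× the target
N50, concatenates cross-chromosome chimeras at the misjoin rate,
optionally reverse-complements fragments, and records every junction and
orientation; an inert-spacer option inserts contact-dead sequence between
domains for gap-shift scoring.  High-copy repeat families live on their
own scaffolds with multiple insertion sites on a home chromosome, a
diffuse multi-chromosome contact background, and proportionally elevated
coverage.

What the generator does **not** emulate: sequence-level realism (codon
structure, splice sites, real repeat sequences), coverage and mappability
biases (so balancing is exercised only mildly), restriction-fragment
geometry, inter-cell heterogeneity, and compartment or loop-dot
structure.  Passing tests therefore demonstrate estimator correctness on
an idealised rod-chromosome contact model, not robustness to every
artefact of a real library.

## Problem sizes and study conditions

Tests and the acceptance script run the desk profile (40 Mb, 10⁶ pairs,
5 seeds for boundary and scaling studies, 3 seeds for assembly studies).
The karyotype study uses the full-scale 3-Mb rod cutoff with 8×5-Mb
chromosomes and ~500-kb scaffolds: the ratio of contact range to scaffold
size sets how many neighbours each scaffold links to, and the assembly
problem is only faithful at the realistic ratio (at a 1-Mb cutoff each
scaffold sees ~2 neighbours and chain clustering becomes ill-posed in a
way the real data is not).  The *P(s)* studies report both the scaled
(1-Mb) and full-scale (3-Mb) cutoff recoveries.

## Known limitations

* Auto-selection of the cluster count k from merge-height gaps is
  reliable on clean chains but degrades when high-copy repeat scaffolds
  participate in clustering; set-aside material should be excluded first
  or k given explicitly.
* Exact reproduction of curated boundary/site counts from real data is
  out of reach by construction: published counts of this kind depend on
  manual curation steps that have no algorithmic definition here.
* `segment_regimes` assumes at most three log-linear regimes between the
  fitted knots; curves with gradual curvature get nearest piecewise
  approximations, and the knot near a hard truncation is biased (use
  `detect_drop` for the cutoff).
* The divergent-stripe enrichment observable after balancing depends on
  the stripe's separation band; only its sign and ordering are stable
  observables, not its magnitude.
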