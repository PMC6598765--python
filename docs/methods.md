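# Methods

## Calibration model

CUT&RUN yields fragments from up to three genomes per sample: the primary
genome under study, an optional heterologous spike-in added in constant
amount per sample, and *E. coli* DNA carried over from fusion-protein
purification. Because a constant number of antibody-coated beads is used
per sample, the carry-over DNA input is constant across a series; the
*sequenced* carry-over count then scales only with the sample's technical
depth (library recovery and sequencing allocation). Dividing signal by the
carry-over count therefore cancels technical depth while preserving
biological differences — the same logic as a deliberate spike-in, available
post hoc.

The calibration factor is `factor = multiplier / calib_count` with
`calib_count` the spike-in or carry-over fragment count (config `mode`) and
`multiplier` a positive display scale, default 10,000. The multiplier is
dimensionless and cancels from any between-sample comparison; it only sets
the magnitude of calibrated values. Zero calibration counts are an error,
not a silent NaN: a sample without spike-in simply cannot be calibrated in
spike-in mode (it usually still can in carry-over mode).

Concordance between the two candidate calibrants is summarized as Pearson's
*r* on raw (untransformed) counts per condition group. Raw-count Pearson
reproduces the published per-protocol values of the reference table
(0.92, 0.99, 0.94, 0.90) at two decimals; a log-scale variant was
considered and rejected because the reference values are matched by the
raw-count statistic. Groups need ≥ 3 samples and nonzero variance in both
vectors; degenerate groups yield NaN with a warning. Fragments (mapped
pairs), not reads, are the counting unit throughout.

## (TA)n masking

Some libraries contain contaminating reads of alternating T/A sequence.
The masking module finds all *maximal* strictly alternating T/A runs of at
least `min_run_length` bp (default 25, the length of a (TA)12T query) in a
genome, merges them, and removes fragments overlapping any such region by
≥ 1 bp. The scanner is exact: case-insensitive, both phases (TA… and AT…),
with N and any non-T/A base terminating a run. An alignment-based search
with the same query would admit imperfect matches and return somewhat more
regions; the exact scanner is deterministic, dependency-free and
conservative, so genome-wide region counts from alignment-based searches
are not comparable targets.

## Coverage normalization

`fragment_depth` produces run-length-encoded per-bp fragment depth.
`fractional_count_track` rescales it by `G / Σ_y depth(y)` where `G` is the
genome size and the denominator is the summed per-bp depth (total fragment
base pairs). With this reading the base-pair-weighted genome-wide mean is
exactly 1 and uniformly distributed coverage maps to 1 at every base pair —
the property that defines the normalization. Normalizing by fragment
*count* instead would not have that property for finite-length fragments.
No mappability or GC correction is applied. Zero-valued runs are implicit
and omitted from bedGraph output; values are printed with 5 significant
digits, integers without a trailing `.0`.

## Peak QC

Peak scores are arithmetic means of track values over the inclusive window
`[summit − flank, summit + flank]` (2·flank + 1 bp, default 301),
truncated at chromosome ends, with uncovered base pairs counted as zero.
The zero-fill choice (rather than treating uncovered bases as missing)
matches the bedGraph convention that absent intervals are zero coverage.

The IgG filter computes the configured percentile (default 99) of all
IgG-control peak scores by linear interpolation between order statistics —
the convention of mainstream statistical environments — and removes peaks
with scores *strictly greater* than that threshold. On scores 1…100 the
99th percentile is 99.01 and exactly the maximum-score peak is removed;
with all-equal scores nothing is removed.

Correlation matrices use the complete-rows policy: any peak row with a
missing entry in any sample is dropped before *all* pairwise correlations
(not pairwise-complete deletion), mirroring `cor(m, use="complete.obs")`.
R² is the square of Pearson's r, so it is invariant to positive affine
rescaling of any column — calibration scaling cannot change it, which is
asserted as a property test.

FRiP counts fragments overlapping ≥ 1 peak by ≥ 1 bp, divided by total
fragments; it is invariant to peak order and to merging overlapping peaks.
The down-sampling series draws each depth independently from the full set
with a seeded PRNG (a `nested=True` option subsamples each depth from the
previous one instead; independent draws are the default as the simpler
reading, and the two agree in expectation).

## Interval conventions

BED convention everywhere: 0-based half-open intervals; overlap requires at
least one shared base pair, so book-ended intervals do not overlap but *do*
merge (bedtools-merge semantics). Strand is ignored. Duplicate fragments
are kept — pooling is a multiset union and no deduplication step is
exposed. Sampling without replacement uses NumPy's PCG64 generator over the
sorted fragment index with an explicit required seed; there is no hidden
global random state.

## Synthetic experiments

The simulator emulates a multi-sample, three-genome experiment on toy
genomes (defaults: 1 Mb primary, 100 kb spike-in, 100 kb carry-over; all
sizes configurable). Per sample `i`:

- `N_i ~ Poisson(primary_depth_i · d_i · yield_i)` primary fragments,
- `S_i ~ Poisson(spike_rate · d_i)` spike-in fragments,
- `C_i ~ Poisson(carryover_rate · d_i)` carry-over fragments,

where `d_i` is a per-sample *technical depth factor* (sequencing/recovery
depth) and `yield_i` an optional *biological* yield multiplier (digestion
time-course) applied to the primary genome only. Modeling the spike-in and
carry-over *amounts* as constant while letting sequenced counts scale with
`d_i` is what the constant-bead mechanism implies, and it is exactly what
makes the carry-over a valid calibrant: with purely independent Poisson
counts the across-sample concordance would be ~0 and calibration would
correct nothing.

Primary fragments are a mixture: with probability `contamination_rate` a
premature-release artifact; otherwise uniform background with probability
`background_rate` (default 0.2); otherwise peak-derived, the peak chosen
with probability proportional to enrichment × length and the fragment
midpoint uniform within the peak. Premature release digests accessible
DNA — which includes the marked peak regions themselves — with per-site
intensity varying stochastically between samples because release timing is
uncontrolled; artifact fragments are therefore drawn half uniformly over
the genome and half from the peak regions under per-sample
Dirichlet-random site weights. This is the mechanism by which the
standard-protocol arm of a simulated time course shows degraded
between-sample peak-vector R² relative to the high-calcium/low-salt
(zero-contamination) arm.

Fragment lengths are truncated normal, mean 150 / sd 30 bp (nucleosomal
scale), floored at 20 bp; positions are placed by midpoint and clipped to
chromosome bounds. Default peak sets are 30 non-overlapping 1 kb intervals
with lognormal enrichment folds around 20 (log-sd 0.6) — heterogeneous
peak strengths keep peak-vector correlations informative. Everything is
reproducible from `(seed, sample_index)` via NumPy `SeedSequence`.

Canonical scenarios:

- `SimConfig.depth_series`: 20 samples, technical depth spanning 100-fold
  (geometric), base primary depth 5,000 expected fragments, spike rate
  1,000, carry-over rate 3,000 — a calibration-series design with constant
  biology.
- `SimConfig.timecourse`: yields (1, 2, 4, 8, 16) over base depth 1,000 —
  an increasing-yield digestion series; `contamination_rate` 0 models the
  high-calcium/low-salt protocol and 0.3 the standard protocol. No
  quantitative time→yield law is claimed; yields are free configuration.

These problem sizes (1 Mb genomes, 10³–10⁵ fragments per sample) were
chosen as the smallest scale at which peak enrichment, Poisson count noise
and calibration behave as in genome-scale data while a full simulated
series runs in seconds.

### What the simulator does and does not capture

It captures: multi-genome count composition, technical-depth confounding
and its removal by calibration, peak enrichment over background, Poisson
sampling noise, low-complexity (TA)n runs (optional implants in generated
sequences), and protocol-dependent background contamination. It does not
capture: read-level sequence errors or alignment ambiguity, cross-mapping
between genomes, mappability/GC structure, antibody-efficiency or
digestion-kinetics biochemistry, or duplicate-fragment artifacts. Passing
tests therefore demonstrate the correctness and statistical behavior of
the computations, not performance on any particular real dataset.

## Numerical choices and degenerate inputs

- Percentiles: NumPy `method="linear"` interpolation.
- Conservation of the fractional-count mean is asserted to 1e-9 (float64
  accumulation over ≤ 10⁶ bp is far more accurate than that).
- Coverage tracks are canonicalized on construction: zero runs dropped,
  book-ended equal-value runs coalesced; overlapping runs are an error.
- Empty inputs error loudly (empty chrom.sizes, empty IgG score list,
  empty fragment set for FRiP, all-zero depth for normalization) rather
  than returning NaN.
- Correlation of a zero-variance column is reported as NaN with a warning,
  never as 0 or 1.

## Known limitations

- Fragments are consumed as BED; BAM/BEDPE extraction is upstream.
- Peak calling is out of scope; peaks with summits are inputs.
- The (TA)n scanner's exact-run definition is deliberately narrower than an
  alignment-based search with the same query.
- The concordance diagnostic assumes ≥ 3 samples per group and constant
  bead input per sample; violations surface as warnings, not corrections.
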