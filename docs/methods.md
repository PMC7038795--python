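# Methods

This note documents the models behind `lbcmap`, the defaults that matter, and
the choices made where the design was genuinely open.

## Coordinate contract

All coordinates are 0-based half-open `[start, end)` (BED-native); lengths
are `end − start`. Empty intervals are rejected everywhere. Input dialects
that are 1-based are out of scope; converting on ingest is the caller's
responsibility.

## Border calling

**Model.** The mapped reads of a dissected chromomere are approximately a
homogeneous Poisson process over the chromomere's genomic span (rate
λ₁ ≈ depth/span), superimposed on a much sparser background: amplification
contamination mapping anywhere on the chromosome and spillover reads mapping
into the adjacent chromomeres (rate λ₀ ≪ λ₁ near the cluster). The analysis
has three steps:

1. **Gap clustering.** Reads are sorted by start (exact-coordinate duplicates
   collapsed first — DOP-PCR copies); a new cluster begins whenever
   `start − previous end` exceeds `gap_threshold` (default 1 Mb: below the
   smallest expected chromomere of 1.5 Mb, far above read spacing at any
   useful depth). This is exactly equivalent to selecting maximal gap-free
   runs, and `split_into_clusters`/`call_borders` (with exclusion disabled)
   are tested for identity against a brute-force oracle that enumerates all
   contiguous subsequences.
2. **Main-cluster selection.** The cluster with the most reads wins; ties go
   to the leftmost cluster and mark the call ambiguous. A call is also
   ambiguous when the main cluster holds < `min_main_fraction` (0.8) of the
   reads or any rival holds ≥ `second_cluster_max_fraction` (0.25). The
   ambiguity criteria are operational definitions — the notion of an
   "ambiguous border" has no canonical quantitative form — and both defaults
   are configuration, not biology.
3. **Distant-read exclusion.** Stray reads that fall within `gap_threshold`
   of the cluster hull chain into the main cluster and would otherwise drag a
   border outward by hundreds of kb. The exclusion implements the two-density
   MLE: for cluster-vs-background rates λ₁, λ₀, a contiguous run of reads
   maximizes its Poisson likelihood when each inter-read gap *g* contributes
   a score `1 − g/τ` with `τ = ln(λ₁/λ₀)/(λ₁ − λ₀) ≈ μ·ln(λ₁/λ₀)`
   (μ = mean spacing). `exclude_distant_reads` estimates μ from the central
   reads of the cluster (the outermost max(12, m/10) reads per side are left
   out — that is where stray reads sit), uses a fixed prior density ratio
   `background_ratio = 60` (≈ (0.93/0.07) × the flank-to-chromomere span
   ratio at the default noise rates), and keeps the maximum-scoring
   contiguous run around the cluster center. Distant single reads and sparse
   chains score negative and are dropped; a dense run of reads beyond even a
   large gap scores positive and is kept. Clusters under 20 reads are never
   trimmed — their spacing statistics carry no signal.

**Why not a pure fixed threshold?** With spillover reads uniform over a
1.5–3.5 Mb neighbor, the distance from the border to the nearest stray read
is far below any fixed threshold that also avoids splitting the true cluster
(an order-statistics argument: the true maximum intra-cluster spacing is
≈ μ·ln m, while stray reads arrive at rate ≈ 2/Mb next to the border), so a
fixed-threshold rule cannot keep border errors at the read-spacing scale.
The likelihood trim is scale-free and leaves borders within the maximum
intra-chromomere read spacing of the truth in ≳97% of noisy simulations at
depth 1000.

**Borders** are the extreme read coordinates of the retained main cluster —
no extrapolation beyond observed reads. Border precision is therefore limited
by local read spacing, i.e. by sequencing depth.

## Feature profiling

* Gene density: genes counted by **midpoint** membership, so a complete
  chromomere tiling counts every gene exactly once; density = count / size
  in Mb.
* Repeat content: covered-base fraction of the **union** of repeat intervals
  clipped to the chromomere — invariant under re-partitioning of the same
  repeat bases and never exceeding 1.
* Class labels (`gene_rich` / `repeat_rich` / `mixed`) come from thresholds
  (defaults: gene_rich ≥ 4 genes/Mb with repeats < 0.3; repeat_rich ≥ 0.3
  repeat fraction with ≤ 1 gene/Mb). These are reporting conveniences
  calibrated to the synthetic class profiles, not biological claims.
* Ambiguous calls are refused: a density over unreliable borders is itself
  unreliable.

## Domain comparison

* **Compartment fractions.** frac_A/frac_B are base overlaps with A/B blocks
  divided by chromomere length; frac_NA is the uncovered remainder; the three
  sum to 1 to 1e-9 by construction and the computation is tested against
  per-base label counting.
* **Border switches.** A switch point is a shared boundary of two abutting
  blocks with opposite labels; a boundary abutting an uncovered gap is not a
  switch. A border "sees" a switch when one lies in the closed window
  `[border − w, border + w]` (default w = 500 kb), clipped at the chromosome.
  The cohort proportion pools left and right borders:
  (# true indicators) / (2 × included chromomeres); per-side proportions are
  also reported. For an alternating profile with block length L and uniform
  borders the expected proportion is min(1, 2w/L) — used as an analytic
  oracle in the tests.
* **Fractional TAD counts.** A TAD wholly inside the chromomere counts 1; a
  TAD partially overlapping it — including a TAD that strictly contains it —
  counts 0.5; zero-length abutment at a shared half-open boundary is no
  overlap. This is the simplest rule that generates a half-integer scale
  with minimum 0.5 for any overlapped chromomere, and it is monotone: the
  count never decreases when the chromomere is extended.
* Summaries (mean/min/max per TAD set, switch proportions) are computed over
  non-ambiguous chromomeres unless `include_ambiguous` is set; with zero
  included chromomeres all summary statistics are NA and a warning is
  emitted.

## Synthetic data

What the generators emulate, and what they deliberately do not:

* **Chromomere map**: a gap-free left-to-right tiling; spans uniform in
  1.5–3.5 Mb (common) or 4–5 Mb (marker), marker probability 0.1 by default;
  the last chromomere is truncated at the chromosome end. Real chromomere
  maps are also exhaustive tilings of the dissected chromosome arm.
* **Dissection reads** (default depth 1000 per chromomere): start uniform in
  the chromomere; fragment length triangular (150, 200, 350) bp — the
  simplest law matching the library's observed range and mode; 2%
  contamination uniform over the chromosome; 5% spillover uniform over a
  random adjacent chromomere (mirroring the observed signal in neighbors);
  10% exact-position PCR duplicates. The noise rates are repository choices —
  no measured values exist — kept deliberately pessimistic for a purified
  library. Depth 1000 is a conservative figure for a pooled chip run; border
  precision scales with it.
* **Compartments**: alternating A/B blocks of a geometric number of 100 kb
  bins (mean 12 bins ≈ 1.2 Mb, the megabase scale of real compartments);
  all boundaries bin-aligned. Real profiles have long-range autocorrelation
  and chromosome-arm trends the geometric model lacks.
* **TAD sets**: gamma-distributed lengths (CV 0.4) with exponential boundary
  gaps; presets DI-like (mean 1.0 Mb, gap 50 kb) and Armatus-like (mean
  0.4 Mb, gap 10 kb), sized so a 2.5 Mb chromomere overlaps ≈ 2.5 and ≈ 6
  TADs respectively.
* **Annotations**: per chromomere, Poisson gene counts (common 5/Mb, marker
  0.5/Mb; genes 5–50 kb, non-overlapping) and repeats placed until a target
  covered fraction (common 0.1, marker 0.5; elements 0.5–5 kb) — final
  coverage lands within one element length of the target.

No sequence-level simulation (no bases, GC bias, mappability or aligner
artifacts): passing tests demonstrate the interval-level analysis logic, not
robustness to alignment pathology. All generators draw from
`numpy.random.default_rng(seed)`; nothing touches global random state.

## Pipeline and reproducibility

The pipeline derives one sub-seed per stage and per sample from the global
seed via `SeedSequence` spawn keys hashed with CRC32 (process-independent),
so adding a sample never changes earlier samples' data. Outputs are written
only after all stages succeed; failures carry the stage name. Report numerics
are fixed to 6 decimals and the run log contains no timestamps, making
identical config + seed runs byte-identical. Problem sizes in the test suite
and acceptance script (200 recovery replicates, 500 oracle instances, 500
cohort chromomeres, a 25 Mb fixture chromosome) were chosen as the smallest
cohorts at which the measured rates and means are stable to well within the
asserted bands.

## Known limitations

* Border calling assumes one dissected chromomere per sample; doublet
  dissections surface as ambiguous calls rather than two calls.
* The exclusion step's `background_ratio` is a prior, not an estimate from
  the sample; for real data with very different noise structure it may need
  adjustment (it enters only logarithmically).
* Compartment input must be non-overlapping per chromosome; overlapping
  eigenvector tracks must be resolved upstream.
* The comparison is descriptive (fractions, indicators, counts); it makes no
  statistical claim about boundary concordance beyond them.
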