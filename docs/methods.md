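# Methods

Scientific conventions, estimators and the synthetic-data model implemented
by `loopaxis`. Everything below is what the code does; numerical claims
about recovery quality are made only where the test suite computes them.

## Coordinates and formats

All intervals are 0-based, half-open `[start, end)` on named chromosomes
(BED convention). A `GenomeLayout` is an ordered list of
`(chromosome, length)` pairs read from a two-column TSV (faidx `.fai` files
are accepted; extra columns are ignored). `FeatureSet`s are kept sorted by
`(chromosome, start, end)` with optional float scores; BED3/BED6 and
10-column narrowPeak are read and written with line-precise error messages,
and writing is deterministic so identical data round-trips byte-for-byte.

## Interval algebra

- **Merge** with gap threshold `g`: two consecutive intervals are merged
  when they overlap or touch, or when the gap between them is strictly less
  than `g` base pairs. The strictness matters downstream: the peak cascade
  merges regions *closer than* 350 bp, so a 350-bp gap survives.
- **Intersect** returns the intervals of the first set that overlap the
  second at one or more bases; **subtract** removes covered bases, so an
  interval can be split into fragments (which inherit its score).
- **k-of-n consensus** returns maximal regions covered by at least `k` of
  `n` input sets, computed by a per-base event sweep over the merged inputs.
  With `k = 1` it equals the merged union. A site-level mode instead keeps
  whole intervals supported by at least `k` sets — appropriate when the
  unit of interest is the called site, not the base. The 2-of-3 consensus
  of Red1/Hop1/Rec8 ChIP calls is the standard definition of axis sites.

All four operations are validated against a per-base boolean oracle on
hundreds of randomized instances (`tests/test_acceptance.py`).

## Peak consolidation

ChIP peaks are typically called at several significance cutoffs (default
q-value cutoffs 0.05, 10⁻², 10⁻⁴) and in replicate. The cascade reduces
this redundancy:

1. **Minimal region**: pool all calls, group transitively overlapping peaks
   into connected components, and keep the shortest member of each
   component (ties broken by leftmost start, then input order). The
   shortest call is the most stringent localization of the shared signal.
2. **Merge** regions separated by less than 350 bp — fragments of one
   hotspot rather than distinct sites at typical inter-hotspot distances.
3. **t = 0 h removal**: peaks overlapping any peak called before meiotic
   induction are removed *whole*; a site with pre-induction signal is
   suspect in its entirety.
4. **Blacklist trim**: artifact regions (e.g. peaks in untagged or
   no-antibody controls, pooled and merged) are subtracted *by coordinate*;
   a real peak that brushes an artifact keeps its clean part.
5. **Length filter**: retain fragments strictly longer than 200 bp.

A `ConsolidationLog` records the count surviving each stage.

## Shuffle-null overlap tests

Spatial association between two feature sets is tested against a
constrained shuffle null: each interval of the query set is re-placed
uniformly at random (per chromosome by default, or genome-wide with
chromosomes chosen by length), keeping its length, avoiding a forbidden
set and avoiding overlap among placed intervals, by rejection sampling
(an interval that cannot be placed in 10 000 attempts raises an error
naming the chromosome). With `n` shuffles the empirical enrichment p-value
is

    p = (1 + #{shuffled overlap count ≥ real count}) / (n + 1),

mirrored for depletion, plus a Mann–Whitney rank test on per-interval
overlap indicators. With the conventional `n = 10` the smallest attainable
p is 1/11 and the statistic is discrete, so the reported p is
*conservative*: under the null it stochastically dominates Uniform(0, 1),
with ties contributing extra mass at high p. Calibration is therefore
assessed on the randomized tie-broken transform

    p* = (#{shuffled > real} + U · (1 + #{shuffled = real})) / (n + 1),
    U ~ Uniform(0, 1),

which is exactly Uniform(0, 1) if and only if the real count is
exchangeable with the shuffled counts. The acceptance suite verifies both
uniformity of p* (Kolmogorov–Smirnov over 500 independent null data sets)
and that the reported p always dominates p*.

## Signal-track numerics

- **BinnedTrack**: one float vector per chromosome at a fixed bin size
  (default 20 bp), NaN marking missing data. bedGraph input is rasterized
  with length-weighted averaging when record boundaries cross bins;
  uncovered bases count as 0. Output is run-length compressed and NaN bins
  are omitted, so write(read(x)) is byte-stable.
- **RPKM**: value × 10⁹ / (library size × bin width).
- **Background correction**: mean over signal replicates minus mean over
  control replicates, optionally floored at zero.
- **Hann smoothing**: an `M`-tap normalized Hann window,
  `w_j = 0.5 (1 − cos(2πj/(M−1)))` scaled to unit sum, with
  `M = round(window / bin)` forced odd so the filter is centered. At
  chromosome edges and next to NaN bins the kernel is renormalized over
  the available bins, so a constant track is an exact fixed point and the
  impulse response equals the closed-form kernel to machine precision.
  Typical windows for visual landscape comparison are 2.5–50 kb.
- **Pileups**: the mean track value in 20-bp offset bins within a flank of
  feature midpoints (midpoint = ⌊(start+end)/2⌋), averaging only features
  that contribute data at each offset; a heatmap variant keeps rows sorted
  by score. **Window quantification** averages (or sums) bins in a
  fixed-width window centered on each midpoint — 600 bp for hotspot-scale
  and 2 kb for axis-scale signal are common choices — and can exclude
  features whose window overlaps another set by at least a given fraction
  (default: exclude at ≥ 10 % overlap). **Percentile partitioning** uses
  rank-based equal-count bins (stable ranks, bin sizes differing by at
  most one); the "strongest 20 %" is deciles 8–9. **Windowed correlation**
  computes Pearson and Spearman coefficients between two tracks averaged
  in fixed windows (e.g. 100 bp) genome-wide, dropping windows where
  either track is missing.

## Double-cut interference

For two DSB sites cut in the same cell, interference is quantified from
Southern-blot band fractions of a physical fragment spanning both sites:

- `f1`: fraction of molecules cut at site 1 (single-cut band 1 plus, for
  short-range fragments, the double-cut species that co-migrate with it).
- `f2_raw`: fraction in single-cut band 2. On short-range blots double
  cuts are *lost* from this band (the double-cut fragment migrates
  elsewhere), so `f2_raw` underestimates the site-2 cut probability.
- `dc_central_raw`: double-cut signal at one central probe locus; with a
  probe detecting 1 of `m` equivalent double-cut species (default
  `m = 3`), the observed double-cut fraction is `DC_obs = m · dc_central_raw`.

The expected fraction under independence is `DC_exp = f1 · (f2_raw + DC_obs)`
for short-range fragments — adding the lost double cuts back into the
site-2 marginal — and `DC_exp = f1 · f2_raw` for mid-range fragments
(pulsed-field gels) where band 2 already contains them. Interference is

    I = 1 − DC_obs / DC_exp,

so I = 0 means independence, I → 1 means complete suppression of double
cutting, and I = −1 means double cuts occur at twice the independent
expectation (negative interference / concerted cutting). `I` is undefined
(NaN) when both observed and expected are zero.

Omitting the loss correction when it is needed biases the estimate
*downward*: at independence with cut probabilities `p1 = p2 = 0.1`, the
uncorrected expected value uses `f2_raw = p2(1 − p1)`, giving
`E[Î] ≈ 1 − 1/(1 − p1) = −p1/(1 − p1) ≈ −0.111` — a spurious signal of
negative interference. The cohort simulator reproduces this bias and the
test suite verifies both its direction and magnitude.

**Percent of input**: `%IP = 100 · q_ip / (q_input · D · V)` with dilution
factor `D = 20` and volume factor `V = 10` by default, matching the common
practice of quantifying a 1:20 input dilution and using a 10-fold larger
share of the IP than of the input.

## Synthetic-data model

The generator produces landscapes in which every downstream quantity has a
known ground truth. Defaults describe one fixed simulated condition; they are
chosen for biological plausibility, not tuned to any estimator.

**Genome**: 16 chromosomes totalling ~12 Mb with unequal lengths
(yeast-like scale).

**Features**: `n_hotspots = 3000` hotspots of width 190 bp (a nucleosome-
depleted promoter scale), placed uniformly per chromosome in proportion to
length, rejecting placements closer than `hotspot_min_separation = 1500` bp
to another hotspot — hotspots occupy distinct promoter NDRs, and without a
minimum separation the ±500 bp break-end kernels of neighboring hotspots
would overlap substantially, which is not the regime the quantification
windows are meant for. Per-cell cleavage strengths are log-normal
(log-mean ln 0.002, σ = 1.2, clipped at 0.15), spanning more than two
orders of magnitude as hotspot heat does. Axis sites (width 800 bp) are
quasi-periodic at ~15 kb spacing with ±3 kb jitter, and hotspots and axis
sites never overlap — loop versus axis locations are spatially distinct.

**ChIP tracks** (20-bp bins): expected coverage is background
(0.02 reads/bp) plus Gaussian kernels at feature midpoints; observed
counts are Poisson per bin. The kinase-like library (`tel1`) places two
kernels per hotspot at ±500 bp (`bimodal_offset`, sd 200 bp) — the two
resected break ends — plus broader axis-site kernels (sd 400 bp); the
nuclease-like library (`spo11`) places a single kernel at the midpoint
(sd 100 bp) with stronger axis signal; `untagged` and `t0` controls are
background only. Kernel gains (2000/3000 per unit strength) give ~1.8 M
reads per library, a realistic depth at which the bimodal structure of
strong hotspots is resolved at one-bin accuracy; at very shallow depth the
mode positions wander, which is a property of the data, not the estimator.

**Cohorts**: each cell's outcome at two sites is multinomial over
{no cut, site 1 only, site 2 only, double cut} with
`P(DC) = (1 − I) p1 p2` (checked for feasibility) and marginals preserved.
The measured `BlotQuant` applies the band-assignment rules above, with
double-cut loss from band 2 on (short-range) or off (mid-range).

**qPCR plates**: `q_ip = enrichment · q_input · D · V` with multiplicative
mean-1 log-normal noise (`σ² = ln(1 + cv²)`); at `cv = 0` percent-input
recovery is exact.

`simulate_all` writes a complete fixture directory — genome TSV, hotspot
and axis BED, four bedGraphs, cohort and plate tables and a `truth.json` —
deterministically: identical configurations produce byte-identical
directories.

### What the generator does and does not emulate

It emulates the *statistical structure* the estimators consume: feature
geometry, strength heterogeneity, kernel shapes, Poisson counting noise,
band-assignment conventions and plate noise. It does not emulate read
alignment, fragment-length effects, chromatin accessibility bias, copy-
number variation, replication timing, or any sequence-dependent effect;
tracks are generated directly in binned space.

## Limitations

- The shuffle null treats intervals as independent; clustered query sets
  make the test anti-conservative for clustering-driven associations.
- The empirical p with 10 shuffles cannot fall below 1/11; strong claims
  need more shuffles.
- The interference estimator is a plug-in ratio; no standard error is
  attached to a single blot. Replicate cohorts (as in the tests) are the
  intended route to uncertainty.
- Pileups average over features and do not model per-feature covariates;
  heatmap rows are provided for inspection instead.
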