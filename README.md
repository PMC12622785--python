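# loopaxis

Genomic-interval statistics and ChIP signal numerics for analyses of meiotic
DNA double-strand-break (DSB) hotspots and chromosome-axis sites in compact
genomes such as *Saccharomyces cerevisiae*, together with a synthetic-data
generator that produces complete, fully characterized test landscapes.

In meiosis, Spo11 cuts DNA preferentially at hotspots located in chromatin
loops, while axis proteins (Red1, Hop1, Rec8) occupy a distinct, roughly
periodic set of sites. Kinases such as Tel1 are recruited to the two ends of
a break, producing a bimodal ChIP footprint around hotspot midpoints, and
DSB formation at nearby sites can interfere. Analyzing such data requires a
small set of recurring primitives, which this package implements:

- **Interval algebra** (`loopaxis.intervals`) — BED/narrowPeak I/O on
  0-based half-open coordinates, merging with a gap threshold, intersection,
  subtraction, k-of-n multi-set consensus (e.g. sites called in at least 2
  of 3 axis-protein ChIP experiments) and overlap/Venn tabulation.
- **Peak consolidation** (`loopaxis.peaks`) — the cascade used to turn
  peak calls at several significance cutoffs into one clean set: reduce
  overlapping calls to the smallest "minimal region", merge regions closer
  than 350 bp, remove whole peaks present before induction (t = 0 h), trim
  coordinates overlapping a blacklist, and keep fragments longer than
  200 bp.
- **Signal tracks** (`loopaxis.tracks`) — binned coverage vectors with
  bedGraph I/O, RPKM normalization, background subtraction, Hann-window
  smoothing, average profiles ("pileups") around feature midpoints, heatmap
  matrices, fixed-width window quantification with overlap-based exclusion,
  rank-based percentile partitioning and genome-wide windowed correlation.
- **Interference statistics** (`loopaxis.interference`) — percent-of-input
  qPCR quantification with dilution/volume corrections, and the double-cut
  interference statistic I = 1 − DC_obs/DC_exp from Southern-blot band
  fractions, including the correction for double cuts lost from the
  single-cut band.
- **Synthetic data** (`loopaxis.simulate`) — a generator that plants
  hotspots and axis sites with known positions and strengths on a
  16-chromosome genome, draws Poisson read counts from bimodal (break-end)
  or unimodal kernels, simulates per-cell double-cut cohorts with tunable
  interference, and writes complete fixture directories deterministically.

See [docs/methods.md](docs/methods.md) for the scientific conventions,
estimators and generator model in detail.

## Worked example

Simulate a default landscape (16 chromosomes, ~12 Mb, 3 000 hotspots),
recover the planted structure and test hotspot/axis spatial exclusion:

```python
import numpy as np
from scipy import stats
from loopaxis import (SimConfig, simulate_features, simulate_chip_tracks,
                      pileup_profile, window_signal, partition_by_percentile,
                      overlap_significance, simulate_dsb_cohort,
                      interference_from_blot)

cfg = SimConfig(seed=11)
hotspots, axis = simulate_features(cfg)
sim = simulate_chip_tracks(cfg, hotspots, axis)

# bimodal Tel1 footprint around the strongest 20% of hotspots
top = hotspots.select(partition_by_percentile(hotspots.scores, 10) >= 8)
prof = pileup_profile(sim.tracks["tel1"], top, flank=5000, bin=20)
off, v = prof.offsets, prof.values
neg = off[off < 0][np.nanargmax(v[off < 0])]
pos = off[off > 0][np.nanargmax(v[off > 0])]
print(f"Tel1 modes at {neg:+d} / {pos:+d} bp around hotspot midpoints")

# 600-bp window quantification recovers the planted strengths
ws = window_signal(sim.tracks["tel1"], hotspots, 600)
ok = ~ws["value"].isna().to_numpy()
r = stats.pearsonr(ws["value"].to_numpy()[ok], hotspots.scores[ok]).statistic
print(f"600-bp window signal vs true strength: r = {r:.3f}")

# hotspots avoid axis sites: shuffle-null depletion test
res = overlap_significance(hotspots, axis, cfg.genome, n_shuffles=10, seed=1)
print(f"hotspot/axis overlaps: {res.real_count} real, "
      f"depletion p = {res.p_depletion:.3f}")

# double-cut interference from a simulated 100,000-cell cohort
cohort = simulate_dsb_cohort(100_000, 0.1, 0.1, 0.5, seed=2)
i_hat = interference_from_blot(cohort.measured).interference
print(f"interference estimate at true I = 0.5: {i_hat:.3f}")
```

Output:

```text
Tel1 modes at -510 / +510 bp around hotspot midpoints
600-bp window signal vs true strength: r = 0.985
hotspot/axis overlaps: 0 real, depletion p = 0.091
interference estimate at true I = 0.5: 0.492
```

The true break-end offset is ±500 bp; the pileup localizes both modes to
the adjacent 20-bp bin. With 10 constrained shuffles the smallest possible
empirical p is 1/11 ≈ 0.091, which the fully excluded hotspot/axis pair
attains.

A command-line interface mirrors the library (`loopaxis --help`):
consensus calling, shuffle tests, peak consolidation from a YAML config,
pileups, interference tables, percent-input tables and fixture generation.

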