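"""Synthetic meiotic DSB landscapes, ChIP coverage and double-cut cohorts.

The generators emulate the experimental system being modeled: a
budding-yeast-scale genome with
~3,000 DSB hotspots (~190 bp wide) whose per-cell cleavage frequencies span
orders of magnitude up to ~15% for the strongest, interspersed chromosome-axis
sites, ChIP coverage in which Tel1 forms a bimodal (two DSB ends) signal
around hotspot midpoints while Spo11 forms a single narrow peak and dominates
at axis sites, background-only untagged/t0 control tracks, per-chromatid
double-cut cohorts under a tunable interference parameter, and qPCR plates
for the percent-input calculation. Everything is deterministic under a seed.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeLayout
from .interference import BlotQuant, QpcrMeasurement
from .intervals import FeatureSet
from .tracks import BinnedTrack

__all__ = ["SimConfig", "DsbCohort", "SimTracks", "default_genome",
           "simulate_features", "simulate_chip_tracks",
           "simulate_dsb_cohort", "simulate_qpcr_plate", "simulate_all"]


def default_genome() -> GenomeLayout:
    """A 16-chromosome, ~12 Mb yeast-like layout (rounded S. cerevisiae
    chromosome lengths)."""
    lengths = [230_000, 813_000, 341_000, 1_532_000, 577_000, 270_000,
               1_091_000, 563_000, 440_000, 746_000, 667_000, 1_078_000,
               924_000, 784_000, 1_091_000, 948_000]
    names = ["chrI", "chrII", "chrIII", "chrIV", "chrV", "chrVI", "chrVII",
             "chrVIII", "chrIX", "chrX", "chrXI", "chrXII", "chrXIII",
             "chrXIV", "chrXV", "chrXVI"]
    return GenomeLayout(list(zip(names, lengths)))


@dataclass
class SimConfig:
    """Parameters of the synthetic landscape and ChIP coverage.

    Hotspot strengths are per-cell cleavage fractions drawn log-normal
    (``strength_logmean``/``strength_logsd``) and clipped at ``strength_max``
    (the strongest hotspots are cleaved in ~15% of cells). Axis sites recur
    quasi-periodically every ``axis_spacing`` bp with uniform jitter. Tel1
    coverage around a hotspot is two Gaussians at +/- ``bimodal_offset``
    (the two break ends); Spo11 is a single narrower Gaussian; axis kernels
    are Spo11-weighted more heavily than Tel1. Gains are expected reads per
    bin at the kernel peak per unit strength (hotspots) or absolute (axis).
    """

    seed: int = 0
    genome: GenomeLayout = field(default_factory=default_genome)
    n_hotspots: int = 3000
    hotspot_width: int = 190
    hotspot_min_separation: int = 1500
    strength_logmean: float = float(np.log(0.002))
    strength_logsd: float = 1.2
    strength_max: float = 0.15
    axis_spacing: int = 15_000
    axis_width: int = 800
    axis_jitter: int = 3_000
    tel1_mode: str = "bimodal"          # "bimodal" or "none"
    bimodal_offset: int = 500
    tel1_sd: float = 200.0
    spo11_sd: float = 100.0
    tel1_gain: float = 2000.0
    spo11_gain: float = 3000.0
    tel1_axis_gain: float = 8.0
    spo11_axis_gain: float = 32.0
    axis_sd: float = 400.0
    background_rate: float = 0.02       # expected reads per bp, all tracks
    bin_size: int = 20


@dataclass
class SimTracks:
    """Simulated coverage tracks with their noise-free expectations."""

    tracks: dict[str, BinnedTrack]
    expected: dict[str, BinnedTrack]
    library_sizes: dict[str, float]


@dataclass
class DsbCohort:
    """Per-chromatid cut outcomes at two hotspots and the derived blot.

    Outcomes partition ``n_cells`` chromatids into (no cut, site I only,
    site II only, double cut) with P(double) = (1 - I_true) * p1 * p2,
    marginals p1 and p2 preserved. ``measured`` is the BlotQuant a Southern
    blot would report: under ``dc_loss_on_f2`` the double-cut molecules are
    absent from the site-II band, and the central double-cut probe divides
    its signal over ``probe_loci`` parental loci.
    """

    n_cells: int
    p1: float
    p2: float
    i_true: float
    n_none: int
    n_site1_only: int
    n_site2_only: int
    n_double: int
    measured: BlotQuant

    @property
    def outcome_counts(self) -> tuple[int, int, int, int]:
        return (self.n_none, self.n_site1_only, self.n_site2_only, self.n_double)


# -- feature landscape ---------------------------------------------------------

def _place_axis(cfg: SimConfig, rng: np.random.Generator) -> FeatureSet:
    recs = []
    half = cfg.axis_width // 2
    for name, length in cfg.genome.chromosomes:
        n_sites = max(int(length // cfg.axis_spacing), 1)
        for i in range(n_sites):
            center = int((i + 0.5) * cfg.axis_spacing
                         + rng.integers(-cfg.axis_jitter, cfg.axis_jitter + 1))
            s = max(center - half, 0)
            e = min(s + cfg.axis_width, length)
            if e - s >= cfg.axis_width // 2:
                recs.append((name, s, e))
    return FeatureSet.from_records(recs, name="axis")


def _place_nonoverlapping(rng: np.random.Generator, genome: GenomeLayout,
                          counts: dict[str, int], width: int,
                          forbidden: FeatureSet, separation: int = 0,
                          max_attempts: int = 10_000) -> list[tuple[str, int, int]]:
    """Uniform rejection placement of fixed-width intervals, disjoint from
    ``forbidden`` and pairwise separated by at least ``separation`` bp."""
    forb: dict[str, tuple[list, list]] = {}
    for c, (s, e, _) in forbidden.by_chrom().items():
        forb[c] = (list(map(int, s)), list(map(int, e)))
    out = []
    for c, n in counts.items():
        fstarts, fends = forb.get(c, ([], []))
        # placed intervals are stored padded by the separation; equal padded
        # lengths keep the sorted-by-start predecessor check exact
        pstarts: list[int] = []
        pends: list[int] = []
        clen = genome.length(c)
        for _ in range(n):
            for _attempt in range(max_attempts):
                s = int(rng.integers(0, clen - width + 1))
                e = s + width
                i = bisect_right(fstarts, e - 1)
                if i > 0 and fends[i - 1] > s:
                    continue
                j = bisect_right(pstarts, e - 1)
                if j > 0 and pends[j - 1] > s:
                    continue
                jj = bisect_right(pstarts, s - separation)
                pstarts.insert(jj, s - separation)
                pends.insert(jj, e + separation)
                out.append((c, s, e))
                break
            else:
                raise RuntimeError(f"hotspot placement infeasible on {c}")
    return out


def simulate_features(cfg: SimConfig) -> tuple[FeatureSet, FeatureSet]:
    """Draw the hotspot and axis landscapes.

    Returns ``(hotspots, axis)``: hotspots carry per-cell cleavage strengths
    as scores and are disjoint from axis sites (DSBs are depleted in axis
    regions) and from one another.
    """
    rng = np.random.default_rng(cfg.seed)
    axis = _place_axis(cfg, rng)
    total = cfg.genome.total_length
    counts = {}
    assigned = 0
    for name, length in cfg.genome.chromosomes:
        c = int(cfg.n_hotspots * length / total)
        counts[name] = c
        assigned += c
    # hand the rounding remainder to the largest chromosomes
    by_len = sorted(cfg.genome.chromosomes, key=lambda t: -t[1])
    for i in range(cfg.n_hotspots - assigned):
        counts[by_len[i % len(by_len)][0]] += 1
    recs = _place_nonoverlapping(rng, cfg.genome, counts, cfg.hotspot_width,
                                 axis, separation=cfg.hotspot_min_separation)
    strengths = rng.lognormal(cfg.strength_logmean, cfg.strength_logsd,
                              size=len(recs))
    strengths = np.minimum(strengths, cfg.strength_max)
    hotspots = FeatureSet([r[0] for r in recs], [r[1] for r in recs],
                          [r[2] for r in recs], name="hotspots")
    # FeatureSet sorts by coordinate; strengths are i.i.d. so attaching them
    # post-sort preserves the distribution
    hotspots = FeatureSet(hotspots.chroms, hotspots.starts, hotspots.ends,
                          strengths, name="hotspots")
    return hotspots, axis


# -- coverage tracks -----------------------------------------------------------

def _add_gaussian(vec: np.ndarray, bin_size: int, center: int,
                  peak: float, sd: float) -> None:
    """Add a Gaussian kernel (peak height ``peak`` at ``center``) evaluated
    at bin centers, truncated at 4 sd."""
    lo = max(int((center - 4 * sd) // bin_size), 0)
    hi = min(int((center + 4 * sd) // bin_size) + 1, len(vec))
    if hi <= lo:
        return
    x = (np.arange(lo, hi) + 0.5) * bin_size
    vec[lo:hi] += peak * np.exp(-0.5 * ((x - center) / sd) ** 2)


def expected_tracks(cfg: SimConfig, hotspots: FeatureSet,
                    axis: FeatureSet) -> dict[str, BinnedTrack]:
    """Noise-free expected coverage (reads per bin) for each factor."""
    bg = cfg.background_rate * cfg.bin_size
    out = {}
    for factor in ("tel1", "spo11", "untagged", "t0"):
        tr = BinnedTrack(cfg.genome, cfg.bin_size)
        for c in tr.data:
            tr.data[c] += bg
        out[factor] = tr
    mids = hotspots.midpoints()
    strengths = hotspots.scores
    for i in range(len(hotspots)):
        c, mid, s = hotspots.chroms[i], int(mids[i]), float(strengths[i])
        if cfg.tel1_mode == "bimodal":
            _add_gaussian(out["tel1"].data[c], cfg.bin_size,
                          mid - cfg.bimodal_offset, cfg.tel1_gain * s, cfg.tel1_sd)
            _add_gaussian(out["tel1"].data[c], cfg.bin_size,
                          mid + cfg.bimodal_offset, cfg.tel1_gain * s, cfg.tel1_sd)
        elif cfg.tel1_mode != "none":
            raise ValueError(f"unknown tel1_mode {cfg.tel1_mode!r}")
        _add_gaussian(out["spo11"].data[c], cfg.bin_size,
                      mid, cfg.spo11_gain * s, cfg.spo11_sd)
    amids = axis.midpoints()
    for i in range(len(axis)):
        c, mid = axis.chroms[i], int(amids[i])
        if cfg.tel1_mode == "bimodal":
            _add_gaussian(out["tel1"].data[c], cfg.bin_size, mid,
                          cfg.tel1_axis_gain, cfg.axis_sd)
        _add_gaussian(out["spo11"].data[c], cfg.bin_size, mid,
                      cfg.spo11_axis_gain, cfg.axis_sd)
    return out


def simulate_chip_tracks(cfg: SimConfig, hotspots: FeatureSet,
                         axis: FeatureSet) -> SimTracks:
    """Poisson-sample read counts per bin from the expected coverage.

    The untagged and t = 0 h controls are background-only. Library sizes are
    the realized total counts per track.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    expected = expected_tracks(cfg, hotspots, axis)
    tracks, libsizes = {}, {}
    for factor in ("tel1", "spo11", "untagged", "t0"):
        exp = expected[factor]
        tr = BinnedTrack(cfg.genome, cfg.bin_size)
        for c, _ in cfg.genome.chromosomes:
            tr.data[c] = rng.poisson(exp.data[c]).astype(float)
        tracks[factor] = tr
        libsizes[factor] = tr.total()
    return SimTracks(tracks=tracks, expected=expected, library_sizes=libsizes)


# -- double-cut cohorts --------------------------------------------------------

def simulate_dsb_cohort(n_cells: int, p1: float, p2: float, i_true: float,
                        seed: int = 0, dc_loss_on_f2: bool = True,
                        probe_loci: int = 3) -> DsbCohort:
    """Draw per-chromatid cut outcomes at two hotspots.

    P(double cut) = (1 - i_true) * p1 * p2 (clipped to the feasible joint
    range); marginal cut probabilities stay p1 and p2. The derived
    :class:`BlotQuant` reflects the measurement model: f1 counts every
    chromatid cut at site I, f2_raw loses the double-cut molecules when
    ``dc_loss_on_f2``, and the central probe spreads its double-cut signal
    over ``probe_loci`` loci.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("cut probabilities must be in [0, 1]")
    p_dc = (1.0 - i_true) * p1 * p2
    if p_dc > min(p1, p2) + 1e-12:
        raise ValueError(
            f"P(double) = {p_dc} exceeds a marginal; joint distribution infeasible")
    p_dc = min(max(p_dc, 0.0), min(p1, p2))
    probs = [1.0 - p1 - p2 + p_dc, p1 - p_dc, p2 - p_dc, p_dc]
    if probs[0] < -1e-12:
        raise ValueError("p1 + p2 - P(double) exceeds 1; infeasible")
    probs[0] = max(probs[0], 0.0)
    rng = np.random.default_rng(seed)
    n_none, n1, n2, n_dc = rng.multinomial(n_cells, probs)
    f1 = (n1 + n_dc) / n_cells
    f2 = (n2 / n_cells) if dc_loss_on_f2 else (n2 + n_dc) / n_cells
    measured = BlotQuant(f1=f1, f2_raw=f2,
                         dc_central_raw=n_dc / (probe_loci * n_cells),
                         probe_loci=probe_loci)
    return DsbCohort(n_cells=n_cells, p1=p1, p2=p2, i_true=i_true,
                     n_none=int(n_none), n_site1_only=int(n1),
                     n_site2_only=int(n2), n_double=int(n_dc),
                     measured=measured)


# -- qPCR plates ---------------------------------------------------------------

def simulate_qpcr_plate(true_enrichment: float, dilution: float = 20.0,
                        volume_factor: float = 10.0, noise_cv: float = 0.0,
                        n_replicates: int = 3, seed: int = 0,
                        q_input: float = 1.0) -> list[QpcrMeasurement]:
    """Simulate technical qPCR replicates for one locus.

    ``q_ip`` is set so that percent_ip returns 100 * true_enrichment in
    expectation, with multiplicative log-normal technical noise of the given
    coefficient of variation.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    q_ip_true = true_enrichment * q_input * dilution * volume_factor
    if noise_cv == 0:
        noise = np.ones(n_replicates)
    else:
        sigma2 = np.log1p(noise_cv ** 2)
        noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n_replicates)
    return [QpcrMeasurement(q_ip=q_ip_true * w, q_input=q_input,
                            dilution_factor=dilution,
                            volume_factor=volume_factor)
            for w in noise]


# -- one-call fixture writer ---------------------------------------------------

def simulate_all(cfg: SimConfig, outdir) -> dict:
    """Write a complete synthetic fixture directory.

    Produces genome.tsv, hotspots.bed (score = strength), axis.bed, four
    bedGraph coverage tracks, bands.tsv (double-cut cohort blot at several
    interference values), plate.tsv and truth.json (ground-truth parameters).
    Byte-identical under a fixed seed.
    """
    import json
    from pathlib import Path

    from .intervals import write_features
    from .tracks import write_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.genome.write(outdir / "genome.tsv")
    hotspots, axis = simulate_features(cfg)
    write_features(hotspots, outdir / "hotspots.bed", "bed")
    write_features(axis, outdir / "axis.bed", "bed")
    sim = simulate_chip_tracks(cfg, hotspots, axis)
    for factor, tr in sim.tracks.items():
        write_bedgraph(tr, outdir / f"{factor}.bedgraph")
    i_values = [-1.0, -0.5, 0.0, 0.5, 0.9]
    with open(outdir / "bands.tsv", "w") as fh:
        fh.write("i_true\tf1\tf2_raw\tdc_central_raw\tprobe_loci\n")
        for j, i_true in enumerate(i_values):
            cohort = simulate_dsb_cohort(100_000, 0.1, 0.1, i_true,
                                         seed=cfg.seed * 1000 + j)
            b = cohort.measured
            fh.write(f"{i_true}\t{b.f1!r}\t{b.f2_raw!r}\t"
                     f"{b.dc_central_raw!r}\t{b.probe_loci}\n")
    plate = simulate_qpcr_plate(0.0025, noise_cv=0.1, seed=cfg.seed + 7)
    with open(outdir / "plate.tsv", "w") as fh:
        fh.write("q_ip\tq_input\tdilution\tvolume_factor\n")
        for m in plate:
            fh.write(f"{m.q_ip!r}\t{m.q_input!r}\t{m.dilution_factor!r}\t"
                     f"{m.volume_factor!r}\n")
    truth = {
        "seed": cfg.seed,
        "n_hotspots": len(hotspots),
        "n_axis": len(axis),
        "bimodal_offset": cfg.bimodal_offset,
        "strength_max": float(np.max(hotspots.scores)),
        "library_sizes": {k: float(v) for k, v in sim.library_sizes.items()},
        "interference_values": i_values,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
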