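"""Binned coverage-track numerics: bedGraph I/O, RPKM normalization,
background subtraction, Hann smoothing, pile-up profiles, heatmap matrices,
percentile partitions and window correlations.

A :class:`BinnedTrack` stores one float vector per chromosome at a fixed bin
size; NaN marks missing data, distinct from 0 coverage. Pile-ups average the
track in fixed offset bins around feature midpoints (e.g. RPKM per 20-bp bin
within +/-5 kb of hotspot centers), excluding out-of-chromosome bins from the
per-offset means rather than zero-filling them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout
from .intervals import FeatureSet, max_overlap_per_interval

__all__ = [
    "BinnedTrack", "Profile", "ProfileMatrix",
    "read_bedgraph", "write_bedgraph",
    "normalize_rpkm", "background_correct", "hann_smooth", "hann_kernel",
    "pileup_profile", "profile_matrix", "window_signal",
    "partition_by_percentile", "window_correlation",
]


@dataclass
class BinnedTrack:
    """Fixed-bin numeric signal per chromosome.

    ``data[chrom]`` has ``ceil(length / bin_size)`` float entries; the last
    bin may cover fewer than ``bin_size`` bases. NaN means missing (as opposed
    to an observed 0).
    """

    genome: GenomeLayout
    bin_size: int
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name, length in self.genome.chromosomes:
            n = -(-length // self.bin_size)
            if name not in self.data:
                self.data[name] = np.zeros(n)
            elif len(self.data[name]) != n:
                raise ValueError(
                    f"{name}: expected {n} bins, got {len(self.data[name])}")

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.genome, self.bin_size,
                           {c: v.copy() for c, v in self.data.items()})

    def total(self) -> float:
        """Genome-wide sum of bin values (NaN ignored)."""
        return float(sum(np.nansum(v) for v in self.data.values()))

    def _check_compatible(self, other: "BinnedTrack") -> None:
        if self.bin_size != other.bin_size:
            raise ValueError("bin sizes differ")
        if self.genome.chromosomes != other.genome.chromosomes:
            raise ValueError("genome layouts differ")


# -- bedGraph I/O --------------------------------------------------------------

def read_bedgraph(path, genome: GenomeLayout, bin_size: int) -> BinnedTrack:
    """Rasterize a 4-column bedGraph onto fixed bins.

    A bin's value is the length-weighted mean of the records it intersects,
    with uncovered bases contributing 0 (raw-coverage semantics). Overlapping
    records and unknown chromosomes are errors.
    """
    track = BinnedTrack(genome, bin_size)
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{i}: expected 4 columns")
            c = parts[0]
            if c not in genome:
                raise ValueError(f"{path}:{i}: unknown chromosome {c!r}")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ValueError(f"{path}:{i}: malformed record") from None
            if not 0 <= s < e <= genome.length(c):
                raise ValueError(f"{path}:{i}: interval out of bounds")
            by_chrom.setdefault(c, []).append((s, e, v))
    for c, recs in by_chrom.items():
        recs.sort()
        prev_end = -1
        acc = track.data[c]
        for s, e, v in recs:
            if s < prev_end:
                raise ValueError(f"{path}: overlapping bedGraph records on {c}")
            prev_end = e
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                acc[b0] += v * (e - s)
            else:
                acc[b0] += v * ((b0 + 1) * bin_size - s)
                if b1 > b0 + 1:
                    acc[b0 + 1:b1] += v * bin_size
                acc[b1] += v * (e - b1 * bin_size)
        length = genome.length(c)
        widths = np.full(len(acc), float(bin_size))
        if length % bin_size:
            widths[-1] = length % bin_size
        acc /= widths
    return track


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Emit run-length-compressed 4-column bedGraph; NaN bins are omitted."""
    with open(path, "w") as fh:
        for c, length in track.genome.chromosomes:
            v = track.data[c]
            if len(v) == 0:
                continue
            bs = track.bin_size
            run_start = 0
            run_val = v[0] if len(v) else None
            for i in range(1, len(v) + 1):
                cur = v[i] if i < len(v) else None
                same = (cur is not None and
                        (cur == run_val or (np.isnan(cur) and np.isnan(run_val))))
                if not same:
                    if not np.isnan(run_val):
                        end = min(i * bs, length)
                        fh.write(f"{c}\t{run_start * bs}\t{end}\t{_fmtval(run_val)}\n")
                    run_start, run_val = i, cur
            # loop writes the final run at i == len(v)


def _fmtval(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(float(x))


# -- normalization and correction ----------------------------------------------

def normalize_rpkm(track: BinnedTrack, library_size: float) -> BinnedTrack:
    """Reads-per-kilobase-per-million: value * 1e9 / (library_size * bin_size)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    factor = 1e9 / (library_size * track.bin_size)
    out = track.copy()
    for c in out.data:
        out.data[c] *= factor
    return out


def background_correct(replicates, controls=(), floor_at_zero: bool = False) -> BinnedTrack:
    """Subtract control tracks from each replicate, then average replicates.

    Controls (untagged/input, and the t = 0 h sample where applicable) are
    subtracted from every replicate; the corrected replicates are then
    averaged bin-wise. With ``floor_at_zero`` negative bins clip to 0.
    """
    if isinstance(replicates, BinnedTrack):
        replicates = [replicates]
    replicates = list(replicates)
    controls = list(controls)
    if not replicates:
        raise ValueError("at least one replicate required")
    ref = replicates[0]
    for t in replicates[1:] + controls:
        ref._check_compatible(t)
    out = BinnedTrack(ref.genome, ref.bin_size)
    for c in out.data:
        acc = np.zeros_like(out.data[c])
        for rep in replicates:
            corrected = rep.data[c].copy()
            for ctl in controls:
                corrected = corrected - ctl.data[c]
            acc += corrected
        acc /= len(replicates)
        if floor_at_zero:
            acc = np.maximum(acc, 0.0)
        out.data[c] = acc
    return out


# -- Hann smoothing ------------------------------------------------------------

def hann_kernel(m: int) -> np.ndarray:
    """Normalized Hann window of ``m`` taps:
    w_j = 0.5 (1 - cos(2 pi j / (m - 1))), j = 0..m-1, scaled to sum 1."""
    if m < 1:
        raise ValueError("kernel length must be >= 1")
    if m == 1:
        return np.ones(1)
    j = np.arange(m)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * j / (m - 1)))
    return w / w.sum()


def hann_smooth(track: BinnedTrack, window: int) -> BinnedTrack:
    """Smooth with a normalized Hann window of ``window`` base pairs.

    The tap count is window / bin_size rounded to the nearest odd integer.
    At chromosome edges (and across NaN bins) the kernel is truncated and
    renormalized over the available data.
    """
    if window < track.bin_size:
        raise ValueError("window must be at least one bin")
    m = int(round(window / track.bin_size))
    if m % 2 == 0:
        m += 1
    kernel = hann_kernel(m)
    out = track.copy()
    for c, v in track.data.items():
        valid = ~np.isnan(v)
        filled = np.where(valid, v, 0.0)
        num = np.convolve(filled, kernel, mode="same")
        den = np.convolve(valid.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        sm[~valid] = np.nan
        out.data[c] = sm
    return out


# -- range statistics over a track ---------------------------------------------

def _range_stats(track: BinnedTrack, chrom: str,
                 starts: np.ndarray, ends: np.ndarray):
    """Integral of the bin step function and NaN-contamination flag over
    arbitrary [start, end) ranges (clipped to the chromosome)."""
    v = track.data[chrom]
    bs = track.bin_size
    length = track.genome.length(chrom)
    starts = np.clip(starts, 0, length)
    ends = np.clip(ends, 0, length)
    nan_mask = np.isnan(v)
    filled = np.where(nan_mask, 0.0, v)
    cum = np.concatenate(([0.0], np.cumsum(filled) * bs))
    cum_nan = np.concatenate(([0], np.cumsum(nan_mask.astype(np.int64))))

    def integral(x):
        k = x // bs
        frac = x - k * bs
        return cum[k] + filled[np.minimum(k, len(v) - 1)] * frac

    total = integral(ends) - integral(starts)
    # a range touches NaN iff it intersects a NaN bin
    k0, k1 = starts // bs, (np.maximum(ends, starts + 1) - 1) // bs
    touched = (cum_nan[np.minimum(k1, len(v) - 1) + 1] - cum_nan[k0]) > 0
    touched &= ends > starts
    return total, touched


def _range_means(track: BinnedTrack, chrom: str,
                 starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Length-weighted mean of the track over [start, end) ranges; NaN when
    the range is empty after clipping or touches missing data."""
    length = track.genome.length(chrom)
    cs = np.clip(starts, 0, length)
    ce = np.clip(ends, 0, length)
    total, touched = _range_stats(track, chrom, starts, ends)
    widths = (ce - cs).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = total / widths
    means[widths <= 0] = np.nan
    means[touched] = np.nan
    return means


# -- pile-ups and heatmaps -----------------------------------------------------

@dataclass
class Profile:
    """Mean signal in fixed offset bins around feature midpoints."""

    offsets: np.ndarray      # bp, bin centers, symmetric about 0
    values: np.ndarray       # mean signal per offset bin (NaN if no features)
    n_features: np.ndarray   # contributing feature count per offset bin
    flank: int
    bin: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.values,
                             "n": self.n_features})


@dataclass
class ProfileMatrix:
    """Per-feature signal rows around feature midpoints, in stable row order."""

    offsets: np.ndarray
    matrix: np.ndarray          # shape (n_features, n_offsets), NaN = missing
    row_order: np.ndarray       # indices into the input FeatureSet
    order_key: str
    flank: int
    bin: int

    def column_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)


def _feature_matrix(track: BinnedTrack, centers: FeatureSet,
                    flank: int, bin: int) -> tuple[np.ndarray, np.ndarray]:
    if len(centers) == 0:
        raise ValueError("no features to profile")
    if flank % bin:
        raise ValueError("flank must be a multiple of bin")
    n_off = 2 * flank // bin
    offsets = -flank + bin * np.arange(n_off) + bin // 2
    mids = centers.midpoints()
    rows = np.full((len(centers), n_off), np.nan)
    edges = -flank + bin * np.arange(n_off + 1)
    for c, (_, _, idx) in centers.by_chrom().items():
        if c not in track.data:
            continue
        cmids = mids[idx]
        for row_i, mid in zip(idx, cmids):
            s = mid + edges[:-1]
            e = mid + edges[1:]
            length = track.genome.length(c)
            inside = (s >= 0) & (e <= length)
            if inside.any():
                vals = _range_means(track, c, s[inside], e[inside])
                rows[row_i, inside] = vals
    return offsets, rows


def pileup_profile(track: BinnedTrack, centers: FeatureSet,
                   flank: int = 5000, bin: int = 20) -> Profile:
    """Average the track in ``bin``-bp offset bins within +/- ``flank`` bp of
    each feature midpoint. Offset bins falling outside a feature's chromosome
    are excluded from that offset's mean (not zero-filled)."""
    offsets, rows = _feature_matrix(track, centers, flank, bin)
    n_feat = (~np.isnan(rows)).sum(axis=0)
    sums = np.nansum(np.nan_to_num(rows, nan=0.0), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_feat > 0, sums / n_feat, np.nan)
    return Profile(offsets=offsets, values=values, n_features=n_feat,
                   flank=flank, bin=bin)


def profile_matrix(track: BinnedTrack, centers: FeatureSet,
                   order_by: str = "score", descending: bool = True,
                   flank: int = 5000, bin: int = 20) -> ProfileMatrix:
    """Per-feature pile-up rows sorted by score (ties: genomic order).

    The column means of the matrix equal the corresponding
    :func:`pileup_profile` values wherever the same features contribute.
    """
    if order_by == "score":
        if centers.scores is None:
            raise ValueError("feature set carries no score to order by")
        key = centers.scores
    else:
        raise ValueError(f"unknown ordering key {order_by!r}")
    offsets, rows = _feature_matrix(track, centers, flank, bin)
    order = np.argsort(-key if descending else key, kind="stable")
    return ProfileMatrix(offsets=offsets, matrix=rows[order], row_order=order,
                         order_key=order_by, flank=flank, bin=bin)


# -- per-feature window quantification ------------------------------------------

def window_signal(track: BinnedTrack, features: FeatureSet, width: int,
                  stat: str = "mean_bin_value",
                  exclude_overlap: tuple[FeatureSet, float] | None = None) -> pd.DataFrame:
    """Quantify the track in a fixed-width window centered on each feature.

    ``stat='mean_bin_value'`` is the length-weighted mean bin value over the
    window; ``'summed_count'`` is the window integral divided by the bin size
    (total count when the track holds counts per bin). With
    ``exclude_overlap=(axis, 0.10)``, windows overlapping the exclusion set
    by >= 10% of their width are flagged excluded and their value set to NaN.
    Windows are clipped at chromosome ends.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if stat not in ("mean_bin_value", "summed_count"):
        raise ValueError(f"unknown stat {stat!r}")
    mids = features.midpoints()
    win_start = mids - width // 2
    win_end = win_start + width
    values = np.full(len(features), np.nan)
    for c, (_, _, idx) in features.by_chrom().items():
        if c not in track.data:
            continue
        s, e = win_start[idx], win_end[idx]
        if stat == "mean_bin_value":
            values[idx] = _range_means(track, c, s, e)
        else:
            total, touched = _range_stats(track, c, s, e)
            total = total / track.bin_size
            total[touched] = np.nan
            values[idx] = total
    excluded = np.zeros(len(features), dtype=bool)
    if exclude_overlap is not None:
        excl_set, max_fraction = exclude_overlap
        windows = FeatureSet(features.chroms, np.maximum(win_start, 0), win_end)
        ov = max_overlap_per_interval(windows, excl_set)
        excluded = ov >= max_fraction * width
        values = np.where(excluded, np.nan, values)
    out = pd.DataFrame({"chrom": features.chroms.astype(str),
                        "start": win_start, "end": win_end,
                        "value": values, "excluded": excluded})
    return out


def partition_by_percentile(scores, n_bins: int = 10) -> np.ndarray:
    """Rank-based equal-count percentile bins, 0 = weakest .. n_bins-1 =
    strongest; ties resolved by stable rank so bin sizes differ by <= 1."""
    scores = np.asarray(scores, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = len(scores)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} features, got {n}")
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def window_correlation(a: BinnedTrack, b: BinnedTrack,
                       window: int = 100) -> tuple[float, float, float]:
    """Pearson r, Spearman rho and R^2 (= r^2 of the least-squares fit)
    between the per-window mean signals of two tracks over the genome,
    computed in non-overlapping ``window``-bp windows. Windows missing in
    either track are excluded."""
    if a.genome.chromosomes != b.genome.chromosomes:
        raise ValueError("genome layouts differ")
    va, vb = [], []
    for c, length in a.genome.chromosomes:
        edges = np.arange(0, length, window)
        s = edges
        e = np.minimum(edges + window, length)
        va.append(_range_means(a, c, s, e))
        vb.append(_range_means(b, c, s, e))
    x = np.concatenate(va)
    y = np.concatenate(vb)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("fewer than 3 shared windows")
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return r, rho, r * r
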