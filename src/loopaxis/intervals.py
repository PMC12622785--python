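"""Interval algebra over genomic feature sets.

All coordinates are 0-based half-open (BED convention). A :class:`FeatureSet`
holds sorted intervals with an optional per-interval score (e.g. DSB strength
in NormHpM units, or Hop1 RPKM). The algebra here — gap-merging, selection
intersect, per-base subtraction, k-of-n consensus and overlap tables — is the
substrate for defining chromosome-axis sites from Red1/Hop1/Rec8 peaks and for
the hotspot/axis/peak overlap statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout

__all__ = [
    "FeatureSet",
    "OverlapTable",
    "read_features",
    "write_features",
    "merge_intervals",
    "merge",
    "intersect",
    "subtract",
    "k_of_n_consensus",
    "overlap_table",
    "max_overlap_per_interval",
    "overlaps_any",
]


class FeatureSet:
    """A named, sorted collection of genomic intervals with optional scores.

    Intervals are kept sorted by ``(chrom, start, end)``. ``scores`` is either
    ``None`` or a float array aligned with the intervals; missing per-record
    scores are NaN.
    """

    __slots__ = ("name", "chroms", "starts", "ends", "scores")

    def __init__(self, chroms, starts, ends, scores=None, name: str = ""):
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("chroms, starts, ends must have equal length")
        if scores is not None:
            scores = np.asarray(scores, dtype=float)
            if len(scores) != len(starts):
                raise ValueError("scores length must match interval count")
        if np.any(starts < 0):
            raise ValueError("negative start coordinate")
        if np.any(starts >= ends):
            raise ValueError("intervals must satisfy start < end (half-open)")
        order = np.lexsort((ends, starts, chroms.astype(str)))
        self.name = name
        self.chroms = chroms[order]
        self.starts = starts[order]
        self.ends = ends[order]
        self.scores = scores[order] if scores is not None else None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def empty(cls, name: str = "") -> "FeatureSet":
        return cls(np.array([], dtype=object), [], [], name=name)

    @classmethod
    def from_records(cls, records: Iterable[tuple], name: str = "") -> "FeatureSet":
        """Build from ``(chrom, start, end[, score])`` tuples."""
        records = list(records)
        if not records:
            return cls.empty(name)
        chroms = [r[0] for r in records]
        starts = [r[1] for r in records]
        ends = [r[2] for r in records]
        scores = [r[3] for r in records] if len(records[0]) > 3 else None
        return cls(chroms, starts, ends, scores, name=name)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chroms.astype(str),
                           "start": self.starts, "end": self.ends})
        if self.scores is not None:
            df["score"] = self.scores
        return df

    # -- basics ---------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        for i in range(len(self)):
            yield (self.chroms[i], int(self.starts[i]), int(self.ends[i]))

    def __repr__(self) -> str:
        return f"FeatureSet({self.name!r}, n={len(self)})"

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def midpoints(self) -> np.ndarray:
        """Feature centers, ``floor((start + end) / 2)``."""
        return (self.starts + self.ends) // 2

    def chrom_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chroms:
            seen.setdefault(c)
        return list(seen)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends, original_indices)`` views."""
        out = {}
        for c in self.chrom_names():
            m = self.chroms == c
            out[c] = (self.starts[m], self.ends[m], np.flatnonzero(m))
        return out

    def select(self, mask_or_index) -> "FeatureSet":
        idx = np.asarray(mask_or_index)
        scores = self.scores[idx] if self.scores is not None else None
        return FeatureSet(self.chroms[idx], self.starts[idx], self.ends[idx],
                          scores, name=self.name)

    def validate_against(self, genome: GenomeLayout) -> None:
        for i in range(len(self)):
            c = self.chroms[i]
            if c not in genome:
                raise ValueError(f"interval on chromosome {c!r} absent from genome layout")
            if self.ends[i] > genome.length(c):
                raise ValueError(
                    f"interval {c}:{self.starts[i]}-{self.ends[i]} exceeds "
                    f"chromosome length {genome.length(c)}")


# -- file I/O (BED3/BED6 and ENCODE narrowPeak) --------------------------------

def read_features(path, format: str = "bed", genome: GenomeLayout | None = None,
                  name: str | None = None) -> FeatureSet:
    """Read a BED3/BED6 or ENCODE narrowPeak file into a FeatureSet.

    BED score comes from column 5; narrowPeak score is column 7 (signalValue).
    When a genome layout is given, intervals on unknown chromosomes or
    exceeding chromosome bounds are rejected.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown format {format!r}")
    chroms, starts, ends, scores = [], [], [], []
    any_score = False
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if format == "narrowPeak":
                    if len(parts) < 10:
                        raise ValueError("narrowPeak requires 10 columns")
                    score = float(parts[6])
                    any_score = True
                else:
                    if len(parts) < 3:
                        raise ValueError("BED requires at least 3 columns")
                    if len(parts) >= 5:
                        score = float(parts[4])
                        any_score = True
                    else:
                        score = float("nan")
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{i}: malformed line ({e})") from None
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            scores.append(score)
    fs = FeatureSet(np.array(chroms, dtype=object), starts, ends,
                    scores if any_score else None,
                    name=name if name is not None else str(path))
    if genome is not None:
        fs.validate_against(genome)
    return fs


def write_features(fs: FeatureSet, path, format: str = "bed") -> None:
    """Write BED (3 or 6 columns depending on scores) or 10-column narrowPeak."""
    with open(path, "w") as fh:
        for i in range(len(fs)):
            c, s, e = fs.chroms[i], fs.starts[i], fs.ends[i]
            score = fs.scores[i] if fs.scores is not None else None
            if format == "bed":
                if score is None:
                    fh.write(f"{c}\t{s}\t{e}\n")
                else:
                    fh.write(f"{c}\t{s}\t{e}\t{fs.name or 'feature'}_{i}\t{_fmt(score)}\t.\n")
            elif format == "narrowPeak":
                sig = _fmt(score) if score is not None else "0"
                fh.write(f"{c}\t{s}\t{e}\t{fs.name or 'peak'}_{i}\t0\t.\t{sig}\t-1\t-1\t-1\n")
            else:
                raise ValueError(f"unknown format {format!r}")


def _fmt(x: float) -> str:
    # Integral scores print without a trailing .0 so BED round-trips cleanly.
    if np.isnan(x):
        return "."
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


# -- core algebra --------------------------------------------------------------

def merge_intervals(fs: FeatureSet, max_gap: int = 0) -> FeatureSet:
    """Merge intervals separated by a gap smaller than ``max_gap``.

    Overlapping or book-ended intervals are always merged; a positive gap g
    closes iff g < max_gap (the strict reading of "distance <350 bp were
    merged"). Scores are dropped.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out_c, out_s, out_e = [], [], []
    for c, (starts, ends, _) in fs.by_chrom().items():
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            gap = s - cur_e
            if gap <= 0 or gap < max_gap:
                cur_e = max(cur_e, e)
            else:
                out_c.append(c); out_s.append(cur_s); out_e.append(cur_e)
                cur_s, cur_e = s, e
        out_c.append(c); out_s.append(cur_s); out_e.append(cur_e)
    return FeatureSet(np.array(out_c, dtype=object), out_s, out_e, name=fs.name)


merge = merge_intervals


def max_overlap_per_interval(a: FeatureSet, b: FeatureSet) -> np.ndarray:
    """For each interval of ``a``, the largest base-pair overlap with any
    single interval of ``b`` (0 if none)."""
    out = np.zeros(len(a), dtype=np.int64)
    b_chrom = b.by_chrom()
    for c, (a_s, a_e, a_idx) in a.by_chrom().items():
        if c not in b_chrom:
            continue
        b_s, b_e, _ = b_chrom[c]
        # broadcast per chromosome; set sizes here are modest
        ov = (np.minimum(a_e[:, None], b_e[None, :])
              - np.maximum(a_s[:, None], b_s[None, :]))
        out[a_idx] = np.maximum(ov.max(axis=1), 0) if ov.size else 0
    return out


def overlaps_any(a: FeatureSet, b: FeatureSet, min_overlap: int = 1) -> np.ndarray:
    """Boolean mask: which intervals of ``a`` overlap some interval of ``b``
    by at least ``min_overlap`` bp."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    return max_overlap_per_interval(a, b) >= min_overlap


def intersect(a: FeatureSet, b: FeatureSet, min_overlap: int = 1) -> FeatureSet:
    """Selection intersect: intervals of ``a`` overlapping ``b`` by at least
    ``min_overlap`` bp, with a's coordinates and scores preserved."""
    return a.select(overlaps_any(a, b, min_overlap))


def subtract(a: FeatureSet, b: FeatureSet) -> FeatureSet:
    """Per-base set difference ``a \\ b``; intervals may split into fragments,
    which inherit the parent's score."""
    if len(b) == 0:
        return a
    b_merged = merge_intervals(b, 0).by_chrom()
    out: list[tuple] = []
    has_scores = a.scores is not None
    for i in range(len(a)):
        c, s, e = a.chroms[i], int(a.starts[i]), int(a.ends[i])
        score = a.scores[i] if has_scores else None
        if c not in b_merged:
            out.append((c, s, e, score))
            continue
        b_s, b_e, _ = b_merged[c]
        cur = s
        for bs, be in zip(b_s, b_e):
            if be <= cur:
                continue
            if bs >= e:
                break
            if bs > cur:
                out.append((c, cur, int(bs), score))
            cur = max(cur, int(be))
        if cur < e:
            out.append((c, cur, e, score))
    if not out:
        return FeatureSet.empty(a.name)
    chroms = np.array([r[0] for r in out], dtype=object)
    scores = [r[3] for r in out] if has_scores else None
    return FeatureSet(chroms, [r[1] for r in out], [r[2] for r in out],
                      scores, name=a.name)


def k_of_n_consensus(sets: Sequence[FeatureSet], k: int,
                     mode: str = "per_base") -> FeatureSet:
    """Consensus regions covered by at least ``k`` of ``n`` input sets.

    ``per_base`` (canonical): maximal intervals where the per-base count of
    covering input sets is >= k; used with Red1/Hop1/Rec8 and k=2 to define
    chromosome-axis sites. ``site_level``: whole intervals from any input set
    that overlap (>=1 bp) intervals of at least k-1 *other* sets.
    """
    n = len(sets)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if mode == "site_level":
        kept: list[FeatureSet] = []
        for i, fs in enumerate(sets):
            if len(fs) == 0:
                continue
            hits = np.zeros(len(fs), dtype=int)
            for j, other in enumerate(sets):
                if j == i or len(other) == 0:
                    continue
                hits += overlaps_any(fs, other).astype(int)
            kept.append(fs.select(hits >= k - 1))
        if not kept:
            return FeatureSet.empty("consensus")
        allc = np.concatenate([f.chroms for f in kept])
        alls = np.concatenate([f.starts for f in kept])
        alle = np.concatenate([f.ends for f in kept])
        return merge_intervals(FeatureSet(allc, alls, alle, name="consensus"), 0)
    if mode != "per_base":
        raise ValueError(f"unknown consensus mode {mode!r}")
    # per-base: within one set overlapping intervals count once, so merge first
    merged = [merge_intervals(s, 0) if len(s) else s for s in sets]
    chrom_names: dict[str, None] = {}
    for s in merged:
        for c in s.chrom_names():
            chrom_names.setdefault(c)
    out: list[tuple] = []
    for c in chrom_names:
        events: list[tuple[int, int]] = []
        for s in merged:
            m = s.chroms == c
            for st, en in zip(s.starts[m], s.ends[m]):
                events.append((int(st), 1))
                events.append((int(en), -1))
        events.sort()
        depth = 0
        run_start = None
        for pos, delta in events:
            new_depth = depth + delta
            if depth < k <= new_depth and run_start is None:
                run_start = pos
            elif new_depth < k <= depth and run_start is not None:
                if pos > run_start:
                    out.append((c, run_start, pos))
                run_start = None
            depth = new_depth
        # events are balanced, depth returns to 0 so run_start closes
    if not out:
        return FeatureSet.empty("consensus")
    fs = FeatureSet.from_records(out, name="consensus")
    return merge_intervals(fs, 0)  # coalesce book-ended runs across event ties


@dataclass
class OverlapTable:
    """Pairwise query-vs-reference overlap counts/percentages plus the
    per-query 'alone' fraction and Venn-style exclusive combination counts.

    ``counts.loc[q, r]`` is the number of intervals of query set q that
    overlap reference set r by >= min_overlap bp (categories non-exclusive);
    ``alone`` counts query intervals overlapping none of the references.
    ``venn[q]`` maps a tuple of reference names to the number of q intervals
    overlapping exactly that combination.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    totals: pd.Series
    alone_counts: pd.Series
    alone_percentages: pd.Series
    venn: dict[str, dict[tuple[str, ...], int]] = field(default_factory=dict)


def overlap_table(queries: Sequence[FeatureSet], refs: Sequence[FeatureSet],
                  min_overlap: int = 1) -> OverlapTable:
    """Tabulate, for each query set, how many of its intervals overlap each
    reference set (>= min_overlap bp) and how many overlap none of them."""
    qnames = [q.name or f"query{i}" for i, q in enumerate(queries)]
    rnames = [r.name or f"ref{i}" for i, r in enumerate(refs)]
    counts = pd.DataFrame(0, index=qnames, columns=rnames, dtype=int)
    alone = pd.Series(0, index=qnames, dtype=int)
    totals = pd.Series([len(q) for q in queries], index=qnames, dtype=int)
    venn: dict[str, dict[tuple[str, ...], int]] = {}
    for qn, q in zip(qnames, queries):
        masks = []
        for rn, r in zip(rnames, refs):
            m = overlaps_any(q, r, min_overlap) if len(q) and len(r) else \
                np.zeros(len(q), dtype=bool)
            counts.loc[qn, rn] = int(m.sum())
            masks.append(m)
        stacked = np.column_stack(masks) if masks else np.zeros((len(q), 0), bool)
        alone[qn] = int((~stacked.any(axis=1)).sum()) if len(q) else 0
        combos: dict[tuple[str, ...], int] = {}
        for row in stacked:
            key = tuple(rn for rn, hit in zip(rnames, row) if hit)
            combos[key] = combos.get(key, 0) + 1
        venn[qn] = combos
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts.div(totals, axis=0) * 100.0
        alone_pct = alone / totals * 100.0
    return OverlapTable(counts=counts, percentages=pct, totals=totals,
                        alone_counts=alone, alone_percentages=alone_pct,
                        venn=venn)
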