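"""Peak consolidation downstream of a peak caller, and the hyper-ChIPable
blacklist.

ChIP of chromosomal proteins in yeast yields spurious signal at
"hyper-ChIPable" loci that show up even in untagged and pre-meiotic (t = 0 h)
controls. The consolidation cascade implemented here takes peak calls made at
several p-value cutoffs and from replicate samples, keeps the smallest region
of each overlapping group, merges near-adjacent regions, removes peaks present
at t = 0 h, trims coordinates overlapping the blacklist, and retains peaks
longer than a minimum length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import FeatureSet, merge_intervals, overlaps_any, subtract

__all__ = ["CutoffPeakSets", "Blacklist", "build_blacklist",
           "minimal_region_reduce", "consolidate_peaks", "ConsolidationLog"]

#: MACS2 p-value cutoffs used for multi-cutoff calling, most to least lenient.
DEFAULT_CUTOFFS = (0.05, 1e-2, 1e-4)


@dataclass
class CutoffPeakSets:
    """Peak sets per replicate and per p-value cutoff.

    ``sets[replicate][cutoff]`` is the FeatureSet called at that cutoff.
    """

    sets: Mapping[str, Mapping[float, FeatureSet]]

    def all_sets(self) -> list[FeatureSet]:
        out = []
        for rep in self.sets:
            for cutoff in self.sets[rep]:
                out.append(self.sets[rep][cutoff])
        return out


@dataclass
class Blacklist:
    """Merged excluded regions (hyper-ChIPable loci)."""

    regions: FeatureSet

    def __len__(self) -> int:
        return len(self.regions)


def build_blacklist(controls: Sequence[FeatureSet]) -> Blacklist:
    """Union-merge negative-control peak sets into a blacklist.

    Typical inputs are broad-peak calls from the untagged and the two tagged
    pre-meiotic control samples.
    """
    if not controls:
        raise ValueError("at least one control peak set required")
    nonempty = [c for c in controls if len(c)]
    if not nonempty:
        return Blacklist(FeatureSet.empty("blacklist"))
    chroms = np.concatenate([c.chroms for c in nonempty])
    starts = np.concatenate([c.starts for c in nonempty])
    ends = np.concatenate([c.ends for c in nonempty])
    pooled = FeatureSet(chroms, starts, ends, name="blacklist")
    return Blacklist(merge_intervals(pooled, 0))


def minimal_region_reduce(peaksets: Sequence[FeatureSet]) -> FeatureSet:
    """Reduce overlapping peaks across pooled inputs to the smallest member.

    Peaks from all inputs are grouped into overlap-connected components
    (sharing >= 1 bp); each component is represented by its shortest interval
    (ties: leftmost, then first input order). Disjoint peaks pass through.
    The chosen interval keeps its score when present.
    """
    if not peaksets:
        raise ValueError("at least one peak set required")
    records = []  # (chrom, start, end, score, set_idx, row_idx)
    for si, fs in enumerate(peaksets):
        sc = fs.scores
        for ri in range(len(fs)):
            records.append((fs.chroms[ri], int(fs.starts[ri]), int(fs.ends[ri]),
                            float(sc[ri]) if sc is not None else np.nan, si, ri))
    if not records:
        return FeatureSet.empty("reduced")
    records.sort(key=lambda r: (str(r[0]), r[1], r[2]))
    out = []
    any_score = False
    comp: list[tuple] = []
    comp_end = None

    def flush():
        nonlocal any_score
        best = min(comp, key=lambda r: (r[2] - r[1], r[1], r[4], r[5]))
        if not np.isnan(best[3]):
            any_score = True
        out.append(best)

    prev_chrom = None
    for rec in records:
        c, s, e = rec[0], rec[1], rec[2]
        if comp and c == prev_chrom and s < comp_end:
            comp.append(rec)
            comp_end = max(comp_end, e)
        else:
            if comp:
                flush()
            comp = [rec]
            comp_end = e
            prev_chrom = c
    flush()
    chroms = np.array([r[0] for r in out], dtype=object)
    scores = [r[3] for r in out] if any_score else None
    return FeatureSet(chroms, [r[1] for r in out], [r[2] for r in out],
                      scores, name="reduced")


@dataclass
class ConsolidationLog:
    """Counts surviving each stage of the consolidation cascade."""

    input: int = 0
    after_minimal_region: int = 0
    after_merge: int = 0
    after_t0_removal: int = 0
    after_blacklist_trim: int = 0
    after_length_filter: int = 0
    stages: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"input": self.input,
                "minimal_region": self.after_minimal_region,
                "merge": self.after_merge,
                "t0_removal": self.after_t0_removal,
                "blacklist_trim": self.after_blacklist_trim,
                "length_filter": self.after_length_filter}


def consolidate_peaks(raw: CutoffPeakSets | Sequence[FeatureSet],
                      t0_peaks: FeatureSet | None = None,
                      blacklist: Blacklist | None = None,
                      merge_gap: int = 350,
                      min_len: int = 200,
                      merge_before_t0: bool = True,
                      return_log: bool = False):
    """Run the full peak-consolidation cascade.

    Stages: minimal-region reduction over all replicates x cutoffs ->
    merge regions closer than ``merge_gap`` -> remove whole peaks overlapping
    ``t0_peaks`` -> trim coordinates overlapping the blacklist -> retain
    fragments strictly longer than ``min_len``. The t = 0 h subtraction is
    whole-peak removal while the blacklist trims coordinates, reflecting the
    two distinct treatments the upstream protocol applies.
    """
    sets = raw.all_sets() if isinstance(raw, CutoffPeakSets) else list(raw)
    if not sets or all(len(s) == 0 for s in sets):
        raise ValueError("no input peaks")
    log = ConsolidationLog(input=sum(len(s) for s in sets))

    fs = minimal_region_reduce(sets)
    log.after_minimal_region = len(fs)

    def do_merge(f):
        return merge_intervals(f, merge_gap) if len(f) else f

    def do_t0(f):
        if t0_peaks is None or len(t0_peaks) == 0 or len(f) == 0:
            return f
        return f.select(~overlaps_any(f, t0_peaks))

    if merge_before_t0:
        fs = do_merge(fs)
        log.after_merge = len(fs)
        fs = do_t0(fs)
        log.after_t0_removal = len(fs)
    else:
        fs = do_t0(fs)
        log.after_t0_removal = len(fs)
        fs = do_merge(fs)
        log.after_merge = len(fs)

    if blacklist is not None and len(blacklist.regions) and len(fs):
        fs = subtract(fs, blacklist.regions)
    log.after_blacklist_trim = len(fs)

    if len(fs):
        fs = fs.select(fs.lengths > min_len)
    log.after_length_filter = len(fs)
    fs.name = "consolidated"
    if return_log:
        return fs, log
    return fs
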