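"""Shared fixtures and a per-base boolean oracle for interval operations.

The oracle materializes interval sets as boolean base arrays on small
chromosomes, so set algebra reduces to elementwise boolean logic that is
independent of the sweep-line implementations under test.
"""

from __future__ import annotations

import numpy as np
import pytest

from loopaxis.genome import GenomeLayout
from loopaxis.intervals import FeatureSet


@pytest.fixture
def small_genome():
    return GenomeLayout([("chrA", 10_000), ("chrB", 8_000)])


def mask_of(fs: FeatureSet, genome: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-base coverage mask of a feature set."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in genome.chromosomes}
    for c, s, e in fs:
        masks[c][s:e] = True
    return masks


def count_of(sets, genome: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-base count of how many sets cover each base."""
    counts = {c: np.zeros(l, dtype=int) for c, l in genome.chromosomes}
    for fs in sets:
        m = mask_of(fs, genome)
        for c in counts:
            counts[c] += m[c].astype(int)
    return counts


def runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open (start, end)."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def intervals_of(masks: dict[str, np.ndarray]) -> list[tuple[str, int, int]]:
    out = []
    for c in sorted(masks):
        out.extend((c, s, e) for s, e in runs_of(masks[c]))
    return out


def random_feature_set(rng: np.random.Generator, genome: GenomeLayout,
                       n: int, max_len: int = 500, name: str = "rand") -> FeatureSet:
    """Random (possibly overlapping) intervals across the genome."""
    recs = []
    chroms = genome.chromosomes
    for _ in range(n):
        c, length = chroms[rng.integers(len(chroms))]
        l = int(rng.integers(1, max_len + 1))
        s = int(rng.integers(0, length - l + 1))
        recs.append((c, s, s + l))
    return FeatureSet.from_records(recs, name=name)
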