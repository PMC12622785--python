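"""Genome layout: an ordered list of chromosome names and lengths.

Coordinates throughout the package are 0-based, half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths in base pairs.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs. Names must be unique and
        lengths strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __init__(self, chromosomes):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome layout")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "_index", {n: l for n, l in chroms})

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome layout") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    @classmethod
    def read(cls, path) -> "GenomeLayout":
        """Read a 2+ column ``chrom\\tlength`` TSV (faidx .fai accepted;
        extra columns ignored)."""
        chroms = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{i}: expected at least 2 columns")
                try:
                    length = int(parts[1])
                except ValueError:
                    raise ValueError(f"{path}:{i}: length {parts[1]!r} is not an integer")
                chroms.append((parts[0], length))
        if not chroms:
            raise ValueError(f"{path}: no chromosomes found")
        return cls(chroms)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for n, l in self.chromosomes:
                fh.write(f"{n}\t{l}\n")
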