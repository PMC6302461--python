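"""Genome coordinate system and fixed-width binning.

Every downstream stage addresses the genome through dense global bin
indices: chromosomes are kept in file order, each chromosome is tiled
with non-overlapping fixed-width bins (the trailing bin may be short),
and bins are numbered consecutively across chromosomes. Coordinates
are 0-based, half-open throughout the package; format conversions
(1-based contact lists) happen in the readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeLayout",
    "Bin",
    "load_chrom_sizes",
    "make_bins",
    "locate_bin",
]

DEFAULT_BIN_SIZE = 1000


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths (bp).

    Order is meaningful: it fixes the global bin numbering.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {', '.join(dupes)}")
        for name, length in self.chromosomes:
            if not name:
                raise ValueError("empty chromosome name")
            if not isinstance(length, (int, np.integer)) or length < 1:
                raise ValueError(f"chromosome {name!r}: length must be a positive integer, got {length!r}")
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def lengths(self) -> list[int]:
        return [c[1] for c in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        try:
            return dict(self.chromosomes)[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_index(self, chrom: str) -> int:
        for i, (name, _) in enumerate(self.chromosomes):
            if name == chrom:
                return i
        raise KeyError(f"unknown chromosome {chrom!r}")

    def n_bins(self, bin_size: int = DEFAULT_BIN_SIZE) -> int:
        return int(sum(-(-l // bin_size) for l in self.lengths))

    def bin_offsets(self, bin_size: int = DEFAULT_BIN_SIZE) -> dict[str, int]:
        """Global index of each chromosome's first bin."""
        offsets: dict[str, int] = {}
        acc = 0
        for name, length in self.chromosomes:
            offsets[name] = acc
            acc += -(-length // bin_size)
        return offsets

    def bin_chrom_ids(self, bin_size: int = DEFAULT_BIN_SIZE) -> np.ndarray:
        """Chromosome ordinal for every global bin index (vectorised lookups)."""
        counts = [-(-l // bin_size) for l in self.lengths]
        return np.repeat(np.arange(len(counts)), counts)


@dataclass(frozen=True)
class Bin:
    """A fixed-width genome segment; ``end - start`` may be short at a chromosome tail."""

    chrom: str
    start: int
    end: int
    global_index: int

    def __post_init__(self) -> None:
        if not (1 <= self.end - self.start):
            raise ValueError(f"bin [{self.start}, {self.end}) on {self.chrom} is empty")


def load_chrom_sizes(path) -> GenomeLayout:
    """Parse a UCSC-style two-column chrom.sizes file.

    Raises ``ValueError`` naming the offending line for duplicate names,
    non-numeric or non-positive lengths, and for an empty file.
    """
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns, got {line!r}")
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric length {fields[1]!r}") from None
            if length < 1:
                raise ValueError(f"{path}:{lineno}: non-positive length {length} for {name!r}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return GenomeLayout(tuple(chroms))


def make_bins(layout: GenomeLayout, bin_size: int = DEFAULT_BIN_SIZE) -> list[Bin]:
    """Tile every chromosome with half-open fixed-width bins.

    Per chromosome the bin count is ``ceil(length / bin_size)``; the last
    bin is truncated at the chromosome end rather than dropped.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    bins: list[Bin] = []
    idx = 0
    for name, length in layout.chromosomes:
        for start in range(0, length, bin_size):
            bins.append(Bin(name, start, min(start + bin_size, length), idx))
            idx += 1
    return bins


def locate_bin(layout: GenomeLayout, chrom: str, pos: int, bin_size: int = DEFAULT_BIN_SIZE) -> int:
    """Global index of the unique bin containing ``pos`` (0-based)."""
    length = layout.length_of(chrom)
    if not (0 <= pos < length):
        raise ValueError(f"position {pos} out of range for {chrom} (length {length})")
    return layout.bin_offsets(bin_size)[chrom] + pos // bin_size
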