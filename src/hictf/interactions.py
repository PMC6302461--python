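"""Contact-list reading, bin-pair aggregation, and interaction filtering.

A raw Hi-C contact list (chrom1, pos1, chrom2, pos2, read_count) is mapped
onto the fixed 1-kb bins, duplicate bin pairs are summed, and two filters
are applied before any statistics: very close intra-chromosomal pairs
(genomic separation under one bin width) are discarded as self-ligation
artefacts, and low-intensity interactions (fewer than ``min_reads``
supporting reads, default 6) are discarded as likely noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import DEFAULT_BIN_SIZE, GenomeLayout

__all__ = [
    "ContactRecord",
    "InteractionSet",
    "read_contacts",
    "bin_contacts",
    "filter_interactions",
    "subset_interactions",
    "count_distribution",
    "write_interactions",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 6
DEFAULT_MIN_SEPARATION_BINS = 2


@dataclass(frozen=True)
class ContactRecord:
    """One validated contact-list row; positions already 0-based."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    count: int
    line: int = 0  # source line number, for error reporting


@dataclass
class InteractionSet:
    """Aggregated bin-pair interactions over one genome layout.

    Pairs are canonical (``bin_a < bin_b``) and unique; ``n`` holds the
    summed read counts and ``is_inter`` flags inter-chromosomal pairs.
    ``provenance`` accumulates the parameters and removal counts of every
    transformation applied.
    """

    layout: GenomeLayout
    bin_size: int
    bin_a: np.ndarray
    bin_b: np.ndarray
    n: np.ndarray
    is_inter: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_a = np.asarray(self.bin_a, dtype=np.int64)
        self.bin_b = np.asarray(self.bin_b, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.is_inter = np.asarray(self.is_inter, dtype=bool)
        if not (self.bin_a < self.bin_b).all():
            raise ValueError("interactions must be stored canonically with bin_a < bin_b")
        keys = self.bin_a * self.layout.n_bins(self.bin_size) + self.bin_b
        if len(np.unique(keys)) != len(keys):
            raise ValueError("duplicate bin pairs in InteractionSet")

    def __len__(self) -> int:
        return len(self.n)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with genomic coordinates of both bin starts."""
        offsets = self.layout.bin_offsets(self.bin_size)
        names = self.layout.names
        starts = np.array(list(offsets.values()))
        chrom_of = self.layout.bin_chrom_ids(self.bin_size)

        def coords(idx: np.ndarray) -> tuple[list[str], np.ndarray]:
            cid = chrom_of[idx]
            return [names[i] for i in cid], (idx - starts[cid]) * self.bin_size

        chrom_a, start_a = coords(self.bin_a)
        chrom_b, start_b = coords(self.bin_b)
        return pd.DataFrame(
            {
                "chrom_a": chrom_a,
                "start_a": start_a,
                "chrom_b": chrom_b,
                "start_b": start_b,
                "bin_a": self.bin_a,
                "bin_b": self.bin_b,
                "n": self.n,
                "is_inter": self.is_inter,
            }
        )


def read_contacts(path, layout: GenomeLayout) -> list[ContactRecord]:
    """Read a 5-column contact TSV (chrom1, pos1, chrom2, pos2, count).

    Positions in the file are 1-based (the common pair-list convention)
    and are converted to 0-based here. ``#`` comment lines are skipped.
    Malformed lines, unknown chromosomes, out-of-range positions and
    counts < 1 raise ``ValueError`` with the line number.
    """
    lengths = dict(layout.chromosomes)
    records: list[ContactRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated columns, got {len(fields)}")
            chrom1, chrom2 = fields[0], fields[2]
            try:
                pos1, pos2, count = int(fields[1]), int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position or count") from None
            for chrom, pos in ((chrom1, pos1), (chrom2, pos2)):
                if chrom not in lengths:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if not (1 <= pos <= lengths[chrom]):
                    raise ValueError(
                        f"{path}:{lineno}: position {pos} out of range for {chrom} (length {lengths[chrom]})"
                    )
            if count < 1:
                raise ValueError(f"{path}:{lineno}: read count must be >= 1, got {count}")
            records.append(ContactRecord(chrom1, pos1 - 1, chrom2, pos2 - 1, count, lineno))
    return records


def bin_contacts(
    records: list[ContactRecord], layout: GenomeLayout, bin_size: int = DEFAULT_BIN_SIZE
) -> InteractionSet:
    """Assign each contact to its canonical bin pair and sum duplicate pairs.

    Records whose two ends fall in one bin cannot form a pair and are
    dropped (their number and read total are logged and recorded in
    provenance).
    """
    offsets = layout.bin_offsets(bin_size)
    if not records:
        return InteractionSet(
            layout,
            bin_size,
            np.empty(0, np.int64),
            np.empty(0, np.int64),
            np.empty(0, np.int64),
            np.empty(0, bool),
            provenance={"bin_size": bin_size, "records_in": 0, "same_bin_dropped": 0, "same_bin_reads": 0},
        )
    a = np.array([offsets[r.chrom1] + r.pos1 // bin_size for r in records], dtype=np.int64)
    b = np.array([offsets[r.chrom2] + r.pos2 // bin_size for r in records], dtype=np.int64)
    counts = np.array([r.count for r in records], dtype=np.int64)

    same = a == b
    n_same = int(same.sum())
    reads_same = int(counts[same].sum())
    if n_same:
        logger.info("dropped %d same-bin contact record(s) carrying %d reads", n_same, reads_same)
    a, b, counts = a[~same], b[~same], counts[~same]
    lo, hi = np.minimum(a, b), np.maximum(a, b)

    n_bins = layout.n_bins(bin_size)
    keys = lo * n_bins + hi
    uniq, inverse = np.unique(keys, return_inverse=True)
    summed = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(summed, inverse, counts)
    bin_a, bin_b = uniq // n_bins, uniq % n_bins

    chrom_of = layout.bin_chrom_ids(bin_size)
    is_inter = chrom_of[bin_a] != chrom_of[bin_b]
    return InteractionSet(
        layout,
        bin_size,
        bin_a,
        bin_b,
        summed,
        is_inter,
        provenance={
            "bin_size": bin_size,
            "records_in": len(records),
            "same_bin_dropped": n_same,
            "same_bin_reads": reads_same,
        },
    )


def filter_interactions(
    iset: InteractionSet,
    min_reads: int = DEFAULT_MIN_READS,
    min_separation_bins: int = DEFAULT_MIN_SEPARATION_BINS,
) -> InteractionSet:
    """Apply the close-pair and low-intensity filters.

    Intra-chromosomal pairs whose bin indices differ by less than
    ``min_separation_bins`` (default 2, i.e. identical-or-adjacent 1-kb
    bins — genomic separation under 1 kb) are removed first; then any
    interaction with ``n < min_reads`` is removed. Idempotent.
    """
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    if min_separation_bins < 1:
        raise ValueError(f"min_separation_bins must be >= 1, got {min_separation_bins}")
    close = ~iset.is_inter & ((iset.bin_b - iset.bin_a) < min_separation_bins)
    weak = iset.n < min_reads
    keep = ~close & ~weak
    n_close = int(close.sum())
    n_weak = int((weak & ~close).sum())
    logger.info(
        "filter_interactions: removed %d close intra-chromosomal pair(s), %d low-read pair(s); %d kept",
        n_close,
        n_weak,
        int(keep.sum()),
    )
    prov = dict(iset.provenance)
    prov.update(
        {
            "min_reads": min_reads,
            "min_separation_bins": min_separation_bins,
            "removed_close": n_close,
            "removed_low_reads": n_weak,
        }
    )
    return InteractionSet(
        iset.layout, iset.bin_size, iset.bin_a[keep], iset.bin_b[keep], iset.n[keep], iset.is_inter[keep], prov
    )


def subset_interactions(iset: InteractionSet, which: str = "inter") -> InteractionSet:
    """Restrict to inter-chromosomal pairs, intra pairs, or keep all."""
    if which == "all":
        mask = np.ones(len(iset), dtype=bool)
    elif which == "inter":
        mask = iset.is_inter
    elif which == "intra":
        mask = ~iset.is_inter
    else:
        raise ValueError(f"unknown subset selector {which!r}; expected 'all', 'inter' or 'intra'")
    prov = dict(iset.provenance)
    prov["subset"] = which
    return InteractionSet(
        iset.layout, iset.bin_size, iset.bin_a[mask], iset.bin_b[mask], iset.n[mask], iset.is_inter[mask], prov
    )


def count_distribution(iset: InteractionSet) -> pd.DataFrame:
    """Histogram of read counts with the cumulative share of interactions.

    Columns: ``n``, ``count``, ``cum_share`` (fraction of interactions
    with read count <= that row's ``n``).
    """
    if len(iset) == 0:
        return pd.DataFrame({"n": pd.Series(dtype=np.int64), "count": pd.Series(dtype=np.int64), "cum_share": pd.Series(dtype=float)})
    values, counts = np.unique(iset.n, return_counts=True)
    cum = np.cumsum(counts) / counts.sum()
    return pd.DataFrame({"n": values, "count": counts, "cum_share": cum})


def write_interactions(iset: InteractionSet, path) -> None:
    """Write the interaction table as TSV (chrom_a, start_a, chrom_b, start_b, n, is_inter)."""
    df = iset.to_frame()[["chrom_a", "start_a", "chrom_b", "start_b", "n", "is_inter"]]
    df.to_csv(path, sep="\t", index=False)


def read_interactions(path, layout: GenomeLayout, bin_size: int = DEFAULT_BIN_SIZE) -> InteractionSet:
    """Read back a table written by :func:`write_interactions`."""
    df = pd.read_csv(path, sep="\t")
    offsets = layout.bin_offsets(bin_size)
    bin_a = np.array([offsets[c] + s // bin_size for c, s in zip(df["chrom_a"], df["start_a"])], np.int64)
    bin_b = np.array([offsets[c] + s // bin_size for c, s in zip(df["chrom_b"], df["start_b"])], np.int64)
    return InteractionSet(
        layout, bin_size, bin_a, bin_b, df["n"].to_numpy(np.int64), df["is_inter"].to_numpy(bool),
        provenance={"source": str(path)},
    )
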