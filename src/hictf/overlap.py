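"""TF binding sites: bin marking, interaction labelling, overlapping-ratio curves.

Binding intervals (BED4+, the 4th column naming the TF) are collapsed to
the set of 1-kb bins each site touches. An interaction is *positive* for a
TF when at least one of its two bins is bound. The overlapping ratio at an
intensity threshold T is |A∩B| / |A|, where A is the set of interactions
with read count n >= T and B the TF's positive interactions — the per-TF
curve of this ratio over a threshold grid is the statistic both detection
methods consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DEFAULT_BIN_SIZE, GenomeLayout
from .interactions import InteractionSet

__all__ = [
    "TFBSRecord",
    "TFBindingMap",
    "LabelMatrix",
    "RatioCurve",
    "read_tfbs",
    "mark_bins",
    "label_interactions",
    "ratio_curves",
    "write_curves",
]

DEFAULT_CURVE_GRID = range(6, 101)  # reporting grid; the chi-square scan uses 7..45


@dataclass(frozen=True)
class TFBSRecord:
    """One binding interval (0-based half-open) attributed to a TF."""

    tf: str
    chrom: str
    start: int
    end: int


@dataclass
class TFBindingMap:
    """Per-TF set of bound global bin indices.

    TFs with no sites are kept with an empty set so they stay visible
    (and reportable as untestable) downstream.
    """

    layout: GenomeLayout
    bin_size: int
    bound: dict[str, frozenset[int]]

    @property
    def tfs(self) -> list[str]:
        return list(self.bound)


@dataclass
class LabelMatrix:
    """Per-(interaction, TF) positivity plus the aligned read-count vector."""

    tfs: list[str]
    matrix: np.ndarray  # bool, shape (n_interactions, n_tfs)
    n: np.ndarray  # int read counts, shape (n_interactions,)
    iset: InteractionSet | None = None  # needed only for coordinate-level export

    def column(self, tf: str) -> np.ndarray:
        try:
            return self.matrix[:, self.tfs.index(tf)]
        except ValueError:
            raise KeyError(f"unknown TF {tf!r}") from None


@dataclass
class RatioCurve:
    """|A∩B|/|A| for one TF over a threshold grid.

    ``ratio`` is NaN (and ``defined`` False) wherever |A| = 0; an
    undefined point is never reported as 0.
    """

    tf: str
    thresholds: np.ndarray
    size_a: np.ndarray
    size_ab: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.size_a > 0

    @property
    def ratio(self) -> np.ndarray:
        out = np.full(len(self.thresholds), np.nan)
        d = self.defined
        out[d] = self.size_ab[d] / self.size_a[d]
        return out

    def at(self, threshold: int) -> tuple[int, int]:
        """(|A|, |A∩B|) at one threshold."""
        i = np.nonzero(self.thresholds == threshold)[0]
        if len(i) == 0:
            raise KeyError(f"threshold {threshold} not on the curve grid")
        return int(self.size_a[i[0]]), int(self.size_ab[i[0]])


def read_tfbs(path, layout: GenomeLayout) -> list[TFBSRecord]:
    """Read a BED4+ file of binding sites; the name column is the TF.

    Intervals are validated against the layout (within chromosome bounds,
    start < end); one file may interleave many TFs.
    """
    lengths = dict(layout.chromosomes)
    records: list[TFBSRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED4+ required (chrom, start, end, tf name)")
            chrom, name = fields[0], fields[3]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer interval bounds") from None
            if chrom not in lengths:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0 or end > lengths[chrom]:
                raise ValueError(f"{path}:{lineno}: interval [{start}, {end}) outside {chrom} (length {lengths[chrom]})")
            if not name:
                raise ValueError(f"{path}:{lineno}: empty TF name")
            records.append(TFBSRecord(name, chrom, start, end))
    return records


def mark_bins(
    records: list[TFBSRecord],
    layout: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
    tf_universe: list[str] | None = None,
) -> TFBindingMap:
    """Collapse binding intervals to bound bins (>= 1 bp overlap marks a bin).

    A site spanning a bin boundary marks every touched bin. ``tf_universe``
    may add TFs with no sites so they are retained with empty bin sets.
    """
    offsets = layout.bin_offsets(bin_size)
    bound: dict[str, set[int]] = {}
    if tf_universe is not None:
        for tf in tf_universe:
            bound[tf] = set()
    for rec in records:
        first = rec.start // bin_size
        last = (rec.end - 1) // bin_size
        base = offsets[rec.chrom]
        bound.setdefault(rec.tf, set()).update(range(base + first, base + last + 1))
    return TFBindingMap(layout, bin_size, {tf: frozenset(b) for tf, b in bound.items()})


def label_interactions(iset: InteractionSet, binding: TFBindingMap) -> LabelMatrix:
    """Mark interaction i positive for tf iff either of its bins is bound."""
    if binding.layout is not iset.layout and binding.layout != iset.layout:
        raise ValueError("interaction set and binding map use different genome layouts")
    if binding.bin_size != iset.bin_size:
        raise ValueError("interaction set and binding map use different bin sizes")
    n_bins = iset.layout.n_bins(iset.bin_size)
    tfs = binding.tfs
    matrix = np.zeros((len(iset), len(tfs)), dtype=bool)
    for j, tf in enumerate(tfs):
        bins = binding.bound[tf]
        if not bins:
            continue
        mask = np.zeros(n_bins, dtype=bool)
        mask[np.fromiter(bins, dtype=np.int64)] = True
        matrix[:, j] = mask[iset.bin_a] | mask[iset.bin_b]
    return LabelMatrix(tfs, matrix, iset.n.copy(), iset)


def ratio_curves(labels: LabelMatrix, t_grid=DEFAULT_CURVE_GRID) -> dict[str, RatioCurve]:
    """Overlapping-ratio curve for every TF over ``t_grid`` (sorted ascending).

    Counting is exact: at each threshold T, |A| is the number of
    interactions with n >= T and |A∩B| the number of those positive for
    the TF. Implemented by sorting once on n and taking suffix sums, so
    the full grid costs O(I log I + I·P).
    """
    thresholds = np.asarray(list(t_grid), dtype=np.int64)
    if len(thresholds) == 0:
        raise ValueError("empty threshold grid")
    if not np.all(np.diff(thresholds) > 0):
        raise ValueError("threshold grid must be strictly ascending")
    n_int = len(labels.n)
    order = np.argsort(labels.n, kind="stable")
    sorted_n = labels.n[order]
    # suffix[i, j] = number of positives for tf j among interactions ranked i..end by n
    sorted_m = labels.matrix[order].astype(np.int64)
    suffix = np.vstack([np.cumsum(sorted_m[::-1], axis=0)[::-1], np.zeros((1, len(labels.tfs)), np.int64)])
    first_ge = np.searchsorted(sorted_n, thresholds, side="left")
    size_a = n_int - first_ge
    size_ab = suffix[first_ge, :]  # shape (len(thresholds), n_tfs)
    return {
        tf: RatioCurve(tf, thresholds.copy(), size_a.copy(), size_ab[:, j].copy())
        for j, tf in enumerate(labels.tfs)
    }


def write_curves(curves: dict[str, RatioCurve], path) -> None:
    """Write all curves as a long TSV (tf, T, size_A, size_AB, ratio)."""
    frames = []
    for tf, c in curves.items():
        frames.append(
            pd.DataFrame(
                {"tf": tf, "T": c.thresholds, "size_A": c.size_a, "size_AB": c.size_ab, "ratio": c.ratio}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_curves(path) -> dict[str, RatioCurve]:
    """Read back a long TSV written by :func:`write_curves`."""
    df = pd.read_csv(path, sep="\t")
    curves: dict[str, RatioCurve] = {}
    for tf, g in df.groupby("tf", sort=False):
        g = g.sort_values("T")
        curves[str(tf)] = RatioCurve(
            str(tf),
            g["T"].to_numpy(np.int64),
            g["size_A"].to_numpy(np.int64),
            g["size_AB"].to_numpy(np.int64),
        )
    return curves


def plot_curves(curves: dict[str, RatioCurve], path, highlight: list[str] | None = None) -> None:
    """Plot every TF's ratio curve; ``highlight`` TFs in colour, the rest dashed grey."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    highlight = highlight or []
    fig, ax = plt.subplots(figsize=(8, 5))
    for tf, c in curves.items():
        if tf in highlight:
            ax.plot(c.thresholds, c.ratio, label=tf, lw=1.5)
        else:
            ax.plot(c.thresholds, c.ratio, color="0.7", ls="--", lw=0.5)
    ax.set_xlabel("threshold T (reads)")
    ax.set_ylabel("overlapping ratio |A∩B|/|A|")
    if highlight:
        ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
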