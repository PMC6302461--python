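"""Chi-square threshold scan for differential TF binding across interaction intensity.

For each TF and each threshold T in an inclusive integer grid (default
7..45), interactions are cross-classified by intensity (n >= T vs n < T)
and TF positivity into a 2x2 table; Pearson's chi-square with 1 df tests
whether the TF's binding is distributed differently between the strong
and weak groups. P-values are Bonferroni-adjusted over the family of all
testable (TF, T) cells by default (a per-TF family is available), and a
TF is called significant when at least one adjusted p falls below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .overlap import LabelMatrix

__all__ = [
    "Untestable",
    "ContingencyTable",
    "ScanResult",
    "contingency",
    "chisq_test",
    "scan",
    "significant_tfs",
]

DEFAULT_T_MIN = 7
DEFAULT_T_MAX = 45
DEFAULT_ALPHA = 0.05


class Untestable(Exception):
    """A contingency table with a zero margin; no p-value is defined."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-classification at threshold T.

    Rows: intensity (A: n >= T, Ā: n < T); columns: TF positivity (B, B̄).
    ``a11`` = |A∩B|, ``a12`` = |Ā∩B|, ``a21`` = |A∩B̄|, ``a22`` = |Ā∩B̄|.
    """

    a11: int
    a12: int
    a21: int
    a22: int
    T: int

    @property
    def total(self) -> int:
        return self.a11 + self.a12 + self.a21 + self.a22

    @property
    def testable(self) -> bool:
        """All four margins positive (both rows and both columns occupied)."""
        return (
            self.a11 + self.a21 > 0
            and self.a12 + self.a22 > 0
            and self.a11 + self.a12 > 0
            and self.a21 + self.a22 > 0
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]], dtype=np.int64)


def contingency(labels: LabelMatrix, tf: str, T: int) -> ContingencyTable:
    """Build the 2x2 table for one TF at one threshold by exact counting."""
    if T < 1:
        raise ValueError(f"threshold must be >= 1, got {T}")
    pos = labels.column(tf)
    strong = labels.n >= T
    return ContingencyTable(
        a11=int(np.sum(strong & pos)),
        a12=int(np.sum(~strong & pos)),
        a21=int(np.sum(strong & ~pos)),
        a22=int(np.sum(~strong & ~pos)),
        T=T,
    )


def _pearson_2x2(a11, a12, a21, a22, yates: bool = False):
    """Vectorised Pearson chi-square on 2x2 cells (df = 1).

    Closed form: stat = N (ad - bc)^2 / (r1 r2 c1 c2), with the Yates
    variant subtracting N/2 from |ad - bc| (floored at 0) when requested.
    """
    a11 = np.asarray(a11, dtype=float)
    a12 = np.asarray(a12, dtype=float)
    a21 = np.asarray(a21, dtype=float)
    a22 = np.asarray(a22, dtype=float)
    n = a11 + a12 + a21 + a22
    r1, r2 = a11 + a12, a21 + a22
    c1, c2 = a11 + a21, a12 + a22
    det = np.abs(a11 * a22 - a12 * a21)
    if yates:
        det = np.maximum(det - n / 2.0, 0.0)
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * det**2 / denom, np.nan)
    return stat


def chisq_test(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test (df = 1) on a 2x2 table.

    Continuity correction is off by default. A zero margin raises
    :class:`Untestable` rather than producing a spurious statistic.
    """
    if not table.testable:
        raise Untestable(f"zero margin in 2x2 table at T={table.T}: {table.as_array().tolist()}")
    stat = float(_pearson_2x2(table.a11, table.a12, table.a21, table.a22, yates=yates))
    return stat, float(stats.chi2.sf(stat, df=1))


@dataclass
class ScanResult:
    """Full scan output.

    ``cells``: one row per (tf, T) with the table, statistic, raw and
    adjusted p, and testability. ``summary``: per-TF counts of thresholds
    with raw p < alpha and adjusted p < alpha. ``family_size`` is the
    Bonferroni multiplier m actually used (untestable cells excluded).
    """

    cells: pd.DataFrame
    summary: pd.DataFrame
    family_size: int | dict[str, int]
    alpha: float
    bonferroni_family: str


def scan(
    labels: LabelMatrix,
    T_min: int = DEFAULT_T_MIN,
    T_max: int = DEFAULT_T_MAX,
    alpha: float = DEFAULT_ALPHA,
    yates: bool = False,
    bonferroni_family: str = "global",
) -> ScanResult:
    """Test every (TF, T) cell on the inclusive grid T_min..T_max.

    ``bonferroni_family`` is ``"global"`` (m = all testable cells across
    TFs and thresholds) or ``"per-tf"`` (m = testable thresholds of that
    TF). Untestable cells carry no p-value and do not count toward m.
    """
    if T_min > T_max:
        raise ValueError(f"T_min {T_min} > T_max {T_max}")
    if bonferroni_family not in ("global", "per-tf"):
        raise ValueError(f"unknown bonferroni_family {bonferroni_family!r}")
    thresholds = np.arange(T_min, T_max + 1)
    n = labels.n
    total = len(n)
    strong = n[None, :] >= thresholds[:, None]  # (T, I)
    n_strong = strong.sum(axis=1)  # |A| per threshold
    pos_total = labels.matrix.sum(axis=0)  # |B| per tf
    a11 = strong.astype(np.int64) @ labels.matrix.astype(np.int64)  # (T, P)
    a21 = n_strong[:, None] - a11
    a12 = pos_total[None, :] - a11
    a22 = total - a11 - a12 - a21

    testable = (
        ((a11 + a21) > 0) & ((a12 + a22) > 0) & ((a11 + a12) > 0) & ((a21 + a22) > 0)
    )
    stat = _pearson_2x2(a11, a12, a21, a22, yates=yates)
    praw = np.where(testable, stats.chi2.sf(np.where(testable, stat, 0.0), df=1), np.nan)

    if bonferroni_family == "global":
        m = int(testable.sum())
        padj = np.minimum(praw * max(m, 1), 1.0)
        family: int | dict[str, int] = m
    else:
        m_per_tf = testable.sum(axis=0)  # per tf
        padj = np.minimum(praw * np.maximum(m_per_tf, 1)[None, :], 1.0)
        family = {tf: int(m_per_tf[j]) for j, tf in enumerate(labels.tfs)}

    rows = []
    for j, tf in enumerate(labels.tfs):
        for i, T in enumerate(thresholds):
            rows.append(
                (
                    tf,
                    int(T),
                    int(a11[i, j]),
                    int(a12[i, j]),
                    int(a21[i, j]),
                    int(a22[i, j]),
                    stat[i, j] if testable[i, j] else np.nan,
                    praw[i, j],
                    padj[i, j],
                    bool(testable[i, j]),
                )
            )
    cells = pd.DataFrame(
        rows, columns=["tf", "T", "a11", "a12", "a21", "a22", "statistic", "p", "p_adj", "testable"]
    )
    grouped = cells.groupby("tf", sort=False)
    summary = pd.DataFrame(
        {
            "tf": list(grouped.groups),
            "n_raw_sig": grouped.apply(lambda g: int((g["p"] < alpha).sum()), include_groups=False).values,
            "n_adj_sig": grouped.apply(lambda g: int((g["p_adj"] < alpha).sum()), include_groups=False).values,
            "n_testable": grouped["testable"].sum().astype(int).values,
        }
    )
    return ScanResult(cells, summary, family, alpha, bonferroni_family)


def significant_tfs(result: ScanResult, alpha: float | None = None) -> list[str]:
    """TFs with at least one Bonferroni-adjusted p below alpha.

    Ordered by the number of significant thresholds (descending), ties
    broken alphabetically.
    """
    alpha = result.alpha if alpha is None else alpha
    counts = (
        result.cells.assign(sig=result.cells["p_adj"] < alpha)
        .groupby("tf", sort=False)["sig"]
        .sum()
    )
    hits = counts[counts > 0]
    return sorted(hits.index, key=lambda tf: (-int(hits[tf]), tf))
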