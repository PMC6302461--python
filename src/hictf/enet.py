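"""Bootstrapped elastic-net selection of TFs associated with interaction intensity.

The regression treats each integer read level n in a range (e.g. 6..40)
as one observation: the response is n itself and the predictors are the
overlapping ratios of all TFs evaluated at threshold n. An elastic-net
linear model (mixed L1/L2 penalty, strength chosen by k-fold
cross-validation) is fitted to bootstrap resamples of the rows, B times
per range over five nested ranges; the per-TF count of resamples in
which its coefficient is nonzero is the stability score, and a TF is
selected when that count exceeds 5% of B in any range or 5% of the grand
total across ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .overlap import RatioCurve

__all__ = [
    "DesignMatrix",
    "BootstrapSelection",
    "build_design",
    "fit_once",
    "bootstrap_select",
    "DEFAULT_RANGES",
]

DEFAULT_RANGES: tuple[tuple[int, int], ...] = ((6, 40), (6, 45), (6, 50), (6, 55), (6, 60))
DEFAULT_B = 500
DEFAULT_THRESHOLD = 0.05
DEFAULT_MIXING = 0.5
DEFAULT_FOLDS = 10
MIN_DESIGN_ROWS = 10
# numerical settings of the coordinate-descent CV: a 30-point log-spaced
# penalty grid and a 1e-3 duality-gap tolerance resolve the CV minimum
# well at these design sizes (35-55 rows) at a fraction of the cost of
# finer grids
N_ALPHAS = 30
CD_TOL = 1e-3
CD_MAX_ITER = 2000


@dataclass
class DesignMatrix:
    """One row per defined read level in a range; columns are TF ratios."""

    levels: np.ndarray  # the read levels n kept as rows
    y: np.ndarray  # response = n
    X: np.ndarray  # (rows, n_tfs) overlapping ratios
    tfs: list[str]
    range_id: tuple[int, int]
    dropped_levels: list[int] = field(default_factory=list)


def build_design(curves: dict[str, RatioCurve], n_range: tuple[int, int]) -> DesignMatrix:
    """Assemble the design for one read range [n_lo, n_hi] (inclusive).

    Levels at which the ratio is undefined (|A| = 0, which is shared by
    all TFs at a given level) are dropped and recorded. Fewer than 10
    usable rows is an error: the fit would be meaningless.
    """
    n_lo, n_hi = n_range
    if n_lo > n_hi:
        raise ValueError(f"bad range [{n_lo}, {n_hi}]")
    tfs = list(curves)
    if not tfs:
        raise ValueError("no ratio curves supplied")
    levels = np.arange(n_lo, n_hi + 1)
    cols = []
    defined = np.ones(len(levels), dtype=bool)
    for tf in tfs:
        c = curves[tf]
        idx = np.searchsorted(c.thresholds, levels)
        if idx.max(initial=0) >= len(c.thresholds) or not np.array_equal(c.thresholds[idx], levels):
            raise ValueError(f"curve for {tf!r} does not cover range [{n_lo}, {n_hi}]")
        defined &= c.defined[idx]
        cols.append(c.ratio[idx])
    X = np.column_stack(cols)
    dropped = [int(l) for l in levels[~defined]]
    levels, X = levels[defined], X[defined]
    if len(levels) < MIN_DESIGN_ROWS:
        raise ValueError(
            f"range [{n_lo}, {n_hi}] leaves only {len(levels)} usable rows (< {MIN_DESIGN_ROWS})"
        )
    return DesignMatrix(levels, levels.astype(float), X, tfs, (n_lo, n_hi), dropped)


def _effective_folds(rows: int, folds: int) -> int:
    # 10-fold CV on a short bootstrap resample can yield degenerate folds
    if rows < 2 * folds:
        return max(3, rows // 5)
    return folds


def fit_once(
    design: DesignMatrix,
    mixing: float = DEFAULT_MIXING,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    rows: np.ndarray | None = None,
) -> dict[str, float]:
    """One elastic-net fit with CV-chosen penalty; returns {tf: beta} for nonzero coefficients.

    Predictors are standardised before fitting and coefficients reported
    on the original scale; the intercept is unpenalised. ``rows`` selects
    a (possibly repeated) subset of design rows, used by the bootstrap.
    A constant response or all-constant predictors yields an empty
    selection with a warning.
    """
    if not (0 < mixing <= 1):
        raise ValueError(f"mixing weight must be in (0, 1], got {mixing}")
    X = design.X if rows is None else design.X[rows]
    y = design.y if rows is None else design.y[rows]
    k = _effective_folds(len(y), folds)
    if len(y) < k:
        raise ValueError(f"{len(y)} rows cannot support {k}-fold cross-validation")
    sd = X.std(axis=0)
    mu = X.mean(axis=0)
    live = sd > 0
    if y.std() == 0 or not live.any():
        warnings.warn("degenerate design (constant response or predictors); empty selection")
        return {}
    Xs = np.zeros_like(X)
    Xs[:, live] = (X[:, live] - mu[live]) / sd[live]
    cv = KFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    model = ElasticNetCV(
        l1_ratio=mixing, alphas=N_ALPHAS, cv=cv, max_iter=CD_MAX_ITER, tol=CD_TOL,
        random_state=seed % (2**32),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on near-degenerate resamples
        model.fit(Xs, y)
    beta = np.zeros(len(design.tfs))
    beta[live] = model.coef_[live] / sd[live]  # back to the original predictor scale
    return {tf: float(b) for tf, b in zip(design.tfs, beta) if b != 0.0}


@dataclass
class BootstrapSelection:
    """Per-TF bootstrap selection counts and effect summaries.

    ``counts``: DataFrame indexed by TF with one column per range plus
    ``total``. ``mean_beta``: mean coefficient over the resamples where
    the TF was selected (NaN if never). ``sign_consistency``: fraction of
    those resamples sharing the majority coefficient sign. ``selected``:
    the default call — count > threshold*B in any range OR >
    threshold*(n_ranges*B) in total; the two sub-criteria are also kept.
    """

    counts: pd.DataFrame
    mean_beta: pd.Series
    sign_consistency: pd.Series
    selected_per_range: pd.Series
    selected_total: pd.Series
    selected: pd.Series
    params: dict

    def selected_tfs(self) -> list[str]:
        """Selected TFs ordered by total count (desc), then name."""
        hits = self.counts.loc[self.selected, "total"]
        return sorted(hits.index, key=lambda tf: (-int(hits[tf]), tf))

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["mean_beta"] = self.mean_beta
        df["sign_consistency"] = self.sign_consistency
        df["selected_per_range"] = self.selected_per_range
        df["selected_total"] = self.selected_total
        df["selected"] = self.selected
        return df.reset_index(names="tf")


def bootstrap_select(
    curves: dict[str, RatioCurve],
    ranges: tuple[tuple[int, int], ...] = DEFAULT_RANGES,
    B: int = DEFAULT_B,
    threshold: float = DEFAULT_THRESHOLD,
    mixing: float = DEFAULT_MIXING,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> BootstrapSelection:
    """Bootstrap the elastic-net fit B times per range and score TF stability.

    Child seeds for every (range, resample) are derived deterministically
    from the master seed, so the whole procedure is reproducible exactly.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    designs = [build_design(curves, r) for r in ranges]
    tfs = designs[0].tfs
    range_names = [f"n{lo}-{hi}" for lo, hi in ranges]
    counts = np.zeros((len(tfs), len(ranges)), dtype=np.int64)
    beta_sums = np.zeros(len(tfs))
    pos_counts = np.zeros(len(tfs), dtype=np.int64)
    neg_counts = np.zeros(len(tfs), dtype=np.int64)
    tf_index = {tf: i for i, tf in enumerate(tfs)}

    master = np.random.default_rng(seed)
    for ri, design in enumerate(designs):
        rng = np.random.default_rng(master.integers(2**31))
        for b in range(B):
            rows = rng.integers(0, len(design.y), size=len(design.y))
            child_seed = int(rng.integers(2**31))
            betas = fit_once(design, mixing=mixing, folds=folds, seed=child_seed, rows=rows)
            for tf, beta in betas.items():
                i = tf_index[tf]
                counts[i, ri] += 1
                beta_sums[i] += beta
                if beta > 0:
                    pos_counts[i] += 1
                else:
                    neg_counts[i] += 1

    total = counts.sum(axis=1)
    count_df = pd.DataFrame(counts, index=pd.Index(tfs, name="tf"), columns=range_names)
    count_df["total"] = total
    with np.errstate(invalid="ignore"):
        mean_beta = pd.Series(np.where(total > 0, beta_sums / np.maximum(total, 1), np.nan), index=count_df.index)
        sign_cons = pd.Series(
            np.where(total > 0, np.maximum(pos_counts, neg_counts) / np.maximum(total, 1), np.nan),
            index=count_df.index,
        )
    per_range_cut = threshold * B
    total_cut = threshold * B * len(ranges)
    sel_range = pd.Series((counts > per_range_cut).any(axis=1), index=count_df.index)
    sel_total = pd.Series(total > total_cut, index=count_df.index)
    params = {
        "B": B,
        "threshold": threshold,
        "mixing": mixing,
        "folds": folds,
        "seed": seed,
        "ranges": [list(r) for r in ranges],
        "per_range_cutoff": per_range_cut,
        "total_cutoff": total_cut,
        "penalty_choice": "cv-min",
        "n_alphas": N_ALPHAS,
        "standardized_predictors": True,
        "intercept_penalized": False,
    }
    return BootstrapSelection(count_df, mean_beta, sign_cons, sel_range, sel_total, sel_range | sel_total, params)
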