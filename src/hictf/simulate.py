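"""Synthetic yeast-like Hi-C interaction and TF-binding simulator with ground truth.

The generator emulates the statistical structure the detection methods
assume, not chromatin physics: a 16-chromosome ~12 Mb genome at 1-kb
bins; ~3,500 "active" bins that participate in interactions; a
heavy-tailed read-count distribution (geometric tail on n − 6, tuned so
roughly half the interactions carry <= 10 reads and counts above 100 are
vanishingly rare); and ~100 TFs of which a small planted subset binds
bins with probability increasing in the bin's interaction intensity
(softmax over exp(b0 + b1·s), s = log1p(max read count touching the
bin)). Null TFs bind uniformly. Every output is a pure function of the
configuration and its master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome import DEFAULT_BIN_SIZE, GenomeLayout
from .interactions import InteractionSet
from .overlap import TFBSRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_interactions",
    "simulate_tfbs",
    "write_fixture",
    "YEAST_CHROM_LENGTHS",
]

# Rounded S. cerevisiae (sacCer3) chromosome lengths, kb resolution.
YEAST_CHROM_LENGTHS: tuple[int, ...] = (
    230000, 813000, 317000, 1532000, 577000, 270000, 1091000, 563000,
    440000, 746000, 667000, 1078000, 924000, 784000, 1091000, 948000,
)

# Geometric success parameter such that P(n <= 10 | n >= 6) = 0.5:
# 1 - (1-p)^5 = 0.5  =>  p = 1 - 0.5**(1/5)
GEOM_P_HALF_AT_10 = 1.0 - 0.5 ** (1.0 / 5.0)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-scale conditions."""

    n_chrom: int = 16
    chrom_lengths: tuple[int, ...] = YEAST_CHROM_LENGTHS
    bin_size: int = DEFAULT_BIN_SIZE
    n_interactions: int = 50_000
    n_active_bins: int = 3_500  # unique fragments participating in interactions
    intra_fraction: float = 0.0
    count_model: str = "geometric"  # or "powerlaw"
    geom_p: float = GEOM_P_HALF_AT_10
    powerlaw_exponent: float = 2.5
    min_count: int = 6
    count_cap: int | None = None
    n_tfs: int = 100
    n_planted: int = 10
    sites_per_tf: int = 150
    site_length: int = 12
    b0: float = 0.0
    b1: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom != len(self.chrom_lengths):
            raise ValueError("n_chrom must match len(chrom_lengths)")
        if any(l < self.bin_size for l in self.chrom_lengths):
            raise ValueError("every chromosome must hold at least one full bin")
        if not (0 <= self.n_planted <= self.n_tfs):
            raise ValueError("planted TFs must be a subset of the TF universe")
        if self.n_planted == self.n_tfs and self.n_tfs > 0:
            raise ValueError("at least one TF must remain null")
        if self.b1 < 0:
            raise ValueError("effect size b1 must be >= 0")
        for name, v in (("n_interactions", self.n_interactions), ("n_active_bins", self.n_active_bins),
                        ("sites_per_tf", self.sites_per_tf), ("site_length", self.site_length)):
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.count_model not in ("geometric", "powerlaw"):
            raise ValueError(f"unknown count model {self.count_model!r}")

    @property
    def tf_names(self) -> list[str]:
        width = len(str(max(self.n_tfs, 1)))
        return [f"TF{i + 1:0{width}d}" for i in range(self.n_tfs)]

    @property
    def planted_tfs(self) -> list[str]:
        return self.tf_names[: self.n_planted]


@dataclass
class GroundTruth:
    """Which TFs carry a planted intensity effect, and how strong."""

    planted: dict[str, bool]
    effect: dict[str, float]

    @property
    def planted_tfs(self) -> list[str]:
        return [tf for tf, p in self.planted.items() if p]


def simulate_genome(cfg: SimulationConfig) -> GenomeLayout:
    """Roman-numeral-named chromosomes with the configured lengths."""
    numerals = [_roman(i + 1) for i in range(cfg.n_chrom)]
    return GenomeLayout(tuple((f"chr{r}", int(l)) for r, l in zip(numerals, cfg.chrom_lengths)))


def _roman(n: int) -> str:
    out = []
    for value, sym in ((1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
                       (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")):
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def _draw_counts(cfg: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    if cfg.count_model == "geometric":
        counts = cfg.min_count + rng.geometric(cfg.geom_p, size=size) - 1
    else:
        # discrete power law on k = 1, 2, ... shifted to start at min_count
        k = np.rint(rng.pareto(cfg.powerlaw_exponent - 1.0, size=size)).astype(np.int64)
        counts = cfg.min_count + k
    if cfg.count_cap is not None:
        counts = np.minimum(counts, cfg.count_cap)
    return counts.astype(np.int64)


def simulate_interactions(layout: GenomeLayout, cfg: SimulationConfig) -> InteractionSet:
    """Draw bin pairs among the active-bin universe with heavy-tailed counts.

    Pairs are sampled uniformly (inter-chromosomal unless the configured
    intra fraction admits same-chromosome pairs), duplicates merged by
    summing their counts, so the returned set holds <= n_interactions
    unique pairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_bins = layout.n_bins(cfg.bin_size)
    if cfg.n_active_bins > n_bins:
        raise ValueError(f"n_active_bins {cfg.n_active_bins} exceeds total bins {n_bins}")
    active = np.sort(rng.choice(n_bins, size=cfg.n_active_bins, replace=False))
    chrom_of = layout.bin_chrom_ids(cfg.bin_size)

    # crude upper bound on distinct admissible pairs
    max_pairs = cfg.n_active_bins * (cfg.n_active_bins - 1) // 2
    if cfg.n_interactions > max_pairs:
        raise ValueError(f"n_interactions {cfg.n_interactions} exceeds available distinct pairs {max_pairs}")

    want = cfg.n_interactions
    pairs = np.empty((0, 2), dtype=np.int64)
    while len(pairs) < want:
        m = max(2 * (want - len(pairs)), 1000)
        a = active[rng.integers(0, len(active), size=m)]
        b = active[rng.integers(0, len(active), size=m)]
        ok = a != b
        if cfg.intra_fraction == 0.0:
            ok &= chrom_of[a] != chrom_of[b]
        else:
            intra = chrom_of[a] == chrom_of[b]
            drop = intra & (rng.random(m) > cfg.intra_fraction)
            ok &= ~drop
        cand = np.stack([np.minimum(a, b), np.maximum(a, b)], axis=1)[ok]
        pairs = np.concatenate([pairs, cand])[:want]

    counts = _draw_counts(cfg, rng, len(pairs))
    keys = pairs[:, 0] * n_bins + pairs[:, 1]
    uniq, inverse = np.unique(keys, return_inverse=True)
    summed = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(summed, inverse, counts)
    bin_a, bin_b = uniq // n_bins, uniq % n_bins
    is_inter = chrom_of[bin_a] != chrom_of[bin_b]
    return InteractionSet(
        layout, cfg.bin_size, bin_a, bin_b, summed, is_inter,
        provenance={"simulated": True, "seed": cfg.seed, "count_model": cfg.count_model,
                    "n_pairs_drawn": int(want), "n_unique_pairs": int(len(uniq))},
    )


def bin_intensity(layout: GenomeLayout, iset: InteractionSet, bin_size: int) -> np.ndarray:
    """s_j = log1p(max read count over interactions touching bin j), 0 if untouched."""
    n_bins = layout.n_bins(bin_size)
    best = np.zeros(n_bins, dtype=np.int64)
    np.maximum.at(best, iset.bin_a, iset.n)
    np.maximum.at(best, iset.bin_b, iset.n)
    return np.log1p(best)


def simulate_tfbs(
    layout: GenomeLayout, iset: InteractionSet, cfg: SimulationConfig
) -> tuple[list[TFBSRecord], GroundTruth]:
    """Place binding sites for every TF; planted TFs prefer high-intensity bins.

    A null TF draws each site's bin uniformly; a planted TF draws bin j
    with probability proportional to exp(b0 + b1 * s_j). Site intervals
    (length ``site_length``, clipped at chromosome ends) are placed at a
    uniform offset within the chosen bin.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n_bins = layout.n_bins(cfg.bin_size)
    if cfg.sites_per_tf > n_bins:
        raise ValueError(f"sites_per_tf {cfg.sites_per_tf} exceeds bin count {n_bins}")
    s = bin_intensity(layout, iset, cfg.bin_size)
    logits = cfg.b0 + cfg.b1 * s
    planted_p = np.exp(logits - logits.max())
    planted_p /= planted_p.sum()

    chrom_of = layout.bin_chrom_ids(cfg.bin_size)
    names = layout.names
    lengths = layout.lengths
    offsets = layout.bin_offsets(cfg.bin_size)
    first_bin = np.array(list(offsets.values()))

    records: list[TFBSRecord] = []
    truth_planted: dict[str, bool] = {}
    truth_effect: dict[str, float] = {}
    planted_set = set(cfg.planted_tfs)
    for tf in cfg.tf_names:
        is_planted = tf in planted_set
        truth_planted[tf] = is_planted
        truth_effect[tf] = cfg.b1 if is_planted else 0.0
        if is_planted and cfg.b1 > 0:
            bins = rng.choice(n_bins, size=cfg.sites_per_tf, replace=True, p=planted_p)
        else:
            bins = rng.integers(0, n_bins, size=cfg.sites_per_tf)
        for j in np.sort(bins):
            cid = chrom_of[j]
            chrom = names[cid]
            bin_start = (j - first_bin[cid]) * cfg.bin_size
            bin_end = min(bin_start + cfg.bin_size, lengths[cid])
            start = int(bin_start + rng.integers(0, max(bin_end - bin_start - 1, 1)))
            end = min(start + cfg.site_length, lengths[cid])
            records.append(TFBSRecord(tf, chrom, start, end))
    return records, GroundTruth(truth_planted, truth_effect)


def write_fixture(directory, cfg: SimulationConfig) -> dict[str, Path]:
    """Generate a full fixture and write it as the plain-text dialects the readers consume.

    Emits ``chrom.sizes``, ``contacts.tsv`` (1-based positions, one row
    per aggregated bin pair), ``tfbs.bed`` and ``ground_truth.json`` (the
    serialized configuration plus per-TF truth). Re-reading the files
    through the package's readers reproduces the in-memory objects
    exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layout = simulate_genome(cfg)
    iset = simulate_interactions(layout, cfg)
    tfbs, truth = simulate_tfbs(layout, iset, cfg)

    sizes = directory / "chrom.sizes"
    with open(sizes, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")

    contacts = directory / "contacts.tsv"
    frame = iset.to_frame()
    with open(contacts, "w") as fh:
        fh.write("#chrom1\tpos1\tchrom2\tpos2\tcount\n")
        for row in frame.itertuples(index=False):
            fh.write(f"{row.chrom_a}\t{row.start_a + 1}\t{row.chrom_b}\t{row.start_b + 1}\t{row.n}\n")

    bed = directory / "tfbs.bed"
    with open(bed, "w") as fh:
        for rec in tfbs:
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.tf}\n")

    truth_path = directory / "ground_truth.json"
    payload = {
        "config": asdict(cfg),
        "planted": truth.planted,
        "effect": truth.effect,
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"chrom_sizes": sizes, "contacts": contacts, "tfbs": bed, "ground_truth": truth_path}
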