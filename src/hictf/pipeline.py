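"""End-to-end orchestration: configuration, staging, provenance.

``run_all`` executes bin → filter → label → curves → chi-square scan →
elastic-net bootstrap → trend scan → combine → link export and writes
every stage's table plus a provenance JSON capturing the fully resolved
configuration, so any bundle can be regenerated from its own provenance.
Inputs are either files (contacts + TFBS + chrom.sizes) or the synthetic
generator; all defaults are the study's stated analysis settings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chisq, enet, interactions, overlap, trend
from .genome import DEFAULT_BIN_SIZE, load_chrom_sizes
from .simulate import SimulationConfig, simulate_genome, simulate_interactions, simulate_tfbs

__all__ = ["RunConfig", "validate_config", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully resolved pipeline parameters (defaults = the study's settings)."""

    # inputs: either all three paths, or simulate=True
    contacts: str | None = None
    tfbs: str | None = None
    chrom_sizes: str | None = None
    simulate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # binning & filtering
    bin_size: int = DEFAULT_BIN_SIZE
    min_reads: int = interactions.DEFAULT_MIN_READS
    min_separation_bins: int = interactions.DEFAULT_MIN_SEPARATION_BINS
    subset: str = "inter"
    # chi-square scan
    T_min: int = chisq.DEFAULT_T_MIN
    T_max: int = chisq.DEFAULT_T_MAX
    alpha: float = chisq.DEFAULT_ALPHA
    yates: bool = False
    bonferroni_family: str = "global"
    multiple_testing: str = "bonferroni"
    # reporting curve grid
    curve_T_min: int = 6
    curve_T_max: int = 100
    # elastic net
    enet_mixing: float = enet.DEFAULT_MIXING
    enet_folds: int = enet.DEFAULT_FOLDS
    enet_B: int = enet.DEFAULT_B
    enet_threshold: float = enet.DEFAULT_THRESHOLD
    enet_ranges: tuple[tuple[int, int], ...] = enet.DEFAULT_RANGES
    # link export
    link_T: int = 20
    # misc
    seed: int = 0
    out_dir: str = "hictf_out"

    @property
    def per_range_cutoff(self) -> float:
        return self.enet_threshold * self.enet_B

    @property
    def total_cutoff(self) -> float:
        return self.enet_threshold * self.enet_B * len(self.enet_ranges)


def validate_config(user: dict | RunConfig | None = None) -> RunConfig:
    """Fill defaults and cross-check a user configuration.

    Accepts a (possibly nested) dict as produced by a YAML/JSON config
    file, or an existing RunConfig; every violation found is reported in
    one error message.
    """
    if user is None:
        user = {}
    if isinstance(user, RunConfig):
        cfg = user
    else:
        unknown = set(user) - {f.name for f in dataclasses.fields(RunConfig)}
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        user = dict(user)
        if "sim" in user and isinstance(user["sim"], dict):
            user["sim"] = SimulationConfig(**user["sim"])
        if "enet_ranges" in user:
            user["enet_ranges"] = tuple(tuple(r) for r in user["enet_ranges"])
        cfg = RunConfig(**user)

    problems: list[str] = []
    if cfg.bin_size < 1:
        problems.append(f"bin_size must be >= 1 (got {cfg.bin_size})")
    if cfg.min_reads < 1:
        problems.append(f"min_reads must be >= 1 (got {cfg.min_reads})")
    if cfg.min_separation_bins < 1:
        problems.append(f"min_separation_bins must be >= 1 (got {cfg.min_separation_bins})")
    if cfg.subset not in ("all", "inter", "intra"):
        problems.append(f"subset must be all|inter|intra (got {cfg.subset!r})")
    if cfg.T_min > cfg.T_max:
        problems.append(f"T range [{cfg.T_min}, {cfg.T_max}] is empty")
    if cfg.curve_T_min > cfg.curve_T_max:
        problems.append(f"curve grid [{cfg.curve_T_min}, {cfg.curve_T_max}] is empty")
    if not (cfg.curve_T_min <= cfg.T_min and cfg.T_max <= cfg.curve_T_max):
        problems.append("scan thresholds must lie within the curve grid")
    if not (0 < cfg.alpha < 1):
        problems.append(f"alpha must be in (0, 1) (got {cfg.alpha})")
    if cfg.bonferroni_family not in ("global", "per-tf"):
        problems.append(f"bonferroni_family must be global|per-tf (got {cfg.bonferroni_family!r})")
    if cfg.multiple_testing not in ("bonferroni",):
        problems.append(f"multiple_testing must be bonferroni (got {cfg.multiple_testing!r})")
    if not (0 < cfg.enet_mixing <= 1):
        problems.append(f"enet_mixing must be in (0, 1] (got {cfg.enet_mixing})")
    if cfg.enet_folds < 3:
        problems.append(f"enet_folds must be >= 3 (got {cfg.enet_folds})")
    if cfg.enet_B < 1:
        problems.append(f"enet_B must be >= 1 (got {cfg.enet_B})")
    if not (0 < cfg.enet_threshold < 1):
        problems.append(f"enet_threshold must be in (0, 1) (got {cfg.enet_threshold})")
    for lo, hi in cfg.enet_ranges:
        if lo > hi:
            problems.append(f"elastic-net range [{lo}, {hi}] is empty")
        if not (cfg.curve_T_min <= lo and hi <= cfg.curve_T_max):
            problems.append(f"elastic-net range [{lo}, {hi}] outside the curve grid")
    if cfg.link_T < 1:
        problems.append(f"link_T must be >= 1 (got {cfg.link_T})")
    if not cfg.simulate:
        given = [k for k in ("contacts", "tfbs", "chrom_sizes") if getattr(cfg, k) is not None]
        # an all-defaults config is valid; partially specified file inputs are not
        if given and len(given) < 3:
            missing = [k for k in ("contacts", "tfbs", "chrom_sizes") if getattr(cfg, k) is None]
            problems.append(f"file inputs also require {', '.join(missing)}")
    if problems:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(problems))
    return cfg


def _provenance(cfg: RunConfig, extra: dict) -> dict:
    payload = dataclasses.asdict(cfg)
    payload.pop("out_dir")  # not part of the science; keeps bundles comparable across directories
    payload["enet_ranges"] = [list(r) for r in cfg.enet_ranges]
    payload["per_range_cutoff"] = cfg.per_range_cutoff
    payload["total_cutoff"] = cfg.total_cutoff
    payload.update(extra)
    return payload


def run_all(cfg: RunConfig | dict | None = None) -> dict:
    """Execute the full pipeline and write the result bundle to ``cfg.out_dir``.

    Returns the in-memory results (layout, interaction set, curves, scan,
    selection, trend table, combined result, paths). Deterministic given
    the configuration: rerunning with the same config and seed rewrites
    byte-identical files.
    """
    cfg = validate_config(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if cfg.simulate:
            sim = dataclasses.replace(cfg.sim, seed=cfg.seed, bin_size=cfg.bin_size)
            layout = simulate_genome(sim)
            iset_raw = simulate_interactions(layout, sim)
            tfbs_records, truth = simulate_tfbs(layout, iset_raw, sim)
            tf_universe = sim.tf_names
        elif cfg.chrom_sizes is None:
            raise ValueError("no inputs: provide contacts/tfbs/chrom_sizes or set simulate=true")
        else:
            layout = load_chrom_sizes(cfg.chrom_sizes)
            records = interactions.read_contacts(cfg.contacts, layout)
            iset_raw = interactions.bin_contacts(records, layout, cfg.bin_size)
            tfbs_records = overlap.read_tfbs(cfg.tfbs, layout)
            truth = None
            tf_universe = None
        logger.info("input: %d aggregated bin pairs", len(iset_raw))

        stage = "filter"
        iset = interactions.filter_interactions(iset_raw, cfg.min_reads, cfg.min_separation_bins)
        iset = interactions.subset_interactions(iset, cfg.subset)
        logger.info("filter: %d interactions kept (subset=%s)", len(iset), cfg.subset)
        interactions.write_interactions(iset, out / "interactions.tsv")

        stage = "label"
        binding = overlap.mark_bins(tfbs_records, layout, cfg.bin_size, tf_universe=tf_universe)
        labels = overlap.label_interactions(iset, binding)

        stage = "curves"
        curves = overlap.ratio_curves(labels, range(cfg.curve_T_min, cfg.curve_T_max + 1))
        overlap.write_curves(curves, out / "curves.tsv")

        empty = len(iset) == 0
        if empty:
            logger.warning("no interactions after filtering; writing an empty result bundle")

        stage = "scan"
        scan_res = chisq.scan(
            labels, cfg.T_min, cfg.T_max, cfg.alpha, yates=cfg.yates, bonferroni_family=cfg.bonferroni_family
        )
        scan_res.cells.to_csv(out / "scan.tsv", sep="\t", index=False, float_format="%.10g")
        scan_res.summary.to_csv(out / "scan_summary.tsv", sep="\t", index=False)
        scan_sig = chisq.significant_tfs(scan_res)
        logger.info("scan: %d TF(s) Bonferroni-significant", len(scan_sig))

        stage = "enet"
        if empty:
            selection = None
            enet_sel: list[str] = []
            enet_counts: dict[str, int] = {}
            (out / "enet_selection.tsv").write_text("tf\ttotal\tselected\n")
        else:
            selection = enet.bootstrap_select(
                curves,
                ranges=cfg.enet_ranges,
                B=cfg.enet_B,
                threshold=cfg.enet_threshold,
                mixing=cfg.enet_mixing,
                folds=cfg.enet_folds,
                seed=cfg.seed,
            )
            selection.to_frame().to_csv(out / "enet_selection.tsv", sep="\t", index=False, float_format="%.10g")
            enet_sel = selection.selected_tfs()
            enet_counts = {tf: int(c) for tf, c in selection.counts["total"].items()}
        logger.info("elastic net: %d TF(s) selected", len(enet_sel))

        stage = "trend"
        trend_df = trend.run_trend_scan(curves, ranges=cfg.enet_ranges, alpha=cfg.alpha)
        trend_df.to_csv(out / "trend.tsv", sep="\t", index=False, float_format="%.10g")

        stage = "combine"
        combined = trend.combine(scan_sig, enet_sel, enet_counts)
        combined.evidence.to_csv(out / "combined.tsv", sep="\t", index=False)
        logger.info("combined: %d TF(s) supported by both methods", len(combined.intersection))

        stage = "export"
        trend.export_links(labels, combined.intersection, cfg.link_T, out / "links.bedpe")

        stage = "provenance"
        prov = _provenance(
            cfg,
            {
                "n_interactions_raw": len(iset_raw),
                "n_interactions": len(iset),
                "n_tfs": len(labels.tfs),
                "filter": iset.provenance,
                "bonferroni_m": scan_res.family_size,
                "enet": selection.params if selection is not None else None,
                "chisq_significant": scan_sig,
                "enet_selected": enet_sel,
                "intersection": combined.intersection,
            },
        )
        with open(out / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "layout": layout,
        "interactions": iset,
        "labels": labels,
        "curves": curves,
        "scan": scan_res,
        "scan_significant": scan_sig,
        "selection": selection,
        "enet_selected": enet_sel,
        "trend": trend_df,
        "combined": combined,
        "truth": truth,
        "out_dir": out,
    }
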