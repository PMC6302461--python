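import numpy as np
import pytest

import hictf
from hictf.overlap import LabelMatrix


@pytest.fixture
def tiny_layout():
    return hictf.GenomeLayout((("chrI", 2500), ("chrII", 1000), ("chrIII", 3200)))


def make_labels(n_reads, columns, tfs=None):
    """LabelMatrix straight from arrays, for statistic-level tests."""
    matrix = np.asarray(columns, dtype=bool).T
    if matrix.ndim == 1:
        matrix = matrix[:, None]
    tfs = tfs or [f"tf{j}" for j in range(matrix.shape[1])]
    return LabelMatrix(list(tfs), matrix, np.asarray(n_reads, dtype=np.int64))


@pytest.fixture
def hand_labels():
    """Four interactions with reads {6,10,20,50}; the TF is positive on 20 and 50."""
    return make_labels([6, 10, 20, 50], [[False, False, True, True]], ["Ste12"])


def small_config(**kw):
    """Down-scaled simulation for fast unit tests (4 chromosomes, 2k interactions)."""
    defaults = dict(
        n_chrom=4,
        chrom_lengths=(60_000, 80_000, 50_000, 70_000),
        n_interactions=2_000,
        n_active_bins=120,
        n_tfs=20,
        n_planted=3,
        sites_per_tf=15,
        seed=7,
    )
    defaults.update(kw)
    return hictf.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_planted():
    """One fully prepared planted dataset shared across tests.

    Uses the default yeast-like genome but fewer interactions and TFs;
    large enough that the planted intensity effect is Bonferroni-detectable.
    """
    cfg = hictf.SimulationConfig(n_interactions=20_000, n_tfs=40, n_planted=5, seed=7, b1=2.0)
    layout = hictf.simulate_genome(cfg)
    raw = hictf.simulate_interactions(layout, cfg)
    tfbs, truth = hictf.simulate_tfbs(layout, raw, cfg)
    iset = hictf.subset_interactions(hictf.filter_interactions(raw), "inter")
    binding = hictf.mark_bins(tfbs, layout, cfg.bin_size, tf_universe=cfg.tf_names)
    labels = hictf.label_interactions(iset, binding)
    curves = hictf.ratio_curves(labels, range(6, 101))
    return {
        "cfg": cfg,
        "layout": layout,
        "raw": raw,
        "iset": iset,
        "tfbs": tfbs,
        "truth": truth,
        "binding": binding,
        "labels": labels,
        "curves": curves,
    }
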