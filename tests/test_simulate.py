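import json

import numpy as np
import pytest

import hictf
from hictf import (
    SimulationConfig,
    simulate_genome,
    simulate_interactions,
    simulate_tfbs,
    write_fixture,
)

from conftest import small_config


def test_simulate_genome_shapes_and_determinism():
    cfg = SimulationConfig(seed=5)
    layout = simulate_genome(cfg)
    assert len(layout.chromosomes) == 16
    assert 11e6 < sum(layout.lengths) < 13e6  # yeast-like total
    assert layout.names[0] == "chrI" and layout.names[15] == "chrXVI"
    assert simulate_genome(cfg).chromosomes == layout.chromosomes
    custom = simulate_genome(small_config(n_chrom=2, chrom_lengths=(10_000, 5_000)))
    assert custom.lengths == [10_000, 5_000]


def test_simulate_interactions_count_distribution():
    cfg = SimulationConfig(seed=3, n_interactions=10_000)
    layout = simulate_genome(cfg)
    iset = simulate_interactions(layout, cfg)
    assert np.median(iset.n) <= 12
    assert iset.n.max() >= 60
    assert iset.n.min() >= 6
    assert iset.is_inter.all()  # intra_fraction defaults to 0
    # heavy-ish tail, monotone-decreasing histogram beyond the mode
    dist = hictf.count_distribution(iset)
    counts = dist["count"].to_numpy()
    mode = counts.argmax()
    tail = counts[mode:]
    # allow small wobble in sparse tail bins but require overall decline
    assert tail[0] > tail[len(tail) // 2] > tail[-1]


def test_simulate_interactions_deterministic_and_unique_pairs():
    cfg = small_config(seed=9)
    layout = simulate_genome(cfg)
    a = simulate_interactions(layout, cfg)
    b = simulate_interactions(layout, cfg)
    assert np.array_equal(a.bin_a, b.bin_a) and np.array_equal(a.n, b.n)
    keys = a.bin_a * layout.n_bins(cfg.bin_size) + a.bin_b
    assert len(np.unique(keys)) == len(keys)


def test_simulate_interactions_rejects_oversubscription():
    cfg = small_config(n_active_bins=10, n_interactions=2_000)
    layout = simulate_genome(cfg)
    with pytest.raises(ValueError, match="distinct pairs"):
        simulate_interactions(layout, cfg)


def test_simulate_tfbs_effect_off_and_on():
    cfg_off = small_config(seed=21, b1=0.0)
    layout = simulate_genome(cfg_off)
    iset = simulate_interactions(layout, cfg_off)
    recs_off, truth_off = simulate_tfbs(layout, iset, cfg_off)
    assert set(truth_off.planted) == set(cfg_off.tf_names)
    assert truth_off.planted_tfs == cfg_off.planted_tfs
    assert all(v == 0.0 for v in truth_off.effect.values())

    cfg_on = small_config(seed=21, b1=2.0)
    recs_on, truth_on = simulate_tfbs(layout, iset, cfg_on)
    # planted sites concentrate on bins touched by strong interactions
    s = hictf.simulate.bin_intensity(layout, iset, cfg_on.bin_size)
    offsets = layout.bin_offsets(cfg_on.bin_size)

    def mean_intensity(records, tfs):
        vals = [
            s[offsets[r.chrom] + r.start // cfg_on.bin_size]
            for r in records
            if r.tf in tfs
        ]
        return float(np.mean(vals))

    planted = set(cfg_on.planted_tfs)
    nulls = set(cfg_on.tf_names) - planted
    assert mean_intensity(recs_on, planted) > mean_intensity(recs_on, nulls) + 0.5


def test_simulate_tfbs_deterministic():
    cfg = small_config(seed=2)
    layout = simulate_genome(cfg)
    iset = simulate_interactions(layout, cfg)
    a, _ = simulate_tfbs(layout, iset, cfg)
    b, _ = simulate_tfbs(layout, iset, cfg)
    assert a == b


def test_ratio_curves_separate_planted_from_null_across_seeds():
    """Planted TFs' mean ratio-curve slope exceeds the null TFs' for b1 >= 1."""
    planted_slopes, null_slopes = [], []
    for seed in range(8):
        cfg = small_config(seed=300 + seed, b1=1.5)
        layout = simulate_genome(cfg)
        iset = hictf.subset_interactions(
            hictf.filter_interactions(simulate_interactions(layout, cfg)), "inter"
        )
        tfbs, truth = simulate_tfbs(layout, iset, cfg)
        binding = hictf.mark_bins(tfbs, layout, cfg.bin_size, tf_universe=cfg.tf_names)
        labels = hictf.label_interactions(iset, binding)
        for tf, c in hictf.ratio_curves(labels, range(6, 31)).items():
            d = c.defined
            if d.sum() < 10:
                continue
            slope = np.polyfit(c.thresholds[d], c.ratio[d], 1)[0]
            (planted_slopes if truth.planted[tf] else null_slopes).append(slope)
    assert np.mean(planted_slopes) > np.mean(null_slopes)


def test_write_fixture_round_trip(tmp_path):
    cfg = small_config(seed=13)
    paths = write_fixture(tmp_path / "fx", cfg)
    assert set(paths) == {"chrom_sizes", "contacts", "tfbs", "ground_truth"}

    layout = hictf.load_chrom_sizes(paths["chrom_sizes"])
    assert layout.chromosomes == simulate_genome(cfg).chromosomes

    iset_direct = simulate_interactions(layout, cfg)
    iset_read = hictf.bin_contacts(
        hictf.read_contacts(paths["contacts"], layout), layout, cfg.bin_size
    )
    assert np.array_equal(iset_read.bin_a, iset_direct.bin_a)
    assert np.array_equal(iset_read.bin_b, iset_direct.bin_b)
    assert np.array_equal(iset_read.n, iset_direct.n)

    recs_direct, truth = simulate_tfbs(layout, iset_direct, cfg)
    recs_read = hictf.read_tfbs(paths["tfbs"], layout)
    assert sorted(recs_read, key=lambda r: (r.tf, r.chrom, r.start)) == sorted(
        recs_direct, key=lambda r: (r.tf, r.chrom, r.start)
    )

    payload = json.loads(paths["ground_truth"].read_text())
    assert payload["planted"] == truth.planted
    assert payload["config"]["seed"] == cfg.seed
    # regeneratable: the embedded config reproduces the same contacts file
    cfg2 = SimulationConfig(**{**payload["config"], "chrom_lengths": tuple(payload["config"]["chrom_lengths"])})
    paths2 = write_fixture(tmp_path / "fx2", cfg2)
    assert paths2["contacts"].read_text() == paths["contacts"].read_text()

    # a different seed must change the data
    paths3 = write_fixture(tmp_path / "fx3", small_config(seed=14))
    assert paths3["contacts"].read_text() != paths["contacts"].read_text()


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimulationConfig(n_chrom=2)  # mismatched lengths tuple
    with pytest.raises(ValueError):
        small_config(n_planted=21)
    with pytest.raises(ValueError):
        small_config(b1=-1.0)
    with pytest.raises(ValueError):
        small_config(count_model="weird")
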