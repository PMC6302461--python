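import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hictf
from hictf import (
    bin_contacts,
    count_distribution,
    filter_interactions,
    read_contacts,
    subset_interactions,
)
from hictf.interactions import read_interactions, write_interactions


def write_contacts(tmp_path, text):
    p = tmp_path / "contacts.tsv"
    p.write_text(text)
    return p


def test_read_contacts_parses_and_converts_to_zero_based(tmp_path, tiny_layout):
    p = write_contacts(tmp_path, "# comment\nchrI\t500\tchrII\t700\t8\n")
    recs = read_contacts(p, tiny_layout)
    assert len(recs) == 1
    r = recs[0]
    assert (r.chrom1, r.pos1, r.chrom2, r.pos2, r.count) == ("chrI", 499, "chrII", 699, 8)


@pytest.mark.parametrize(
    "line",
    [
        "chrX\t500\tchrII\t700\t8",  # unknown chromosome
        "chrI\t500\tchrII\t700\t0",  # count < 1
        "chrI\t0\tchrII\t700\t8",  # 1-based position cannot be 0
        "chrI\t2501\tchrII\t700\t8",  # beyond chromosome end
        "chrI\t500\tchrII\t700",  # too few columns
        "chrI\tfoo\tchrII\t700\t8",  # non-integer position
    ],
)
def test_read_contacts_rejects_malformed(tmp_path, tiny_layout, line):
    p = write_contacts(tmp_path, line + "\n")
    with pytest.raises(ValueError, match=":1"):
        read_contacts(p, tiny_layout)


def test_bin_contacts_aggregates_and_canonicalizes(tmp_path, tiny_layout):
    # same canonical pair appears in both orientations plus a same-bin record
    p = write_contacts(
        tmp_path,
        "chrI\t500\tchrII\t700\t3\n"
        "chrII\t800\tchrI\t200\t4\n"
        "chrI\t100\tchrI\t900\t9\n",
    )
    iset = bin_contacts(read_contacts(p, tiny_layout), tiny_layout, 1000)
    assert len(iset) == 1
    assert iset.n[0] == 7
    assert iset.bin_a[0] < iset.bin_b[0]
    assert iset.is_inter[0]
    assert iset.provenance["same_bin_dropped"] == 1
    assert iset.provenance["same_bin_reads"] == 9


def test_aggregation_conserves_reads(tmp_path, tiny_layout):
    rng = np.random.default_rng(0)
    lines = []
    total = 0
    lengths = dict(tiny_layout.chromosomes)
    names = tiny_layout.names
    for _ in range(200):
        c1, c2 = rng.choice(names, 2)
        p1 = int(rng.integers(1, lengths[c1] + 1))
        p2 = int(rng.integers(1, lengths[c2] + 1))
        k = int(rng.integers(1, 20))
        total += k
        lines.append(f"{c1}\t{p1}\t{c2}\t{p2}\t{k}")
    p = write_contacts(tmp_path, "\n".join(lines) + "\n")
    iset = bin_contacts(read_contacts(p, tiny_layout), tiny_layout, 1000)
    assert int(iset.n.sum()) + iset.provenance["same_bin_reads"] == total


def _random_iset(layout, seed, n=100):
    rng = np.random.default_rng(seed)
    n_bins = layout.n_bins(1000)
    pairs = set()
    while len(pairs) < n:
        a, b = rng.integers(0, n_bins, 2)
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    pairs = sorted(pairs)
    bin_a = np.array([p[0] for p in pairs])
    bin_b = np.array([p[1] for p in pairs])
    chrom_of = layout.bin_chrom_ids(1000)
    return hictf.InteractionSet(
        layout, 1000, bin_a, bin_b,
        rng.integers(1, 40, len(pairs)), chrom_of[bin_a] != chrom_of[bin_b],
    )


def test_filter_removes_adjacent_intra_and_low_reads(tiny_layout):
    # bins 0,1 are adjacent on chrI; bins 3,4 sit on different chromosomes
    iset = hictf.InteractionSet(
        tiny_layout, 1000,
        np.array([0, 0, 3, 3]), np.array([1, 2, 4, 5]),
        np.array([50, 6, 5, 6]),
        np.array([False, False, True, True]),
    )
    kept = filter_interactions(iset)
    # adjacent intra pair dies despite n=50; inter pair with n=5 dies; n=6 survive
    assert list(kept.n) == [6, 6]
    assert kept.provenance["removed_close"] == 1
    assert kept.provenance["removed_low_reads"] == 1
    assert not (~kept.is_inter & (kept.bin_b - kept.bin_a < 2)).any()


@given(seed=st.integers(0, 50))
@settings(max_examples=15, deadline=None)
def test_filter_idempotent_and_commutes_with_subset(seed):
    layout = hictf.GenomeLayout((("chrI", 9000), ("chrII", 7000), ("chrIII", 5000)))
    iset = _random_iset(layout, seed)
    once = filter_interactions(iset)
    twice = filter_interactions(once)
    assert np.array_equal(once.bin_a, twice.bin_a)
    assert np.array_equal(once.n, twice.n)
    a = subset_interactions(filter_interactions(iset), "inter")
    b = filter_interactions(subset_interactions(iset, "inter"))
    assert np.array_equal(a.bin_a, b.bin_a)
    assert np.array_equal(a.bin_b, b.bin_b)
    assert np.array_equal(a.n, b.n)


def test_subset_selectors(tiny_layout):
    iset = hictf.InteractionSet(
        tiny_layout, 1000,
        np.array([0, 3]), np.array([2, 4]),
        np.array([6, 8]), np.array([False, True]),
    )
    assert list(subset_interactions(iset, "inter").n) == [8]
    assert list(subset_interactions(iset, "intra").n) == [6]
    assert len(subset_interactions(iset, "all")) == 2
    only_inter = subset_interactions(iset, "inter")
    assert len(subset_interactions(only_inter, "intra")) == 0  # empty, not an error
    with pytest.raises(ValueError):
        subset_interactions(iset, "bogus")


def test_count_distribution_counts_and_cumulative_share(tiny_layout):
    iset = hictf.InteractionSet(
        tiny_layout, 1000,
        np.array([0, 0, 3]), np.array([2, 4, 5]),
        np.array([6, 6, 10]), np.array([False, True, True]),
    )
    dist = count_distribution(iset)
    assert dict(zip(dist["n"], dist["count"])) == {6: 2, 10: 1}
    assert dist["cum_share"].iloc[-1] == 1.0
    assert abs(dist.loc[dist["n"] == 6, "cum_share"].iloc[0] - 2 / 3) < 1e-12
    empty = subset_interactions(iset, "intra")
    assert count_distribution(subset_interactions(empty, "inter")).empty


def test_interactions_tsv_round_trip(tmp_path, tiny_layout):
    iset = _random_iset(tiny_layout, 3, n=20)  # the tiny layout has only 28 distinct pairs
    path = tmp_path / "interactions.tsv"
    write_interactions(iset, path)
    back = read_interactions(path, tiny_layout, 1000)
    assert np.array_equal(back.bin_a, iset.bin_a)
    assert np.array_equal(back.bin_b, iset.bin_b)
    assert np.array_equal(back.n, iset.n)
    assert np.array_equal(back.is_inter, iset.is_inter)
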