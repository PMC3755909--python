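"""Gene-cluster detection, Fisher adjacency test, density and duplication."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from kaikobuild.cluster_analysis import (
    ContingencyTable2x2, adjacency_table, chromosome_density_ratio,
    detect_clusters, duplication_fraction, fisher_exact_2x2, summarize_clusters,
)


def _calls(rows):
    return pd.DataFrame(rows, columns=["locus_id", "tissue", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# cluster detection
# ---------------------------------------------------------------------------

def test_gap_threshold_splits_chains():
    calls = _calls([
        ("g1", "midgut", "chr1", 0, 10_000),
        ("g2", "midgut", "chr1", 100_000, 110_000),     # gap 90 kb -> chained
        ("g3", "midgut", "chr1", 260_000, 270_000),     # gap 150 kb -> breaks
    ])
    found = detect_clusters(calls)
    assert len(found) == 1
    assert found[0].members == ["g1", "g2"]


def test_isolated_or_cross_tissue_loci_make_no_cluster():
    calls = _calls([
        ("g1", "midgut", "chr1", 0, 10_000),
        ("g2", "ovary", "chr1", 20_000, 30_000),
        ("g3", "midgut", "chr2", 40_000, 50_000),
    ])
    assert detect_clusters(calls) == []


def test_planted_cluster_recovered_from_truth(small_sim):
    cfg, _genome, truth, _records = small_sim
    g = truth.genes[~truth.genes.unplaced]
    calls = g.rename(columns={"gene_id": "locus_id"})[
        ["locus_id", "tissue", "chrom", "start", "end"]
    ].assign(tissue=lambda d: d.tissue.where(d.tissue != "broad", ""))
    found = detect_clusters(calls)
    spec = cfg.cluster_plant_spec[0]
    planted = truth.genes[truth.genes.cluster_id == "cl00"]
    hits = [c for c in found if c.tissue == spec.tissue and
            set(planted.gene_id) <= set(c.members)]
    assert len(hits) == 1
    assert len(hits[0].members) >= spec.n_genes


def test_detection_idempotent_and_order_free():
    rng = np.random.default_rng(3)
    rows = [(f"g{i}", rng.choice(["midgut", "ovary", ""]), "chr1",
             int(rng.integers(0, 2_000_000)), 0) for i in range(60)]
    rows = [(l, t, c, s, s + 5000) for l, t, c, s, _e in rows]
    a = detect_clusters(_calls(rows))
    b = detect_clusters(_calls(rows[::-1]))
    assert [(c.tissue, c.members) for c in a] == [(c.tissue, c.members) for c in b]


def test_raising_gap_never_decreases_clustered_count():
    rng = np.random.default_rng(4)
    rows = [(f"g{i}", "wing", "chr1", int(p), int(p) + 2000)
            for i, p in enumerate(sorted(rng.integers(0, 3_000_000, size=40)))]
    counts = []
    for gap in (10_000, 50_000, 100_000, 400_000):
        found = detect_clusters(_calls(rows), cluster_gap=gap)
        counts.append(sum(len(c.members) for c in found))
    assert counts == sorted(counts)


def test_summary_matches_hand_computation():
    calls = _calls(
        [(f"m{i}", "midgut", "chr1", i * 10_000, i * 10_000 + 2000) for i in range(4)]
        + [("x1", "ovary", "chr2", 0, 2000)]
    )
    found = detect_clusters(calls)
    summary = summarize_clusters(calls, found).set_index("tissue")
    assert summary.loc["midgut", "n_specific"] == 4
    assert summary.loc["midgut", "n_clustered"] == 4
    assert summary.loc["midgut", "fraction_clustered_pct"] == 100
    assert summary.loc["ovary", "n_clustered"] == 0
    assert summary.loc["ovary", "fraction_clustered_pct"] == 0
    assert summary.loc["Total", "n_specific"] == 5
    assert summary.loc["Total", "fraction_clustered_pct"] == 80


# ---------------------------------------------------------------------------
# adjacency + Fisher
# ---------------------------------------------------------------------------

def _loci(labels):
    return pd.DataFrame([
        dict(locus_id=f"g{i}", chrom="chr1", start=i * 1000, tissue=t)
        for i, t in enumerate(labels)
    ])


def test_alternating_labels_empty_both_specific_cell():
    tab = adjacency_table(_loci(["midgut", "", "midgut", "", "midgut", ""]))
    assert tab.a == 0
    assert tab.b == 3 and tab.c == 2


def test_uniform_specific_labels_fill_single_cell():
    tab = adjacency_table(_loci(["midgut"] * 5), same_tissue=True)
    assert (tab.a, tab.b, tab.c, tab.d) == (4, 0, 0, 0)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 0, 0, 0)


def _fisher_oracle(a, b, c, d):
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        return Fraction(1)
    den = comb(n, c1)
    probs = [
        Fraction(comb(r1, x) * comb(r2, c1 - x), den)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    ]
    obs = Fraction(comb(r1, a) * comb(r2, c1 - a), den)
    return sum(p for p in probs if p <= obs)


@pytest.mark.parametrize("table,expected", [
    ((1, 1, 1, 1), Fraction(1)),
    ((2, 0, 0, 2), Fraction(1, 3)),
    ((5, 0, 0, 5), Fraction(2, 252)),
    ((3, 0, 0, 0), Fraction(1)),          # zero margin
])
def test_fisher_known_values(table, expected):
    assert fisher_exact_2x2(ContingencyTable2x2(*table)) == pytest.approx(
        float(expected), abs=1e-15
    )


def test_planted_clusters_reject_independence():
    from kaikobuild.simulate import ClusterSpec, SimulationConfig, simulate_annotation

    clusters = [
        ClusterSpec("ovary", "chr2", 100_000, 12, 5),
        ClusterSpec("midgut", "chr3", 150_000, 10, 4),
        ClusterSpec("wing", "chr4", 120_000, 8, 0),
        ClusterSpec("testis", "chrZ", 200_000, 14, 0),
        ClusterSpec("epidermis", "chr5", 120_000, 9, 0),
        ClusterSpec("brain", "chr2", 150_000, 10, 0),
        ClusterSpec("fat_body", "chr6", 100_000, 7, 0),
        ClusterSpec("silk_gland", "chr3", 100_000, 8, 0),
    ]
    cfg = SimulationConfig(seed=6, n_genes=600, n_chromosomes=6,
                           chromosome_length=2_200_000,
                           cluster_plant_spec=clusters, n_unplaced_genes=0)
    truth = simulate_annotation(cfg)
    g = truth.genes[~truth.genes.unplaced]
    calls = g.rename(columns={"gene_id": "locus_id"})[
        ["locus_id", "chrom", "start", "tissue"]
    ].assign(tissue=lambda d: d.tissue.where(d.tissue != "broad", ""))
    assert fisher_exact_2x2(adjacency_table(calls)) < 1e-3


def test_fisher_agrees_with_scipy_cross_check():
    rng = np.random.default_rng(8)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
        ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        ref = float(sstats.fisher_exact([[a, b], [c, d]]).pvalue)
        assert ours == pytest.approx(ref, abs=1e-7)


# ---------------------------------------------------------------------------
# duplication + density
# ---------------------------------------------------------------------------

def test_identical_pair_fully_duplicated(rng):
    s = "".join(rng.choice(list("ACGT"), size=600))
    frac, n = duplication_fraction({"g1": s, "g2": s})
    assert (frac, n) == (1.0, 2)


def test_unrelated_pair_not_duplicated(rng):
    a = "".join(rng.choice(list("ACGT"), size=1000))
    b = "".join(rng.choice(list("ACGT"), size=1000))
    frac, n = duplication_fraction({"g1": a, "g2": b})
    assert (frac, n) == (0.0, 0)


def test_planted_family_yields_half_duplicated(rng):
    founder = "".join(rng.choice(list("ACGT"), size=800))
    seqs = {}
    for i in range(5):
        copy = list(founder)
        for pos in rng.integers(0, 800, size=24):     # ~3% divergence
            copy[pos] = "ACGT"[int(rng.integers(4))]
        seqs[f"fam{i}"] = "".join(copy)
    for i in range(5):
        seqs[f"unrel{i}"] = "".join(rng.choice(list("ACGT"), size=800))
    frac, n = duplication_fraction(seqs)
    assert n == 5
    assert frac == pytest.approx(0.5)


def test_density_ratio_uniform_and_concentrated():
    lengths = {"chrA": 1_000_000, "chrB": 1_000_000}
    concentrated = pd.DataFrame(
        [dict(locus_id=f"g{i}", tissue="testis", chrom="chrA") for i in range(10)]
    )
    assert chromosome_density_ratio(concentrated, "testis", "chrA", lengths) == 2.0
    even = pd.DataFrame(
        [dict(locus_id=f"g{i}", tissue="testis", chrom=("chrA" if i % 2 else "chrB"))
         for i in range(10)]
    )
    assert chromosome_density_ratio(even, "testis", "chrA", lengths) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        chromosome_density_ratio(even, "silk_gland", "chrA", lengths)
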