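import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_track
from rloopscape.gene_profiles import (
    QpcrSample,
    anchored_exon1_segment,
    exon2_boxplot_stats,
    gene_mean_enrichment,
    group_by_expression,
    ks_two_sample,
    metagene_spliced,
    metagene_whole_gene,
    qpcr_relative_enrichment,
    whole_gene_log2fc,
)
from rloopscape.genome_io import GeneModel, Interval


def _gene(gid, exons, strand="+", gene_class="protein_coding", **kw):
    ivs = tuple(Interval("c", s, e, strand) for s, e in exons)
    return GeneModel(gid, gene_class, strand, ivs, **kw)


# ---------------------------------------------------------------------------
# per-gene means


def test_gene_mean_enrichment_examples():
    track = make_track({"c": [1.0] * 10})
    g = _gene("g", [(120, 380)])
    assert gene_mean_enrichment(track, g) == pytest.approx(1.0)
    track = make_track({"c": [2.0, 2.0, 4.0]})
    g = _gene("g", [(0, 150)])
    assert gene_mean_enrichment(track, g) == pytest.approx(8 / 3)
    g1 = _gene("g1", [(50, 100)])
    assert gene_mean_enrichment(track, g1) == pytest.approx(2.0)


def test_gene_mean_base_weighted():
    track = make_track({"c": [2.0, 4.0]})
    g = _gene("g", [(25, 100)])  # 25 bp at 2, 50 bp at 4
    assert gene_mean_enrichment(track, g) == pytest.approx((25 * 2 + 50 * 4) / 75)


# ---------------------------------------------------------------------------
# expression grouping


def test_group_sizes_match_partition_arithmetic():
    rng = np.random.default_rng(0)
    expr = pd.Series(rng.lognormal(0, 1, 5864), index=[f"g{i:04d}" for i in range(5864)])
    grouping = group_by_expression(expr, n_high=500, n_very_high=90)
    sizes = grouping.sizes()
    assert (sizes["C1"], sizes["C2"], sizes["C3"], sizes["C4"]) == (1788, 1788, 1788, 500)
    assert sizes["C4-max"] == 90
    assert set(grouping.groups["C4-max"]) <= set(grouping.groups["C4"])
    assert set(grouping.groups["C1-0"]) <= set(grouping.groups["C1"])


def test_grouping_deterministic_on_ties_and_permutation_invariant():
    ids = [f"g{i}" for i in range(10)]
    expr = pd.Series(1.0, index=ids)
    a = group_by_expression(expr, n_high=2, n_very_high=1)
    b = group_by_expression(expr.sample(frac=1, random_state=3), n_high=2, n_very_high=1)
    assert a.groups == b.groups
    # ties broken lexicographically: the last two ids go to C4
    assert a.groups["C4"] == sorted(ids)[-2:]


def test_grouping_toy_sort_oracle():
    rng = np.random.default_rng(7)
    vals = rng.random(10)
    expr = pd.Series(vals, index=[f"g{i}" for i in range(10)])
    grouping = group_by_expression(expr, n_high=1, n_very_high=1)
    order = sorted(expr.index, key=lambda g: (expr[g], g))
    assert grouping.groups["C4"] == [order[-1]]
    assert grouping.groups["C1"] == order[:3]
    assert grouping.groups["C2"] == order[3:6]
    assert grouping.groups["C3"] == order[6:9]


def test_grouping_rejects_oversized_top_group():
    expr = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(ValueError):
        group_by_expression(expr, n_high=2, n_very_high=1)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


def _brute_force_D(x, y):
    pooled = sorted(set(x) | set(y))
    best = 0.0
    for t in pooled:
        fx = sum(v <= t for v in x) / len(x)
        fy = sum(v <= t for v in y) / len(y)
        best = max(best, abs(fx - fy))
    return best


def test_ks_identical_and_disjoint():
    assert ks_two_sample([1, 2, 3], [1, 2, 3]).D == 0.0
    assert ks_two_sample([1, 2, 3], [4, 5, 6]).D == 1.0


def test_ks_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n1, n2 = rng.integers(1, 201, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(loc=rng.uniform(-1, 1), size=n2)
        r = ks_two_sample(x, y)
        assert abs(r.D - _brute_force_D(list(x), list(y))) < 1e-12


def test_ks_statistic_agrees_with_scipy():
    rng = np.random.default_rng(13)
    x, y = rng.normal(size=80), rng.normal(0.4, size=120)
    r = ks_two_sample(x, y)
    assert r.D == pytest.approx(stats.ks_2samp(x, y).statistic, abs=1e-15)
    # p follows the Kolmogorov distribution at sqrt(effective n) * D
    en = 80 * 120 / 200
    assert r.p == pytest.approx(stats.kstwobign.sf(math.sqrt(en) * r.D), rel=1e-9)


def test_ks_rejects_empty_sample():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


# ---------------------------------------------------------------------------
# metagene: anchor rule and binning


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("e1_len,anchored", [(50, False), (99, False), (100, True), (150, True)])
def test_exon1_anchor_rule(strand, e1_len, anchored):
    if strand == "+":
        exons = [(1000, 1000 + e1_len), (1000 + e1_len + 200, 1000 + e1_len + 700)]
    else:
        exons = [(2000, 2000 + e1_len), (1000, 1500)]
    g = _gene("g", exons, strand=strand)
    seg = anchored_exon1_segment(g)
    e1 = g.exons[0]
    if anchored:
        assert seg == e1  # 5' end at the start codon
    elif strand == "+":
        assert (seg.start, seg.end) == (e1.end - 100, e1.end)  # 5'SS - 100
    else:
        assert (seg.start, seg.end) == (e1.start, e1.start + 100)


def test_metagene_zero_when_ip_equals_input():
    scores = {"c": np.arange(1.0, 41.0)}
    track = make_track(scores)
    g = GeneModel("g", "protein_coding", "+", (
        Interval("c", 100, 250, "+"), Interval("c", 700, 1200, "+")))
    mat = metagene_spliced(track, track, [g])
    np.testing.assert_allclose(mat.values, 0.0, atol=1e-12)


def test_metagene_binning_conserves_gene_mean():
    rng = np.random.default_rng(5)
    track = make_track({"c": rng.random(100)})
    g = GeneModel("g", "protein_coding", "+", (Interval("c", 120, 2370, "+"),))
    mat = metagene_whole_gene(track, [g], n_bins=37)
    assert mat.values[0].mean() == pytest.approx(gene_mean_enrichment(track, g), abs=1e-9)


def test_metagene_orientation_symmetry():
    L = 10_000
    rng = np.random.default_rng(8)
    scores = rng.random(L // 50)
    fwd = make_track({"c": scores})
    rev = make_track({"c": scores[::-1]})
    g_plus = GeneModel("g", "protein_coding", "+", (
        Interval("c", 1000, 1060, "+"), Interval("c", 1300, 2000, "+")))
    # mirrored gene: [s,e) -> [L-e, L-s), strand flipped
    g_minus = GeneModel("g", "protein_coding", "-", (
        Interval("c", L - 1060, L - 1000, "-"), Interval("c", L - 2000, L - 1300, "-")))
    m1 = metagene_spliced(fwd, fwd, [g_plus])
    m2 = metagene_spliced(rev, rev, [g_minus])
    np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)
    w1 = metagene_whole_gene(fwd, [g_plus], flank=200, n_bins=20)
    w2 = metagene_whole_gene(rev, [g_minus], flank=200, n_bins=20)
    np.testing.assert_allclose(w1.values, w2.values, atol=1e-12)


def test_metagene_skips_multi_intron_genes(caplog):
    track = make_track({"c": np.ones(100)})
    g3 = GeneModel("g3", "protein_coding", "+", (
        Interval("c", 0, 100, "+"), Interval("c", 200, 300, "+"), Interval("c", 400, 500, "+")))
    g1 = GeneModel("g1", "protein_coding", "+", (
        Interval("c", 600, 760, "+"), Interval("c", 900, 1400, "+")))
    mat = metagene_spliced(track, track, [g3, g1])
    assert mat.gene_ids == ["g1"]


def test_whole_gene_aggregation_mean_vs_median():
    track = make_track({"c": np.ones(100)})
    genes = [
        GeneModel("a", "other", "+", (Interval("c", 0, 500, "+"),)),
        GeneModel("b", "other", "+", (Interval("c", 1000, 1500, "+"),)),
        GeneModel("z", "other", "+", (Interval("c", 3000, 3500, "+"),)),
    ]
    mat = metagene_whole_gene(track, genes, n_bins=10)
    mat.values[2, :] = 100.0  # one outlier row
    np.testing.assert_allclose(mat.aggregate("median"), 1.0)
    np.testing.assert_allclose(mat.aggregate("mean"), 34.0)


def test_single_gene_aggregate_equals_row():
    track = make_track({"c": np.arange(100.0)})
    g = GeneModel("g", "other", "+", (Interval("c", 100, 2100, "+"),))
    mat = metagene_whole_gene(track, [g], n_bins=8)
    np.testing.assert_array_equal(mat.aggregate(), mat.values[0])


# ---------------------------------------------------------------------------
# exon-2 statistics


def test_exon2_stats_constant_and_slice_oracle():
    track = make_track({"c": np.ones(100)})
    rpg = GeneModel("rpg", "protein_coding", "+", (
        Interval("c", 100, 260, "+"), Interval("c", 400, 900, "+")), is_rpg=True)
    nrpg = GeneModel("nrpg", "protein_coding", "+", (
        Interval("c", 2000, 2160, "+"), Interval("c", 2300, 2800, "+")))
    mat = metagene_spliced(track, track, [rpg, nrpg])
    mat.values[:, mat.segment_slice("exon2")] = 0.5
    stats_df = exon2_boxplot_stats(mat, {"rpg": rpg, "nrpg": nrpg})
    assert stats_df["exon2_mean_log2fc"].tolist() == [0.5, 0.5]
    assert stats_df["group"].tolist() == ["RPG i-genes", "NRPG i-genes"]
    rng = np.random.default_rng(2)
    mat.values[:] = rng.random(mat.values.shape)
    stats_df = exon2_boxplot_stats(mat, {"rpg": rpg, "nrpg": nrpg})
    sl = mat.segment_slice("exon2")
    np.testing.assert_allclose(
        stats_df["exon2_mean_log2fc"], mat.values[:, sl].mean(axis=1)
    )


def test_whole_gene_log2fc():
    ip = make_track({"c": np.full(20, 4.0)})
    inp = make_track({"c": np.full(20, 1.0)})
    g = GeneModel("g", "protein_coding", "+", (Interval("c", 100, 900, "+"),))
    df = whole_gene_log2fc(ip, inp, [g], epsilon=0.0)
    assert df["mean_log2fc"].iloc[0] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# ChIP-QPCR ddCt


def test_qpcr_closed_forms():
    samples = [
        QpcrSample("CEN16", ct_input=15.0, ct_beads=22.0, ct_ip=18.0),
        QpcrSample("tQ", ct_input=15.0, ct_beads=22.0, ct_ip=20.0),
        QpcrSample("flat", ct_input=16.0, ct_beads=23.0, ct_ip=16.0),
    ]
    out = qpcr_relative_enrichment(samples, "CEN16")
    assert out.loc["tQ", "ip_raw"] == 2.0 ** -5 == 0.03125
    assert out.loc["flat", "ip_raw"] == 1.0
    assert out.loc["CEN16", "ip_relative"] == 1.0
    assert out.loc["CEN16", "noab_relative"] == 1.0
    assert out.loc["tQ", "ip_relative"] == pytest.approx((2.0 ** -5) / (2.0 ** -3))


def test_qpcr_missing_ct_rejected():
    with pytest.raises(ValueError, match="ct_ip"):
        QpcrSample("x", ct_input=15.0, ct_beads=22.0, ct_ip=float("nan"))
    with pytest.raises(ValueError, match="reference"):
        qpcr_relative_enrichment(
            [QpcrSample("x", 15.0, 22.0, 18.0)], reference="CEN16"
        )
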