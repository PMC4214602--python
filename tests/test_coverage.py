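import numpy as np
import pandas as pd
import pytest

from rloopscape.coverage import (
    ReadSet,
    exclude_loci,
    extend_and_bin,
    intergenic_mean,
    normalize,
    read_bed6,
    resolve_multimappers,
    smooth,
    write_bed6,
)
from rloopscape.genome_io import Interval


def _reads(rows, candidates=None):
    df = pd.DataFrame(rows, columns=["contig", "start", "strand", "read_length", "n_hits"])
    return ReadSet(reads=df, candidates=candidates or {})


def _track_from_counts(counts_by_contig, window_size=50, fragment_length=200):
    """Build a DepthTrack directly from per-base coverage counts."""
    from rloopscape.coverage import DepthTrack

    numerators, denominators, lengths = {}, {}, {}
    for c, cov in counts_by_contig.items():
        cov = np.asarray(cov)
        L = len(cov)
        n_win = -(-L // window_size)
        padded = np.zeros(n_win * window_size, dtype=cov.dtype)
        padded[:L] = cov
        numerators[c] = padded.reshape(n_win, window_size).sum(axis=1)
        denominators[c] = np.full(n_win, window_size, dtype=np.int64)
        lengths[c] = L
    return DepthTrack(
        window_size=window_size,
        fragment_length=fragment_length,
        contig_lengths=lengths,
        numerators=numerators,
        denominators=denominators,
        base_coverage={c: np.asarray(v) for c, v in counts_by_contig.items()},
    )


# ---------------------------------------------------------------------------
# fragment extension geometry


def test_single_plus_read_geometry():
    track = extend_and_bin(_reads([("c", 0, "+", 50, 1)]), {"c": 400})
    np.testing.assert_array_equal(track.values("c"), [1, 1, 1, 1, 0, 0, 0, 0])


def test_minus_read_extends_upstream():
    track = extend_and_bin(_reads([("c", 399, "-", 50, 1)]), {"c": 400})
    # fragment [200, 400): enumerate covered bases independently
    expected = np.zeros(400)
    for base in range(399, 399 - 200, -1):
        expected[base] = 1
    np.testing.assert_array_equal(track.base_coverage["c"], expected)
    np.testing.assert_array_equal(track.values("c"), [0, 0, 0, 0, 1, 1, 1, 1])


def test_depth_linearity():
    one = extend_and_bin(_reads([("c", 10, "+", 50, 1)]), {"c": 400})
    two = extend_and_bin(_reads([("c", 10, "+", 50, 1)] * 2), {"c": 400})
    np.testing.assert_array_equal(two.values("c"), 2 * one.values("c"))


def test_fragment_clipped_at_contig_end():
    track = extend_and_bin(_reads([("c", 350, "+", 50, 1)]), {"c": 400})
    assert track.base_coverage["c"].sum() == 50  # only 50 bases fit


def test_fragment_shorter_than_read_rejected():
    with pytest.raises(ValueError, match="fragment_length"):
        extend_and_bin(_reads([("c", 0, "+", 50, 1)]), {"c": 400}, fragment_length=40)


# ---------------------------------------------------------------------------
# smoothing


def test_smooth_preserves_constant():
    track = _track_from_counts({"c": np.full(500, 4)})
    sm = smooth(track)
    np.testing.assert_allclose(sm.values("c"), 4.0)


def test_smooth_matches_per_base_moving_average_oracle():
    rng = np.random.default_rng(0)
    cov = rng.integers(0, 6, size=650)
    sm = smooth(_track_from_counts({"c": cov}))
    for w in range(13):
        lo, hi = max(w * 50 - 25, 0), min(w * 50 + 75, 650)
        assert sm.values("c")[w] == pytest.approx(cov[lo:hi].mean(), abs=1e-12)


def test_smooth_middle_window_example():
    cov = np.concatenate([np.zeros(50), np.full(50, 3), np.zeros(50)])
    sm = smooth(_track_from_counts({"c": cov}))
    # centered 100 bp around the middle window: 25*0 + 50*3 + 25*0 over 100
    assert sm.values("c")[1] == pytest.approx(1.5)


def test_smooth_conserves_total_signal_away_from_edges():
    rng = np.random.default_rng(1)
    cov = np.zeros(1000, dtype=np.int64)
    cov[100:900] = rng.integers(0, 5, 800)  # zero margin removes edge effects
    track = _track_from_counts({"c": cov})
    sm = smooth(track)
    assert sm.values("c").sum() * 50 == pytest.approx(cov.sum())


# ---------------------------------------------------------------------------
# multimapper handling and exclusion


def test_unique_read_unchanged_in_both_modes():
    rs = _reads([("c", 5, "+", 50, 1)])
    for mode in ("random", "unique_only"):
        out = resolve_multimappers(rs, mode, seed=1)
        assert out.reads.iloc[0]["start"] == 5


def test_random_assignment_deterministic_under_seed():
    rows = [("c", i, "+", 50, 2) for i in range(1000)]
    cands = {i: [("c", i, "+"), ("c", i + 5000, "+")] for i in range(1000)}
    a = resolve_multimappers(_reads(rows, cands), "random", seed=42)
    b = resolve_multimappers(_reads(rows, cands), "random", seed=42)
    pd.testing.assert_frame_equal(a.reads, b.reads)
    # and both candidate locations actually get used
    assert a.reads["start"].gt(4000).any() and a.reads["start"].lt(4000).any()


def test_unique_only_count_filter():
    rows = [("c", i, "+", 50, 2 if i < 300 else 1) for i in range(1000)]
    cands = {i: [("c", i, "+"), ("c", i + 5000, "+")] for i in range(300)}
    out = resolve_multimappers(_reads(rows, cands), "unique_only", seed=0)
    assert len(out) == 700


def test_multimapper_without_candidates_rejected():
    with pytest.raises(ValueError, match="candidate"):
        resolve_multimappers(_reads([("c", 0, "+", 50, 3)]), "random", seed=0)


def test_exclude_loci_examples_and_oracle():
    rs = _reads([("c", i * 37 % 900, "+", 50, 1) for i in range(200)])
    assert exclude_loci(rs, []) is rs
    excl = [Interval("c", 100, 180), Interval("c", 400, 420), Interval("c", 800, 880)]
    out = exclude_loci(rs, excl)
    # O(n*m) brute-force overlap oracle
    kept_oracle = []
    for _, r in rs.reads.iterrows():
        s, e = r["start"], r["start"] + 50
        if not any(s < iv.end and iv.start < e for iv in excl):
            kept_oracle.append(s)
    assert out.reads["start"].tolist() == kept_oracle
    inside = _reads([("c", 110, "+", 50, 1)])
    assert len(exclude_loci(inside, excl)) == 0


# ---------------------------------------------------------------------------
# intergenic mean and normalization


def test_intergenic_mean_uniform():
    track = _track_from_counts({"c": np.full(500, 4)})
    bg = intergenic_mean(track, [Interval("c", 0, 500)])
    assert float(bg) == 4.0


def test_intergenic_mean_excludes_zero_windows():
    cov = np.concatenate([np.zeros(50), np.full(50, 2), np.full(50, 4)])
    track = _track_from_counts({"c": cov})
    bg = intergenic_mean(track, [Interval("c", 0, 150)])
    assert float(bg) == 3.0  # zero-coverage window dropped


def test_intergenic_mean_matches_direct_recomputation():
    rng = np.random.default_rng(3)
    cov = rng.integers(0, 4, size=2000)
    track = _track_from_counts({"c": cov})
    inter = [Interval("c", 0, 730), Interval("c", 1000, 2000)]
    bg = intergenic_mean(track, inter)
    vals = track.values("c")
    eligible = [w for w in range(40) if (w * 50 >= 1000 or (w + 1) * 50 <= 730)]
    direct = np.mean([vals[w] for w in eligible if vals[w] > 0])
    assert float(bg) == pytest.approx(direct, rel=1e-12)
    assert bg.n_windows == sum(1 for w in eligible if vals[w] > 0)


def test_intergenic_mean_requires_coverage():
    track = _track_from_counts({"c": np.zeros(200, dtype=np.int64)})
    with pytest.raises(ValueError, match="simulate or sequence deeper"):
        intergenic_mean(track, [Interval("c", 0, 200)])


def test_normalize_self_and_elementwise():
    rng = np.random.default_rng(4)
    cov = rng.integers(1, 9, size=1000)
    track = _track_from_counts({"c": cov})
    bg = intergenic_mean(track, [Interval("c", 0, 1000)])
    ent = normalize(track, bg)
    np.testing.assert_allclose(ent.scores["c"], track.values("c") / float(bg), rtol=1e-12)
    uniform = _track_from_counts({"c": np.full(500, 7)})
    ent2 = normalize(uniform, intergenic_mean(uniform, [Interval("c", 0, 500)]))
    np.testing.assert_array_equal(ent2.scores["c"], 1.0)


def test_normalize_rejects_nonpositive_background():
    track = _track_from_counts({"c": np.full(500, 7)})
    with pytest.raises(ValueError, match="positive"):
        normalize(track, 0.0)


def test_scale_invariance_bit_identical():
    rng = np.random.default_rng(5)
    rows = [("c", int(s), "+" if rng.random() < 0.5 else "-", 50, 1)
            for s in rng.integers(60, 1940, size=300)]
    base = _reads(rows)
    inter = [Interval("c", 0, 700), Interval("c", 1300, 2000)]

    def scores(rs):
        track = smooth(extend_and_bin(rs, {"c": 2000}))
        return normalize(track, intergenic_mean(track, inter)).scores["c"]

    ref = scores(base)
    for r in (2, 10):
        dup = ReadSet(reads=pd.concat([base.reads] * r, ignore_index=True))
        assert np.array_equal(scores(dup), ref)


# ---------------------------------------------------------------------------
# BED6 I/O


def test_bed6_round_trip(tmp_path):
    rows = [("c", 10, "+", 50, 1), ("c", 99, "-", 50, 3)]
    cands = {1: [("c", 99, "-"), ("d", 500, "-"), ("c", 700, "-")]}
    rs = _reads(rows, cands)
    bed, sidecar = tmp_path / "r.bed", tmp_path / "r.cand.tsv"
    write_bed6(rs, bed, sidecar=sidecar)
    back = read_bed6(bed, sidecar=sidecar)
    pd.testing.assert_frame_equal(back.reads, rs.reads)
    assert back.candidates == cands
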