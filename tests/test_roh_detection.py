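"""ROH caller vs brute force, F_ROH, homozygosity, length classes, min-SNP rule."""

import math

import numpy as np
import pytest

from rohdiv.io_formats import GenotypeDataset, MarkerMap
from rohdiv.roh_detection import (ROHCallParams, call_roh,
                                  class_froh_from_coverages, froh,
                                  genome_length_bp, length_class_table,
                                  min_snp_threshold, observed_homozygosity,
                                  ROHSegment)


def one_chrom_ds(calls_row, positions, sample="S1"):
    n = len(positions)
    mm = MarkerMap(["1"] * n, positions, [f"m{j}" for j in range(n)],
                   ["A"] * n, ["G"] * n)
    calls = np.asarray([calls_row], dtype=np.uint8)
    return GenotypeDataset(mm, [sample], calls)


def brute_force_roh(calls, pos, min_snps, min_length_kb, max_gap_kb,
                    max_kb_per_snp):
    """Oracle: maximal homozygous runs, gap-split, then minima filters."""
    hom = [(c == 0 or c == 2) for c in calls]
    runs, start = [], None
    for j, h in enumerate(hom):
        if h and start is None:
            start = j
        if not h and start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, len(hom) - 1))
    out = []
    for a, b in runs:
        piece = [a]
        for j in range(a, b):
            if (pos[j + 1] - pos[j]) / 1000.0 > max_gap_kb:
                piece.append(j)      # last index of current piece
                piece.append(j + 1)  # first index of next
        piece.append(b)
        for s, e in zip(piece[::2], piece[1::2]):
            n = e - s + 1
            kb = (pos[e] - pos[s] + 1) / 1000.0
            if n >= min_snps and kb >= min_length_kb and kb / n <= max_kb_per_snp:
                out.append((s, e))
    return out


def test_uninterrupted_run_is_one_segment():
    """100 homozygous SNPs over 1.5 Mb yield exactly one 100-SNP segment."""
    pos = (np.arange(100) * 15_000 + 1).tolist()  # 15 kb spacing
    ds = one_chrom_ds([0] * 50 + [2] * 50, pos)
    segs = call_roh(ds, ROHCallParams())
    assert len(segs) == 1
    s = segs[0]
    assert (s.n_snps, s.start, s.end) == (100, 1, 99 * 15_000 + 1)


def test_het_splits_run_with_strict_params():
    """A single het under W=1, H=0, T=1 splits the run in two (or kills it)."""
    pos = (np.arange(21) * 10_000 + 1).tolist()
    calls = [0] * 10 + [1] + [2] * 10
    ds = one_chrom_ds(calls, pos)
    p = ROHCallParams(window_snps=1, max_het_per_window=0,
                      max_missing_per_window=0, hit_threshold=1.0,
                      min_snps=5, min_length_kb=50, max_gap_kb=1000,
                      max_kb_per_snp=50)
    segs = call_roh(ds, p)
    assert len(segs) == 2
    assert [s.n_snps for s in segs] == [10, 10]
    # raise the minimum above both halves: nothing survives
    p2 = ROHCallParams(window_snps=1, max_het_per_window=0,
                       max_missing_per_window=0, hit_threshold=1.0,
                       min_snps=15, min_length_kb=50, max_gap_kb=1000,
                       max_kb_per_snp=50)
    assert call_roh(ds, p2) == []


def test_gap_split_and_density():
    pos = [1, 10_001, 20_001, 1_200_001, 1_210_001, 1_220_001]
    ds = one_chrom_ds([0] * 6, pos)
    p = ROHCallParams(window_snps=1, max_het_per_window=0,
                      max_missing_per_window=0, hit_threshold=1.0,
                      min_snps=3, min_length_kb=10, max_gap_kb=1000,
                      max_kb_per_snp=50)
    segs = call_roh(ds, p)
    assert [(s.start, s.end) for s in segs] == [(1, 20_001), (1_200_001, 1_220_001)]


@pytest.mark.parametrize("seed", range(25))
def test_caller_matches_brute_force_in_simplified_regime(seed):
    """Windowed caller == exhaustive run enumeration when W=L, H=M=0, T=1/W."""
    rng = np.random.default_rng(seed)
    for _ in range(20):
        m = int(rng.integers(10, 61))
        calls = rng.choice([0, 1, 2, 3], size=m, p=[0.42, 0.12, 0.4, 0.06])
        pos = np.cumsum(rng.integers(1_000, 200_000, size=m))
        W = int(rng.integers(2, 8))
        min_kb = float(rng.choice([10, 50, 200]))
        p = ROHCallParams(window_snps=W, max_het_per_window=0,
                          max_missing_per_window=0, hit_threshold=1.0 / W,
                          min_snps=W, min_length_kb=min_kb, max_gap_kb=500,
                          max_kb_per_snp=1e9)
        ds = one_chrom_ds(calls.tolist(), pos.tolist())
        got = [(int(np.flatnonzero(pos == s.start)[0]),
                int(np.flatnonzero(pos == s.end)[0])) for s in call_roh(ds, p)]
        want = brute_force_roh(calls.tolist(), pos.tolist(), W, min_kb, 500, 1e9)
        assert got == want


def test_reported_segments_satisfy_contract(rng):
    """Post-hoc validator: every emitted segment respects all five constraints."""
    m = 400
    calls = rng.choice([0, 1, 2, 3], size=(3, m), p=[0.46, 0.04, 0.46, 0.04])
    pos = np.cumsum(rng.integers(5_000, 40_000, size=m))
    mm = MarkerMap(["1"] * m, pos, [f"m{j}" for j in range(m)], ["A"] * m, ["G"] * m)
    ds = GenotypeDataset(mm, ["a", "b", "c"], calls.astype(np.uint8))
    p = ROHCallParams(window_snps=20, max_het_per_window=1,
                      max_missing_per_window=2, hit_threshold=0.05,
                      min_snps=25, min_length_kb=200, max_gap_kb=500,
                      max_kb_per_snp=60)
    for s in call_roh(ds, p):
        assert s.n_snps >= p.min_snps
        assert s.length_kb >= p.min_length_kb
        assert s.length_kb / s.n_snps <= p.max_kb_per_snp
        i0 = int(np.flatnonzero(pos == s.start)[0])
        i1 = int(np.flatnonzero(pos == s.end)[0])
        assert np.all(np.diff(pos[i0:i1 + 1]) / 1000.0 <= p.max_gap_kb)
        row = calls[["a", "b", "c"].index(s.sample)]
        assert row[i0] in (0, 2) and row[i1] in (0, 2)


def test_unsorted_map_rejected(rng):
    ds = one_chrom_ds([0, 0, 0], [300, 100, 200])
    with pytest.raises(Exception):
        call_roh(ds, ROHCallParams(window_snps=1))


def test_small_chromosome_skipped_with_warning():
    ds = one_chrom_ds([0] * 5, [1, 2, 3, 4, 5])
    with pytest.warns(UserWarning, match="fewer SNPs"):
        assert call_roh(ds, ROHCallParams(window_snps=50)) == []


def test_froh_limits():
    """No segments -> 0; one segment over the whole marker span -> 1."""
    pos = (np.arange(10) * 100_000 + 1).tolist()
    ds = one_chrom_ds([0] * 10, pos)
    assert froh([], ds)[0].f_roh == 0.0
    seg = ROHSegment("S1", "1", pos[0], pos[-1], 10)
    r = froh([seg], ds)[0]
    assert r.f_roh == pytest.approx(1.0)
    assert r.n_segments == 1


def test_genome_length_sums_chromosome_spans():
    mm = MarkerMap(["1", "1", "2", "2"], [100, 600, 50, 150],
                   ["a", "b", "c", "d"], ["A"] * 4, ["G"] * 4)
    ds = GenotypeDataset(mm, ["s"], np.zeros((1, 4), dtype=np.uint8))
    assert genome_length_bp(ds) == 501 + 101


def test_observed_homozygosity_counts(rng):
    """Monomorphic markers are excluded from numerator and denominator."""
    mm = MarkerMap(["1"] * 4, [1, 2, 3, 4], list("abcd"), ["A"] * 4, ["G"] * 4)
    calls = np.array([[0, 0, 2, 3],
                      [0, 1, 2, 0],
                      [0, 2, 1, 0]], dtype=np.uint8)
    # marker 'a' is monomorphic (all hom-ref) -> excluded everywhere
    ds = GenotypeDataset(mm, ["x", "y", "z"], calls)
    t = observed_homozygosity(ds)
    assert t.loc["x", "o_hom"] == 2 and t.loc["x", "n_nonmissing"] == 2
    assert t.loc["x", "o_hom_pct"] == pytest.approx(100.0)
    assert t.loc["y", "o_hom_pct"] == pytest.approx(50.0)
    # all-hom sample at polymorphic markers scores 100%
    ds2 = one_chrom_ds([0, 2, 0], [1, 2, 3])
    ds2.calls = np.vstack([ds2.calls, np.array([[2, 0, 1]], np.uint8)])
    ds2.samples = ["S1", "S2"]
    assert observed_homozygosity(ds2).loc["S1", "o_hom_pct"] == pytest.approx(100.0)


def test_length_class_table_single_segment():
    """A 3 Mb segment in a 100 Mb genome covers 3% of the 2-4 Mb class only."""
    pos = [1, 100_000_000]
    ds = one_chrom_ds([0, 0], pos)
    seg = ROHSegment("S1", "1", 1_000_000, 4_000_000 - 1, 50)
    t = length_class_table([seg], ds)
    assert t.loc["2-4 Mb", "genome_coverage_pct"] == pytest.approx(3.0, rel=1e-6)
    assert t.loc["1-2 Mb", "genome_coverage_pct"] == 0.0
    # cumulative convention: the shortest class equals overall F_ROH
    assert t.loc["1-2 Mb", "class_froh_mean"] == pytest.approx(0.03, rel=1e-6)
    assert t.loc[">16 Mb", "class_froh_mean"] == 0.0


def test_class_froh_coverage_identity(rng):
    """class_froh(c) − class_froh(next) == coverage(c)/100 on random segments."""
    pos = [1, 200_000_000]
    ds = one_chrom_ds([0, 0], pos)
    segs = []
    start = 1
    for k in range(40):
        ln = int(rng.uniform(1e6, 3e7))
        segs.append(ROHSegment("S1", "1", start, start + ln - 1, 100))
        start += ln + 100_000
    t = length_class_table(segs, ds)
    fr = t["class_froh_mean"].to_numpy()
    cov = t["genome_coverage_pct"].to_numpy()
    assert np.allclose(fr[:-1] - fr[1:], cov[:-1] / 100.0)
    assert np.allclose(fr[-1], cov[-1] / 100.0)
    # identity helper matches the table
    assert np.allclose(class_froh_from_coverages(cov), fr)
    # classes partition the called footprint
    total = sum(s.length_bp for s in segs) / genome_length_bp(ds)
    assert cov.sum() / 100.0 == pytest.approx(total)


def test_min_snp_threshold_formula_and_monotonicity():
    """Study-scale inputs give L=56; L decreases as heterozygosity grows."""
    assert min_snp_threshold(None, 0.05, 158_378, 244, 0.31) == 56
    ls = [min_snp_threshold(None, 0.05, 10_000, 50, h) for h in (0.1, 0.3, 0.5, 0.9)]
    assert ls == sorted(ls, reverse=True)
    # doubling samples adds at most log(2)/|log(1-het)| SNPs
    l1 = min_snp_threshold(None, 0.05, 10_000, 50, 0.31)
    l2 = min_snp_threshold(None, 0.05, 10_000, 100, 0.31)
    assert 0 <= l2 - l1 <= math.log(2) / -math.log(0.69) + 1
    with pytest.raises(ValueError):
        min_snp_threshold(None, 0.05, 100, 10, 0.0)
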