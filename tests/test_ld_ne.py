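"""LD r², quantile binning, Sved inversion, decay interpolation, ΔF changes."""

import numpy as np
import pandas as pd
import pytest

from rohdiv.io_formats import GenotypeDataset, MarkerMap
from rohdiv.ld_ne import (bin_ld, decay_half_distance, delta_f_percent_change,
                          pairwise_r2, sved_ne)

from conftest import random_dataset


def dosage_ds(cols, positions, chrom=None):
    cols = np.asarray(cols, dtype=np.uint8)
    n_samples, m = cols.shape
    chrom = chrom or ["1"] * m
    mm = MarkerMap(chrom, positions, [f"m{j}" for j in range(m)],
                   ["A"] * m, ["G"] * m)
    return GenotypeDataset(mm, [f"S{i}" for i in range(n_samples)], cols)


def brute_r2(ds, max_kb):
    """Oracle: plain double loop over all pairs with pairwise-complete r²."""
    out = {}
    m = ds.n_markers
    dos = ds.dosage()
    for i in range(m):
        for j in range(i + 1, m):
            if ds.markers.chrom[i] != ds.markers.chrom[j]:
                continue
            d = abs(int(ds.markers.pos[j]) - int(ds.markers.pos[i]))
            if d > max_kb * 1000:
                continue
            x, y = dos[:, i], dos[:, j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 2:
                continue
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(x[ok], y[ok])[0, 1]
            if np.isfinite(r):
                out[(str(ds.markers.ids[i]), str(ds.markers.ids[j]))] = r * r
    return out


def test_identical_dosages_give_r2_one():
    col = [0, 1, 2, 2, 0, 1]
    ds = dosage_ds(np.array([col, col]).T, [100, 200])
    pairs = pairwise_r2(ds, 10)
    assert len(pairs) == 1
    assert pairs["r2"].iloc[0] == pytest.approx(1.0)


def test_r2_invariant_to_allele_flip_and_order():
    rng = np.random.default_rng(5)
    a = rng.choice([0, 1, 2], size=30)
    b = rng.choice([0, 1, 2], size=30)
    ds1 = dosage_ds(np.array([a, b]).T, [100, 5000])
    ds2 = dosage_ds(np.array([2 - a, b]).T, [100, 5000])  # 0<->2 relabel
    r1 = pairwise_r2(ds1, 10)["r2"].iloc[0]
    r2 = pairwise_r2(ds2, 10)["r2"].iloc[0]
    assert r1 == pytest.approx(r2)


def test_independent_markers_mean_r2_near_1_over_n():
    """E[r²] for unlinked loci is ~1/n — the classic finite-sample bias."""
    rng = np.random.default_rng(17)
    n, m = 50, 400
    p = rng.uniform(0.2, 0.8, size=m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.uint8)
    pos = np.arange(m) * 1000 + 1
    ds = dosage_ds(calls, pos.tolist())
    pairs = pairwise_r2(ds, max_distance_kb=2)  # adjacent pairs only
    mean_r2 = pairs["r2"].mean()
    assert mean_r2 == pytest.approx(1.0 / n, abs=0.01)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_windowed_implementation_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, 12, 200, n_chrom=3, missing_rate=0.1, spacing=30_000)
    got = {(r.id1, r.id2): r.r2 for r in
           pairwise_r2(ds, max_distance_kb=500).itertuples()}
    want = brute_r2(ds, 500)
    assert set(got) == set(want)
    for k in want:
        assert got[k] == pytest.approx(want[k], abs=1e-10)


def test_bin_ld_equal_counts_and_means():
    df = pd.DataFrame({"distance_bp": np.arange(10) * 100 + 50,
                       "r2": np.linspace(1, 0.1, 10),
                       "id1": "a", "id2": "b", "chrom": "1"})
    bins = bin_ld(df, 2)
    assert bins["n_pairs"].tolist() == [5, 5]
    assert bins["mean_r2"].iloc[0] == pytest.approx(df["r2"][:5].mean())
    assert bins["mean_distance_bp"].iloc[1] == pytest.approx(df["distance_bp"][5:].mean())
    with pytest.raises(ValueError):
        bin_ld(df, 11)


def test_bin_ld_ties_stable():
    df = pd.DataFrame({"distance_bp": [100] * 4, "r2": [0.1, 0.2, 0.3, 0.4]})
    bins = bin_ld(df, 2)
    assert bins["mean_r2"].tolist() == pytest.approx([0.15, 0.35])


def test_sved_closed_form():
    """r̄²=0.5 at c=0.01 M: N_e=25, t=50, ΔF=0.02."""
    bins = pd.DataFrame({"mean_distance_bp": [1_000_000], "mean_r2": [0.5]})
    ne = sved_ne(bins)
    assert ne["c_morgans"].iloc[0] == pytest.approx(0.01)
    assert ne["t_generations"].iloc[0] == pytest.approx(50.0)
    assert ne["ne"].iloc[0] == pytest.approx(25.0)
    assert ne["delta_f"].iloc[0] == pytest.approx(0.02)


def test_sved_monotone_and_limits():
    bins = pd.DataFrame({"mean_distance_bp": [1e6] * 3,
                         "mean_r2": [0.2, 0.5, 0.99]})
    ne = sved_ne(bins)["ne"].to_numpy()
    assert ne[0] > ne[1] > ne[2]          # N_e decreasing in r²
    assert ne[2] == pytest.approx((1 / 0.99 - 1) / 0.04)  # ->0 as r²->1
    bad = pd.DataFrame({"mean_distance_bp": [1e6], "mean_r2": [0.0]})
    with pytest.raises(ValueError):
        sved_ne(bad)


def test_sved_sample_size_correction_flagged():
    bins = pd.DataFrame({"mean_distance_bp": [1e6], "mean_r2": [0.5]})
    ne = sved_ne(bins, n_samples=50, sample_size_correction=True)
    assert ne.attrs["sample_size_correction"] is True
    assert ne["ne"].iloc[0] == pytest.approx((1 / 0.48 - 1) / 0.04)


def test_decay_half_distance_boundary_and_interpolation():
    b1 = pd.DataFrame({"mean_distance_bp": [10_000, 100_000],
                       "mean_r2": [0.6, 0.3]})
    assert decay_half_distance(b1) == pytest.approx(100_000)
    b2 = pd.DataFrame({"mean_distance_bp": [10_000, 50_000],
                       "mean_r2": [0.6, 0.2]})
    # half-max 0.3 crossed linearly: 10k + (0.6-0.3)/(0.6-0.2)*40k = 40 kb
    assert decay_half_distance(b2) == pytest.approx(40_000)
    b3 = pd.DataFrame({"mean_distance_bp": [1e4, 2e4], "mean_r2": [0.6, 0.55]})
    assert decay_half_distance(b3) is None


def test_decay_half_distance_matches_root_finding(rng):
    """On a smooth monotone curve the interpolation agrees with a dense root scan."""
    d = np.linspace(1e4, 2e6, 60)
    r = 0.6 / (1 + d / 2e5)
    bins = pd.DataFrame({"mean_distance_bp": d, "mean_r2": r})
    got = decay_half_distance(bins)
    dd = np.linspace(d[0], d[-1], 2_000_001)
    rr = np.interp(dd, d, r)
    want = dd[np.argmax(rr <= r.max() / 2)]
    assert got == pytest.approx(want, rel=1e-3)


def test_delta_f_percent_change_values():
    """0.0061 -> 0.0285 is a +367% rise; equal values 0%; doubling +100%."""
    ch = delta_f_percent_change([0.0061, 0.0285])
    assert ch[0] == pytest.approx(367.2, abs=0.1)
    assert delta_f_percent_change([0.5, 0.5])[0] == 0.0
    assert delta_f_percent_change([0.01, 0.02])[0] == pytest.approx(100.0)
    with pytest.raises(ValueError):
        delta_f_percent_change([0.0, 0.1])
    with pytest.raises(ValueError):
        delta_f_percent_change([0.1])
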