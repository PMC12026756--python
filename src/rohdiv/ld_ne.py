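"""LD decay, Sved effective population size, and inbreeding-rate trajectory.

Pairwise linkage disequilibrium is measured as the squared Pearson
correlation (r²) of unphased genotype dosages between same-chromosome
marker pairs within a distance window. Pairs are pooled genome-wide and
sorted into equal-count distance bins; each bin's mean distance maps to a
recombination fraction ``c`` (Morgans, at a fixed 1 cM/Mb), which under
Sved's drift-recombination equilibrium

    E[r²] ≈ 1 / (1 + 4 N_e c)

is inverted to an effective population size

    N_e(t) = (1/r̄² − 1) / (4 c),   t = 1/(2 c) generations ago,

with the per-generation inbreeding rate ΔF = 1/(2 N_e). An optional
small-sample correction subtracts 1/n (the expectation of r² for unlinked
loci in n samples) from r̄² before inversion; it is off by default and
recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeDataset

BP_PER_MORGAN = 100_000_000  # 1 cM/Mb genetic map


@dataclass
class LDPair:
    id1: str
    id2: str
    chrom: str
    distance_bp: int
    r2: float


def pairwise_r2(ds: GenotypeDataset, max_distance_kb: float = 1000.0,
                min_informative: int = 2) -> pd.DataFrame:
    """All same-chromosome dosage-r² pairs within ``max_distance_kb``.

    Missing calls are dropped pairwise; pairs with fewer than
    ``min_informative`` complete samples or a monomorphic member are
    skipped (counted in the ``skipped`` attribute of the result).
    """
    ds.markers.validate()
    max_bp = max_distance_kb * 1000.0
    dos = ds.dosage()
    rows = []
    skipped = 0
    for chrom in ds.markers.chromosomes():
        idx = ds.markers.chrom_slice(chrom)
        pos = ds.markers.pos[idx]
        ids = ds.markers.ids[idx]
        X = dos[:, idx]
        valid = ~np.isnan(X)
        m = len(idx)
        hi = np.searchsorted(pos, pos + max_bp, side="right")
        for i in range(m - 1):
            j0, j1 = i + 1, hi[i]
            if j1 <= j0:
                continue
            xi = X[:, i]
            vi = valid[:, i]
            Y = X[:, j0:j1]
            mask = vi[:, None] & valid[:, j0:j1]
            n = mask.sum(axis=0)
            xm = np.where(mask, xi[:, None], 0.0)
            ym = np.where(mask, Y, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sx = xm.sum(axis=0)
                sy = ym.sum(axis=0)
                sxx = (xm * xm).sum(axis=0)
                syy = (ym * ym).sum(axis=0)
                sxy = (xm * ym).sum(axis=0)
                cov = sxy - sx * sy / n
                vx = sxx - sx * sx / n
                vy = syy - sy * sy / n
                r2 = cov * cov / (vx * vy)
            for k in range(j1 - j0):
                if n[k] < min_informative or not np.isfinite(r2[k]):
                    skipped += 1
                    continue
                rows.append((str(ids[i]), str(ids[j0 + k]), chrom,
                             int(pos[j0 + k] - pos[i]), float(r2[k])))
    df = pd.DataFrame(rows, columns=["id1", "id2", "chrom", "distance_bp", "r2"])
    df.attrs["skipped"] = skipped
    return df


def bin_ld(pairs: pd.DataFrame, n_bins: int = 100) -> pd.DataFrame:
    """Equal-count (quantile) distance bins with per-bin mean distance/r².

    Ties in distance are broken by stable sort order so bin sizes differ
    by at most one pair.
    """
    if len(pairs) == 0:
        raise ValueError("no LD pairs to bin")
    if n_bins > len(pairs):
        raise ValueError(f"n_bins={n_bins} exceeds number of pairs {len(pairs)}")
    order = np.argsort(pairs["distance_bp"].to_numpy(), kind="stable")
    chunks = np.array_split(order, n_bins)
    rows = []
    for b, ch in enumerate(chunks):
        d = pairs["distance_bp"].to_numpy()[ch]
        r = pairs["r2"].to_numpy()[ch]
        rows.append({"bin": b + 1, "n_pairs": len(ch),
                     "min_distance_bp": int(d.min()), "max_distance_bp": int(d.max()),
                     "mean_distance_bp": float(d.mean()), "mean_r2": float(r.mean())})
    return pd.DataFrame(rows).set_index("bin")


def sved_ne(bins: pd.DataFrame, n_samples: int | None = None,
            sample_size_correction: bool = False,
            bp_per_morgan: float = BP_PER_MORGAN) -> pd.DataFrame:
    """Map each LD bin to (c, t, N_e, ΔF) via Sved's formula."""
    out = bins.copy()
    r2 = out["mean_r2"].to_numpy(dtype=float)
    if sample_size_correction:
        if not n_samples:
            raise ValueError("sample_size_correction requires n_samples")
        r2 = r2 - 1.0 / n_samples
    if np.any(r2 <= 0) or np.any(r2 >= 1):
        raise ValueError("mean r2 must lie in (0, 1) for Sved inversion")
    c = out["mean_distance_bp"].to_numpy(dtype=float) / bp_per_morgan
    if np.any(c <= 0):
        raise ValueError("zero recombination distance in a bin")
    out["c_morgans"] = c
    out["t_generations"] = 1.0 / (2.0 * c)
    out["ne"] = (1.0 / r2 - 1.0) / (4.0 * c)
    out["delta_f"] = 1.0 / (2.0 * out["ne"])
    out.attrs["sample_size_correction"] = sample_size_correction
    return out


def decay_half_distance(bins: pd.DataFrame) -> float | None:
    """Distance (bp) where mean r² first falls to half its maximum.

    Linear interpolation between adjacent (distance, r²) bin points,
    scanning outward in distance; ``None`` if never reached.
    """
    if len(bins) < 2:
        raise ValueError("need at least two bins")
    b = bins.sort_values("mean_distance_bp")
    d = b["mean_distance_bp"].to_numpy(dtype=float)
    r = b["mean_r2"].to_numpy(dtype=float)
    half = r.max() / 2.0
    if r[0] <= half:
        return float(d[0])
    for i in range(1, len(r)):
        if r[i] <= half:
            frac = (r[i - 1] - half) / (r[i - 1] - r[i])
            return float(d[i - 1] + frac * (d[i] - d[i - 1]))
    return None


def delta_f_percent_change(delta_f: pd.Series | np.ndarray) -> np.ndarray:
    """Percent change between consecutive ΔF values, old → new.

    ``delta_f`` is ordered from the older interval to the newer one;
    element i of the result is (new_i+1 − old_i)/old_i × 100.
    """
    x = np.asarray(delta_f, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two intervals")
    if np.any(x[:-1] == 0):
        raise ValueError("percent change undefined from a zero baseline")
    return (x[1:] - x[:-1]) / x[:-1] * 100.0
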