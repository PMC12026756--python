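"""Per-marker two-cohort fixation index (Weir–Cockerham 1984).

For two cohorts with sample sizes n_i, alternate-allele frequencies p_i
and observed heterozygote fractions h_i, the estimator partitions the
allele-frequency variance into components a (between populations),
b (between individuals within populations) and c (within individuals),
and reports F_ST = a / (a + b + c). Values may be negative at individual
markers (sampling noise around zero differentiation) and are reported
unclamped; a genome-wide estimate uses the ratio of summed components.
Markers with F_ST above a threshold (default 0.75, strict inequality) are
flagged as candidate fixed/breed-defining differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import GenotypeDataset, HET, HOM_ALT, MISSING


def _cohort_stats(calls: np.ndarray):
    """Per-marker (n genotyped, alt freq, het fraction) for one cohort."""
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0).astype(float)
    alt = np.where(nonmiss, calls, 0).sum(axis=0).astype(float)
    het = ((calls == HET) & nonmiss).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        h = het / n
    return n, p, h


def weir_cockerham_components(n1, p1, h1, n2, p2, h2):
    """Variance components (a, b, c) of the two-population estimator."""
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
        c = h_bar / 2.0
    return a, b, c


def fst_per_marker(ds: GenotypeDataset, threshold: float = 0.75,
                   exclude_samples: list[str] | None = None) -> pd.DataFrame:
    """Weir–Cockerham F_ST at every marker between the dataset's two cohorts.

    ``exclude_samples`` accepts a precomputed relative-exclusion list
    (e.g. first-degree relatives found by an external kinship tool).
    Markers where either cohort has fewer than 2 genotyped samples, or
    where a+b+c = 0, get NaN.
    """
    if ds.cohorts is None:
        raise ValueError("dataset has no cohort labels")
    if exclude_samples:
        excl = set(exclude_samples)
        keep = [i for i, s in enumerate(ds.samples) if s not in excl]
        ds = ds.subset_samples(keep)
    labels = pd.unique(ds.cohorts)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 cohorts, found {list(labels)}")
    g1 = ds.calls[ds.cohorts == labels[0]]
    g2 = ds.calls[ds.cohorts == labels[1]]
    n1, p1, h1 = _cohort_stats(g1)
    n2, p2, h2 = _cohort_stats(g2)
    a, b, c = weir_cockerham_components(n1, p1, h1, n2, p2, h2)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / denom
    fst = np.where((n1 >= 2) & (n2 >= 2) & (denom != 0), fst, np.nan)
    m = ds.markers
    df = pd.DataFrame({
        "id": m.ids, "chrom": m.chrom, "pos": m.pos,
        f"n_{labels[0]}": n1.astype(int), f"freq_{labels[0]}": p1,
        f"n_{labels[1]}": n2.astype(int), f"freq_{labels[1]}": p2,
        "a": a, "b": b, "c": c, "fst": fst,
        "high_fst": fst > threshold,
    })
    df.attrs["cohorts"] = tuple(labels)
    df.attrs["threshold"] = threshold
    return df


def genome_wide_fst(records: pd.DataFrame) -> float:
    """Multi-locus Weir–Cockerham estimate: sum(a) / sum(a+b+c)."""
    ok = records[["a", "b", "c"]].notna().all(axis=1)
    a = records.loc[ok, "a"].sum()
    abc = records.loc[ok, ["a", "b", "c"]].to_numpy().sum()
    if abc == 0:
        raise ValueError("zero total variance; genome-wide F_ST undefined")
    return float(a / abc)


def flag_high_fst(records: pd.DataFrame, threshold: float = 0.75) -> pd.DataFrame:
    """Markers with F_ST strictly above ``threshold``."""
    return records[records["fst"] > threshold].copy()
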