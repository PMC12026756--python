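"""Window-based runs-of-homozygosity calling and genomic inbreeding (F_ROH).

The caller reproduces the classic sliding-window approach used for
unphased array and sequence genotypes:

1. every span of ``window_snps`` consecutive SNPs on a chromosome is
   *accepting* if it contains at most ``max_het_per_window`` heterozygous
   and ``max_missing_per_window`` missing calls;
2. a SNP is *in-run* if at least a fraction ``hit_threshold`` of the
   windows covering it are accepting;
3. maximal stretches of in-run SNPs become candidate segments, trimmed to
   the outermost homozygous non-missing call;
4. candidates are split wherever the gap between consecutive SNPs exceeds
   ``max_gap_kb``;
5. survivors must carry at least ``min_snps`` SNPs, span at least
   ``min_length_kb``, and be dense enough (kb per SNP <= ``max_kb_per_snp``).

F_ROH is the summed ROH length divided by the marker-covered autosomal
genome length — the standard genomic inbreeding coefficient.

Two presets bracket the data types compared in dog diversity work:
``array_preset`` (min length 1000 kb, one het tolerated per window, to
capture recent plus ancestral autozygosity while skipping LD-scale runs)
and ``wgs_preset`` (min length 70 kb with zero heterozygotes, for dense
sequence variants). The minimum SNP count can be derived from the data
with :func:`min_snp_threshold` to bound the expected number of
false-positive runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import GenotypeDataset, HET, HOM_ALT, HOM_REF, MISSING


@dataclass(frozen=True)
class ROHCallParams:
    window_snps: int = 50           # W
    max_het_per_window: int = 1     # H
    max_missing_per_window: int = 5  # M
    hit_threshold: float = 0.05     # T: fraction of accepting windows
    min_snps: int = 100             # L
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    max_kb_per_snp: float = 50.0    # density: segment kb / SNP count

    def __post_init__(self):
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if not (0 < self.hit_threshold <= 1):
            raise ValueError("hit_threshold must be in (0, 1]")
        if min(self.min_snps, self.min_length_kb, self.max_gap_kb,
               self.max_kb_per_snp) <= 0:
            raise ValueError("minima must be positive")


def array_preset(**overrides) -> ROHCallParams:
    """Parameters for sparse common-allele array panels (min 1000 kb)."""
    return replace(ROHCallParams(min_length_kb=1000.0), **overrides)


def wgs_preset(**overrides) -> ROHCallParams:
    """Parameters for dense sequence panels: 70 kb minimum, zero hets."""
    return replace(ROHCallParams(min_length_kb=70.0, max_het_per_window=0,
                                 max_kb_per_snp=50.0), **overrides)


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int  # bp, 1-based inclusive
    end: int    # bp, inclusive
    n_snps: int
    snp1: str = ""
    snp2: str = ""

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass
class FrohResult:
    sample: str
    f_roh: float
    total_length_kb: float
    n_segments: int
    mean_length_kb: float


def _call_chromosome(calls: np.ndarray, pos: np.ndarray, p: ROHCallParams):
    """Yield (start_idx, end_idx) marker-index spans passing all filters."""
    m = len(pos)
    W = p.window_snps
    if m < W:
        return
    het = calls == HET
    mis = calls == MISSING
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(mis)])
    # window w covers SNPs w .. w+W-1
    n_win = m - W + 1
    w_het = ch[W:] - ch[:-W]
    w_mis = cm[W:] - cm[:-W]
    accepting = (w_het <= p.max_het_per_window) & (w_mis <= p.max_missing_per_window)
    ca = np.concatenate([[0], np.cumsum(accepting)])
    j = np.arange(m)
    lo = np.maximum(0, j - W + 1)
    hi = np.minimum(j, n_win - 1)
    covering = hi - lo + 1
    acc_cov = ca[hi + 1] - ca[lo]
    in_run = acc_cov / covering >= p.hit_threshold

    # maximal in-run stretches
    edges = np.flatnonzero(np.diff(np.concatenate([[0], in_run.astype(np.int8), [0]])))
    hom = (calls == HOM_REF) | (calls == HOM_ALT)
    gaps_kb = np.diff(pos) / 1000.0
    for s, e in zip(edges[::2], edges[1::2] - 1):
        # trim to outermost homozygous non-missing call
        hom_idx = np.flatnonzero(hom[s:e + 1])
        if hom_idx.size == 0:
            continue
        s2, e2 = s + hom_idx[0], s + hom_idx[-1]
        # split at large inter-SNP gaps
        cut = np.flatnonzero(gaps_kb[s2:e2] > p.max_gap_kb) + s2
        bounds = [s2] + [c + 1 for c in cut] + [e2 + 1]
        for a, b in zip(bounds[:-1], bounds[1:]):
            b -= 1
            if b < a:
                continue
            # re-trim piece ends to homozygous calls
            piece = np.flatnonzero(hom[a:b + 1])
            if piece.size == 0:
                continue
            a2, b2 = a + piece[0], a + piece[-1]
            n_snps = b2 - a2 + 1
            length_kb = (pos[b2] - pos[a2] + 1) / 1000.0
            if (n_snps >= p.min_snps and length_kb >= p.min_length_kb
                    and length_kb / n_snps <= p.max_kb_per_snp):
                yield a2, b2


def call_roh(ds: GenotypeDataset, params: ROHCallParams | None = None) -> list[ROHSegment]:
    """Call ROH segments for every sample in the dataset."""
    p = params or ROHCallParams()
    ds.markers.validate()
    segments: list[ROHSegment] = []
    for chrom in ds.markers.chromosomes():
        idx = ds.markers.chrom_slice(chrom)
        pos = ds.markers.pos[idx]
        if len(idx) < p.window_snps:
            warnings.warn(f"chromosome {chrom}: fewer SNPs ({len(idx)}) than "
                          f"window size {p.window_snps}; skipped")
            continue
        ids = ds.markers.ids[idx]
        sub = ds.calls[:, idx]
        for i, sid in enumerate(ds.samples):
            for a, b in _call_chromosome(sub[i], pos, p):
                segments.append(ROHSegment(
                    sample=sid, chrom=chrom, start=int(pos[a]), end=int(pos[b]),
                    n_snps=int(b - a + 1), snp1=str(ids[a]), snp2=str(ids[b])))
    return segments


def genome_length_bp(ds: GenotypeDataset) -> int:
    """Marker-covered autosomal span: sum over chromosomes of (max−min+1)."""
    if ds.n_markers == 0:
        raise ValueError("empty marker map")
    total = 0
    for chrom in ds.markers.chromosomes():
        p = ds.markers.pos[ds.markers.chrom_slice(chrom)]
        total += int(p.max() - p.min() + 1)
    return total


def froh(segments: list[ROHSegment], ds: GenotypeDataset) -> list[FrohResult]:
    """Per-sample F_ROH = summed ROH length / marker-covered genome length."""
    genome = genome_length_bp(ds)
    by_sample: dict[str, list[ROHSegment]] = {s: [] for s in ds.samples}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    out = []
    for sid in ds.samples:
        segs = by_sample[sid]
        total_bp = sum(s.length_bp for s in segs)
        total_kb = total_bp / 1000.0
        out.append(FrohResult(
            sample=sid, f_roh=total_bp / genome, total_length_kb=total_kb,
            n_segments=len(segs),
            mean_length_kb=total_kb / len(segs) if segs else 0.0))
    return out


def froh_frame(results: list[FrohResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).set_index("sample")


def observed_homozygosity(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-sample homozygous-call count and percent.

    The denominator counts non-missing calls at markers polymorphic in the
    cohort (monomorphic markers — a single allele among all non-missing
    calls, no heterozygotes — are excluded entirely).
    """
    calls = ds.calls
    any_het = (calls == HET).any(axis=0)
    any_ref = ((calls == HOM_REF) | (calls == HET)).any(axis=0)
    any_alt = ((calls == HOM_ALT) | (calls == HET)).any(axis=0)
    poly = any_het | (any_ref & any_alt)
    sub = calls[:, poly]
    hom = ((sub == HOM_REF) | (sub == HOM_ALT)).sum(axis=1)
    nonmiss = (sub != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(nonmiss > 0, 100.0 * hom / nonmiss, np.nan)
    return pd.DataFrame({"o_hom": hom, "n_nonmissing": nonmiss, "o_hom_pct": pct},
                        index=ds.samples)


DEFAULT_CLASS_BOUNDS_MB = (1.0, 2.0, 4.0, 8.0, 16.0)


def length_class_table(segments: list[ROHSegment], ds: GenotypeDataset,
                       class_bounds_mb=DEFAULT_CLASS_BOUNDS_MB) -> pd.DataFrame:
    """ROH length-class decomposition (counts, coverage, cumulative F_ROH).

    Classes are [b_i, b_{i+1}) Mb with a final open class >= b_last.
    ``genome_coverage_pct`` of a class is the cohort mean of (summed segment
    length in the class / genome length) × 100. ``class_froh`` uses the
    cumulative-from-below convention: mean F_ROH over segments with length
    >= the class lower bound, so the shortest class equals the overall
    F_ROH and consecutive classes differ exactly by the coverage fraction
    of the class between them.
    """
    bounds = list(class_bounds_mb)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("class bounds must be increasing")
    genome = genome_length_bp(ds)
    samples = list(ds.samples)
    n = len(samples)
    sidx = {s: i for i, s in enumerate(samples)}
    lengths_mb = np.array([s.length_bp / 1e6 for s in segments])
    seg_sample = np.array([sidx[s.sample] for s in segments], dtype=int) \
        if segments else np.zeros(0, dtype=int)

    rows = []
    uppers = bounds[1:] + [math.inf]
    for lo, hi in zip(bounds, uppers):
        in_class = (lengths_mb >= lo) & (lengths_mb < hi) if len(lengths_mb) else \
            np.zeros(0, dtype=bool)
        ge_lo = lengths_mb >= lo if len(lengths_mb) else np.zeros(0, dtype=bool)
        count_per = np.bincount(seg_sample[in_class], minlength=n)
        len_in_class = np.bincount(seg_sample[in_class],
                                   weights=lengths_mb[in_class] * 1e6, minlength=n)
        len_ge = np.bincount(seg_sample[ge_lo],
                             weights=lengths_mb[ge_lo] * 1e6, minlength=n)
        label = f"{lo:g}-{hi:g} Mb" if hi != math.inf else f">{lo:g} Mb"
        rows.append({
            "length_class": label,
            "mean_n_roh": count_per.mean() if n else 0.0,
            "genome_coverage_pct": 100.0 * (len_in_class / genome).mean() if n else 0.0,
            "class_froh_mean": (len_ge / genome).mean() if n else 0.0,
            "class_froh_sd": (len_ge / genome).std(ddof=1) if n > 1 else np.nan,
            "mean_length_in_class_mb": lengths_mb[in_class].mean()
            if in_class.any() else np.nan,
        })
    return pd.DataFrame(rows).set_index("length_class")


def class_froh_from_coverages(coverages_pct) -> np.ndarray:
    """Cumulative class-F_ROH implied by per-class genome coverages (%).

    class_froh[i] = sum of coverage fractions of classes with lower bound
    >= that of class i — the algebraic identity linking the coverage and
    cumulative-F_ROH columns of a length-class table.
    """
    cov = np.asarray(coverages_pct, dtype=float) / 100.0
    return cov[::-1].cumsum()[::-1]


def min_snp_threshold(ds: GenotypeDataset | None, alpha: float,
                      n_markers: int | None = None, n_samples: int | None = None,
                      mean_het: float | None = None) -> int:
    """Minimum SNPs per ROH bounding expected false positives below alpha.

    L = ceil( ln(alpha / (n_markers * n_samples)) / ln(1 - het) ), where
    het is the mean observed heterozygosity across individuals and SNPs:
    the probability that L consecutive independent calls are all homozygous
    by chance, multiplied by the number of tests, stays below alpha.
    Pass a dataset, or the three quantities explicitly.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if ds is not None:
        n_markers = ds.n_markers
        n_samples = ds.n_samples
        nonmiss = (ds.calls != MISSING).sum()
        mean_het = (ds.calls == HET).sum() / nonmiss if nonmiss else 0.0
    if mean_het is None or n_markers is None or n_samples is None:
        raise ValueError("need a dataset or explicit n_markers/n_samples/mean_het")
    if mean_het <= 0:
        raise ValueError("mean heterozygosity is zero; threshold undefined")
    return math.ceil(math.log(alpha / (n_markers * n_samples)) / math.log(1.0 - mean_het))
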