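"""Cross-cohort ROH sharing in fixed genomic windows.

Each chromosome is tiled with fixed-width windows (default 100 kb)
anchored at the first marker position; for every window and cohort we
count the samples carrying at least one ROH whose closed interval
intersects the window — each sample counts once per window no matter how
many of its segments touch it. Runs of adjacent windows where the shared
fraction exceeds a threshold merge into candidate selection/identity
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MarkerMap
from .roh_detection import ROHSegment


@dataclass
class Window:
    chrom: str
    index: int  # 1-based within chromosome
    start: int  # bp, inclusive
    end: int    # bp, inclusive


def make_windows(markers: MarkerMap, width_bp: int = 100_000) -> list[Window]:
    """Tile each chromosome's marker span with fixed-width windows.

    Windows are anchored at the first marker position, consecutive and
    disjoint; the last window is truncated at the last marker position.
    """
    if width_bp <= 0:
        raise ValueError("width must be positive")
    windows = []
    for chrom in markers.chromosomes():
        pos = markers.pos[markers.chrom_slice(chrom)]
        if len(pos) == 0:
            continue
        first, last = int(pos.min()), int(pos.max())
        start, k = first, 1
        while start <= last:
            end = min(start + width_bp - 1, last)
            windows.append(Window(chrom, k, start, end))
            start += width_bp
            k += 1
    return windows


def count_sharing(windows: list[Window], segments: list[ROHSegment],
                  cohort_of: dict, cohort_sizes: dict) -> pd.DataFrame:
    """Fraction of each cohort with >= 1 ROH overlapping each window.

    ``cohort_of`` maps sample id -> cohort label; ``cohort_sizes`` gives
    the denominator per cohort (total samples, not just ROH carriers).
    """
    cohorts = list(cohort_sizes)
    # (window row index) lookup per chromosome
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    starts = {c: np.array([windows[i].start for i in idx])
              for c, idx in by_chrom.items()}

    seen: set = set()  # (cohort, sample, window row) dedup
    counts = np.zeros((len(windows), len(cohorts)), dtype=int)
    cidx = {c: k for k, c in enumerate(cohorts)}
    for seg in segments:
        rows = by_chrom.get(seg.chrom)
        if not rows:
            continue
        coh = cohort_of.get(seg.sample)
        if coh not in cidx:
            continue
        st = starts[seg.chrom]
        # windows with start <= seg.end and end >= seg.start
        lo = int(np.searchsorted(st, seg.start, side="right")) - 1
        lo = max(lo, 0)
        hi = int(np.searchsorted(st, seg.end, side="right"))
        for r in rows[lo:hi]:
            w = windows[r]
            if w.start <= seg.end and w.end >= seg.start:
                key = (coh, seg.sample, r)
                if key not in seen:
                    seen.add(key)
                    counts[r, cidx[coh]] += 1
    rows_out = []
    for i, w in enumerate(windows):
        row = {"chrom": w.chrom, "window": w.index, "start": w.start, "end": w.end}
        for c in cohorts:
            row[f"count_{c}"] = counts[i, cidx[c]]
            row[f"pct_{c}"] = 100.0 * counts[i, cidx[c]] / cohort_sizes[c]
        rows_out.append(row)
    return pd.DataFrame(rows_out)


def high_sharing_regions(share: pd.DataFrame, cohort: str,
                         threshold_pct: float = 90.0) -> pd.DataFrame:
    """Merge adjacent windows whose sharing exceeds ``threshold_pct``.

    Strict inequality; adjacency means consecutive window indices on the
    same chromosome. Returns one row per merged region with the peak
    percentage observed inside it.
    """
    if not (0 < threshold_pct <= 100):
        raise ValueError("threshold must be in (0, 100]")
    col = f"pct_{cohort}"
    qual = share[share[col] > threshold_pct].sort_values(["chrom", "window"])
    regions = []
    cur = None
    for row in qual.itertuples():
        if (cur is not None and row.chrom == cur["chrom"]
                and row.window == cur["last_window"] + 1):
            cur["end"] = row.end
            cur["last_window"] = row.window
            cur["n_windows"] += 1
            cur["peak_pct"] = max(cur["peak_pct"], getattr(row, col))
        else:
            if cur is not None:
                regions.append(cur)
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end,
                   "first_window": row.window, "last_window": row.window,
                   "n_windows": 1, "peak_pct": getattr(row, col)}
    if cur is not None:
        regions.append(cur)
    df = pd.DataFrame(regions, columns=["chrom", "start", "end", "first_window",
                                        "last_window", "n_windows", "peak_pct"])
    return df.drop(columns=["last_window"])


def regions_to_bed(regions: pd.DataFrame, path) -> None:
    """Write merged regions as BED (0-based half-open conversion)."""
    with open(path, "w") as fh:
        for r in regions.itertuples():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tshared_{r.chrom}_{r.first_window}\n")
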