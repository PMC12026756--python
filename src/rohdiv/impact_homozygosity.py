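"""Homozygosity of functionally annotated variants (SnpEff impact classes).

Variants carry SnpEff-style ``ANN`` annotations (comma-separated effect
entries, pipe-delimited fields, predicted impact in field 3). Impacts are
collapsed to three analysis categories: HIGH, MODERATE, and NEUTRAL
(= LOW plus MODIFIER merged, de-duplicated per variant). A variant with
annotations in several categories is tallied in each of them, so category
totals may exceed the distinct-variant count by design.

Per sample and category we count homozygous-reference, heterozygous,
homozygous-alternate and missing genotypes; the alternate allele is the
effect allele throughout, and percent homozygous-alternate uses the
non-missing denominator. The Pearson correlation between genomic
inbreeding (F_ROH) and the percent-homozygous figures indicates how much
of the observed inbreeding sits in functionally consequential variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeDataset, HET, HOM_ALT, HOM_REF, MISSING
from .roh_detection import DEFAULT_CLASS_BOUNDS_MB, FrohResult, ROHSegment

CATEGORIES = ("HIGH", "MODERATE", "NEUTRAL")
_IMPACT_TO_CATEGORY = {"HIGH": "HIGH", "MODERATE": "MODERATE",
                       "LOW": "NEUTRAL", "MODIFIER": "NEUTRAL"}


@dataclass
class ImpactTally:
    sample: str
    category: str
    hom_ref: int
    het: int
    hom_alt: int
    missing: int

    @property
    def total(self) -> int:
        return self.hom_ref + self.het + self.hom_alt + self.missing

    @property
    def pct_hom_alt(self) -> float:
        denom = self.hom_ref + self.het + self.hom_alt
        return 100.0 * self.hom_alt / denom if denom else float("nan")


def categorize_variants(ann_strings: list) -> tuple[list[frozenset], int]:
    """Category set per variant from ANN strings; returns (sets, n_malformed).

    Each ANN entry contributes the category of its impact field; LOW and
    MODIFIER both map to NEUTRAL (counted once). Variants with no usable
    annotation get an empty set and are counted as malformed/unannotated.
    """
    out = []
    n_bad = 0
    for ann in ann_strings:
        cats = set()
        ok = False
        if ann:
            for entry in str(ann).split(","):
                fields = entry.split("|")
                if len(fields) < 3:
                    continue
                impact = fields[2].strip().upper()
                if impact in _IMPACT_TO_CATEGORY:
                    cats.add(_IMPACT_TO_CATEGORY[impact])
                    ok = True
        if not ok:
            n_bad += 1
        out.append(frozenset(cats))
    if n_bad:
        warnings.warn(f"{n_bad} variants had no parseable impact annotation")
    return out, n_bad


def tally(ds: GenotypeDataset, categories: list[frozenset]) -> list[ImpactTally]:
    """Genotype-class counts per sample within each impact category."""
    if len(categories) != ds.n_markers:
        raise ValueError("one category set per variant required")
    tallies = []
    for cat in CATEGORIES:
        idx = np.array([cat in c for c in categories], dtype=bool)
        sub = ds.calls[:, idx]
        for i, sid in enumerate(ds.samples):
            row = sub[i]
            tallies.append(ImpactTally(
                sample=sid, category=cat,
                hom_ref=int((row == HOM_REF).sum()), het=int((row == HET).sum()),
                hom_alt=int((row == HOM_ALT).sum()),
                missing=int((row == MISSING).sum())))
    return tallies


def tally_frame(tallies: list[ImpactTally]) -> pd.DataFrame:
    df = pd.DataFrame([{**vars(t), "total": t.total, "pct_hom_alt": t.pct_hom_alt}
                       for t in tallies])
    return df.set_index(["sample", "category"])


def correlate_froh_impact(froh_results: list[FrohResult] | pd.Series,
                          tallies: list[ImpactTally] | pd.Series,
                          category: str = "NEUTRAL") -> tuple[float, float]:
    """Pearson r and r² between per-sample F_ROH and % homozygous-alternate.

    Accepts package result objects or two aligned pandas Series (sample id
    index), e.g. columns transcribed from a published per-individual table.
    """
    if isinstance(froh_results, pd.Series):
        f = froh_results
    else:
        f = pd.Series({r.sample: r.f_roh for r in froh_results})
    if isinstance(tallies, pd.Series):
        p = tallies
    else:
        p = pd.Series({t.sample: t.pct_hom_alt for t in tallies
                       if t.category == category})
    f, p = f.align(p, join="inner")
    if len(f) < 3:
        raise ValueError("need at least 3 paired samples")
    r = stats.pearsonr(f.to_numpy(dtype=float), p.to_numpy(dtype=float)).statistic
    return float(r), float(r * r)


def variants_in_roh(ds: GenotypeDataset, categories: list[frozenset],
                    segments: list[ROHSegment], category: str = "HIGH",
                    class_bounds_mb=DEFAULT_CLASS_BOUNDS_MB) -> pd.DataFrame:
    """Count category variants falling inside ROH, by segment length class.

    A variant is "in ROH" for a sample when its position lies within one of
    that sample's closed segments; the row reports both variant-sample
    pairs and distinct variants (in ROH for at least one sample).
    """
    bounds = list(class_bounds_mb) + [np.inf]
    labels = [f"{lo:g}-{hi:g} Mb" if np.isfinite(hi) else f">{lo:g} Mb"
              for lo, hi in zip(bounds[:-1], bounds[1:])]
    want = np.array([category in c for c in categories], dtype=bool)
    m = ds.markers
    by_sample_chrom: dict = {}
    for seg in segments:
        by_sample_chrom.setdefault((seg.sample, seg.chrom), []).append(seg)
    pair_counts = dict.fromkeys(labels, 0)
    distinct: dict[str, set] = {lab: set() for lab in labels}
    for j in np.flatnonzero(want):
        chrom, pos = m.chrom[j], int(m.pos[j])
        for sid in ds.samples:
            for seg in by_sample_chrom.get((sid, chrom), ()):
                if seg.start <= pos <= seg.end:
                    mb = seg.length_bp / 1e6
                    k = np.searchsorted(bounds, mb, side="right") - 1
                    k = min(max(k, 0), len(labels) - 1)
                    pair_counts[labels[k]] += 1
                    distinct[labels[k]].add(str(m.ids[j]))
                    break  # one containing segment per (variant, sample)
    return pd.DataFrame({
        "length_class": labels,
        "variant_sample_pairs": [pair_counts[lab] for lab in labels],
        "distinct_variants": [len(distinct[lab]) for lab in labels],
    }).set_index("length_class")
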