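"""End-to-end orchestration: simulate → QC → every homozygosity measure.

``run_pipeline`` drives a complete synthetic-cohort analysis and writes
one CSV per stage, all deterministic given the config seed. It exists so
a single call exercises the whole measurement chain the way the analysis
scripts do, and so reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io_formats, ld_ne, roh_detection, roh_sharing
from .pedigree_inbreeding import cohort_fped_table
from .synthetic_data import SimConfig, gene_drop, simulate_pedigree, truth_frame


@dataclass
class RunConfig:
    sim: SimConfig
    out_dir: str
    fped_depths: tuple = (5, 10, math.inf)
    roh_alpha: float = 0.05
    ld_max_distance_kb: float = 1000.0
    ld_n_bins: int = 20
    share_window_bp: int = 100_000
    qc: io_formats.QCThresholds = field(
        default_factory=lambda: io_formats.QCThresholds(biallelic_snv_only=False))


def _roh_for(ds, preset, alpha):
    try:
        L = roh_detection.min_snp_threshold(ds, alpha)
    except ValueError:
        L = preset().min_snps
    params = preset(min_snps=max(L, 2))
    segs = roh_detection.call_roh(ds, params)
    return segs, roh_detection.froh(segs, ds), params


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic pipeline; returns a summary dict (also saved)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = simulate_pedigree(cfg.sim)
    dense, array, truth = gene_drop(sim, cfg.sim)
    sim.pedigree.to_csv(out / "pedigree.csv")
    truth_frame(truth).to_csv(out / "truth.csv")

    ids = [t.id for t in truth]
    per_dog, summary = cohort_fped_table(sim.pedigree, ids, cfg.fped_depths)
    per_dog.round(4).to_csv(out / "fped.csv")

    dense_qc, _ = io_formats.apply_qc(dense, cfg.qc)
    array_qc, _ = io_formats.apply_qc(array, cfg.qc)

    results = {"seed": cfg.sim.seed, "n_dogs": len(ids)}
    froh_cols = {}
    for name, ds, preset in (("wgs", dense_qc, roh_detection.wgs_preset),
                             ("array", array_qc, roh_detection.array_preset)):
        segs, fr, params = _roh_for(ds, preset, cfg.roh_alpha)
        io_formats.write_hom(segs, out / f"roh_{name}.hom")
        fdf = roh_detection.froh_frame(fr)
        fdf.round(5).to_csv(out / f"froh_{name}.csv")
        froh_cols[name] = fdf["f_roh"]
        results[f"froh_{name}_mean"] = round(float(fdf["f_roh"].mean()), 4)
        results[f"roh_{name}_min_snps"] = params.min_snps
        lct = roh_detection.length_class_table(segs, ds)
        lct.round(4).to_csv(out / f"roh_classes_{name}.csv")
        if name == "array":
            windows = roh_sharing.make_windows(ds.markers, cfg.share_window_bp)
            share = roh_sharing.count_sharing(
                windows, segs, {s: "COHORT" for s in ds.samples},
                {"COHORT": ds.n_samples})
            share.to_csv(out / "roh_sharing.csv", index=False)

    pairs = ld_ne.pairwise_r2(array_qc.subset_markers(
        array_qc.markers.chrom_slice(array_qc.markers.chromosomes()[0])),
        cfg.ld_max_distance_kb)
    if len(pairs) >= cfg.ld_n_bins:
        bins = ld_ne.bin_ld(pairs, cfg.ld_n_bins)
        ne = ld_ne.sved_ne(bins)
        ne.round(6).to_csv(out / "ld_ne.csv")
        results["ne_most_recent"] = round(float(ne["ne"].iloc[-1]), 2)

    comp = pd.DataFrame({
        "f_ped": per_dog.iloc[:, -1],
        "true_autozygosity": truth_frame(truth)["true_autozygosity"],
        "froh_wgs": froh_cols["wgs"],
        "froh_array": froh_cols["array"],
    })
    comp.round(5).to_csv(out / "inbreeding_comparison.csv")
    results["fped_mean"] = round(float(comp["f_ped"].mean()), 4)
    results["true_autozygosity_mean"] = round(float(comp["true_autozygosity"].mean()), 4)
    with open(out / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results
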