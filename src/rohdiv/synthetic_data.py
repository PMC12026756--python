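"""Synthetic pedigrees and gene-dropped genotypes with known autozygosity.

Real dog-breed datasets (array genotypes, WGS variants, registry
pedigrees) are rarely redistributable, so every estimator in this package
is validated against simulations in which the truth is known exactly:

* a multi-generation pedigree is built under a chosen mating scheme —
  random, full-sib loops, or a popular-sire regime where a small fraction
  of males performs all matings;
* founders carry two uniquely labelled haplotypes; meioses drop them
  through the pedigree with Poisson crossovers (Haldane model, no
  interference) at a fixed cM/Mb rate;
* an individual's *true autozygosity* is the fraction of the genome where
  its two homologs carry the same founder-haplotype label — the quantity
  F_PED estimates in expectation and F_ROH estimates from markers;
* two marker panels are laid over the same haplotypes: a *sequence-like*
  dense panel with a rare-variant-heavy founder frequency distribution
  (Beta(0.2, 2) alternate-allele frequencies), and an *array-like* sparse
  panel ascertained to common alleles (realized MAF above a floor, thinned
  to a target spacing) — mimicking why array data overestimates
  inbreeding relative to sequence data;
* genotyping error (default 0.002) flips a call to a random different
  state and missingness (default 0.02) masks calls.

A small forward Wright–Fisher haplotype simulator provides
drift-recombination-equilibrium data for validating the LD-based N_e
estimator against a known constant population size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeDataset, MarkerMap, MISSING
from .pedigree_inbreeding import Pedigree, f_ped


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimConfig:
    """Study-scale defaults: a closed breed bred for ~8 generations.

    ``seed`` is mandatory; every stochastic step flows from it.
    """

    seed: int
    n_founders: int = 40
    n_generations: int = 8
    n_per_generation: int = 50
    offspring_per_mating_mean: float = 2.5
    mating_scheme: str = "random"  # random | full_sib_loop | popular_sire
    popular_sire_fraction: float = 0.25
    n_chromosomes: int = 30
    chromosome_length_bp: int = 100_000_000
    recomb_rate_cm_per_mb: float = 1.0
    dense_marker_spacing_bp: int = 4_000
    dense_freq_beta: tuple = (0.2, 2.0)
    array_marker_spacing_bp: int = 15_000
    array_maf_floor: float = 0.10
    genotyping_error_rate: float = 0.002
    missingness_rate: float = 0.02

    def __post_init__(self):
        for r in (self.popular_sire_fraction, self.array_maf_floor,
                  self.genotyping_error_rate, self.missingness_rate):
            if not (0 <= r <= 1):
                raise ConfigError("rates must be in [0, 1]")
        if self.dense_marker_spacing_bp <= 0 or self.array_marker_spacing_bp <= 0:
            raise ConfigError("marker spacings must be positive")
        if self.n_founders < 2:
            raise ConfigError("need at least 2 founders")
        if self.mating_scheme not in ("random", "full_sib_loop", "popular_sire"):
            raise ConfigError(f"unknown mating scheme {self.mating_scheme!r}")

    @property
    def morgans_per_chromosome(self) -> float:
        return self.chromosome_length_bp * self.recomb_rate_cm_per_mb / 1e8


@dataclass
class TruthRecord:
    id: str
    true_f_ped: float
    true_autozygosity: float


@dataclass
class SimulatedPedigree:
    pedigree: Pedigree
    sex: dict          # id -> "M" | "F"
    generation: dict   # id -> int (founders = 0)

    def generation_ids(self, g: int) -> list[str]:
        return [i for i, gg in self.generation.items() if gg == g]

    @property
    def last_generation(self) -> int:
        return max(self.generation.values())


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig) -> SimulatedPedigree:
    rng = np.random.default_rng(cfg.seed)
    parents: dict = {}
    sex: dict = {}
    generation: dict = {}
    founders = [f"F{i:04d}" for i in range(cfg.n_founders)]
    for k, fid in enumerate(founders):
        parents[fid] = (None, None)
        sex[fid] = "M" if k % 2 == 0 else "F"  # alternate sexes
        generation[fid] = 0

    prev = founders
    counter = 0
    for g in range(1, cfg.n_generations + 1):
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if not males or not females:
            raise ConfigError(f"generation {g - 1} lacks one sex; no matings possible")
        if cfg.mating_scheme == "popular_sire":
            n_sires = max(1, math.ceil(cfg.popular_sire_fraction * len(males)))
            sire_pool = list(rng.choice(males, size=n_sires, replace=False))
        else:
            sire_pool = males

        offspring: list[str] = []
        if cfg.mating_scheme == "full_sib_loop":
            # mate brother-sister pairs family by family; founders pair up
            fams: dict = {}
            for i in prev:
                fams.setdefault(parents[i], []).append(i)
            pairs = []
            for sibs in fams.values():
                ms = [i for i in sibs if sex[i] == "M"]
                fs = [i for i in sibs if sex[i] == "F"]
                if ms and fs:
                    pairs.append((ms[0], fs[0]))
            if not pairs:
                raise ConfigError("no opposite-sex full-sib pair available")
            while len(offspring) < cfg.n_per_generation:
                s, d = pairs[rng.integers(len(pairs))]
                offspring.extend(_litter(parents, sex, generation, s, d, g,
                                         counter, cfg, rng))
                counter += 1
        else:
            while len(offspring) < cfg.n_per_generation:
                s = sire_pool[rng.integers(len(sire_pool))]
                d = females[rng.integers(len(females))]
                offspring.extend(_litter(parents, sex, generation, s, d, g,
                                         counter, cfg, rng))
                counter += 1
        prev = offspring

    ped = Pedigree(parents)
    return SimulatedPedigree(ped, sex, generation)


def _litter(parents, sex, generation, sire, dam, g, mating_no, cfg, rng):
    n = 1 + rng.poisson(max(cfg.offspring_per_mating_mean - 1.0, 0.0))
    ids = []
    for k in range(n):
        iid = f"G{g}_{mating_no:04d}_{k}"
        parents[iid] = (sire, dam)
        sex[iid] = "M" if (len(parents) % 2 == 0) else "F"
        generation[iid] = g
        ids.append(iid)
    return ids


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------
# a haplotype mosaic is (starts, labels): segment k covers
# [starts[k], starts[k+1]) in 0-based bp, carrying founder-haplotype label
# labels[k]; starts[0] == 0.

def _recombine(hapA, hapB, length_bp: int, morgans: float, rng) -> tuple:
    n_x = rng.poisson(morgans)
    if n_x == 0:
        return hapA if rng.integers(2) == 0 else hapB
    cuts = np.sort(rng.integers(1, length_bp, size=n_x)).astype(np.int64)
    src = int(rng.integers(2))
    haps = (hapA, hapB)
    starts_out, labels_out = [], []
    bounds = np.concatenate([[0], cuts, [length_bp]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a == b:
            src ^= 1
            continue
        s, l = haps[src]
        i0 = int(np.searchsorted(s, a, side="right")) - 1
        i1 = int(np.searchsorted(s, b, side="left"))
        seg_starts = np.maximum(s[i0:i1], a)
        for st, lb in zip(seg_starts, l[i0:i1]):
            if labels_out and labels_out[-1] == lb:
                continue
            starts_out.append(int(st))
            labels_out.append(int(lb))
        src ^= 1
    return np.array(starts_out, dtype=np.int64), np.array(labels_out, dtype=np.int64)


def _ibd_fraction(hap1, hap2, length_bp: int) -> float:
    """Fraction of [0, length) where the two mosaics share a label."""
    s1, l1 = hap1
    s2, l2 = hap2
    bounds = np.unique(np.concatenate([s1, s2, [0, length_bp]]))
    bounds = bounds[(bounds >= 0) & (bounds <= length_bp)]
    shared = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        lab1 = l1[np.searchsorted(s1, a, side="right") - 1]
        lab2 = l2[np.searchsorted(s2, a, side="right") - 1]
        if lab1 == lab2:
            shared += b - a
    return shared / length_bp


def _drop_haplotypes(sim: SimulatedPedigree, cfg: SimConfig, rng):
    """Gene-drop all chromosomes; returns {id: [(hap1, hap2) per chrom]}."""
    ped = sim.pedigree
    order = sorted(ped.ids(), key=lambda i: sim.generation[i])
    L = cfg.chromosome_length_bp
    M = cfg.morgans_per_chromosome
    haps: dict = {}
    label = 0
    for iid in order:
        s, d = ped.get_parents(iid)
        if s is None:
            h = []
            for _ in range(cfg.n_chromosomes):
                h.append(((np.array([0], dtype=np.int64), np.array([label], np.int64)),
                          (np.array([0], dtype=np.int64), np.array([label + 1], np.int64))))
            label += 2
            haps[iid] = h
        else:
            h = []
            for c in range(cfg.n_chromosomes):
                g1 = _recombine(*haps[s][c], L, M, rng)
                g2 = _recombine(*haps[d][c], L, M, rng)
                h.append((g1, g2))
            haps[iid] = h
    return haps


def true_autozygosity(haps_for_id, cfg: SimConfig) -> float:
    L = cfg.chromosome_length_bp
    return float(np.mean([_ibd_fraction(h1, h2, L) for h1, h2 in haps_for_id]))


def _dense_panel_positions(cfg: SimConfig) -> np.ndarray:
    sp = cfg.dense_marker_spacing_bp
    return np.arange(sp, cfg.chromosome_length_bp + 1, sp, dtype=np.int64)


def _genotypes_for(haps, ids, founder_alleles, positions_by_chrom):
    """Alt-dosage call matrix for ``ids`` over the per-chromosome panels."""
    blocks = []
    for c, pos in enumerate(positions_by_chrom):
        alle = founder_alleles[c]  # (n_founder_haplotypes, n_markers)
        rows = np.empty((len(ids), len(pos)), dtype=np.uint8)
        for i, iid in enumerate(ids):
            (s1, l1), (s2, l2) = haps[iid][c]
            lab1 = l1[np.searchsorted(s1, pos - 1, side="right") - 1]
            lab2 = l2[np.searchsorted(s2, pos - 1, side="right") - 1]
            rows[i] = alle[lab1, np.arange(len(pos))] + alle[lab2, np.arange(len(pos))]
        blocks.append(rows)
    return np.hstack(blocks)


def _inject_noise(calls: np.ndarray, cfg: SimConfig, rng) -> np.ndarray:
    out = calls.copy()
    if cfg.genotyping_error_rate > 0:
        err = rng.random(out.shape) < cfg.genotyping_error_rate
        # flip to a uniformly random *different* non-missing state
        shift = rng.integers(1, 3, size=out.shape)
        out[err] = ((out[err] + shift[err]) % 3).astype(np.uint8)
    if cfg.missingness_rate > 0:
        out[rng.random(out.shape) < cfg.missingness_rate] = MISSING
    return out


def gene_drop(sim: SimulatedPedigree, cfg: SimConfig,
              sample_ids: list[str] | None = None, compute_f_ped: bool = True):
    """Drop founder haplotypes through the pedigree and genotype two panels.

    Returns (dense GenotypeDataset, array-like GenotypeDataset,
    TruthRecord list) for ``sample_ids`` (default: the last generation).
    The dense panel draws founder alternate-allele frequencies from
    Beta(*cfg.dense_freq_beta*); the array panel subsamples dense markers
    whose realized MAF (among founder haplotypes) clears
    ``cfg.array_maf_floor``, thinned to ``cfg.array_marker_spacing_bp``.
    """
    sim.pedigree.check_acyclic()
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    haps = _drop_haplotypes(sim, cfg, rng)
    if sample_ids is None:
        sample_ids = sim.generation_ids(sim.last_generation)
    sample_ids = [str(s) for s in sample_ids]

    n_hap = 2 * cfg.n_founders
    a, b = cfg.dense_freq_beta
    founder_alleles, dense_pos, array_masks = [], [], []
    for c in range(cfg.n_chromosomes):
        pos = _dense_panel_positions(cfg)
        freqs = rng.beta(a, b, size=len(pos))
        alle = (rng.random((n_hap, len(pos))) < freqs).astype(np.uint8)
        founder_alleles.append(alle)
        dense_pos.append(pos)
        maf = alle.mean(axis=0)
        maf = np.minimum(maf, 1 - maf)
        cand = maf >= cfg.array_maf_floor
        keep = np.zeros(len(pos), dtype=bool)
        last = -np.inf
        for j in np.flatnonzero(cand):
            if pos[j] - last >= cfg.array_marker_spacing_bp:
                keep[j] = True
                last = pos[j]
        array_masks.append(keep)

    dense_calls = _genotypes_for(haps, sample_ids, founder_alleles, dense_pos)
    chrom_labels = np.concatenate([
        np.full(len(p), str(c + 1), dtype=object) for c, p in enumerate(dense_pos)])
    all_pos = np.concatenate(dense_pos)
    ids = np.array([f"{c}_{p}" for c, p in zip(chrom_labels, all_pos)], dtype=object)
    ref = np.full(len(all_pos), "A", dtype=object)
    alt = np.full(len(all_pos), "G", dtype=object)
    dense_map = MarkerMap(chrom_labels, all_pos, ids, ref, alt)
    mask = np.concatenate(array_masks)

    noisy_dense = _inject_noise(dense_calls, cfg, rng)
    dense_ds = GenotypeDataset(dense_map, sample_ids, noisy_dense)
    array_ds = GenotypeDataset(dense_map.subset(np.flatnonzero(mask)), sample_ids,
                               _inject_noise(dense_calls[:, mask], cfg, rng))

    truth = []
    for iid in sample_ids:
        fp = f_ped(sim.pedigree, iid).f_ped if compute_f_ped else float("nan")
        truth.append(TruthRecord(iid, fp, true_autozygosity(haps[iid], cfg)))
    return dense_ds, array_ds, truth


def truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truth]).set_index("id")


def fullsib_offspring_autozygosity(cfg: SimConfig, n_replicates: int = 200) -> np.ndarray:
    """True autozygosity of a full-sib-mating offspring, replicated.

    Pedigree: two unrelated founders → two full sibs → one offspring,
    whose expected autozygosity is F = 0.25.  Only IBD mosaics are
    simulated (no genotypes), so replication is cheap.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.chromosome_length_bp
    M = cfg.morgans_per_chromosome
    out = np.empty(n_replicates)
    for rep in range(n_replicates):
        vals = []
        for _ in range(cfg.n_chromosomes):
            f0 = ((np.array([0]), np.array([0])), (np.array([0]), np.array([1])))
            f1 = ((np.array([0]), np.array([2])), (np.array([0]), np.array([3])))
            sib1 = (_recombine(*f0, L, M, rng), _recombine(*f1, L, M, rng))
            sib2 = (_recombine(*f0, L, M, rng), _recombine(*f1, L, M, rng))
            child = (_recombine(*sib1, L, M, rng), _recombine(*sib2, L, M, rng))
            vals.append(_ibd_fraction(child[0], child[1], L))
        out[rep] = np.mean(vals)
    return out


def selfing_offspring_autozygosity(cfg: SimConfig, n_replicates: int = 200) -> np.ndarray:
    """True autozygosity of a self-mating offspring (expected 0.5).

    Selfing is disallowed in the pedigree schemes; this test-mode helper
    mates an individual's two gametes directly.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.chromosome_length_bp
    M = cfg.morgans_per_chromosome
    out = np.empty(n_replicates)
    for rep in range(n_replicates):
        vals = []
        for _ in range(cfg.n_chromosomes):
            ind = ((np.array([0]), np.array([0])), (np.array([0]), np.array([1])))
            child = (_recombine(*ind, L, M, rng), _recombine(*ind, L, M, rng))
            vals.append(_ibd_fraction(child[0], child[1], L))
        out[rep] = np.mean(vals)
    return out


# ---------------------------------------------------------------------------
# two-cohort differentiation fixture (Balding–Nichols)
# ---------------------------------------------------------------------------

def simulate_two_cohorts(n_markers: int, n_per_cohort: int, f_target: float,
                         seed: int, labels=("A", "B"),
                         marker_spacing_bp: int = 10_000) -> GenotypeDataset:
    """Two Hardy–Weinberg cohorts with Balding–Nichols divergence.

    Ancestral frequencies p ~ Uniform(0.05, 0.95); each cohort's frequency
    is Beta(p(1−F)/F, (1−p)(1−F)/F) so that F_ST between the cohorts is
    ``f_target`` in expectation.
    """
    if not (0 < f_target < 1):
        raise ConfigError("f_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_markers)
    fr = (1.0 - f_target) / f_target
    p1 = rng.beta(p * fr, (1 - p) * fr)
    p2 = rng.beta(p * fr, (1 - p) * fr)
    g1 = rng.binomial(2, p1, size=(n_per_cohort, n_markers)).astype(np.uint8)
    g2 = rng.binomial(2, p2, size=(n_per_cohort, n_markers)).astype(np.uint8)
    pos = np.arange(1, n_markers + 1, dtype=np.int64) * marker_spacing_bp
    mm = MarkerMap(np.full(n_markers, "1", dtype=object), pos,
                   np.array([f"m{j}" for j in range(n_markers)], dtype=object),
                   np.full(n_markers, "A", dtype=object),
                   np.full(n_markers, "G", dtype=object))
    samples = [f"{labels[0]}{i}" for i in range(n_per_cohort)] + \
              [f"{labels[1]}{i}" for i in range(n_per_cohort)]
    cohorts = np.array([labels[0]] * n_per_cohort + [labels[1]] * n_per_cohort,
                       dtype=object)
    return GenotypeDataset(mm, samples, np.vstack([g1, g2]), cohorts)


# ---------------------------------------------------------------------------
# impact-annotation fixture
# ---------------------------------------------------------------------------

_EXAMPLE_EFFECT = {"HIGH": "frameshift_variant", "MODERATE": "missense_variant",
                   "LOW": "synonymous_variant", "MODIFIER": "5_prime_UTR_variant"}


def annotate_synthetic_impacts(ds: GenotypeDataset, proportions: dict, seed: int,
                               multi_category_fraction: float = 0.1) -> list[str]:
    """SnpEff-style ANN strings per variant with known impact proportions.

    ``proportions`` maps HIGH/MODERATE/LOW/MODIFIER to probabilities
    summing to 1. A ``multi_category_fraction`` of variants receives a
    second annotation from a different impact class to exercise
    multi-category counting.
    """
    if abs(sum(proportions.get(k, 0.0) for k in _EXAMPLE_EFFECT) - 1.0) > 1e-9:
        raise ConfigError("impact proportions must sum to 1")
    rng = np.random.default_rng(seed)
    impacts = list(_EXAMPLE_EFFECT)
    probs = np.array([proportions.get(k, 0.0) for k in impacts])
    ann = []
    for j in range(ds.n_markers):
        chosen = [impacts[rng.choice(len(impacts), p=probs)]]
        if rng.random() < multi_category_fraction:
            others = [k for k in impacts if k != chosen[0] and probs[impacts.index(k)] > 0]
            if others:
                chosen.append(others[rng.integers(len(others))])
        entries = []
        for imp in chosen:
            entries.append("|".join([
                str(ds.markers.alt[j]), _EXAMPLE_EFFECT[imp], imp,
                f"GENE{j % 97}", f"ENSG{j % 97:06d}", "transcript",
                f"ENST{j % 97:06d}", "protein_coding", "1/1", "c.1A>G"]))
        ann.append(",".join(entries))
    return ann


# ---------------------------------------------------------------------------
# forward Wright–Fisher haplotype simulator (LD / N_e validation)
# ---------------------------------------------------------------------------

def wright_fisher_genotypes(n_diploid: int, n_sample: int, n_markers: int,
                            chromosome_length_bp: int, generations: int,
                            seed: int, recomb_rate_cm_per_mb: float = 1.0
                            ) -> GenotypeDataset:
    """Constant-size forward Wright–Fisher simulation of one chromosome.

    2N haplotypes evolve for ``generations`` rounds of random union of
    recombined gametes (Poisson crossovers, Haldane). Initial alternate
    frequencies are Uniform(0.1, 0.9); markers monomorphic at the end are
    dropped.  Returns genotypes for ``n_sample`` sampled diploids.
    """
    rng = np.random.default_rng(seed)
    L = chromosome_length_bp
    morgans = L * recomb_rate_cm_per_mb / 1e8
    pos = np.sort(rng.choice(np.arange(1, L), size=n_markers, replace=False))
    p0 = rng.uniform(0.1, 0.9, size=n_markers)
    haps = (rng.random((2 * n_diploid, n_markers)) < p0).astype(np.uint8)
    for _ in range(generations):
        new = np.empty_like(haps)
        for g in range(n_diploid):
            for h in range(2):
                pa, pb = rng.integers(2 * n_diploid, size=2)
                n_x = rng.poisson(morgans)
                if n_x == 0:
                    gam = haps[pa if rng.integers(2) == 0 else pb]
                else:
                    cuts = np.sort(rng.integers(1, L, size=n_x))
                    seg = np.searchsorted(cuts, pos, side="right")
                    use_a = (seg + rng.integers(2)) % 2 == 0
                    gam = np.where(use_a, haps[pa], haps[pb])
                new[2 * g + h] = gam
        haps = new
    take = rng.choice(n_diploid, size=n_sample, replace=False)
    calls = (haps[2 * take] + haps[2 * take + 1]).astype(np.uint8)
    freq = haps.mean(axis=0)
    keep = (freq > 0) & (freq < 1)
    mm = MarkerMap(np.full(keep.sum(), "1", dtype=object), pos[keep],
                   np.array([f"wf{j}" for j in np.flatnonzero(keep)], dtype=object),
                   np.full(keep.sum(), "A", dtype=object),
                   np.full(keep.sum(), "G", dtype=object))
    return GenotypeDataset(mm, [f"S{i}" for i in range(n_sample)], calls[:, keep])
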