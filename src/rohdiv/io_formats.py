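"""Genotype containers, standard-format readers/writers, and QC filters.

The in-memory substrate for every analysis in this package is a
:class:`GenotypeDataset`: a samples × markers matrix of diploid calls coded

====  =====================
code  meaning
====  =====================
0     homozygous reference
1     heterozygous
2     homozygous alternate
3     missing
====  =====================

together with a physical :class:`MarkerMap`. Readers exist for PLINK text
(PED/MAP), PLINK binary v1.00 SNP-major (BED/BIM/FAM) and VCF 4.x; matching
writers make every reader round-trippable so synthetic fixtures can exercise
the full file path.

Orientation convention
----------------------
For BED/BIM/FAM the BIM A1 column is treated as the **alternate / effect
allele**: call code 2 means "homozygous for A1".  Note that PLINK itself
recodes A1 to the minor allele by default, so datasets written by other
tools may need ``--keep-allele-order`` upstream for the codes to agree.

Coordinates are 1-based and intervals closed throughout; chromosome labels
are strings without a ``chr`` prefix; the default autosome set is 1–38
(canine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, 3

CANINE_AUTOSOMES = tuple(str(c) for c in range(1, 39))

_VALID_ALLELES = set("ACGT012")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class EmptyCohortError(ValueError):
    """Raised when QC removes every sample."""


def _norm_chrom(label) -> str:
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


@dataclass(frozen=True)
class MarkerMap:
    """Physical map of biallelic markers.

    Positions are 1-based bp.  Within a chromosome positions must be
    strictly increasing (checked by :meth:`validate`); marker ids unique.
    """

    chrom: np.ndarray  # str labels, no "chr" prefix
    pos: np.ndarray    # int64, 1-based bp
    ids: np.ndarray    # str
    ref: np.ndarray    # str (A2 in PLINK terms)
    alt: np.ndarray    # str (A1 / effect allele)

    def __post_init__(self):
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=np.int64))
        for name in ("ids", "ref", "alt"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=object))

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def validate(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate marker ids")
        for c in self.chromosomes():
            p = self.pos[self.chrom_slice(c)]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise FormatError(f"positions not strictly increasing on chromosome {c}")

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.chrom[idx], self.pos[idx], self.ids[idx],
                         self.ref[idx], self.alt[idx])


@dataclass
class GenotypeDataset:
    """Samples × markers call matrix plus map and optional cohort labels."""

    markers: MarkerMap
    samples: list[str]
    calls: np.ndarray  # uint8 (n_samples, n_markers), codes 0/1/2/3
    cohorts: np.ndarray | None = None  # str per sample

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise FormatError(
                f"call matrix shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.markers)})")
        if self.calls.size and self.calls.max() > 3:
            raise FormatError("call codes must be in {0,1,2,3}")
        if self.cohorts is not None:
            self.cohorts = np.asarray(self.cohorts, dtype=object)
            if len(self.cohorts) != len(self.samples):
                raise FormatError("cohort labels must match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_samples(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return GenotypeDataset(
            self.markers, [self.samples[i] for i in idx], self.calls[idx],
            None if self.cohorts is None else self.cohorts[idx])

    def subset_markers(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return GenotypeDataset(self.markers.subset(idx), list(self.samples),
                               self.calls[:, idx], self.cohorts)

    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage (float) with NaN for missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d


@dataclass(frozen=True)
class QCThresholds:
    """Sample/marker call-rate filters and variant-class restriction.

    Defaults mirror array practice in dog studies: drop samples with
    call rate < 94% and markers with call rate < 95%, keep biallelic
    SNVs on autosomes 1–38.
    """

    min_sample_call_rate: float = 0.94
    min_marker_call_rate: float = 0.95
    biallelic_snv_only: bool = True
    autosomes: tuple = CANINE_AUTOSOMES

    def __post_init__(self):
        if not (0 <= self.min_sample_call_rate <= 1 and 0 <= self.min_marker_call_rate <= 1):
            raise ValueError("call rates must be in [0, 1]")


@dataclass
class QCReport:
    removed_samples: list[str] = field(default_factory=list)
    removed_markers: list[str] = field(default_factory=list)
    dropped_multiallelic: int = 0

    @property
    def empty(self) -> bool:
        return not (self.removed_samples or self.removed_markers or self.dropped_multiallelic)


# ---------------------------------------------------------------------------
# PLINK text (PED / MAP)
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Read PLINK text PED/MAP into a GenotypeDataset.

    Allele pairs are encoded against the MAP alternate allele (column 5 of
    our extended 6-column MAP; plain 4-column MAPs infer alleles from the
    data); "0 0" becomes missing.
    """
    map_rows = []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (4, 6):
            raise FormatError(f"MAP line has {len(parts)} columns, expected 4 or 6")
        map_rows.append(parts)
    n_markers = len(map_rows)
    chrom = [_norm_chrom(r[0]) for r in map_rows]
    ids = [r[1] for r in map_rows]
    pos = [int(r[3]) for r in map_rows]
    has_alleles = map_rows and len(map_rows[0]) == 6
    ref = [r[4] for r in map_rows] if has_alleles else [""] * n_markers
    alt = [r[5] for r in map_rows] if has_alleles else [""] * n_markers

    samples, rows = [], []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_markers:
            raise FormatError(
                f"PED line has {len(parts)} columns, expected {6 + 2 * n_markers}")
        samples.append(parts[1])
        alleles = parts[6:]
        for a in alleles:
            if a not in _VALID_ALLELES:
                raise FormatError(f"invalid allele symbol {a!r}")
        rows.append(alleles)

    # infer ref/alt from data for 4-column maps: first seen = ref, other = alt
    if not has_alleles:
        for j in range(n_markers):
            seen = []
            for r in rows:
                for a in (r[2 * j], r[2 * j + 1]):
                    if a != "0" and a not in seen:
                        seen.append(a)
            seen += ["A", "G"]  # placeholders for (near-)monomorphic columns
            ref[j], alt[j] = sorted(seen[:2])[0], sorted(seen[:2])[1]

    calls = np.full((len(samples), n_markers), MISSING, dtype=np.uint8)
    for i, r in enumerate(rows):
        for j in range(n_markers):
            a1, a2 = r[2 * j], r[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            n_alt = (a1 == alt[j]) + (a2 == alt[j])
            n_ref = (a1 == ref[j]) + (a2 == ref[j])
            if n_alt + n_ref != 2:
                raise FormatError(
                    f"allele {a1}/{a2} at marker {ids[j]} not in {{{ref[j]},{alt[j]}}}")
            calls[i, j] = n_alt
    mm = MarkerMap(chrom, pos, ids, ref, alt)
    return GenotypeDataset(mm, samples, calls)


def write_ped_map(ds: GenotypeDataset, ped_path, map_path) -> None:
    """Write PLINK text files (6-column MAP carrying ref/alt)."""
    with open(map_path, "w") as fh:
        for j in range(ds.n_markers):
            m = ds.markers
            fh.write(f"{m.chrom[j]}\t{m.ids[j]}\t0\t{m.pos[j]}\t{m.ref[j]}\t{m.alt[j]}\n")
    code_to_pair = {
        HOM_REF: lambda j: (ds.markers.ref[j], ds.markers.ref[j]),
        HET: lambda j: (ds.markers.ref[j], ds.markers.alt[j]),
        HOM_ALT: lambda j: (ds.markers.alt[j], ds.markers.alt[j]),
        MISSING: lambda j: ("0", "0"),
    }
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.samples):
            fields = ["FAM", sid, "0", "0", "0", "-9"]
            for j in range(ds.n_markers):
                fields.extend(code_to_pair[ds.calls[i, j]](j))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (BED / BIM / FAM), v1.00 SNP-major
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit genotype codes in the BED layout, with A1 = alternate allele:
#   00 -> hom A1 (hom-alt)   10 -> het   11 -> hom A2 (hom-ref)   01 -> missing
_BED_TO_CALL = np.array([HOM_ALT, MISSING, HET, HOM_REF], dtype=np.uint8)
_CALL_TO_BED = np.array([0b11, 0b10, 0b00, 0b01], dtype=np.uint8)


def read_bed_bim_fam(prefix) -> GenotypeDataset:
    """Read a PLINK binary fileset ``prefix``.bed/.bim/.fam."""
    prefix = str(prefix)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype=str)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    samples = list(fam[1])
    n_samples, n_markers = len(samples), len(bim)
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError("bad BED magic bytes (expected v1.00 SNP-major)")
    bytes_per_marker = (n_samples + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != bytes_per_marker * n_markers:
        raise FormatError(
            f"BED payload {len(body)} bytes != {bytes_per_marker}*{n_markers}")
    if n_markers == 0:
        codes = np.zeros((n_samples, 0), dtype=np.uint8)
    else:
        body = body.reshape(n_markers, bytes_per_marker)
        # expand 2-bit fields: sample i lives in bits (2i % 8) of byte i//4
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        expanded = (body[:, :, None] >> shifts[None, None, :]) & 0b11
        expanded = expanded.reshape(n_markers, bytes_per_marker * 4)[:, :n_samples]
        codes = _BED_TO_CALL[expanded].T
    mm = MarkerMap([_norm_chrom(c) for c in bim["chrom"]],
                   bim["pos"].astype(np.int64).to_numpy(),
                   bim["id"].to_numpy(dtype=object),
                   bim["a2"].to_numpy(dtype=object),
                   bim["a1"].to_numpy(dtype=object))
    return GenotypeDataset(mm, samples, codes)


def write_bed_bim_fam(ds: GenotypeDataset, prefix) -> None:
    prefix = str(prefix)
    m = ds.markers
    with open(prefix + ".bim", "w") as fh:
        for j in range(ds.n_markers):
            fh.write(f"{m.chrom[j]}\t{m.ids[j]}\t0\t{m.pos[j]}\t{m.alt[j]}\t{m.ref[j]}\n")
    with open(prefix + ".fam", "w") as fh:
        for sid in ds.samples:
            fh.write(f"FAM {sid} 0 0 0 -9\n")
    n_samples = ds.n_samples
    bytes_per_marker = (n_samples + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        bed_codes = _CALL_TO_BED[ds.calls]  # (n_samples, n_markers)
        padded = np.ones((bytes_per_marker * 4, ds.n_markers), dtype=np.uint8) * 0b00
        padded[:n_samples] = bed_codes
        padded = padded.reshape(bytes_per_marker, 4, ds.n_markers)
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)[None, :, None]
        packed = np.bitwise_or.reduce(padded << shifts, axis=1).astype(np.uint8)
        fh.write(packed.T.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, region: str | None = None, *, biallelic_snv_only: bool = True,
             autosomes: tuple | None = None):
    """Read a VCF into (GenotypeDataset, ANN strings per variant, drop count).

    ANN INFO strings are preserved verbatim (``None`` where absent) so the
    impact analysis can re-parse them. When ``biallelic_snv_only`` is set,
    multiallelic records and non-SNVs are silently dropped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom_l, pos_l, ids_l, ref_l, alt_l, ann_l, rows = [], [], [], [], [], [], []
    dropped = 0
    it = vcf(region) if region else vcf
    for v in it:
        if biallelic_snv_only and (len(v.ALT) != 1 or not v.is_snp):
            dropped += 1
            continue
        c = _norm_chrom(v.CHROM)
        if autosomes is not None and c not in autosomes:
            dropped += 1
            continue
        if v.gt_types is None:
            raise FormatError("VCF record lacks GT field")
        chrom_l.append(c)
        pos_l.append(v.POS)
        ids_l.append(v.ID if v.ID else f"{c}_{v.POS}")
        ref_l.append(v.REF)
        alt_l.append(v.ALT[0] if v.ALT else ".")
        ann_l.append(v.INFO.get("ANN"))
        rows.append(np.asarray(v.gt_types, dtype=np.uint8))  # gts012: 0/1/2, 3=missing
    vcf.close()
    if rows:
        calls = np.vstack(rows).T
    else:
        calls = np.zeros((len(samples), 0), dtype=np.uint8)
    mm = MarkerMap(chrom_l, pos_l, ids_l, ref_l, alt_l)
    return GenotypeDataset(mm, samples, calls), ann_l, dropped


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(ds: GenotypeDataset, path, ann: list | None = None) -> None:
    """Write a minimal VCF 4.2 with optional ANN INFO strings."""
    m = ds.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in m.chromosomes():
            idx = m.chrom_slice(c)
            fh.write(f"##contig=<ID={c},length={int(m.pos[idx].max()) + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.samples) + "\n")
        for j in range(ds.n_markers):
            info = f"ANN={ann[j]}" if ann is not None and ann[j] else "."
            gts = "\t".join(_GT_STR[c] for c in ds.calls[:, j])
            fh.write(f"{m.chrom[j]}\t{m.pos[j]}\t{m.ids[j]}\t{m.ref[j]}\t{m.alt[j]}"
                     f"\t.\tPASS\t{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def apply_qc(ds: GenotypeDataset, q: QCThresholds,
             exclude_samples: list[str] | None = None):
    """Apply sample-then-marker call-rate filters.

    Order mirrors array-pipeline practice: explicit exclusions (duplicate
    hook) → sample call rate → marker call rate. Returns (dataset, QCReport).
    """
    report = QCReport()
    keep = np.ones(ds.n_samples, dtype=bool)
    if exclude_samples:
        excl = set(exclude_samples)
        keep = np.array([s not in excl for s in ds.samples])
        report.removed_samples.extend(s for s in ds.samples if s in excl)
    ds2 = ds.subset_samples(np.flatnonzero(keep))

    if q.biallelic_snv_only:
        m = ds2.markers
        ok = np.array([c in q.autosomes and r != a and len(str(r)) == 1 and len(str(a)) == 1
                       for c, r, a in zip(m.chrom, m.ref, m.alt)])
        report.removed_markers.extend(m.ids[~ok])
        ds2 = ds2.subset_markers(np.flatnonzero(ok))

    if ds2.n_markers:
        call_rate = 1.0 - (ds2.calls == MISSING).mean(axis=1)
        keep_s = call_rate >= q.min_sample_call_rate
        report.removed_samples.extend(np.array(ds2.samples, dtype=object)[~keep_s])
        ds2 = ds2.subset_samples(np.flatnonzero(keep_s))
    if ds2.n_samples == 0:
        raise EmptyCohortError("QC removed every sample")

    if ds2.n_samples:
        m_rate = 1.0 - (ds2.calls == MISSING).mean(axis=0)
        keep_m = m_rate >= q.min_marker_call_rate
        report.removed_markers.extend(ds2.markers.ids[~keep_m])
        ds2 = ds2.subset_markers(np.flatnonzero(keep_m))
    return ds2, report


# ---------------------------------------------------------------------------
# PLINK-style .hom segment tables
# ---------------------------------------------------------------------------

def write_hom(segments, path) -> None:
    """Write ROH segments as a PLINK-style .hom table."""
    rows = [{"FID": "FAM", "IID": s.sample, "CHR": s.chrom, "SNP1": s.snp1,
             "SNP2": s.snp2, "POS1": s.start, "POS2": s.end,
             "KB": s.length_kb, "NSNP": s.n_snps} for s in segments]
    pd.DataFrame(rows, columns=["FID", "IID", "CHR", "SNP1", "SNP2",
                                "POS1", "POS2", "KB", "NSNP"]).to_csv(
        path, sep="\t", index=False)


def read_hom(path):
    """Read a .hom table back into ROHSegment records."""
    from .roh_detection import ROHSegment

    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str, "IID": str})
    return [ROHSegment(sample=r.IID, chrom=str(r.CHR), start=int(r.POS1),
                       end=int(r.POS2), n_snps=int(r.NSNP),
                       snp1=str(r.SNP1), snp2=str(r.SNP2))
            for r in df.itertuples()]
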