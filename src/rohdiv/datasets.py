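"""Published per-individual summary tables for a Bearded Collie cohort.

A 2025 survey of homozygosity in the Bearded Collie breed compared
pedigree inbreeding (registry pedigree, n = 11,989, ~28 generations deep),
SNP-array F_ROH (n = 244) and WGS F_ROH (n = 23 of the array dogs), plus
variant-impact homozygosity from SnpEff annotations. The raw genotypes
are not deposited, but the per-individual columns printed in the study's
tables are, and several headline quantities are recomputable from them
alone. This module transcribes those columns; functions elsewhere in the
package consume them as ordinary inputs.

All values are exactly as printed (2 decimals for coefficients, 1 for
percentages). Dog order is identical across tables.
"""

from __future__ import annotations

import pandas as pd

DOG_IDS = [
    "BC1570", "BC1696", "BC1838", "BC1852", "BC1893", "BC1894", "BC1895",
    "BC1896", "BC1899", "BC1901", "BC1904", "BC1905", "BC1909", "BC1911",
    "BC1916", "BC1918", "BC1936", "BC1943", "BC1944", "BC1945", "BC1952",
    "BC0057", "BC0058",
]

# pedigree inbreeding of the 23-dog subset at three generation depths,
# with pedigree depth and unique-ancestor counts
PEDIGREE_TABLE = pd.DataFrame({
    "max_generations": [23, 26, 26, 27, 28, 28, 26, 23, 25, 30, 24, 27, 29,
                        27, 27, 27, 26, 23, 25, 28, 30, 27, 29],
    "unique_ancestors": [192, 247, 256, 344, 399, 289, 270, 192, 289, 504,
                         196, 368, 425, 331, 405, 270, 396, 266, 219, 317,
                         557, 253, 502],
    "f_ped_all": [0.31, 0.29, 0.31, 0.32, 0.27, 0.27, 0.26, 0.31, 0.25, 0.29,
                  0.33, 0.26, 0.32, 0.28, 0.25, 0.34, 0.27, 0.21, 0.29, 0.29,
                  0.27, 0.41, 0.28],
    "f_ped_10g": [0.31, 0.28, 0.30, 0.27, 0.23, 0.25, 0.24, 0.31, 0.24, 0.23,
                  0.33, 0.22, 0.23, 0.23, 0.23, 0.29, 0.26, 0.21, 0.28, 0.27,
                  0.15, 0.39, 0.17],
    "f_ped_5g": [0.13, 0.09, 0.11, 0.13, 0.06, 0.05, 0.05, 0.13, 0.04, 0.01,
                 0.07, 0.05, 0.04, 0.01, 0.01, 0.11, 0.07, 0.03, 0.11, 0.07,
                 0.01, 0.22, 0.05],
}, index=DOG_IDS)

# genomic inbreeding of the same dogs from the array and sequence panels
FROH_TABLE = pd.DataFrame({
    "froh_snp": [0.37, 0.39, 0.35, 0.37, 0.43, 0.32, 0.34, 0.38, 0.28, 0.31,
                 0.44, 0.31, 0.31, 0.32, 0.35, 0.45, 0.34, 0.24, 0.31, 0.36,
                 0.38, 0.46, 0.35],
    "froh_wgs": [0.27, 0.35, 0.34, 0.36, 0.40, 0.24, 0.33, 0.36, 0.18, 0.30,
                 0.39, 0.28, 0.29, 0.30, 0.33, 0.40, 0.33, 0.22, 0.29, 0.34,
                 0.37, 0.43, 0.35],
}, index=DOG_IDS)

# cohort mean ROH lengths (kb) from the array panel: full breed cohort
# (n=244), 23-dog subset, multi-breed pedigree cohort, mixed-breed cohort
MEAN_ROH_LENGTH_KB = {
    "bearded_collie": 6586.0,
    "bearded_collie_subset": 6854.0,
    "pedigree": 5060.0,
    "mixed_breed": 3654.0,
}

# ROH length-class decomposition of the 244-dog array cohort:
# per-class mean segment counts, genome coverage (%), cumulative F_ROH
LENGTH_CLASS_TABLE = pd.DataFrame({
    "mean_n_roh": [34.87, 23.40, 20.47, 16.08, 10.55],
    "genome_coverage_pct": [2.23, 3.02, 5.27, 8.22, 12.63],
    "class_froh_mean": [0.31, 0.29, 0.26, 0.21, 0.13],
}, index=["1-2 Mb", "2-4 Mb", "4-8 Mb", "8-16 Mb", ">16 Mb"])

# percent homozygous-alternate per SnpEff impact category, per dog
IMPACT_PCT_TABLE = pd.DataFrame({
    "pct_hom_alt_high": [12.9, 12.0, 12.6, 13.1, 12.8, 13.0, 12.8, 11.7,
                         11.0, 11.9, 14.2, 13.0, 12.5, 12.3, 11.7, 14.6,
                         13.7, 11.3, 11.5, 11.9, 13.9, 14.6, 13.5],
    "pct_hom_alt_moderate": [13.2, 13.0, 12.6, 13.1, 14.4, 13.2, 12.6, 12.7,
                             11.8, 12.0, 13.8, 13.0, 12.2, 12.7, 13.0, 14.6,
                             13.9, 11.3, 12.6, 13.0, 13.8, 14.8, 13.5],
    "pct_hom_alt_neutral": [22.9, 23.5, 23.0, 24.2, 25.2, 22.1, 22.6, 23.4,
                            20.6, 22.6, 25.1, 22.6, 22.4, 22.2, 23.3, 25.6,
                            23.6, 20.7, 22.1, 23.2, 24.0, 26.0, 23.5],
}, index=DOG_IDS)

# per-generation inbreeding rate (ΔF) endpoints of the LD-decay
# trajectory: 50 generations ago vs the most recent 5-generation interval
DELTA_F_50G = 0.0061
DELTA_F_5G = 0.0285

# study-scale inputs for the false-positive minimum-SNP formula
N_ARRAY_SNPS = 158_378
N_ARRAY_DOGS = 244
MEAN_OBSERVED_HET = 0.31
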