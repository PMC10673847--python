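"""Published multi-method benchmark: best PPV per method and trait.

This table transcribes a published locus-level (±500 kb) benchmark of 18
locus-nomination methods across five traits — three psychiatric (bipolar
disorder BPD, major depressive disorder MDD, schizophrenia SCZ) and two
blood-cell (mean platelet volume MPV, white blood cell count WBC). For each
method the best PPV across its database options is recorded, together with
the rank the benchmark printed (Olympic worst-tie ranking, methods without
any nominations ranked 18) and the printed median rank across the five
traits.

It serves as a fixed reference input for :func:`gwasbench.evaluate.
rank_methods` and :func:`gwasbench.evaluate.median_rank`: recomputing ranks
from the PPV columns should reproduce the printed ranks. One known
inconsistency exists in the source: the printed BPD ranks for Sherlock
(PPV 0.182, rank 11) and fgwas (PPV 0.143, rank 10) are swapped relative to
any ranking of the printed PPVs, which also shifts fgwas's printed median
rank (10) away from the recomputed one (11).
"""

from __future__ import annotations

from .evaluate import median_rank, rank_methods

TRAITS = ("BPD", "MDD", "SCZ", "MPV", "WBC")

N_METHODS = 18

#: Best PPV per method and trait; None marks a method that nominated nothing.
BEST_PPV: dict[str, dict[str, float | None]] = {
    "MTAG":          {"BPD": 0.571, "MDD": 1.000, "SCZ": 1.000, "MPV": None,  "WBC": 1.000},
    "TWAS/FUSION":   {"BPD": 0.500, "MDD": None,  "SCZ": 0.500, "MPV": 0.533, "WBC": 0.368},
    "UTMOST":        {"BPD": 0.333, "MDD": 0.000, "SCZ": 0.500, "MPV": 0.440, "WBC": 0.300},
    "JEPEG":         {"BPD": 0.333, "MDD": None,  "SCZ": 1.000, "MPV": 0.333, "WBC": 0.375},
    "COLOC":         {"BPD": 0.200, "MDD": 0.000, "SCZ": 0.600, "MPV": 0.607, "WBC": 0.566},
    "EUGENE":        {"BPD": 0.500, "MDD": None,  "SCZ": 0.400, "MPV": 0.329, "WBC": 0.282},
    "Sherlock":      {"BPD": 0.182, "MDD": 0.000, "SCZ": 0.286, "MPV": 0.690, "WBC": 0.538},
    "MOLOC":         {"BPD": 0.000, "MDD": 0.000, "SCZ": 0.667, "MPV": 0.455, "WBC": 0.500},
    "GPA":           {"BPD": 0.231, "MDD": 0.000, "SCZ": 0.275, "MPV": 0.451, "WBC": 0.335},
    "Suggestive":    {"BPD": 0.286, "MDD": 0.000, "SCZ": 0.455, "MPV": 0.338, "WBC": 0.349},
    "fgwas":         {"BPD": 0.143, "MDD": 0.077, "SCZ": 0.190, "MPV": 0.442, "WBC": 0.250},
    "GenoSkyline":   {"BPD": 0.083, "MDD": None,  "SCZ": 0.273, "MPV": 0.285, "WBC": 0.250},
    "GenoCanyon":    {"BPD": 0.079, "MDD": 0.000, "SCZ": 0.196, "MPV": 0.222, "WBC": 0.207},
    "LSMM":          {"BPD": 0.185, "MDD": None,  "SCZ": 0.181, "MPV": 0.216, "WBC": 0.225},
    "SMR":           {"BPD": None,  "MDD": None,  "SCZ": 0.000, "MPV": 0.429, "WBC": 0.400},
    "Weighted eQTL": {"BPD": None,  "MDD": None,  "SCZ": None,  "MPV": 0.667, "WBC": 0.667},
    "fastENLOC":     {"BPD": None,  "MDD": None,  "SCZ": None,  "MPV": None,  "WBC": None},
    "Sveinbjornsson": {"BPD": None, "MDD": None,  "SCZ": None,  "MPV": None,  "WBC": None},
}

#: Rank per method and trait as printed in the published benchmark.
PUBLISHED_RANKS: dict[str, dict[str, int]] = {
    "MTAG":          {"BPD": 1,  "MDD": 1,  "SCZ": 2,  "MPV": 18, "WBC": 1},
    "TWAS/FUSION":   {"BPD": 3,  "MDD": 18, "SCZ": 6,  "MPV": 4,  "WBC": 8},
    "UTMOST":        {"BPD": 5,  "MDD": 9,  "SCZ": 6,  "MPV": 8,  "WBC": 11},
    "JEPEG":         {"BPD": 5,  "MDD": 18, "SCZ": 2,  "MPV": 11, "WBC": 7},
    "COLOC":         {"BPD": 8,  "MDD": 9,  "SCZ": 4,  "MPV": 3,  "WBC": 3},
    "EUGENE":        {"BPD": 3,  "MDD": 18, "SCZ": 8,  "MPV": 12, "WBC": 12},
    "Sherlock":      {"BPD": 11, "MDD": 9,  "SCZ": 9,  "MPV": 1,  "WBC": 4},
    "MOLOC":         {"BPD": 14, "MDD": 9,  "SCZ": 3,  "MPV": 5,  "WBC": 5},
    "GPA":           {"BPD": 7,  "MDD": 9,  "SCZ": 10, "MPV": 6,  "WBC": 10},
    "Suggestive":    {"BPD": 6,  "MDD": 9,  "SCZ": 7,  "MPV": 10, "WBC": 9},
    "fgwas":         {"BPD": 10, "MDD": 2,  "SCZ": 13, "MPV": 7,  "WBC": 14},
    "GenoSkyline":   {"BPD": 12, "MDD": 18, "SCZ": 11, "MPV": 13, "WBC": 14},
    "GenoCanyon":    {"BPD": 13, "MDD": 9,  "SCZ": 12, "MPV": 14, "WBC": 16},
    "LSMM":          {"BPD": 9,  "MDD": 18, "SCZ": 14, "MPV": 15, "WBC": 15},
    "SMR":           {"BPD": 18, "MDD": 18, "SCZ": 15, "MPV": 9,  "WBC": 6},
    "Weighted eQTL": {"BPD": 18, "MDD": 18, "SCZ": 18, "MPV": 2,  "WBC": 2},
    "fastENLOC":     {"BPD": 18, "MDD": 18, "SCZ": 18, "MPV": 18, "WBC": 18},
    "Sveinbjornsson": {"BPD": 18, "MDD": 18, "SCZ": 18, "MPV": 18, "WBC": 18},
}

#: Published median rank across the five traits.
PUBLISHED_MEDIAN_RANK: dict[str, int] = {
    "MTAG": 1, "TWAS/FUSION": 6, "UTMOST": 8, "JEPEG": 7, "COLOC": 4,
    "EUGENE": 12, "Sherlock": 9, "MOLOC": 5, "GPA": 9, "Suggestive": 9,
    "fgwas": 10, "GenoSkyline": 13, "GenoCanyon": 13, "LSMM": 15,
    "SMR": 15, "Weighted eQTL": 18, "fastENLOC": 18, "Sveinbjornsson": 18,
}

METHODS = tuple(BEST_PPV)


def recompute_ranks(trait: str) -> dict[str, int]:
    """Olympic-rank the published best-PPV column for one trait."""
    column = {m: BEST_PPV[m][trait] for m in METHODS}
    return rank_methods(column, n_total=N_METHODS)


def recompute_median_ranks() -> dict[str, float | None]:
    """Median rank per method over the five recomputed per-trait ranks."""
    per_trait = {t: recompute_ranks(t) for t in TRAITS}
    return {m: median_rank([per_trait[t][m] for t in TRAITS]) for m in METHODS}
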