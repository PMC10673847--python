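"""Classification of nominations against a gold standard and method ranking.

The gold standard is the set of loci significant exclusively in a later,
larger GWAS wave. True/false positives are judged from the nominated side,
false negatives and sensitivity from the gold side; these counts can differ
when one nominated locus covers two gold loci, so both are carried:

- SN = gold loci covered / total gold loci
- PPV = nominated items confirmed / total nominated items
- F1 = harmonic mean of SN and PPV

True negatives are never defined: a variant non-significant in the earlier
wave may simply be underpowered, so metrics requiring a TN count are
deliberately avoided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .loci import Locus, gene_to_locus, merge_loci, overlap_length
from .nominate import bonferroni_significant
from .sumstats import NominationSet

log = logging.getLogger(__name__)


@dataclass
class ClassificationResult:
    """TP/FP/FN counts, item lists, and SN/PPV/F1 for one method-trait-
    strategy combination. ``tp_nominated`` counts confirmed nominated items;
    ``gold_covered`` counts gold items covered — the two coincide unless a
    nominated locus covers several gold loci."""

    level: str
    tp_nominated: int
    fp: int
    fn: int
    gold_covered: int
    sn: float | None
    ppv: float | None
    f1: float | None
    tp_items: list = field(default_factory=list)
    fp_items: list = field(default_factory=list)
    fn_items: list = field(default_factory=list)
    covered_gold_items: list = field(default_factory=list)


@dataclass(frozen=True)
class EvalConfig:
    """Overlap requirements and matching modes of the evaluation."""

    flank: int = 500_000
    min_overlap_locus: int = 250_000
    min_overlap_gene_boundaries: int = 2_500
    gene_locus_mode: str = "id_match"  # id_match | boundaries | midpoint_flank
    id_mode: str = "ensembl"  # ensembl | symbol
    n_methods_total: int = 18
    gene_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_overlap_locus < 1 or self.min_overlap_gene_boundaries < 1:
            raise ConfigurationError("minimum overlaps must be >= 1")
        if self.gene_locus_mode not in ("id_match", "boundaries", "midpoint_flank"):
            raise ConfigurationError(f"unknown gene_locus_mode {self.gene_locus_mode!r}")
        if self.id_mode not in ("ensembl", "symbol"):
            raise ConfigurationError(f"unknown id_mode {self.id_mode!r}")


def compute_f1(sn: float | None, ppv: float | None) -> float | None:
    """Harmonic mean of SN and PPV; 0 when both are 0, absent when either is."""
    if sn is None or ppv is None:
        return None
    if sn + ppv == 0:
        return 0.0
    return 2.0 * sn * ppv / (sn + ppv)


def _metrics(level, tp_nominated, fp, gold_covered, fn, tp_items, fp_items,
             fn_items, covered_items) -> ClassificationResult:
    sn = gold_covered / (gold_covered + fn) if gold_covered + fn > 0 else None
    ppv = tp_nominated / (tp_nominated + fp) if tp_nominated + fp > 0 else None
    return ClassificationResult(
        level=level, tp_nominated=tp_nominated, fp=fp, fn=fn,
        gold_covered=gold_covered, sn=sn, ppv=ppv, f1=compute_f1(sn, ppv),
        tp_items=tp_items, fp_items=fp_items, fn_items=fn_items,
        covered_gold_items=covered_items,
    )


def classify_variant_level(
    nominated: NominationSet, gold_sig: pd.DataFrame
) -> ClassificationResult:
    """Exact (chrom, pos) matching of nominated variants against gold-wave
    genome-wide significant variants. Both sides are expected to already
    exclude the earlier wave's significant regions."""
    if nominated.level != "variant":
        raise ConfigurationError(
            f"variant-level classification got a {nominated.level!r}-level nomination set"
        )
    nom = {(c, int(p)) for c, p in zip(nominated.items.get("chrom", []),
                                       nominated.items.get("pos", []))}
    gold = {(c, int(p)) for c, p in zip(gold_sig["chrom"], gold_sig["pos"])}
    tp = sorted(nom & gold)
    fp = sorted(nom - gold)
    fn = sorted(gold - nom)
    return _metrics("variant", len(tp), len(fp), len(tp), len(fn),
                    [f"{c}:{p}" for c, p in tp], [f"{c}:{p}" for c, p in fp],
                    [f"{c}:{p}" for c, p in fn], [f"{c}:{p}" for c, p in tp])


def classify_locus_level(
    nominated_loci: Sequence[Locus],
    gold_loci: Sequence[Locus],
    cfg: EvalConfig | None = None,
    min_overlap: int | None = None,
) -> ClassificationResult:
    """Locus-to-locus classification with a minimum-overlap requirement.

    A nominated locus is a TP when it overlaps at least one gold locus by
    ≥ ``min_overlap`` bases and a FP otherwise; a gold locus is covered when
    some nominated locus overlaps it by ≥ ``min_overlap`` and a FN otherwise.
    Each nominated locus counts once toward PPV and each gold locus once
    toward SN, whatever the multiplicity of the overlaps.
    """
    if min_overlap is None:
        min_overlap = (cfg or EvalConfig()).min_overlap_locus
    if min_overlap < 1:
        raise ConfigurationError("min_overlap must be >= 1")
    nom_hit = [False] * len(nominated_loci)
    gold_hit = [False] * len(gold_loci)
    for i, n in enumerate(nominated_loci):
        for j, g in enumerate(gold_loci):
            if overlap_length(n, g) >= min_overlap:
                nom_hit[i] = True
                gold_hit[j] = True
    tp_items = [n.key for n, h in zip(nominated_loci, nom_hit) if h]
    fp_items = [n.key for n, h in zip(nominated_loci, nom_hit) if not h]
    covered = [g.key for g, h in zip(gold_loci, gold_hit) if h]
    fn_items = [g.key for g, h in zip(gold_loci, gold_hit) if not h]
    return _metrics("locus", len(tp_items), len(fp_items), len(covered),
                    len(fn_items), tp_items, fp_items, fn_items, covered)


def significant_gold_genes(gold_genes: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Gold-side gene significance: Bonferroni on the count of genes with a
    valid p-value."""
    mask, threshold = bonferroni_significant(gold_genes["pvalue"], alpha)
    log.info("gold gene significance: %d of %d genes below %s",
             int(mask.sum()), len(gold_genes), threshold)
    return gold_genes[mask].reset_index(drop=True)


def _gene_keys(frame: pd.DataFrame, id_mode: str) -> set[str]:
    col = "gene_id" if id_mode == "ensembl" else "symbol"
    if col not in frame.columns:
        return set()
    vals = frame[col].dropna()
    return set(vals.astype(str))


def classify_gene_level(
    nominated: NominationSet,
    gold_genes: pd.DataFrame,
    cfg: EvalConfig | None = None,
    gold_loci: Sequence[Locus] | None = None,
) -> ClassificationResult:
    """Gene-level classification against Bonferroni-significant gold genes.

    ``id_match`` mode matches on Ensembl IDs or symbols. ``boundaries`` and
    ``midpoint_flank`` modes convert genes to loci (merging overlapping gene
    loci first, to avoid double counting) and delegate to
    :func:`classify_locus_level` with the mode's minimum overlap (2,500 b for
    annotated boundaries, 250,000 b for midpoint windows). The gold side of
    the locus modes defaults to loci built from the significant gold genes in
    the same mode; pass ``gold_loci`` to compare against variant-based gold
    loci instead.
    """
    cfg = cfg or EvalConfig()
    if nominated.level != "gene":
        raise ConfigurationError(
            f"gene-level classification got a {nominated.level!r}-level nomination set"
        )
    gold_sig = significant_gold_genes(gold_genes, cfg.gene_alpha)

    if cfg.gene_locus_mode == "id_match":
        if cfg.id_mode == "ensembl" and (
            "gene_id" not in nominated.items.columns
            or nominated.items.get("gene_id", pd.Series(dtype=object)).isna().all()
        ) and len(nominated.items):
            raise ConfigurationError(
                "nominations carry no Ensembl IDs; use id_mode='symbol'"
            )
        nom_keys = _gene_keys(nominated.items, cfg.id_mode)
        gold_keys = _gene_keys(gold_sig, cfg.id_mode)
        tp = sorted(nom_keys & gold_keys)
        fp = sorted(nom_keys - gold_keys)
        fn = sorted(gold_keys - nom_keys)
        return _metrics("gene", len(tp), len(fp), len(tp), len(fn), tp, fp, fn, tp)

    mode = cfg.gene_locus_mode
    min_overlap = (cfg.min_overlap_gene_boundaries if mode == "boundaries"
                   else cfg.min_overlap_locus)
    # Resolve nominated genes to coordinates: join on the gold gene table by
    # id/symbol unless the nomination file carried its own coordinates.
    items = nominated.items
    if {"chrom", "start", "end"} <= set(items.columns):
        nom_genes = items
    else:
        key = "gene_id" if cfg.id_mode == "ensembl" else "symbol"
        lookup = gold_genes.dropna(subset=[key]).drop_duplicates(subset=[key])
        nom_genes = items.dropna(subset=[key]).merge(
            lookup[[key, "chrom", "start", "end"]], on=key, how="inner"
        )
        n_unresolved = len(items) - len(nom_genes)
        if n_unresolved:
            log.info("classify_gene_level: %d nominated genes had no annotated "
                     "coordinates and were dropped", n_unresolved)
    nom_loci = merge_loci(
        gene_to_locus(row, mode=mode, flank=cfg.flank)
        for row in nom_genes.to_dict("records")
    )
    if gold_loci is None:
        gold_loci = merge_loci(
            gene_to_locus(row, mode=mode, flank=cfg.flank)
            for row in gold_sig.to_dict("records")
        )
    result = classify_locus_level(nom_loci, gold_loci, min_overlap=min_overlap)
    result.level = "gene"
    return result


def rank_methods(
    best_ppv_by_method: Mapping[str, float | None],
    n_total: int = 18,
) -> dict[str, int]:
    """Olympic (worst-tie) competition ranking of methods by best PPV.

    A method's rank is the number of methods whose PPV is ≥ its own, so tied
    methods all share the lowest (numerically largest) rank of their group.
    Methods that nominated nothing (absent PPV) rank ``n_total``, below any
    method with a PPV of 0.
    """
    methods = list(best_ppv_by_method)
    if len(set(methods)) != len(methods):
        raise ConfigurationError("duplicate method names in ranking input")
    ppvs = [best_ppv_by_method[m] for m in methods]
    present = [v for v in ppvs if v is not None and not (isinstance(v, float) and np.isnan(v))]
    ranks: dict[str, int] = {}
    for m, v in zip(methods, ppvs):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            ranks[m] = n_total
        else:
            ranks[m] = sum(1 for other in present if other >= v)
    return ranks


def median_rank(ranks: Sequence[int]) -> float | None:
    """Aggregate per-trait ranks: the middle order statistic, taking the
    lower middle for even counts."""
    if not ranks:
        return None
    ordered = sorted(ranks)
    return ordered[(len(ordered) - 1) // 2]


def overlap_sensitivity_sweep(
    nominated_loci: Sequence[Locus],
    gold_loci: Sequence[Locus],
    overlaps: Sequence[int] = (1, 250_000, 500_000, 750_000),
) -> pd.DataFrame:
    """Re-classify under each minimum-overlap requirement.

    TP counts are monotone non-increasing in the overlap requirement.
    """
    rows = []
    for ov in overlaps:
        if ov < 1:
            raise ConfigurationError("overlap values must be positive")
        res = classify_locus_level(nominated_loci, gold_loci, min_overlap=int(ov))
        rows.append({
            "min_overlap": int(ov), "tp": res.tp_nominated, "fp": res.fp,
            "fn": res.fn, "gold_covered": res.gold_covered,
            "sn": res.sn, "ppv": res.ppv, "f1": res.f1,
        })
    return pd.DataFrame(rows)
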