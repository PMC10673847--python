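"""End-to-end evaluation runs: configuration, pipeline, and report tables.

A run reads two waves of summary statistics, defines significant loci in
each, removes wave-1 regions from the wave-2 gold standard, applies each
configured nomination method to wave 1, filters nominations identically
against the wave-1 regions, classifies at locus level, and emits metrics,
scatter (SN vs PPV with quadrant assignment), ranking, and optionally an
ensemble membership matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .ensemble import build_ensemble_matrix, flag_gold, ppv_by_support
from .errors import ConfigurationError
from .evaluate import (ClassificationResult, EvalConfig, classify_locus_level,
                       rank_methods)
from .loci import (LocusConfig, define_loci, exclude_overlapping,
                   exclude_points_in_loci, loci_to_frame, windows_from_points,
                   write_loci)
from .nominate import (WeightedEqtlConfig, nominate_suggestive,
                       nominate_sveinbjornsson, weighted_eqtl_nominate)
from .sumstats import (ColumnMap, NominationSet, dedupe_by_position,
                       read_nominations, read_sumstats, truncate_pvalues)

log = logging.getLogger(__name__)

BUILTIN_METHODS = ("suggestive", "sveinbjornsson", "weighted_eqtl")


@dataclass
class MethodSpec:
    """One nomination method in a run: a built-in procedure applied to the
    wave-1 statistics, or an external nomination file."""

    name: str
    kind: str  # one of BUILTIN_METHODS or "file"
    path: str | None = None
    level: str = "variant"
    columns: dict = field(default_factory=dict)
    weighted_eqtl: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in BUILTIN_METHODS + ("file",):
            raise ConfigurationError(f"unknown method kind {self.kind!r}")
        if self.kind == "file" and not self.path:
            raise ConfigurationError(f"method {self.name!r}: file methods need a path")


@dataclass
class RunConfig:
    """Configuration of a full evaluation run."""

    trait: str
    wave1: str
    wave2: str
    out_dir: str
    columns: dict = field(default_factory=dict)
    annotations: str | None = None
    methods: list[MethodSpec] = field(default_factory=list)
    locus: LocusConfig = field(default_factory=LocusConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    build_ensemble: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        methods = [MethodSpec(**m) for m in raw.pop("methods", [])]
        locus = LocusConfig(**raw.pop("locus", {}))
        eval_cfg = EvalConfig(**raw.pop("eval", {}))
        return cls(methods=methods, locus=locus, eval=eval_cfg, **raw)


def quadrant_assign(sn: float | None, ppv: float | None) -> str | None:
    """Quadrant of the SN-vs-PPV plane with strict 0.5 boundaries.

    I: both high; II: high PPV, low SN; IV: high SN, low PPV; III: both low.
    Points on the 0.5 lines fall in quadrant III (boundaries are strict).
    """
    if sn is None or ppv is None:
        return None
    if sn > 0.5 and ppv > 0.5:
        return "I"
    if ppv > 0.5:
        return "II"
    if sn > 0.5:
        return "IV"
    return "III"


def _read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df


def _run_method(spec: MethodSpec, wave1: pd.DataFrame,
                annotations: pd.DataFrame | None, colmap: ColumnMap) -> NominationSet:
    if spec.kind == "suggestive":
        return nominate_suggestive(wave1, method=spec.name)
    if spec.kind == "sveinbjornsson":
        return nominate_sveinbjornsson(wave1, annotations, method=spec.name)
    if spec.kind == "weighted_eqtl":
        cfg = WeightedEqtlConfig(**spec.weighted_eqtl)
        return weighted_eqtl_nominate(wave1, annotations, cfg, method=spec.name)
    return read_nominations(spec.path, level=spec.level, colmap=spec.columns,
                            method=spec.name, sumstats=wave1)


def run_full_evaluation(cfg: RunConfig) -> dict:
    """Execute the pipeline and write the report bundle to ``cfg.out_dir``.

    Returns a dict with the gold loci, per-method classification results,
    the metrics frame, and (when enabled) the ensemble matrix. Reports are
    deterministic given the config: reruns produce byte-identical TSVs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    colmap = ColumnMap.from_dict(cfg.columns) if cfg.columns else ColumnMap()

    def stage(name: str):
        log.info("[%s] %s", cfg.trait, name)

    stage("reading wave 1 and wave 2 summary statistics")
    wave1 = dedupe_by_position(truncate_pvalues(read_sumstats(cfg.wave1, colmap)))
    wave2 = dedupe_by_position(truncate_pvalues(read_sumstats(cfg.wave2, colmap)))
    annotations = _read_annotations(cfg.annotations) if cfg.annotations else None

    stage("defining significant loci in each wave")
    gwas1_loci = define_loci(wave1, cfg.locus)
    gwas2_loci = define_loci(wave2, cfg.locus)
    write_loci(gwas1_loci, out / "gwas1_loci.tsv")
    write_loci(gwas2_loci, out / "gwas2_loci.tsv")

    stage("excluding wave-1 regions from the gold standard")
    gold = exclude_overlapping(gwas2_loci, gwas1_loci, min_overlap=1)
    log.info("[%s] gold standard: %d of %d wave-2 loci retained",
             cfg.trait, len(gold), len(gwas2_loci))
    write_loci(gold, out / "gold_loci.tsv")

    metrics_rows = []
    per_item_rows = []
    results: dict[str, ClassificationResult] = {}
    loci_by_method = {}
    for spec in cfg.methods:
        stage(f"nominating with {spec.name}")
        nom = _run_method(spec, wave1, annotations, colmap)
        if nom.level != "variant":
            raise ConfigurationError(
                f"method {spec.name!r}: run_full_evaluation currently classifies "
                "variant-level nominations at locus level; gene-level sets go "
                "through evaluate.classify_gene_level"
            )
        kept = exclude_points_in_loci(nom.items, gwas1_loci)
        log.info("[%s] %s: %d nominated, %d outside wave-1 regions",
                 cfg.trait, spec.name, len(nom.items), len(kept))
        nom_loci = windows_from_points(kept, flank=cfg.eval.flank, hla=cfg.locus)
        nom_loci = exclude_overlapping(nom_loci, gwas1_loci, min_overlap=1)
        loci_by_method[spec.name] = nom_loci
        res = classify_locus_level(nom_loci, gold, cfg.eval)
        results[spec.name] = res
        metrics_rows.append({
            "method": spec.name, "n_nominated_points": len(kept),
            "n_nominated_loci": len(nom_loci), "tp": res.tp_nominated,
            "fp": res.fp, "fn": res.fn, "gold_covered": res.gold_covered,
            "sn": res.sn, "ppv": res.ppv, "f1": res.f1,
            "quadrant": quadrant_assign(res.sn, res.ppv) if nom_loci else None,
        })
        for cls, keys in (("TP", res.tp_items), ("FP", res.fp_items),
                          ("FN", res.fn_items)):
            per_item_rows.extend(
                {"method": spec.name, "class": cls, "locus": k} for k in keys)

    metrics = pd.DataFrame(metrics_rows)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False, na_rep="NA")
    pd.DataFrame(per_item_rows).to_csv(out / "classification_items.tsv",
                                       sep="\t", index=False)

    if metrics_rows:
        stage("ranking methods by PPV")
        best_ppv = {
            r["method"]: (r["ppv"] if r["n_nominated_loci"] > 0 else None)
            for r in metrics_rows
        }
        ranks = rank_methods(best_ppv, n_total=cfg.eval.n_methods_total)
        ranking = pd.DataFrame({
            "method": list(ranks), "best_ppv": [best_ppv[m] for m in ranks],
            "rank": [ranks[m] for m in ranks],
        }).sort_values(["rank", "method"], kind="mergesort")
        ranking.to_csv(out / "ranking.tsv", sep="\t", index=False, na_rep="NA")

    matrix = None
    if cfg.build_ensemble and loci_by_method:
        stage("building ensemble membership matrix")
        matrix = build_ensemble_matrix(loci_by_method,
                                       min_overlap=cfg.eval.min_overlap_locus)
        flag_gold(matrix, gold, min_overlap=cfg.eval.min_overlap_locus)
        matrix.to_frame().to_csv(out / "ensemble_matrix.tsv", sep="\t", index=False)
        ppv_by_support(matrix).to_csv(out / "ppv_by_support.tsv", sep="\t",
                                      index=False, na_rep="NA")

    return {
        "gwas1_loci": gwas1_loci, "gwas2_loci": gwas2_loci, "gold": gold,
        "results": results, "metrics": metrics, "ensemble": matrix,
        "loci_by_method": loci_by_method,
    }
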