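"""Nomination procedures operating directly on summary statistics.

Three procedures are implemented: a suggestive p-value band, annotation-
category thresholds (loss-of-function / moderate / low / other, each with
its own family-wise-error-weighted cutoff), and weighted-Bonferroni eQTL
prioritization where each variant's p-value is divided by a mean-one
normalized weight before thresholding. Generic Bonferroni and
Benjamini–Hochberg significance helpers are provided for score tables
produced by external tools.

Nomination sets exclude nothing themselves: removal of regions already
significant in the earlier GWAS wave is the evaluation layer's job so that
every method is filtered identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .sumstats import NominationSet

log = logging.getLogger(__name__)

GENOME_WIDE_SIG = 5e-8
SUGGESTIVE_UPPER = 1e-5

#: Per-category p-value cutoffs of the annotation-threshold method. Each
#: category's cutoff reflects the prior likelihood that variants of that
#: functional class alter protein function; "other" is the stringent
#: catch-all.
SVEINBJORNSSON_THRESHOLDS = {
    "loss_of_function": 5.5e-7,
    "moderate": 1.1e-7,
    "low": 1.0e-8,
    "other": 1.7e-9,
}

IMPACT_CATEGORIES = tuple(SVEINBJORNSSON_THRESHOLDS)


@dataclass(frozen=True)
class WeightedEqtlConfig:
    """Parameters of the weighted-Bonferroni eQTL nomination.

    ``alpha`` and ``power`` are the family-wise error target and the power
    target under which the binary weighting scheme was derived; ``M`` (the
    number of included variants) and ``epsilon`` (the eSNP fraction) are
    normally derived from the data and may be pinned here for reporting.
    ``binary_ratio`` is the relative eSNP/non-eSNP raw weight of the binary
    scheme — the closed-form optimum is a function of (alpha, power, M,
    epsilon) that we keep explicit and configurable rather than baked in.
    """

    alpha: float = 0.05
    power: float = 0.6
    M: int | None = None
    epsilon: float | None = None
    mode: str = "general"
    binary_ratio: float = 2.0
    sig_threshold: float = GENOME_WIDE_SIG

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "general"):
            raise ConfigurationError(f"unknown weighted-eQTL mode {self.mode!r}")
        if self.binary_ratio <= 0:
            raise ConfigurationError("binary_ratio must be positive")
        if self.epsilon is not None and not 0 < self.epsilon < 1:
            raise ConfigurationError("epsilon must lie in (0, 1)")
        if self.M is not None and self.M < 1:
            raise ConfigurationError("M must be >= 1")


def nominate_suggestive(records: pd.DataFrame, method: str = "suggestive") -> NominationSet:
    """Variants with 5e-8 ≤ p < 1e-5: the lenient band just short of
    genome-wide significance. Already genome-wide significant variants are
    not included."""
    mask = (records["pvalue"] >= GENOME_WIDE_SIG) & (records["pvalue"] < SUGGESTIVE_UPPER)
    items = records.loc[mask, ["chrom", "pos", "pvalue"]].reset_index(drop=True)
    return NominationSet(method=method, level="variant", items=items)


def _join_annotations(records: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    return records.merge(
        annotations, on=["chrom", "pos"], how="left", validate="one_to_one"
    )


def nominate_sveinbjornsson(
    records: pd.DataFrame,
    annotations: pd.DataFrame,
    method: str = "sveinbjornsson",
) -> NominationSet:
    """Nominate variants whose p-value clears their annotation category's
    threshold. Variants without an annotation default to the stringent
    "other" category."""
    if annotations is None:
        raise ConfigurationError("annotation-threshold nomination requires an annotation table")
    merged = _join_annotations(records, annotations[["chrom", "pos", "impact_category"]])
    cat = merged["impact_category"].fillna("other")
    unknown = set(cat.unique()) - set(IMPACT_CATEGORIES)
    if unknown:
        raise ConfigurationError(f"unknown impact categories: {sorted(unknown)}")
    cutoff = cat.map(SVEINBJORNSSON_THRESHOLDS).to_numpy(dtype=float)
    mask = merged["pvalue"].to_numpy(dtype=float) < cutoff
    items = merged.loc[mask, ["chrom", "pos", "pvalue"]].reset_index(drop=True)
    return NominationSet(method=method, level="variant", items=items)


def eqtl_weights(
    is_esnp: np.ndarray,
    eqtl_pvalue: np.ndarray | None,
    cfg: WeightedEqtlConfig,
) -> np.ndarray:
    """Raw then mean-one-normalized weights over all M variants.

    General mode: w = sqrt(−log10 p_eQTL) for eSNPs, 1 otherwise.
    Binary mode: w = binary_ratio for eSNPs, 1 otherwise.
    """
    is_esnp = np.asarray(is_esnp, dtype=bool)
    raw = np.ones(is_esnp.shape, dtype=float)
    if cfg.mode == "general":
        if eqtl_pvalue is None:
            raise ConfigurationError("general weighting requires eQTL p-values for eSNPs")
        ep = np.asarray(eqtl_pvalue, dtype=float)
        bad = is_esnp & (~np.isfinite(ep) | (ep <= 0) | (ep >= 1))
        if bad.any():
            raise ConfigurationError(
                f"{int(bad.sum())} eSNPs have eQTL p-values outside (0, 1)"
            )
        raw[is_esnp] = np.sqrt(-np.log10(ep[is_esnp]))
    else:
        raw[is_esnp] = cfg.binary_ratio
    return raw / raw.mean()


def weighted_eqtl_nominate(
    records: pd.DataFrame,
    annotations: pd.DataFrame,
    cfg: WeightedEqtlConfig | None = None,
    method: str = "weighted_eqtl",
) -> NominationSet:
    """Weighted-Bonferroni nomination: p_weighted = min(1, p / w) with
    mean-one weights over all M included variants; nominate where
    p_weighted < 5e-8.

    Mean-one normalization preserves the family-wise error rate: under the
    null the expected nomination count is sum_i(w_i · 5e-8) = M · 5e-8,
    identical to the unweighted procedure. Rows whose eSNP flag is set but
    whose eQTL p-value falls outside (0, 1) are rejected with a warning
    before weighting.
    """
    cfg = cfg or WeightedEqtlConfig()
    if annotations is None:
        raise ConfigurationError("weighted-eQTL nomination requires an annotation table")
    cols = ["chrom", "pos", "is_esnp"]
    if "eqtl_pvalue" in annotations.columns:
        cols.append("eqtl_pvalue")
    merged = _join_annotations(records, annotations[cols])
    merged["is_esnp"] = merged["is_esnp"].fillna(False).astype(bool)
    if cfg.mode == "general":
        ep = merged.get("eqtl_pvalue", pd.Series(np.nan, index=merged.index))
        ep = pd.to_numeric(ep, errors="coerce")
        bad = merged["is_esnp"] & (ep.isna() | (ep <= 0) | (ep >= 1))
        if bad.any():
            log.warning("weighted_eqtl_nominate: rejecting %d eSNP rows with invalid "
                        "eQTL p-values", int(bad.sum()))
            merged = merged[~bad].reset_index(drop=True)
            ep = ep[~bad.to_numpy()].reset_index(drop=True)
        weights = eqtl_weights(merged["is_esnp"].to_numpy(), ep.to_numpy(), cfg)
    else:
        weights = eqtl_weights(merged["is_esnp"].to_numpy(), None, cfg)
    p_weighted = np.minimum(1.0, merged["pvalue"].to_numpy(dtype=float) / weights)
    mask = p_weighted < cfg.sig_threshold
    items = merged.loc[mask, ["chrom", "pos", "pvalue"]].reset_index(drop=True)
    items["pvalue_weighted"] = p_weighted[mask]
    return NominationSet(method=method, level="variant", items=items)


def bonferroni_significant(
    pvalues, alpha: float = 0.05
) -> tuple[np.ndarray, float | None]:
    """Boolean mask of p < alpha / n_valid, plus the threshold.

    Entries that are missing or non-finite are excluded from the count of
    valid tests and never flagged. With no valid p-values the mask is all
    false and the threshold is None.
    """
    p = np.asarray(pd.to_numeric(pd.Series(pvalues), errors="coerce"), dtype=float)
    valid = np.isfinite(p)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return np.zeros(p.shape, dtype=bool), None
    threshold = alpha / n_valid
    mask = np.zeros(p.shape, dtype=bool)
    mask[valid] = p[valid] < threshold
    return mask, threshold


def fdr_significant(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values and the mask of q < ``q``.

    Missing p-values get a NaN q-value and are never flagged. This is the
    standard step-up procedure with monotone adjustment, not a local-FDR
    density estimate.
    """
    p = np.asarray(pd.to_numeric(pd.Series(pvalues), errors="coerce"), dtype=float)
    valid = np.isfinite(p)
    qvals = np.full(p.shape, np.nan)
    mask = np.zeros(p.shape, dtype=bool)
    if valid.any():
        _, qv, _, _ = multipletests(p[valid], alpha=q, method="fdr_bh")
        qvals[valid] = qv
        mask[valid] = qv < q
    return mask, qvals


@dataclass(frozen=True)
class SignificanceRule:
    """How to call significance on a method's score table: a fixed p-value
    threshold, a Bonferroni correction on the number of valid p-values, or
    BH FDR at level ``level``."""

    kind: str = "bonferroni"
    level: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_threshold", "bonferroni", "fdr"):
            raise ConfigurationError(f"unknown significance rule {self.kind!r}")
        if not 0 < self.level < 1:
            raise ConfigurationError("significance level must lie in (0, 1)")

    def apply(self, pvalues) -> np.ndarray:
        if self.kind == "fixed_threshold":
            p = np.asarray(pd.to_numeric(pd.Series(pvalues), errors="coerce"), dtype=float)
            return np.isfinite(p) & (p < self.level)
        if self.kind == "bonferroni":
            return bonferroni_significant(pvalues, self.level)[0]
        return fdr_significant(pvalues, self.level)[0]
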