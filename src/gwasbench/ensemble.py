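"""Stepwise loci × methods membership matrix and PPV by method support.

The matrix underlies UpSet-style intersection analysis: methods are
processed from the largest to the smallest number of nominated loci; the
first method contributes all of its loci, and each subsequent method
contributes only loci that do not already overlap a matrix locus by at
least the minimum overlap. Every contributed locus is tested against every
method's nominations to fill its membership row, so rows are complete at
insertion time regardless of processing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .loci import Locus, overlap_length


@dataclass
class EnsembleMatrix:
    """Deduplicated loci × methods boolean membership with per-locus gold flags."""

    loci: list[Locus]
    methods: list[str]
    membership: np.ndarray  # bool, shape (n_loci, n_methods)
    gold_flag: np.ndarray | None = None  # bool, shape (n_loci,)
    contributed_by: list[str] = field(default_factory=list)

    def support(self) -> np.ndarray:
        """Number of nominating methods per matrix locus."""
        return self.membership.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.membership.astype(int), columns=self.methods)
        df.insert(0, "chrom", [l.chrom for l in self.loci])
        df.insert(1, "start", [l.start for l in self.loci])
        df.insert(2, "end", [l.end for l in self.loci])
        df["n_methods"] = self.support()
        if self.gold_flag is not None:
            df["gold"] = self.gold_flag.astype(int)
        return df


def build_ensemble_matrix(
    nominations_by_method: Mapping[str, Sequence[Locus]],
    min_overlap: int = 250_000,
) -> EnsembleMatrix:
    """Build the stepwise matrix.

    Methods are ordered by descending locus count, ties broken by method
    name; per-method loci are expected to be already merged and filtered of
    earlier-wave regions. The output is independent of the order of each
    method's input loci.
    """
    methods = sorted(nominations_by_method, key=lambda m: (-len(nominations_by_method[m]), m))
    matrix_loci: list[Locus] = []
    rows: list[list[bool]] = []
    contributed: list[str] = []
    for method in methods:
        for locus in sorted(nominations_by_method[method],
                            key=lambda l: (l.chrom, l.start, l.end)):
            if any(overlap_length(locus, existing) >= min_overlap
                   for existing in matrix_loci):
                continue
            row = [
                any(overlap_length(locus, other) >= min_overlap
                    for other in nominations_by_method[m])
                for m in methods
            ]
            # the contributor always owns its locus, even when the locus is
            # narrower than the overlap requirement
            row[methods.index(method)] = True
            matrix_loci.append(locus)
            rows.append(row)
            contributed.append(method)
    membership = (np.array(rows, dtype=bool) if rows
                  else np.zeros((0, len(methods)), dtype=bool))
    return EnsembleMatrix(loci=matrix_loci, methods=list(methods),
                          membership=membership, contributed_by=contributed)


def flag_gold(
    matrix: EnsembleMatrix,
    gold_loci: Sequence[Locus],
    min_overlap: int = 250_000,
) -> EnsembleMatrix:
    """Mark each matrix locus as confirmed when it overlaps a gold locus by
    ≥ ``min_overlap`` bases."""
    matrix.gold_flag = np.array([
        any(overlap_length(l, g) >= min_overlap for g in gold_loci)
        for l in matrix.loci
    ], dtype=bool)
    return matrix


def ppv_by_support(matrix: EnsembleMatrix) -> pd.DataFrame:
    """PPV stratified by the number of nominating methods.

    Both the cumulative reading (all loci nominated by ≥ k methods — the
    sense in which a minimum number of methods achieves a target PPV) and
    the exact-k stratification are reported, since PPV need not increase
    monotonically with support. Strata with no loci carry an absent PPV.
    """
    if matrix.gold_flag is None:
        raise ValueError("gold flags not populated; call flag_gold first")
    support = matrix.support()
    gold = matrix.gold_flag
    rows = []
    for k in range(1, len(matrix.methods) + 1):
        cum = support >= k
        exact = support == k
        rows.append({
            "support": k,
            "n_loci_cumulative": int(cum.sum()),
            "ppv_cumulative": float(gold[cum].mean()) if cum.any() else None,
            "n_loci_exact": int(exact.sum()),
            "ppv_exact": float(gold[exact].mean()) if exact.any() else None,
        })
    return pd.DataFrame(rows)
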