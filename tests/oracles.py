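"""Independent brute-force oracles used to cross-check interval logic.

Every oracle here represents genomic intervals as explicit Python sets of
base coordinates, so overlap questions reduce to set intersection. That is
exact and obviously correct but only feasible for the small coordinate
spaces used in randomized cross-checks; the package's own implementations
never see these routines.
"""

from __future__ import annotations

import pandas as pd


def bases(chrom: str, start: int, end: int) -> set[tuple[str, int]]:
    return {(chrom, b) for b in range(start, end + 1)}


def brute_define_loci(records: pd.DataFrame, sig_threshold: float, flank: int):
    """Stepwise window definition by literal set arithmetic.

    Returns a list of (chrom, start, end, sorted members) tuples sorted by
    (chrom, start), after merging any window groups that share a base.
    """
    sig = [
        (str(r.chrom), int(r.pos), float(r.pvalue))
        for r in records.itertuples(index=False)
        if r.pvalue < sig_threshold
    ]
    remaining = sorted(sig, key=lambda t: (t[2], t[0], t[1]))
    windows = []  # (chrom, base-set, member positions)
    while remaining:
        chrom, pos, _ = remaining[0]
        window = bases(chrom, pos - flank, pos + flank)
        inside = [t for t in remaining if (t[0], t[1]) in window]
        windows.append((chrom, window, {t[1] for t in inside}))
        remaining = [t for t in remaining if (t[0], t[1]) not in window]
    # merge windows sharing any base, to a fixpoint
    merged = True
    while merged:
        merged = False
        for i in range(len(windows)):
            for j in range(i + 1, len(windows)):
                if windows[i][1] & windows[j][1]:
                    ci, bi, mi = windows[i]
                    _, bj, mj = windows[j]
                    windows[i] = (ci, bi | bj, mi | mj)
                    del windows[j]
                    merged = True
                    break
            if merged:
                break
    out = []
    for chrom, base_set, members in windows:
        coords = [b for _, b in base_set]
        out.append((chrom, min(coords), max(coords), tuple(sorted(members))))
    return sorted(out)


def brute_classify(nominated, gold, min_overlap: int):
    """Locus classification by counting shared bases per pair.

    ``nominated`` and ``gold`` are sequences of (chrom, start, end) tuples.
    Returns (tp_nominated, fp, gold_covered, fn).
    """
    nom_sets = [bases(*t) for t in nominated]
    gold_sets = [bases(*t) for t in gold]
    nom_hit = [any(len(n & g) >= min_overlap for g in gold_sets) for n in nom_sets]
    gold_hit = [any(len(n & g) >= min_overlap for n in nom_sets) for g in gold_sets]
    tp = sum(nom_hit)
    covered = sum(gold_hit)
    return tp, len(nom_sets) - tp, covered, len(gold_sets) - covered


def brute_ensemble(loci_by_method, min_overlap: int):
    """Stepwise membership matrix by literal set arithmetic.

    ``loci_by_method`` maps method name to a list of (chrom, start, end)
    tuples. Returns (ordered methods, list of (locus tuple, membership row)).
    """
    methods = sorted(loci_by_method, key=lambda m: (-len(loci_by_method[m]), m))
    base_sets = {m: [bases(*t) for t in loci_by_method[m]] for m in methods}
    rows = []
    matrix_sets = []
    for m in methods:
        for locus, bset in sorted(zip(loci_by_method[m], base_sets[m]),
                                  key=lambda t: t[0]):
            if any(len(bset & existing) >= min_overlap for existing in matrix_sets):
                continue
            row = tuple(
                True if mm == m else
                any(len(bset & other) >= min_overlap for other in base_sets[mm])
                for mm in methods
            )
            matrix_sets.append(bset)
            rows.append((locus, row))
    return methods, rows
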