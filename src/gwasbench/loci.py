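"""Locus definition, merging, exclusion, and interval arithmetic.

A locus is a contiguous genomic interval, 1-based and closed at both ends.
Significant loci are built by the stepwise window procedure: take the most
significant remaining variant, open a ±``flank`` window around it, absorb
every significant variant inside the window, and repeat until none remain;
overlapping windows on a chromosome are then combined, and any chromosome-6
locus touching the extended HLA/MHC region (25–35 Mb) is unioned with that
fixed interval and collapsed into a single HLA locus.

Start coordinates may run below 1: windows are deliberately not clipped at
chromosome ends, so metrics are insensitive to a lead variant sitting near a
telomere. The BED writer clamps at zero (BED is 0-based, half-open) and flags
clamped records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sumstats import chrom_sort_key, normalize_chrom

log = logging.getLogger(__name__)


@dataclass
class Locus:
    """A contiguous genomic interval with optional lead variant and members."""

    chrom: str
    start: int
    end: int
    lead_pos: int | None = None
    lead_p: float | None = None
    members: list[int] = field(default_factory=list)
    is_hla: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus start {self.start} > end {self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class LocusConfig:
    """Parameters of the stepwise locus definition.

    ``sig_threshold`` is the genome-wide significance cutoff, ``flank`` the
    half-width of the window around each lead, and the ``hla_*`` fields the
    fixed extended HLA/MHC interval collapsed into a single locus.
    """

    sig_threshold: float = 5e-8
    flank: int = 500_000
    hla_chrom: str = "6"
    hla_start: int = 25_000_000
    hla_end: int = 35_000_000

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if self.hla_start >= self.hla_end:
            raise ValueError("hla_start must be < hla_end")


def overlap_length(a: Locus, b: Locus) -> int:
    """Shared bases between two closed intervals; 0 if disjoint or on
    different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def merge_loci(loci: Iterable[Locus]) -> list[Locus]:
    """Combine loci that share at least one base on the same chromosome.

    Lead fields of a merged locus come from the smallest-p constituent;
    ``is_hla`` propagates if any constituent carries it.
    """
    ordered = sorted(loci, key=lambda l: (chrom_sort_key(l.chrom), l.start, l.end))
    out: list[Locus] = []
    for loc in ordered:
        if out and out[-1].chrom == loc.chrom and loc.start <= out[-1].end:
            prev = out[-1]
            prev.end = max(prev.end, loc.end)
            prev.members = sorted(set(prev.members) | set(loc.members))
            prev.is_hla = prev.is_hla or loc.is_hla
            if loc.lead_p is not None and (prev.lead_p is None or loc.lead_p < prev.lead_p):
                prev.lead_pos, prev.lead_p = loc.lead_pos, loc.lead_p
        else:
            out.append(Locus(loc.chrom, loc.start, loc.end, loc.lead_pos,
                             loc.lead_p, list(loc.members), loc.is_hla))
    return out


def _collapse_hla(loci: list[Locus], cfg: LocusConfig) -> list[Locus]:
    hla_box = Locus(cfg.hla_chrom, cfg.hla_start, cfg.hla_end)
    touching = [l for l in loci if overlap_length(l, hla_box) > 0]
    if not touching:
        return loci
    rest = [l for l in loci if overlap_length(l, hla_box) == 0]
    members = sorted({m for l in touching for m in l.members})
    leads = [(l.lead_p, l.lead_pos) for l in touching if l.lead_p is not None]
    lead_p, lead_pos = min(leads) if leads else (None, None)
    merged = Locus(
        cfg.hla_chrom,
        min(cfg.hla_start, min(l.start for l in touching)),
        max(cfg.hla_end, max(l.end for l in touching)),
        lead_pos=lead_pos,
        lead_p=lead_p,
        members=members,
        is_hla=True,
    )
    # The union may have grown into a previously disjoint neighbour.
    return merge_loci(rest + [merged])


def define_loci(records: pd.DataFrame, cfg: LocusConfig | None = None) -> list[Locus]:
    """Stepwise significant-locus definition on deduplicated summary statistics.

    Returns pairwise non-overlapping loci per chromosome; every variant with
    ``pvalue < cfg.sig_threshold`` is a member of exactly one returned locus.
    Lead-selection ties (equal p) are broken by ascending (chrom, pos) so the
    result is independent of input row order.
    """
    cfg = cfg or LocusConfig()
    sig = records[records["pvalue"] < cfg.sig_threshold]
    if sig.empty:
        return []
    chroms = sig["chrom"].to_numpy()
    pos = sig["pos"].to_numpy(dtype=np.int64)
    pval = sig["pvalue"].to_numpy(dtype=float)
    ckey = [chrom_sort_key(c) for c in chroms]

    order = sorted(range(len(sig)), key=lambda i: (pval[i], ckey[i], pos[i]))
    alive = np.ones(len(sig), dtype=bool)
    windows: list[Locus] = []
    for i in order:
        if not alive[i]:
            continue
        lo, hi = pos[i] - cfg.flank, pos[i] + cfg.flank
        inside = alive & (chroms == chroms[i]) & (pos >= lo) & (pos <= hi)
        windows.append(Locus(
            str(chroms[i]), int(lo), int(hi),
            lead_pos=int(pos[i]), lead_p=float(pval[i]),
            members=sorted(int(p) for p in pos[inside]),
        ))
        alive &= ~inside
    merged = merge_loci(windows)
    return _collapse_hla(merged, cfg)


def windows_from_points(
    points: pd.DataFrame,
    flank: int = 500_000,
    hla: LocusConfig | None = None,
) -> list[Locus]:
    """One ±``flank`` window per (chrom, pos) point, merged wherever windows
    share at least one base. Lead fields are filled from the smallest-p point
    when the frame carries a ``pvalue`` column. Pass a :class:`LocusConfig`
    as ``hla`` to additionally collapse the extended HLA region.
    """
    has_p = "pvalue" in points.columns
    windows = [
        Locus(
            normalize_chrom(row.chrom),
            int(row.pos) - flank,
            int(row.pos) + flank,
            lead_pos=int(row.pos),
            lead_p=float(row.pvalue) if has_p and not pd.isna(row.pvalue) else None,
            members=[int(row.pos)],
        )
        for row in points.itertuples(index=False)
    ]
    merged = merge_loci(windows)
    if hla is not None:
        merged = _collapse_hla(merged, hla)
    return merged


def exclude_overlapping(
    target: Sequence[Locus],
    exclusion: Sequence[Locus],
    min_overlap: int = 1,
) -> list[Locus]:
    """Remove target loci overlapping any exclusion locus by ≥ ``min_overlap``
    bases (the default, 1, removes any degree of overlap)."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    kept = [
        t for t in target
        if all(overlap_length(t, e) < min_overlap for e in exclusion)
    ]
    log.info("exclude_overlapping: removed %d of %d loci", len(target) - len(kept), len(target))
    return kept


def exclude_points_in_loci(points: pd.DataFrame, loci: Sequence[Locus]) -> pd.DataFrame:
    """Drop points (chrom, pos rows) lying inside any locus interval.

    The loci are expected to already embody the ±flank boundary, so no extra
    padding is applied here.
    """
    if not loci or points.empty:
        return points.reset_index(drop=True)
    keep = np.ones(len(points), dtype=bool)
    chroms = points["chrom"].to_numpy()
    pos = points["pos"].to_numpy(dtype=np.int64)
    for loc in loci:
        keep &= ~((chroms == loc.chrom) & (pos >= loc.start) & (pos <= loc.end))
    removed = int((~keep).sum())
    if removed:
        log.info("exclude_points_in_loci: removed %d of %d points", removed, len(points))
    return points[keep].reset_index(drop=True)


def gene_to_locus(gene, mode: str = "midpoint_flank", flank: int = 500_000) -> Locus:
    """Turn a gene record (object or mapping with chrom/start/end) into a locus.

    ``boundaries`` uses the annotated gene boundaries; ``midpoint_flank``
    opens a ±``flank`` window around floor((start+end)/2). Neither mode clips
    at chromosome ends or centromeres.
    """
    get = gene.get if hasattr(gene, "get") else lambda k, d=None: getattr(gene, k, d)
    chrom = normalize_chrom(get("chrom"))
    start, end = int(get("start")), int(get("end"))
    pvalue = get("pvalue")
    pvalue = None if pvalue is None or pd.isna(pvalue) else float(pvalue)
    if mode == "boundaries":
        mid = (start + end) // 2
        return Locus(chrom, start, end, lead_pos=mid, lead_p=pvalue, members=[mid])
    if mode == "midpoint_flank":
        mid = (start + end) // 2
        return Locus(chrom, mid - flank, mid + flank, lead_pos=mid, lead_p=pvalue, members=[mid])
    raise ValueError(f"unknown gene_to_locus mode {mode!r}")


LOCI_COLUMNS = ("chrom", "start", "end", "lead_pos", "lead_p", "n_members", "is_hla")


def loci_to_frame(loci: Sequence[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": l.chrom, "start": l.start, "end": l.end,
                "lead_pos": l.lead_pos, "lead_p": l.lead_p,
                "n_members": len(l.members), "is_hla": l.is_hla,
            }
            for l in loci
        ],
        columns=list(LOCI_COLUMNS),
    )


def write_loci(loci: Sequence[Locus], path) -> None:
    """Write loci as TSV (1-based closed coordinates)."""
    loci_to_frame(loci).to_csv(path, sep="\t", index=False, na_rep=".")


def read_loci(path) -> list[Locus]:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    out = []
    for row in df.itertuples(index=False):
        out.append(Locus(
            normalize_chrom(row.chrom), int(row.start), int(row.end),
            lead_pos=None if pd.isna(row.lead_pos) else int(row.lead_pos),
            lead_p=None if pd.isna(row.lead_p) else float(row.lead_p),
            is_hla=bool(row.is_hla),
        ))
    return out


def write_loci_bed(loci: Sequence[Locus], path) -> int:
    """Write loci as BED (0-based, half-open): start = max(0, start − 1).

    Internal coordinates may run below 1 (windows are unclipped); such
    records are clamped at zero on write. Returns the number clamped.
    """
    n_clamped = 0
    with open(path, "w") as fh:
        for l in loci:
            bed_start = l.start - 1
            if bed_start < 0:
                bed_start = 0
                n_clamped += 1
            name = f"lead={l.lead_pos}" if l.lead_pos is not None else "."
            fh.write(f"{l.chrom}\t{bed_start}\t{l.end}\t{name}\n")
    if n_clamped:
        log.warning("write_loci_bed: clamped %d loci with start < 1 at zero", n_clamped)
    return n_clamped
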