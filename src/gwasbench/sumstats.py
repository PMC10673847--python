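"""Reading, harmonizing, and writing GWAS summary statistics and related tables.

Summary statistics are carried as :class:`pandas.DataFrame` objects with the
canonical columns ``chrom`` (string, no ``chr`` prefix), ``pos`` (1-based
integer), ``rsid``, ``a1``, ``a2``, ``freq``, ``effect``, and ``pvalue``.
Gene tables carry ``gene_id``, ``symbol``, ``chrom``, ``start``, ``end``,
``pvalue``, and a derived ``midpoint`` (``floor((start + end) / 2)``).

Coordinates are 1-based and inclusive throughout the package; the BED writer
in :mod:`gwasbench.loci` is the only place the half-open 0-based convention
appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ColumnMappingError, ConfigurationError

log = logging.getLogger(__name__)

#: Smallest representable p-value; smaller parsed values (including exact
#: zeros produced by underflow) are raised to this floor.
PVALUE_FLOOR = 7.41e-323

SUMSTAT_COLUMNS = ("chrom", "pos", "rsid", "a1", "a2", "freq", "effect", "pvalue")

#: Tokens commonly used for a missing field in delimited summary statistics.
NA_TOKENS = {"", ".", "na", "nan", "n/a", "null", "none", "-"}

NOMINATION_LEVELS = ("variant", "gene", "locus")


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to column headers in a file.

    ``chrom``, ``pos`` and ``pvalue`` are mandatory for summary statistics;
    the rest are optional and silently skipped when ``None``.
    """

    chrom: str = "CHR"
    pos: str = "POS"
    pvalue: str = "P"
    rsid: str | None = "SNP"
    a1: str | None = None
    a2: str | None = None
    freq: str | None = None
    effect: str | None = None
    sep: str | None = None  # None -> any whitespace

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "ColumnMap":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown column-mapping keys: {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass
class NominationSet:
    """A named method's nominations at one evaluation level.

    ``items`` is a DataFrame whose schema depends on ``level``:

    - ``variant``: ``chrom``, ``pos`` (and optionally ``pvalue``)
    - ``gene``: ``gene_id``, ``symbol`` (and optionally ``score``, ``chrom``,
      ``pos`` for methods that report their own coordinates)
    - ``locus``: ``chrom``, ``start``, ``end``
    """

    method: str
    level: str
    items: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.level not in NOMINATION_LEVELS:
            raise ConfigurationError(
                f"unknown nomination level {self.level!r}; expected one of {NOMINATION_LEVELS}"
            )

    def __len__(self) -> int:
        return len(self.items)


def normalize_chrom(label: object) -> str:
    """Strip a leading ``chr`` prefix and canonicalize case."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.lower() in {"x", "y", "mt", "m"} else s


def chrom_sort_key(label: str) -> tuple[int, str]:
    """Sort key placing autosomes numerically, then X/Y/MT, then the rest."""
    try:
        return (int(label), "")
    except (TypeError, ValueError):
        pass
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if label in special:
        return (special[label], "")
    return (99, str(label))


def _sorted_by_position(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iat[i], df["pos"].iat[i]))
    return df.iloc[order].reset_index(drop=True)


def _parse_series(raw: pd.Series, kind: str) -> pd.Series:
    s = raw.astype(str).str.strip()
    s = s.mask(s.str.lower().isin(NA_TOKENS))
    if kind == "float":
        return pd.to_numeric(s, errors="coerce")
    if kind == "int":
        return pd.to_numeric(s, errors="coerce")
    return s


def read_sumstats(path, colmap: ColumnMap | Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read delimited summary statistics into the canonical frame.

    Rows with an unparseable chromosome, position, or p-value (missing,
    negative, or > 1) are dropped and counted; the count is logged and stored
    in ``df.attrs["n_dropped"]``. A p-value of exactly zero is retained — it
    is the job of :func:`truncate_pvalues` to raise it to the floor.
    Records are returned sorted by (chrom, pos).
    """
    if colmap is None:
        colmap = ColumnMap()
    elif isinstance(colmap, Mapping):
        colmap = ColumnMap.from_dict(colmap)
    try:
        raw = pd.read_csv(path, sep=colmap.sep or r"\s+", dtype=str, engine="python")
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.columns.size == 0:
        log.warning("empty summary-statistics file: %s", path)
        df = pd.DataFrame({c: pd.Series(dtype="object") for c in SUMSTAT_COLUMNS})
        df.attrs["n_dropped"] = 0
        return df

    for mandatory in ("chrom", "pos", "pvalue"):
        name = getattr(colmap, mandatory)
        if name not in raw.columns:
            raise ColumnMappingError(
                f"mandatory column {name!r} (field {mandatory!r}) not found in {path}"
            )

    out = pd.DataFrame(index=raw.index)
    out["chrom"] = raw[colmap.chrom].map(normalize_chrom)
    out["pos"] = _parse_series(raw[colmap.pos], "int")
    out["pvalue"] = _parse_series(raw[colmap.pvalue], "float")
    for fld in ("rsid", "a1", "a2"):
        name = getattr(colmap, fld)
        out[fld] = _parse_series(raw[name], "str") if name in raw.columns and name else pd.NA
    for fld in ("freq", "effect"):
        name = getattr(colmap, fld)
        out[fld] = _parse_series(raw[name], "float") if name in raw.columns and name else np.nan

    ok = (
        out["pos"].notna()
        & (out["pos"] >= 1)
        & out["pvalue"].notna()
        & (out["pvalue"] >= 0)
        & (out["pvalue"] <= 1)
        & (out["chrom"].str.len() > 0)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("read_sumstats(%s): dropped %d unparseable rows", path, n_dropped)
    df = out[ok].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df = _sorted_by_position(df[list(SUMSTAT_COLUMNS)])
    if df.empty:
        log.warning("no parseable rows in summary-statistics file: %s", path)
    df.attrs["n_dropped"] = n_dropped
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write the canonical frame as tab-separated text.

    The round trip ``read_sumstats(write_sumstats(df))`` preserves
    (chrom, pos, pvalue) exactly: floats are written with Python's shortest
    round-trip representation.
    """
    out = df.copy()
    header = {"chrom": "CHR", "pos": "POS", "rsid": "SNP", "a1": "A1",
              "a2": "A2", "freq": "FRQ", "effect": "BETA", "pvalue": "P"}
    out = out[list(SUMSTAT_COLUMNS)].rename(columns=header)
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def truncate_pvalues(df: pd.DataFrame, floor: float = PVALUE_FLOOR) -> pd.DataFrame:
    """Raise every p-value below ``floor`` (including zeros) to ``floor``.

    Idempotent and order-preserving.
    """
    out = df.copy()
    p = out["pvalue"].to_numpy(dtype=float, copy=True)
    p[p < floor] = floor
    out["pvalue"] = p
    return out


def dedupe_by_position(df: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly one record per (chrom, pos): the one with the smallest
    p-value, ties broken by lexicographically smallest rsid, then by first
    occurrence. Idempotent."""
    if df.empty:
        return df.copy().reset_index(drop=True)
    work = df.copy()
    work["_order"] = np.arange(len(work))
    # NaN rsids sort after real ones so a named record wins an exact-p tie.
    work["_rsid_key"] = work["rsid"].astype("string").fillna("￿")
    work = work.sort_values(
        ["pvalue", "_rsid_key", "_order"], kind="mergesort"
    ).drop_duplicates(subset=["chrom", "pos"], keep="first")
    out = work.drop(columns=["_order", "_rsid_key"])
    return _sorted_by_position(out)


def filter_valid(df: pd.DataFrame, require: Iterable[str] = ()) -> pd.DataFrame:
    """Keep only records whose ``require``d fields are present.

    ``require`` is a subset of {"rsid", "freq", "effect"}. The retention
    count is logged.
    """
    require = set(require)
    allowed = {"rsid", "freq", "effect"}
    if not require <= allowed:
        raise ConfigurationError(f"require must be a subset of {allowed}, got {require}")
    mask = pd.Series(True, index=df.index)
    for fld in require:
        mask &= df[fld].notna()
    out = df[mask].reset_index(drop=True)
    log.info("filter_valid: retained %d of %d records (require=%s)",
             len(out), len(df), sorted(require))
    return out


@dataclass(frozen=True)
class GeneColumnMap:
    gene_id: str = "GENE"
    chrom: str = "CHR"
    start: str = "START"
    end: str = "END"
    symbol: str | None = "SYMBOL"
    pvalue: str | None = "P"
    sep: str | None = None


def read_gene_table(path, colmap: GeneColumnMap | Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a gene score table (id, symbol, chrom, start, end, p-value).

    Rows with malformed boundaries (unparseable, or start > end) are dropped
    with a warning; both ``gene_id`` and ``symbol`` are retained for dual-key
    matching. ``midpoint`` = floor((start + end) / 2).
    """
    if colmap is None:
        colmap = GeneColumnMap()
    elif isinstance(colmap, Mapping):
        colmap = GeneColumnMap(**dict(colmap))
    raw = pd.read_csv(path, sep=colmap.sep or r"\s+", dtype=str, engine="python")
    for mandatory in ("gene_id", "chrom", "start", "end"):
        name = getattr(colmap, mandatory)
        if name not in raw.columns:
            raise ColumnMappingError(f"mandatory column {name!r} not found in {path}")
    out = pd.DataFrame(index=raw.index)
    out["gene_id"] = _parse_series(raw[colmap.gene_id], "str")
    out["symbol"] = (
        _parse_series(raw[colmap.symbol], "str")
        if colmap.symbol and colmap.symbol in raw.columns
        else pd.NA
    )
    out["chrom"] = raw[colmap.chrom].map(normalize_chrom)
    out["start"] = _parse_series(raw[colmap.start], "int")
    out["end"] = _parse_series(raw[colmap.end], "int")
    out["pvalue"] = (
        _parse_series(raw[colmap.pvalue], "float")
        if colmap.pvalue and colmap.pvalue in raw.columns
        else np.nan
    )
    ok = (
        out["gene_id"].notna()
        & out["start"].notna()
        & out["end"].notna()
        & (out["start"] <= out["end"])
        & (out["start"] >= 1)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("read_gene_table(%s): dropped %d malformed rows", path, n_bad)
    df = out[ok].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["midpoint"] = (df["start"] + df["end"]) // 2
    df = df.reset_index(drop=True)
    df.attrs["n_dropped"] = n_bad
    return df


def read_nominations(
    path,
    level: str,
    colmap: Mapping[str, str] | None = None,
    method: str | None = None,
    sumstats: pd.DataFrame | None = None,
) -> NominationSet:
    """Read a per-method nomination file.

    - ``variant`` level: columns for chrom+pos, or an rsid column resolved
      against ``sumstats`` (unresolvable rsids are dropped and counted).
    - ``gene`` level: ``gene_id`` and/or ``symbol`` column (plus optional
      score and coordinate-override columns for methods that report their
      own positions).
    - ``locus`` level: chrom+start+end columns.
    """
    if level not in NOMINATION_LEVELS:
        raise ConfigurationError(
            f"unknown nomination level {level!r}; expected one of {NOMINATION_LEVELS}"
        )
    method = method or str(path)
    colmap = dict(colmap or {})
    sep = colmap.pop("sep", None) or r"\s+"
    raw = pd.read_csv(path, sep=sep, dtype=str, engine="python")
    if raw.empty:
        return NominationSet(method=method, level=level, items=pd.DataFrame())

    def col(field: str, default: str) -> str | None:
        name = colmap.get(field, default)
        return name if name in raw.columns else None

    n_dropped = 0
    if level == "variant":
        c_chrom, c_pos = col("chrom", "CHR"), col("pos", "POS")
        if c_chrom and c_pos:
            items = pd.DataFrame({
                "chrom": raw[c_chrom].map(normalize_chrom),
                "pos": _parse_series(raw[c_pos], "int"),
            })
            if (c_p := col("pvalue", "P")):
                items["pvalue"] = _parse_series(raw[c_p], "float")
            ok = items["pos"].notna()
            n_dropped = int((~ok).sum())
            items = items[ok].astype({"pos": np.int64}).reset_index(drop=True)
        else:
            c_rsid = col("rsid", "SNP")
            if not c_rsid:
                raise ColumnMappingError(
                    f"variant nominations in {path} need chrom+pos or an rsid column"
                )
            if sumstats is None:
                raise ConfigurationError(
                    "rsid-only nominations require a harmonized sumstats frame to resolve against"
                )
            rsids = _parse_series(raw[c_rsid], "str")
            lookup = sumstats.dropna(subset=["rsid"]).set_index("rsid")
            resolved = rsids[rsids.isin(lookup.index)]
            n_dropped = len(rsids) - len(resolved)
            if n_dropped:
                log.info("read_nominations(%s): %d unresolvable rsids dropped", path, n_dropped)
            hit = lookup.loc[resolved, ["chrom", "pos"]].reset_index(drop=True)
            items = hit.astype({"pos": np.int64})
    elif level == "gene":
        c_id, c_sym = col("gene_id", "GENE"), col("symbol", "SYMBOL")
        if not (c_id or c_sym):
            raise ColumnMappingError(f"gene nominations in {path} need a gene id or symbol column")
        items = pd.DataFrame({
            "gene_id": _parse_series(raw[c_id], "str") if c_id else pd.NA,
            "symbol": _parse_series(raw[c_sym], "str") if c_sym else pd.NA,
        })
        if (c_score := col("score", "SCORE")):
            items["score"] = _parse_series(raw[c_score], "float")
        # Coordinate override for methods reporting their own positions.
        c_chrom, c_pos = col("chrom", "CHR"), col("pos", "POS")
        if c_chrom and c_pos:
            items["chrom"] = raw[c_chrom].map(normalize_chrom)
            items["pos"] = _parse_series(raw[c_pos], "int")
        ok = items["gene_id"].notna() | items["symbol"].notna()
        n_dropped = int((~ok).sum())
        items = items[ok].reset_index(drop=True)
    else:  # locus
        c_chrom = col("chrom", "CHR")
        c_start, c_end = col("start", "START"), col("end", "END")
        if not (c_chrom and c_start and c_end):
            raise ColumnMappingError(f"locus nominations in {path} need chrom+start+end columns")
        items = pd.DataFrame({
            "chrom": raw[c_chrom].map(normalize_chrom),
            "start": _parse_series(raw[c_start], "int"),
            "end": _parse_series(raw[c_end], "int"),
        })
        ok = items["start"].notna() & items["end"].notna() & (items["start"] <= items["end"])
        n_dropped = int((~ok).sum())
        items = items[ok].astype({"start": np.int64, "end": np.int64}).reset_index(drop=True)

    return NominationSet(method=method, level=level, items=items, n_dropped=n_dropped)
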