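import numpy as np
import pandas as pd
import pytest

from gwasbench.loci import Locus
from gwasbench.sumstats import SUMSTAT_COLUMNS


def make_sumstats(rows):
    """Build a canonical sumstats frame from (chrom, pos, pvalue[, rsid]) tuples."""
    records = []
    for row in rows:
        chrom, pos, p = row[0], row[1], row[2]
        rsid = row[3] if len(row) > 3 else f"rs{pos}"
        records.append({
            "chrom": str(chrom), "pos": int(pos), "rsid": rsid,
            "a1": "A", "a2": "G", "freq": 0.3, "effect": 0.1,
            "pvalue": float(p),
        })
    df = pd.DataFrame(records, columns=list(SUMSTAT_COLUMNS))
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in SUMSTAT_COLUMNS})
    return df


def random_small_loci(rng, n, chroms=("1", "2"), span=2_000, width_max=120):
    """Random small-coordinate loci for brute-force cross-checks."""
    out = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(1, span))
        width = int(rng.integers(1, width_max))
        out.append(Locus(chrom, start, start + width))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_sumstats_file(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(
        "CHR\tPOS\tSNP\tP\n"
        "1\t100\trs1\t0.01\n"
        "chr2\t200\trs2\t1e-9\n"
        "1\t50\trs3\t0.5\n"
    )
    return path
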