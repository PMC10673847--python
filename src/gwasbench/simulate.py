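"""Synthetic two-wave GWAS generator with planted causal loci.

The generator emulates the structure the evaluation framework consumes: two
waves of the same trait over the same variant set, where the second,
larger-sample wave reaches genome-wide significance at a superset of the
planted loci. Per-variant z-scores are standard normal under the null; near
a planted lead they gain a shared distance-decayed signal component scaled
by the square root of the wave's sample size, so wave 2 recovers everything
wave 1 does and more. No linkage-disequilibrium matrix is simulated — the
distance decay exists to exercise locus collapsing, which is all the
evaluation framework ever sees.

All randomness flows from one root seed through named substreams, so adding
a stage never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, PlacementError
from .loci import Locus, overlap_length
from .sumstats import SUMSTAT_COLUMNS, NominationSet

DEFAULT_CHROM_LENGTHS = {"1": 50_000_000, "2": 50_000_000}


def substream(seed: int, name: str) -> np.random.Generator:
    """A named RNG substream derived from the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=[int(seed), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic two-wave GWAS.

    ``effect_scale`` is the per-locus lead noncentrality (expected |z|) at
    the reference sample size ``n1``; wave 2's signal scales by
    sqrt(n2 / n1). ``decay_bp`` is the exponential distance-decay scale of
    the signal around each planted lead (signal extends to 3·decay_bp).
    Planted leads are spaced at least ``min_lead_spacing`` apart so planted
    loci are unambiguous.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    n_variants: int = 20_000
    n_causal_loci: int = 6
    effect_scale: float = 4.5
    n1: int = 25_000
    n2: int = 100_000
    decay_bp: int = 50_000
    min_lead_spacing: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n2 > self.n1 >= 1:
            raise ConfigurationError("need n2 > n1 >= 1")
        if self.decay_bp <= 0:
            raise ConfigurationError("decay_bp must be positive")
        if self.n_variants < 1 or self.n_causal_loci < 0:
            raise ConfigurationError("n_variants >= 1 and n_causal_loci >= 0 required")
        if not self.chrom_lengths:
            raise ConfigurationError("chrom_lengths must not be empty")


def _allocate(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``total`` items over ``weights``."""
    weights = np.asarray(weights, dtype=float)
    shares = total * weights / weights.sum()
    counts = np.floor(shares).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(shares - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


def _plant_leads(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    chroms = sorted(cfg.chrom_lengths)
    counts = _allocate(cfg.n_causal_loci,
                       [cfg.chrom_lengths[c] for c in chroms])
    leads: list[tuple[str, int]] = []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        length = cfg.chrom_lengths[chrom]
        seg = length / (k + 1)
        jitter_scale = max(1, int(min(seg / 4, cfg.min_lead_spacing / 4)))
        positions = sorted(
            int(np.clip((i + 1) * seg + rng.integers(-jitter_scale, jitter_scale + 1),
                        1, length))
            for i in range(k)
        )
        for a, b in zip(positions, positions[1:]):
            if b - a < cfg.min_lead_spacing:
                raise ConfigurationError(
                    f"cannot place {k} leads ≥ {cfg.min_lead_spacing} bp apart "
                    f"on chromosome {chrom} of length {length}"
                )
        leads.extend((chrom, p) for p in positions)
    return leads


def _unique_positions(rng: np.random.Generator, n: int, length: int,
                      reserved: np.ndarray) -> np.ndarray:
    """n distinct positions in [1, length] avoiding ``reserved``."""
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        draw = rng.integers(1, length + 1, size=(n - out.size) * 2)
        pool = np.setdiff1d(np.unique(draw), reserved)
        out = np.unique(np.concatenate([out, pool]))
    rng.shuffle(out)
    return np.sort(out[:n])


def simulate_two_wave_gwas(
    cfg: SimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, int]]]:
    """Generate (wave1, wave2, planted leads).

    Both waves share the same variant set; each planted lead is itself a
    variant. P-values are two-sided normal tails of the z-scores, so under
    a pure null (``effect_scale = 0``) they are uniform on (0, 1).
    Byte-identical output is guaranteed for a fixed config.
    """
    cfg = cfg or SimConfig()
    leads = _plant_leads(cfg, substream(cfg.seed, "leads"))
    pos_rng = substream(cfg.seed, "positions")
    noise1 = substream(cfg.seed, "noise-wave1")
    noise2 = substream(cfg.seed, "noise-wave2")
    meta_rng = substream(cfg.seed, "metadata")

    chroms = sorted(cfg.chrom_lengths)
    lead_by_chrom = {c: np.array(sorted(p for cc, p in leads if cc == c), dtype=np.int64)
                     for c in chroms}
    n_free = cfg.n_variants - len(leads)
    if n_free < 0:
        raise ConfigurationError("n_variants smaller than the number of planted leads")
    counts = _allocate(n_free, [cfg.chrom_lengths[c] for c in chroms])

    chrom_col: list[str] = []
    pos_col: list[np.ndarray] = []
    signal_col: list[np.ndarray] = []
    for chrom, k in zip(chroms, counts):
        lead_pos = lead_by_chrom[chrom]
        pos = _unique_positions(pos_rng, k, cfg.chrom_lengths[chrom], lead_pos)
        pos = np.sort(np.concatenate([pos, lead_pos]))
        if lead_pos.size:
            idx = np.searchsorted(lead_pos, pos)
            left = np.abs(pos - lead_pos[np.clip(idx - 1, 0, lead_pos.size - 1)])
            right = np.abs(lead_pos[np.clip(idx, 0, lead_pos.size - 1)] - pos)
            dist = np.minimum(left, right)
        else:
            dist = np.full(pos.shape, np.iinfo(np.int64).max)
        signal = np.where(
            dist <= 3 * cfg.decay_bp,
            cfg.effect_scale * np.exp(-dist / cfg.decay_bp),
            0.0,
        )
        chrom_col.extend([chrom] * pos.size)
        pos_col.append(pos)
        signal_col.append(signal)

    pos_all = np.concatenate(pos_col)
    signal_all = np.concatenate(signal_col)
    n = pos_all.size
    base = pd.DataFrame({
        "chrom": chrom_col,
        "pos": pos_all,
        "rsid": [f"rs{i + 1}" for i in range(n)],
        "a1": "A",
        "a2": "G",
        "freq": meta_rng.uniform(0.05, 0.95, size=n),
    })

    waves = []
    for n_wave, noise in ((cfg.n1, noise1), (cfg.n2, noise2)):
        z = signal_all * np.sqrt(n_wave / cfg.n1) + noise.standard_normal(n)
        df = base.copy()
        df["effect"] = z / np.sqrt(n_wave)
        df["pvalue"] = 2.0 * stats.norm.sf(np.abs(z))
        waves.append(df[list(SUMSTAT_COLUMNS)])
    return waves[0], waves[1], leads


def make_nominations(
    gold_loci: Sequence[Locus],
    n_tp: int,
    n_fp: int,
    *,
    gwas1_loci: Sequence[Locus] = (),
    chrom_lengths: dict[str, int] | None = None,
    flank: int = 500_000,
    min_overlap: int = 250_000,
    seed: int = 0,
    method: str = "synthetic",
    max_tries: int = 10_000,
) -> NominationSet:
    """A nomination set of controlled composition.

    ``n_tp`` points are placed at the leads (or midpoints) of distinct gold
    loci and ``n_fp`` decoy points at least 2·flank + min_overlap away from
    every gold and earlier-wave locus and from each other, so the downstream
    window/classification pipeline returns exactly TP = n_tp, FP = n_fp,
    FN = |gold| − n_tp. Raises :class:`PlacementError` when the genome is
    too crowded to place the decoys.
    """
    if n_tp > len(gold_loci):
        raise ConfigurationError("n_tp exceeds the number of gold loci")
    chrom_lengths = chrom_lengths or dict(DEFAULT_CHROM_LENGTHS)
    rng = substream(seed, "nominations")

    chosen = rng.choice(len(gold_loci), size=n_tp, replace=False) if n_tp else []
    points: list[tuple[str, int]] = []
    for i in sorted(int(j) for j in np.asarray(chosen)):
        g = gold_loci[i]
        pos = g.lead_pos if g.lead_pos is not None else (g.start + g.end) // 2
        window = Locus(g.chrom, pos - flank, pos + flank)
        for other in gold_loci:
            if other is not g and overlap_length(window, other) >= min_overlap:
                raise PlacementError(
                    f"gold loci too close: window at {g.chrom}:{pos} also covers {other.key}"
                )
        points.append((g.chrom, pos))

    margin = 2 * flank + min_overlap
    avoid = list(gold_loci) + list(gwas1_loci)
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    decoys: list[tuple[str, int]] = []
    tries = 0
    while len(decoys) < n_fp:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n_fp} decoys after {max_tries} tries; genome too small"
            )
        chrom = str(rng.choice(chroms, p=weights))
        pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
        if any(l.chrom == chrom and l.start - margin <= pos <= l.end + margin
               for l in avoid):
            continue
        if any(c == chrom and abs(p - pos) < margin for c, p in decoys):
            continue
        decoys.append((chrom, pos))

    all_points = points + decoys
    items = pd.DataFrame(all_points, columns=["chrom", "pos"]).astype({"pos": np.int64})
    return NominationSet(method=method, level="variant", items=items)


# Impact-category order used by ``impact_probs``.
IMPACT_ORDER = ("loss_of_function", "moderate", "low", "other")


def simulate_annotations(
    records: pd.DataFrame,
    esnp_fraction: float = 0.1,
    impact_probs: Sequence[float] = (0.002, 0.01, 0.088, 0.9),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variant annotation table: impact category draws and eSNP flags.

    eSNPs receive an eQTL p-value drawn uniformly on the log10 scale over
    [1e-20, 1e-4], a deliberately left-skewed spread of clearly significant
    expression associations.
    """
    if not 0 < esnp_fraction < 1:
        raise ConfigurationError("esnp_fraction must lie in (0, 1)")
    probs = np.asarray(impact_probs, dtype=float)
    if probs.shape != (4,) or probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
        raise ConfigurationError("impact_probs must be a 4-vector of probabilities summing to 1")
    rng = substream(seed, "annotations")
    n = len(records)
    categories = rng.choice(IMPACT_ORDER, size=n, p=probs)
    is_esnp = rng.random(n) < esnp_fraction
    eqtl_p = np.full(n, np.nan)
    eqtl_p[is_esnp] = 10.0 ** rng.uniform(-20, -4, size=int(is_esnp.sum()))
    return pd.DataFrame({
        "chrom": records["chrom"].to_numpy(),
        "pos": records["pos"].to_numpy(),
        "impact_category": categories,
        "is_esnp": is_esnp,
        "eqtl_pvalue": eqtl_p,
    })


def simulate_gene_table(
    chrom_lengths: dict[str, int] | None = None,
    n_genes: int = 200,
    sig_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """A gene score table with a planted fraction of significant genes.

    Exactly ``round(n_genes * sig_fraction)`` genes receive a p-value below
    the Bonferroni threshold 0.05 / n_genes; the rest draw uniformly above
    it, so the Bonferroni-significant gold set equals the planted set. Genes
    are placed without overlap constraints — overlapping genes exercise the
    locus-merge rule downstream.
    """
    chrom_lengths = chrom_lengths or dict(DEFAULT_CHROM_LENGTHS)
    rng = substream(seed, "genes")
    chroms = sorted(chrom_lengths)
    counts = _allocate(n_genes, [chrom_lengths[c] for c in chroms])
    rows = []
    gene_idx = 0
    for chrom, k in zip(chroms, counts):
        length = chrom_lengths[chrom]
        starts = np.sort(rng.integers(1, max(2, length - 200_000), size=k))
        widths = rng.integers(2_000, 200_000, size=k)
        for s, w in zip(starts, widths):
            gene_idx += 1
            rows.append({
                "gene_id": f"ENSG{gene_idx:011d}",
                "symbol": f"GENE{gene_idx}",
                "chrom": chrom,
                "start": int(s),
                "end": int(min(s + w, length)),
            })
    df = pd.DataFrame(rows)
    n_sig = int(round(n_genes * sig_fraction))
    threshold = 0.05 / n_genes
    pvals = rng.uniform(threshold, 1.0, size=n_genes)
    sig_idx = rng.choice(n_genes, size=n_sig, replace=False)
    pvals[sig_idx] = 10.0 ** rng.uniform(np.log10(threshold) - 8,
                                         np.log10(threshold) - 0.5, size=n_sig)
    df["pvalue"] = pvals
    df["midpoint"] = (df["start"] + df["end"]) // 2
    return df
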