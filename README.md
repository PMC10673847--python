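# gwasbench

Wave-based benchmarking of GWAS locus-nomination methods.

When a genome-wide association study (GWAS) is underpowered, many methods
promise to "functionally weight" its summary statistics — using variant
annotation, pleiotropy, or eQTL evidence — and nominate trait-associated
loci the study itself could not call significant. `gwasbench` implements
the evaluation framework that judges such claims against what a later,
larger GWAS wave of the same trait actually found. It is written for
statistical geneticists who want to benchmark a nomination method (or an
ensemble of them) with nothing but delimited summary-statistics files.

## What it computes

Given two waves of summary statistics for one trait:

1. **Locus definition.** Significant loci in each wave are built stepwise:
   the smallest-p variant opens a ±500 kb window, absorbs every significant
   variant inside it, and the process repeats; overlapping windows merge,
   and any chromosome-6 locus touching the extended HLA/MHC region
   (chr6:25–35 Mb) collapses into a single locus. Intervals are 1-based and
   closed throughout.
2. **Gold standard.** Wave-2 loci with any overlap against wave-1 loci are
   removed: the truth set is what became significant *only* in the larger
   wave.
3. **Classification.** Each method's nominations (variants, genes, or loci)
   are filtered by the same wave-1 exclusion, windowed, and classified:
   a nominated locus is a true positive when it overlaps a gold locus by at
   least 250 kb. Sensitivity is computed from the gold side
   (SN = covered gold loci / all gold loci), positive predictive value from
   the nominated side (PPV = confirmed nominations / all nominations), and
   F1 = 2·SN·PPV/(SN+PPV). No true-negative-based metric is defined.
4. **Ranking and ensembles.** Methods are Olympic-ranked by best PPV per
   trait (ties share the worst rank; methods nominating nothing rank 18,
   below a PPV of 0) and aggregated by median rank; a stepwise
   loci-by-methods membership matrix supports UpSet-style intersection
   analysis and PPV-by-support curves.

Three nomination procedures ship built in — the suggestive band
(5×10⁻⁸ ≤ p < 10⁻⁵), per-annotation-category thresholds, and
weighted-Bonferroni eQTL prioritization with mean-one normalized weights
(p_w = p / w, w = √(−log₁₀ p_eQTL) for eSNPs) — plus generic Bonferroni
and Benjamini–Hochberg significance rules for external score tables. A
synthetic two-wave generator with planted causal loci makes every stage
testable offline. See `docs/methods.md` for the full model.

## Worked example

```python
import pathlib
from gwasbench.report import MethodSpec, RunConfig, run_full_evaluation
from gwasbench.simulate import SimConfig, simulate_two_wave_gwas, simulate_annotations
from gwasbench.sumstats import write_sumstats

d = pathlib.Path("demo"); d.mkdir(exist_ok=True)
wave1, wave2, truth = simulate_two_wave_gwas(SimConfig(seed=42))
write_sumstats(wave1, d / "wave1.tsv")
write_sumstats(wave2, d / "wave2.tsv")
simulate_annotations(wave1, seed=42).to_csv(d / "annotations.tsv", sep="\t", index=False)

cfg = RunConfig(
    trait="SYN", wave1=str(d / "wave1.tsv"), wave2=str(d / "wave2.tsv"),
    out_dir=str(d / "out"), annotations=str(d / "annotations.tsv"),
    methods=[MethodSpec(name="suggestive", kind="suggestive"),
             MethodSpec(name="sveinbjornsson", kind="sveinbjornsson"),
             MethodSpec(name="weighted_eqtl", kind="weighted_eqtl")],
)
bundle = run_full_evaluation(cfg)
print(bundle["metrics"].to_string(index=False))
```

prints

```
        method  n_nominated_points  n_nominated_loci  tp  fp  fn  gold_covered  sn  ppv  f1 quadrant
    suggestive                   8                 3   3   0   0             3 1.0  1.0 1.0        I
sveinbjornsson                   0                 0   0   0   3             0 0.0  NaN NaN     None
 weighted_eqtl                   0                 0   0   0   3             0 0.0  NaN NaN     None
```

The simulation planted six causal loci; wave 1 (n = 25,000) reached
significance at three of them, wave 2 (n = 100,000) at all six, so the
gold standard holds the three loci novel in wave 2. Eight wave-1 variants
sit in the suggestive band outside wave-1 loci; their merged windows cover
all three gold loci with nothing spurious (SN = PPV = F1 = 1, quadrant I).
The two stringent procedures nominate nothing at this effect size — their
cutoffs are tighter than genome-wide significance and everything passing
them lies inside already-excluded wave-1 loci — so they count three false
negatives, an undefined PPV, and are excluded from scatter reporting
(they would receive the bottom rank, 18, in a ranking table).

The same pipeline runs from the shell:

```bash
gwasbench simulate --out-dir demo --seed 42
gwasbench define-loci --sumstats demo/wave1.tsv --out demo/l1.tsv
gwasbench nominate --method suggestive --sumstats demo/wave1.tsv --out demo/nom.tsv
gwasbench evaluate --nominations demo/nom.tsv --gwas1 demo/l1.tsv \
    --gwas2 demo/l2.tsv --out-prefix demo/eval
gwasbench run-all --config run.yaml   # everything from a YAML run config
```

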