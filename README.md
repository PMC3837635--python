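# chipscore

Scoring transcription-factor (TF) target genes from ChIP-seq peak data.

Given a list of called peaks (summit position and intensity) and a gene
annotation, which genes does the profiled TF regulate?  `chipscore`
implements the full decision chain as a tested Python library with a thin
CLI: four **peak-to-gene assignment** strategies, six **scoring methods**,
and an **evaluation battery** that compares scorings by the overlap of
their top-*k* target lists with independent rankings (e.g. differential
expression after perturbing the TF).  A seeded simulator generates
synthetic genomes, peaks and perturbation expression, so the entire
pipeline is testable without any genomic downloads.

## Methods

Every method anchors on one representative TSS per gene (the most 5′
transcript start) and measures peak positions by their summit.  Signed
distance `d` is negative upstream of the TSS, positive downstream.

| method | assignment | score per gene |
|---|---|---|
| Binary | window ±5 kb | 1 if any peak in the window, else 0 |
| Linear | window ±L (50 kb) | Σᵢ (1 − \|dᵢ\|/L) |
| Ouyang (TFAS) | all peaks ≤ 1 Mb | Σₖ gₖ·exp(−\|dₖ\|/d₀), gₖ = peak intensity, d₀ = 5 kb |
| Cheng (TIP) | window ±10 kb | z-score of Σⱼ wⱼ·xᵢⱼ, where wⱼ is the mean binding profile around all TSSs and xᵢⱼ the gene's binned signal |
| Chen | closest peak | s(b) = max(0, 1 − E(b)/O(b)) at the nearest-peak distance bin b, with E(b) from uniform peak re-placement |
| ClosestGene | each peak → nearest TSS ≤ 1 Mb | Σₖ −ln(pₖ), pₖ = empirical fraction of all peak–TSS distances (strand-split upstream/downstream) at \|dₖ\| or closer |

Peaks with intensity above 200 are excluded on load; annotations are
restricted to protein-coding, miRNA and lincRNA genes on autosomes + chrX
(all configurable via `AnnotationFilter`).

Evaluation compares the top-500 genes of two rankings; ties at a discrete
cutoff (Binary) are resampled 1,000 times and the mean overlap reported.
Per ChIP-seq/expression pair, overlaps are normalised by subtracting the
across-method mean; a permutation null of two random k-lists (expected
overlap k²/N) yields z-scores.  Gene-density diagnostics and Fisher-exact
gene-set enrichment of top lists are included.

## Worked example

```python
from chipscore import (MethodConfig, ScoreTable, SimulationConfig,
                       make_ranked_list, score_all_methods,
                       simulate_experiment, topk_overlap)

data = simulate_experiment(SimulationConfig(seed=7))   # 5,000 genes, 500 true targets
tables = score_all_methods(data["genes"], data["peaks"], MethodConfig(rng_seed=7),
                           chrom_sizes=data["chrom_sizes"])
expr = ScoreTable(data["expression"].set_index("gene_id")["abs_log2fc"], "expression")
er = make_ranked_list(expr, 500)
for m, t in tables.items():
    print(m, topk_overlap(make_ranked_list(t, 500), er, 500, seed=7))
```

prints (a random pair of 500-lists would overlap by ≈ 50):

```
binary 147.4
linear 146.0
ouyang 206.0
cheng 189.0
chen 130.2
closestgene 256.0
```

i.e. on this simulated perturbation the intensity- and distance-aware
scorers recover far more of the expression-responsive genes in their top
500 than Binary or Chen, with ClosestGene ahead.  The `examples/`
directory has one narrative script per capability (scoring, evaluation,
the ClosestGene score anatomy, gene-density bias).

## Command line

```bash
chipscore simulate --seed 3 --out fixtures/          # synthetic GTF/narrowPeak/expression
chipscore score --peaks fixtures/peaks.narrowPeak \
                --annotation fixtures/annotation.gtf \
                --method all --out scores/           # six ranked score TSVs + manifest
chipscore evaluate --mode perturbation \
                   --scores scores/scores_linear.tsv ... \
                   --expression fixtures/expression.tsv --out report.tsv
```

All commands are deterministic given (inputs, config, seed); reruns
produce byte-identical score tables.

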