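"""Synthetic genomes, ChIP-seq peak sets and perturbation expression.

Generates seeded test data with the statistical structure the scoring
methods assume: a multi-chromosome genome whose TSS positions mix uniform
and clustered (gene-dense) placement; a designated subset of "true target"
genes that attract peaks at two-sided exponentially distributed distances
from their TSS, on top of a uniform background of non-functional peaks;
log-normal peak intensities truncated at the standard intensity cap; and
perturbation |log2 fold changes| elevated for true targets.

Everything is emitted in the same formats the loaders consume (gene
TSV/GTF, narrowPeak, expression TSV), so fixtures flow through the full
pipeline.  Identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import collapse_to_representative_tss, TRANSCRIPT_COLUMNS, PEAK_COLUMNS

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_peaks",
    "simulate_perturbation_expression",
    "simulate_experiment",
    "write_narrowpeak",
    "write_gtf",
    "write_expression_tsv",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults give a desk-scale genome (5 chromosomes x 20 Mb carrying
    5,000 genes, i.e. one gene per 20 kb) with moderate gene-density
    heterogeneity, 500 true targets each attracting ~3 peaks at
    exponentially distributed distances (5 kb scale, 60% upstream), a
    uniform peak background of 1 peak / 100 kb, log-normal intensities
    truncated at the 200 pileup cap, and a 2-unit |log2FC| shift for true
    targets over noise sd 0.5.
    """

    n_chroms: int = 5
    chrom_length: int = 20_000_000
    n_genes: int = 5_000
    gene_density_heterogeneity: float = 0.5
    n_true_targets: int = 500
    exponential_scale: float = 5_000.0
    upstream_fraction: float = 0.6
    background_peak_rate: float = 1e-5
    peaks_per_target: float = 3.0
    intensity_lognormal: tuple[float, float] = (3.0, 1.0)
    intensity_cap: float = 200.0
    truncate_intensity: bool = True
    fc_effect: float = 2.0
    fc_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_length, self.n_genes) < 1:
            raise ValueError("n_chroms, chrom_length and n_genes must be >= 1")
        for name in ("gene_density_heterogeneity", "upstream_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_true_targets", "background_peak_rate", "peaks_per_target",
                     "fc_effect", "fc_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_true_targets > self.n_genes:
            raise ValueError("n_true_targets exceeds n_genes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SimulationConfig field(s): {sorted(unknown)}")
        if "intensity_lognormal" in data:
            data["intensity_lognormal"] = tuple(data["intensity_lognormal"])
        return cls(**data)

    def chrom_sizes(self) -> dict[str, int]:
        return {str(i + 1): self.chrom_length for i in range(self.n_chroms)}


# margin kept free of TSSs at chromosome ends so transcripts fit
_EDGE_MARGIN = 10_000
_CLUSTER_SD = 100_000
_GENES_PER_CLUSTER = 50


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a transcript table (annotation) for a synthetic genome.

    TSS positions are a mixture of uniform placement and Gaussian clusters
    (the gene-dense regions), mixed by ``gene_density_heterogeneity``.
    Each gene gets 1-4 transcripts with distinct starts so that TSS
    collapsing is exercised; the most 5' start is the intended TSS.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = _EDGE_MARGIN, config.chrom_length - _EDGE_MARGIN
    if hi <= lo:
        raise ValueError("chrom_length too small for the edge margin")
    capacity = config.n_chroms * (hi - lo)
    if config.n_genes > capacity // 10:
        raise ValueError(
            f"cannot pack {config.n_genes} genes with distinct TSSs into "
            f"{config.n_chroms} x {config.chrom_length} bp")

    chroms = rng.integers(0, config.n_chroms, size=config.n_genes)
    n_clusters = max(1, config.n_genes // _GENES_PER_CLUSTER)
    centers_chrom = rng.integers(0, config.n_chroms, size=n_clusters)
    centers_pos = rng.integers(lo, hi, size=n_clusters)
    clustered = rng.random(config.n_genes) < config.gene_density_heterogeneity

    tss = np.empty(config.n_genes, dtype=np.int64)
    uniform_draws = rng.integers(lo, hi, size=config.n_genes)
    cluster_idx = rng.integers(0, n_clusters, size=config.n_genes)
    cluster_off = rng.normal(0.0, _CLUSTER_SD, size=config.n_genes)
    for i in range(config.n_genes):
        if clustered[i]:
            chroms[i] = centers_chrom[cluster_idx[i]]
            pos = int(np.clip(centers_pos[cluster_idx[i]] + cluster_off[i], lo, hi))
            tss[i] = pos
        else:
            tss[i] = uniform_draws[i]
    # resolve duplicate (chrom, tss) collisions by redrawing uniformly
    seen = set()
    for i in range(config.n_genes):
        while (int(chroms[i]), int(tss[i])) in seen:
            tss[i] = int(rng.integers(lo, hi))
        seen.add((int(chroms[i]), int(tss[i])))

    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    n_tx = rng.integers(1, 5, size=config.n_genes)
    width = config.n_genes and int(np.ceil(np.log10(config.n_genes + 1)))
    records = []
    for i in range(config.n_genes):
        gene_id = f"G{i:0{width}d}"
        chrom = str(int(chroms[i]) + 1)
        # alternative starts downstream of the representative TSS
        offsets = np.concatenate([[0], np.sort(rng.integers(1, 5_000, size=int(n_tx[i]) - 1))]) \
            if n_tx[i] > 1 else np.array([0])
        offsets = np.unique(offsets)
        length = int(rng.integers(1_000, 8_000))
        for j, off in enumerate(offsets):
            if strands[i] == "+":
                start = int(tss[i] + off)
                end = start + length
            else:
                end = int(tss[i] - off)
                start = max(1, end - length)
            records.append((f"G{i:0{width}d}.T{j}", gene_id, chrom, strands[i],
                            start, end, "protein_coding"))
    df = pd.DataFrame(records, columns=TRANSCRIPT_COLUMNS)
    return df.sort_values(["chrom", "start", "transcript_id"], kind="mergesort").reset_index(drop=True)


def pick_true_targets(genes: pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> list[str]:
    """Uniformly sample the set of true target gene ids."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ids = np.sort(genes["gene_id"].to_numpy())
    chosen = rng.choice(ids, size=config.n_true_targets, replace=False)
    return sorted(chosen)


def simulate_peaks(
    genes: pd.DataFrame,
    true_targets: list[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    with_origin: bool = False,
) -> pd.DataFrame:
    """Simulate a ChIP-seq peak set.

    Each true target attracts Poisson(``peaks_per_target``) peaks whose
    signed TSS distances follow a two-sided exponential
    (``exponential_scale``; ``upstream_fraction`` of mass upstream).
    Background peaks arrive uniformly at ``background_peak_rate`` per bp
    per chromosome.  Intensities are log-normal, truncated (clipped) at
    ``intensity_cap`` unless ``truncate_intensity`` is off.

    With ``with_origin`` the output gains an ``origin_gene`` column naming
    the target a peak was placed around ("" for background peaks) — ground
    truth for estimator-recovery checks.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    gene_idx = genes.set_index("gene_id")
    records = []  # (chrom, summit, origin)
    for gid in sorted(true_targets):
        row = gene_idx.loc[gid]
        n = int(rng.poisson(config.peaks_per_target))
        if n == 0:
            continue
        mags = rng.exponential(config.exponential_scale, size=n)
        upstream = rng.random(n) < config.upstream_fraction
        signed = np.where(upstream, -mags, mags)
        if row["strand"] == "+":
            summits = int(row["tss"]) + signed
        else:
            summits = int(row["tss"]) - signed
        for s in summits:
            s = int(np.clip(round(s), 1, config.chrom_length))
            records.append((str(row["chrom"]), s, gid))
    for c in range(config.n_chroms):
        n_bg = int(rng.poisson(config.background_peak_rate * config.chrom_length))
        for s in rng.integers(1, config.chrom_length + 1, size=n_bg):
            records.append((str(c + 1), int(s), ""))

    mu, sigma = config.intensity_lognormal
    intensities = rng.lognormal(mu, sigma, size=len(records))
    if config.truncate_intensity:
        intensities = np.minimum(intensities, config.intensity_cap)
    peaks = pd.DataFrame(records, columns=["chrom", "summit", "origin_gene"])
    peaks["intensity"] = intensities
    peaks = peaks.sort_values(["chrom", "summit", "origin_gene"],
                              kind="mergesort").reset_index(drop=True)
    peaks.insert(0, "peak_id", [f"P{i:06d}" for i in range(len(peaks))])
    cols = PEAK_COLUMNS + (["origin_gene"] if with_origin else [])
    return peaks[cols]


def simulate_perturbation_expression(
    genes: pd.DataFrame,
    true_targets: list[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate |log2 fold changes| of a TF perturbation experiment.

    Non-targets: |Normal(0, fc_noise_sd)|.  True targets:
    |Normal(fc_effect, fc_noise_sd)| — differential expression elevated by
    the perturbation of their regulator.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    is_target = genes["gene_id"].isin(set(true_targets)).to_numpy()
    mean = np.where(is_target, config.fc_effect, 0.0)
    fc = np.abs(rng.normal(mean, config.fc_noise_sd))
    return pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(), "abs_log2fc": fc})


def simulate_experiment(config: SimulationConfig) -> dict[str, object]:
    """One full synthetic study: annotation, genes, targets, peaks, expression.

    Sub-steps use decorrelated child seeds of ``config.seed``; the result
    is fully determined by the config.
    """
    transcripts = simulate_genome(config)
    genes = collapse_to_representative_tss(transcripts)
    targets = pick_true_targets(genes, config)
    peaks = simulate_peaks(genes, targets, config)
    expression = simulate_perturbation_expression(genes, targets, config)
    return {
        "transcripts": transcripts,
        "genes": genes,
        "true_targets": targets,
        "peaks": peaks,
        "expression": expression,
        "chrom_sizes": config.chrom_sizes(),
    }


# ---------------------------------------------------------------------------
# writers (formats the loaders consume)

def write_narrowpeak(peaks: pd.DataFrame, path: str | Path, peak_halfwidth: int = 100) -> None:
    """Write peaks as ENCODE narrowPeak; summit offset round-trips exactly."""
    with open(path, "w") as fh:
        for row in peaks.itertuples(index=False):
            start0 = max(0, row.summit - 1 - peak_halfwidth)
            end0 = row.summit - 1 + peak_halfwidth + 1
            offset = row.summit - 1 - start0
            fh.write(
                f"{row.chrom}\t{start0}\t{end0}\t{row.peak_id}\t0\t.\t"
                f"{row.intensity:.6g}\t-1\t-1\t{offset}\n"
            )


def write_gtf(transcripts: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in transcripts.itertuples(index=False):
            attrs = (
                f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}"; '
                f'gene_biotype "{row.biotype}";'
            )
            fh.write(
                f"{row.chrom}\tchipscore\ttranscript\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index=False)
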