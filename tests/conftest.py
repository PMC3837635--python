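"""Shared fixtures: small random genomes and independent brute-force oracles.

The oracle functions here deliberately use naive all-pairs loops over plain
Python records so they stay independent of the package's sorted-sweep
implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from chipscore.annotation import GENE_COLUMNS, PEAK_COLUMNS


def random_genes(rng: np.random.Generator, n: int, n_chroms: int = 3,
                 chrom_length: int = 5_000_000) -> pd.DataFrame:
    chroms = rng.integers(1, n_chroms + 1, size=n).astype(str)
    tss = rng.integers(1, chrom_length, size=n)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    df = pd.DataFrame({
        "gene_id": [f"g{i:04d}" for i in range(n)],
        "chrom": chroms, "strand": strand, "tss": tss.astype(np.int64),
    })
    return df[GENE_COLUMNS]


def random_peaks(rng: np.random.Generator, n: int, n_chroms: int = 3,
                 chrom_length: int = 5_000_000) -> pd.DataFrame:
    df = pd.DataFrame({
        "peak_id": [f"p{i:05d}" for i in range(n)],
        "chrom": rng.integers(1, n_chroms + 1, size=n).astype(str),
        "summit": rng.integers(1, chrom_length, size=n).astype(np.int64),
        "intensity": rng.lognormal(3, 1, size=n).clip(max=200),
    })
    return df[PEAK_COLUMNS]


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_instance(rng):
    """200 genes, 1,000 peaks — the standard oracle-equivalence instance."""
    return random_genes(rng, 200), random_peaks(rng, 1000)


# ---------------------------------------------------------------------------
# brute-force oracles

def oracle_signed_distance(summit: int, tss: int, strand: str) -> int:
    return summit - tss if strand == "+" else tss - summit


def oracle_pairs_within(genes: pd.DataFrame, peaks: pd.DataFrame, radius: int):
    """All (gene_id, peak_id, signed_distance) with |d| <= radius, any order."""
    out = []
    for g in genes.itertuples(index=False):
        for p in peaks.itertuples(index=False):
            if g.chrom != p.chrom:
                continue
            d = oracle_signed_distance(p.summit, g.tss, g.strand)
            if abs(d) <= radius:
                out.append((g.gene_id, p.peak_id, d))
    return sorted(out)


def oracle_closest_peak(genes: pd.DataFrame, peaks: pd.DataFrame):
    """gene_id -> (peak_id, signed_distance) by min |d| with the documented ties."""
    out = {}
    for g in genes.itertuples(index=False):
        best = None
        for p in peaks.itertuples(index=False):
            if g.chrom != p.chrom:
                continue
            d = oracle_signed_distance(p.summit, g.tss, g.strand)
            key = (abs(d), 0 if d < 0 else 1, p.peak_id)
            if best is None or key < best[0]:
                best = (key, p.peak_id, d)
        if best is not None:
            out[g.gene_id] = (best[1], best[2])
    return out


def oracle_closest_gene(genes: pd.DataFrame, peaks: pd.DataFrame, cap: int):
    """peak_id -> (gene_id, signed_distance) by min |d| within cap."""
    out = {}
    for p in peaks.itertuples(index=False):
        best = None
        for g in genes.itertuples(index=False):
            if g.chrom != p.chrom:
                continue
            d = oracle_signed_distance(p.summit, g.tss, g.strand)
            key = (abs(d), 0 if d < 0 else 1, g.gene_id)
            if best is None or key < best[0]:
                best = (key, g.gene_id, d)
        if best is not None and best[0][0] <= cap:
            out[p.peak_id] = (best[1], best[2])
    return out


def oracle_linear_scores(genes, peaks, L: int):
    scores = {}
    for g in genes.itertuples(index=False):
        total = 0.0
        for p in peaks.itertuples(index=False):
            if g.chrom != p.chrom:
                continue
            d = abs(oracle_signed_distance(p.summit, g.tss, g.strand))
            if d <= L:
                total += 1.0 - d / L
        scores[g.gene_id] = total
    return scores


def oracle_ouyang_scores(genes, peaks, d0: float, cap: int):
    scores = {}
    for g in genes.itertuples(index=False):
        total = 0.0
        for p in peaks.itertuples(index=False):
            if g.chrom != p.chrom:
                continue
            d = abs(oracle_signed_distance(p.summit, g.tss, g.strand))
            if d <= cap:
                total += p.intensity * math.exp(-d / d0)
        scores[g.gene_id] = total
    return scores


def oracle_distance_pool(genes, peaks, cap: int):
    """(upstream |d| list, downstream |d| list) over all pairs within cap."""
    up, down = [], []
    for g in genes.itertuples(index=False):
        for p in peaks.itertuples(index=False):
            if g.chrom != p.chrom:
                continue
            d = oracle_signed_distance(p.summit, g.tss, g.strand)
            if abs(d) > cap:
                continue
            (down if d >= 0 else up).append(abs(d))
    return sorted(up), sorted(down)


def oracle_closest_gene_scores(genes, peaks, cap: int):
    """ClosestGene scores via the all-pairs pool and per-peak -ln(CDF)."""
    up, down = oracle_distance_pool(genes, peaks, cap)
    assign = oracle_closest_gene(genes, peaks, cap)
    scores = {g: 0.0 for g in genes["gene_id"]}
    for peak_id, (gene_id, d) in assign.items():
        pool = up if d < 0 else down
        frac = sum(1 for x in pool if x <= abs(d)) / len(pool)
        scores[gene_id] += -math.log(frac)
    return scores
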