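"""Evaluation battery for TF-target scorings.

Scorings are compared through the overlap of their top-k genes (k = 500 by
default) with a reference ranking — differential expression after
perturbing the TF, a second ChIP-seq experiment for the same TF, or a
random null.  Discrete scores (Binary) can leave many genes tied at the
cutoff; the tied block is then resampled uniformly and the mean overlap
reported.  Per ChIP-seq/expression pair, overlaps are normalised by
subtracting the across-method mean so methods are compared relative to the
pair's difficulty.  A permutation null (two independent uniform k-subsets)
yields z-scores; its expected overlap is k²/N.

Also here: gene-density diagnostics (how gene-rich the neighbourhoods of a
method's top targets are) and generic Fisher-exact gene-set enrichment of
a top-k list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ScoreTable

__all__ = [
    "RankedList",
    "make_ranked_list",
    "topk_overlap",
    "normalize_overlaps",
    "permutation_null",
    "consistency_analysis",
    "gene_density",
    "gene_set_enrichment",
]

DEFAULT_K = 500


@dataclass
class RankedList:
    """Top-k selection from a score table, tie-aware.

    ``certain`` are genes strictly above the cutoff score; ``tie_block``
    the genes sharing the cutoff score, of which ``n_fill`` must be drawn
    to complete the top k.  When the cutoff is unambiguous, tie_block
    holds exactly n_fill genes.
    """

    order: list[str]
    k: int
    certain: frozenset[str]
    tie_block: frozenset[str]
    n_fill: int

    @property
    def has_ties(self) -> bool:
        return len(self.tie_block) > self.n_fill

    def top_set(self) -> frozenset[str]:
        if self.has_ties:
            raise ValueError("ambiguous top-k: cutoff score is tied; use topk_overlap")
        return self.certain | self.tie_block


def make_ranked_list(table: ScoreTable, k: int = DEFAULT_K) -> RankedList:
    """Rank genes (score desc, gene_id asc) and mark the cutoff tie block."""
    ranked = table.ranked()
    n = len(ranked)
    if k > n:
        raise ValueError(f"k={k} exceeds the gene universe ({n})")
    scores = ranked.to_numpy()
    ids = ranked.index.to_numpy()
    cutoff = scores[k - 1]
    certain = frozenset(ids[scores > cutoff])
    tie_block = frozenset(ids[scores == cutoff])
    return RankedList(list(ids), k, certain, tie_block, k - len(certain))


def _as_ranked(x: ScoreTable | RankedList, k: int) -> RankedList:
    return x if isinstance(x, RankedList) else make_ranked_list(x, k)


def topk_overlap(
    a: ScoreTable | RankedList,
    b: ScoreTable | RankedList,
    k: int = DEFAULT_K,
    tie_resamples: int = 1000,
    seed: int = 0,
) -> float:
    """Overlap of two top-k gene lists, resampling cutoff ties.

    If either list has more genes tied at its cutoff score than fit in the
    top k, the tied genes are drawn uniformly at random ``tie_resamples``
    times (seeded) and the mean overlap returned; otherwise the exact
    intersection size.
    """
    ra, rb = _as_ranked(a, k), _as_ranked(b, k)
    if ra.k != rb.k:
        raise ValueError("ranked lists built with different k")
    if not (ra.has_ties or rb.has_ties):
        return float(len(ra.top_set() & rb.top_set()))
    rng = np.random.default_rng(seed)
    tie_a = np.array(sorted(ra.tie_block))
    tie_b = np.array(sorted(rb.tie_block))
    total = 0.0
    for _ in range(tie_resamples):
        sa = ra.certain | set(rng.choice(tie_a, size=ra.n_fill, replace=False))
        sb = rb.certain | set(rng.choice(tie_b, size=rb.n_fill, replace=False))
        total += len(sa & sb)
    return total / tie_resamples


def normalize_overlaps(overlaps: dict[str, float]) -> dict[str, float]:
    """Subtract the across-method mean overlap for one dataset pair.

    The result measures how much better (or worse) than the average method
    each method did on that pair; values sum to zero.
    """
    if len(overlaps) < 2:
        raise ValueError("need at least two methods to normalise")
    mean = sum(overlaps.values()) / len(overlaps)
    return {m: v - mean for m, v in overlaps.items()}


def permutation_null(
    k: int,
    universe_size: int,
    resamples: int = 2000,
    seed: int = 0,
    observed: float | None = None,
) -> dict[str, float]:
    """Null distribution of the overlap of two random top-k lists.

    Draws two independent uniform k-subsets of an N-gene universe
    ``resamples`` times; returns the Monte-Carlo mean and sd (the analytic
    mean is k²/N) and, if ``observed`` is given, its z-score.  A zero-sd
    degenerate null (e.g. k = N) raises for the z-score.
    """
    if k > universe_size:
        raise ValueError(f"k={k} exceeds universe size {universe_size}")
    rng = np.random.default_rng(seed)
    counts = np.empty(resamples, dtype=np.int64)
    mask = np.zeros(universe_size, dtype=bool)
    for i in range(resamples):
        first = rng.choice(universe_size, size=k, replace=False)
        second = rng.choice(universe_size, size=k, replace=False)
        mask[first] = True
        counts[i] = int(mask[second].sum())
        mask[first] = False
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    out = {"mean": mean, "sd": sd, "n_resamples": float(resamples)}
    if observed is not None:
        if not sd > 0:
            raise ValueError("degenerate null (sd = 0): z-score undefined")
        out["z"] = (observed - mean) / sd
    return out


def consistency_analysis(
    tables: dict[str, ScoreTable],
    metadata: dict[str, tuple[str, str]],
    k: int = DEFAULT_K,
    tie_resamples: int = 1000,
    seed: int = 0,
) -> dict[str, object]:
    """Cross-experiment consistency of top-k target lists.

    ``metadata`` maps experiment id -> (tf, system).  All experiment pairs
    are compared by top-k overlap and partitioned into ``same_TF`` (same
    factor), ``same_system`` (different factor, same cellular system) and
    ``cross_system`` groups.  Adjacent groups are compared with two-sided
    Welch t-tests; a p-value is NaN when a group has fewer than two
    overlaps.

    Returns ``pairs`` (DataFrame: exp_a, exp_b, group, overlap),
    ``group_means`` and ``p_values``.
    """
    ids = sorted(tables)
    ranked = {e: make_ranked_list(tables[e], k) for e in ids}
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            tf_a, sys_a = metadata[a]
            tf_b, sys_b = metadata[b]
            if tf_a == tf_b:
                group = "same_TF"
            elif sys_a == sys_b:
                group = "same_system"
            else:
                group = "cross_system"
            ov = topk_overlap(ranked[a], ranked[b], k, tie_resamples, seed)
            rows.append((a, b, group, ov))
    pairs = pd.DataFrame(rows, columns=["exp_a", "exp_b", "group", "overlap"])
    group_means = {
        g: float(pairs.loc[pairs["group"] == g, "overlap"].mean())
        if (pairs["group"] == g).any() else float("nan")
        for g in ("same_TF", "same_system", "cross_system")
    }
    p_values = {}
    for ga, gb in (("same_TF", "same_system"), ("same_system", "cross_system")):
        xa = pairs.loc[pairs["group"] == ga, "overlap"].to_numpy()
        xb = pairs.loc[pairs["group"] == gb, "overlap"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            p_values[f"{ga}_vs_{gb}"] = float("nan")
        else:
            p_values[f"{ga}_vs_{gb}"] = float(
                stats.ttest_ind(xa, xb, equal_var=False).pvalue)
    return {"pairs": pairs, "group_means": group_means, "p_values": p_values}


def gene_density(
    genes: pd.DataFrame, targets: set[str] | list[str], region: int = 1_000_000
) -> pd.Series:
    """Number of genes within a ``region``-wide window around each target's TSS.

    The window is centred on the TSS (± region/2, boundaries inclusive)
    and the count includes the target itself.  High values flag targets in
    gene-dense neighbourhoods.
    """
    half = region // 2
    targets = set(targets)
    out = {}
    for chrom, gsub in genes.groupby("chrom", sort=True):
        tss = np.sort(gsub["tss"].to_numpy(dtype=np.int64))
        sub_targets = gsub[gsub["gene_id"].isin(targets)]
        for gene_id, t in zip(sub_targets["gene_id"], sub_targets["tss"]):
            lo = np.searchsorted(tss, t - half, side="left")
            hi = np.searchsorted(tss, t + half, side="right")
            out[gene_id] = hi - lo
    missing = targets - set(out)
    if missing:
        raise KeyError(f"target gene(s) not in annotation: {sorted(missing)[:5]}")
    return pd.Series(out, dtype=int).sort_index()


def gene_set_enrichment(
    top_genes: set[str] | frozenset[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each gene set in a top-k list.

    Each set is restricted to the universe and tested on the 2x2 table
    (in top-k x in set).  Sets disjoint from the universe are skipped with
    a warning.  Returns a DataFrame with per-set counts, odds ratio and
    enrichment p-value; ``significant`` marks p < ``p_threshold``.
    """
    universe = set(universe)
    top = set(top_genes) & universe
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        if not members:
            warnings.warn(f"gene set {name!r} is disjoint from the universe; skipped")
            continue
        a = len(top & members)
        b = len(top) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, len(members), float(odds), float(p), p < p_threshold))
    return pd.DataFrame(
        rows, columns=["set", "in_top", "set_size", "odds_ratio", "p_value", "significant"]
    )
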