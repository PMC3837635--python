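"""Peak-to-gene assignment strategies.

Four ways of deciding which ChIP-seq peaks a gene is scored on:

* ``window`` — every peak within a fixed symmetric window around the TSS
  (many-to-many; used by the Binary and Linear scores)
* ``all_peaks`` — every same-chromosome peak up to a distance cap
  (many-to-many; used by the TFAS/Ouyang score)
* ``closest_peak`` — each gene gets only its nearest peak (used by the
  Chen score)
* ``closest_gene`` — each peak is given to the gene with the nearest TSS,
  so a gene's peaks are exactly those closer to it than to any other gene
  (used by the ClosestGene score)

All distances are summit-to-representative-TSS and signed by the gene's
strand: negative = upstream (5'), positive = downstream (3').  Gene bodies
are never consulted.  Ties are broken deterministically: smaller |distance|
first, then upstream before downstream, then lexicographic id.

Each strategy runs as a sorted sweep per chromosome,
O((n + m) log(n + m)) in the number of genes and peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Assignment",
    "signed_distance",
    "signed_distances",
    "assign_window",
    "assign_all_peaks",
    "assign_closest_peak",
    "assign_closest_gene",
]

ASSIGNMENT_COLUMNS = ["gene_id", "peak_id", "distance"]


@dataclass(frozen=True)
class Assignment:
    """Result of one peak-to-gene assignment strategy.

    ``table`` has one row per (gene, peak) pair with the signed
    summit-to-TSS distance; ``strategy`` is one of ``window``,
    ``all_peaks``, ``closest_peak``, ``closest_gene``; ``cap`` is the
    half-width / distance cap in bp (None for closest_peak).
    """

    table: pd.DataFrame
    strategy: str
    cap: int | None

    def peaks_for(self, gene_id: str) -> pd.DataFrame:
        return self.table[self.table["gene_id"] == gene_id]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["strategy"] = self.strategy
        out.to_csv(path, sep="\t", index=False)


def signed_distance(summit: int, tss: int, strand: str) -> int:
    """Signed summit-to-TSS distance; negative = upstream of the TSS."""
    if strand == "+":
        return int(summit) - int(tss)
    if strand == "-":
        return int(tss) - int(summit)
    raise ValueError(f"unknown strand {strand!r}")


def signed_distances(summits: np.ndarray, tss: int, strand: str) -> np.ndarray:
    """Vectorised :func:`signed_distance` for one gene and many summits."""
    raw = np.asarray(summits, dtype=np.int64) - np.int64(tss)
    return raw if strand == "+" else -raw


def _sorted_peaks_by_chrom(peaks: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {}
    for chrom, sub in peaks.groupby("chrom", sort=True):
        out[chrom] = sub.sort_values(["summit", "peak_id"], kind="mergesort").reset_index(drop=True)
    return out


def _range_rows(left: np.ndarray, right: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-gene [left, right) index ranges into flat (gene_row, peak_row) pairs."""
    counts = right - left
    total = int(counts.sum())
    gene_rows = np.repeat(np.arange(left.size), counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    peak_rows = np.repeat(left, counts) + offsets
    return gene_rows, peak_rows


def _assign_within(genes: pd.DataFrame, peaks: pd.DataFrame, radius: int) -> pd.DataFrame:
    """All (gene, peak) pairs with |signed distance| <= radius (inclusive)."""
    parts = []
    by_chrom = _sorted_peaks_by_chrom(peaks)
    for chrom, gsub in genes.groupby("chrom", sort=True):
        psub = by_chrom.get(chrom)
        if psub is None:
            continue
        summits = psub["summit"].to_numpy(dtype=np.int64)
        tss = gsub["tss"].to_numpy(dtype=np.int64)
        left = np.searchsorted(summits, tss - radius, side="left")
        right = np.searchsorted(summits, tss + radius, side="right")
        gene_rows, peak_rows = _range_rows(left, right)
        if gene_rows.size == 0:
            continue
        raw = summits[peak_rows] - tss[gene_rows]
        sign = np.where(gsub["strand"].to_numpy()[gene_rows] == "+", 1, -1)
        parts.append(
            pd.DataFrame(
                {
                    "gene_id": gsub["gene_id"].to_numpy()[gene_rows],
                    "peak_id": psub["peak_id"].to_numpy()[peak_rows],
                    "distance": raw * sign,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=ASSIGNMENT_COLUMNS)
    table = pd.concat(parts, ignore_index=True)
    table["absd"] = table["distance"].abs()
    table = table.sort_values(["gene_id", "absd", "distance", "peak_id"], kind="mergesort")
    return table.drop(columns="absd").reset_index(drop=True)


def assign_window(genes: pd.DataFrame, peaks: pd.DataFrame, half_width: int) -> Assignment:
    """Assign to each gene the peaks within ±half_width of its TSS.

    Boundaries are inclusive; a peak may be assigned to several genes.
    """
    if not half_width > 0:
        raise ValueError("half_width must be positive")
    return Assignment(_assign_within(genes, peaks, int(half_width)), "window", int(half_width))


def assign_all_peaks(genes: pd.DataFrame, peaks: pd.DataFrame, cap: int = 1_000_000) -> Assignment:
    """Assign to each gene every same-chromosome peak within ``cap`` bp of its TSS."""
    if not cap > 0:
        raise ValueError("cap must be positive")
    return Assignment(_assign_within(genes, peaks, int(cap)), "all_peaks", int(cap))


def _nearest_candidates(
    positions: np.ndarray, ids: np.ndarray, query: int
) -> tuple[int, np.ndarray]:
    """Minimum |position - query| over a sorted array, with all argmins.

    Returns (min_distance, row_indices_of_all_candidates); `ids` is only
    used for its length.  Assumes positions non-empty.
    """
    pos = np.searchsorted(positions, query)
    dmin = None
    if pos > 0:
        dmin = query - positions[pos - 1]
    if pos < positions.size:
        d = positions[pos] - query
        dmin = d if dmin is None else min(dmin, d)
    cands = []
    for value in {query - dmin, query + dmin}:
        lo = np.searchsorted(positions, value, side="left")
        hi = np.searchsorted(positions, value, side="right")
        if hi > lo:
            cands.append(np.arange(lo, hi))
    return int(dmin), np.concatenate(cands)


def _tie_break(rows: np.ndarray, upstream: np.ndarray, ids: np.ndarray) -> int:
    """Pick one row: upstream before downstream, then lexicographic id."""
    order = sorted(range(rows.size), key=lambda i: (0 if upstream[i] else 1, ids[rows[i]]))
    return int(rows[order[0]])


def assign_closest_peak(genes: pd.DataFrame, peaks: pd.DataFrame) -> Assignment:
    """Assign to each gene its single nearest peak (by |summit - TSS|).

    Genes on peak-free chromosomes receive no peak.  Ties are broken
    upstream-first, then by peak_id.
    """
    by_chrom = _sorted_peaks_by_chrom(peaks)
    records = []
    for chrom, gsub in genes.groupby("chrom", sort=True):
        psub = by_chrom.get(chrom)
        if psub is None or psub.empty:
            continue
        summits = psub["summit"].to_numpy(dtype=np.int64)
        pids = psub["peak_id"].to_numpy()
        for gene_id, tss, strand in zip(gsub["gene_id"], gsub["tss"], gsub["strand"]):
            dmin, rows = _nearest_candidates(summits, pids, int(tss))
            dists = signed_distances(summits[rows], int(tss), strand)
            row = _tie_break(rows, dists < 0, pids) if rows.size > 1 else int(rows[0])
            d = signed_distance(int(summits[row]), int(tss), strand)
            records.append((gene_id, pids[row], d))
    table = pd.DataFrame(records, columns=ASSIGNMENT_COLUMNS)
    table = table.sort_values(["gene_id", "peak_id"], kind="mergesort").reset_index(drop=True)
    return Assignment(table, "closest_peak", None)


def assign_closest_gene(
    genes: pd.DataFrame, peaks: pd.DataFrame, cap: int = 1_000_000
) -> Assignment:
    """Assign each peak to the gene with the nearest representative TSS.

    Peaks whose nearest TSS is farther than ``cap`` are discarded, so each
    peak belongs to at most one gene and a gene's peak list contains
    exactly the peaks closer to it than to any other gene.  Equidistant
    genes are tie-broken upstream-relation first, then by gene_id.
    """
    if not cap > 0:
        raise ValueError("cap must be positive")
    records = []
    genes_by_chrom = {
        chrom: sub.sort_values(["tss", "gene_id"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in genes.groupby("chrom", sort=True)
    }
    for chrom, psub in peaks.groupby("chrom", sort=True):
        gsub = genes_by_chrom.get(chrom)
        if gsub is None or gsub.empty:
            continue
        tss = gsub["tss"].to_numpy(dtype=np.int64)
        gids = gsub["gene_id"].to_numpy()
        strands = gsub["strand"].to_numpy()
        for peak_id, summit in zip(psub["peak_id"], psub["summit"]):
            dmin, rows = _nearest_candidates(tss, gids, int(summit))
            if dmin > cap:
                continue
            if rows.size > 1:
                upstream = np.array(
                    [signed_distance(int(summit), int(tss[r]), strands[r]) < 0 for r in rows]
                )
                row = _tie_break(rows, upstream, gids)
            else:
                row = int(rows[0])
            d = signed_distance(int(summit), int(tss[row]), strands[row])
            records.append((gids[row], peak_id, d))
    table = pd.DataFrame(records, columns=ASSIGNMENT_COLUMNS)
    table = table.sort_values(["gene_id", "peak_id"], kind="mergesort").reset_index(drop=True)
    return Assignment(table, "closest_gene", int(cap))
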