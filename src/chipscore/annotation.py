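"""Gene annotation and peak I/O.

Parses gene annotations (GTF or a simple transcript TSV) and ChIP-seq peak
files (BED6, ENCODE narrowPeak, or a summit TSV), applies biotype /
chromosome / peak-intensity filters, and collapses transcripts to a single
representative TSS per gene (the most 5' transcript start with respect to
the gene's strand).

Coordinate conventions
----------------------
All internal coordinates are 1-based positions, matching GTF.  BED and
narrowPeak inputs (0-based, half-open) are converted on read: a narrowPeak
summit is ``start + offset + 1``; when no summit offset is available the
interval midpoint ``start + (end - start) // 2 + 1`` is used.  Distances are
differences of positions, so only consistency matters.

Chromosome names are normalised by stripping a leading ``chr`` prefix so
Ensembl- and UCSC-style annotations can be mixed.

In-memory containers are pandas DataFrames:

* transcripts: columns ``transcript_id, gene_id, chrom, strand, start, end,
  biotype`` (start/end 1-based inclusive)
* genes: columns ``gene_id, chrom, strand, tss``
* peaks: columns ``peak_id, chrom, summit, intensity``
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationFilter",
    "DEFAULT_BIOTYPES",
    "TRANSCRIPT_COLUMNS",
    "GENE_COLUMNS",
    "PEAK_COLUMNS",
    "normalize_chrom",
    "load_transcripts",
    "collapse_to_representative_tss",
    "load_peaks",
    "write_genes_tsv",
    "read_genes_tsv",
    "write_peaks_tsv",
    "read_peaks_tsv",
]

TRANSCRIPT_COLUMNS = ["transcript_id", "gene_id", "chrom", "strand", "start", "end", "biotype"]
GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss"]
PEAK_COLUMNS = ["peak_id", "chrom", "summit", "intensity"]

DEFAULT_BIOTYPES = frozenset({"protein_coding", "miRNA", "lincRNA"})

#: autosome or chrX after ``chr``-prefix stripping
_AUTOSOME_OR_X = re.compile(r"^(\d+|X)$")

_VALID_STRANDS = {"+", "-"}


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix (Ensembl vs UCSC dialects)."""
    name = str(name)
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class AnnotationFilter:
    """Filters applied when loading annotations and peaks.

    Parameters
    ----------
    allowed_biotypes
        Transcript biotypes kept.  Default: protein-coding, miRNA and
        lincRNA genes.
    allowed_chroms
        Chromosomes kept (names compared after ``chr`` stripping).  ``None``
        means the default whitelist: autosomes and chromosome X.
    intensity_cap
        Peaks with intensity strictly above this pileup height are dropped
        (default 200); extreme pileups are typically mapping artifacts.
    """

    allowed_biotypes: frozenset[str] = DEFAULT_BIOTYPES
    allowed_chroms: frozenset[str] | None = None
    intensity_cap: float = 200.0

    def __post_init__(self) -> None:
        if not self.allowed_biotypes:
            raise ValueError("allowed_biotypes must be non-empty")
        if self.allowed_chroms is not None and not self.allowed_chroms:
            raise ValueError("allowed_chroms must be non-empty or None")
        if not self.intensity_cap > 0:
            raise ValueError("intensity_cap must be positive")

    def chrom_allowed(self, chrom: str) -> bool:
        name = normalize_chrom(chrom)
        if self.allowed_chroms is None:
            return bool(_AUTOSOME_OR_X.match(name))
        return name in {normalize_chrom(c) for c in self.allowed_chroms}


def _check_strands(strands: pd.Series, path: str) -> None:
    bad = set(strands.unique()) - _VALID_STRANDS
    if bad:
        raise ValueError(f"{path}: unknown strand symbol(s) {sorted(bad)!r}; expected '+' or '-'")


def load_transcripts(path: str | Path, filt: AnnotationFilter | None = None) -> pd.DataFrame:
    """Load transcripts from a GTF file or the documented TSV dialect.

    The TSV dialect has a header line with the columns
    ``transcript_id gene_id chrom strand start end biotype`` (1-based
    inclusive coordinates).  GTF ``transcript`` features are read with their
    ``gene_id``, ``transcript_id`` and ``gene_biotype`` attributes.

    Returns a DataFrame with :data:`TRANSCRIPT_COLUMNS`, restricted to the
    filter's biotype and chromosome whitelists and sorted by
    (chrom, start, transcript_id) for deterministic downstream order.
    """
    filt = filt or AnnotationFilter()
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        df = _read_gtf_transcripts(path)
    else:
        df = _read_transcript_tsv(path)

    _check_strands(df["strand"], str(path))
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "transcript_id"].tolist()
        raise ValueError(f"{path}: start > end for transcript(s) {bad}")

    df["chrom"] = df["chrom"].map(normalize_chrom)
    keep = df["biotype"].isin(filt.allowed_biotypes) & df["chrom"].map(filt.chrom_allowed)
    df = df.loc[keep]
    df = df.sort_values(["chrom", "start", "transcript_id"], kind="mergesort")
    return df.reset_index(drop=True)[TRANSCRIPT_COLUMNS]


def _read_gtf_transcripts(path: Path) -> pd.DataFrame:
    import pyranges as pr

    gr = pr.read_gtf(str(path))
    df = gr.df
    for col in ("gene_id", "transcript_id", "gene_biotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: GTF lacks required attribute '{col}'")
    df = df[df["Feature"] == "transcript"]
    if df.empty:
        raise ValueError(f"{path}: no 'transcript' features in GTF")
    # pyranges stores Start 0-based half-open; restore the GTF 1-based start
    return pd.DataFrame(
        {
            "transcript_id": df["transcript_id"].astype(str).to_numpy(),
            "gene_id": df["gene_id"].astype(str).to_numpy(),
            "chrom": df["Chromosome"].astype(str).to_numpy(),
            "strand": df["Strand"].astype(str).to_numpy(),
            "start": df["Start"].to_numpy(dtype=np.int64) + 1,
            "end": df["End"].to_numpy(dtype=np.int64),
            "biotype": df["gene_biotype"].astype(str).to_numpy(),
        }
    )


def _read_transcript_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: could not parse transcript TSV: {exc}") from exc
    missing = set(TRANSCRIPT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: transcript TSV missing column(s) {sorted(missing)}")
    for col, line_based in (("start", True), ("end", True)):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            lineno = int(vals.index[vals.isna()][0]) + 2  # +1 header, +1 1-based
            raise ValueError(f"{path}: malformed {col} at line {lineno}")
        df[col] = vals.astype(np.int64)
    df["transcript_id"] = df["transcript_id"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    return df[TRANSCRIPT_COLUMNS]


def collapse_to_representative_tss(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Collapse transcripts to one representative TSS per gene.

    The representative TSS is the most 5' transcript start with respect to
    the gene's strand: min(start) on ``+``, max(end) on ``-``.  Every
    transcript of a gene must share chromosome and strand.

    Returns a gene DataFrame (:data:`GENE_COLUMNS`) sorted by
    (chrom, tss, gene_id).
    """
    if transcripts.empty:
        return pd.DataFrame(columns=GENE_COLUMNS)
    grouped = transcripts.groupby("gene_id", sort=True)
    n_chrom = grouped["chrom"].nunique()
    n_strand = grouped["strand"].nunique()
    mixed = sorted(set(n_chrom[n_chrom > 1].index) | set(n_strand[n_strand > 1].index))
    if mixed:
        raise ValueError(f"gene(s) with transcripts on mixed chromosomes/strands: {mixed}")

    first = grouped.agg(chrom=("chrom", "first"), strand=("strand", "first"))
    min_start = grouped["start"].min()
    max_end = grouped["end"].max()
    tss = min_start.where(first["strand"] == "+", max_end)
    genes = pd.DataFrame(
        {
            "gene_id": first.index,
            "chrom": first["chrom"].to_numpy(),
            "strand": first["strand"].to_numpy(),
            "tss": tss.to_numpy(dtype=np.int64),
        }
    )
    genes = genes.sort_values(["chrom", "tss", "gene_id"], kind="mergesort")
    return genes.reset_index(drop=True)


def load_peaks(
    path: str | Path,
    filt: AnnotationFilter | None = None,
    *,
    tsv_intensity_column: str = "intensity",
) -> pd.DataFrame:
    """Load ChIP-seq peaks from narrowPeak, BED6 or a summit TSV.

    File kind is chosen by extension: ``.narrowPeak`` (summit = start +
    column-10 offset, falling back to the midpoint when the offset is -1;
    intensity = signalValue), ``.bed`` (summit = interval midpoint,
    intensity = score column), anything else the TSV dialect with header
    ``peak_id chrom summit intensity`` (summit already 1-based).

    Peaks with intensity above ``filt.intensity_cap`` and peaks on
    non-whitelisted chromosomes are dropped.  Output is sorted by
    (chrom, summit, peak_id).
    """
    filt = filt or AnnotationFilter()
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".narrowpeak":
        df = _read_narrowpeak(path)
    elif suffix == ".bed":
        df = _read_bed_peaks(path)
    else:
        df = _read_peak_tsv(path, tsv_intensity_column)

    if (df["summit"] < 0).any():
        raise ValueError(f"{path}: negative summit coordinate")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    keep = (df["intensity"] <= filt.intensity_cap) & df["chrom"].map(filt.chrom_allowed)
    df = df.loc[keep]
    df = df.sort_values(["chrom", "summit", "peak_id"], kind="mergesort")
    return df.reset_index(drop=True)[PEAK_COLUMNS]


def _validate_bed_intervals(df: pd.DataFrame, path: Path) -> None:
    if (df["start"] < 0).any():
        lineno = int(df.index[df["start"] < 0][0]) + 1
        raise ValueError(f"{path}: negative coordinate at line {lineno}")
    if (df["end"] < df["start"]).any():
        lineno = int(df.index[df["end"] < df["start"]][0]) + 1
        raise ValueError(f"{path}: end < start at line {lineno}")


def _read_narrowpeak(path: Path) -> pd.DataFrame:
    names = [
        "chrom", "start", "end", "name", "score",
        "strand", "signalValue", "pValue", "qValue", "peak",
    ]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    except Exception as exc:
        raise ValueError(f"{path}: could not parse narrowPeak: {exc}") from exc
    if df["peak"].isna().any() or df["signalValue"].isna().any():
        raise ValueError(f"{path}: narrowPeak requires 10 columns")
    _validate_bed_intervals(df, path)
    offset = df["peak"].to_numpy(dtype=np.int64)
    start = df["start"].to_numpy(dtype=np.int64)
    end = df["end"].to_numpy(dtype=np.int64)
    midpoint = start + (end - start) // 2
    summit0 = np.where(offset >= 0, start + offset, midpoint)
    return pd.DataFrame(
        {
            "peak_id": df["name"].astype(str).to_numpy(),
            "chrom": df["chrom"].to_numpy(),
            "summit": summit0 + 1,
            "intensity": df["signalValue"].to_numpy(dtype=float),
        }
    )


def _read_bed_peaks(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
        df = df.iloc[:, :5]
        df.columns = ["chrom", "start", "end", "name", "score"]
    except Exception as exc:
        raise ValueError(f"{path}: could not parse BED: {exc}") from exc
    if df["score"].isna().any():
        raise ValueError(f"{path}: BED peaks require 5 columns (score carries intensity)")
    _validate_bed_intervals(df, path)
    start = df["start"].to_numpy(dtype=np.int64)
    end = df["end"].to_numpy(dtype=np.int64)
    return pd.DataFrame(
        {
            "peak_id": df["name"].astype(str).to_numpy(),
            "chrom": df["chrom"].to_numpy(),
            "summit": start + (end - start) // 2 + 1,
            "intensity": df["score"].to_numpy(dtype=float),
        }
    )


def _read_peak_tsv(path: Path, intensity_column: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    except Exception as exc:
        raise ValueError(f"{path}: could not parse peak TSV: {exc}") from exc
    required = {"peak_id", "chrom", "summit", intensity_column}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: peak TSV missing column(s) {sorted(missing)}")
    out = pd.DataFrame(
        {
            "peak_id": df["peak_id"].astype(str),
            "chrom": df["chrom"],
            "summit": pd.to_numeric(df["summit"]).astype(np.int64),
            "intensity": pd.to_numeric(df[intensity_column]).astype(float),
        }
    )
    return out


def write_genes_tsv(genes: pd.DataFrame, path: str | Path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene TSV missing column(s) {sorted(missing)}")
    df["tss"] = df["tss"].astype(np.int64)
    return df[GENE_COLUMNS]


def write_peaks_tsv(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_peaks_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "peak_id": str})
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: peak TSV missing column(s) {sorted(missing)}")
    df["summit"] = df["summit"].astype(np.int64)
    df["intensity"] = df["intensity"].astype(float)
    return df[PEAK_COLUMNS]
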