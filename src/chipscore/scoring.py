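"""TF-gene association scores.

Six ways of turning a peak-to-gene assignment into a per-gene score of how
strongly a transcription factor is associated with each gene:

========  ==================  =============================================
method    assignment          score
========  ==================  =============================================
binary    window ±5 kb        1 if any peak in the window, else 0
linear    window ±50 kb       sum of (1 - |d|/L) over peaks in the window
ouyang    all peaks ≤ 1 Mb    TFAS: sum of intensity * exp(-|d|/d0)
cheng     window ±10 kb       TIP: z-score of the profile-weighted signal
chen      closest peak        non-random-binding proportion at the
                              nearest-peak distance bin
closestgene  closest gene     sum of -ln(p) over assigned peaks, p the
          ≤ 1 Mb              empirical fraction of all peak-TSS distances
                              at or below the peak's distance (strand-split
                              upstream / downstream)
========  ==================  =============================================

Every gene of the annotation appears in every score table; genes without
assigned peaks score 0 (cheng scores are z-scores and may be negative).
Rankings sort by score descending with gene_id as the deterministic
tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
import hashlib

import numpy as np
import pandas as pd
import yaml

from .assignment import Assignment, assign_closest_peak, signed_distances

__all__ = [
    "MethodConfig",
    "ScoreTable",
    "DistanceDistribution",
    "TssProfile",
    "NearestDistanceModel",
    "METHODS",
    "score_binary",
    "score_linear",
    "score_ouyang",
    "build_tss_profile",
    "score_cheng",
    "fit_nearest_distance_model",
    "score_chen",
    "build_distance_distribution",
    "score_closest_gene",
    "score_all_methods",
]

METHODS = ("binary", "linear", "ouyang", "cheng", "chen", "closestgene")

DEFAULT_CHEN_BINS = (0, 100, 500, 1_000, 2_000, 5_000, 10_000, 20_000, 50_000, 100_000, 500_000, 1_000_000)


@dataclass(frozen=True)
class MethodConfig:
    """Tunable parameters of the six scoring methods (all lengths in bp).

    ``ouyang_d0`` is the TFAS exponential decay constant and is
    experiment-specific in practice (e.g. 500 bp for E2F1 versus the
    5 kb default); override it per experiment via configuration, never in
    code.  ``chen_bins`` are the nearest-peak distance bin edges of the
    Chen non-random-binding model; ``chen_shuffles`` uniform re-placements
    of the peak summits estimate its random expectation.
    """

    binary_half_width: int = 5_000
    linear_half_width: int = 50_000
    ouyang_d0: float = 5_000.0
    ouyang_cap: int = 1_000_000
    cheng_half_width: int = 10_000
    cheng_bin: int = 100
    cheng_kernel_width: int = 200
    closestgene_cap: int = 1_000_000
    chen_bins: tuple[int, ...] = DEFAULT_CHEN_BINS
    chen_shuffles: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("binary_half_width", "linear_half_width", "ouyang_d0", "ouyang_cap",
                     "cheng_half_width", "cheng_bin", "closestgene_cap"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        edges = np.asarray(self.chen_bins)
        if edges[0] != 0 or not np.all(np.diff(edges) > 0):
            raise ValueError("chen_bins must be strictly increasing from 0")
        if self.chen_shuffles < 1:
            raise ValueError("chen_shuffles must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MethodConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown MethodConfig field(s): {sorted(unknown)}")
        if "chen_bins" in data:
            data["chen_bins"] = tuple(data["chen_bins"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ScoreTable:
    """Per-gene TF association scores for one (experiment, method) pair.

    ``scores`` is a float Series indexed by gene_id covering every gene of
    the annotation.  ``ranked`` orders genes by score descending, gene_id
    ascending.
    """

    scores: pd.Series
    method: str
    experiment: str = ""

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate gene_ids in score table")

    def ranked(self) -> pd.Series:
        df = self.scores.rename("score").reset_index().rename(columns={"index": "gene_id"})
        df.columns = ["gene_id", "score"]
        df = df.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
        return df.set_index("gene_id")["score"]

    def to_tsv(self, path: str | Path, config_hash: str = "") -> None:
        ranked = self.ranked()
        with open(path, "w") as fh:
            fh.write(f"# method: {self.method}\n")
            fh.write(f"# experiment: {self.experiment}\n")
            if config_hash:
                fh.write(f"# config: {config_hash}\n")
            fh.write("gene_id\tscore\trank\n")
            for rank, (gene_id, score) in enumerate(ranked.items(), start=1):
                fh.write(f"{gene_id}\t{score:.10g}\t{rank}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable":
        method = experiment = ""
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition(":")
                if key.strip() == "method":
                    method = value.strip()
                elif key.strip() == "experiment":
                    experiment = value.strip()
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
        return cls(df.set_index("gene_id")["score"], method=method, experiment=experiment)


def _full_scores(genes: pd.DataFrame, partial: pd.Series, fill: float = 0.0) -> pd.Series:
    idx = pd.Index(genes["gene_id"], name="gene_id")
    return partial.reindex(idx, fill_value=fill).astype(float)


def _require_strategy(assignment: Assignment, strategy: str, method: str) -> None:
    if assignment.strategy != strategy:
        raise ValueError(
            f"{method} requires a {strategy!r} assignment, got {assignment.strategy!r}"
        )


def score_binary(genes: pd.DataFrame, assignment: Assignment, experiment: str = "") -> ScoreTable:
    """Binary score: 1 if the gene has any peak within the ±5 kb window."""
    _require_strategy(assignment, "window", "binary")
    hit = assignment.table.groupby("gene_id").size() > 0
    return ScoreTable(_full_scores(genes, hit.astype(float)), "binary", experiment)


def score_linear(
    genes: pd.DataFrame, assignment: Assignment, experiment: str = ""
) -> ScoreTable:
    """Linear score: sum over window peaks of 1 - |d|/L.

    Weights fall linearly from 1 at the TSS to 0 at the window edge L
    (the assignment's half-width).
    """
    _require_strategy(assignment, "window", "linear")
    L = float(assignment.cap)
    tab = assignment.table
    if (tab["distance"].abs() > L).any():
        raise ValueError("assignment contains peaks beyond the linear window")
    weights = 1.0 - tab["distance"].abs() / L
    scores = weights.groupby(tab["gene_id"]).sum()
    return ScoreTable(_full_scores(genes, scores), "linear", experiment)


def score_ouyang(
    genes: pd.DataFrame,
    assignment: Assignment,
    peaks: pd.DataFrame,
    config: MethodConfig | None = None,
    experiment: str = "",
) -> ScoreTable:
    """TF association strength (TFAS): intensity-weighted exponential decay.

    score(g) = sum_k g_k * exp(-|d_k| / d0) over the gene's assigned peaks,
    where g_k is the peak intensity and d0 the decay constant.
    """
    config = config or MethodConfig()
    _require_strategy(assignment, "all_peaks", "ouyang")
    tab = assignment.table
    intensity = peaks.set_index("peak_id")["intensity"]
    if tab["peak_id"].isin(intensity.index).sum() < len(tab):
        missing = set(tab["peak_id"]) - set(intensity.index)
        raise ValueError(f"peaks missing intensity: {sorted(missing)[:5]}")
    tab = tab[tab["distance"].abs() <= config.ouyang_cap]
    g = intensity.loc[tab["peak_id"]].to_numpy(dtype=float)
    contrib = g * np.exp(-tab["distance"].abs().to_numpy(dtype=float) / config.ouyang_d0)
    scores = pd.Series(contrib).groupby(tab["gene_id"].to_numpy()).sum()
    return ScoreTable(_full_scores(genes, scores), "ouyang", experiment)


# ---------------------------------------------------------------------------
# Cheng (TIP)

@dataclass
class TssProfile:
    """Average binding profile around TSSs and per-gene binned signal.

    ``signal`` is the genes x bins matrix of binned coverage, bin order
    always 5'→3' (minus-strand genes are flipped).  ``weights`` is the
    across-gene mean profile normalised to sum to 1.
    """

    gene_ids: np.ndarray
    signal: np.ndarray
    weights: np.ndarray
    half_width: int
    bin_size: int


def _bin_peak_kernel(
    gsub: pd.DataFrame, psub: pd.DataFrame, half_width: int, bin_size: int, kernel_width: int
) -> np.ndarray:
    """Mean reconstructed pileup per bin: rectangular kernel around summits."""
    n_bins = 2 * half_width // bin_size
    out = np.zeros((len(gsub), n_bins))
    if psub is None or psub.empty:
        return out
    summits = psub["summit"].to_numpy(dtype=np.int64)
    heights = psub["intensity"].to_numpy(dtype=float)
    order = np.argsort(summits, kind="stable")
    summits, heights = summits[order], heights[order]
    half_k = kernel_width // 2
    for i, (tss, strand) in enumerate(zip(gsub["tss"], gsub["strand"])):
        lo = np.searchsorted(summits, tss - half_width - half_k)
        hi = np.searchsorted(summits, tss + half_width + half_k, side="right")
        for s, h in zip(summits[lo:hi], heights[lo:hi]):
            # rectangular kernel occupies [s - half_k, s + half_k) on the genome
            rel_lo, rel_hi = s - half_k - tss, s + half_k - tss
            if strand == "-":
                rel_lo, rel_hi = -rel_hi, -rel_lo
            b_lo = max(0.0, (rel_lo + half_width) / bin_size)
            b_hi = min(float(n_bins), (rel_hi + half_width) / bin_size)
            if b_hi <= b_lo:
                continue
            first, last = int(np.floor(b_lo)), int(np.ceil(b_hi))
            for b in range(first, last):
                overlap = min(b + 1, b_hi) - max(b, b_lo)  # in bin units
                out[i, b] += h * overlap
    return out


def _bin_coverage(
    gsub: pd.DataFrame, cov: pd.DataFrame, half_width: int, bin_size: int
) -> np.ndarray:
    """Mean per-base coverage per bin from bedGraph-style intervals.

    ``cov`` columns: start (0-based), end (half-open), value; one chromosome.
    """
    n_bins = 2 * half_width // bin_size
    out = np.zeros((len(gsub), n_bins))
    if cov is None or cov.empty:
        return out
    cov = cov.sort_values("start", kind="mergesort")
    starts = cov["start"].to_numpy(dtype=np.int64)
    ends = cov["end"].to_numpy(dtype=np.int64)
    values = cov["value"].to_numpy(dtype=float)
    for i, (tss, strand) in enumerate(zip(gsub["tss"], gsub["strand"])):
        # window in 0-based genome coordinates
        win_lo, win_hi = tss - 1 - half_width, tss - 1 + half_width
        lo = np.searchsorted(ends, win_lo, side="right")
        hi = np.searchsorted(starts, win_hi, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            s, e = max(s, win_lo), min(e, win_hi)
            if e <= s:
                continue
            rel_lo, rel_hi = s - (tss - 1), e - (tss - 1)
            if strand == "-":
                rel_lo, rel_hi = -rel_hi, -rel_lo
            b_lo = (rel_lo + half_width) / bin_size
            b_hi = (rel_hi + half_width) / bin_size
            first, last = int(np.floor(b_lo)), int(np.ceil(b_hi))
            for b in range(max(first, 0), min(last, n_bins)):
                overlap = min(b + 1, b_hi) - max(b, b_lo)
                out[i, b] += v * overlap * bin_size
    return out / bin_size


def build_tss_profile(
    genes: pd.DataFrame,
    peaks: pd.DataFrame | None = None,
    coverage: pd.DataFrame | None = None,
    config: MethodConfig | None = None,
) -> TssProfile:
    """Build the TIP binding profile around all TSSs.

    The signal source is binned coverage (bedGraph DataFrame with columns
    ``chrom, start, end, value``) when given, else a pileup reconstructed
    from peaks with a rectangular kernel (``cheng_kernel_width`` wide,
    height = intensity) centred on each summit.  Minus-strand genes are
    orientation-flipped so bins always run 5'→3'.  The profile weights are
    the across-gene mean signal per bin, normalised to sum to 1.
    """
    config = config or MethodConfig()
    if coverage is None and peaks is None:
        raise ValueError("need peaks or coverage")
    half_width, bin_size = config.cheng_half_width, config.cheng_bin
    blocks = []
    gene_ids = []
    for chrom, gsub in genes.groupby("chrom", sort=True):
        gsub = gsub.sort_values(["tss", "gene_id"], kind="mergesort")
        if coverage is not None:
            sub = coverage[coverage["chrom"] == chrom]
            block = _bin_coverage(gsub, sub, half_width, bin_size)
        else:
            sub = peaks[peaks["chrom"] == chrom]
            block = _bin_peak_kernel(gsub, sub, half_width, bin_size, config.cheng_kernel_width)
        blocks.append(block)
        gene_ids.extend(gsub["gene_id"])
    signal = np.vstack(blocks) if blocks else np.zeros((0, 2 * half_width // bin_size))
    col_means = signal.mean(axis=0) if signal.size else np.array([])
    total = col_means.sum()
    if not total > 0:
        raise ValueError("total signal is zero; TSS profile undefined")
    return TssProfile(
        gene_ids=np.asarray(gene_ids, dtype=object),
        signal=signal,
        weights=col_means / total,
        half_width=half_width,
        bin_size=bin_size,
    )


def score_cheng(profile: TssProfile, experiment: str = "") -> ScoreTable:
    """TIP score: z-standardised profile-weighted signal.

    Raw score s_i = sum_j w_j x_ij; the reported score is
    z_i = (s_i - mean(s)) / sd(s) with the sample standard deviation.
    Negative z-scores are kept; ranking is score-descending regardless.
    """
    s = profile.signal @ profile.weights
    sd = s.std(ddof=1) if s.size > 1 else 0.0
    if not sd > 0:
        raise ValueError("degenerate TIP scores: zero standard deviation")
    z = (s - s.mean()) / sd
    return ScoreTable(pd.Series(z, index=pd.Index(profile.gene_ids, name="gene_id")),
                      "cheng", experiment)


# ---------------------------------------------------------------------------
# Chen

@dataclass
class NearestDistanceModel:
    """Non-random-binding proportions by nearest-peak distance bin.

    For each distance bin b: O(b) = observed number of genes whose nearest
    peak summit lies at that |distance|; E(b) = the same count averaged
    over uniform re-placements of the peak summits; the bin score is
    s(b) = max(0, 1 - E(b)/O(b)) — the estimated fraction of genes in the
    bin whose nearest peak is not there by chance.
    """

    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    scores: np.ndarray

    def score_for_distance(self, distance: float) -> float:
        b = _distance_bin(self.bin_edges, abs(distance))
        return float(self.scores[b]) if b is not None else 0.0


def _distance_bin(edges: np.ndarray, d: float) -> int | None:
    """Bin index for |distance| d; bins are [e_b, e_{b+1}), last bin closed."""
    if d < edges[0] or d > edges[-1]:
        return None
    b = int(np.searchsorted(edges, d, side="right")) - 1
    return min(b, len(edges) - 2)


def _nearest_abs_distances(genes: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """|distance| from each gene's TSS to its nearest same-chromosome summit."""
    out = []
    for chrom, gsub in genes.groupby("chrom", sort=True):
        summits = np.sort(peaks.loc[peaks["chrom"] == chrom, "summit"].to_numpy(dtype=np.int64))
        if summits.size == 0:
            continue
        tss = gsub["tss"].to_numpy(dtype=np.int64)
        pos = np.searchsorted(summits, tss)
        left = np.where(pos > 0, tss - summits[np.maximum(pos - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(pos < summits.size, summits[np.minimum(pos, summits.size - 1)] - tss,
                         np.iinfo(np.int64).max)
        out.append(np.minimum(left, right))
    return np.concatenate(out) if out else np.array([], dtype=np.int64)


def fit_nearest_distance_model(
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    config: MethodConfig | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> NearestDistanceModel:
    """Fit the Chen non-random-binding model.

    Observed counts histogram the per-gene nearest-peak |distance| into
    ``chen_bins``.  Expected counts average the same histogram over
    ``chen_shuffles`` re-draws of the summits, uniform per chromosome with
    the real per-chromosome peak counts (seeded by ``rng_seed``).
    Chromosome lengths come from ``chrom_sizes`` when given, else from the
    largest coordinate seen on each chromosome.
    """
    config = config or MethodConfig()
    if peaks.empty:
        raise ValueError("no peaks: nearest-distance model undefined")
    edges = np.asarray(config.chen_bins, dtype=float)
    observed_d = _nearest_abs_distances(genes, peaks)
    observed, _ = np.histogram(observed_d, bins=edges)

    rng = np.random.default_rng(config.rng_seed)
    sizes = dict(chrom_sizes or {})
    per_chrom = peaks.groupby("chrom").size()
    for chrom, n in per_chrom.items():
        if chrom not in sizes:
            hi = int(peaks.loc[peaks["chrom"] == chrom, "summit"].max())
            gs = genes.loc[genes["chrom"] == chrom, "tss"]
            if len(gs):
                hi = max(hi, int(gs.max()))
            sizes[chrom] = hi
    acc = np.zeros(len(edges) - 1)
    for _ in range(config.chen_shuffles):
        parts = []
        for chrom, n in per_chrom.items():
            parts.append(pd.DataFrame({
                "chrom": chrom,
                "summit": rng.integers(1, sizes[chrom] + 1, size=int(n)),
            }))
        shuffled = pd.concat(parts, ignore_index=True)
        d = _nearest_abs_distances(genes, shuffled)
        hist, _ = np.histogram(d, bins=edges)
        acc += hist
    expected = acc / config.chen_shuffles

    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(observed > 0, np.maximum(0.0, 1.0 - expected / observed), 0.0)
    return NearestDistanceModel(edges, observed.astype(float), expected, scores)


def score_chen(
    genes: pd.DataFrame,
    assignment: Assignment,
    model: NearestDistanceModel,
    experiment: str = "",
) -> ScoreTable:
    """Chen score: the model's bin score at the gene's nearest-peak distance.

    Genes without a nearest peak inside the largest bin score 0.
    """
    _require_strategy(assignment, "closest_peak", "chen")
    tab = assignment.table
    scores = pd.Series(
        [model.score_for_distance(d) for d in tab["distance"]],
        index=pd.Index(tab["gene_id"], name="gene_id"),
        dtype=float,
    )
    return ScoreTable(_full_scores(genes, scores), "chen", experiment)


# ---------------------------------------------------------------------------
# ClosestGene

@dataclass
class DistanceDistribution:
    """Strand-split empirical peak-to-TSS distance distributions.

    Built from ALL peak-TSS pairs within the cap (not only assigned
    pairs), pooled across chromosomes; distance exactly 0 counts as
    downstream.  ``cdf(side, d)`` is the fraction of that side's pairs at
    |distance| <= d — never 0 at an observed distance.
    """

    upstream: np.ndarray  # sorted |distance|
    downstream: np.ndarray
    cap: int

    @property
    def n_upstream(self) -> int:
        return self.upstream.size

    @property
    def n_downstream(self) -> int:
        return self.downstream.size

    def cdf(self, side: str, d: float) -> float:
        arr = self.upstream if side == "upstream" else self.downstream
        return float(np.searchsorted(arr, d, side="right")) / arr.size

    def cdf_many(self, signed: np.ndarray) -> np.ndarray:
        signed = np.asarray(signed)
        absd = np.abs(signed)
        up = signed < 0
        out = np.empty(signed.size, dtype=float)
        out[up] = np.searchsorted(self.upstream, absd[up], side="right") / self.upstream.size
        out[~up] = np.searchsorted(self.downstream, absd[~up], side="right") / self.downstream.size
        return out


def build_distance_distribution(
    genes: pd.DataFrame, peaks: pd.DataFrame, cap: int = 1_000_000
) -> DistanceDistribution:
    """Empirical distance distributions from all peak-TSS pairs within ``cap``.

    Upstream pairs have signed distance in [-cap, 0), downstream in
    [0, +cap]; each side needs at least one pair.
    """
    if not cap > 0:
        raise ValueError("cap must be positive")
    up_parts, down_parts = [], []
    for chrom, gsub in genes.groupby("chrom", sort=True):
        summits = np.sort(peaks.loc[peaks["chrom"] == chrom, "summit"].to_numpy(dtype=np.int64))
        if summits.size == 0:
            continue
        for tss, strand in zip(gsub["tss"], gsub["strand"]):
            lo = np.searchsorted(summits, tss - cap)
            hi = np.searchsorted(summits, tss + cap, side="right")
            d = signed_distances(summits[lo:hi], int(tss), strand)
            up_parts.append(-d[d < 0])
            down_parts.append(d[d >= 0])
    upstream = np.sort(np.concatenate(up_parts)) if up_parts else np.array([])
    downstream = np.sort(np.concatenate(down_parts)) if down_parts else np.array([])
    for side, arr in (("upstream", upstream), ("downstream", downstream)):
        if arr.size == 0:
            raise ValueError(f"no peak-TSS pairs on the {side} side within the cap")
    return DistanceDistribution(upstream, downstream, int(cap))


def score_closest_gene(
    genes: pd.DataFrame,
    assignment: Assignment,
    dist: DistanceDistribution,
    experiment: str = "",
) -> ScoreTable:
    """ClosestGene score: sum over assigned peaks of -ln(p_k).

    p_k is the empirical fraction of all same-side peak-TSS distances at
    the peak's |distance| or closer — the probability of seeing a peak
    that close by chance.  The natural logarithm is used; genes without
    assigned peaks score 0.
    """
    _require_strategy(assignment, "closest_gene", "closestgene")
    tab = assignment.table
    if len(tab):
        if tab["distance"].abs().max() > dist.cap:
            raise ValueError("assignment contains peaks beyond the distance-distribution cap")
        p = dist.cdf_many(tab["distance"].to_numpy(dtype=np.int64))
        contrib = -np.log(p)
        scores = pd.Series(contrib).groupby(tab["gene_id"].to_numpy()).sum()
    else:
        scores = pd.Series(dtype=float)
    return ScoreTable(_full_scores(genes, scores), "closestgene", experiment)


# ---------------------------------------------------------------------------

def score_all_methods(
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    config: MethodConfig | None = None,
    experiment: str = "",
    coverage: pd.DataFrame | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> dict[str, ScoreTable]:
    """Run all six scoring methods on one experiment's peaks."""
    from .assignment import assign_window, assign_all_peaks, assign_closest_gene

    config = config or MethodConfig()
    out: dict[str, ScoreTable] = {}
    out["binary"] = score_binary(
        genes, assign_window(genes, peaks, config.binary_half_width), experiment)
    out["linear"] = score_linear(
        genes, assign_window(genes, peaks, config.linear_half_width), experiment)
    out["ouyang"] = score_ouyang(
        genes, assign_all_peaks(genes, peaks, config.ouyang_cap), peaks, config, experiment)
    profile = build_tss_profile(genes, peaks=peaks, coverage=coverage, config=config)
    out["cheng"] = score_cheng(profile, experiment)
    model = fit_nearest_distance_model(genes, peaks, config, chrom_sizes)
    out["chen"] = score_chen(genes, assign_closest_peak(genes, peaks), model, experiment)
    dist = build_distance_distribution(genes, peaks, config.closestgene_cap)
    out["closestgene"] = score_closest_gene(
        genes, assign_closest_gene(genes, peaks, config.closestgene_cap), dist, experiment)
    return out
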