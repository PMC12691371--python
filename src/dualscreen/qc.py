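"""Quality-control statistics for pooled-screen count data.

Covers the standard sequencing-level QC panel for CRISPR screens: mapping
ratio, missed (zero-count) guides, read-threshold coverage, the Gini index
of the count distribution, replicate correlations, and a PCA summary of
sample profiles.  Reported percentages are rounded half-up to two decimals,
the convention of screen sequencing summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .containers import CountTable, ScreenDesign, ValidationError, as_count_frame

__all__ = [
    "round_half_up",
    "mapping_ratio",
    "missed_guide_stats",
    "above_threshold_stats",
    "gini_index",
    "replicate_correlations",
    "pca_summary",
    "qc_report",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (so 0.005 -> 0.01, unlike banker's rounding)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def _pct(numerator: int, denominator: int) -> float:
    """Exact percentage of two integers, half-up rounded to 2 decimals."""
    ratio = Decimal(numerator) * 100 / Decimal(denominator)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def mapping_ratio(total_reads: int, mapped_reads: int) -> float:
    """Percent of reads mappable to the library, to two decimals."""
    if total_reads <= 0:
        raise ValidationError("total_reads must be positive")
    if mapped_reads < 0 or mapped_reads > total_reads:
        raise ValidationError("mapped_reads must be within [0, total_reads]")
    return _pct(mapped_reads, total_reads)


def missed_guide_stats(counts, library_size: int) -> pd.DataFrame:
    """Per-sample zero-count (missed guide) statistics.

    Rows absent from the table count as zeros, so ``zero_count`` =
    (library_size - observed rows) + observed zeros.
    """
    frame = as_count_frame(counts)
    if library_size < len(frame):
        raise ValidationError(
            f"library_size {library_size} < observed rows {len(frame)}"
        )
    absent = library_size - len(frame)
    zero_count = (frame == 0).sum(axis=0) + absent
    zero_pct = zero_count.map(lambda z: _pct(int(z), library_size))
    return pd.DataFrame({"zero_count": zero_count, "zero_pct": zero_pct})


def above_threshold_stats(counts, threshold: int, library_size: int) -> pd.DataFrame:
    """Per-sample count and percent of rows with reads >= threshold."""
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    frame = as_count_frame(counts)
    above = (frame >= threshold).sum(axis=0)
    above_pct = above.map(lambda a: _pct(int(a), library_size))
    return pd.DataFrame({"above_count": above, "above_pct": above_pct})


def gini_index(values) -> float:
    """Gini index of a non-negative vector: mean absolute difference over
    all ordered pairs divided by twice the mean.

    Computed with the sorted-vector identity, which agrees with the
    brute-force double loop to machine precision.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("gini_index needs a 1-D vector of length >= 2")
    if (x < 0).any():
        raise ValidationError("gini_index requires non-negative values")
    total = x.sum()
    if total == 0:
        raise ValidationError("gini_index undefined for an all-zero vector")
    n = len(x)
    xs = np.sort(x)
    ranks = np.arange(1, n + 1)
    # G = sum_i sum_j |x_i - x_j| / (2 n^2 mean) = (2 sum i*x_(i) - (n+1) sum x) / (n sum x)
    return float((2.0 * np.sum(ranks * xs) - (n + 1) * total) / (n * total))


def replicate_correlations(
    counts, design: ScreenDesign, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of log2(count + pseudocount) sample profiles.

    Returns the full sample correlation matrix and a grouped summary with
    the mean within-group (same timepoint and condition) and
    between-timepoint correlations.  Constant samples yield NaN entries
    rather than a silent 0.
    """
    frame = as_count_frame(counts)
    if frame.shape[1] < 2:
        raise ValidationError("need at least two samples for correlations")
    log = np.log2(frame + pseudocount)
    constant = log.std(axis=0, ddof=0) == 0
    matrix = log.corr(method="pearson")
    for s in log.columns[constant]:
        matrix.loc[s, :] = np.nan
        matrix.loc[:, s] = np.nan
    np.fill_diagonal(matrix.values, 1.0)

    meta = design.frame.set_index("sample_id")
    rows = []
    samples = [s for s in matrix.columns if s in meta.index]
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            same_group = (
                meta.loc[a, "timepoint"] == meta.loc[b, "timepoint"]
                and meta.loc[a, "condition"] == meta.loc[b, "condition"]
            )
            same_tp = meta.loc[a, "timepoint"] == meta.loc[b, "timepoint"]
            kind = (
                "within_group"
                if same_group
                else ("within_timepoint" if same_tp else "between_timepoint")
            )
            rows.append((a, b, kind, matrix.loc[a, b]))
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "kind", "correlation"])
    summary = pairs.groupby("kind")["correlation"].mean().to_frame("mean_correlation")
    return matrix, summary


def pca_summary(
    counts, n_components: int = 3, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of centered log2 sample profiles (samples as observations).

    Returns sample coordinates on the leading components and the
    variance-explained fractions (non-increasing, summing to <= 1).
    """
    frame = as_count_frame(counts)
    n_samples = frame.shape[1]
    if n_components > n_samples:
        raise ValidationError("n_components exceeds the number of samples")
    x = np.log2(frame.to_numpy(dtype=float).T + pseudocount)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    coords = pd.DataFrame(
        (u * s)[:, :n_components],
        index=frame.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return coords, frac[:n_components]


@dataclass
class QCReport:
    """Per-sample QC table plus correlation and PCA summaries."""

    per_sample: pd.DataFrame
    correlation_matrix: pd.DataFrame
    correlation_summary: pd.DataFrame
    pca_coordinates: pd.DataFrame
    pca_variance_fractions: np.ndarray


def qc_report(
    counts,
    design: ScreenDesign,
    library_size: int | None = None,
    read_stats: pd.DataFrame | None = None,
    threshold: int = 10,
    pseudocount: float = 1.0,
    n_components: int = 3,
) -> QCReport:
    """Assemble the per-sample QC panel.

    ``read_stats`` may carry per-sample ``total_reads`` and ``mapped_reads``
    columns from the upstream aligner; without it, totals fall back to
    column sums (mapped == total, as counts are post-mapping).
    """
    frame = as_count_frame(counts)
    if library_size is None:
        library_size = len(frame)
    missed = missed_guide_stats(frame, library_size)
    above = above_threshold_stats(frame, threshold, library_size)
    rows = []
    for sample in frame.columns:
        if read_stats is not None and sample in read_stats.index:
            total = int(read_stats.loc[sample, "total_reads"])
            mapped = int(read_stats.loc[sample, "mapped_reads"])
        else:
            total = mapped = int(frame[sample].sum())
        rows.append(
            {
                "sample_id": sample,
                "total_reads": total,
                "mapped_reads": mapped,
                "mapped_pct": mapping_ratio(total, mapped),
                "zero_count": int(missed.loc[sample, "zero_count"]),
                "zero_pct": missed.loc[sample, "zero_pct"],
                "gini": round(gini_index(frame[sample].to_numpy()), 4),
                "above_threshold_count": int(above.loc[sample, "above_count"]),
                "above_threshold_pct": above.loc[sample, "above_pct"],
            }
        )
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    matrix, summary = replicate_correlations(frame, design, pseudocount)
    n_comp = min(n_components, frame.shape[1])
    coords, frac = pca_summary(frame, n_comp, pseudocount)
    return QCReport(per_sample, matrix, summary, coords, frac)
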