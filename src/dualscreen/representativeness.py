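"""Cell-line representativeness against chemotherapy non-responders.

Three complementary analyses decide whether a cell line is a faithful model
of the non-responder patient population:

1. co-clustering with non-responders on the differentially expressed genes
   between responders and non-responders;
2. the average Spearman correlation with non-responder samples over the
   most variable genes of the cell-line panel, thresholded by rank;
3. co-clustering on single-sample gene-set enrichment (ssGSEA) profiles of
   hallmark gene sets.

Each analysis yields a binary label per cell line; the overall
representativeness score is the label sum (0..3), ranked with ties broken
by the average Spearman correlation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess_expression",
    "remove_batch_effects",
    "differential_expression",
    "cocluster_labels",
    "top_variable_genes",
    "spearman_representativeness",
    "ssgsea_scores",
    "ssgsea_cocluster_labels",
    "overall_representativeness",
]


def preprocess_expression(
    values: pd.DataFrame,
    probe_gene_map: pd.Series,
    background: float | pd.Series,
    background_fraction: float = 0.8,
) -> pd.DataFrame:
    """Background filtering and probe-to-gene collapse for log2 intensities.

    A probe is removed when its expression is below the background level in
    at least ``background_fraction`` of samples (boundary inclusive).  When
    several probes map to one gene, the per-sample median is used.
    """
    below = values.lt(background, axis=0 if np.isscalar(background) else 1)
    frac_below = below.mean(axis=1)
    kept = values.loc[frac_below < background_fraction]
    if kept.empty:
        raise ValidationError("no probes left after background filtering")
    genes = probe_gene_map.reindex(kept.index)
    kept = kept.loc[genes.notna()]
    genes = genes.loc[kept.index]
    collapsed = kept.groupby(genes.values).median()
    collapsed.index.name = "gene"
    return collapsed


def remove_batch_effects(matrix, batches) -> pd.DataFrame:
    """Per-gene batch mean-centering (the fixed-effect batch correction).

    Every gene's per-batch mean is subtracted and the grand mean added
    back, so after correction batch means agree to numerical precision.
    Single-sample batches are allowed (their samples are centered to the
    grand mean); this is logged.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    batches = pd.Series(batches, index=values.columns) if not isinstance(
        batches, pd.Series
    ) else batches.reindex(values.columns)
    if batches.isna().any():
        raise ValidationError("batch label missing for some samples")
    if batches.nunique() < 2:
        return values.copy()
    sizes = batches.value_counts()
    singletons = sizes[sizes == 1]
    if len(singletons):
        logger.info("batch(es) with a single sample: %s", list(singletons.index))
    grand = values.mean(axis=1)
    corrected = values.copy()
    for batch, cols in values.T.groupby(batches).groups.items():
        cols = list(cols)
        batch_mean = values[cols].mean(axis=1)
        corrected[cols] = values[cols].sub(batch_mean, axis=0).add(grand, axis=0)
    if isinstance(matrix, ExpressionMatrix):
        return dataclasses.replace(matrix, values=corrected)
    return corrected


def _signed_fold_change(diff_log2: np.ndarray) -> np.ndarray:
    """Signed linear fold change: 2**d for d >= 0, -2**(-d) otherwise."""
    return np.where(diff_log2 >= 0, np.exp2(diff_log2), -np.exp2(-diff_log2))


def differential_expression(
    matrix,
    group_a,
    group_b,
    fc_threshold: float = 1.5,
    adj_p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-gene Welch t-test of group A vs group B on log2 values.

    Fold change is reported on the signed linear scale
    (``FC = 2**diff`` when A is higher, ``-2**(-diff)`` otherwise) so a
    threshold like "greater than 1.5 or less than -1.5" applies directly.
    Genes with zero variance in both groups get p = 1 (equal means) or
    p = 0 (a deterministic difference).  BH adjustment across genes;
    ``selected`` marks |FC| >= fc_threshold and adjusted p < threshold.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    a = values[list(group_a)].to_numpy(dtype=float)
    b = values[list(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("need at least 2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & np.isclose(diff, 0.0), 1.0, p)
    p = np.where(degenerate & ~np.isclose(diff, 0.0), 0.0, p)
    adj_p = multipletests(p, method="fdr_bh")[1]
    fc = _signed_fold_change(diff)
    table = pd.DataFrame(
        {
            "diff_log2": diff,
            "fold_change": fc,
            "t_statistic": t,
            "p_value": p,
            "adj_p": adj_p,
        },
        index=values.index,
    )
    table["selected"] = (np.abs(fc) >= fc_threshold) & (adj_p < adj_p_threshold)
    return table


def _correlation_linkage(values: pd.DataFrame, method: str = "average"):
    """Hierarchical clustering of samples on (1 - Pearson) distance."""
    corr = np.corrcoef(values.to_numpy(dtype=float).T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return linkage(squareform(dist, checks=False), method=method)


def cocluster_labels(
    matrix,
    response: pd.Series,
    cell_lines,
    k: int = 2,
    method: str = "average",
) -> pd.Series:
    """Cluster patients and cell lines together; label cell lines by
    whether their cluster holds the majority of non-responder samples.

    Average-linkage hierarchical clustering on (1 - Pearson) distance over
    samples, cut into ``k`` clusters.  A cell line gets label 1 iff its
    cluster contains strictly more than half of all non-responder samples.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if k > values.shape[1]:
        raise ValidationError("k exceeds the number of samples")
    link = _correlation_linkage(values, method=method)
    assignment = pd.Series(
        fcluster(link, t=k, criterion="maxclust"), index=values.columns
    )
    nr_samples = response.index[response == "non_responder"]
    nr_clusters = assignment.reindex(nr_samples).dropna()
    labels = {}
    for cell in cell_lines:
        cluster = assignment[cell]
        n_nr_here = int((nr_clusters == cluster).sum())
        labels[cell] = int(n_nr_here * 2 > len(nr_clusters))
    return pd.Series(labels, name="label_cluster")


def top_variable_genes(values: pd.DataFrame, n: int = 2000) -> list[str]:
    """The ``n`` genes with the largest standard deviation across samples
    (sample sd, ddof=1); ties broken deterministically by gene name."""
    if n > len(values):
        raise ValidationError(f"requested {n} genes but only {len(values)} available")
    sd = values.std(axis=1, ddof=1)
    order = pd.DataFrame(
        {"sd": sd.to_numpy(), "gene_name": values.index.to_numpy()}
    ).sort_values(["sd", "gene_name"], ascending=[False, True], kind="mergesort")
    return order["gene_name"].head(n).tolist()


def spearman_representativeness(
    cell_values: pd.DataFrame,
    nonresponder_values: pd.DataFrame,
    genes,
    top_rank: int = 100,
) -> pd.DataFrame:
    """Average Spearman correlation of each cell line with the
    non-responder samples over the given gene list.

    Returns per-cell-line ``rho_bar``, 1-based rank (descending by
    ``rho_bar``), and the binary label ``rank <= top_rank``.  Constant
    expression vectors yield undefined correlations, which are excluded
    from the average (logged).
    """
    genes = list(genes)
    cells = cell_values.loc[genes]
    patients = nonresponder_values.loc[genes]
    rho_bar = {}
    for cell in cells.columns:
        x = cells[cell].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.info("cell line %s constant over gene list; rho undefined", cell)
            rho_bar[cell] = np.nan
            continue
        rhos = []
        for patient in patients.columns:
            y = patients[patient].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                logger.info("patient %s constant over gene list; excluded", patient)
                continue
            rhos.append(stats.spearmanr(x, y).statistic)
        rho_bar[cell] = float(np.mean(rhos)) if rhos else np.nan
    table = pd.DataFrame({"rho_bar": pd.Series(rho_bar)})
    table["spearman_rank"] = (
        table["rho_bar"].rank(ascending=False, method="min").astype("Int64")
    )
    table["label_spearman"] = (table["spearman_rank"] <= top_rank).astype(int)
    return table


def ssgsea_scores(
    values: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores (gene sets x samples).

    Per sample, genes are ranked by expression (ties broken by gene name
    for determinism); the enrichment score is the sum over ranked positions
    of the difference between the rank-weighted in-set ECDF (weight =
    rank**alpha) and the unweighted out-of-set ECDF.  With
    ``normalize=True`` all scores are divided by the global max - min
    across the matrix, the usual cross-sample normalization.
    """
    n_genes, n_samples = values.shape
    gene_index = values.index
    masks = {}
    for name, members in sets:
        mask = gene_index.isin(members)
        if not mask.any():
            logger.warning("gene set %s has no members in the matrix; dropped", name)
            continue
        masks[name] = mask
    if not masks:
        raise ValidationError("no gene set overlaps the expression matrix")

    scores = np.empty((len(masks), n_samples))
    x = values.to_numpy(dtype=float)
    # rank 1 = lowest expression; descending walk visits high ranks first
    name_order = np.argsort(gene_index.to_numpy())
    for j in range(n_samples):
        col = x[:, j]
        # stable tie-break: sort by (expression, gene name)
        order_asc = np.lexsort((gene_index.to_numpy(), col))
        rank = np.empty(n_genes)
        rank[order_asc] = np.arange(1, n_genes + 1)
        desc = order_asc[::-1]
        weights = rank[desc] ** alpha
        for i, (name, mask) in enumerate(masks.items()):
            in_set = mask[desc]
            w_in = np.where(in_set, weights, 0.0)
            cdf_in = np.cumsum(w_in)
            total_in = cdf_in[-1]
            cdf_out = np.cumsum(~in_set) / (n_genes - in_set.sum())
            scores[i, j] = float(np.sum(cdf_in / total_in - cdf_out))
    result = pd.DataFrame(scores, index=list(masks), columns=values.columns)
    if normalize:
        spread = result.to_numpy().max() - result.to_numpy().min()
        if spread > 0:
            result = result / spread
    return result


def ssgsea_cocluster_labels(
    ssgsea: pd.DataFrame,
    response: pd.Series,
    cell_lines,
    k: int = 2,
    method: str = "average",
) -> pd.Series:
    """Co-clustering labels computed on the gene-set x sample score matrix."""
    labels = cocluster_labels(ssgsea, response, cell_lines, k=k, method=method)
    return labels.rename("label_ssgsea")


def overall_representativeness(
    label_cluster: pd.Series,
    label_spearman: pd.Series,
    label_ssgsea: pd.Series,
    rho_bar: pd.Series,
) -> pd.DataFrame:
    """Sum the three similarity labels and rank cell lines.

    ``overall_score`` = label_cluster + label_spearman + label_ssgsea in
    {0..3}; ranking is by score descending with ties broken by the average
    Spearman correlation descending.  A missing label is a hard error
    naming the cell line.
    """
    cells = list(label_cluster.index)
    for name, series in (
        ("label_spearman", label_spearman),
        ("label_ssgsea", label_ssgsea),
        ("rho_bar", rho_bar),
    ):
        missing = set(cells) - set(series.index)
        extra = set(series.index) - set(cells)
        if missing or extra:
            raise ValidationError(
                f"{name} missing for cell line(s): {sorted(missing | extra)}"
            )
    table = pd.DataFrame(
        {
            "label_cluster": label_cluster.astype(int),
            "label_spearman": label_spearman.reindex(cells).astype(int),
            "label_ssgsea": label_ssgsea.reindex(cells).astype(int),
            "rho_bar": rho_bar.reindex(cells).astype(float),
        }
    )
    table["overall_score"] = (
        table["label_cluster"] + table["label_spearman"] + table["label_ssgsea"]
    )
    order = table.sort_values(
        ["overall_score", "rho_bar"], ascending=[False, False], kind="mergesort"
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    table["overall_rank"] = ranks.reindex(table.index)
    return table.sort_values("overall_rank")
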