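"""Dual-knockout interaction scoring and synthetic-lethality consensus.

A dual construct expresses two guides; its log2 fold change (LFC) is
compared with the additive expectation from the two single-knockout
fitnesses, estimated from pairings with safe-harbor guides.  The residual

    delta = LFC(g_i, g_j) - (f_i + f_j)

is the genetic-interaction signal: negative delta means the double knockout
is depleted beyond the additive expectation, i.e. a synthetic-lethal (SL)
interaction.  Four scoring methods aggregate deltas per unordered gene
pair -- the mean-delta (Horlbeck-style) score, a median score, an
sgRNA-derived score correcting at guide rather than gene resolution (the
latter two with or without background normalization against safe-safe
constructs), and a robust rank-aggregation statistic.  Consensus takes the
top decile of each method and keeps pairs flagged by at least
``min_methods`` methods.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    SAFE,
    CountTable,
    DualDesign,
    GuideLibrary,
    ScreenDesign,
    ValidationError,
    as_count_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "construct_lfc",
    "single_gene_fitness",
    "SingleFitnessTable",
    "pair_deltas",
    "sl_score_horlbeck",
    "sl_score_median",
    "sl_score_sgrna_derived",
    "sl_score_rank_agg",
    "score_sl_table",
    "consensus_sl_pairs",
    "select_cdko_candidates",
    "sl_network_hubs",
    "SLNetwork",
]

DEFAULT_METHODS = ("horlbeck", "median", "sgrna", "rra")


def construct_lfc(
    counts,
    design: ScreenDesign,
    dual: DualDesign,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Replicate-averaged log2 fold change per construct (Tend vs pooled T0).

    Constructs present in the design but missing from the count table are
    treated as zero counts (logged).  Returns a frame indexed by
    construct_id with one column per Tend sample plus the replicate
    average ``lfc``.
    """
    frame = as_count_frame(counts)
    t0 = design.t0_samples
    if not t0:
        raise ValidationError("design has no T0 samples")
    tend = design.frame[design.frame["timepoint"] == "Tend"]
    if tend.empty:
        raise ValidationError("design has no Tend samples")
    frame = frame.reindex(dual.construct_ids)
    n_missing = int(frame.isna().any(axis=1).sum())
    if n_missing:
        logger.info("%d construct(s) missing from counts; treated as zero", n_missing)
        frame = frame.fillna(0.0)
    log_ref = np.log2(frame[t0].mean(axis=1) + pseudocount)
    out = pd.DataFrame(index=frame.index)
    for sample in tend["sample_id"]:
        out[sample] = np.log2(frame[sample] + pseudocount) - log_ref
    out["lfc"] = out[list(tend["sample_id"])].mean(axis=1)
    return out


@dataclass
class SingleFitnessTable:
    """Single-knockout fitness from safe pairings, at guide and gene level."""

    guide: pd.Series  # guide_id -> f_guide (log2)
    gene: pd.Series  # gene -> f_gene (log2, median over the gene's guides)

    def gene_fitness_of(self, gene: str) -> float:
        return float(self.gene[gene])


def single_gene_fitness(
    lfc: pd.DataFrame, dual: DualDesign, library: GuideLibrary
) -> SingleFitnessTable:
    """Estimate single-knockout fitness from safe-paired constructs.

    ``f_guide`` is the mean LFC of the guide's safe-paired constructs over
    both cassette positions (for safe guides: over safe-safe constructs);
    ``f_gene`` is the median over the gene's guides.  Guides without any
    safe pairing are excluded (logged).
    """
    frame = dual.frame
    values = lfc["lfc"].reindex(frame["construct_id"]).to_numpy()
    safe1 = frame["gene_pos1"].to_numpy() == SAFE
    safe2 = frame["gene_pos2"].to_numpy() == SAFE
    pieces = []
    # partner-is-safe constructs, attributed to the non-safe position's guide;
    # safe-safe constructs are attributed to both safe guides
    pieces.append(pd.DataFrame({"guide": frame.loc[safe2, "guide_pos1"],
                                "value": values[safe2]}))
    pieces.append(pd.DataFrame({"guide": frame.loc[safe1, "guide_pos2"],
                                "value": values[safe1]}))
    stacked = pd.concat(pieces, ignore_index=True)
    f_guide = stacked.groupby("guide")["value"].mean()
    gene_of = library.gene_of()
    no_safe = set(library.guide_ids) - set(f_guide.index)
    if no_safe:
        logger.info("guide(s) without safe pairings excluded: %d", len(no_safe))
    f_gene = f_guide.groupby(f_guide.index.map(gene_of)).median()
    f_guide.index.name = "guide_id"
    f_gene.index.name = "gene"
    return SingleFitnessTable(guide=f_guide, gene=f_gene)


def pair_deltas(
    lfc: pd.DataFrame,
    dual: DualDesign,
    fitness: SingleFitnessTable,
    level: str = "gene",
) -> pd.DataFrame:
    """Per-construct interaction deltas: LFC minus additive expectation.

    ``level`` selects whether the additive expectation uses gene-level
    (median-over-guides) or guide-level fitness.  Returns one row per
    construct with its unordered ``pair`` key, ordered ``pair_label``
    (orientation), a ``category`` (pair / same_gene / single_safe /
    safe_safe) and the ``delta``.
    """
    if level not in {"gene", "guide"}:
        raise ValidationError("level must be 'gene' or 'guide'")
    frame = dual.frame.copy()
    frame["lfc"] = lfc["lfc"].reindex(frame["construct_id"]).to_numpy()
    if level == "gene":
        f1 = fitness.gene.reindex(frame["gene_pos1"]).to_numpy()
        f2 = fitness.gene.reindex(frame["gene_pos2"]).to_numpy()
    else:
        f1 = fitness.guide.reindex(frame["guide_pos1"]).to_numpy()
        f2 = fitness.guide.reindex(frame["guide_pos2"]).to_numpy()
    frame["delta"] = frame["lfc"] - (f1 + f2)
    safe1 = frame["gene_pos1"] == SAFE
    safe2 = frame["gene_pos2"] == SAFE
    category = np.where(
        safe1 & safe2,
        "safe_safe",
        np.where(
            safe1 | safe2,
            "single_safe",
            np.where(frame["gene_pos1"] == frame["gene_pos2"], "same_gene", "pair"),
        ),
    )
    frame["category"] = category
    keep = frame["delta"].notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%d construct(s) without usable fitness dropped", dropped)
    return frame.loc[
        keep, ["construct_id", "pair", "pair_label", "category", "delta"]
    ].reset_index(drop=True)


def _pair_table(deltas: pd.DataFrame) -> pd.DataFrame:
    return deltas[deltas["category"] == "pair"]


def sl_score_horlbeck(
    lfc: pd.DataFrame,
    fitness: SingleFitnessTable,
    dual: DualDesign,
    min_constructs: int = 4,
) -> pd.DataFrame:
    """Mean interaction delta per unordered gene pair (gene-level fitness)."""
    deltas = _pair_table(pair_deltas(lfc, dual, fitness, level="gene"))
    grouped = deltas.groupby("pair")["delta"].agg(["mean", "size"])
    return pd.DataFrame(
        {
            "score": grouped["mean"],
            "n_constructs": grouped["size"],
            "low_confidence": grouped["size"] < min_constructs,
        }
    )


def sl_score_median(
    lfc: pd.DataFrame,
    fitness: SingleFitnessTable,
    dual: DualDesign,
    background_normalize: bool = True,
    min_constructs: int = 4,
) -> pd.DataFrame:
    """Median interaction delta per pair, optionally background-normalized
    by the median delta of safe-safe constructs."""
    all_deltas = pair_deltas(lfc, dual, fitness, level="gene")
    deltas = _pair_table(all_deltas).copy()
    if background_normalize:
        background = all_deltas.loc[all_deltas["category"] == "safe_safe", "delta"]
        if background.empty:
            raise ValidationError("no safe-safe constructs for background normalization")
        deltas["delta"] = deltas["delta"] - background.median()
    grouped = deltas.groupby("pair")["delta"].agg(["median", "size"])
    return pd.DataFrame(
        {
            "score": grouped["median"],
            "n_constructs": grouped["size"],
            "low_confidence": grouped["size"] < min_constructs,
        }
    )


def sl_score_sgrna_derived(
    lfc: pd.DataFrame,
    fitness: SingleFitnessTable,
    dual: DualDesign,
    background_normalize: bool = True,
    min_constructs: int = 4,
) -> pd.DataFrame:
    """Guide-resolution interaction score: deltas against guide-level
    fitness, averaged per orientation and then across the two orientations;
    optionally background-normalized by the safe-safe mean delta."""
    all_deltas = pair_deltas(lfc, dual, fitness, level="guide")
    deltas = _pair_table(all_deltas).copy()
    if background_normalize:
        background = all_deltas.loc[all_deltas["category"] == "safe_safe", "delta"]
        if background.empty:
            raise ValidationError("no safe-safe constructs for background normalization")
        deltas["delta"] = deltas["delta"] - background.mean()
    per_orientation = deltas.groupby(["pair", "pair_label"])["delta"].mean()
    score = per_orientation.groupby("pair").mean()
    sizes = deltas.groupby("pair")["delta"].size()
    return pd.DataFrame(
        {
            "score": score,
            "n_constructs": sizes,
            "low_confidence": sizes < min_constructs,
        }
    )


def _rra_rho(sorted_ranks: np.ndarray) -> np.ndarray:
    """Robust rank aggregation rho for rows of sorted percentile ranks.

    For a pair with sorted ranks r_(1) <= ... <= r_(n), rho is the minimum
    over k of the Beta(k, n - k + 1) CDF at r_(k) -- the probability that
    the k-th smallest of n uniform ranks is at most r_(k).
    """
    n = sorted_ranks.shape[1]
    k = np.arange(1, n + 1)
    cdf = stats.beta.cdf(sorted_ranks, k[None, :], (n - k + 1)[None, :])
    return cdf.min(axis=1)


def sl_score_rank_agg(
    lfc: pd.DataFrame,
    fitness: SingleFitnessTable,
    dual: DualDesign,
    n_permutations: int = 0,
    seed: int | None = None,
    min_constructs: int = 4,
) -> pd.DataFrame:
    """Rank-aggregation SL statistic per pair (smaller = stronger SL).

    Guide-level deltas of all constructs are converted to ascending
    percentile ranks; each pair's rho is the minimum Beta(k, n-k+1) CDF
    over its k-th smallest ranks.  With ``n_permutations > 0`` a permutation
    p-value is attached by shuffling the construct-to-pair assignment.
    """
    if 0 < n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} is very small for a permutation p",
            stacklevel=2,
        )
    all_deltas = pair_deltas(lfc, dual, fitness, level="guide")
    n_total = len(all_deltas)
    ranks = stats.rankdata(all_deltas["delta"].to_numpy(), method="average") / n_total
    all_deltas = all_deltas.assign(rank=ranks)
    pairs = _pair_table(all_deltas)

    sizes = pairs.groupby("pair")["rank"].size()
    rho_values: dict[str, float] = {}
    for n in sizes.unique():
        names = sorted(sizes.index[sizes == n])
        block = pairs[pairs["pair"].isin(names)].sort_values(["pair", "rank"])
        mat = block["rank"].to_numpy().reshape(len(names), int(n))
        rho_values.update(zip(names, _rra_rho(mat)))
    rho = pd.Series(rho_values)
    result = pd.DataFrame(
        {
            "score": rho.reindex(sizes.index),
            "n_constructs": sizes,
            "low_confidence": sizes < min_constructs,
        }
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        rank_pool = pairs["rank"].to_numpy()
        null = {n: np.empty(n_permutations) for n in sizes.unique()}
        for n in null:
            draws = rng.choice(len(rank_pool), size=(n_permutations, int(n)))
            null[n] = _rra_rho(np.sort(rank_pool[draws], axis=1))
        pvals = np.empty(len(result))
        for i, (pair, row) in enumerate(result.iterrows()):
            dist = np.sort(null[int(row["n_constructs"])])
            pvals[i] = (1 + np.searchsorted(dist, row["score"], side="right")) / (
                n_permutations + 1
            )
        result["p_value"] = pvals
    return result


def score_sl_table(
    lfc: pd.DataFrame,
    dual: DualDesign,
    library: GuideLibrary,
    methods=DEFAULT_METHODS,
    background_normalize: bool = True,
    min_constructs: int = 4,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every unordered distinct-gene pair with the requested methods.

    Returns one row per pair with one score column per method (for the
    rank-aggregation method the column holds rho; smaller = stronger SL;
    for all others more negative = stronger SL), plus the construct count
    and low-confidence flag.
    """
    fitness = single_gene_fitness(lfc, dual, library)
    columns = {}
    meta = None
    for method in methods:
        if method == "horlbeck":
            table = sl_score_horlbeck(lfc, fitness, dual, min_constructs)
        elif method == "median":
            table = sl_score_median(lfc, fitness, dual, background_normalize, min_constructs)
        elif method == "sgrna":
            table = sl_score_sgrna_derived(
                lfc, fitness, dual, background_normalize, min_constructs
            )
        elif method == "rra":
            table = sl_score_rank_agg(lfc, fitness, dual, seed=seed,
                                      min_constructs=min_constructs)
        else:
            raise ValidationError(f"unknown SL scoring method {method!r}")
        columns[method] = table["score"]
        meta = table[["n_constructs", "low_confidence"]]
    scores = pd.DataFrame(columns)
    scores = scores.join(meta)
    scores.index.name = "pair"
    return scores


def consensus_sl_pairs(
    scores: pd.DataFrame,
    methods=None,
    top_fraction: float = 0.10,
    min_methods: int = 3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Top-decile consensus across scoring methods.

    Per method the ``ceil(top_fraction * n_pairs)`` strongest-SL pairs
    (most negative score; smallest rho for rank aggregation -- both are the
    ascending head) are flagged; the consensus set is the pairs flagged by
    at least ``min_methods`` methods.  Also returns Venn-region counts
    keyed by the '+'-joined method subset.
    """
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must be in (0, 1]")
    if methods is None:
        methods = [m for m in scores.columns if m in DEFAULT_METHODS]
    if len(methods) < min_methods:
        raise ValidationError(
            f"only {len(methods)} score columns present; min_methods={min_methods}"
        )
    n_pairs = len(scores)
    n_flag = math.ceil(top_fraction * n_pairs)
    out = scores.copy()
    for method in methods:
        order = pd.DataFrame(
            {"value": scores[method].to_numpy(), "pair_name": scores.index}
        ).sort_values(["value", "pair_name"], kind="mergesort")
        flagged = set(order["pair_name"].iloc[:n_flag])
        out[f"hit_{method}"] = out.index.isin(flagged)
    hit_cols = [f"hit_{m}" for m in methods]
    out["n_methods_hit"] = out[hit_cols].sum(axis=1)
    out["consensus"] = out["n_methods_hit"] >= min_methods
    venn: dict[str, int] = {}
    grouped = out.groupby(hit_cols).size()
    for key, count in grouped.items():
        if not isinstance(key, tuple):
            key = (key,)
        subset = [m for m, hit in zip(methods, key) if hit]
        if subset:
            venn["+".join(subset)] = int(count)
    return out, venn


def select_cdko_candidates(
    hallmark_genes,
    expression_counts,
    beta,
    control_condition: str = "control",
    expr_threshold: float = 50.0,
    essentiality_band: float = 1.0,
) -> tuple[list[str], dict[str, int]]:
    """Candidate genes for a dual-knockout library.

    A gene qualifies when it (i) belongs to the cell-death hallmark list,
    (ii) is expressed above ``expr_threshold`` read counts, and (iii) is
    non-essential in the genome-wide screen (|beta| <= essentiality_band in
    the control arm).  Returns the selected genes (hallmark order) and
    Venn-region counts for the three criteria.
    """
    hallmark = list(dict.fromkeys(hallmark_genes))
    expr = pd.Series(expression_counts, dtype=float)
    if isinstance(beta, pd.DataFrame):
        beta_control = beta.loc[beta["condition"] == control_condition].set_index(
            "gene"
        )["beta"]
    else:
        beta_control = pd.Series(beta, dtype=float)
    set_hallmark = set(hallmark)
    set_expressed = set(expr.index[expr > expr_threshold])
    set_nonessential = set(
        beta_control.index[beta_control.abs() <= essentiality_band]
    )
    universe = set_hallmark | set_expressed | set_nonessential
    names = ("hallmark", "expressed", "nonessential")
    members = (set_hallmark, set_expressed, set_nonessential)
    venn: dict[str, int] = {}
    for r in range(1, 4):
        for combo in itertools.combinations(range(3), r):
            inside = set(universe)
            for i in range(3):
                if i in combo:
                    inside &= members[i]
                else:
                    inside -= members[i]
            venn["&".join(names[i] for i in combo)] = len(inside)
    selected = [
        g for g in hallmark if g in set_expressed and g in set_nonessential
    ]
    return selected, venn


@dataclass
class SLNetwork:
    """Undirected SL interaction network with hub annotation."""

    graph: "object"
    degrees: pd.Series
    hubs: list[str]
    hub_threshold: int


def sl_network_hubs(consensus_pairs, hub_threshold: int = 10) -> SLNetwork:
    """Build the SL network from consensus pairs and extract hub genes.

    Nodes are genes, edges are consensus pairs (simple, undirected); hubs
    are genes incident to at least ``hub_threshold`` consensus partners.
    """
    import networkx as nx

    graph = nx.Graph()
    for pair in consensus_pairs:
        if isinstance(pair, str):
            a, b = pair.split("__")
        else:
            a, b = pair
        graph.add_edge(a, b)
    degrees = pd.Series(dict(graph.degree()), dtype=int).sort_values(ascending=False)
    hubs = sorted(degrees.index[degrees >= hub_threshold])
    return SLNetwork(graph=graph, degrees=degrees, hubs=hubs, hub_threshold=hub_threshold)
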