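"""Gene essentiality scoring from pooled-screen counts.

The chain is: control-guide median-ratio normalization -> guide-level log2
fold changes between the end timepoint and the pooled T0 baseline -> gene
beta scores (mean of the gene's guide LFCs, on the log2 scale, negative =
depleted = essential) with permutation p-values and Benjamini-Hochberg FDR.
Re-sensitizer selection, list overlap, hypergeometric gene-set enrichment
and the drug-combination additivity t-test also live here.

The beta estimator is deliberately a transparent mean of control-normalized
guide log2 fold changes: it shares the sign convention and approximate log2
scale of likelihood-based screen scorers, so the conventional +/-1 cutoffs
carry over, while remaining deterministic and easily audited.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    SAFE,
    CountTable,
    GeneSetCollection,
    GuideLibrary,
    ScreenDesign,
    ValidationError,
    as_count_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_counts",
    "guide_lfc",
    "gene_beta",
    "select_resensitizers",
    "overlap_genes",
    "hypergeometric_enrichment",
    "additivity_test",
    "AdditivityResult",
]


def normalize_counts(counts, control_guides=None) -> CountTable:
    """Median-ratio normalization anchored on control guides.

    The per-sample size factor is the median, over control guides, of the
    ratio of that guide's count to its geometric mean across samples; each
    sample is divided by its factor.  Control guides with a zero count in
    any sample are excluded from factor estimation (their geometric mean is
    degenerate).  When no control guides are given, all guides are used,
    with a warning -- the classic median-ratio fallback.
    """
    frame = as_count_frame(counts).astype(float)
    if control_guides is None or len(control_guides) == 0:
        warnings.warn(
            "no control guides supplied; falling back to all-guide median-ratio "
            "normalization",
            stacklevel=2,
        )
        anchor = frame
    else:
        control_guides = [g for g in control_guides if g in frame.index]
        if not control_guides:
            raise ValidationError("none of the control guides are present in the table")
        anchor = frame.loc[control_guides]
        all_zero = (anchor == 0).all(axis=0)
        if all_zero.any():
            raise ValidationError(
                "all control guides have zero counts in sample(s): "
                f"{list(anchor.columns[all_zero])}"
            )
    positive = (anchor > 0).all(axis=1)
    anchor = anchor.loc[positive]
    if anchor.empty:
        raise ValidationError("no anchor guides with positive counts in every sample")
    log_geomean = np.log(anchor).mean(axis=1)
    ratios = np.log(anchor).sub(log_geomean, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    normalized = frame.div(size_factors, axis=1)
    return CountTable(normalized)


def guide_lfc(
    norm_counts, design: ScreenDesign, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Guide-level log2 fold changes of each Tend replicate vs the pooled T0.

    The T0 reference is the mean of the T0 replicates (the screen branches
    into arms after T0, so a single pooled baseline is shared).  Returns a
    long frame with columns guide_id, condition, replicate, lfc.
    """
    frame = as_count_frame(norm_counts)
    t0 = design.t0_samples
    if not t0:
        raise ValidationError("design has no T0 samples")
    t0_ref = frame[t0].mean(axis=1)
    rows = []
    tend = design.frame[design.frame["timepoint"] == "Tend"]
    if tend.empty:
        raise ValidationError("design has no Tend samples")
    log_ref = np.log2(t0_ref + pseudocount)
    for _, row in tend.iterrows():
        sample = row["sample_id"]
        lfc = np.log2(frame[sample] + pseudocount) - log_ref
        rows.append(
            pd.DataFrame(
                {
                    "guide_id": frame.index,
                    "condition": row["condition"],
                    "replicate": row["replicate"],
                    "lfc": lfc.to_numpy(),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    if not np.isfinite(out["lfc"]).all():
        raise ValidationError("non-finite log2 fold change encountered")
    return out


def gene_beta(
    lfc: pd.DataFrame,
    library: GuideLibrary,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene beta scores per condition with permutation p-values and BH FDR.

    beta(gene, condition) = mean over the gene's guides of the
    replicate-averaged LFC.  The null distribution for a gene with m guides
    is the mean LFC of m guides drawn at random from all targeting guides;
    the two-sided p-value is ``(1 + #more extreme) / (n_permutations + 1)``.
    Genes without guides in the table are excluded (logged).
    """
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} is very small; p-values will be coarse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    gene_of = library.gene_of()
    per_guide = (
        lfc.groupby(["condition", "guide_id"], sort=True)["lfc"].mean().reset_index()
    )
    per_guide["gene"] = per_guide["guide_id"].map(gene_of)
    targeting = per_guide[per_guide["gene"].notna() & (per_guide["gene"] != SAFE)]
    missing = set(library.genes) - set(targeting["gene"])
    if missing:
        logger.info("genes with no guides in the LFC table: %d", len(missing))

    results = []
    for condition, block in targeting.groupby("condition", sort=True):
        values = block.set_index("guide_id")["lfc"]
        genes = block.groupby("gene")["lfc"].agg(["mean", "size"])
        pool = values.to_numpy()
        pvals = np.empty(len(genes))
        for m, sub in genes.groupby("size"):
            draw = rng.integers(0, len(pool), size=(n_permutations, int(m)))
            null = pool[draw].mean(axis=1)
            null_abs = np.sort(np.abs(null))
            obs = np.abs(sub["mean"].to_numpy())
            n_ge = len(null_abs) - np.searchsorted(null_abs, obs, side="left")
            pvals[genes.index.get_indexer(sub.index)] = (1.0 + n_ge) / (
                n_permutations + 1.0
            )
        fdr = multipletests(pvals, method="fdr_bh")[1]
        results.append(
            pd.DataFrame(
                {
                    "gene": genes.index,
                    "condition": condition,
                    "beta": genes["mean"].to_numpy(),
                    "n_guides": genes["size"].to_numpy(),
                    "p_value": pvals,
                    "fdr": fdr,
                }
            )
        )
    return pd.concat(results, ignore_index=True)


def select_resensitizers(
    beta: pd.DataFrame,
    control_condition: str = "control",
    drug_condition: str = "drug:cisplatin",
    thr_control: float = 1.0,
    thr_drug: float = -1.0,
) -> list[str]:
    """Genes tolerated (beta > thr_control) untreated but depleted
    (beta < thr_drug) under drug; sorted by drug beta, most depleted first."""
    present = set(beta["condition"])
    for cond in (control_condition, drug_condition):
        if cond not in present:
            raise ValidationError(f"condition {cond!r} absent from beta table")
    wide = beta.pivot(index="gene", columns="condition", values="beta")
    mask = (wide[control_condition] > thr_control) & (wide[drug_condition] < thr_drug)
    selected = wide[mask].sort_values(drug_condition, ascending=True)
    return selected.index.tolist()


def overlap_genes(list_a, list_b) -> tuple[list[str], int]:
    """Set intersection preserving the order of ``list_a``."""
    set_b = set(list_b)
    intersection = [g for g in dict.fromkeys(list_a) if g in set_b]
    return intersection, len(intersection)


def hypergeometric_enrichment(
    gene_list, sets: GeneSetCollection, universe
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For a universe of size N, a list of size n and a set with K members in
    the universe overlapping the list in k genes, the p-value is
    P(X >= k) for X ~ Hypergeom(N, K, n).  Set members outside the universe
    are ignored (count logged).  BH adjustment across sets.
    """
    universe = list(dict.fromkeys(universe))
    universe_set = set(universe)
    gene_list = [g for g in dict.fromkeys(gene_list)]
    outside = set(gene_list) - universe_set
    if outside:
        raise ValidationError(
            f"gene list members outside the universe: {sorted(outside)[:5]}"
        )
    n_universe, n_list = len(universe), len(gene_list)
    list_set = set(gene_list)
    rows = []
    for name, members in sets:
        in_universe = [m for m in members if m in universe_set]
        dropped = len(members) - len(in_universe)
        if dropped:
            logger.info("set %s: %d member(s) outside universe ignored", name, dropped)
        overlap = sorted(list_set.intersection(in_universe))
        k, K = len(overlap), len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, n_universe, K, n_list)) if K else 1.0
        rows.append((name, K, k, p, ";".join(overlap)))
    table = pd.DataFrame(
        rows, columns=["set_name", "set_size", "overlap", "p_value", "overlap_members"]
    )
    table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1] if len(table) else []
    return table


@dataclass
class AdditivityResult:
    expected_additive_mean: float
    combo_mean: float
    t_statistic: float
    p_value: float
    verdict: str


def additivity_test(effect_a, effect_b, effect_combo, alpha: float = 0.05) -> AdditivityResult:
    """Compare a drug combination against the additive single-effect sum.

    Replicate inhibition fractions of each single agent are added pairwise
    to form the additive expectation, then compared with the combination
    group by a two-sided Welch t-test.  The verdict is synergistic when the
    combination inhibits significantly more than the additive expectation,
    antagonistic when significantly less, otherwise additive.
    """
    a = np.asarray(effect_a, dtype=float)
    b = np.asarray(effect_b, dtype=float)
    combo = np.asarray(effect_combo, dtype=float)
    if min(len(a), len(b), len(combo)) < 2:
        raise ValidationError("need at least 2 replicates per group")
    if len(a) != len(b):
        raise ValidationError("single-agent groups must have matching replicates")
    expected = a + b
    if expected.var(ddof=1) == 0 and combo.var(ddof=1) == 0:
        if np.isclose(expected.mean(), combo.mean()):
            t, p = 0.0, 1.0
        else:
            t = np.inf if combo.mean() > expected.mean() else -np.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(combo, expected, equal_var=False)
        t, p = float(t), float(p)
    diff = combo.mean() - expected.mean()
    if p < alpha and diff > 0:
        verdict = "synergistic"
    elif p < alpha and diff < 0:
        verdict = "antagonistic"
    else:
        verdict = "additive"
    return AdditivityResult(
        expected_additive_mean=float(expected.mean()),
        combo_mean=float(combo.mean()),
        t_statistic=t,
        p_value=p,
        verdict=verdict,
    )
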