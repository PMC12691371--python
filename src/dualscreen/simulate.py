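"""Synthetic screen counts and transcriptome cohorts with known planted truth.

Every generator is deterministic for a fixed seed and returns its truth
object alongside the data, so downstream stages can be tested end-to-end
without external data.

Count model
-----------
Guide (or construct) abundances follow a log-normal skew; per-sample counts
are negative binomial around ``depth * relative_abundance`` with the
size/dispersion parameterization ``var = mu + mu**2 / dispersion`` (the
Poisson limit is recovered as dispersion -> inf).  End-timepoint means are
the baseline means scaled by ``2**effect`` where the effect is the planted
log2 fitness (plus interaction, for dual constructs).

Default parameter choices emulate the sequencing regime of a well-executed
dual-knockout screen: ~300 reads per construct, a near-even library
(null Gini around 0.05), and a ~1% tail of poorly represented constructs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    SAFE,
    CountTable,
    DualDesign,
    ExpressionMatrix,
    GeneSetCollection,
    GuideLibrary,
    ScreenDesign,
    ValidationError,
    pair_key,
)
from .io import build_dual_design, make_screen_design, make_synthetic_library

__all__ = [
    "ScreenTruth",
    "CohortTruth",
    "simulate_genome_screen",
    "simulate_cdko_screen",
    "simulate_transcriptome_cohort",
    "make_genome_truth",
    "make_cdko_truth",
    "make_cohort_truth",
    "make_hallmark_like_sets",
    "default_genome_scenario",
    "default_cdko_scenario",
    "default_cohort_scenario",
]


# ---------------------------------------------------------------------------
# truth objects


@dataclass
class ScreenTruth:
    """Planted truth for a pooled screen simulation.

    Parameters
    ----------
    guide_fitness
        Per-guide log2 fitness over the screen duration (safe guides are 0
        by construction).
    beta_true
        Gene x condition log2 essentiality effects (genome screens).
    gamma_true
        Unordered gene-pair key -> log2 interaction effect (dual screens);
        pairs not listed have no interaction.
    dispersion
        Negative-binomial size parameter; ``np.inf`` gives Poisson counts.
    depth
        Expected reads per guide/construct per sample.
    tau
        SD of guide-level jitter around the gene effect (guide efficiency).
    sigma_construct
        SD of construct-level log2 noise shared across replicates (dual
        screens only).
    """

    guide_fitness: pd.Series
    beta_true: pd.DataFrame | None = None
    gamma_true: pd.Series | None = None
    dispersion: float = 400.0
    depth: float = 300.0
    tau: float = 0.0
    sigma_construct: float = 0.0
    sigma_log: float = 0.05
    dropout_fraction: float = 0.0
    dropout_scale: float = 0.05
    guide_effect: pd.DataFrame | None = None
    construct_lfc_true: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if self.depth <= 0:
            raise ValidationError("sequencing depth must be positive")

    def gamma_of(self, pair: str) -> float:
        if self.gamma_true is None:
            return 0.0
        return float(self.gamma_true.get(pair, 0.0))


@dataclass
class CohortTruth:
    """Planted truth for a transcriptome cohort simulation.

    ``deg_delta`` maps planted differentially expressed genes to their log2
    shift in non-responders; ``lambdas`` gives each cell line's mixing weight
    toward the non-responder centroid (1 = perfect model, 0 = unrelated).
    """

    deg_delta: pd.Series
    batch_offsets: dict[str, float]
    lambdas: tuple[float, ...]
    sigma: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    centroid_sd: float = 1.0
    sigma_cell: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("residual noise sigma must be positive")
        for lam in self.lambdas:
            if not 0.0 <= lam <= 1.0:
                raise ValidationError(f"lambda {lam} outside [0, 1]")


# ---------------------------------------------------------------------------
# count sampling helpers


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, dispersion) with var = mu + mu**2/dispersion; Poisson at inf."""
    mu = np.asarray(mu, dtype=float)
    if not np.isfinite(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def _relative_abundance(
    rng: np.random.Generator,
    n: int,
    sigma_log: float,
    dropout_fraction: float,
    dropout_scale: float,
) -> np.ndarray:
    """Log-normal abundance skew with an optional poorly represented tail."""
    abundance = rng.lognormal(mean=0.0, sigma=sigma_log, size=n)
    if dropout_fraction > 0:
        n_drop = int(round(dropout_fraction * n))
        if n_drop:
            drop_idx = rng.choice(n, size=n_drop, replace=False)
            abundance[drop_idx] *= dropout_scale
    return abundance / abundance.mean()


# ---------------------------------------------------------------------------
# genome-wide screen


def make_genome_truth(
    library: GuideLibrary,
    conditions=("control", "drug:cisplatin"),
    n_resensitizers: int = 0,
    beta_control: float = 1.5,
    beta_drug: float = -2.0,
    seed: int = 0,
    depth: float = 500.0,
    dispersion: float = 400.0,
    tau: float = 0.3,
    sigma_log: float = 0.05,
) -> ScreenTruth:
    """Truth object with ``n_resensitizers`` genes planted at
    (beta_control, beta_drug) and all other genes null."""
    rng = np.random.default_rng(seed)
    genes = library.genes
    beta = pd.DataFrame(0.0, index=genes, columns=list(conditions))
    if n_resensitizers:
        planted = rng.choice(genes, size=n_resensitizers, replace=False)
        drug_conditions = [c for c in conditions if c != "control"]
        beta.loc[planted, "control"] = beta_control
        for cond in drug_conditions:
            beta.loc[planted, cond] = beta_drug
    fitness = pd.Series(0.0, index=library.guide_ids)
    return ScreenTruth(
        guide_fitness=fitness,
        beta_true=beta,
        dispersion=dispersion,
        depth=depth,
        tau=tau,
        sigma_log=sigma_log,
    )


def simulate_genome_screen(
    library: GuideLibrary,
    truth: ScreenTruth,
    design: ScreenDesign,
    seed: int,
    noiseless: bool = False,
) -> tuple[CountTable, ScreenTruth]:
    """Simulate guide counts for a genome-wide screen.

    T0 counts are NB around ``depth * abundance``; each Tend sample in
    condition ``c`` has mean ``T0_mean * 2**(f_guide + beta[gene, c] +
    jitter)`` with guide-level jitter ~ Normal(0, tau).  With
    ``noiseless=True`` the expected (real-valued) counts are returned,
    which makes closed-form checks exact.
    """
    rng = np.random.default_rng(seed)
    guides = library.guide_ids
    gene_of = library.gene_of()
    n = len(guides)
    abundance = _relative_abundance(
        rng, n, truth.sigma_log, truth.dropout_fraction, truth.dropout_scale
    )
    t0_mean = truth.depth * abundance

    beta = truth.beta_true
    conditions = list(beta.columns) if beta is not None else ["control"]
    effect = pd.DataFrame(0.0, index=guides, columns=conditions)
    for cond in conditions:
        per_gene = (
            beta[cond].reindex(gene_of.values).fillna(0.0).to_numpy()
            if beta is not None
            else np.zeros(n)
        )
        jitter = rng.normal(0.0, truth.tau, size=n) if truth.tau > 0 else np.zeros(n)
        is_safe = (gene_of.values == SAFE)
        jitter[is_safe] = 0.0
        effect[cond] = truth.guide_fitness.to_numpy() + per_gene + jitter

    columns = {}
    for _, row in design.frame.iterrows():
        sample, tp, cond = row["sample_id"], row["timepoint"], row["condition"]
        if tp == "T0":
            mean = t0_mean
        else:
            mean = t0_mean * np.exp2(effect[cond].to_numpy())
        if noiseless:
            columns[sample] = mean
        else:
            columns[sample] = _nb_sample(rng, mean, truth.dispersion)
    counts = pd.DataFrame(columns, index=guides)
    out_truth = dataclasses.replace(truth, guide_effect=effect)
    return CountTable(counts), out_truth


# ---------------------------------------------------------------------------
# dual-knockout screen


def make_cdko_truth(
    library: GuideLibrary,
    n_planted: int = 20,
    gamma: float = -2.0,
    gene_fitness_sd: float = 0.4,
    tau: float = 0.3,
    depth: float = 300.0,
    dispersion: float = 400.0,
    sigma_construct: float = 0.35,
    sigma_log: float = 0.04,
    dropout_fraction: float = 0.005,
    seed: int = 0,
    planted_pairs: list[str] | None = None,
) -> ScreenTruth:
    """Truth for a dual-knockout screen: per-guide fitness around a gene
    effect, plus ``n_planted`` gene pairs with interaction ``gamma``."""
    rng = np.random.default_rng(seed)
    genes = library.genes
    gene_fit = pd.Series(rng.normal(0.0, gene_fitness_sd, size=len(genes)), index=genes)
    gene_of = library.gene_of()
    jitter = rng.normal(0.0, tau, size=len(library)) if tau > 0 else np.zeros(len(library))
    fitness = pd.Series(
        [
            0.0 if gene_of[g] == SAFE else gene_fit[gene_of[g]]
            for g in library.guide_ids
        ],
        index=library.guide_ids,
    )
    fitness += np.where(gene_of.loc[fitness.index] == SAFE, 0.0, jitter)
    if planted_pairs is None:
        all_pairs = [
            pair_key(a, b)
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
        ]
        chosen = rng.choice(len(all_pairs), size=n_planted, replace=False)
        planted_pairs = [all_pairs[i] for i in sorted(chosen)]
    gamma_true = pd.Series(gamma, index=pd.Index(planted_pairs, name="pair"))
    return ScreenTruth(
        guide_fitness=fitness,
        gamma_true=gamma_true,
        dispersion=dispersion,
        depth=depth,
        tau=tau,
        sigma_construct=sigma_construct,
        sigma_log=sigma_log,
        dropout_fraction=dropout_fraction,
    )


def simulate_cdko_screen(
    dual: DualDesign,
    truth: ScreenTruth,
    n_replicates: int = 3,
    seed: int = 0,
    noiseless: bool = False,
) -> tuple[CountTable, ScreenDesign, ScreenTruth]:
    """Simulate construct counts for a dual-knockout screen.

    The true construct log2 fold change is ``f_i + f_j + gamma[pair] + eps``
    with construct-level ``eps ~ Normal(0, sigma_construct)`` shared across
    replicates; counts are NB around ``depth * abundance`` (T0) and around
    the T0 mean scaled by ``2**lfc`` (Tend).  Both orientations of every
    guide pair are generated because the design is a full cross.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    frame = dual.frame
    n = len(frame)
    fitness = truth.guide_fitness
    f1 = fitness.reindex(frame["guide_pos1"]).to_numpy()
    f2 = fitness.reindex(frame["guide_pos2"]).to_numpy()
    gamma = np.zeros(n)
    if truth.gamma_true is not None and len(truth.gamma_true):
        gamma = truth.gamma_true.reindex(frame["pair"]).fillna(0.0).to_numpy()
    eps = (
        rng.normal(0.0, truth.sigma_construct, size=n)
        if truth.sigma_construct > 0
        else np.zeros(n)
    )
    lfc_true = f1 + f2 + gamma + eps
    abundance = _relative_abundance(
        rng, n, truth.sigma_log, truth.dropout_fraction, truth.dropout_scale
    )
    t0_mean = truth.depth * abundance
    tend_mean = t0_mean * np.exp2(lfc_true)

    design = make_screen_design(conditions=("control",), n_replicates=n_replicates)
    columns = {}
    for _, row in design.frame.iterrows():
        mean = t0_mean if row["timepoint"] == "T0" else tend_mean
        if noiseless:
            columns[row["sample_id"]] = mean
        else:
            columns[row["sample_id"]] = _nb_sample(rng, mean, truth.dispersion)
    counts = pd.DataFrame(columns, index=pd.Index(frame["construct_id"], name="construct_id"))
    out_truth = dataclasses.replace(
        truth,
        construct_lfc_true=pd.Series(lfc_true, index=counts.index),
    )
    return CountTable(counts), design, out_truth


# ---------------------------------------------------------------------------
# transcriptome cohort


def make_cohort_truth(
    n_genes: int = 1500,
    n_deg: int = 150,
    delta: float = 1.5,
    batches=("cohortA", "cohortB", "cohortC"),
    batch_offset_scale: float = 0.8,
    lambdas: tuple[float, ...] = (0.9, 0.7, 0.5, 0.2, 0.0),
    sigma: float = 0.5,
    seed: int = 0,
) -> CohortTruth:
    """Cohort truth: ``n_deg`` planted DEGs (half up-, half down-shifted by
    ``delta`` log2 units in non-responders), per-batch offsets, and one
    representativeness weight per cell line."""
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"GENE{i + 1:0{width}d}" for i in range(n_genes)]
    deg_genes = rng.choice(genes, size=n_deg, replace=False)
    signs = np.ones(n_deg)
    signs[n_deg // 2 :] = -1.0
    deg_delta = pd.Series(delta * signs, index=deg_genes)
    offsets = {
        b: float(o)
        for b, o in zip(batches, rng.normal(0.0, batch_offset_scale, size=len(batches)))
    }
    return CohortTruth(
        deg_delta=deg_delta,
        batch_offsets=offsets,
        lambdas=tuple(lambdas),
        sigma=sigma,
    )


def simulate_transcriptome_cohort(
    truth: CohortTruth,
    n_responders: int = 15,
    n_nonresponders: int = 29,
    n_celllines: int | None = None,
    n_genes: int = 1500,
    seed: int = 0,
    timepoint: str = "baseline",
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Simulate a patient cohort plus cell lines of tunable similarity.

    Patient expression is ``baseline + delta(DEGs, non-responders) +
    batch offset + Normal(0, sigma)``.  Cell line ``c`` is the mixture
    ``lambda_c * (non-responder centroid) + (1 - lambda_c) * (independent
    centroid) + noise``.  The default group sizes (29 non-responders vs 15
    responders) are the baseline-cohort sizes of the study design this
    generator emulates.
    """
    if n_responders < 2 or n_nonresponders < 2:
        raise ValidationError("need at least 2 samples per response group")
    if n_celllines is None:
        n_celllines = len(truth.lambdas)
    if n_celllines > len(truth.lambdas):
        raise ValidationError("more cell lines requested than lambdas in truth")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = pd.Index([f"GENE{i + 1:0{width}d}" for i in range(n_genes)], name="gene")
    missing = set(truth.deg_delta.index) - set(genes)
    if missing:
        raise ValidationError("DEG list extends beyond the gene universe")
    baseline = rng.normal(truth.baseline_mean, truth.baseline_sd, size=n_genes)
    delta = truth.deg_delta.reindex(genes).fillna(0.0).to_numpy()

    batches = list(truth.batch_offsets)
    columns, meta_rows = {}, []
    samples = [("R", "responder", i) for i in range(n_responders)] + [
        ("NR", "non_responder", i) for i in range(n_nonresponders)
    ]
    for tag, response, i in samples:
        batch = batches[i % len(batches)]
        shift = delta if response == "non_responder" else 0.0
        values = (
            baseline
            + shift
            + truth.batch_offsets[batch]
            + rng.normal(0.0, truth.sigma, size=n_genes)
        )
        name = f"{tag}_{i + 1:02d}"
        columns[name] = values
        meta_rows.append((name, "patient", response, timepoint, batch))

    nr_centroid = baseline + delta
    sigma_cell = truth.sigma_cell if truth.sigma_cell is not None else truth.sigma
    for c in range(n_celllines):
        lam = truth.lambdas[c]
        independent = baseline + rng.normal(0.0, truth.centroid_sd, size=n_genes)
        values = (
            lam * nr_centroid
            + (1.0 - lam) * independent
            + rng.normal(0.0, sigma_cell, size=n_genes)
        )
        name = f"CELL_{c + 1:02d}"
        columns[name] = values
        meta_rows.append((name, "cell_line", "NA", "NA", "cell_line_panel"))

    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "kind", "response", "timepoint", "batch"]
    ).set_index("sample_id")
    return ExpressionMatrix(values, meta), truth


def make_hallmark_like_sets(
    genes,
    n_sets: int = 50,
    set_size: int = 30,
    deg_genes=None,
    n_deg_sets: int = 10,
    seed: int = 0,
) -> GeneSetCollection:
    """Synthetic hallmark-shaped collection: ``n_sets`` sets of ``set_size``
    genes; the first ``n_deg_sets`` sets are enriched for the planted DEGs so
    pathway-level scores separate responders from non-responders."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    deg_genes = list(deg_genes) if deg_genes is not None else []
    sets = {}
    for s in range(n_sets):
        name = f"HALLMARK_SYN_{s + 1:02d}"
        if s < n_deg_sets and deg_genes:
            n_from_deg = min(set_size // 2, len(deg_genes))
            members = list(rng.choice(deg_genes, size=n_from_deg, replace=False))
            rest = rng.choice(genes, size=set_size - n_from_deg, replace=False)
            members.extend(rest)
        else:
            members = list(rng.choice(genes, size=set_size, replace=False))
        sets[name] = list(dict.fromkeys(members))
    return GeneSetCollection(sets, {name: "synthetic" for name in sets})


# ---------------------------------------------------------------------------
# default desk-scale scenarios


def default_genome_scenario(
    seed: int = 0,
    n_genes: int = 2000,
    guides_per_gene: int = 3,
    n_safe: int = 100,
    n_resensitizers: int = 10,
):
    """Desk-scale genome screen: 2,000 genes x 3 guides + 100 safe guides,
    triplicate control and drug arms, 10 planted re-sensitizers."""
    library = make_synthetic_library(n_genes, guides_per_gene, n_safe)
    design = make_screen_design(conditions=("control", "drug:cisplatin"), n_replicates=3)
    truth = make_genome_truth(
        library, n_resensitizers=n_resensitizers, seed=seed
    )
    counts, truth = simulate_genome_screen(library, truth, design, seed=seed)
    return library, design, counts, truth


def default_cdko_scenario(
    seed: int = 0,
    n_genes: int = 40,
    guides_per_gene: int = 3,
    n_safe: int = 10,
    n_planted: int = 20,
    gamma: float = -2.0,
    noiseless: bool = False,
    full_scale: bool = False,
):
    """Desk-scale dual-knockout screen: 40 genes x 3 guides + 10 safe guides
    (130 guides, 16,900 constructs), 20 planted interactions at gamma = -2.
    ``full_scale=True`` switches to the 71-gene x 3 + 17-safe (230 guide)
    design."""
    if full_scale:
        n_genes, guides_per_gene, n_safe = 71, 3, 17
    library = make_synthetic_library(n_genes, guides_per_gene, n_safe)
    dual = build_dual_design(library)
    kwargs = {}
    if noiseless:
        kwargs = dict(tau=0.0, sigma_construct=0.0, dropout_fraction=0.0)
    truth = make_cdko_truth(library, n_planted=n_planted, gamma=gamma, seed=seed, **kwargs)
    counts, design, truth = simulate_cdko_screen(
        dual, truth, n_replicates=3, seed=seed, noiseless=noiseless
    )
    return library, dual, design, counts, truth


def default_cohort_scenario(seed: int = 0, n_genes: int = 1500):
    """Desk-scale cohort: 29 non-responders vs 15 responders across three
    batches, five cell lines with representativeness 0.9 .. 0.0, and a
    50-set hallmark-shaped collection."""
    truth = make_cohort_truth(n_genes=n_genes, seed=seed)
    matrix, truth = simulate_transcriptome_cohort(
        truth, n_responders=15, n_nonresponders=29, n_genes=n_genes, seed=seed
    )
    sets = make_hallmark_like_sets(
        matrix.genes, deg_genes=truth.deg_delta.index, seed=seed
    )
    return matrix, truth, sets
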