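"""Model/Results objects tying the pipeline stages together.

Each model is constructed from validated data containers; ``fit()`` runs
the corresponding analysis chain and returns a results object carrying the
estimates, their uncertainty, diagnostics, and a ``summary()`` table.
The functional modules (:mod:`dualscreen.qc`, :mod:`dualscreen.essentiality`,
:mod:`dualscreen.sl`, :mod:`dualscreen.representativeness`) do the actual
work; these classes orchestrate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import essentiality as ess
from . import qc as qc_mod
from . import representativeness as rep
from . import sl as sl_mod
from .containers import (
    CountTable,
    DualDesign,
    ExpressionMatrix,
    GeneSetCollection,
    GuideLibrary,
    ScreenDesign,
    ValidationError,
)

__all__ = [
    "GenomeScreen",
    "GenomeScreenResults",
    "DualKnockoutScreen",
    "DualScreenResults",
    "CellLinePanel",
    "RepresentativenessResults",
]


class GenomeScreen:
    """Genome-wide pooled knockout screen: counts + design + guide library.

    ``fit()`` normalizes on control (safe) guides, computes guide log2 fold
    changes against the pooled T0 baseline, and estimates per-gene beta
    scores with permutation p-values per condition.
    """

    def __init__(
        self,
        counts: CountTable,
        design: ScreenDesign,
        library: GuideLibrary,
    ) -> None:
        self.counts = counts
        self.design = design
        self.library = library

    def qc(self, **kwargs) -> qc_mod.QCReport:
        return qc_mod.qc_report(self.counts, self.design, **kwargs)

    def fit(
        self,
        control_guides=None,
        pseudocount: float = 1.0,
        n_permutations: int = 10000,
        seed: int | None = None,
    ) -> "GenomeScreenResults":
        if control_guides is None:
            control_guides = self.library.safe_guides
        normalized = ess.normalize_counts(self.counts, control_guides)
        lfc = ess.guide_lfc(normalized, self.design, pseudocount)
        beta = ess.gene_beta(lfc, self.library, n_permutations, seed)
        return GenomeScreenResults(self, beta, lfc, normalized)


@dataclass
class GenomeScreenResults:
    """Gene beta scores per condition with permutation p-values."""

    model: GenomeScreen
    beta_table: pd.DataFrame
    guide_lfc: pd.DataFrame
    normalized_counts: CountTable

    def beta_wide(self) -> pd.DataFrame:
        return self.beta_table.pivot(index="gene", columns="condition", values="beta")

    def select_resensitizers(
        self,
        control_condition: str = "control",
        drug_condition: str | None = None,
        thr_control: float = 1.0,
        thr_drug: float = -1.0,
    ) -> list[str]:
        if drug_condition is None:
            drugs = [c for c in self.beta_table["condition"].unique() if c != control_condition]
            if len(drugs) != 1:
                raise ValidationError(
                    "drug_condition must be given when several drug arms are present"
                )
            drug_condition = drugs[0]
        return ess.select_resensitizers(
            self.beta_table, control_condition, drug_condition, thr_control, thr_drug
        )

    def summary(self) -> str:
        lines = ["Genome-wide screen: gene beta scores", "=" * 44]
        for cond, block in self.beta_table.groupby("condition"):
            lines.append(
                f"{cond}: {len(block)} genes, "
                f"beta range [{block['beta'].min():.2f}, {block['beta'].max():.2f}], "
                f"{int((block['fdr'] < 0.05).sum())} at FDR < 0.05"
            )
        top = self.beta_table.sort_values("beta").head(5)
        lines.append("Most depleted genes:")
        lines.append(
            top[["gene", "condition", "beta", "p_value", "fdr"]].to_string(index=False)
        )
        return "\n".join(lines)

    def plot_beta_scatter(
        self,
        control_condition: str = "control",
        drug_condition: str | None = None,
        thr_control: float = 1.0,
        thr_drug: float = -1.0,
        ax=None,
    ):
        """Control-vs-drug beta scatter with the re-sensitizer region marked."""
        import matplotlib.pyplot as plt

        wide = self.beta_wide()
        if drug_condition is None:
            drug_condition = [c for c in wide.columns if c != control_condition][0]
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(wide[control_condition], wide[drug_condition], s=6, alpha=0.5)
        ax.axvline(thr_control, color="crimson", lw=0.8, ls="--")
        ax.axhline(thr_drug, color="crimson", lw=0.8, ls="--")
        ax.set_xlabel(f"beta ({control_condition})")
        ax.set_ylabel(f"beta ({drug_condition})")
        return ax


class DualKnockoutScreen:
    """Dual-guide double-knockout screen for genetic-interaction scoring."""

    def __init__(
        self,
        counts: CountTable,
        design: ScreenDesign,
        dual: DualDesign,
        library: GuideLibrary,
    ) -> None:
        self.counts = counts
        self.design = design
        self.dual = dual
        self.library = library

    def qc(self, **kwargs) -> qc_mod.QCReport:
        return qc_mod.qc_report(self.counts, self.design, **kwargs)

    def fit(
        self,
        methods=sl_mod.DEFAULT_METHODS,
        pseudocount: float = 1.0,
        background_normalize: bool = True,
        min_constructs: int = 4,
        seed: int | None = None,
    ) -> "DualScreenResults":
        lfc = sl_mod.construct_lfc(self.counts, self.design, self.dual, pseudocount)
        fitness = sl_mod.single_gene_fitness(lfc, self.dual, self.library)
        scores = sl_mod.score_sl_table(
            lfc,
            self.dual,
            self.library,
            methods=methods,
            background_normalize=background_normalize,
            min_constructs=min_constructs,
            seed=seed,
        )
        return DualScreenResults(self, scores, fitness, lfc, tuple(methods))


@dataclass
class DualScreenResults:
    """Per-pair SL scores for every requested method."""

    model: DualKnockoutScreen
    score_table: pd.DataFrame
    fitness: sl_mod.SingleFitnessTable
    construct_lfc: pd.DataFrame
    methods: tuple[str, ...]

    def consensus(
        self, top_fraction: float = 0.10, min_methods: int = 3
    ) -> tuple[pd.DataFrame, dict[str, int]]:
        return sl_mod.consensus_sl_pairs(
            self.score_table,
            methods=list(self.methods),
            top_fraction=top_fraction,
            min_methods=min_methods,
        )

    def network(
        self,
        top_fraction: float = 0.10,
        min_methods: int = 3,
        hub_threshold: int = 10,
    ) -> sl_mod.SLNetwork:
        flagged, _ = self.consensus(top_fraction, min_methods)
        pairs = flagged.index[flagged["consensus"]]
        return sl_mod.sl_network_hubs(pairs, hub_threshold)

    def summary(self, top_fraction: float = 0.10, min_methods: int = 3) -> str:
        flagged, _ = self.consensus(top_fraction, min_methods)
        n_cons = int(flagged["consensus"].sum())
        lines = [
            "Dual-knockout screen: synthetic-lethality scores",
            "=" * 48,
            f"pairs scored: {len(self.score_table)}  methods: {', '.join(self.methods)}",
            f"consensus (top {top_fraction:.0%}, >= {min_methods} methods): {n_cons} pairs",
        ]
        cols = [m for m in self.methods if m != "rra"]
        strongest = flagged[flagged["consensus"]].sort_values(cols[0]).head(5)
        if len(strongest):
            lines.append("Strongest consensus pairs:")
            lines.append(strongest[list(self.methods)].round(3).to_string())
        return "\n".join(lines)

    def plot_score_distributions(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for method in self.methods:
            if method == "rra":
                continue
            ax.hist(self.score_table[method], bins=50, histtype="step", label=method)
        ax.set_xlabel("SL score (log2)")
        ax.set_ylabel("pairs")
        ax.legend()
        return ax


class CellLinePanel:
    """Patient cohort + cell-line panel representativeness analysis."""

    def __init__(
        self,
        matrix: ExpressionMatrix,
        gene_sets: GeneSetCollection,
    ) -> None:
        self.matrix = matrix
        self.gene_sets = gene_sets

    def fit(
        self,
        fc_threshold: float = 1.5,
        adj_p_threshold: float = 0.01,
        n_top_genes: int = 2000,
        top_rank: int = 100,
        k: int = 2,
        alpha: float = 0.25,
        correct_batches: bool = True,
    ) -> "RepresentativenessResults":
        matrix = self.matrix
        patients = matrix.patients
        cells = matrix.cell_lines
        if not cells:
            raise ValidationError("expression matrix contains no cell lines")
        values = matrix.values
        if correct_batches:
            patient_values = rep.remove_batch_effects(
                values[patients], matrix.meta.loc[patients, "batch"]
            )
            values = pd.concat([patient_values, values[cells]], axis=1)
        response = matrix.meta.loc[patients, "response"]
        nonresp = [s for s in patients if response[s] == "non_responder"]
        resp = [s for s in patients if response[s] == "responder"]

        deg = rep.differential_expression(
            values, nonresp, resp, fc_threshold, adj_p_threshold
        )
        deg_genes = deg.index[deg["selected"]].tolist()
        if not deg_genes:
            raise ValidationError("no differentially expressed genes selected")
        label_cluster = rep.cocluster_labels(
            values.loc[deg_genes], response, cells, k=k
        )

        n_top = min(n_top_genes, len(values))
        variable = rep.top_variable_genes(values[cells], n=n_top)
        spearman = rep.spearman_representativeness(
            values[cells], values[nonresp], variable, top_rank=top_rank
        )

        scores = rep.ssgsea_scores(values, self.gene_sets, alpha=alpha)
        label_ssgsea = rep.ssgsea_cocluster_labels(scores, response, cells, k=k)

        report = rep.overall_representativeness(
            label_cluster,
            spearman["label_spearman"],
            label_ssgsea,
            spearman["rho_bar"],
        )
        report["spearman_rank"] = spearman["spearman_rank"]
        return RepresentativenessResults(self, report, deg, scores)


@dataclass
class RepresentativenessResults:
    """Per-cell-line similarity labels, label sum, and overall ranking."""

    model: CellLinePanel
    report: pd.DataFrame
    deg_table: pd.DataFrame
    ssgsea_matrix: pd.DataFrame

    @property
    def top_cell_line(self) -> str:
        return self.report.index[0]

    def summary(self) -> str:
        n_deg = int(self.deg_table["selected"].sum())
        lines = [
            "Cell-line representativeness vs non-responders",
            "=" * 48,
            f"differentially expressed genes selected: {n_deg}",
            self.report[
                ["label_cluster", "label_spearman", "label_ssgsea", "rho_bar",
                 "overall_score", "overall_rank"]
            ]
            .round(3)
            .to_string(),
        ]
        return "\n".join(lines)
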