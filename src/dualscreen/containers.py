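"""Light-weight validated containers for pooled-screen and expression data.

Each container wraps a :class:`pandas.DataFrame` (or two) and enforces the
structural invariants the pipeline relies on -- unique identifiers, integral
non-negative counts, complete sample sheets.  They intentionally stay thin:
all analysis code operates on the underlying frames.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Pseudo-gene assigned to safe-harbor (non-targeting) guides.
SAFE = "SAFE"

#: Separator used to form dual-construct identifiers from the two guide ids.
CONSTRUCT_SEPARATOR = "~"

#: Separator used to form unordered gene-pair keys (lexicographically sorted).
PAIR_SEPARATOR = "__"

VALID_ROLES = frozenset({"targeting", "safe"})
VALID_TIMEPOINTS = frozenset({"T0", "Tend"})


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def pair_key(gene_a: str, gene_b: str) -> str:
    """Unordered gene-pair key: lexicographically sorted, joined by ``__``."""
    a, b = sorted((gene_a, gene_b))
    return f"{a}{PAIR_SEPARATOR}{b}"


@dataclass
class GuideLibrary:
    """Guide annotations: guide -> target gene, with safe guides flagged.

    ``frame`` columns: ``guide_id``, ``gene``, ``role``.  Safe guides carry
    the :data:`SAFE` sentinel in the ``gene`` column, never a gene symbol.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"guide_id", "gene", "role"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"guide library missing columns: {sorted(missing)}")
        dup = self.frame["guide_id"][self.frame["guide_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate guide_id(s): {sorted(dup.unique().tolist())}"
            )
        bad_roles = set(self.frame["role"]) - VALID_ROLES
        if bad_roles:
            raise ValidationError(f"unknown guide role(s): {sorted(bad_roles)}")
        frame = self.frame.copy()
        frame.loc[frame["role"] == "safe", "gene"] = SAFE
        targeting = frame[frame["role"] == "targeting"]
        empty = targeting["gene"].isna() | (targeting["gene"] == "") | (
            targeting["gene"] == SAFE
        )
        if empty.any():
            raise ValidationError(
                "targeting guides without a gene symbol: "
                f"{targeting.loc[empty, 'guide_id'].tolist()}"
            )
        self.frame = frame.reset_index(drop=True)

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.frame["guide_id"])

    @property
    def genes(self) -> list[str]:
        """Distinct targeted genes (safe pseudo-gene excluded)."""
        mask = self.frame["role"] == "targeting"
        return sorted(self.frame.loc[mask, "gene"].unique())

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def safe_guides(self) -> list[str]:
        return self.frame.loc[self.frame["role"] == "safe", "guide_id"].tolist()

    def gene_of(self) -> pd.Series:
        """guide_id -> gene mapping (safe guides map to SAFE)."""
        return self.frame.set_index("guide_id")["gene"]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class DualDesign:
    """Fully crossed two-position dual-guide construct design.

    ``frame`` columns: ``construct_id``, ``guide_pos1``, ``guide_pos2``,
    ``gene_pos1``, ``gene_pos2``, ``pair_label`` (ordered, position order) and
    ``pair`` (unordered alias, sorted gene names) -- the unordered alias is
    what interaction scoring aggregates over.
    """

    frame: pd.DataFrame
    library: GuideLibrary

    def __post_init__(self) -> None:
        known = set(self.library.guide_ids)
        for col in ("guide_pos1", "guide_pos2"):
            unknown = set(self.frame[col]) - known
            if unknown:
                raise ValidationError(
                    f"{col} references guides absent from library: {sorted(unknown)[:5]}"
                )
        if self.frame["construct_id"].duplicated().any():
            raise ValidationError("duplicate construct_id in dual design")

    @property
    def construct_ids(self) -> pd.Index:
        return pd.Index(self.frame["construct_id"])

    @property
    def n_constructs(self) -> int:
        return len(self.frame)

    @property
    def n_ordered_pair_labels(self) -> int:
        """Ordered targeted-gene pair labels; safe pairings excluded."""
        mask = (self.frame["gene_pos1"] != SAFE) & (self.frame["gene_pos2"] != SAFE)
        return self.frame.loc[mask, "pair_label"].nunique()

    @property
    def n_safe_safe_constructs(self) -> int:
        mask = (self.frame["gene_pos1"] == SAFE) & (self.frame["gene_pos2"] == SAFE)
        return int(mask.sum())

    @property
    def n_unordered_pairs(self) -> int:
        """Unordered distinct-gene targeted pairs (the screened-pair count)."""
        mask = (
            (self.frame["gene_pos1"] != SAFE)
            & (self.frame["gene_pos2"] != SAFE)
            & (self.frame["gene_pos1"] != self.frame["gene_pos2"])
        )
        return self.frame.loc[mask, "pair"].nunique()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CountTable:
    """Integer (or, after normalization, real-valued) counts: rows x samples."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            dups = self.frame.index[self.frame.index.duplicated()].unique()
            raise ValidationError(f"duplicate row ids: {sorted(dups)[:5]}")
        if self.frame.isna().any().any():
            raise ValidationError("count table contains missing cells")
        if (self.frame.to_numpy() < 0).any():
            raise ValidationError("count table contains negative values")

    @property
    def row_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.columns

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ScreenDesign:
    """Sample sheet: sample -> timepoint, condition, replicate."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "timepoint", "condition", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"screen design missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in screen design")
        bad_tp = set(self.frame["timepoint"]) - VALID_TIMEPOINTS
        if bad_tp:
            raise ValidationError(f"unknown timepoint(s): {sorted(bad_tp)}")
        if not (self.frame["timepoint"] == "T0").any():
            raise ValidationError("screen design has no T0 sample")
        reps = self.frame["replicate"]
        if (reps.astype(int) != reps).any() or (reps.astype(int) < 1).any():
            raise ValidationError("replicate must be a positive integer")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.frame["sample_id"])

    @property
    def t0_samples(self) -> list[str]:
        mask = self.frame["timepoint"] == "T0"
        return self.frame.loc[mask, "sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        mask = self.frame["timepoint"] == "Tend"
        return sorted(self.frame.loc[mask, "condition"].unique())

    def tend_samples(self, condition: str | None = None) -> pd.DataFrame:
        mask = self.frame["timepoint"] == "Tend"
        if condition is not None:
            mask &= self.frame["condition"] == condition
        return self.frame.loc[mask]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): set name -> description + members."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class ExpressionMatrix:
    """log2 expression (genes x samples) with per-sample metadata.

    ``meta`` is indexed by sample id with columns ``kind`` (patient or
    cell_line), ``response`` (responder / non_responder / NA), ``timepoint``
    (baseline / post_chemo / NA) and ``batch``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")
        self.meta = self.meta.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata matches all keyword equalities."""
        mask = pd.Series(True, index=self.meta.index)
        for key, value in conditions.items():
            mask &= self.meta[key] == value
        return self.meta.index[mask].tolist()

    @property
    def cell_lines(self) -> list[str]:
        return self.samples_where(kind="cell_line")

    @property
    def patients(self) -> list[str]:
        return self.samples_where(kind="patient")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return dataclasses.replace(self, values=self.values.loc[list(genes)])


def as_count_frame(obj) -> pd.DataFrame:
    """Accept a CountTable or a plain DataFrame and return the frame."""
    if isinstance(obj, CountTable):
        return obj.frame
    if isinstance(obj, pd.DataFrame):
        return obj
    raise TypeError(f"expected CountTable or DataFrame, got {type(obj).__name__}")
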