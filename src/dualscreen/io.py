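"""Readers/writers for the tabular formats the pipeline touches.

All tabular I/O is tab-separated with a header row; gene sets use the
standard GMT format.  Construction of the fully crossed dual-guide design
also lives here because it is pure library bookkeeping.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CONSTRUCT_SEPARATOR,
    SAFE,
    CountTable,
    DualDesign,
    GeneSetCollection,
    GuideLibrary,
    ScreenDesign,
    ValidationError,
    pair_key,
)


def read_guide_library(path: str | Path) -> GuideLibrary:
    """Read a guide library TSV with columns guide_id, gene, role.

    Safe guides are normalized to the SAFE sentinel.  Duplicate guide ids and
    unknown roles are hard errors.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame.columns = [c.strip() for c in frame.columns]
    return GuideLibrary(frame[["guide_id", "gene", "role"]])


def write_guide_library(library: GuideLibrary, path: str | Path) -> None:
    library.frame.to_csv(path, sep="\t", index=False)


def make_synthetic_library(
    n_genes: int,
    guides_per_gene: int = 3,
    n_safe: int = 0,
    gene_prefix: str = "G",
    genes: list[str] | None = None,
) -> GuideLibrary:
    """Build a synthetic guide library with ``n_genes`` targeted genes.

    Gene names default to ``G001``.. and guides to ``G001_g1``..; safe-harbor
    guides are named ``SAFE_s1``.. and carry the SAFE sentinel.
    """
    if genes is None:
        width = max(3, len(str(n_genes)))
        genes = [f"{gene_prefix}{i + 1:0{width}d}" for i in range(n_genes)]
    rows = []
    for gene in genes:
        for j in range(guides_per_gene):
            rows.append((f"{gene}_g{j + 1}", gene, "targeting"))
    for j in range(n_safe):
        rows.append((f"SAFE_s{j + 1}", SAFE, "safe"))
    frame = pd.DataFrame(rows, columns=["guide_id", "gene", "role"])
    return GuideLibrary(frame)


def build_dual_design(
    library: GuideLibrary, separator: str = CONSTRUCT_SEPARATOR
) -> DualDesign:
    """Full cross of all guides over the two cassette positions.

    For ``n`` guides this yields exactly ``n**2`` constructs.  Each construct
    carries the ordered gene-pair label (position order) and an unordered
    alias used by interaction scoring.
    """
    if len(library) == 0:
        raise ValidationError("cannot build a dual design from an empty library")
    guides = library.frame["guide_id"].to_numpy(dtype=str)
    genes = library.frame["gene"].to_numpy(dtype=str)
    n = len(guides)
    idx1 = np.repeat(np.arange(n), n)
    idx2 = np.tile(np.arange(n), n)
    g1, g2 = guides[idx1], guides[idx2]
    gene1, gene2 = genes[idx1], genes[idx2]
    first = gene1 <= gene2
    lo = np.where(first, gene1, gene2)
    hi = np.where(first, gene2, gene1)
    frame = pd.DataFrame(
        {
            "construct_id": np.char.add(np.char.add(g1, separator), g2),
            "guide_pos1": g1,
            "guide_pos2": g2,
            "gene_pos1": gene1,
            "gene_pos2": gene2,
            "pair_label": np.char.add(np.char.add(gene1, "|"), gene2),
            "pair": np.char.add(np.char.add(lo, "__"), hi),
        }
    )
    return DualDesign(frame, library)


def read_count_table(path: str | Path, design: ScreenDesign | None = None) -> CountTable:
    """Read a counts TSV (first column row id, remaining columns samples).

    Cells must be non-negative integers; violations are reported with their
    row/sample coordinates.  When a design is given, every sample column must
    appear in it and the columns are aligned to the design order.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        frame_num = frame.apply(pd.to_numeric, errors="coerce")
        bad = frame_num.isna()
        if bad.any().any():
            row, col = _first_bad_cell(bad)
            raise ValidationError(
                f"non-numeric count at row {row!r}, sample {col!r}"
            )
        frame = frame_num
        values = frame.to_numpy()
    nonint = frame != np.floor(frame)
    if nonint.any().any():
        row, col = _first_bad_cell(nonint)
        raise ValidationError(
            f"non-integer count {frame.loc[row, col]!r} at row {row!r}, sample {col!r}"
        )
    neg = frame < 0
    if neg.any().any():
        row, col = _first_bad_cell(neg)
        raise ValidationError(f"negative count at row {row!r}, sample {col!r}")
    frame = frame.astype(np.int64)
    if design is not None:
        extra = set(frame.columns) - set(design.sample_ids)
        if extra:
            raise ValidationError(
                f"samples in count file absent from design: {sorted(extra)}"
            )
        present = [s for s in design.sample_ids if s in frame.columns]
        frame = frame[present]
    return CountTable(frame)


def _first_bad_cell(mask: pd.DataFrame) -> tuple:
    stacked = mask.stack()
    row, col = stacked[stacked].index[0]
    return row, col


def write_count_table(counts: CountTable, path: str | Path, row_label: str = "id") -> None:
    frame = counts.frame.copy()
    frame.index.name = row_label
    frame.to_csv(path, sep="\t")


def read_screen_design(path: str | Path) -> ScreenDesign:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "timepoint": str,
                                               "condition": str})
    return ScreenDesign(frame)


def write_screen_design(design: ScreenDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def make_screen_design(
    conditions=("control",),
    n_replicates: int = 3,
    n_t0: int | None = None,
) -> ScreenDesign:
    """Standard pooled-screen sample sheet: shared T0 + one Tend arm per condition."""
    if n_t0 is None:
        n_t0 = n_replicates
    rows = [(f"T0_{r + 1}", "T0", "baseline", r + 1) for r in range(n_t0)]
    for cond in conditions:
        tag = cond.replace("drug:", "")
        for r in range(n_replicates):
            rows.append((f"Tend_{tag}_{r + 1}", "Tend", cond, r + 1))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "timepoint", "condition", "replicate"]
    )
    return ScreenDesign(frame)


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes.

    Duplicate members within a set are removed (first occurrence kept).
    Lines with fewer than three fields are hard errors with their line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line {lineno} has {len(fields)} fields; expected >= 3"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *members]) + "\n")


def read_expression_matrix(values_path, meta_path):
    from .containers import ExpressionMatrix

    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta)


def write_expression_matrix(matrix, values_path, meta_path) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    matrix.meta.to_csv(meta_path, sep="\t")
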