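"""Dependency-screen counting and MTT viability arithmetic.

Works on CSV matrices in the DepMap portal layout (rows = cell lines,
columns = genes, headers like ``"FTO (79068)"``). A line counts as
dependent on a gene when its dependency probability is strictly greater
than 0.5; gene-effect scores sit on a scale where 0 is non-essential and
−1 is the median of common essential genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "load_dependency_matrix",
    "load_lineage_map",
    "resolve_gene_column",
    "count_dependent",
    "summarize_gene_effect",
    "ViabilityResult",
    "mtt_viability",
]


def load_dependency_matrix(path) -> pd.DataFrame:
    """Load a DepMap-style CSV (first column = ModelID) indexed by line."""
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate cell-line identifiers: {dups}")
    return df


def load_lineage_map(path) -> pd.DataFrame:
    """Load a lineage annotation CSV (ModelID, lineage[, subtype])."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "modelid" not in cols or "lineage" not in cols:
        raise ValueError("lineage map needs ModelID and lineage columns")
    return df.rename(
        columns={cols["modelid"]: "ModelID", cols["lineage"]: "lineage"}
    )


def resolve_gene_column(matrix: pd.DataFrame, gene: str) -> str:
    """Find the matrix column for a gene symbol.

    Exact match first, then the portal's ``"SYMBOL (ENTREZID)"`` form by
    symbol prefix. Ambiguity or absence raises.
    """
    if gene in matrix.columns:
        return gene
    prefix = [
        c for c in matrix.columns
        if c.split(" (")[0] == gene or c.split(" ")[0] == gene
    ]
    if len(prefix) == 1:
        return prefix[0]
    if len(prefix) > 1:
        raise KeyError(f"gene {gene!r} matches multiple columns: {prefix}")
    raise KeyError(f"gene {gene!r} not found in matrix")


def _gene_values(
    matrix: pd.DataFrame, gene: str, subset: Sequence[str] | None
) -> pd.Series:
    col = resolve_gene_column(matrix, gene)
    vals = matrix[col]
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("subset must be non-empty when given")
        present = vals.index.intersection(subset)
        if len(present) == 0:
            raise ValueError("subset shares no cell lines with the matrix")
        vals = vals.loc[present]
    vals = vals.dropna()
    if vals.empty:
        raise ValueError(f"all values missing for gene {gene!r}")
    return vals


def count_dependent(
    matrix: pd.DataFrame,
    gene: str,
    threshold: float = 0.5,
    subset: Sequence[str] | None = None,
) -> tuple[int, int]:
    """Count lines dependent on a gene: probability strictly > threshold.

    Returns ``(n_dependent, n_total)`` over lines with a non-missing
    probability (a line without a score cannot be classified, so missing
    values are excluded from both counts). ``subset`` restricts to a set
    of line identifiers, e.g. the AML lineage.
    """
    vals = _gene_values(matrix, gene, subset)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("probabilities outside [0,1]; wrong matrix kind?")
    return int((vals > threshold).sum()), int(vals.size)


def summarize_gene_effect(
    matrix: pd.DataFrame,
    gene: str,
    subset: Sequence[str] | None = None,
) -> dict:
    """Summaries of a gene-effect column over non-missing values."""
    vals = _gene_values(matrix, gene, subset)
    return {
        "n": int(vals.size),
        "median": float(vals.median()),
        "frac_le_m05": float((vals <= -0.5).mean()),
        "frac_le_m1": float((vals <= -1.0).mean()),
    }


@dataclass(frozen=True)
class ViabilityResult:
    viability_pct: float
    n_treated: int
    n_control: int


def mtt_viability(
    treated: Sequence[float], control: Sequence[float]
) -> ViabilityResult:
    """Viability % = 100 · mean(treated) / mean(control) absorbances."""
    t = np.asarray(list(treated), dtype=float)
    c = np.asarray(list(control), dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("treated and control must be non-empty")
    if c.mean() <= 0:
        raise ValueError("control mean absorbance must be > 0")
    return ViabilityResult(
        100.0 * float(t.mean()) / float(c.mean()), int(t.size), int(c.size)
    )
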