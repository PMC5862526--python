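"""Ranking candidate marker genes by induction frequency and consistency.

A candidate panel is scored on a grid of (structure, experience) *cells*:
within each cell the fold inductions of the replicate mice are averaged.
Two per-gene statistics are computed on this grid:

* ``frequency_count`` (#) — in how many cells the mean fold induction
  reaches a threshold (default two-fold), out of
  n_structures x n_experiences possible appearances;
* ``avg_variance`` (S²) — the mean over cells of the within-cell
  variance of induction magnitude, a measure of (in)consistency.

Genes are ranked highest-frequency-first and lowest-variance-first; the
combined rank is the rank of the rank sum, and the top genes form the
marker panel.  Control cohorts (rows normalized against their own
group) are excluded from the grid by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import schema as S
from .errors import FeatureError, SchemaError

__all__ = [
    "induction_frequency",
    "induction_variance",
    "rank_markers",
    "select_markers",
]


def _drop_controls(folds: pd.DataFrame, include_controls: bool) -> pd.DataFrame:
    if include_controls or S.CONTROL_GROUP not in folds.columns:
        return folds
    return folds[folds[S.EXPERIENCE] != folds[S.CONTROL_GROUP]]


def _cell_stats(folds: pd.DataFrame, scale: str, ddof: int) -> pd.DataFrame:
    if scale == "log2":
        folds = folds.assign(**{S.FOLD: np.log2(folds[S.FOLD])})
    elif scale != "fold":
        raise SchemaError(f"unknown variance scale: {scale!r}")
    g = folds.groupby([S.GENE, S.STRUCTURE, S.EXPERIENCE], sort=False)[S.FOLD]
    return pd.DataFrame({"mean": g.mean(), "var": g.var(ddof=ddof), "n": g.size()})


def induction_frequency(
    folds: pd.DataFrame,
    threshold: float = 2.0,
    strict: bool = False,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Count, per gene, the cells whose mean fold induction reaches threshold.

    Returns a frame indexed by gene with ``frequency_count`` and the
    ``denominator`` (number of non-empty cells on the structure x
    experience grid).  ``strict=True`` uses > instead of >=.
    """
    if threshold <= 0:
        raise FeatureError("threshold must be > 0")
    folds = _drop_controls(folds, include_controls)
    cells = _cell_stats(folds, scale="fold", ddof=1)
    hit = cells["mean"] > threshold if strict else cells["mean"] >= threshold
    count = hit.groupby(level=S.GENE, sort=False).sum().astype(int)
    denom = cells.groupby(level=S.GENE, sort=False).size()
    return pd.DataFrame({"frequency_count": count, "denominator": denom})


def induction_variance(
    folds: pd.DataFrame,
    scale: str = "fold",
    cells: str = "all",
    threshold: float = 2.0,
    ddof: int = 1,
    include_controls: bool = False,
) -> pd.Series:
    """Per-gene average within-cell variance of induction magnitude (S²).

    The variance is taken across replicate mice within each (structure,
    experience) cell, then averaged over cells.  ``scale`` selects the
    induction unit (linear ``"fold"``, default, or ``"log2"``);
    ``cells="induced"`` averages only over cells whose mean induction
    reaches ``threshold``.
    """
    folds = _drop_controls(folds, include_controls)
    stats = _cell_stats(folds, scale=scale, ddof=ddof)
    usable = stats.dropna(subset=["var"])  # singleton cells carry no variance
    if usable.empty:
        raise FeatureError("every cell is a singleton; variance undefined")
    if cells == "induced":
        ref = _cell_stats(folds, "fold", ddof)
        usable = usable[ref.loc[usable.index, "mean"] >= threshold]
    elif cells != "all":
        raise SchemaError(f"unknown cell-inclusion mode: {cells!r}")
    return usable.groupby(level=S.GENE, sort=False)["var"].mean().rename("S2")


def _lexico_rank(primary: pd.Series, ascending: bool) -> pd.Series:
    """Integer ranks 1..n; ties broken lexicographically by gene name."""
    order = sorted(
        primary.index, key=lambda g: ((primary[g] if ascending else -primary[g]), g)
    )
    return pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank").reindex(
        primary.index
    )


def rank_markers(
    freq: pd.Series | pd.DataFrame, var: pd.Series, n_select: int
) -> tuple[pd.DataFrame, list[str]]:
    """Combine frequency and inverse-variance rankings; pick the top panel.

    ``combined_rank`` is the rank of (frequency rank + variance rank),
    where frequency ranks descending (most frequent first) and variance
    ranks ascending (most consistent first); all ties break
    lexicographically by gene name.  Returns the full ranking table and
    the ``n_select`` top genes.
    """
    if isinstance(freq, pd.DataFrame):
        denominator = freq.get("denominator")
        freq = freq["frequency_count"]
    else:
        denominator = None
    if set(freq.index) != set(var.index):
        raise FeatureError("frequency and variance tables cover different gene sets")
    if not 1 <= n_select <= len(freq):
        raise FeatureError(f"n_select={n_select} outside [1, {len(freq)}]")
    var = var.reindex(freq.index)
    freq_rank = _lexico_rank(freq.astype(float), ascending=False)
    var_rank = _lexico_rank(var.astype(float), ascending=True)
    combined = _lexico_rank((freq_rank + var_rank).astype(float), ascending=True)
    table = pd.DataFrame(
        {
            "frequency_count": freq,
            "S2": var,
            "freq_rank": freq_rank,
            "var_rank": var_rank,
            "combined_rank": combined,
        }
    )
    if denominator is not None:
        table.insert(1, "denominator", denominator)
    table = table.sort_values("combined_rank")
    selected = list(table.index[:n_select])
    table["selected"] = table.index.isin(selected)
    table.index.name = S.GENE
    return table, selected


def select_markers(
    folds: pd.DataFrame,
    threshold: float = 2.0,
    n_select: int = 5,
    variance_scale: str = "fold",
    variance_cells: str = "all",
) -> tuple[pd.DataFrame, list[str]]:
    """One-call frequency + variance ranking from a fold table."""
    freq = induction_frequency(folds, threshold=threshold)
    var = induction_variance(
        folds, scale=variance_scale, cells=variance_cells, threshold=threshold
    )
    return rank_markers(freq, var, n_select)
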