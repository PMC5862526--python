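"""Ct normalization: global-reference ΔCt, ΔΔCt fold induction, feature assembly.

The quantitation chain for qPCR follows the ΔΔCt convention with an
assumed primer efficiency of 100%, i.e. one PCR cycle corresponds to one
doubling of transcript (one log2 unit):

* ΔCt normalizes each gene's Ct to a per-sample reference — either a
  single housekeeping gene or the mean Ct over a set of stably expressed
  reference genes (the "global-normalization" value).
* ΔΔCt subtracts the mean ΔCt of the sample's control group, and fold
  induction is ``2 ** -ΔΔCt``.

A *sample* is one (mouse, structure) RNA preparation; a mouse contributes
one sample per dissected structure.  Control-group membership is encoded
in the ``control_group`` column: each row names the experience label of
the control group it is normalized against, and control animals point at
their own experience so that their folds average (geometrically) to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import schema as S
from .errors import FeatureError, MissingReferenceError, NormalizationError, SchemaError

__all__ = [
    "FeatureMatrix",
    "validate_ct_table",
    "global_reference_ct",
    "delta_ct",
    "fold_induction",
    "assemble_features",
]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the raw Ct table against the expected schema.

    Returns the table unchanged on success; raises :class:`SchemaError`
    naming the offending column or rows otherwise.
    """
    missing = [c for c in S.CT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"Ct table is missing required columns: {missing}")
    ct = pd.to_numeric(table[S.CT], errors="coerce")
    bad = table.index[~np.isfinite(ct) | (ct <= 0)]
    if len(bad):
        raise SchemaError(
            f"non-numeric, non-finite or non-positive Ct values at rows {list(bad[:10])}"
        )
    dup = table.duplicated([S.MOUSE, S.STRUCTURE, S.GENE])
    if dup.any():
        raise SchemaError(
            f"duplicate (mouse, structure, gene) measurements at rows "
            f"{list(table.index[dup][:10])}"
        )
    return table


def global_reference_ct(
    table: pd.DataFrame, reference_genes: list[str] | None = None
) -> pd.Series:
    """Per-sample global-normalization Ct value.

    The reference value for a sample is the arithmetic mean Ct of the
    reference genes measured in that sample.

    Returns a Series indexed by (mouse_id, structure), in cycles.
    """
    if reference_genes is None:
        reference_genes = S.REFERENCE_GENES
    ref_rows = table[table[S.GENE].isin(reference_genes)]
    samples = table.groupby([S.MOUSE, S.STRUCTURE], sort=False).size().index
    means = ref_rows.groupby([S.MOUSE, S.STRUCTURE], sort=False)[S.CT].mean()
    missing = samples.difference(means.index)
    if len(missing):
        raise MissingReferenceError(
            f"samples with no measured reference gene: {list(missing[:10])}"
        )
    return means.reindex(samples)


def delta_ct(
    table: pd.DataFrame,
    mode: str = "global",
    reference: list[str] | str | None = None,
) -> pd.DataFrame:
    """Normalize Ct values to a per-sample reference (ΔCt).

    Parameters
    ----------
    mode
        ``"global"`` — reference is the mean Ct over a reference gene set
        (the global-normalization value); the reference genes themselves
        are excluded from the output.  ``"single_gene"`` — reference is
        one housekeeping gene (e.g. GAPDH), kept by name.
    reference
        The reference gene list (global mode, defaults to the stable
        8-gene panel) or the single housekeeping gene name.

    Returns a tidy frame with a ``delta_ct`` column (cycles).
    """
    validate_ct_table(table)
    if mode == "global":
        ref_genes = list(S.REFERENCE_GENES) if reference is None else list(reference)
        ref = global_reference_ct(table, ref_genes)
        out = table[~table[S.GENE].isin(ref_genes)].copy()
    elif mode == "single_gene":
        if not isinstance(reference, str):
            raise SchemaError("single_gene mode requires a reference gene name")
        ref_genes = [reference]
        ref = global_reference_ct(table, ref_genes)
        out = table.copy()
    else:
        raise SchemaError(f"unknown normalization mode: {mode!r}")
    sample_idx = pd.MultiIndex.from_frame(out[[S.MOUSE, S.STRUCTURE]])
    out[S.DELTA_CT] = out[S.CT].to_numpy() - ref.reindex(sample_idx).to_numpy()
    return out.drop(columns=[S.CT])


def fold_induction(dct: pd.DataFrame) -> pd.DataFrame:
    """ΔΔCt fold induction relative to each sample's control group.

    The control group of a row is the set of samples whose ``experience``
    equals the row's ``control_group``, restricted to the same structure
    and gene.  Averaging is done on the ΔCt (log) scale, i.e. the control
    baseline is a geometric mean of expression, and::

        fold = 2 ** -(ΔCt_sample - mean ΔCt_control)

    Control animals reference their own group, so for any control group
    and gene the geometric mean of fold over its members is 1.
    """
    if S.DELTA_CT not in dct.columns:
        raise SchemaError("fold_induction expects a delta_ct column; run delta_ct first")
    ctrl_mean = (
        dct.groupby([S.EXPERIENCE, S.STRUCTURE, S.GENE], sort=False)[S.DELTA_CT]
        .mean()
    )
    key = pd.MultiIndex.from_frame(dct[[S.CONTROL_GROUP, S.STRUCTURE, S.GENE]])
    baseline = ctrl_mean.reindex(key)
    if baseline.isna().any():
        bad = key[np.asarray(baseline.isna())][:10]
        raise NormalizationError(
            "empty control group for (control_group, structure, gene): "
            f"{list(bad)}"
        )
    out = dct.copy()
    out[S.FOLD] = 2.0 ** -(out[S.DELTA_CT].to_numpy() - baseline.to_numpy())
    return out.drop(columns=[S.DELTA_CT])


@dataclass
class FeatureMatrix:
    """A rectangular mouse x (gene, structure) feature table with labels.

    ``values`` is indexed by mouse_id with one column per feature
    ("gene:structure"); ``labels`` maps mouse_id -> experience class;
    ``transform`` records the scale of the values ("linear" fold or
    "log2" fold).
    """

    values: pd.DataFrame
    labels: pd.Series
    transform: str = "log2"

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            raise FeatureError("every mouse in the feature matrix needs a label")
        if self.values.isna().any().any():
            raise FeatureError("feature matrix must be complete (no missing values)")

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def classes(self) -> list:
        return sorted(pd.unique(self.labels))

    def __len__(self) -> int:
        return len(self.values)

    def select(self, features: list[str]) -> "FeatureMatrix":
        """Restrict to a feature subset (order as given)."""
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise FeatureError(f"unknown features: {missing}")
        return replace(self, values=self.values[list(features)])

    def with_labels(self, labels: pd.Series) -> "FeatureMatrix":
        return replace(self, labels=labels.reindex(self.values.index))


def assemble_features(
    folds: pd.DataFrame,
    genes: list[str] | None = None,
    structures: list[str] | None = None,
    transform: str = "log2",
    missing_policy: str = "drop",
    drop_controls: bool = True,
) -> FeatureMatrix:
    """Pivot a fold table into per-mouse feature vectors.

    One row per mouse, one column per requested (gene, structure)
    feature.  ``transform="log2"`` stores log2 fold (symmetric in
    induction/repression); ``"linear"`` stores the raw fold ratio.

    ``missing_policy``: ``"drop"`` removes mice lacking any feature,
    ``"strict"`` raises listing them, ``"impute"`` fills gaps with the
    no-induction value (fold 1, log2 fold 0).

    Control animals (rows normalized against their own group, i.e.
    experience == control_group) exist to anchor the fold scale, not to
    be decoded; ``drop_controls`` excludes them.
    """
    genes = list(S.MARKER_GENES) if genes is None else list(genes)
    structures = list(S.STRUCTURES) if structures is None else list(structures)
    if not genes or not structures:
        raise FeatureError("genes and structures must be nonempty")
    if transform not in ("linear", "log2"):
        raise FeatureError(f"unknown transform: {transform!r}")

    if drop_controls and S.CONTROL_GROUP in folds.columns:
        folds = folds[folds[S.EXPERIENCE] != folds[S.CONTROL_GROUP]]
    sub = folds[folds[S.GENE].isin(genes) & folds[S.STRUCTURE].isin(structures)]
    wide = sub.pivot_table(
        index=S.MOUSE, columns=[S.GENE, S.STRUCTURE], values=S.FOLD, aggfunc="mean"
    )
    columns = [(g, s) for g in genes for s in structures]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(columns))
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        if missing_policy == "strict":
            report = {
                m: [S.feature_name(g, s) for (g, s) in wide.columns[wide.loc[m].isna()]]
                for m in incomplete
            }
            raise FeatureError(f"mice with missing features: {report}")
        if missing_policy == "drop":
            wide = wide.drop(index=incomplete)
        elif missing_policy == "impute":
            wide = wide.fillna(1.0)
        else:
            raise FeatureError(f"unknown missing_policy: {missing_policy!r}")
    if transform == "log2":
        wide = np.log2(wide)
    wide.columns = [S.feature_name(g, s) for (g, s) in wide.columns]

    labels = (
        folds.drop_duplicates(S.MOUSE).set_index(S.MOUSE)[S.EXPERIENCE]
    ).reindex(wide.index)
    return FeatureMatrix(values=wide, labels=labels, transform=transform)
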