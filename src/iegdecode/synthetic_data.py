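"""Synthetic Ct-level and feature-level datasets with known ground truth.

The generator emulates the design of a multi-structure immediate-early
gene induction study: a panel of marker genes measured by qPCR across
several brain structures, in cohorts of mice that each underwent one
labeled experience.  Each experience class has a characteristic mean
log2 fold-induction pattern over (gene, structure) features; mice vary
around the class mean with Gaussian noise on the log2 scale (Ct is a
log2 quantity by construction, so Gaussian Ct error and Gaussian log2
fold error are the same model).  One PCR cycle is one log2 unit of
expression (100% primer efficiency assumed).

Two kinds of output are produced:

* :func:`generate_feature_matrix` — the per-mouse feature vectors
  directly, on the log2 fold scale (the decoding substrate).
* :func:`generate_ct_dataset` — raw Ct measurements including reference
  genes and baseline control cohorts, suitable for exercising the full
  ΔΔCt normalization chain; piping them through :mod:`.normalization`
  recovers the configured effects in expectation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema as S
from .errors import ConfigurationError
from .normalization import FeatureMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_feature_matrix",
    "generate_ct_dataset",
    "default_config",
    "sparse_signature_config",
    "null_config",
    "DEFAULT_EXPERIENCES",
]

#: Default experience classes: pharmacological and naturalistic rewarding
#: and aversive experiences, acute and repeated.
DEFAULT_EXPERIENCES = [
    "cocaine_acute",
    "cocaine_repeated",
    "cocaine_challenge",
    "licl_acute",
    "licl_repeated",
    "saline_acute",
    "saline_repeated",
    "sucrose_acute",
    "sucrose_repeated",
    "feeding_reinstatement",
]


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic dataset.

    ``effect`` maps (experience, gene, structure) to the mean log2 fold
    induction of that feature in that class; absent keys mean 0.  The
    ``informative_mask`` is the set of (gene, structure) features with a
    nonzero effect in at least one class; it is derived from ``effect``
    unless given explicitly, in which case it must agree.
    """

    experiences: list[str]
    genes: list[str]
    structures: list[str]
    reference_genes: list[str] = field(default_factory=lambda: list(S.REFERENCE_GENES))
    n_per_class: int = 5
    effect: dict[tuple[str, str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.5
    baseline_ct: dict[str, float] = field(default_factory=dict)
    ct_noise_sd: float = 0.25
    seed: int = 0
    informative_mask: frozenset[tuple[str, str]] | None = None
    #: When True, all cohorts are normalized against one common baseline
    #: cohort instead of one matched control cohort per experience.
    #: Per-experience controls share their cohort's finite-sample
    #: normalization error with their treated group, which imprints a
    #: class-correlated offset on the folds even at zero effect; a
    #: calibration (null) design must therefore use a shared baseline.
    shared_control: bool = False

    def __post_init__(self) -> None:
        if not self.experiences or not self.genes or not self.structures:
            raise ConfigurationError(
                "experiences, genes and structures must all be nonempty"
            )
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        for (e, g, s) in self.effect:
            if e not in self.experiences or g not in self.genes or s not in self.structures:
                raise ConfigurationError(f"effect key outside the declared design: {(e, g, s)}")
        derived = frozenset(
            (g, s) for (e, g, s), v in self.effect.items() if v != 0.0
        )
        if self.informative_mask is None:
            self.informative_mask = derived
        elif frozenset(self.informative_mask) != derived:
            raise ConfigurationError(
                "informative_mask disagrees with the nonzero entries of effect"
            )
        if not self.baseline_ct:
            self.baseline_ct = {g: 24.0 for g in self.genes}
            self.baseline_ct.update({r: 20.0 for r in self.reference_genes})

    def effect_of(self, experience: str, gene: str, structure: str) -> float:
        return self.effect.get((experience, gene, structure), 0.0)

    @property
    def features(self) -> list[tuple[str, str]]:
        return [(g, s) for g in self.genes for s in self.structures]


@dataclass
class GroundTruth:
    """What the generator knows: labels, true effects, informative features."""

    labels: dict[str, str]
    true_effect: dict[tuple[str, str, str], float]
    informative_mask: frozenset[tuple[str, str]]


def _mouse_ids(config: SimulationConfig) -> dict[str, list[str]]:
    ids, counter = {}, itertools.count(1)
    for e in config.experiences:
        ids[e] = [f"m{next(counter):03d}" for _ in range(config.n_per_class)]
    return ids


def generate_feature_matrix(
    config: SimulationConfig,
) -> tuple[FeatureMatrix, GroundTruth]:
    """Draw per-mouse log2 fold feature vectors around the class means.

    Feature value for a mouse of class e at feature (g, s) is
    ``effect(e, g, s) + Normal(0, noise_sd)``; bit-identical given the
    same config and seed.
    """
    rng = np.random.default_rng(config.seed)
    ids = _mouse_ids(config)
    features = config.features
    rows, labels = [], {}
    for e in config.experiences:
        mu = np.array([config.effect_of(e, g, s) for (g, s) in features])
        for m in ids[e]:
            rows.append(mu + rng.normal(0.0, config.noise_sd, size=len(features)))
            labels[m] = e
    values = pd.DataFrame(
        np.asarray(rows),
        index=pd.Index(list(labels), name=S.MOUSE),
        columns=[S.feature_name(g, s) for (g, s) in features],
    )
    fm = FeatureMatrix(
        values=values, labels=pd.Series(labels, name=S.EXPERIENCE), transform="log2"
    )
    truth = GroundTruth(
        labels=labels,
        true_effect=dict(config.effect),
        informative_mask=frozenset(config.informative_mask),
    )
    return fm, truth


def generate_ct_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a raw Ct table with treated cohorts and baseline controls.

    For every experience a matched control cohort of the same size is
    generated (experience label ``control:<experience>``); treated rows
    point at it through the ``control_group`` column and control rows
    point at themselves.  Marker-gene Ct is ``baseline - effect`` plus
    biological (``noise_sd``) and technical (``ct_noise_sd``) Gaussian
    noise in cycles; reference genes carry technical noise only.
    """
    if not config.reference_genes:
        raise ConfigurationError("generate_ct_dataset needs at least one reference gene")
    for g in list(config.genes) + list(config.reference_genes):
        if g not in config.baseline_ct:
            raise ConfigurationError(f"baseline_ct missing for gene {g!r}")
    rng = np.random.default_rng(config.seed)
    ids = _mouse_ids(config)
    counter = itertools.count(1000)
    records, labels = [], {}

    def emit(mouse: str, experience: str, control_group: str, eff_class: str | None) -> None:
        labels[mouse] = experience
        for s in config.structures:
            for g in config.genes:
                eff = config.effect_of(eff_class, g, s) if eff_class else 0.0
                ct = (
                    config.baseline_ct[g]
                    - eff
                    + rng.normal(0.0, config.noise_sd)
                    + rng.normal(0.0, config.ct_noise_sd)
                )
                records.append((mouse, s, experience, 1, control_group, g, ct))
            for r in config.reference_genes:
                ct = config.baseline_ct[r] + rng.normal(0.0, config.ct_noise_sd)
                records.append((mouse, s, experience, 1, control_group, r, ct))

    if config.shared_control:
        ctrl = "control:common"
        for e in config.experiences:
            for m in ids[e]:
                emit(m, e, ctrl, e)
        for _ in range(config.n_per_class):
            emit(f"m{next(counter):04d}", ctrl, ctrl, None)
    else:
        for e in config.experiences:
            ctrl = f"control:{e}"
            for m in ids[e]:
                emit(m, e, ctrl, e)
            for _ in range(config.n_per_class):
                emit(f"m{next(counter):04d}", ctrl, ctrl, None)

    table = pd.DataFrame(records, columns=S.CT_COLUMNS)
    truth = GroundTruth(
        labels=labels,
        true_effect=dict(config.effect),
        informative_mask=frozenset(config.informative_mask),
    )
    return table, truth


def default_config(
    n_per_class: int = 5,
    effect_size: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SimulationConfig:
    """The default study design: 10 classes, 5 genes x 5 structures.

    Each class induces a characteristic disjoint pair of features (drawn
    from the first four genes) at ``effect_size`` log2 units; the fifth
    gene is silent everywhere.  Classes are therefore mutually
    distinguishable by construction while a fifth of the features carry
    no signal.
    """
    genes, structures = list(S.MARKER_GENES), list(S.STRUCTURES)
    experiences = list(DEFAULT_EXPERIENCES)
    effect: dict[tuple[str, str, str], float] = {}
    n_struct = len(structures)
    signal_features = [(g, s) for g in genes[:4] for s in structures]
    for ci, e in enumerate(experiences):
        for fi, (g, s) in enumerate(signal_features):
            if fi % len(experiences) == ci:
                effect[(e, g, s)] = effect_size
    return SimulationConfig(
        experiences=experiences,
        genes=genes,
        structures=structures,
        n_per_class=n_per_class,
        effect=effect,
        noise_sd=noise_sd,
        seed=seed,
    )


def sparse_signature_config(
    n_per_class: int = 5,
    effect_size: float | list[float] = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SimulationConfig:
    """A design with only five informative features out of twenty-five.

    The informative features are the diagonal (gene_i, structure_i)
    pairs; the ten classes are the ten unordered pairs of those five
    features, each induced at ``effect_size`` log2 units.  Useful for
    feature-selection recovery tests: the informative set is small
    enough to fit in the top quartile of a 25-feature ranking.

    ``effect_size`` may be a list of five values, one per diagonal
    feature, to grade the features' signal strength (and hence impose a
    true importance ordering among them).
    """
    genes, structures = list(S.MARKER_GENES), list(S.STRUCTURES)
    experiences = list(DEFAULT_EXPERIENCES)
    diag = [(genes[i], structures[i]) for i in range(5)]
    sizes = (
        [float(effect_size)] * 5
        if np.isscalar(effect_size)
        else [float(v) for v in effect_size]
    )
    if len(sizes) != 5:
        raise ConfigurationError("effect_size list must have one value per diagonal feature")
    pairs = list(itertools.combinations(range(5), 2))  # 10 pairs for 10 classes
    effect: dict[tuple[str, str, str], float] = {}
    for e, (i, j) in zip(experiences, pairs):
        for idx in (i, j):
            g, s = diag[idx]
            effect[(e, g, s)] = sizes[idx]
    return SimulationConfig(
        experiences=experiences,
        genes=genes,
        structures=structures,
        n_per_class=n_per_class,
        effect=effect,
        noise_sd=noise_sd,
        seed=seed,
    )


def null_config(
    n_per_class: int = 5, noise_sd: float = 0.5, seed: int = 0
) -> SimulationConfig:
    """A zero-effect design: pure noise, no class signal anywhere.

    Uses a shared baseline cohort: with no treatment all animals are
    exchangeable, and per-experience control cohorts would leak a
    class-correlated normalization offset into the folds (see
    :class:`SimulationConfig.shared_control`), which is exactly what a
    calibration dataset must not contain.
    """
    return SimulationConfig(
        experiences=list(DEFAULT_EXPERIENCES),
        genes=list(S.MARKER_GENES),
        structures=list(S.STRUCTURES),
        n_per_class=n_per_class,
        effect={},
        noise_sd=noise_sd,
        seed=seed,
        shared_control=True,
    )
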