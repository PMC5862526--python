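"""End-to-end pipeline: simulate/ingest -> normalize -> rank markers ->
assemble features -> decode -> permutation test -> feature selection.

Every stage writes its table under the output directory before the next
stage runs, so a failing stage leaves all earlier outputs on disk.  All
randomness flows from the single run seed through named per-stage
streams derived with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from . import schema as S
from .decoder import loo_evaluate
from .errors import ConfigurationError, IegDecodeError
from .feature_selection import build_cart_tree, rf_importance, rknn_support, top_n_evaluation
from .io import config_hash, read_ct_table, write_feature_matrix, write_table
from .marker_selection import select_markers
from .normalization import assemble_features, delta_ct, fold_induction
from .permutation import permutation_test
from .synthetic_data import (
    default_config,
    generate_ct_dataset,
    null_config,
    sparse_signature_config,
)

log = logging.getLogger("iegdecode")

_DESIGNS = {
    "default": default_config,
    "sparse": sparse_signature_config,
    "null": null_config,
}

#: Stage names, in execution order; used to derive per-stage seeds.
STAGES = ["simulate", "normalize", "markers", "decode", "permute", "feature_select", "tree"]


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one independent 31-bit seed per pipeline stage."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {name: int(s % (2**31)) for name, s in zip(STAGES, state)}


def simulation_config_from(cfg: dict, seed: int):
    sim = dict(cfg.get("simulate", {}))
    design = sim.pop("design", "default")
    if design not in _DESIGNS:
        raise ConfigurationError(f"unknown simulation design: {design!r}")
    sim.setdefault("seed", seed)
    return _DESIGNS[design](**sim)


def run_all(config: dict, out_dir, seed: int = 0) -> dict:
    """Run the full pipeline; returns the manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": seeds,
        "config_hash": config_hash(config),
        "outputs": {},
    }
    stage = "setup"
    try:
        # -- input ----------------------------------------------------
        if "ct_table" in config.get("input", {}):
            stage = "input"
            ct = read_ct_table(config["input"]["ct_table"])
        else:
            stage = "simulate"
            sim = simulation_config_from(config, seeds["simulate"])
            ct, truth = generate_ct_dataset(sim)
            write_table(ct, out / "ct.csv", seed=seeds["simulate"], config=config)
            (out / "ground_truth.json").write_text(
                json.dumps(
                    {
                        "labels": truth.labels,
                        "informative_features": sorted(
                            S.feature_name(g, s) for g, s in truth.informative_mask
                        ),
                    },
                    indent=2,
                )
            )
            manifest["outputs"]["ct"] = "ct.csv"
        log.info("input: %d Ct measurements", len(ct))

        # -- normalize ------------------------------------------------
        stage = "normalize"
        norm = config.get("normalization", {})
        dct = delta_ct(ct, mode=norm.get("mode", "global"), reference=norm.get("reference"))
        folds = fold_induction(dct)
        write_table(folds, out / "folds.csv", seed=seed, config=config)
        manifest["outputs"]["folds"] = "folds.csv"

        # -- marker ranking -------------------------------------------
        stage = "markers"
        mk = config.get("markers", {})
        ranking, selected = select_markers(
            folds,
            threshold=mk.get("threshold", 2.0),
            n_select=mk.get("n_select", 5),
            variance_scale=mk.get("variance_scale", "fold"),
        )
        write_table(ranking.reset_index(), out / "marker_ranking.csv", seed=seed, config=config)
        manifest["marker_panel"] = selected
        manifest["outputs"]["marker_ranking"] = "marker_ranking.csv"

        # -- features + decoding --------------------------------------
        stage = "decode"
        dec = config.get("decoder", {})
        fm = assemble_features(
            folds,
            genes=dec.get("genes"),
            structures=dec.get("structures"),
            transform=dec.get("transform", "log2"),
        )
        write_feature_matrix(fm, out / "features.csv", seed=seed, config=config)
        cm = loo_evaluate(fm, k=dec.get("k", 1))
        write_table(
            cm.to_frame().reset_index(names="actual"),
            out / "confusion.csv",
            seed=seed,
            config=config,
            extra={"overall_accuracy": f"{cm.overall_accuracy:.6f}"},
        )
        manifest["loo_accuracy"] = cm.overall_accuracy
        manifest["outputs"]["confusion"] = "confusion.csv"
        log.info("decode: LOO accuracy %.3f over %d mice", cm.overall_accuracy, cm.total)

        # -- permutation test -----------------------------------------
        stage = "permute"
        perm_cfg = config.get("permutation", {})
        res = permutation_test(
            fm,
            n_permutations=perm_cfg.get("n_permutations", 1000),
            k=dec.get("k", 1),
            seed=seeds["permute"],
        )
        write_table(
            res.to_frame(),
            out / "null.csv",
            seed=seeds["permute"],
            config=config,
            extra={
                "observed_accuracy": f"{res.observed_accuracy:.6f}",
                "empirical_p": f"{res.empirical_p:.6g}",
                "p_add_one": f"{res.p_add_one:.6g}",
            },
        )
        manifest["empirical_p"] = res.empirical_p
        manifest["mid_p"] = res.mid_p
        manifest["p_add_one"] = res.p_add_one
        manifest["outputs"]["null"] = "null.csv"

        # -- feature selection ----------------------------------------
        stage = "feature_select"
        fs = config.get("feature_selection", {})
        support = rknn_support(
            fm, n_subsets=fs.get("n_subsets", 10_000), seed=seeds["feature_select"]
        )
        write_table(
            support.reset_index(), out / "support.csv", seed=seeds["feature_select"], config=config
        )
        importance = rf_importance(
            fm, n_trees=fs.get("n_trees", 1000), seed=seeds["feature_select"]
        )
        write_table(
            importance.reset_index(), out / "mdg.csv", seed=seeds["feature_select"], config=config
        )
        topn = top_n_evaluation(
            fm, support=support, n_grid=fs.get("n_grid", [1, 2, 4, 8, 16, len(fm.feature_names)])
        )
        write_table(topn, out / "top_n.csv", seed=seeds["feature_select"], config=config)
        manifest["outputs"].update(
            {"support": "support.csv", "mdg": "mdg.csv", "top_n": "top_n.csv"}
        )

        # -- descriptive tree -----------------------------------------
        stage = "tree"
        tree = build_cart_tree(fm)
        (out / "tree.txt").write_text(tree.render() + "\n")
        write_table(tree.to_frame(), out / "tree_nodes.csv", seed=seed, config=config)
        manifest["tree_depth"] = tree.depth
        manifest["outputs"]["tree"] = "tree.txt"
    except IegDecodeError as err:
        raise IegDecodeError(f"pipeline failed in stage {stage!r}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
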