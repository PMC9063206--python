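"""End-to-end orchestration: tables -> cohort -> event log -> Petri net ->
timed state samples -> feature bundles -> classifier -> metrics.

``run_pipeline`` is the single entry point used by the CLI, the ablation
driver and the acceptance script; every stochastic stage derives its seed
from the pipeline seed so a run is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import logging

from .cohort import select_cohort, split_cohort
from .config import PipelineConfig
from .discovery import discover
from .dream import estimate_decay_rates, tss_matrix
from .eventlog import build_event_log, fit_artificial_events
from .evaluate import classification_metrics
from .model import assemble_bundles, build_network, fit_baselines, train
from .synthetic_ehr import generate_ehr

logger = logging.getLogger(__name__)

__all__ = ["prepare_features", "run_pipeline"]


def prepare_features(config: PipelineConfig, tables=None, drop_events=()):
    """Run every stage up to (and including) feature-bundle assembly."""
    config.validate()
    if tables is None:
        tables = generate_ehr(config.synthetic)
    members = select_cohort(tables, config.cohort)
    train_m, val_m, test_m = split_cohort(members, config.split_ratios, seed=config.seed)
    splits = {"train": train_m, "validation": val_m, "test": test_m}
    logger.info("cohort %d -> %d/%d/%d", len(members), len(train_m), len(val_m), len(test_m))

    lab_panel = list(config.synthetic.lab_panel)
    art = fit_artificial_events(
        tables, train_m, k=config.n_artificial_clusters, seed=config.seed
    )
    drop = frozenset(drop_events)
    logs = {
        name: build_event_log(tables, mem, art, lab_panel, drop)
        for name, mem in splits.items()
    }
    net = discover(logs["train"], config.discovery_threshold)
    alphas = estimate_decay_rates(net, logs["train"], beta=config.decay_beta)

    tss_data = {}
    norm = None
    for name in ("train", "validation", "test"):
        X, names, params = tss_matrix(
            logs[name], net, alphas,
            beta=config.decay_beta,
            include_counts=config.include_token_counts,
            include_marking=config.include_marking,
            normalize=config.normalize_tss,
            norm_params=norm,
        )
        if name == "train":
            norm = params
        tss_data[name] = (X, names)

    bundles = assemble_bundles(tables, splits, tss_data, lab_panel)
    return {
        "tables": tables,
        "members": members,
        "splits": splits,
        "art_model": art,
        "logs": logs,
        "net": net,
        "alphas": alphas,
        "bundles": bundles,
    }


def _zero_block(bundles, block: str):
    """Replace one NN input block by a single constant column in every split.

    Used by the variable-ablation study: the branch stays structurally
    present (widths must be >= 1) but carries no information.
    """
    import numpy as np

    for b in bundles.values():
        z = np.zeros((b.n, 1))
        setattr(b, block, z)
        setattr(b, f"{block}_names", [f"{block}_removed"])


def run_pipeline(config: PipelineConfig, tables=None, drop_events=(), zero_blocks=(),
                 nn_overrides=None, train_seed=None, baseline_modes=(),
                 prepared=None) -> dict:
    """Full pipeline run; returns features, trained model and test metrics."""
    if prepared is None:
        prepared = prepare_features(config, tables=tables, drop_events=drop_events)
    bundles = prepared["bundles"]
    for block in zero_blocks:
        _zero_block(bundles, block)

    nn_cfg = dataclasses.replace(config.nn, **(nn_overrides or {}))
    if train_seed is not None:
        nn_cfg = dataclasses.replace(nn_cfg, seed=train_seed)
    widths = tuple(
        b.shape[1]
        for b in (bundles["train"].tss, bundles["train"].demographics, bundles["train"].severity)
    )
    network = build_network(widths, nn_cfg)
    trained = train(network, bundles["train"], bundles["validation"], nn_cfg)
    metrics = classification_metrics(
        trained.scores(bundles["test"]), bundles["test"].y,
        threshold=config.classification_threshold,
    )
    result = dict(prepared)
    result.update({"trained": trained, "metrics": metrics, "nn_config": nn_cfg})

    baselines = {}
    for mode in baseline_modes:
        baselines[mode] = fit_baselines(
            bundles["train"], bundles["validation"], mode=mode, seed=config.seed
        )
    result["baselines"] = baselines
    return result
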