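"""Evaluation: AUROC with DeLong confidence intervals, threshold metrics,
train-vs-validation cohort statistics, grouped Monte-Carlo Shapley
attribution and the variable/layer ablation drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["MetricsReport", "auroc_delong", "classification_metrics",
           "compare_cohorts", "grouped_shapley", "ablation_run",
           "plot_group_importance"]


# ---------------------------------------------------------------------------
# DeLong AUROC


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (ties get the average rank), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def auroc_delong(scores, labels, level: float = 0.95):
    """AUROC (Mann-Whitney with half tie credit) and its DeLong CI.

    The variance comes from the structural components ``V10`` (per positive)
    and ``V01`` (per negative); the CI is the normal interval clipped to
    [0, 1].  Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute AUROC")
    all_scores = np.concatenate([pos, neg])
    tz = _midrank(all_scores)
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # structural components per positive
    v01 = 1.0 - (tz[m:] - ty) / m    # per negative
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


@dataclass
class MetricsReport:
    """AUROC with DeLong CI plus threshold-based classification metrics."""

    auroc: float
    ci_low: float
    ci_high: float
    precision: float
    sensitivity: float
    accuracy: float
    f_score: float
    threshold: float
    n: int
    n_positive: int

    def to_dict(self) -> dict:
        return asdict(self)


def classification_metrics(scores, labels, threshold: float = 0.5,
                           level: float = 0.95) -> MetricsReport:
    """Confusion-matrix metrics at the given score threshold plus DeLong AUROC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        logger.warning("single-class labels: AUROC undefined, reported as NaN")
        auc = lo = hi = float("nan")
    else:
        auc, lo, hi = auroc_delong(scores, labels, level)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    if tp + fp == 0:
        logger.warning("no predicted positives at threshold %.3f; precision set to 0", threshold)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / len(labels)
    f = (2 * precision * sensitivity / (precision + sensitivity)
         if precision + sensitivity else 0.0)
    return MetricsReport(auc, lo, hi, precision, sensitivity, accuracy, f,
                         threshold, len(labels), int(labels.sum()))


# ---------------------------------------------------------------------------
# Cohort comparison


def compare_cohorts(train_df: pd.DataFrame, val_df: pd.DataFrame,
                    categorical: list, continuous: list, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square tests for categorical and two-sided t-tests for continuous
    variables between the train and validation cohorts (significance at
    p < ``alpha``)."""
    rows = []
    for var in categorical:
        counts = pd.concat(
            [train_df[var].value_counts(), val_df[var].value_counts()], axis=1
        ).fillna(0.0)
        if counts.shape[0] < 2:
            stat, p, note = 0.0, 1.0, "single category"
        else:
            stat, p, _, _ = stats.chi2_contingency(counts.to_numpy().T)
            note = ""
        rows.append((var, "categorical", float(stat), float(p), p < alpha, note))
    for var in continuous:
        a = train_df[var].to_numpy(dtype=float)
        b = val_df[var].to_numpy(dtype=float)
        if np.var(a) == 0.0 and np.var(b) == 0.0:
            rows.append((var, "continuous", 0.0, 1.0, False, "zero variance"))
            continue
        stat, p = stats.ttest_ind(a, b)
        rows.append((var, "continuous", float(stat), float(p), p < alpha, ""))
    return pd.DataFrame(
        rows, columns=["variable", "kind", "statistic", "p_value", "significant", "note"]
    )


# ---------------------------------------------------------------------------
# Grouped Monte-Carlo Shapley attribution


def grouped_shapley(predict, X: np.ndarray, groups: dict, background: np.ndarray,
                    n_coalitions: int = 200, seed: int = 0):
    """Mean absolute Shapley contribution of each feature group.

    ``groups`` maps group name -> column indices and must partition the
    columns of ``X``.  Masked groups are imputed with the ``background``
    row (training means).  Permutation sampling: each coalition draw walks
    one random group order, accumulating per-instance marginal
    contributions; the per-group output is the mean absolute per-instance
    Shapley estimate with a batch-means Monte-Carlo standard error.
    """
    cols = sorted(c for idx in groups.values() for c in idx)
    if cols != list(range(X.shape[1])):
        raise ValueError("groups must partition the feature columns")
    rng = np.random.default_rng(seed)
    names = list(groups)
    n, _ = X.shape
    contrib = {g: np.zeros(n) for g in names}
    n_batches = min(10, n_coalitions)
    batch_vals = {g: [] for g in names}
    batch_accum = {g: np.zeros(n) for g in names}
    per_batch = n_coalitions // n_batches

    base_row = np.asarray(background, dtype=float)
    for k in range(n_coalitions):
        order = rng.permutation(len(names))
        cur = np.tile(base_row, (n, 1))
        prev = predict(cur)
        for gi in order:
            g = names[gi]
            cur[:, groups[g]] = X[:, groups[g]]
            new = predict(cur)
            delta = new - prev
            contrib[g] += delta
            batch_accum[g] += delta
            prev = new
        if (k + 1) % per_batch == 0:
            for g in names:
                batch_vals[g].append(np.abs(batch_accum[g] / per_batch).mean())
                batch_accum[g][:] = 0.0

    phi = {g: contrib[g] / n_coalitions for g in names}
    values = {g: float(np.abs(phi[g]).mean()) for g in names}
    se = {
        g: float(np.std(batch_vals[g], ddof=1) / np.sqrt(len(batch_vals[g])))
        if len(batch_vals[g]) > 1 else float("nan")
        for g in names
    }
    return values, se, phi


def plot_group_importance(values: dict, path, se: dict | None = None) -> None:
    """Bar chart of mean |Shapley contribution| per variable group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = sorted(values, key=values.get, reverse=True)
    heights = [values[g] for g in names]
    errs = [se[g] for g in names] if se else None
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(names, heights, yerr=errs, color="#4878d0")
    ax.set_ylabel("mean |Shapley contribution|")
    ax.set_title("Grouped feature attribution")
    plt.xticks(rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Ablation drivers

VARIABLE_ABLATIONS = {
    "none": {},
    "severity": {"zero_blocks": ("severity",)},
    "demographics": {"zero_blocks": ("demographics",)},
    "admission_events": {"drop_events": ("admission", "insurance")},
    "artificial_events": {"drop_events": ("artificial",)},
    "comorbidity_events": {"drop_events": ("comorbidity",)},
    "lab_events": {"drop_events": ("lab",)},
}

LAYER_ABLATIONS = {
    "branch_layers_1": {"nn_overrides": {"branch_hidden_sizes": (128,)}},
    "branch_layers_2": {"nn_overrides": {"branch_hidden_sizes": (128, 64)}},
    "branch_layers_3": {"nn_overrides": {}},
    "branch_layers_4": {"nn_overrides": {"branch_hidden_sizes": (128, 64, 32, 16)}},
    "no_post_concat_layer": {"nn_overrides": {"n_post_concat_layers": 0}},
}


def ablation_run(config, drops, n_repeats: int = 10, tables=None,
                 base_drop_events=()):
    """Re-run the pipeline with named components removed.

    ``drops`` is a list of variable-ablation names (event categories or
    input blocks) and/or layer-ablation names.  Each variant re-executes
    conversion -> TSS -> training, retraining the classifier ``n_repeats``
    times with distinct seeds on the same data, and reports the mean/std
    test AUROC.  Removing discharge events is refused: they carry the TSS
    marker.
    """
    from .pipeline import prepare_features, run_pipeline
    from .synthetic_ehr import generate_ehr

    if tables is None:
        tables = generate_ehr(config.synthetic)
    rows = []
    for drop in drops:
        if drop in ("discharge", "discharge_events"):
            raise ValueError("discharge events cannot be removed: they mark the TSS state")
        if drop in VARIABLE_ABLATIONS:
            kw = dict(VARIABLE_ABLATIONS[drop])
        elif drop in LAYER_ABLATIONS:
            kw = dict(LAYER_ABLATIONS[drop])
        else:
            raise ValueError(f"unknown ablation {drop!r}")
        prepared = prepare_features(
            config, tables=tables,
            drop_events=tuple(base_drop_events) + tuple(kw.get("drop_events", ())),
        )
        aurocs = []
        for r in range(n_repeats):
            res = run_pipeline(
                config,
                prepared=prepared,
                zero_blocks=kw.get("zero_blocks", ()),
                nn_overrides=kw.get("nn_overrides"),
                train_seed=config.seed + 1000 * (r + 1),
            )
            aurocs.append(res["metrics"].auroc)
        rows.append((drop, float(np.mean(aurocs)), float(np.std(aurocs)), n_repeats))
        logger.info("ablation %s: mean test AUROC %.3f", drop, rows[-1][1])
    return pd.DataFrame(rows, columns=["variant", "mean_auroc", "std_auroc", "n_repeats"])
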