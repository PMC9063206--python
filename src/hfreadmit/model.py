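"""Feature assembly, the three-branch classifier and the ML baselines.

``FeatureBundle`` carries the three NN input blocks (timed state samples,
demographics, severity scores), the binary label, and — for the baseline
comparison in its second mode — the raw tabular feature table a classical
model would see (admission type, insurance, pooled lab mean/std,
Elixhauser group indicators, demographics, severity scores).

The model-selection contract is enforced by the API: ``train`` touches the
training and validation bundles only, chooses the best epoch by validation
AUROC, and the returned :class:`TrainedModel` is frozen; the test bundle is
first read by ``evaluate.classification_metrics``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .config import NNConfig
from .nn import Adam, ThreeBranchNet
from .severity import ELIXHAUSER_GROUPS, scores_at_discharge

logger = logging.getLogger(__name__)

__all__ = ["FeatureBundle", "TrainedModel", "build_network", "train",
           "fit_baselines", "assemble_bundles", "BASELINE_GRIDS"]

_GENDERS = ["F", "M"]
_ETHNICITIES = ["WHITE", "AFRICAN AMERICAN", "HISPANIC", "OTHERS NON-HISPANIC", "ASIAN"]
_ADM_TYPES = ["ELECTIVE", "EMERGENCY", "URGENT", "NEWBORN"]
_INSURANCES = ["Medicare", "Medicaid", "Private", "Government", "Self-pay"]


@dataclass
class FeatureBundle:
    """One split's features: NN input blocks plus the tabular-mode table."""

    tss: np.ndarray
    demographics: np.ndarray
    severity: np.ndarray
    y: np.ndarray
    tss_names: list = field(default_factory=list)
    demographics_names: list = field(default_factory=list)
    severity_names: list = field(default_factory=list)
    tabular: np.ndarray | None = None
    tabular_names: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)

    def nn_parts(self) -> list:
        return [self.tss, self.demographics, self.severity]

    def nn_matrix(self) -> np.ndarray:
        return np.concatenate(self.nn_parts(), axis=1)

    def validate(self) -> None:
        for block in (self.tss, self.demographics, self.severity):
            if len(block) != self.n:
                raise ValueError("feature block row counts differ")
            if not np.isfinite(block).all():
                raise ValueError("feature bundle contains non-finite values")


def _one_hot(value, categories):
    v = np.zeros(len(categories))
    try:
        v[categories.index(value)] = 1.0
    except ValueError:
        pass  # unknown category encodes as all-zeros
    return v


def demographics_matrix(tables, members, age_params=None):
    """Age (standardized), gender one-hot and ethnicity one-hot per member."""
    pat = tables.patients.set_index("SUBJECT_ID")
    rows = []
    for m in members:
        p = pat.loc[m.patient_id]
        age = (m.discharge_time - p["DOB"]).total_seconds() / (365.25 * 86400.0)
        rows.append(
            np.concatenate(
                [[age], _one_hot(p["GENDER"], _GENDERS), _one_hot(p["ETHNICITY"], _ETHNICITIES)]
            )
        )
    X = np.vstack(rows)
    if age_params is None:
        age_params = (X[:, 0].mean(), X[:, 0].std() or 1.0)
    X[:, 0] = (X[:, 0] - age_params[0]) / age_params[1]
    names = ["age_std"] + [f"gender_{g}" for g in _GENDERS] + [f"ethnicity_{e}" for e in _ETHNICITIES]
    return X, names, age_params


def severity_matrix(tables, members, weighted_elixhauser=False, code_index=None):
    from .severity import codes_by_admission

    if code_index is None:
        code_index = codes_by_admission(tables)
    rows = [
        scores_at_discharge(m, tables, weighted_elixhauser, code_index).as_vector()
        for m in members
    ]
    return np.asarray(rows, dtype=float), ["charlson", "elixhauser"]


def tabular_matrix(tables, members, lab_panel, impute_means=None):
    """Raw tabular features for the baseline models' first input mode.

    Pools each analyte's measurements over all admissions up to the index;
    analytes never measured are NaN and mean-imputed with training values.
    """
    adm = tables.admissions.set_index("HADM_ID")
    item_label = dict(zip(tables.d_labitems["ITEMID"], tables.d_labitems["LABEL"]))
    lab_by_adm = dict(tuple(tables.labevents.groupby("HADM_ID")))
    diag_by_adm = dict(tuple(tables.diagnoses_icd.groupby("HADM_ID")))
    from .severity import elixhauser_groups

    rows = []
    for m in members:
        hadms = list(m.prior_admission_ids) + [m.index_admission_id]
        idx = adm.loc[m.index_admission_id]
        vals = {a: [] for a in lab_panel}
        codes = []
        for h in hadms:
            if h in lab_by_adm:
                for i, v in zip(lab_by_adm[h]["ITEMID"], lab_by_adm[h]["VALUENUM"]):
                    vals[item_label[i]].append(v)
            if h in diag_by_adm:
                codes.extend(diag_by_adm[h]["ICD9_CODE"])
        lab_feats = []
        for a in lab_panel:
            arr = np.asarray(vals[a], dtype=float)
            if len(arr):
                lab_feats += [arr.mean(), arr.std()]
            else:
                lab_feats += [np.nan, np.nan]
        groups = elixhauser_groups(codes)
        grp = [1.0 if g in groups else 0.0 for g in ELIXHAUSER_GROUPS]
        rows.append(
            np.concatenate(
                [
                    _one_hot(idx["ADMISSION_TYPE"], _ADM_TYPES),
                    _one_hot(idx["INSURANCE"], _INSURANCES),
                    lab_feats,
                    grp,
                ]
            )
        )
    X = np.vstack(rows)
    if impute_means is None:
        impute_means = np.nanmean(X, axis=0)
        impute_means = np.where(np.isfinite(impute_means), impute_means, 0.0)
    X = np.where(np.isnan(X), impute_means, X)
    names = (
        [f"admtype_{t}" for t in _ADM_TYPES]
        + [f"insurance_{i}" for i in _INSURANCES]
        + [f"{a}_{s}" for a in lab_panel for s in ("mean", "std")]
        + [f"elix_{g}" for g in ELIXHAUSER_GROUPS]
    )
    return X, names, impute_means


def assemble_bundles(tables, splits, tss_data, lab_panel, weighted_elixhauser=False):
    """Build train/validation/test feature bundles.

    ``tss_data`` maps split name -> (X_tss, tss_names).  All data-dependent
    parameters (age standardization, lab imputation means, severity column
    names) are fit on the training split and reused for validation/test.
    """
    from .severity import codes_by_admission

    bundles = {}
    age_params = impute = None
    code_index = codes_by_admission(tables)
    for name, members in splits.items():
        X_tss, tss_names = tss_data[name]
        demo, demo_names, age_params = demographics_matrix(tables, members, age_params)
        sev, sev_names = severity_matrix(tables, members, weighted_elixhauser, code_index)
        tab, tab_names, impute = tabular_matrix(tables, members, lab_panel, impute)
        # tabular mode sees the same demographics and severity variables
        tab_full = np.concatenate([tab, demo, sev], axis=1)
        bundle = FeatureBundle(
            tss=X_tss,
            demographics=demo,
            severity=sev,
            y=np.asarray([m.label for m in members], dtype=int),
            tss_names=tss_names,
            demographics_names=demo_names,
            severity_names=sev_names,
            tabular=tab_full,
            tabular_names=tab_names + demo_names + sev_names,
        )
        bundle.validate()
        bundles[name] = bundle
    return bundles


# ---------------------------------------------------------------------------
# Neural network


@dataclass
class TrainedModel:
    """A frozen classifier restored to its best-validation-AUROC epoch."""

    network: ThreeBranchNet
    history: list
    best_epoch: int
    input_widths: tuple

    def predict_proba(self, bundle: FeatureBundle) -> np.ndarray:
        return self.network.predict_proba(bundle.nn_parts())

    def scores(self, bundle: FeatureBundle) -> np.ndarray:
        return self.predict_proba(bundle)[:, 1]


def build_network(input_widths, config: NNConfig) -> ThreeBranchNet:
    """Untrained three-branch network per the configured architecture."""
    config.validate()
    return ThreeBranchNet(
        input_widths,
        branch_sizes=tuple(config.branch_hidden_sizes),
        post_size=config.post_concat_size,
        n_post_layers=config.n_post_concat_layers,
        dropout=config.dropout_rate,
        seed=config.seed,
    )


def train(network: ThreeBranchNet, train_bundle: FeatureBundle,
          val_bundle: FeatureBundle, config: NNConfig) -> TrainedModel:
    """Adam / cross-entropy training with per-epoch validation AUROC.

    Runs the full epoch budget, records validation AUROC after every epoch,
    and restores the weights of the best epoch.  Deterministic given
    ``config.seed``.
    """
    y = train_bundle.y
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(config.seed + 1)
    onehot = np.eye(2)[y]
    parts = train_bundle.nn_parts()
    optimizer = Adam(network.parameters(), lr=config.learning_rate)

    history = []
    best_auroc, best_state, best_epoch = -np.inf, None, -1
    n = train_bundle.n
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need >= 2 rows
            network.train_step([p[idx] for p in parts], onehot[idx], optimizer)
        val_scores = network.predict_proba(val_bundle.nn_parts())[:, 1]
        if len(np.unique(val_bundle.y)) < 2:
            auroc = 0.5  # degenerate validation split: AUROC undefined
        else:
            auroc = roc_auc_score(val_bundle.y, val_scores)
        history.append(float(auroc))
        if auroc > best_auroc:
            best_auroc, best_epoch = auroc, epoch
            best_state = network.get_state()
    network.set_state(best_state)
    return TrainedModel(
        network=network,
        history=history,
        best_epoch=best_epoch,
        input_widths=network.input_widths,
    )


# ---------------------------------------------------------------------------
# Baselines

BASELINE_GRIDS = {
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
    "knn": {"n_neighbors": [5, 15, 31]},
    "decision_tree": {"max_depth": [3, 5, 10, None]},
    "random_forest": {"n_estimators": [300], "max_depth": [None, 10], "min_samples_leaf": [1, 5]},
    "xgboost": {"n_estimators": [200], "max_depth": [3, 5], "learning_rate": [0.1]},
    "lightgbm": {"n_estimators": [200], "num_leaves": [15, 31], "learning_rate": [0.1]},
}


def _make_estimator(name, params, seed):
    if name == "svm":
        from sklearn.calibration import CalibratedClassifierCV

        return Pipeline(
            [("scale", StandardScaler()),
             ("clf", CalibratedClassifierCV(
                 SVC(kernel="rbf", random_state=seed, **params), ensemble=False, cv=3))]
        )
    if name == "knn":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", KNeighborsClassifier(**params))]
        )
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0, **params
        )
    if name == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
    raise ValueError(f"unknown baseline {name}")


def fit_baselines(train_bundle: FeatureBundle, val_bundle: FeatureBundle,
                  mode: str = "tabular", grids: dict | None = None, seed: int = 0) -> dict:
    """Grid-search the six classical baselines, selecting on validation AUROC.

    ``mode='tabular'`` feeds the raw tabular variable table;
    ``mode='tss'`` feeds the identical input the NN sees (TSS blocks,
    demographics, severity concatenated).
    """
    if mode == "tabular":
        Xtr, Xva = train_bundle.tabular, val_bundle.tabular
    elif mode == "tss":
        Xtr, Xva = train_bundle.nn_matrix(), val_bundle.nn_matrix()
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'tabular' or 'tss')")
    grids = grids or BASELINE_GRIDS
    results = {}
    for name, grid in grids.items():
        best = None
        for params in ParameterGrid(grid):
            est = _make_estimator(name, params, seed)
            est.fit(Xtr, train_bundle.y)
            auroc = roc_auc_score(val_bundle.y, est.predict_proba(Xva)[:, 1])
            if best is None or auroc > best["val_auroc"]:
                best = {"model": est, "params": params, "val_auroc": float(auroc)}
        results[name] = best
        logger.info("baseline %s (%s mode): val AUROC %.3f %s",
                    name, mode, best["val_auroc"], best["params"])
    return results
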