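"""Editing-efficiency regression: training, nested CV, persistence, SHAP.

Efficiency (percent of reads carrying the intended edit) is regressed on
the 23 design features with gradient-boosted trees (XGBoost, squared
error).  Evaluation uses *grouped nested* cross-validation: outer folds
partition target mutations (group id = genomic position + target allele)
so that no mutation contributes to both training and held-out data, and
an inner grouped CV tunes hyperparameters by randomized search over the
grid below.  PE2 (no ngRNA) and PE3 (with ngRNA) are separate models over
their own feature subsets.

Feature attribution is exact TreeSHAP via XGBoost's native
``pred_contribs`` path, summarized as mean |SHAP| per feature; the ten
RNA-folding scores are additionally aggregated into one value.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import pearsonr, spearmanr
from sklearn.model_selection import ParameterSampler

from .features import FEATURE_NAMES, PE2_FEATURE_NAMES, schema_hash

logger = logging.getLogger("pegrank")

#: hyperparameter grid searched by the inner CV loop
DEFAULT_GRID: dict[str, list] = {
    "max_depth": [2, 5, 9, 14],
    "learning_rate": [0.01, 0.1],
    "min_child_weight": [1, 5, 10],
    "colsample_bylevel": [0.2, 0.6, 1],
    "colsample_bytree": [0.2, 0.6, 1],
    "subsample": [0.2, 0.6, 1],
    "reg_alpha": [0, 0.1, 1],
    "reg_lambda": [0, 1, 2],
}

#: boosting rounds per fit (inner-CV-selected depth does the regularizing)
DEFAULT_N_ESTIMATORS = 300

GROUP_COL = "group_id"
TARGET_COL = "efficiency"


def features_for_system(system: str) -> tuple[str, ...]:
    system = system.upper()
    if system == "PE3":
        return FEATURE_NAMES
    if system == "PE2":
        return PE2_FEATURE_NAMES
    raise ValueError(f"system must be 'PE2' or 'PE3', got {system!r}")


def validate_table(df: pd.DataFrame, feature_names: Sequence[str]) -> None:
    missing = [c for c in (GROUP_COL, TARGET_COL, *feature_names) if c not in df]
    if missing:
        raise ValueError(f"training table lacks columns {missing}")
    if df[list(feature_names)].isna().any().any():
        raise ValueError("training table has missing feature values")
    if (df[GROUP_COL].astype(str).str.len() == 0).any():
        raise ValueError("empty group_id")
    eff = df[TARGET_COL]
    if eff.isna().any() or (eff < 0).any() or (eff > 100).any():
        raise ValueError("efficiency must be within [0, 100]")


def read_training_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_training_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class EfficiencyModel:
    booster: xgb.Booster
    feature_names: tuple[str, ...]
    config: dict
    seed: int
    cv_report: Optional[pd.DataFrame] = None

    @property
    def schema(self) -> str:
        return schema_hash(self.feature_names)

    def _matrix(self, X: pd.DataFrame) -> xgb.DMatrix:
        missing = [c for c in self.feature_names if c not in X]
        if missing:
            raise ValueError(
                f"feature schema mismatch: input lacks {missing}"
            )
        return xgb.DMatrix(
            X[list(self.feature_names)].astype(float),
            feature_names=list(self.feature_names),
        )


def predict(model: EfficiencyModel, X) -> np.ndarray:
    """Predicted efficiency (%), clipped to [0, 100]."""
    if isinstance(X, dict):
        X = pd.DataFrame([X])
    raw = model.booster.predict(model._matrix(X))
    return np.clip(raw, 0.0, 100.0)


def _fit_booster(
    X: pd.DataFrame,
    y: np.ndarray,
    params: dict,
    seed: int,
    n_estimators: int,
) -> xgb.Booster:
    full = dict(
        objective="reg:squarederror",
        tree_method="hist",
        nthread=1,
        seed=seed,
        **params,
    )
    dtrain = xgb.DMatrix(
        X.astype(float), label=y, feature_names=list(X.columns)
    )
    return xgb.train(full, dtrain, num_boost_round=n_estimators)


def _group_folds(
    groups: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded partition of unique groups into k folds (test masks)."""
    uniq = np.array(sorted(set(groups)))
    if len(uniq) < k:
        raise ValueError(
            f"only {len(uniq)} target-mutation groups for {k} folds; "
            "lower the fold count or provide more target mutations"
        )
    order = rng.permutation(len(uniq))
    masks = []
    for chunk in np.array_split(uniq[order], k):
        chunk = set(chunk)
        masks.append(np.fromiter((g in chunk for g in groups), dtype=bool))
    return masks


def _assert_no_leakage(groups, train_mask, test_mask) -> None:
    shared = set(groups[train_mask]) & set(groups[test_mask])
    if shared:
        raise AssertionError(f"group leakage across folds: {sorted(shared)}")


def _spearman(a, b) -> float:
    return float(spearmanr(a, b).statistic)


def _inner_select(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    grid: dict,
    inner_k: int,
    n_candidates: int,
    seed: int,
    n_estimators: int,
) -> dict:
    rng = np.random.default_rng(seed)
    total = int(np.prod([len(v) for v in grid.values()]))
    candidates = list(
        ParameterSampler(
            grid, n_iter=min(n_candidates, total), random_state=seed
        )
    )
    masks = _group_folds(groups, inner_k, rng)
    best, best_score = None, -np.inf
    for params in candidates:
        scores = []
        for test_mask in masks:
            train_mask = ~test_mask
            _assert_no_leakage(groups, train_mask, test_mask)
            bst = _fit_booster(
                X[train_mask], y[train_mask], params, seed, n_estimators
            )
            pred = bst.predict(
                xgb.DMatrix(
                    X[test_mask].astype(float),
                    feature_names=list(X.columns),
                )
            )
            scores.append(_spearman(y[test_mask], pred))
        mean = float(np.mean(scores))
        if mean > best_score:
            best, best_score = params, mean
    return best


def nested_cv_train(
    table: pd.DataFrame,
    system: str = "PE3",
    grid: Optional[dict] = None,
    outer_k: int = 5,
    inner_k: int = 3,
    n_candidates: int = 60,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> EfficiencyModel:
    """Grouped nested CV: outer folds estimate held-out performance, inner
    folds tune hyperparameters; the final model is refit on all rows with
    the most frequently selected parameter set."""
    grid = grid or DEFAULT_GRID
    names = features_for_system(system)
    validate_table(table, names)
    X = table[list(names)].reset_index(drop=True)
    y = table[TARGET_COL].to_numpy(dtype=float)
    groups = table[GROUP_COL].astype(str).to_numpy()
    rng = np.random.default_rng(seed)
    outer_masks = _group_folds(groups, outer_k, rng)

    rows, chosen = [], []
    for fold, test_mask in enumerate(outer_masks):
        train_mask = ~test_mask
        _assert_no_leakage(groups, train_mask, test_mask)
        params = _inner_select(
            X[train_mask],
            y[train_mask],
            groups[train_mask],
            grid,
            inner_k,
            n_candidates,
            seed + fold,
            n_estimators,
        )
        chosen.append(params)
        bst = _fit_booster(
            X[train_mask], y[train_mask], params, seed, n_estimators
        )
        pred = bst.predict(
            xgb.DMatrix(
                X[test_mask].astype(float), feature_names=list(X.columns)
            )
        )
        rows.append(
            {
                "fold": fold,
                "n_test": int(test_mask.sum()),
                "spearman": _spearman(y[test_mask], pred),
                "pearson": float(pearsonr(y[test_mask], pred).statistic),
                "params": json.dumps(params, sort_keys=True),
            }
        )
        logger.info(
            "outer fold %d: spearman %.3f on %d rows",
            fold,
            rows[-1]["spearman"],
            rows[-1]["n_test"],
        )
    report = pd.DataFrame(rows)
    counts = Counter(json.dumps(p, sort_keys=True) for p in chosen)
    top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
    final_params = json.loads(top)
    booster = _fit_booster(X, y, final_params, seed, n_estimators)
    return EfficiencyModel(
        booster=booster,
        feature_names=names,
        config={
            "system": system.upper(),
            "params": final_params,
            "grid": grid,
            "outer_k": outer_k,
            "inner_k": inner_k,
            "n_candidates": n_candidates,
            "n_estimators": n_estimators,
        },
        seed=seed,
        cv_report=report,
    )


def train_test_split_train(
    table: pd.DataFrame,
    split_labels: Sequence[str],
    system: str = "PE2",
    params: Optional[dict] = None,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> EfficiencyModel:
    """Honor an externally supplied train/test split (one label per row)."""
    labels = np.asarray([str(s).lower() for s in split_labels])
    if len(labels) != len(table):
        raise ValueError("one split label per table row required")
    bad = set(labels) - {"train", "test"}
    if bad:
        raise ValueError(f"unlabeled/unknown split labels: {sorted(bad)}")
    names = features_for_system(system)
    validate_table(table, names)
    train_mask = labels == "train"
    test_mask = labels == "test"
    if not test_mask.any() or not train_mask.any():
        raise ValueError("both train and test rows are required")
    X = table[list(names)].reset_index(drop=True)
    y = table[TARGET_COL].to_numpy(dtype=float)
    params = params or {"max_depth": 5, "learning_rate": 0.1}
    booster = _fit_booster(X[train_mask], y[train_mask], params, seed, n_estimators)
    pred = booster.predict(
        xgb.DMatrix(X[test_mask].astype(float), feature_names=list(X.columns))
    )
    report = pd.DataFrame(
        [
            {
                "fold": "test",
                "n_test": int(test_mask.sum()),
                "spearman": _spearman(y[test_mask], pred),
                "pearson": float(pearsonr(y[test_mask], pred).statistic),
                "params": json.dumps(params, sort_keys=True),
            }
        ]
    )
    return EfficiencyModel(
        booster=booster,
        feature_names=names,
        config={"system": system.upper(), "params": params, "split": "external"},
        seed=seed,
        cv_report=report,
    )


# ---------------------------------------------------------------------------
# attribution


@dataclass
class AttributionReport:
    per_feature: pd.Series  # mean |SHAP| per feature, original order
    ranking: pd.Series  # same values sorted descending
    fold_aggregate: float  # sum of the fold_d* means


def explain(model: EfficiencyModel, table: pd.DataFrame) -> AttributionReport:
    """Mean absolute SHAP value per feature (exact TreeSHAP)."""
    contribs = model.booster.predict(
        model._matrix(table), pred_contribs=True
    )
    vals = np.abs(contribs[:, :-1]).mean(axis=0)  # last column is the bias
    per_feature = pd.Series(vals, index=list(model.feature_names))
    fold_cols = [c for c in model.feature_names if c.startswith("fold_d")]
    return AttributionReport(
        per_feature=per_feature,
        ranking=per_feature.sort_values(ascending=False),
        fold_aggregate=float(per_feature[fold_cols].sum()),
    )


# ---------------------------------------------------------------------------
# persistence: a single JSON file embedding schema, config and booster


def save_model(model: EfficiencyModel, path) -> None:
    payload = {
        "format": "pegrank-efficiency-model-v1",
        "feature_names": list(model.feature_names),
        "schema_hash": model.schema,
        "config": model.config,
        "seed": model.seed,
        "cv_report": (
            model.cv_report.to_dict(orient="records")
            if model.cv_report is not None
            else None
        ),
        "booster": json.loads(
            model.booster.save_raw("json").decode("utf-8")
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> EfficiencyModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "pegrank-efficiency-model-v1":
        raise ValueError(f"{path} is not a pegrank model file")
    booster = xgb.Booster()
    booster.load_model(bytearray(json.dumps(payload["booster"]), "utf-8"))
    names = tuple(payload["feature_names"])
    if schema_hash(names) != payload["schema_hash"]:
        raise ValueError("model file schema hash mismatch")
    report = payload["cv_report"]
    return EfficiencyModel(
        booster=booster,
        feature_names=names,
        config=payload["config"],
        seed=payload["seed"],
        cv_report=pd.DataFrame(report) if report is not None else None,
    )
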