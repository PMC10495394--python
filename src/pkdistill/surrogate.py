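"""Random-forest surrogates for the PBPK simulator.

One forest is trained per normalized summary PK metric; separate per-label
models consistently track the simulator better than a single multi-output
model.  Every forest has 150 trees; the remaining hyperparameters (tree
depth, leaf size, features per split) are tuned by cross-validated grid
search on the training split only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold

from .pk import NormalizationScaler
from .ranges import LABEL_COLUMNS, ConfigurationError

__all__ = [
    "N_TREES",
    "DEFAULT_GRID",
    "split_dataset",
    "train_surrogate",
    "train_model_set",
    "SurrogateModelSet",
]

#: Fixed forest size used for every surrogate.
N_TREES = 150

#: Default hyperparameter grid for the cross-validated search.
DEFAULT_GRID: Dict[str, List] = {
    "max_depth": [10, 20, None],
    "min_samples_leaf": [1, 2, 5],
    "max_features": [1.0, "sqrt", 1.0 / 3.0],
}


def split_dataset(
    dataset: pd.DataFrame, test_fraction: float = 0.20, seed: int = 0
) -> pd.Series:
    """Assign each row to 'train' or 'test' uniformly at random.

    No stratification; ``round(n * test_fraction)`` rows land in the test
    split.  Returns a Series aligned with the dataset index.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError(f"test_fraction must be in (0,1): {test_fraction}")
    n = len(dataset)
    if n < 10:
        raise ValueError(f"dataset too small to split: n={n}")
    n_test = int(round(n * test_fraction))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    assign = np.full(n, "train", dtype=object)
    assign[idx[:n_test]] = "test"
    return pd.Series(assign, index=dataset.index, name="split")


def _make_regressor(algorithm: str, seed: int, **params):
    if algorithm == "random_forest":
        return RandomForestRegressor(
            n_estimators=N_TREES, random_state=seed, n_jobs=1, **params
        )
    if algorithm == "gradient_boosting":
        params.pop("max_features", None)
        return GradientBoostingRegressor(
            n_estimators=N_TREES, random_state=seed, **params
        )
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


def train_surrogate(
    features: pd.DataFrame,
    labels: pd.Series,
    grid: Optional[Mapping[str, Sequence]] = None,
    cv_folds: int = 5,
    seed: int = 0,
    algorithm: str = "random_forest",
):
    """Grid-search and fit one 150-tree regressor for a single metric.

    The search is scored by R^2 under k-fold cross-validation on the
    training data only; the winning setting is refit on the full training
    split.  Raises on a constant label, which cannot be regressed.
    """
    if len(features) == 0:
        raise ValueError("empty training split")
    y = labels.to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError(f"label {labels.name!r} is constant in the training split")
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRID)
    if not grid:
        raise ConfigurationError("hyperparameter grid must be non-empty")
    base = _make_regressor(algorithm, seed)
    if algorithm == "gradient_boosting":
        grid.pop("max_features", None)
    search = GridSearchCV(
        base,
        param_grid=grid,
        cv=KFold(n_splits=cv_folds, shuffle=True, random_state=seed),
        scoring="r2",
        n_jobs=1,
        refit=True,
    )
    search.fit(features.to_numpy(float), y)
    model = search.best_estimator_
    model.tuned_params_ = dict(search.best_params_)
    return model


@dataclass
class SurrogateModelSet:
    """The three per-metric regressors plus everything needed to reuse them.

    All models share the same feature columns and train/test split; the
    attached scaler maps normalized predictions back to raw SPKM units.
    """

    models: Dict[str, object]
    feature_names: List[str]
    scaler: NormalizationScaler
    seed: int
    algorithm: str = "random_forest"
    training_fingerprint: str = ""

    def __post_init__(self) -> None:
        missing = [m for m in LABEL_COLUMNS if m not in self.models]
        if missing:
            raise ValueError(f"missing models for metrics: {missing}")

    def predict(
        self, features: pd.DataFrame, denormalize: bool = False
    ) -> pd.DataFrame:
        """Predict normalized SPKM triplets for one or more feature rows.

        Columns are resolved by name and must match the training feature
        list exactly (order-insensitive); missing or extra columns raise.
        """
        have = set(features.columns)
        want = set(self.feature_names)
        missing = sorted(want - have)
        extra = sorted(have - want)
        if missing or extra:
            raise ValueError(
                f"feature columns mismatch: missing={missing} extra={extra}"
            )
        x = features[self.feature_names].to_numpy(float)
        out = pd.DataFrame(
            {m: self.models[m].predict(x) for m in LABEL_COLUMNS},
            index=features.index,
        )
        if denormalize:
            out = self.scaler.denormalize(out)
        return out

    def save(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "feature_names": self.feature_names,
            "seed": self.seed,
            "algorithm": self.algorithm,
            "training_fingerprint": self.training_fingerprint,
            "n_trees": N_TREES,
        }
        (directory / "modelset.json").write_text(json.dumps(meta, indent=2))
        self.scaler.to_json(directory / "scaler.json")
        for name, model in self.models.items():
            joblib.dump(model, directory / f"{name}.joblib")

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "SurrogateModelSet":
        directory = Path(directory)
        meta = json.loads((directory / "modelset.json").read_text())
        models = {
            m: joblib.load(directory / f"{m}.joblib") for m in LABEL_COLUMNS
        }
        return cls(
            models=models,
            feature_names=meta["feature_names"],
            scaler=NormalizationScaler.from_json(directory / "scaler.json"),
            seed=meta["seed"],
            algorithm=meta.get("algorithm", "random_forest"),
            training_fingerprint=meta.get("training_fingerprint", ""),
        )


def _fingerprint(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()[:16]


def train_model_set(
    dataset: pd.DataFrame,
    split: pd.Series,
    scaler: NormalizationScaler,
    feature_names: Sequence[str],
    grid: Optional[Mapping[str, Sequence]] = None,
    cv_folds: int = 5,
    seed: int = 0,
    algorithm: str = "random_forest",
) -> SurrogateModelSet:
    """Train the three per-metric surrogates on the training split."""
    train = dataset.loc[split == "train"]
    feats = train[list(feature_names)]
    models = {
        metric: train_surrogate(
            feats, train[metric], grid=grid, cv_folds=cv_folds, seed=seed,
            algorithm=algorithm,
        )
        for metric in LABEL_COLUMNS
    }
    return SurrogateModelSet(
        models=models,
        feature_names=list(feature_names),
        scaler=scaler,
        seed=seed,
        algorithm=algorithm,
        training_fingerprint=_fingerprint(feats),
    )
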