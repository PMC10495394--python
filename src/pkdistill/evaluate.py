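"""Surrogate fidelity evaluation and reduced-feature-set optimization.

Fidelity against the simulator is quantified two ways: the adjusted
coefficient of determination on the held-out test split,

    R2_adj = 1 - (1 - R2) (n - 1) / (n - k - 1),    R2 = 1 - SSR/SST,

and the distribution of per-sample relative errors on the normalized
metrics, summarized as the fractions of predictions within +/-20% and
+/-40% of the simulator value.

Feature reduction ranks features by mean impurity-importance rank across
the three per-metric forests, then retrains on every nested prefix of that
ranking; the optimal reduced feature set (RFS) maximizes the mean test
adjusted R^2 across the three metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ranges import LABEL_COLUMNS
from .surrogate import SurrogateModelSet, train_model_set

__all__ = [
    "adjusted_r2",
    "relative_error_report",
    "ErrorReport",
    "evaluate_model_set",
    "feature_importance",
    "optimize_reduced_feature_set",
    "RFSResult",
]


def adjusted_r2(reference, predicted, k: int) -> float:
    """Adjusted coefficient of determination with k features.

    ``1 - (1 - R2)(n - 1)/(n - k - 1)`` with ``R2 = 1 - SSR/SST``; requires
    ``n > k + 1`` and a non-constant reference.  ``k = 0`` collapses to the
    unadjusted R^2.
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("reference and predicted must be equal-length vectors")
    n = ref.size
    if n <= k + 1:
        raise ValueError(f"adjustment undefined: n={n} <= k+1={k + 1}")
    sst = float(np.sum((ref - ref.mean()) ** 2))
    if sst == 0:
        raise ValueError("reference vector has zero variance")
    ssr = float(np.sum((ref - pred) ** 2))
    r2 = 1.0 - ssr / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass
class ErrorReport:
    """Relative-error summary for one metric on the test split."""

    bin_edges: np.ndarray  # percent
    frequencies: np.ndarray  # sums to 1 over the histogram
    within_20: float
    within_40: float
    n_used: int
    n_excluded: int  # reference magnitudes below the denominator floor


def relative_error_report(
    reference,
    predicted,
    bin_width: float = 5.0,
    denominator_floor: float = 1e-6,
) -> Tuple[ErrorReport, np.ndarray]:
    """Histogram of per-sample relative errors (percent) on normalized values.

    ``eps_i = 100 (pred_i - ref_i)/ref_i``; rows whose reference magnitude
    falls below ``denominator_floor`` are excluded and counted.  Bins are
    symmetric about zero with the given width; outliers fall into the two
    open end bins.  Returns the report and the error vector itself.
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted must have equal length")
    keep = np.abs(ref) >= denominator_floor
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all reference values fall below the denominator floor")
    errors = 100.0 * (pred[keep] - ref[keep]) / ref[keep]
    span = max(100.0, bin_width * np.ceil(np.max(np.abs(errors)) / bin_width))
    # symmetric edges centered on 0 (0 is a bin center)
    half = bin_width / 2.0
    edges = np.arange(-span - half, span + half + bin_width / 2, bin_width)
    counts, edges = np.histogram(errors, bins=edges)
    report = ErrorReport(
        bin_edges=edges,
        frequencies=counts / errors.size,
        within_20=float(np.mean(np.abs(errors) <= 20.0)),
        within_40=float(np.mean(np.abs(errors) <= 40.0)),
        n_used=int(errors.size),
        n_excluded=n_excluded,
    )
    return report, errors


def evaluate_model_set(
    models: SurrogateModelSet,
    dataset: pd.DataFrame,
    split: pd.Series,
    bin_width: float = 5.0,
    denominator_floor: float = 1e-6,
) -> Dict[str, dict]:
    """Score all three metrics on the test split.

    Returns, per metric: test adjusted R^2 (k = number of model features),
    the +/-20% and +/-40% error fractions, and the error histogram.
    """
    test = dataset.loc[split == "test"]
    preds = models.predict(test[models.feature_names])
    k = len(models.feature_names)
    out: Dict[str, dict] = {}
    for metric in LABEL_COLUMNS:
        ref = test[metric].to_numpy(float)
        pred = preds[metric].to_numpy(float)
        report, _ = relative_error_report(
            ref, pred, bin_width=bin_width, denominator_floor=denominator_floor
        )
        out[metric] = {
            "r2_adj": adjusted_r2(ref, pred, k=k),
            "within_20": report.within_20,
            "within_40": report.within_40,
            "n": int(ref.size),
            "k": k,
            "n_excluded": report.n_excluded,
            "histogram": {
                "edges": report.bin_edges.tolist(),
                "frequencies": report.frequencies.tolist(),
            },
        }
    return out


def feature_importance(models: SurrogateModelSet) -> pd.DataFrame:
    """Impurity-based importances per metric plus an aggregate ranking.

    Each model's importances sum to one.  The aggregate rank orders
    features by their mean rank across the three per-metric models
    (rank 1 = most important; ties broken by mean importance, then name).
    """
    rows: Dict[str, np.ndarray] = {}
    for metric in LABEL_COLUMNS:
        model = models.models[metric]
        if not hasattr(model, "feature_importances_"):
            raise RuntimeError(f"model for {metric!r} is not fitted")
        rows[metric] = np.asarray(model.feature_importances_, dtype=float)
    table = pd.DataFrame(rows, index=pd.Index(models.feature_names, name="feature"))
    ranks = table.rank(ascending=False, method="average")
    table["mean_rank"] = ranks.mean(axis=1)
    table["mean_importance"] = table[list(LABEL_COLUMNS)].mean(axis=1)
    order = table.sort_values(
        ["mean_rank", "mean_importance", "feature"],
        ascending=[True, False, True],
        kind="mergesort",
    ).index
    table["aggregate_rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order
    )
    return table.sort_values("aggregate_rank")


@dataclass
class RFSResult:
    """Outcome of the nested-prefix reduced-feature-set search."""

    optimal_features: List[str]
    score_curve: pd.DataFrame  # one row per subset size
    optimal_models: SurrogateModelSet
    optimal_report: Dict[str, dict]


def optimize_reduced_feature_set(
    dataset: pd.DataFrame,
    split: pd.Series,
    importance: pd.DataFrame,
    models: SurrogateModelSet,
    hyperparams: Optional[Mapping[str, Mapping]] = None,
    bin_width: float = 5.0,
    denominator_floor: float = 1e-6,
    min_size: int = 1,
) -> RFSResult:
    """Search nested prefixes of the importance ranking for the best subset.

    For every size 1..K the three per-metric models are retrained on the
    training split restricted to the top-ranked features (reusing each
    metric's tuned hyperparameters rather than re-running the grid search)
    and scored by test-split adjusted R^2 with k equal to the subset size.
    The optimal set maximizes the mean adjusted R^2 across the three
    metrics; the full score curve is returned alongside the refit models
    and their error report.
    """
    ranked = list(importance.sort_values("aggregate_rank").index)
    if set(ranked) != set(models.feature_names):
        raise ValueError("importance table does not cover the model's features")
    if hyperparams is None:
        hyperparams = {
            m: getattr(models.models[m], "tuned_params_", {}) for m in LABEL_COLUMNS
        }
    grids = {m: {k: [v] for k, v in hp.items()} for m, hp in hyperparams.items()}

    curve_rows = []
    candidates: Dict[int, SurrogateModelSet] = {}
    for size in range(min_size, len(ranked) + 1):
        subset = ranked[:size]
        fitted = {}
        train = dataset.loc[split == "train"]
        from .surrogate import train_surrogate  # local to avoid cycle at import

        for metric in LABEL_COLUMNS:
            fitted[metric] = train_surrogate(
                train[subset],
                train[metric],
                grid=grids[metric],
                cv_folds=2,  # single-point grid; folds are immaterial
                seed=models.seed,
                algorithm=models.algorithm,
            )
        mset = SurrogateModelSet(
            models=fitted,
            feature_names=subset,
            scaler=models.scaler,
            seed=models.seed,
            algorithm=models.algorithm,
        )
        test = dataset.loc[split == "test"]
        preds = mset.predict(test[subset])
        scores = {
            metric: adjusted_r2(
                test[metric].to_numpy(float), preds[metric].to_numpy(float), k=size
            )
            for metric in LABEL_COLUMNS
        }
        curve_rows.append(
            {"size": size, **{f"r2_adj_{m}": s for m, s in scores.items()},
             "mean_r2_adj": float(np.mean(list(scores.values())))}
        )
        candidates[size] = mset
    curve = pd.DataFrame(curve_rows).set_index("size")
    best_size = int(curve["mean_r2_adj"].idxmax())
    best = candidates[best_size]
    report = evaluate_model_set(
        best, dataset, split, bin_width=bin_width, denominator_floor=denominator_floor
    )
    return RFSResult(
        optimal_features=list(best.feature_names),
        score_curve=curve,
        optimal_models=best,
        optimal_report=report,
    )
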