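"""Anesthetic-concentration prediction from per-minute feature tables.

The predictor is a chained pipeline: quantile transformation of the input
features, mutual-information percentile feature selection, an RBF-kernel
support-vector *classifier* trained to discriminate anesthetized from
non-anesthetized minutes, and an RBF-kernel support-vector *regressor*
that receives the classifier's prediction as one extra feature and
predicts the concentration itself.

Evaluation is resampled: the table is iteratively split into a training
two-thirds and a held-out third; all hyper-parameters are tuned per
iteration by 3-fold grid search on the training rows only, and metrics
(R-squared and median absolute error) are pooled over the concatenated
held-out predictions of all iterations.  Age-stratified variants train
one regressor per age group (cutoffs 2 and 4 months) or a single model
with age as an input feature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import partial
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import (
    SelectPercentile,
    mutual_info_classif,
    mutual_info_regression,
)
from sklearn.metrics import accuracy_score, r2_score
from sklearn.model_selection import GridSearchCV, cross_val_predict, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import QuantileTransformer
from sklearn.svm import SVC, SVR

from .features import FeatureTable, concat_tables
from .preprocess import InvalidParameterError

__all__ = [
    "PipelineSpec",
    "IterationResult",
    "ModelResult",
    "AgeStratification",
    "DepthModel",
    "default_grid",
    "fast_grid",
    "train_evaluate",
    "classify_anesthetized",
    "train_age_stratified",
    "train_fraction_robustness",
    "evaluate_metrics",
    "decision_space_map",
    "DecisionSpaceMap",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pipeline construction and grids
# ---------------------------------------------------------------------------

@dataclass
class PipelineSpec:
    """Hyper-parameters chosen for one iteration (classifier and regressor)."""

    classifier_params: dict = field(default_factory=dict)
    regressor_params: dict = field(default_factory=dict)


def default_grid(kind: str) -> dict[str, list]:
    """Full hyper-parameter grid spanning the transform/kernel regimes."""
    grid = {
        "quantile__n_quantiles": [10, 100, 1000],
        "select__percentile": [25, 50, 75, 100],
        "svm__C": [0.1, 1, 10, 100],
        "svm__gamma": ["scale", 0.01, 0.1, 1],
    }
    if kind == "regressor":
        grid["svm__epsilon"] = [0.01, 0.1, 0.5]
    return grid


def fast_grid(kind: str) -> dict[str, list]:
    """Reduced grid for quick experiments and cohort-scale recovery runs."""
    grid = {
        "quantile__n_quantiles": [100],
        "select__percentile": [50, 100],
        "svm__C": [1, 10],
        "svm__gamma": ["scale"],
    }
    if kind == "regressor":
        grid["svm__epsilon"] = [0.1]
    return grid


def _make_pipeline(kind: str, n_train: int) -> Pipeline:
    if kind == "classifier":
        score_func = partial(mutual_info_classif, random_state=0)
        svm = SVC(kernel="rbf")
    else:
        score_func = partial(mutual_info_regression, random_state=0)
        svm = SVR(kernel="rbf")
    return Pipeline(
        [
            ("quantile", QuantileTransformer(n_quantiles=min(100, n_train), random_state=0)),
            ("select", SelectPercentile(score_func=score_func)),
            ("svm", svm),
        ]
    )


def _sanitize_grid(grid: Mapping[str, list], n_train: int, inner_folds: int = 3) -> dict[str, list]:
    # cap n_quantiles at the inner-fold training size to keep the quantile
    # transform well defined on every fold
    out = dict(grid)
    cap = max(2, (n_train * (inner_folds - 1)) // inner_folds)
    if "quantile__n_quantiles" in out:
        vals = sorted({min(int(v), cap) for v in out["quantile__n_quantiles"]})
        out["quantile__n_quantiles"] = vals
    return out


# ---------------------------------------------------------------------------
# fitted chain model
# ---------------------------------------------------------------------------

@dataclass
class DepthModel:
    """Fitted classifier + regressor chain.

    ``predict`` appends the classifier's anesthetized/awake prediction as an
    extra feature before the regressor, mirroring training.
    """

    classifier: Pipeline
    regressor: Pipeline
    spec: PipelineSpec

    def predict(self, X: np.ndarray) -> np.ndarray:
        flag = self.classifier.predict(X).astype(float)
        return self.regressor.predict(np.column_stack([X, flag]))


def _fit_chain(
    X: np.ndarray,
    y: np.ndarray,
    clf_grid: Mapping[str, list],
    reg_grid: Mapping[str, list],
    inner_folds: int,
) -> DepthModel:
    """Tune and fit the chained pipeline on training rows only.

    The regressor's training copy of the classifier feature comes from
    inner cross-validated predictions so the regressor never sees a
    classifier output computed on its own training rows.
    """
    b = (y > 0).astype(int)
    n = len(y)
    clf = GridSearchCV(
        _make_pipeline("classifier", n),
        _sanitize_grid(clf_grid, n, inner_folds),
        cv=inner_folds,
        scoring="accuracy",
        n_jobs=1,
    )
    clf.fit(X, b)
    flag_train = cross_val_predict(clf.best_estimator_, X, b, cv=inner_folds).astype(float)
    Xr = np.column_stack([X, flag_train])
    reg = GridSearchCV(
        _make_pipeline("regressor", n),
        _sanitize_grid(reg_grid, n, inner_folds),
        cv=inner_folds,
        scoring="r2",
        n_jobs=1,
    )
    reg.fit(Xr, y)
    spec = PipelineSpec(
        classifier_params=dict(clf.best_params_), regressor_params=dict(reg.best_params_)
    )
    return DepthModel(classifier=clf.best_estimator_, regressor=reg.best_estimator_, spec=spec)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class IterationResult:
    split_seed: int
    r2: float
    median_abs_error: float
    predictions: pd.DataFrame           # columns: bin, true, predicted
    spec_chosen: PipelineSpec


@dataclass
class ModelResult:
    """Per-iteration predictions plus metrics pooled over held-out rows."""

    per_iteration: list[IterationResult]
    pooled_r2: float
    pooled_median_abs_error: float

    @property
    def summary(self) -> dict[str, float]:
        return {
            "pooled_r2": self.pooled_r2,
            "pooled_median_abs_error": self.pooled_median_abs_error,
            "n_iterations": len(self.per_iteration),
        }


def evaluate_metrics(true: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """Coefficient of determination and median absolute error."""
    true = np.asarray(true, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if true.shape != predicted.shape or len(true) < 2:
        raise InvalidParameterError("need equal-length arrays of length >= 2")
    return {
        "R2": float(r2_score(true, predicted)),
        "median_abs_error": float(np.median(np.abs(true - predicted))),
    }


# ---------------------------------------------------------------------------
# resampled training / evaluation
# ---------------------------------------------------------------------------

def _outer_split(
    n: int,
    test_fraction: float,
    split_seed: int,
    y: np.ndarray,
    groups: np.ndarray | None,
    max_retries: int = 20,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Train/test split that retries (with the next seed) degenerate draws."""
    seed = split_seed
    for _ in range(max_retries):
        if groups is None:
            tr, te = train_test_split(
                np.arange(n), test_size=test_fraction, random_state=seed % (2**31)
            )
        else:
            from sklearn.model_selection import GroupShuffleSplit

            gss = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed % (2**31))
            tr, te = next(gss.split(np.zeros(n), groups=groups))
        b = y[tr] > 0
        if 0 < b.sum() < len(b) and len(np.unique(y[tr])) >= 2:
            return tr, te, seed
        logger.info("degenerate split at seed %d: single class in training, resplitting", seed)
        seed += 1
    raise InvalidParameterError("could not draw a split with both classes in training")


def train_evaluate(
    table: FeatureTable,
    spec_grid: tuple[Mapping[str, list], Mapping[str, list]] | None = None,
    n_iterations: int = 100,
    test_fraction: float = 1.0 / 3.0,
    inner_folds: int = 3,
    seed: int = 0,
    group_by_subject: bool = False,
) -> ModelResult:
    """Resampled nested training and evaluation of the chained pipeline.

    For each of ``n_iterations`` outer splits (training fraction
    ``1 - test_fraction``): tune all hyper-parameters by ``inner_folds``-fold
    grid search on the training rows, fit the classifier-regressor chain,
    and predict the held-out rows.  All transforms are fitted on training
    rows only.  By default splits are at the level of 1-minute rows;
    ``group_by_subject=True`` keeps each subject's rows on one side.
    """
    if not (0 < test_fraction < 1):
        raise InvalidParameterError("test_fraction must lie in (0, 1)")
    X, y = table.X, table.y
    if len(np.unique(y)) < 2:
        raise InvalidParameterError("need >= 2 distinct labels")
    clf_grid, reg_grid = spec_grid or (default_grid("classifier"), default_grid("regressor"))
    if not clf_grid or not reg_grid:
        raise InvalidParameterError("hyper-parameter grid must be nonempty")
    groups = None
    if group_by_subject:
        groups = table.frame["subject_id"].to_numpy()

    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1000, size=n_iterations)
    iterations: list[IterationResult] = []
    all_true, all_pred = [], []
    for s in split_seeds:
        tr, te, used_seed = _outer_split(len(y), test_fraction, int(s), y, groups)
        model = _fit_chain(X[tr], y[tr], clf_grid, reg_grid, inner_folds)
        pred = model.predict(X[te])
        m = evaluate_metrics(y[te], pred)
        iterations.append(
            IterationResult(
                split_seed=used_seed,
                r2=m["R2"],
                median_abs_error=m["median_abs_error"],
                predictions=pd.DataFrame({"bin": te, "true": y[te], "predicted": pred}),
                spec_chosen=model.spec,
            )
        )
        all_true.append(y[te])
        all_pred.append(pred)
    pooled = evaluate_metrics(np.concatenate(all_true), np.concatenate(all_pred))
    return ModelResult(
        per_iteration=iterations,
        pooled_r2=pooled["R2"],
        pooled_median_abs_error=pooled["median_abs_error"],
    )


def classify_anesthetized(
    table: FeatureTable,
    spec_grid: Mapping[str, list] | None = None,
    n_iterations: int = 20,
    test_fraction: float = 1.0 / 3.0,
    inner_folds: int = 3,
    seed: int = 0,
    transfer_table: FeatureTable | None = None,
) -> dict[str, float]:
    """Anesthetized-vs-awake classification accuracy (held-out, resampled).

    With ``transfer_table`` given (e.g. sessions under a different
    anesthetic), each iteration's classifier additionally scores the whole
    transfer table — the cross-anesthetic generalization test.
    """
    X, y = table.X, table.y
    b = (y > 0).astype(int)
    if len(np.unique(b)) < 2:
        raise InvalidParameterError("need both anesthetized and non-anesthetized rows")
    grid = dict(spec_grid) if spec_grid else fast_grid("classifier")
    rng = np.random.default_rng(seed)
    accs, transfer_accs = [], []
    for s in rng.integers(0, 2**31 - 1000, size=n_iterations):
        tr, te, _ = _outer_split(len(y), test_fraction, int(s), y, None)
        clf = GridSearchCV(
            _make_pipeline("classifier", len(tr)),
            _sanitize_grid(grid, len(tr), inner_folds),
            cv=inner_folds,
            scoring="accuracy",
            n_jobs=1,
        )
        clf.fit(X[tr], b[tr])
        accs.append(accuracy_score(b[te], clf.predict(X[te])))
        if transfer_table is not None:
            bt = (transfer_table.y > 0).astype(int)
            transfer_accs.append(accuracy_score(bt, clf.predict(transfer_table.X)))
    out = {"accuracy": float(np.mean(accs)), "n_iterations": n_iterations}
    if transfer_accs:
        out["transfer_accuracy"] = float(np.mean(transfer_accs))
    return out


# ---------------------------------------------------------------------------
# age stratification and robustness
# ---------------------------------------------------------------------------

@dataclass
class AgeStratification:
    cutoffs_months: tuple[float, float] = (2.0, 4.0)
    mode: str = "three_models"  # or "single_model_with_age"

    def group_of(self, age_months: float) -> str:
        lo, hi = self.cutoffs_months
        if age_months < lo:
            return f"0-{int(lo)}"
        if age_months < hi:
            return f"{int(lo)}-{int(hi)}"
        return f"{int(hi)}+"


def train_age_stratified(
    tables: Sequence[FeatureTable],
    strat: AgeStratification | None = None,
    **train_kwargs,
) -> dict[str, ModelResult]:
    """Train per-age-group regressors or one model with age as a feature.

    ``three_models`` mode partitions subjects at the cutoffs (default 2 and
    4 months) and runs the resampled evaluation per group; every group must
    be nonempty.  ``single_model_with_age`` appends ``age_months`` as one
    extra feature column and trains a single model on all subjects.
    """
    strat = strat or AgeStratification()
    combined = concat_tables(list(tables)) if len(tables) > 1 else tables[0]
    if "age_months" not in combined.frame:
        raise InvalidParameterError("tables must carry an age_months column")
    if strat.mode == "single_model_with_age":
        frame = combined.frame.copy()
        aug = FeatureTable(
            frame=frame,
            feature_columns=combined.feature_columns + ["age_months"],
            label_column=combined.label_column,
            meta=dict(combined.meta),
        )
        return {"all": train_evaluate(aug, **train_kwargs)}
    if strat.mode != "three_models":
        raise InvalidParameterError(f"unknown stratification mode {strat.mode!r}")
    groups = combined.frame["age_months"].map(strat.group_of)
    results: dict[str, ModelResult] = {}
    for g in sorted(groups.unique()):
        sub = combined.frame[groups == g].reset_index(drop=True)
        if sub.empty:
            raise InvalidParameterError(f"age group {g} is empty")
        results[g] = train_evaluate(
            FeatureTable(
                frame=sub,
                feature_columns=combined.feature_columns,
                label_column=combined.label_column,
                meta=dict(combined.meta),
            ),
            **train_kwargs,
        )
    return results


def train_fraction_robustness(
    table: FeatureTable,
    train_fraction: float = 0.2,
    **train_kwargs,
) -> ModelResult:
    """Same pipeline trained on a small fraction and tested on the rest."""
    if not (0 < train_fraction < 1):
        raise InvalidParameterError("train_fraction must lie in (0, 1)")
    # rounding keeps e.g. train_fraction=2/3 identical to the default split
    return train_evaluate(
        table, test_fraction=round(1.0 - train_fraction, 12), **train_kwargs
    )


# ---------------------------------------------------------------------------
# decision-space map
# ---------------------------------------------------------------------------

@dataclass
class DecisionSpaceMap:
    """2-D embedding of feature rows with a nearest-neighbor depth background."""

    coords: np.ndarray            # (n, 2)
    predicted: np.ndarray         # (n,)
    true: np.ndarray              # (n,)
    grid_x: np.ndarray
    grid_y: np.ndarray
    grid_value: np.ndarray        # (len(grid_y), len(grid_x))

    def plot(self, ax=None):
        """Render the tessellated decision space (background = predicted depth)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.pcolormesh(self.grid_x, self.grid_y, self.grid_value, shading="auto", alpha=0.6)
        sc = ax.scatter(
            self.coords[:, 0], self.coords[:, 1], c=self.true, edgecolors="k", s=25
        )
        ax.set_xlabel("embedding dim 1")
        ax.set_ylabel("embedding dim 2")
        plt.colorbar(sc, ax=ax, label="anesthetic concentration")
        return ax


def decision_space_map(
    model: DepthModel,
    table: FeatureTable,
    seed: int = 0,
    grid_points: int = 100,
) -> DecisionSpaceMap:
    """Stochastic-neighbor embedding of the rows with a depth tessellation.

    The fitted model's predicted depth per row colors a 1-nearest-neighbor
    regression over the 2-D plane (a Voronoi tessellation of the
    embedding).  Requires at least 10 rows.
    """
    from sklearn.manifold import TSNE

    X = table.X
    n = len(X)
    if n < 10:
        raise InvalidParameterError("need >= 10 rows for a 2-D embedding")
    predicted = model.predict(X)
    perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = tsne.fit_transform(X)
    knn = KNeighborsRegressor(n_neighbors=1).fit(coords, predicted)
    pad = 0.05 * (coords.max(axis=0) - coords.min(axis=0) + 1e-9)
    gx = np.linspace(coords[:, 0].min() - pad[0], coords[:, 0].max() + pad[0], grid_points)
    gy = np.linspace(coords[:, 1].min() - pad[1], coords[:, 1].max() + pad[1], grid_points)
    mx, my = np.meshgrid(gx, gy)
    gv = knn.predict(np.column_stack([mx.ravel(), my.ravel()])).reshape(mx.shape)
    return DecisionSpaceMap(
        coords=coords,
        predicted=predicted,
        true=table.y,
        grid_x=gx,
        grid_y=gy,
        grid_value=gv,
    )
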