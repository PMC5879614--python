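"""Feature encoding, stratified splitting, ridge fitting, and scoring.

The model is a linear map over four numeric features (expression-publication
count, total journal-publication count, expression-publication fraction,
construct count) plus a one-hot encoding of the gene symbol with an explicit
unknown-category bucket.  Fitting minimises

    ||y - X w||^2 + lambda ||w||^2

via the normal equations ``(X'X + lambda I) w = X'y`` — no intercept by
default, and the penalty is applied unscaled (not divided by n).  When an
intercept is requested its column is exempt from the penalty.

Symbols are near-unique per gene, so the design matrix is built sparse; the
normal-equation system stays cheap because indicator columns are mutually
orthogonal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .errors import ConfigurationError, CurategapError
from .feature_table import GeneFeatures

logger = logging.getLogger(__name__)

#: Numeric feature names in fixed design-matrix order.
NUMERIC_FEATURES = (
    "expr_pub_count",
    "total_journal_pub_count",
    "percent_expr_pubs",
    "construct_count",
)

UNKNOWN_SYMBOL = "__unknown__"


@dataclass(frozen=True)
class EncodingSpec:
    """Column layout of the design matrix.

    Numeric features come first in :data:`NUMERIC_FEATURES` order (optionally
    restricted via ``numeric_features``); then one indicator column per known
    symbol; the last column is the reserved unknown-symbol bucket.
    """

    numeric_features: tuple[str, ...] = NUMERIC_FEATURES
    symbol_to_column: Mapping[str, int] = field(default_factory=dict)
    standardize: Mapping[str, tuple[float, float]] | None = None

    @property
    def n_numeric(self) -> int:
        return len(self.numeric_features)

    @property
    def n_columns(self) -> int:
        # +1 for the unknown bucket
        return self.n_numeric + len(self.symbol_to_column) + 1

    @property
    def unknown_column(self) -> int:
        return self.n_columns - 1

    def column_names(self) -> list[str]:
        names = list(self.numeric_features)
        names += [""] * (len(self.symbol_to_column) + 1)
        for symbol, offset in self.symbol_to_column.items():
            names[self.n_numeric + offset] = f"symbol={symbol}"
        names[-1] = f"symbol={UNKNOWN_SYMBOL}"
        return names

    def symbol_columns(self) -> range:
        """Indices of all indicator columns including the unknown bucket."""
        return range(self.n_numeric, self.n_columns)

    @classmethod
    def from_table(
        cls,
        table: Sequence[GeneFeatures],
        numeric_features: tuple[str, ...] = NUMERIC_FEATURES,
    ) -> "EncodingSpec":
        symbols = sorted({g.symbol for g in table})
        return cls(
            numeric_features=tuple(numeric_features),
            symbol_to_column={s: i for i, s in enumerate(symbols)},
        )


@dataclass
class RidgeModel:
    """Fitted weight vector with its hyperparameters and encoding."""

    weights: np.ndarray
    l2_weight: float
    include_intercept: bool
    encoding: EncodingSpec | None = None
    intercept: float = 0.0

    def to_dict(self) -> dict:
        names = (
            self.encoding.column_names()
            if self.encoding is not None
            else [f"x{i}" for i in range(len(self.weights))]
        )
        return {
            "l2_weight": self.l2_weight,
            "include_intercept": self.include_intercept,
            "intercept": self.intercept,
            "weights": dict(zip(names, map(float, self.weights))),
        }


@dataclass(frozen=True)
class SplitResult:
    """Disjoint, exhaustive train/test partition of the gene set."""

    train_gene_ids: tuple[str, ...]
    test_gene_ids: tuple[str, ...]
    train_fraction: float
    seed: int
    n_bins: int

    def __post_init__(self):
        overlap = set(self.train_gene_ids) & set(self.test_gene_ids)
        if overlap:
            raise CurategapError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class RegressionMetrics:
    """The five evaluation metrics; ``r2 == 1 - rse`` by construction."""

    mae: float
    rmse: float
    rae: float
    rse: float
    r2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "rae": self.rae,
            "rse": self.rse,
            "r2": self.r2,
        }


@dataclass(frozen=True)
class FeatureImportance:
    """Permutation importance per original feature (symbol block permuted jointly)."""

    scores: Mapping[str, float]
    metric: str
    n_repeats: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "scores": dict(self.scores),
        }


def encode(
    table: Sequence[GeneFeatures],
    spec: EncodingSpec | None = None,
) -> tuple[sp.csr_matrix, np.ndarray, EncodingSpec]:
    """Build the sparse design matrix and label vector for a feature table.

    When ``spec`` is omitted it is derived from the table itself.  Symbols
    the spec does not know map to the unknown bucket.  Row order is
    preserved.
    """
    if len(table) == 0:
        raise CurategapError("cannot encode an empty feature table")
    if spec is None:
        spec = EncodingSpec.from_table(table)

    n = len(table)
    numeric = np.empty((n, spec.n_numeric), dtype=float)
    for j, feat in enumerate(spec.numeric_features):
        numeric[:, j] = [getattr(g, feat) for g in table]
    if spec.standardize:
        for j, feat in enumerate(spec.numeric_features):
            if feat in spec.standardize:
                mean, std = spec.standardize[feat]
                numeric[:, j] = (numeric[:, j] - mean) / (std if std else 1.0)

    rows = np.arange(n)
    n_symbol_cols = spec.n_columns - spec.n_numeric
    cols = np.array(
        [
            spec.symbol_to_column.get(g.symbol, n_symbol_cols - 1)
            for g in table
        ]
    )
    indicators = sp.csr_matrix(
        (np.ones(n), (rows, cols)), shape=(n, n_symbol_cols)
    )
    X = sp.hstack([sp.csr_matrix(numeric), indicators], format="csr")
    y = np.array([g.y for g in table], dtype=float)
    return X, y, spec


def stratified_split(
    table: Sequence[GeneFeatures],
    train_fraction: float = 0.25,
    n_bins: int = 10,
    seed: int = 0,
) -> SplitResult:
    """Split genes into train/test, stratified on quantile bins of the label.

    Within each bin ``round(train_fraction * bin_size)`` genes go to train,
    selected uniformly at random under ``seed``.  When there are fewer
    distinct label quantiles than requested bins, bins collapse with a
    warning (degenerating to a simple random split at one bin).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    if n_bins < 1:
        raise ConfigurationError("n_bins must be >= 1")

    y = np.array([g.y for g in table], dtype=float)
    n = len(table)
    effective_bins = n_bins
    if n < n_bins:
        warnings.warn(
            f"fewer genes ({n}) than strata ({n_bins}); collapsing to 1 bin",
            stacklevel=2,
        )
        effective_bins = 1

    if effective_bins == 1:
        bin_index = np.zeros(n, dtype=int)
    else:
        quantiles = np.quantile(y, np.linspace(0, 1, effective_bins + 1)[1:-1])
        edges = np.unique(quantiles)
        if len(edges) + 1 < effective_bins:
            logger.info(
                "label ties collapsed %d strata to %d", effective_bins,
                len(edges) + 1,
            )
        bin_index = np.searchsorted(edges, y, side="right")

    rng = np.random.default_rng(seed)
    train_mask = np.zeros(n, dtype=bool)
    for b in np.unique(bin_index):
        members = np.flatnonzero(bin_index == b)
        n_train = int(round(train_fraction * len(members)))
        chosen = rng.choice(members, size=n_train, replace=False)
        train_mask[chosen] = True

    gene_ids = [g.gene_id for g in table]
    return SplitResult(
        train_gene_ids=tuple(gene_ids[i] for i in np.flatnonzero(train_mask)),
        test_gene_ids=tuple(gene_ids[i] for i in np.flatnonzero(~train_mask)),
        train_fraction=train_fraction,
        seed=seed,
        n_bins=n_bins,
    )


def _as_2d(X):
    if sp.issparse(X):
        return X.tocsr()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def fit_ridge(
    X,
    y,
    l2_weight: float = 10.0,
    include_intercept: bool = False,
    encoding: EncodingSpec | None = None,
) -> RidgeModel:
    """Solve ``(X'X + lambda I) w = X'y`` exactly; deterministic.

    The intercept column, when requested, is appended as a column of ones and
    exempted from the penalty.  A singular system at ``l2_weight == 0``
    raises with a hint to use a positive penalty.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise CurategapError(
            f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
        )
    if X.shape[0] < 1:
        raise CurategapError("need at least one sample to fit")
    if l2_weight < 0:
        raise ConfigurationError("l2_weight must be >= 0")

    n_features = X.shape[1]
    if include_intercept:
        ones = np.ones((X.shape[0], 1))
        X_aug = sp.hstack([X, sp.csr_matrix(ones)], format="csr") if sp.issparse(X) \
            else np.hstack([X, ones])
    else:
        X_aug = X

    penalty = np.full(X_aug.shape[1], float(l2_weight))
    if include_intercept:
        penalty[-1] = 0.0

    if sp.issparse(X_aug):
        gram = (X_aug.T @ X_aug).tocsc()
        gram = gram + sp.diags(penalty, format="csc")
        rhs = X_aug.T @ y
        if l2_weight == 0:
            dense = gram.toarray()
            if np.linalg.matrix_rank(dense) < dense.shape[0]:
                raise CurategapError(
                    "normal equations are singular at l2_weight=0; "
                    "use l2_weight > 0 or a pseudo-inverse solver"
                )
            w_aug = np.linalg.solve(dense, rhs)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", sp.SparseEfficiencyWarning)
                w_aug = spsolve(gram, rhs)
    else:
        gram = X_aug.T @ X_aug + np.diag(penalty)
        rhs = X_aug.T @ y
        if l2_weight == 0 and np.linalg.matrix_rank(gram) < gram.shape[0]:
            raise CurategapError(
                "normal equations are singular at l2_weight=0; "
                "use l2_weight > 0 or a pseudo-inverse solver"
            )
        w_aug = np.linalg.solve(gram, rhs)

    if include_intercept:
        weights, intercept = w_aug[:-1], float(w_aug[-1])
    else:
        weights, intercept = w_aug, 0.0
    if len(weights) != n_features:
        raise CurategapError("weight vector width mismatch after solve")
    return RidgeModel(
        weights=np.asarray(weights, dtype=float),
        l2_weight=float(l2_weight),
        include_intercept=include_intercept,
        encoding=encoding,
        intercept=intercept,
    )


def predict(model: RidgeModel, X) -> np.ndarray:
    """Real-valued predictions ``X w`` (+ intercept when fitted with one)."""
    X = _as_2d(X)
    if X.shape[1] != len(model.weights):
        raise CurategapError(
            f"design matrix has {X.shape[1]} columns; model expects "
            f"{len(model.weights)}"
        )
    return np.asarray(X @ model.weights).ravel() + model.intercept


def compute_metrics(y, y_hat) -> RegressionMetrics:
    """MAE, RMSE, relative absolute/squared error and R^2 = 1 - RSE."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or y.size == 0:
        raise CurategapError("y and y_hat must be equal-length and non-empty")
    errors = y - y_hat
    mae = float(np.mean(np.abs(errors)))
    rmse = float(np.sqrt(np.mean(errors**2)))
    baseline_abs = np.sum(np.abs(y - y.mean()))
    baseline_sq = np.sum((y - y.mean()) ** 2)
    if baseline_sq == 0:
        raise CurategapError(
            "y is constant; relative errors (RAE/RSE) are undefined"
        )
    rae = float(np.sum(np.abs(errors)) / baseline_abs)
    rse = float(np.sum(errors**2) / baseline_sq)
    return RegressionMetrics(mae=mae, rmse=rmse, rae=rae, rse=rse, r2=1.0 - rse)


def _permute_feature_rows(X, columns: Sequence[int], perm: np.ndarray):
    """Copy of X with the given columns' rows permuted jointly by ``perm``."""
    columns = list(columns)
    if sp.issparse(X):
        X = X.tocsc(copy=True)
        block = X[:, columns][perm, :]
        X = sp.lil_matrix(X)
        X[:, columns] = block
        return X.tocsr()
    X = np.array(X, dtype=float, copy=True)
    X[:, columns] = X[perm][:, columns]
    return X


def permutation_importance(
    model: RidgeModel,
    X,
    y,
    metric: str = "rmse",
    n_repeats: int = 5,
    seed: int = 0,
) -> FeatureImportance:
    """Score each original feature by the metric degradation after permuting it.

    All indicator columns of the symbol feature (including the unknown
    bucket) are permuted jointly with a single row permutation.  For error
    metrics the score is ``metric(permuted) - metric(baseline)``; for ``r2``
    the sign is flipped so that larger is still more important.
    """
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    if metric not in ("rmse", "mae", "r2"):
        raise ConfigurationError(f"unsupported metric {metric!r}")
    if model.encoding is None:
        raise ConfigurationError(
            "permutation importance needs a model with an EncodingSpec"
        )
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    spec = model.encoding

    def metric_value(y_true, y_pred):
        m = compute_metrics(y_true, y_pred)
        return getattr(m, metric)

    baseline = metric_value(y, predict(model, X))
    feature_columns: dict[str, list[int]] = {
        feat: [j] for j, feat in enumerate(spec.numeric_features)
    }
    feature_columns["symbol"] = list(spec.symbol_columns())

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    scores: dict[str, float] = {}
    for feat, columns in feature_columns.items():
        degradations = []
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            X_perm = _permute_feature_rows(X, columns, perm)
            value = metric_value(y, predict(model, X_perm))
            if metric == "r2":
                degradations.append(baseline - value)
            else:
                degradations.append(value - baseline)
        scores[feat] = float(np.mean(degradations))
    return FeatureImportance(
        scores=scores, metric=metric, n_repeats=n_repeats, seed=seed
    )
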