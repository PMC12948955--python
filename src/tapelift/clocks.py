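"""Epigenetic age clocks: elastic-net training, PC-based training, and
application of externally supplied clock definitions.

Two estimators follow the scikit-learn convention (``fit`` / ``predict``,
fitted attributes with a trailing underscore, ``get_params`` /
``set_params``):

* :class:`DirectClock` — penalized linear regression of chronological age on
  individual CpG β-values.  The objective is the elastic net

      ½ ‖y − Xw − b‖² + λ [ α ‖w‖₁ + (1−α)/2 ‖w‖₂² ]

  with the mixing parameter α (default 0.1, mostly-ridge but sparse) and the
  penalty λ expressed in residual-sum-of-squares units, so that for α = 0 at
  fixed λ the solution is exactly the ridge closed form (XᵀX + λI)⁻¹Xᵀy.
  When λ is not given it is chosen on a path by k-fold cross-validation at
  the minimum mean CV error.  Predictors are standardized internally and
  coefficients are reported on the original β scale.

* :class:`PCClock` — the same elastic-net regression (default α = 0.5) on
  principal-component scores of the training β matrix instead of individual
  CpGs, which averages out probe-level technical noise.  The training probe
  means and the component basis are stored so new samples are projected
  consistently; for prediction the basis and component coefficients collapse
  into an equivalent probe-space weight vector.

Trained or externally supplied clocks are carried as :class:`ClockModel`
records (probe list, weights, intercept, optional age transform, training
means for imputing absent probes) which serialize to a JSON header plus a
TSV weight table and can be applied to any dataset with
:func:`predict_age`, reporting probe coverage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .datasets import MethylationDataset, ValidationError

__all__ = [
    "SplitAssignment",
    "split_train_test",
    "DirectClock",
    "PCClock",
    "ClockModel",
    "train_direct_clock",
    "train_pc_clock",
    "predict_age",
    "evaluate_clock",
    "EvalResult",
    "load_external_clock",
    "save_clock",
    "load_clock",
    "horvath_inverse_transform",
]

TRANSFORMS = ("identity", "horvath-log-linear")
_HORVATH_ADULT_AGE = 20.0


# ---------------------------------------------------------------------------
# train/test split

@dataclass(frozen=True)
class SplitAssignment:
    train: tuple[str, ...]
    test: tuple[str, ...]
    seed: int
    fraction: float


def split_train_test(sample_ids: Sequence[str], fraction: float = 0.8, seed: int = 0) -> SplitAssignment:
    """Uniform random train/test partition; train size = round(fraction·n)."""
    ids = [str(s) for s in sample_ids]
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    n = len(ids)
    if n < 5:
        raise ValidationError("need at least 5 samples to split")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = tuple(ids[i] for i in sorted(perm[:n_train]))
    test = tuple(ids[i] for i in sorted(perm[n_train:]))
    return SplitAssignment(train=train, test=test, seed=int(seed), fraction=float(fraction))


# ---------------------------------------------------------------------------
# estimators

def _check_training_matrix(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (samples × probes)")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y have different numbers of samples")
    if np.isnan(X).any():
        raise ValidationError("X contains missing values; impute before training")
    if np.nanstd(y) == 0:
        raise ValidationError("ages are constant; nothing to fit")
    return X, y


def _probe_names(X, n_features: int):
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"f{i}" for i in range(n_features)]


class DirectClock(RegressorMixin, BaseEstimator):
    """Elastic-net age clock on individual CpGs.

    Parameters
    ----------
    mixing_alpha : float in [0, 1]
        Elastic-net mixing (1 = lasso, 0 = ridge).  Default 0.1.
    penalty_lambda : float or None
        Penalty strength in ½‖r‖² + λ·P(w) units.  None selects λ on a path
        by ``n_folds``-fold cross-validation at minimum mean CV error.
    n_folds, n_lambdas : CV settings (folds are shuffled with ``random_state``
        and the assignment is reproducible).
    standardize : standardize predictors internally; coefficients are always
        returned on the original β scale.
    """

    def __init__(
        self,
        mixing_alpha: float = 0.1,
        penalty_lambda: float | None = None,
        n_folds: int = 10,
        n_lambdas: int = 50,
        standardize: bool = True,
        max_iter: int = 2000,
        tol: float = 1e-4,
        random_state: int | None = 0,
    ):
        self.mixing_alpha = mixing_alpha
        self.penalty_lambda = penalty_lambda
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        if not 0.0 <= self.mixing_alpha <= 1.0:
            raise ValidationError("mixing_alpha must be in [0, 1]")
        probe_ids = _probe_names(X, np.shape(X)[1])
        X, y = _check_training_matrix(X, y)
        n, p = X.shape
        mu = X.mean(axis=0)
        if self.standardize:
            sd = X.std(axis=0, ddof=0)
            sd = np.where(sd == 0, 1.0, sd)
        else:
            sd = np.ones(p)
        Xs = (X - mu) / sd

        # sklearn's per-sample alpha = λ/n maps our ½‖r‖² + λP(w) objective
        # onto its (1/2n)‖r‖² + a·P(w) parameterization.
        l1 = self.mixing_alpha
        if self.penalty_lambda is None:
            if n <= self.n_folds:
                raise ValidationError("need more training samples than CV folds")
            cv = KFold(n_splits=self.n_folds, shuffle=True, random_state=self.random_state)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = ElasticNetCV(
                    l1_ratio=l1 if l1 > 0 else 1e-9,
                    alphas=self.n_lambdas,
                    cv=cv,
                    max_iter=self.max_iter,
                    tol=self.tol,
                    random_state=self.random_state,
                ).fit(Xs, y)
            self.penalty_lambda_ = float(model.alpha_) * n
            self.cv_mean_error_ = model.mse_path_.mean(axis=-1)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = ElasticNet(
                    alpha=self.penalty_lambda / n,
                    l1_ratio=l1,
                    max_iter=self.max_iter,
                    tol=self.tol,
                ).fit(Xs, y)
            self.penalty_lambda_ = float(self.penalty_lambda)
            self.cv_mean_error_ = None

        coef_std = np.asarray(model.coef_, dtype=float)
        self.coef_ = coef_std / sd
        self.intercept_ = float(model.intercept_ - np.sum(coef_std * mu / sd))
        self.probe_ids_ = probe_ids
        self.feature_means_ = mu
        self.n_active_cpgs_ = int(np.count_nonzero(self.coef_))
        pred = self.predict(X)
        self.training_metrics_ = _metrics_dict(pred, y)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def to_clock_model(self) -> "ClockModel":
        check_is_fitted(self, "coef_")
        return ClockModel(
            kind="direct",
            probe_ids=list(self.probe_ids_),
            weights=np.asarray(self.coef_, dtype=float),
            intercept=float(self.intercept_),
            transform="identity",
            training_means=np.asarray(self.feature_means_, dtype=float),
            mixing_alpha=float(self.mixing_alpha),
            penalty_lambda=float(self.penalty_lambda_),
            n_folds=int(self.n_folds),
            n_active_cpgs=int(self.n_active_cpgs_),
            training_metrics=dict(self.training_metrics_),
        )


class PCClock(RegressorMixin, BaseEstimator):
    """Elastic-net age clock on principal-component scores.

    ``n_components=None`` keeps min(n_train − 1, n_probes) components; a
    request beyond the feasible rank is clipped with a warning.  The number
    of active CpGs is the number of probes entering the PCA (every probe
    contributes to dense component loadings).

    Component scores keep their natural PCA scale in the penalized fit
    (``standardize_scores=False``): rescaling near-zero-variance trailing
    components to unit variance would amplify pure noise directions.
    """

    def __init__(
        self,
        mixing_alpha: float = 0.5,
        n_components: int | None = None,
        penalty_lambda: float | None = None,
        n_folds: int = 10,
        n_lambdas: int = 50,
        standardize_scores: bool = False,
        max_iter: int = 2000,
        tol: float = 1e-4,
        random_state: int | None = 0,
    ):
        self.mixing_alpha = mixing_alpha
        self.n_components = n_components
        self.penalty_lambda = penalty_lambda
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.standardize_scores = standardize_scores
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        probe_ids = _probe_names(X, np.shape(X)[1])
        X, y = _check_training_matrix(X, y)
        n, p = X.shape
        max_comp = min(n - 1, p)
        k = max_comp if self.n_components is None else int(self.n_components)
        if k > max_comp:
            warnings.warn(
                f"n_components={k} exceeds feasible rank {max_comp}; clipping"
            )
            k = max_comp
        self.pca_ = PCA(n_components=k, svd_solver="full")
        scores = self.pca_.fit_transform(X)  # centers internally at col means
        self.means_ = self.pca_.mean_.astype(float)

        inner = DirectClock(
            mixing_alpha=self.mixing_alpha,
            penalty_lambda=self.penalty_lambda,
            n_folds=self.n_folds,
            n_lambdas=self.n_lambdas,
            standardize=self.standardize_scores,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(scores, y)
        self.component_coef_ = inner.coef_.copy()
        self.component_intercept_ = float(
            inner.intercept_
        )
        self.penalty_lambda_ = inner.penalty_lambda_
        self.n_active_components_ = int(np.count_nonzero(self.component_coef_))
        # collapse basis projection into probe-space weights:
        # pred = b0 + ((x - means) V^T) c = (b0) + (x - means)·(V^T c)
        self.probe_weights_ = self.pca_.components_.T @ self.component_coef_
        self.intercept_ = float(self.component_intercept_ - self.means_ @ self.probe_weights_)
        self.probe_ids_ = probe_ids
        self.n_active_cpgs_ = p  # CpGs entering the PCA
        pred = self.predict(X)
        self.training_metrics_ = _metrics_dict(pred, y)
        self.n_features_in_ = p
        return self

    def transform(self, X):
        """Project samples onto the stored component basis (training means)."""
        check_is_fitted(self, "pca_")
        return self.pca_.transform(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "probe_weights_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.probe_weights_

    def to_clock_model(self) -> "ClockModel":
        check_is_fitted(self, "probe_weights_")
        return ClockModel(
            kind="pc",
            probe_ids=list(self.probe_ids_),
            weights=np.asarray(self.probe_weights_, dtype=float),
            intercept=float(self.intercept_),
            transform="identity",
            training_means=np.asarray(self.means_, dtype=float),
            mixing_alpha=float(self.mixing_alpha),
            penalty_lambda=float(self.penalty_lambda_),
            n_folds=int(self.n_folds),
            n_active_cpgs=int(self.n_active_cpgs_),
            training_metrics=dict(self.training_metrics_),
            n_components=int(self.pca_.n_components_),
        )


# ---------------------------------------------------------------------------
# portable clock record

@dataclass
class ClockModel:
    """A trained or externally supplied linear age clock.

    For ``pc`` clocks the component basis has been collapsed into an
    equivalent probe-space weight vector (the linear predictor is identical);
    ``training_means`` lets prediction impute probes absent from a target
    dataset at their training-set mean.
    """

    kind: str  # direct | pc | external
    probe_ids: list[str]
    weights: np.ndarray
    intercept: float
    transform: str = "identity"
    training_means: np.ndarray | None = None
    mixing_alpha: float | None = None
    penalty_lambda: float | None = None
    n_folds: int | None = None
    n_active_cpgs: int | None = None
    training_metrics: dict = field(default_factory=dict)
    n_components: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "pc", "external"):
            raise ValidationError(f"unknown clock kind {self.kind!r}")
        if self.transform not in TRANSFORMS:
            raise ValidationError(f"unknown age transform {self.transform!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.probe_ids) != len(self.weights):
            raise ValidationError("probe_ids and weights lengths differ")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids in clock definition")


def horvath_inverse_transform(x: np.ndarray, adult_age: float = _HORVATH_ADULT_AGE) -> np.ndarray:
    """Invert the log-linear age transform used by first-generation clocks."""
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, (1.0 + adult_age) * np.exp(x) - 1.0, (1.0 + adult_age) * x + adult_age)


def predict_age(
    model: ClockModel, ds: MethylationDataset, impute_default: float = 0.5
) -> tuple[pd.Series, dict]:
    """Apply a clock to a dataset, imputing absent probes at training means.

    Returns ``(predictions, coverage_report)``; the report holds ``coverage``
    (fraction of model probes present in the dataset), counts, and the
    applied transform.  Zero coverage is an error.  When probes are missing
    and the model stores no training means they are imputed at
    ``impute_default`` with a warning; missing β cells within present probes
    are imputed the same way.
    """
    idx = pd.Index(model.probe_ids)
    present = idx.intersection(ds.probe_ids)
    coverage = len(present) / len(idx)
    if coverage == 0:
        raise ValidationError("no clock probes present in the dataset")
    if coverage < 1.0:
        warnings.warn(
            f"clock {model.name or model.kind}: only {len(present)} of "
            f"{len(idx)} probes present (coverage {coverage:.2f})"
        )
    means = (
        pd.Series(model.training_means, index=idx)
        if model.training_means is not None
        else pd.Series(impute_default, index=idx)
    )
    B = ds.betas.reindex(idx).copy()
    missing_rows = B.isna().all(axis=1)
    B = B.apply(lambda col: col.fillna(means), axis=0)
    linear = model.intercept + B.to_numpy(dtype=float).T @ model.weights
    if model.transform == "horvath-log-linear":
        pred = horvath_inverse_transform(linear)
    else:
        pred = linear
    report = {
        "coverage": coverage,
        "n_model_probes": len(idx),
        "n_present": len(present),
        "n_imputed": int(missing_rows.sum()),
        "transform": model.transform,
    }
    return pd.Series(pred, index=ds.sample_ids, name="predicted_age"), report


@dataclass
class EvalResult:
    rmse: float
    pearson_r: float
    residuals: pd.Series


def evaluate_clock(pred, true) -> EvalResult:
    """RMSE (years) and Pearson r between predicted and chronological age."""
    pred_s = pd.Series(pred).astype(float)
    true_arr = np.asarray(true, dtype=float)
    if len(pred_s) != len(true_arr):
        raise ValidationError("prediction and truth lengths differ")
    if len(pred_s) < 2:
        raise ValidationError("need at least 2 samples to evaluate")
    resid = pred_s.to_numpy() - true_arr
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.std(pred_s.to_numpy()) == 0 or np.std(true_arr) == 0:
        warnings.warn("constant predictions or ages: Pearson r undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred_s.to_numpy(), true_arr)[0])
    return EvalResult(rmse=rmse, pearson_r=r, residuals=pd.Series(resid, index=pred_s.index))


def _metrics_dict(pred, true) -> dict:
    ev = evaluate_clock(pd.Series(np.asarray(pred)), true)
    return {"rmse": ev.rmse, "pearson_r": ev.pearson_r}


# ---------------------------------------------------------------------------
# serialization

def save_clock(model: ClockModel, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    weights_path = out / "clock_weights.tsv"
    table = pd.DataFrame({"probe_id": model.probe_ids, "weight": model.weights})
    if model.training_means is not None:
        table["training_mean"] = model.training_means
    table.to_csv(weights_path, sep="\t", index=False, float_format="%.17g")
    header = {
        "name": model.name,
        "kind": model.kind,
        "intercept": model.intercept,
        "transform": model.transform,
        "mixing_alpha": model.mixing_alpha,
        "penalty_lambda": model.penalty_lambda,
        "n_folds": model.n_folds,
        "n_active_cpgs": model.n_active_cpgs,
        "training_metrics": model.training_metrics,
        "n_components": model.n_components,
        "weights_file": weights_path.name,
    }
    header_path = out / "clock.json"
    header_path.write_text(json.dumps(header, indent=2))
    return {"header": header_path, "weights": weights_path}


def _load_clock_files(header_path: Path) -> ClockModel:
    header = json.loads(header_path.read_text())
    weights_path = header_path.parent / header["weights_file"]
    table = pd.read_csv(weights_path, sep="\t", dtype={"probe_id": str},
                        float_precision="round_trip")
    if table["probe_id"].duplicated().any():
        dups = table.loc[table["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"duplicate probe ids in clock definition: {dups[:5]}")
    means = (
        table["training_mean"].to_numpy(dtype=float)
        if "training_mean" in table.columns
        else None
    )
    return ClockModel(
        kind=header.get("kind", "external"),
        probe_ids=table["probe_id"].tolist(),
        weights=table["weight"].to_numpy(dtype=float),
        intercept=float(header["intercept"]),
        transform=header.get("transform", "identity"),
        training_means=means,
        mixing_alpha=header.get("mixing_alpha"),
        penalty_lambda=header.get("penalty_lambda"),
        n_folds=header.get("n_folds"),
        n_active_cpgs=header.get("n_active_cpgs"),
        training_metrics=header.get("training_metrics") or {},
        n_components=header.get("n_components"),
        name=header.get("name", ""),
    )


def load_clock(path: str | Path) -> ClockModel:
    """Load a clock saved by :func:`save_clock` (directory or header path)."""
    path = Path(path)
    header = path / "clock.json" if path.is_dir() else path
    return _load_clock_files(header)


def load_external_clock(path: str | Path) -> ClockModel:
    """Load an externally supplied clock definition (JSON header + TSV)."""
    model = _load_clock_files(Path(path))
    model.kind = "external"
    return model


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators

def train_direct_clock(
    betas_train: pd.DataFrame,
    ages_train,
    alpha: float = 0.1,
    n_folds: int = 10,
    seed: int = 0,
    penalty_lambda: float | None = None,
    **kwargs,
) -> ClockModel:
    """Train an elastic-net CpG clock; ``betas_train`` is probes × samples."""
    est = DirectClock(
        mixing_alpha=alpha, n_folds=n_folds, random_state=seed,
        penalty_lambda=penalty_lambda, **kwargs,
    ).fit(betas_train.T, np.asarray(ages_train, dtype=float))
    return est.to_clock_model()


def train_pc_clock(
    betas_train: pd.DataFrame,
    ages_train,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_components: int | None = None,
    preselect: pd.DataFrame | str | None = "auto",
    q_threshold: float = 0.01,
    **kwargs,
) -> ClockModel:
    """Train a PC clock with pre-selection to age-associated probes.

    ``preselect`` is an age-association result table restricting the PCA to
    probes with ``q_value`` below ``q_threshold``; ``"auto"`` (default)
    computes that table from the training data itself, and ``None`` disables
    pre-selection so every probe enters the PCA.  Restricting the PCA to
    age-informative probes is what lets the component scores average away
    probe-level technical noise instead of modeling it.
    """
    if isinstance(preselect, str):
        if preselect != "auto":
            raise ValidationError(f"unknown preselect mode {preselect!r}")
        from .agestats import age_association

        preselect = age_association(betas_train, np.asarray(ages_train, dtype=float))
    if preselect is not None:
        keep = preselect.index[preselect["q_value"] < q_threshold]
        keep = betas_train.index.intersection(keep)
        if len(keep) < 2:
            raise ValidationError("pre-selection leaves fewer than 2 probes")
        betas_train = betas_train.loc[keep]
    est = PCClock(
        mixing_alpha=alpha, n_folds=n_folds, random_state=seed,
        n_components=n_components, **kwargs,
    ).fit(betas_train.T, np.asarray(ages_train, dtype=float))
    return est.to_clock_model()
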