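"""Regression harness: five algorithms × four feature-set configurations.

The harness mirrors a standard chemometrics model comparison: leaf
phosphorus concentration (LPC, mg g⁻¹) is regressed on

* ``OR``       — the original full-band reflectance (2151 features),
* ``SIs``      — the optimized two-band spectral indices (10 features),
* ``CWT``      — the optimized wavelet coefficients (10 features),
* ``SIs+CWT``  — their concatenation (20 features),

with five algorithms: partial least squares regression (PLSR), LASSO,
random forest (RF), support-vector regression with an RBF kernel (SVM),
and a single-hidden-layer back-propagation neural network (BPANN).
Features are standardized to training mean/s.d. for PLSR, LASSO, SVM and
BPANN; RF consumes raw features.  Data flow follows the calibration /
validation discipline: a seeded 70/30 split, feature selection on the
calibration set only, 10-fold cross-validation on the calibration set, and
held-out validation metrics (R², RMSE, AIC, Taylor statistics).

"Default settings" of a specific software stack are not reproducible, so
every hyperparameter is explicit in :class:`HarnessConfig`: PLSR latent
components by inner 5-fold CV up to 10; LASSO penalty by inner 5-fold CV
over a logarithmic grid 1e-4..1e1; RF with 500 trees and square-root
feature subsampling; SVM with C = 1 and kernel width 1/(k·Var(x));
BPANN with 100 logistic hidden units and up to 2000 epochs.

Calibration R² is reported two ways, because training-set fit and
cross-validated skill differ sharply for flexible models (RF especially):
``r2_cal_fit`` is the training-set fit and ``r2_cv`` the 10-fold CV mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .spectra_io import SpectrumSet
from .index_search import IndexFeature, compute_index
from .cwt_features import WaveletFeature, coefficients_at
from .evaluation import TaylorPoint, taylor_statistics

__all__ = [
    "ALGORITHMS",
    "SOURCES",
    "HarnessConfig",
    "FeatureTable",
    "ModelReport",
    "split_dataset",
    "r2_metric",
    "rmse_metric",
    "aic_metric",
    "fit_predict",
    "cross_validate",
    "build_feature_tables",
    "run_matrix",
    "reports_to_frame",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("PLSR", "LASSO", "RF", "SVM", "BPANN")
SOURCES = ("OR", "SIs", "CWT", "SIs+CWT")


@dataclass
class HarnessConfig:
    """Explicit hyperparameters for the five algorithms."""

    pls_max_components: int = 10
    pls_inner_folds: int = 5
    lasso_alphas: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 1, 30)
    )
    lasso_inner_folds: int = 5
    lasso_max_iter: int = 20000
    rf_n_estimators: int = 500
    rf_max_features: str = "sqrt"
    svm_c: float = 1.0
    svm_gamma: str = "scale"
    mlp_hidden_units: int = 100
    mlp_activation: str = "logistic"
    mlp_max_iter: int = 2000


@dataclass
class FeatureTable:
    """A sample × feature matrix with aligned trait values."""

    feature_names: list[str]
    values: np.ndarray
    source: str
    lpc: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.lpc = np.asarray(self.lpc, dtype=np.float64)
        if self.values.shape != (len(self.lpc), len(self.feature_names)):
            raise ValueError("feature table shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ModelReport:
    """One algorithm × one feature source, with all evaluation metrics."""

    algorithm: str
    source: str
    k: int
    n_cal: int
    n_val: int
    r2_cal_fit: float
    r2_val: float
    rmse_val: float
    aic: float
    taylor: TaylorPoint
    r2_cv: float = np.nan
    rmse_cv: float = np.nan
    importances: np.ndarray | None = None


# ----------------------------------------------------------------------
# split and metrics
def split_dataset(
    s: SpectrumSet, cal_fraction: float = 0.7, seed: int = 0
) -> tuple[SpectrumSet, SpectrumSet]:
    """Seeded uniform random 70/30 partition into calibration/validation."""
    s.require_lpc()
    if not 0.0 < cal_fraction < 1.0:
        raise ValueError("cal_fraction must be in (0, 1)")
    n = s.n_samples
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = int(np.floor(cal_fraction * n))
    return s.take(np.sort(perm[:n_cal])), s.take(np.sort(perm[n_cal:]))


def r2_metric(measured, predicted) -> float:
    """Determination coefficient 1 − SSres/SStot (may be negative)."""
    x = np.asarray(measured, dtype=np.float64)
    y = np.asarray(predicted, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("measured and predicted must be equal-length, n >= 2")
    sstot = float(np.sum((x - x.mean()) ** 2))
    if sstot == 0:
        raise ValueError("measured values are constant; R² undefined")
    return 1.0 - float(np.sum((y - x) ** 2)) / sstot


def rmse_metric(measured, predicted) -> float:
    """Root mean square error √(Σ(yᵢ−xᵢ)²/n), in trait units (mg g⁻¹)."""
    x = np.asarray(measured, dtype=np.float64)
    y = np.asarray(predicted, dtype=np.float64)
    if x.shape != y.shape or x.size < 1:
        raise ValueError("measured and predicted must be equal-length, n >= 1")
    return float(np.sqrt(np.mean((y - x) ** 2)))


def aic_metric(measured, predicted, k: int, printed_variant: bool = False) -> float:
    """Least-squares Akaike criterion 2k + n·ln(RSS/n).

    ``printed_variant=True`` substitutes the total sum of squares about the
    measured mean for the residual sum of squares — a formulation sometimes
    printed but not a measure of fit; the residual form is the default.
    """
    x = np.asarray(measured, dtype=np.float64)
    y = np.asarray(predicted, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("measured and predicted must be equal-length, n >= 2")
    n = x.size
    ss = float(np.sum((y - x.mean()) ** 2)) if printed_variant else float(
        np.sum((y - x) ** 2)
    )
    if ss <= 0:
        raise ValueError("zero sum of squares; AIC is -infinity")
    return 2.0 * k + n * float(np.log(ss / n))


# ----------------------------------------------------------------------
# algorithms
def _select_pls_components(X: np.ndarray, y: np.ndarray, hyper: HarnessConfig) -> int:
    n, k = X.shape
    folds = min(hyper.pls_inner_folds, n)
    max_nc = max(1, min(hyper.pls_max_components, k, n - (n // folds) - 1))
    if max_nc == 1 or folds < 2:
        return 1
    kf = KFold(n_splits=folds)
    best_nc, best_mse = 1, np.inf
    for nc in range(1, max_nc + 1):
        errs = []
        for tr, te in kf.split(X):
            m = PLSRegression(n_components=nc, scale=False)
            m.fit(X[tr], y[tr])
            errs.append(np.mean((m.predict(X[te]).ravel() - y[te]) ** 2))
        mse = float(np.mean(errs))
        if mse < best_mse - 1e-12:
            best_mse, best_nc = mse, nc
    return best_nc


class _PLSWithInnerCV:
    """Standardize, pick latent components by inner CV, then fit PLSR."""

    def __init__(self, hyper: HarnessConfig):
        self.hyper = hyper

    def fit(self, X, y):
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.n_components_ = _select_pls_components(Xs, y, self.hyper)
        self.model_ = PLSRegression(n_components=self.n_components_, scale=False)
        self.model_.fit(Xs, y)
        return self

    def predict(self, X):
        return self.model_.predict(self.scaler_.transform(X)).ravel()


def _build_model(algorithm: str, hyper: HarnessConfig, seed: int):
    if algorithm == "PLSR":
        return _PLSWithInnerCV(hyper)
    if algorithm == "LASSO":
        return make_pipeline(
            StandardScaler(),
            LassoCV(
                alphas=hyper.lasso_alphas,
                cv=hyper.lasso_inner_folds,
                max_iter=hyper.lasso_max_iter,
                selection="cyclic",
            ),
        )
    if algorithm == "RF":
        return RandomForestRegressor(
            n_estimators=hyper.rf_n_estimators,
            max_features=hyper.rf_max_features,
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "SVM":
        return make_pipeline(
            StandardScaler(), SVR(kernel="rbf", C=hyper.svm_c, gamma=hyper.svm_gamma)
        )
    if algorithm == "BPANN":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=(hyper.mlp_hidden_units,),
                activation=hyper.mlp_activation,
                max_iter=hyper.mlp_max_iter,
                random_state=seed,
            ),
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def fit_predict(
    algorithm: str,
    train: FeatureTable,
    test: FeatureTable,
    hyper: HarnessConfig | None = None,
    seed: int = 0,
):
    """Fit one algorithm on ``train`` and predict ``test``.

    Returns ``(predictions, info)``; ``info`` carries the fitted model, the
    training-set predictions, and (for RF) per-feature importance scores.
    """
    if train.feature_names != test.feature_names:
        raise ValueError("train and test feature names differ")
    hyper = hyper or HarnessConfig()
    model = _build_model(algorithm, hyper, seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        warnings.filterwarnings("ignore", message=".*convergence.*")
        warnings.filterwarnings("ignore", module="sklearn")
        model.fit(train.values, train.lpc)
        pred = np.asarray(model.predict(test.values), dtype=np.float64).ravel()
        pred_train = np.asarray(model.predict(train.values), dtype=np.float64).ravel()
    if not np.all(np.isfinite(pred)):
        raise ArithmeticError(f"{algorithm} produced non-finite predictions")
    info = {"model": model, "pred_train": pred_train, "importances": None}
    if algorithm == "RF":
        info["importances"] = model.feature_importances_
    return pred, info


def cross_validate(
    algorithm: str,
    table: FeatureTable,
    folds: int = 10,
    seed: int = 0,
    hyper: HarnessConfig | None = None,
) -> tuple[float, float]:
    """Seeded k-fold CV; returns the means of per-fold R² and RMSE."""
    if table.n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    r2s, rmses = [], []
    for tr, te in kf.split(table.values):
        sub_tr = FeatureTable(table.feature_names, table.values[tr], table.source, table.lpc[tr])
        sub_te = FeatureTable(table.feature_names, table.values[te], table.source, table.lpc[te])
        pred, _ = fit_predict(algorithm, sub_tr, sub_te, hyper=hyper, seed=seed)
        rmses.append(rmse_metric(sub_te.lpc, pred))
        if np.ptp(sub_te.lpc) == 0:
            logger.warning("fold with constant measured LPC; its R² excluded")
            continue
        r2s.append(r2_metric(sub_te.lpc, pred))
    return float(np.mean(r2s)), float(np.mean(rmses))


# ----------------------------------------------------------------------
# feature tables and the 4 x 5 run matrix
def _si_matrix(s: SpectrumSet, features: list[IndexFeature]) -> np.ndarray:
    return np.column_stack(
        [compute_index(s, f.index_type, f.lambda1_nm, f.lambda2_nm) for f in features]
    )


def build_feature_tables(
    s_cal: SpectrumSet,
    s_val: SpectrumSet,
    si_features: list[IndexFeature],
    cwt_features_list: list[WaveletFeature],
) -> dict[str, tuple[FeatureTable, FeatureTable]]:
    """Assemble the OR / SIs / CWT / SIs+CWT tables for both splits.

    Feature definitions must have been selected on the calibration set
    only; this function merely evaluates them on each split.
    """
    y_cal, y_val = s_cal.require_lpc(), s_val.require_lpc()
    out: dict[str, tuple[FeatureTable, FeatureTable]] = {}

    or_names = [str(w) for w in s_cal.wavelengths_nm]
    out["OR"] = (
        FeatureTable(or_names, s_cal.reflectance, "OR", y_cal),
        FeatureTable(or_names, s_val.reflectance, "OR", y_val),
    )
    si_names = [f.name for f in si_features]
    out["SIs"] = (
        FeatureTable(si_names, _si_matrix(s_cal, si_features), "SIs", y_cal),
        FeatureTable(si_names, _si_matrix(s_val, si_features), "SIs", y_val),
    )
    cwt_names = [f.name for f in cwt_features_list]
    out["CWT"] = (
        FeatureTable(cwt_names, coefficients_at(s_cal, cwt_features_list), "CWT", y_cal),
        FeatureTable(cwt_names, coefficients_at(s_val, cwt_features_list), "CWT", y_val),
    )
    both = si_names + cwt_names
    out["SIs+CWT"] = (
        FeatureTable(
            both,
            np.hstack([out["SIs"][0].values, out["CWT"][0].values]),
            "SIs+CWT",
            y_cal,
        ),
        FeatureTable(
            both,
            np.hstack([out["SIs"][1].values, out["CWT"][1].values]),
            "SIs+CWT",
            y_val,
        ),
    )
    return out


def run_matrix(
    s_cal: SpectrumSet,
    s_val: SpectrumSet,
    si_features: list[IndexFeature],
    cwt_features_list: list[WaveletFeature],
    hyper: HarnessConfig | None = None,
    seed: int = 0,
    cv_folds: int | None = 10,
) -> list[ModelReport]:
    """Run all five algorithms on all four feature sources (20 reports).

    ``cv_folds=None`` skips the cross-validation columns (reported as NaN)
    for quick directional comparisons; the default performs seeded 10-fold
    CV on the calibration table.
    """
    hyper = hyper or HarnessConfig()
    tables = build_feature_tables(s_cal, s_val, si_features, cwt_features_list)
    reports: list[ModelReport] = []
    for source in SOURCES:
        t_cal, t_val = tables[source]
        for algorithm in ALGORITHMS:
            pred_val, info = fit_predict(algorithm, t_cal, t_val, hyper=hyper, seed=seed)
            r2_cv = rmse_cv = np.nan
            if cv_folds:
                r2_cv, rmse_cv = cross_validate(
                    algorithm, t_cal, folds=cv_folds, seed=seed, hyper=hyper
                )
            reports.append(
                ModelReport(
                    algorithm=algorithm,
                    source=source,
                    k=t_cal.k,
                    n_cal=t_cal.n,
                    n_val=t_val.n,
                    r2_cal_fit=r2_metric(t_cal.lpc, info["pred_train"]),
                    r2_val=r2_metric(t_val.lpc, pred_val),
                    rmse_val=rmse_metric(t_val.lpc, pred_val),
                    aic=aic_metric(t_val.lpc, pred_val, k=t_cal.k),
                    taylor=taylor_statistics(
                        t_val.lpc, pred_val, label=f"{algorithm}-{source}"
                    ),
                    r2_cv=r2_cv,
                    rmse_cv=rmse_cv,
                    importances=info["importances"],
                )
            )
    return reports


def reports_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    """Flatten reports to the comparison-table layout."""
    rows = []
    for r in reports:
        rows.append(
            {
                "source": r.source,
                "k": r.k,
                "model": r.algorithm,
                "r2_cal_fit": r.r2_cal_fit,
                "r2_cv": r.r2_cv,
                "rmse_cv": r.rmse_cv,
                "r2_val": r.r2_val,
                "rmse_val": r.rmse_val,
                "aic": r.aic,
                "taylor_r": r.taylor.pearson_r,
                "taylor_std_ratio": r.taylor.std_ratio,
                "taylor_crmsd": r.taylor.centered_rmsd,
            }
        )
    return pd.DataFrame(rows)
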