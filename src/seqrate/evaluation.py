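"""Evaluation harness: strict LOOCV, repeated 90/10 splits, metrics,
single-feature screening, and the linear-regression baseline.

Every cross-validation routine here refits feature scaling inside each fold
from the training rows only, so held-out data never influences the fitted
fold model (no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from . import feature_assembly, svm_models
from .contact_features import compute_co, compute_lrcn, compute_lrco
from .feature_assembly import FeatureConfig
from .io_formats import KineticLabel, ProteinRecord, ValidationError
from .sequence_features import ss_composition
from .svm_models import HyperParams

__all__ = [
    "EvaluationReport",
    "PipelineReport",
    "LinearBaselineResult",
    "ScreenRow",
    "pearson",
    "mad",
    "loocv_classifier",
    "loocv_regressor",
    "pipeline_loocv",
    "repeated_split_eval",
    "single_feature_screen",
    "linear_baseline",
    "SCREEN_FEATURES",
]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; constant input is an error, not a silent 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError("pearson requires at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("pearson correlation is undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def mad(true: Sequence[float], pred: Sequence[float]) -> float:
    """Mean absolute difference between two equal-length vectors."""
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if true.shape != pred.shape:
        raise ValidationError(f"length mismatch: {true.shape} vs {pred.shape}")
    if true.size < 1:
        raise ValidationError("mad requires at least one observation")
    return float(np.mean(np.abs(true - pred)))


@dataclass
class EvaluationReport:
    """Cross-validated predictions plus the aggregate metrics."""

    protocol: str
    ids: list[str]
    true_values: np.ndarray
    predictions: np.ndarray
    pearson_r: float = np.nan
    mad: float = np.nan
    accuracy: Optional[float] = None
    n_repeats: int = 1
    seed: Optional[int] = None
    per_repeat: list[dict] = field(default_factory=list)


def _fit_fold_classifier(
    X: np.ndarray,
    y_codes: np.ndarray,
    train_idx: np.ndarray,
    hp: HyperParams,
    scaling: str,
):
    """Fit scaling + classifier on the training rows of one fold.

    Exposed separately so leakage can be tested: the returned model is a
    function of ``X[train_idx]`` only.
    """
    scaler = feature_assembly.fit_scaling(X[train_idx], scaling)
    Xt = scaler.transform(X[train_idx])
    clf = svm_models._svc(hp).fit(Xt, y_codes[train_idx])
    return scaler, clf


def _fit_fold_regressor(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    hp: HyperParams,
    scaling: str,
):
    scaler = feature_assembly.fit_scaling(X[train_idx], scaling)
    Xt = scaler.transform(X[train_idx])
    reg = svm_models._svr(hp).fit(Xt, y[train_idx])
    return scaler, reg


def loocv_classifier(
    matrix: np.ndarray,
    labels: Sequence[KineticLabel],
    hp: HyperParams,
    scaling: str = "minmax",
    ids: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Strict leave-one-out evaluation of the kinetic-type classifier."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    labels = list(labels)
    n = X.shape[0]
    if n != len(labels):
        raise ValidationError("matrix rows and labels length differ")
    codes = np.array([svm_models.LABEL_CODE[l] for l in labels])
    for c in (1, -1):
        if int(np.sum(codes == c)) < 2:
            raise ValidationError("LOOCV classification needs >= 2 rows per class")
    preds = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        train_idx = all_idx[all_idx != i]
        scaler, clf = _fit_fold_classifier(X, codes, train_idx, hp, scaling)
        preds[i] = clf.predict(scaler.transform(X[i]))[0]
    acc = float(np.mean(preds == codes))
    return EvaluationReport(
        protocol="LOOCV",
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        true_values=codes.astype(float),
        predictions=preds,
        accuracy=acc,
    )


def loocv_regressor(
    matrix: np.ndarray,
    targets: Sequence[float],
    hp: HyperParams,
    scaling: str = "minmax",
    ids: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Strict leave-one-out evaluation of an ε-SVR rate regressor."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if n != y.size:
        raise ValidationError("matrix rows and targets length differ")
    if n < 3:
        raise ValidationError("LOOCV regression needs at least 3 rows")
    preds = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        train_idx = all_idx[all_idx != i]
        scaler, reg = _fit_fold_regressor(X, y, train_idx, hp, scaling)
        preds[i] = reg.predict(scaler.transform(X[i]))[0]
    try:
        r = pearson(y, preds)
    except ValidationError:
        r = float("nan")  # constant predictions: correlation undefined
    return EvaluationReport(
        protocol="LOOCV",
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        true_values=y,
        predictions=preds,
        pearson_r=r,
        mad=mad(y, preds),
    )


@dataclass
class PipelineReport:
    """LOOCV evaluation of the full two-stage predictor."""

    ids: list[str]
    true_labels: list[KineticLabel]
    pred_labels: list[KineticLabel]
    true_rates: np.ndarray
    pred_rates: np.ndarray
    accuracy: float
    per_class: dict[KineticLabel, dict]  # {"pearson_r": ..., "mad": ..., "n": ...}


def pipeline_loocv(
    records: Sequence[ProteinRecord],
    config: FeatureConfig = FeatureConfig(),
    hp_classifier: HyperParams = svm_models.DEFAULT_CLASSIFIER_HP,
    hp_two_state: HyperParams = svm_models.DEFAULT_REGRESSOR_HP,
    hp_multi_state: HyperParams = svm_models.DEFAULT_REGRESSOR_HP,
) -> PipelineReport:
    """Leave each protein out, train the full two-stage predictor on the
    rest, and predict the held-out protein's kinetic type and rate."""
    records = list(records)
    n = len(records)
    if n < 6:
        raise ValidationError("pipeline LOOCV needs at least 6 records")
    pred_labels: list[KineticLabel] = []
    pred_rates = np.empty(n)
    for i in range(n):
        train = records[:i] + records[i + 1 :]
        bundle = svm_models.train_bundle(
            train, config, hp_classifier, hp_two_state, hp_multi_state
        )
        label, rate = svm_models.predict(bundle, records[i])
        pred_labels.append(label)
        pred_rates[i] = rate
    true_labels = [r.kinetic_label for r in records]
    true_rates = np.array([r.log_rate for r in records])
    acc = float(np.mean([p is t for p, t in zip(pred_labels, true_labels)]))
    per_class: dict[KineticLabel, dict] = {}
    for label in (KineticLabel.TWO_STATE, KineticLabel.MULTI_STATE):
        sel = np.array([t is label for t in true_labels])
        entry: dict = {"n": int(sel.sum())}
        if sel.sum() >= 3:
            try:
                entry["pearson_r"] = pearson(true_rates[sel], pred_rates[sel])
            except ValidationError:
                entry["pearson_r"] = float("nan")
            entry["mad"] = mad(true_rates[sel], pred_rates[sel])
        per_class[label] = entry
    return PipelineReport(
        ids=[r.id for r in records],
        true_labels=true_labels,
        pred_labels=pred_labels,
        true_rates=true_rates,
        pred_rates=pred_rates,
        accuracy=acc,
        per_class=per_class,
    )


def _test_size(n: int, test_fraction: float) -> int:
    # floor(n * fraction), but at least 2 so test-set metrics are defined
    return max(2, int(np.floor(n * test_fraction)))


def repeated_split_eval(
    matrix: np.ndarray,
    targets: Sequence[float],
    hp: HyperParams,
    n_repeats: int = 5,
    test_fraction: float = 0.10,
    seed: int = 0,
    scaling: str = "minmax",
    stratify: Optional[Sequence[KineticLabel]] = None,
    grid_spec: Optional[dict] = None,
    ids: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Repeated random 90/10 split evaluation of a rate regressor.

    Each repeat draws a fresh test set (``floor(n·fraction)``, minimum 2,
    unstratified unless ``stratify`` labels are given), fits scaling and the
    regressor on the training portion only, and scores Pearson r and MAD on
    the test portion.  If ``grid_spec`` is given, hyperparameters are
    re-selected per repeat by LOOCV on the training portion (two-phase
    heuristic); otherwise the supplied ``hp`` is used for every repeat.
    Fully deterministic for a fixed seed.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    n_test = _test_size(n, test_fraction)
    if n_test >= n:
        raise ValidationError("dataset too small for the requested test fraction")
    rng = np.random.default_rng(seed)
    per_repeat = []
    all_true, all_pred = [], []
    for rep in range(n_repeats):
        if stratify is not None:
            test_idx = []
            for label in (KineticLabel.TWO_STATE, KineticLabel.MULTI_STATE):
                cls_idx = np.array([k for k, l in enumerate(stratify) if l is label])
                k = max(1, int(np.floor(len(cls_idx) * test_fraction)))
                test_idx.extend(rng.choice(cls_idx, size=k, replace=False))
            test_idx = np.sort(np.array(test_idx))
        else:
            test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        hp_rep = hp
        if grid_spec is not None:
            result = svm_models.tune_regressor(
                X[train_idx], y[train_idx], grid_spec=grid_spec, scaling=scaling
            )
            hp_rep = result.best
        scaler, reg = _fit_fold_regressor(X, y, train_idx, hp_rep, scaling)
        preds = reg.predict(scaler.transform(X[test_idx]))
        try:
            r = pearson(y[test_idx], preds) if len(test_idx) >= 3 else float("nan")
        except ValidationError:
            r = float("nan")
        per_repeat.append(
            {
                "repeat": rep,
                "test_idx": test_idx.tolist(),
                "pearson_r": r,
                "mad": mad(y[test_idx], preds),
                "hyperparams": hp_rep,
            }
        )
        all_true.extend(y[test_idx])
        all_pred.extend(preds)
    finite_r = [d["pearson_r"] for d in per_repeat if np.isfinite(d["pearson_r"])]
    return EvaluationReport(
        protocol="SPLIT_90_10",
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        true_values=np.array(all_true),
        predictions=np.array(all_pred),
        pearson_r=float(np.mean(finite_r)) if finite_r else float("nan"),
        mad=float(np.mean([d["mad"] for d in per_repeat])),
        n_repeats=n_repeats,
        seed=seed,
        per_repeat=per_repeat,
    )


# The Table-2-style screening feature list: one scalar per protein.
SCREEN_FEATURES = ("L", "LRCO", "CO", "LRCN", "helix", "sheet", "coil")


def _scalar_feature(record: ProteinRecord, name: str, config: FeatureConfig) -> float:
    cp = config.contact_params
    if name == "L":
        return float(record.length)
    if name == "LRCO":
        return compute_lrco(record.contact_map, record.length, cp)
    if name == "CO":
        return compute_co(record.contact_map, record.length, cp)
    if name == "LRCN":
        return compute_lrcn(record.contact_map, record.length, cp)
    if name in ("helix", "sheet", "coil"):
        return getattr(ss_composition(record.ss_string), name)
    raise ValidationError(f"unknown screening feature {name!r}")


@dataclass
class ScreenRow:
    feature: str
    kinetic_class: KineticLabel
    pearson_r: Optional[float]
    mad: Optional[float]
    error: Optional[str] = None


def single_feature_screen(
    records: Sequence[ProteinRecord],
    features: Sequence[str] = SCREEN_FEATURES,
    hp: HyperParams = svm_models.DEFAULT_REGRESSOR_HP,
    config: FeatureConfig = FeatureConfig(),
    scaling: str = "minmax",
) -> list[ScreenRow]:
    """LOOCV single-feature SVR screen, per feature and per kinetic class.

    The reported correlation is signed: its magnitude is the LOOCV
    predicted-vs-true Pearson r, and its sign is the direction of the raw
    feature-rate relationship (predicted-vs-true r is positive for any
    working monotone model, so the direction has to be attached
    explicitly for a Table-of-signed-correlations reading).  A feature that
    is constant within a class yields a row carrying the error, not a crash.
    """
    rows: list[ScreenRow] = []
    for label in (KineticLabel.TWO_STATE, KineticLabel.MULTI_STATE):
        subset = [r for r in records if r.kinetic_label is label]
        if len(subset) < 3:
            raise ValidationError(f"need >= 3 proteins per class, got {len(subset)} for {label}")
        y = np.array([r.log_rate for r in subset])
        for feat in features:
            x = np.array([[_scalar_feature(r, feat, config)] for r in subset])
            if np.all(x == x[0, 0]):
                rows.append(
                    ScreenRow(feat, label, None, None,
                              error="undefined correlation: feature constant across proteins")
                )
                continue
            try:
                report = loocv_regressor(x, y, hp, scaling=scaling)
                if not np.isfinite(report.pearson_r):
                    raise ValidationError("undefined correlation (constant predictions)")
                direction = np.sign(pearson(x.ravel(), y))
                r_signed = float(direction * abs(report.pearson_r))
                rows.append(ScreenRow(feat, label, r_signed, report.mad))
            except ValidationError as exc:
                rows.append(ScreenRow(feat, label, None, None, error=str(exc)))
    return rows


@dataclass
class LinearBaselineResult:
    """OLS baseline: log rate regressed on a chosen predictor subset."""

    predictor_names: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    correlation: float  # between fitted and observed rates
    rmse: float
    f_value: float
    p_value: float
    n: int


def linear_baseline(
    matrix: np.ndarray, targets: Sequence[float], predictor_names: Sequence[str]
) -> LinearBaselineResult:
    """Ordinary least squares of log rate on the chosen predictors, with the
    overall ANOVA F statistic and its p-value."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    y = np.asarray(targets, dtype=float)
    n, p = X.shape
    if len(predictor_names) != p:
        raise ValidationError("predictor_names length does not match matrix columns")
    if n <= p + 1:
        raise ValidationError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValidationError("rank-deficient design matrix (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    fitted = fit.fittedvalues
    coefs = {"intercept": float(fit.params[0])}
    for k, name in enumerate(predictor_names):
        coefs[name] = float(fit.params[k + 1])
    return LinearBaselineResult(
        predictor_names=list(predictor_names),
        coefficients=coefs,
        correlation=pearson(y, fitted),
        rmse=float(np.sqrt(fit.mse_resid)),
        f_value=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        n=n,
    )
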