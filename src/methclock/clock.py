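"""Elastic-net epigenetic clocks for age and sex.

An age clock is a sparse linear model fit by elastic-net regression of
*transformed* age on beta values; a sex clock is the analogous penalized
logistic model.  The penalty strength lambda is chosen by inner K-fold
cross-validation (minimum mean squared error / deviance) on a descending
log-spaced grid, and the reported model is always the refit on the full
training set -- leave-one-out cross-validation (LOOCV) is evaluation only,
repeating the *entire* procedure (probe filtering, imputation,
standardization, lambda selection) without the held-out sample.

Accuracy conventions follow the epigenetic-clock literature: Pearson r
between inverse-transformed predictions and chronological age, MAE as the
*median* absolute error in years, and a prediction counts as accurate when
it falls within max(20% of true age, 1 year).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold

from .io import BetaMatrix, ClockModel, SampleSheet
from .transform import TransformParams, inverse_transform_age, transform_age

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltyConfig",
    "ClockEvaluation",
    "fit_age_clock",
    "predict_age",
    "loocv_age",
    "evaluate_age",
    "fit_sex_clock",
    "predict_sex",
    "loocv_sex",
    "elastic_net_coefficients",
]


@dataclass(frozen=True)
class PenaltyConfig:
    """Elastic-net penalty and inner-CV settings.

    ``mixing`` is the L1/L2 mixing parameter alpha (1 = lasso, 0 = ridge);
    ``lambda_grid`` is either "auto" (glmnet-style descending grid from the
    smallest lambda zeroing every coefficient) or an explicit sequence.
    """

    mixing: float = 0.5
    lambda_grid: object = "auto"
    n_lambda: int = 25
    inner_folds: int = 10
    standardize: bool = True
    seed: int = 0
    max_missing: float = 0.2  # probes missing in more than this fraction are dropped
    tol: float = 1e-3        # coordinate-descent duality-gap tolerance
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass
class ClockEvaluation:
    """Held-out predictions and summary accuracy of an age clock."""

    table: pd.DataFrame  # sample_id, true_age, predicted_age, accurate
    r: float
    mae: float
    accuracy20: float
    n: int


# ---------------------------------------------------------------------------
# shared design-matrix preparation
# ---------------------------------------------------------------------------

def _training_design(beta: BetaMatrix, sample_ids, max_missing: float):
    """Probe filtering and mean imputation on the training samples.

    Probes missing in more than ``max_missing`` of training samples are
    dropped; the remainder are imputed with training means.
    """
    df = beta.to_frame().loc[sample_ids]
    frac = df.isna().mean()
    df = df.loc[:, frac <= max_missing]
    means = df.mean()
    df = df.fillna(means).dropna(axis=1)  # all-missing probes have NaN means
    return df


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, pen: PenaltyConfig) -> np.ndarray:
    if pen.lambda_grid != "auto":
        grid = np.sort(np.asarray(pen.lambda_grid, dtype=float))[::-1]
        if (grid <= 0).any():
            raise ValueError("lambda grid must be positive")
        return grid
    n = Xs.shape[0]
    yc = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * max(pen.mixing, 1e-3))
    lam_max = max(lam_max, 1e-12)
    ratio = 1e-2 if n < Xs.shape[1] else 1e-4
    return lam_max * ratio ** np.linspace(0.0, 1.0, pen.n_lambda)


def elastic_net_coefficients(
    X: np.ndarray, y: np.ndarray, mixing: float, lam: float, tol: float = 1e-10
):
    """Elastic-net fit at a single penalty; returns ``(coef, intercept)``.

    Minimizes ``1/(2n) ||y - b0 - X w||^2 + lam * (mixing ||w||_1 +
    (1 - mixing)/2 ||w||_2^2)`` on the given (already scaled) design.
    """
    est = ElasticNet(alpha=lam, l1_ratio=mixing, fit_intercept=True,
                     max_iter=100_000, tol=tol)
    est.fit(X, y)
    return est.coef_.copy(), float(est.intercept_)


def _destandardize(ws, b0s, mean, sd):
    w = ws / sd
    return w, b0s - float(np.dot(ws, mean / sd))


# ---------------------------------------------------------------------------
# age clock
# ---------------------------------------------------------------------------

def fit_age_clock(
    beta: BetaMatrix,
    sheet: SampleSheet,
    tparams: TransformParams = TransformParams(),
    pen: PenaltyConfig = PenaltyConfig(),
) -> ClockModel:
    """Fit the elastic-net age clock on all samples with a known age.

    The response is the transformed age; lambda is selected by inner K-fold
    CV at minimum mean squared error and the model is refit on everything.
    The returned :class:`ClockModel` holds coefficients on the *raw beta*
    scale (destandardized), so it can be applied with a bare dot product.
    Samples are internally ordered by id, making the fit independent of the
    input ordering.
    """
    meta = sheet.aligned_to(beta)
    meta = meta[np.isfinite(meta["age_years"])].sort_values("sample_id")
    ids = meta["sample_id"].tolist()
    if len(ids) < 10:
        raise ValueError(f"need >= 10 samples with known age, got {len(ids)}")
    if len(ids) < pen.inner_folds:
        raise ValueError("fewer samples than inner CV folds")
    y = transform_age(meta["age_years"].to_numpy(), tparams)

    X = _training_design(beta, ids, pen.max_missing)
    sd_raw = X.to_numpy().std(axis=0)
    X = X.loc[:, sd_raw > 0]
    if X.shape[1] == 0:
        logger.warning("all probes constant; returning intercept-only clock")
        return ClockModel("age", float(np.mean(y)), {}, asm=tparams.asm,
                          offset=tparams.offset, metadata={"n_train": len(ids)})

    probes = list(X.columns)
    Xv = X.to_numpy()
    if pen.standardize:
        mean, sd = Xv.mean(axis=0), Xv.std(axis=0)
        Xs = (Xv - mean) / sd
    else:
        mean, sd = np.zeros(Xv.shape[1]), np.ones(Xv.shape[1])
        Xs = Xv

    grid = _lambda_grid(Xs, y, pen)
    cv = KFold(n_splits=pen.inner_folds, shuffle=True, random_state=pen.seed)
    # Extend the auto grid downward only when the CV error is in free fall
    # at the floor (>= 10x drop over the bottom decade), the signature of
    # near-noiseless data where the error is pure shrinkage bias (~lambda^2,
    # i.e. 100x per decade).  Noise-limited curves plateau long before that
    # and are left alone.
    for _ in range(3):
        est = ElasticNetCV(alphas=grid, l1_ratio=pen.mixing, cv=cv,
                           max_iter=pen.max_iter, tol=pen.tol)
        est.fit(Xs, y)
        if pen.lambda_grid != "auto" or est.alpha_ > grid.min() * (1 + 1e-12):
            break
        mse = est.mse_path_.mean(axis=-1)
        alphas = np.asarray(est.alphas_)  # descending, aligned with mse
        decade_up = int(np.argmin(np.abs(np.log10(alphas)
                                         - (np.log10(alphas[-1]) + 1.0))))
        if not mse[-1] < 0.1 * mse[decade_up]:
            break
        grid = grid.min() * (1e-2) ** np.linspace(0.0, 1.0, pen.n_lambda)
    w, b0 = _destandardize(est.coef_, float(est.intercept_), mean, sd)
    coefficients = {p: float(c) for p, c in zip(probes, w) if c != 0.0}
    return ClockModel(
        "age", b0, coefficients, asm=tparams.asm, offset=tparams.offset,
        metadata={"lambda": float(est.alpha_), "n_train": len(ids),
                  "mixing": pen.mixing},
    )


def _linear_score(model: ClockModel, beta: BetaMatrix, missing_policy: str) -> pd.Series:
    frame = beta.to_frame()
    probes = sorted(model.coefficients)
    if not probes:
        return pd.Series(model.intercept, index=frame.index)
    absent = [p for p in probes if p not in frame.columns]
    sub = frame.reindex(columns=probes)
    n_missing = int(sub.isna().to_numpy().sum())
    if n_missing:
        if missing_policy == "error":
            raise ValueError(
                f"{len(absent)} model probes absent / {n_missing} missing values; "
                "use missing_policy='impute_half' to impute at 0.5"
            )
        if missing_policy != "impute_half":
            raise ValueError("missing_policy must be 'error' or 'impute_half'")
        logger.warning("imputed %d missing model-probe values at 0.5", n_missing)
        sub = sub.fillna(0.5)
    w = np.array([model.coefficients[p] for p in probes])
    return pd.Series(model.intercept + sub.to_numpy() @ w, index=frame.index)


def predict_age(model: ClockModel, beta: BetaMatrix, missing_policy: str = "error") -> pd.Series:
    """Predicted age in years for every sample of ``beta``.

    The linear score ``intercept + sum_j w_j beta_ij`` lives on the
    transformed-age scale and is mapped back through the inverse transform.
    """
    if model.target != "age":
        raise ValueError("model target is not 'age'")
    score = _linear_score(model, beta, missing_policy)
    tparams = TransformParams(asm=model.asm, offset=model.offset)
    pred = inverse_transform_age(score.to_numpy(), tparams)
    n_neg = int((pred < 0).sum())
    if n_neg:
        logger.info("%d predictions below 0 years returned as-is", n_neg)
    return pd.Series(pred, index=score.index, name="predicted_age")


def evaluate_age(
    pred, true, rel_tol: float = 0.20, abs_floor: float = 1.0
) -> ClockEvaluation:
    """Summary accuracy of age predictions against known ages.

    r is the Pearson correlation (NaN when either vector is constant), MAE
    the median absolute error in years, and a prediction is "accurate" when
    ``|pred - true| <= max(rel_tol * true, abs_floor)``.
    """
    pred = pd.Series(pred)
    true_arr = np.asarray(true, dtype=float)
    if len(pred) != len(true_arr) or len(pred) < 2:
        raise ValueError("pred and true must have equal length >= 2")
    p = pred.to_numpy(dtype=float)
    err = np.abs(p - true_arr)
    if np.ptp(p) == 0 or np.ptp(true_arr) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(p, true_arr).statistic)
    accurate = err <= np.maximum(rel_tol * true_arr, abs_floor)
    table = pd.DataFrame({
        "sample_id": pred.index,
        "true_age": true_arr,
        "predicted_age": p,
        "accurate": accurate,
    })
    return ClockEvaluation(
        table=table,
        r=r,
        mae=float(np.median(err)),
        accuracy20=float(np.mean(accurate)),
        n=len(pred),
    )


def loocv_age(
    beta: BetaMatrix,
    sheet: SampleSheet,
    tparams: TransformParams = TransformParams(),
    pen: PenaltyConfig = PenaltyConfig(),
) -> ClockEvaluation:
    """Leave-one-out cross-validated evaluation of the age clock.

    Each sample is predicted by a clock refit from scratch on all other
    samples (full pipeline: probe filtering, imputation, standardization,
    lambda selection).  The summary is computed on the held-out predictions.
    """
    meta = sheet.aligned_to(beta)
    meta = meta[np.isfinite(meta["age_years"])].sort_values("sample_id")
    ids = meta["sample_id"].tolist()
    preds = {}
    for held in ids:
        train_ids = [s for s in ids if s != held]
        sub_sheet = SampleSheet(sheet.data[sheet.data["sample_id"].isin(train_ids)])
        sub_beta = beta.subset_samples(train_ids)
        model = fit_age_clock(sub_beta, sub_sheet, tparams, pen)
        preds[held] = float(
            predict_age(model, beta.subset_samples([held]),
                        missing_policy="impute_half").iloc[0]
        )
    pred = pd.Series([preds[s] for s in ids], index=ids)
    return evaluate_age(pred, meta.set_index("sample_id").loc[ids, "age_years"])


# ---------------------------------------------------------------------------
# sex clock
# ---------------------------------------------------------------------------

def fit_sex_clock(
    beta: BetaMatrix,
    sheet: SampleSheet,
    pen: PenaltyConfig = PenaltyConfig(),
) -> ClockModel:
    """Penalized logistic sex clock on standardized betas.

    The label mapped to positive linear scores is fixed by lexicographic
    order (the larger label), recorded on the model.  The regularization
    strength is chosen by stratified inner CV on log-loss; folds shrink to
    the minority-class count when needed.
    """
    meta = sheet.aligned_to(beta).sort_values("sample_id")
    ids = meta["sample_id"].tolist()
    labels = meta["sex"].to_numpy()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training data contains a single sex")
    positive = classes[-1]
    y = (labels == positive).astype(int)

    X = _training_design(beta, ids, pen.max_missing)
    X = X.loc[:, X.to_numpy().std(axis=0) > 0]
    probes = list(X.columns)
    Xv = X.to_numpy()
    if pen.standardize and probes:
        mean, sd = Xv.mean(axis=0), Xv.std(axis=0)
        Xs = (Xv - mean) / sd
    else:
        mean, sd = np.zeros(Xv.shape[1]), np.ones(Xv.shape[1])
        Xs = Xv
    if not probes:
        raise ValueError("all probes constant; no sex clock can be fit")

    min_class = int(min(np.bincount(y)))
    folds = min(pen.inner_folds, min_class)
    if folds < 2:
        raise ValueError("need >= 2 samples of each sex for inner CV")
    if folds < pen.inner_folds:
        logger.warning("reducing inner folds to %d (minority class size)", folds)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=pen.seed)
    # C capped at 10: on (near-)separable training data larger C only inflates
    # coefficients without changing labels, and saga stops converging
    est = LogisticRegressionCV(
        Cs=np.logspace(-2, 1, 8), solver="saga",
        l1_ratios=[pen.mixing], cv=cv, scoring="neg_log_loss",
        max_iter=5_000, tol=1e-4, random_state=pen.seed,
        use_legacy_attributes=False,
    )
    est.fit(Xs, y)
    w, b0 = _destandardize(est.coef_.ravel(), float(est.intercept_[0]), mean, sd)
    coefficients = {p: float(c) for p, c in zip(probes, w) if c != 0.0}
    return ClockModel(
        "sex", b0, coefficients, positive_label=positive,
        negative_label=classes[0],
        metadata={"C": float(np.ravel(est.C_)[0]), "n_train": len(ids)},
    )


def predict_sex(model: ClockModel, beta: BetaMatrix,
                missing_policy: str = "impute_half") -> pd.DataFrame:
    """Per-sample predicted sex label and probability of the positive label.

    ``probability = logistic(intercept + sum_j w_j beta_ij)``; the label is
    ``positive_label`` iff probability >= 0.5 (ties go to the positive
    label).
    """
    if model.target != "sex":
        raise ValueError("model target is not 'sex'")
    from scipy.special import expit

    score = _linear_score(model, beta, missing_policy)
    prob = expit(score.to_numpy())
    label = np.where(prob >= 0.5, model.positive_label, model.negative_label)
    return pd.DataFrame({"label": label, "probability": prob}, index=score.index)


def loocv_sex(
    beta: BetaMatrix,
    sheet: SampleSheet,
    pen: PenaltyConfig = PenaltyConfig(),
) -> tuple:
    """LOOCV accuracy of the sex clock; returns ``(accuracy, table)``."""
    meta = sheet.aligned_to(beta).sort_values("sample_id")
    ids = meta["sample_id"].tolist()
    truth = meta.set_index("sample_id")["sex"]
    rows = []
    for held in ids:
        train_ids = [s for s in ids if s != held]
        sub_sheet = SampleSheet(sheet.data[sheet.data["sample_id"].isin(train_ids)])
        model = fit_sex_clock(beta.subset_samples(train_ids), sub_sheet, pen)
        out = predict_sex(model, beta.subset_samples([held]))
        rows.append({
            "sample_id": held,
            "true_sex": truth.loc[held],
            "predicted_sex": out["label"].iloc[0],
            "probability": float(out["probability"].iloc[0]),
        })
    table = pd.DataFrame(rows)
    accuracy = float((table["true_sex"] == table["predicted_sex"]).mean())
    return accuracy, table
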