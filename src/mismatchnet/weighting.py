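"""Train/test-mismatch penalty weighting (fictitious-response procedure).

The procedure learns, for every marker, how strongly it discriminates the
prediction target set (a whole family) from the training set, and turns that
into a per-marker penalty factor for the final phenotype model:

1. stack the training and testing genotype matrices and build a fictitious
   0/1 response (0 = training line, 1 = testing line);
2. fit a Lasso of the fictitious response on the stacked markers and keep
   its coefficients ``beta_bin``;
3. set penalty weights ``w_j = 1 / |beta_j,bin|`` — a marker the binary
   Lasso ignores gets an infinite weight (excluded) or, under the "cap"
   policy, a large finite one;
4. refit the phenotype model on the training set only (WLasso / WRidge /
   WENet) with those weights, and predict the testing set.

The testing set's *phenotypes* are never an input to any step; only its
genotypes are used, so no leakage of the quantity being predicted occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import solver
from .config import RunConfig
from .solver import PenaltyWeights

logger = logging.getLogger(__name__)

UNWEIGHTED_MODELS = ("enet", "lasso", "ridge")
WEIGHTED_MODELS = ("wenet", "wlasso", "wridge")
MODELS = UNWEIGHTED_MODELS + WEIGHTED_MODELS


def model_alpha(model: str, enet_alpha: float = 0.5) -> float:
    base = model.lstrip("w") if model.startswith("w") else model
    if model not in MODELS:
        raise ValueError(f"unknown model '{model}' (choose from {MODELS})")
    return {"enet": enet_alpha, "lasso": 1.0, "ridge": 0.0}[base]


@dataclass
class FictitiousResponse:
    """0/1 membership labels: n_trn zeros then n_tst ones."""

    labels: np.ndarray
    n_trn: int
    n_tst: int


@dataclass
class BinaryWeightFit:
    """Coefficients of the train-vs-test discriminating Lasso."""

    beta_bin: np.ndarray
    lambda_bin: float
    selection_rule: str
    family: str


def make_fictitious_response(n_trn: int, n_tst: int) -> FictitiousResponse:
    """Labels marking set membership: 0 for training rows, 1 for testing rows."""
    if n_trn < 1 or n_tst < 1:
        raise ValueError("both sets must be non-empty (a one-class binary "
                         "fit is undefined)")
    labels = np.concatenate([np.zeros(n_trn), np.ones(n_tst)])
    return FictitiousResponse(labels=labels, n_trn=n_trn, n_tst=n_tst)


def fit_binary_lasso(X_trn, X_tst, config: RunConfig | None = None,
                     seed: int | None = None) -> BinaryWeightFit:
    """Lasso of the fictitious 0/1 response on the stacked genotypes.

    By default a squared-error Lasso on the labels (the printed PRSS loss
    applied to 0/1 data); ``config.binary_family = "logistic"`` switches to an
    l1-penalized logistic fit.  Lambda is chosen by k-fold CV within the
    stacked data (rule per config, default lambda_min), seeded.
    """
    cfg = config or RunConfig()
    if seed is None:
        seed = cfg.seed
    Xa = solver._as_matrix(X_trn)
    Xb = solver._as_matrix(X_tst)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError(f"marker count mismatch: {Xa.shape[1]} vs "
                         f"{Xb.shape[1]}")
    fr = make_fictitious_response(Xa.shape[0], Xb.shape[0])
    X = np.vstack([Xa, Xb])
    if np.isclose(X.std(axis=0), 0.0).all():
        raise ValueError("every marker is constant in the stacked data")

    if cfg.binary_family == "logistic":
        beta, lam = _logistic_binary(X, fr.labels, cfg, seed)
        return BinaryWeightFit(beta_bin=beta, lambda_bin=lam,
                               selection_rule=cfg.lambda_rule,
                               family="logistic")

    cv = solver.cross_validate_lambda(X, fr.labels, alpha=1.0, weights=None,
                                      k=cfg.cv_folds, seed=seed,
                                      n_lambda=cfg.n_lambda,
                                      lambda_min_ratio=cfg.lambda_min_ratio,
                                      tol=cfg.tol, max_sweeps=cfg.max_sweeps)
    lam = cv.lambda_1se if cfg.lambda_rule == "1se" else cv.lambda_min
    fit = solver.fit_weighted_enet(X, fr.labels, lam=lam, alpha=1.0,
                                   tol=cfg.tol, max_sweeps=cfg.max_sweeps)
    logger.info("binary lasso: lambda=%.4g, %d/%d nonzero markers",
                lam, fit.n_nonzero, Xa.shape[1])
    return BinaryWeightFit(beta_bin=fit.coefficients, lambda_bin=lam,
                           selection_rule=cfg.lambda_rule,
                           family="squared-error")


def _logistic_binary(X, labels, cfg: RunConfig, seed: int):
    """l1 logistic discriminator (optional flag); standard fit, delegated."""
    from sklearn.linear_model import LogisticRegressionCV

    est = LogisticRegressionCV(Cs=10, cv=cfg.cv_folds, penalty="l1",
                               solver="liblinear", scoring="neg_log_loss",
                               random_state=seed, max_iter=2000)
    est.fit(X, labels.astype(int))
    return est.coef_.ravel(), float(1.0 / est.C_[0])


def compute_weights(beta_bin, policy: str = "exclude",
                    cap: float = 10.0) -> PenaltyWeights:
    """Penalty weights ``w_j = 1 / |beta_j,bin|``.

    A zero binary coefficient yields an infinite raw weight; under policy
    ``"exclude"`` the marker is dropped from the final model, under ``"cap"``
    it gets ``cap * max(finite raw weight)`` instead (all markers kept).
    Finite weights are rescaled to average 1 over the surviving markers.
    """
    beta_bin = np.asarray(beta_bin, dtype=np.float64)
    if beta_bin.ndim != 1:
        raise ValueError("beta_bin must be a vector")
    if policy not in ("exclude", "cap"):
        raise ValueError("policy must be 'exclude' or 'cap'")
    if cap <= 1:
        raise ValueError("cap must exceed 1")
    with np.errstate(divide="ignore"):
        raw = 1.0 / np.abs(beta_bin)
    if policy == "cap":
        finite = np.isfinite(raw)
        if not finite.any():
            raw = np.ones_like(raw)  # nothing discriminates: equal weights
        else:
            raw[~finite] = cap * raw[finite].max()
    elif not np.isfinite(raw).any():
        raise ValueError("all binary coefficients are zero: every marker "
                         "would be excluded (use policy='cap')")
    return PenaltyWeights.from_raw(raw)


def fit_weighted_model(X_trn, y_trn, X_tst, model: str = "wenet",
                       config: RunConfig | None = None,
                       seed: int | None = None,
                       binary_fit: BinaryWeightFit | None = None,
                       weights: PenaltyWeights | None = None):
    """Steps 1-4 end to end: weights from genotypes, weighted refit, predict.

    Fits on ``{X_trn, y_trn}`` only (testing phenotypes are not a parameter);
    returns ``(ElasticNetFit, predictions on X_tst)``.  A precomputed
    ``binary_fit`` or ``weights`` may be supplied to share the discriminator
    across models/traits of the same train/test split.
    """
    cfg = config or RunConfig()
    if seed is None:
        seed = cfg.seed
    if model not in WEIGHTED_MODELS:
        raise ValueError(f"model must be one of {WEIGHTED_MODELS}")
    y_trn = np.asarray(y_trn, dtype=np.float64)
    if y_trn.size != solver._as_matrix(X_trn).shape[0]:
        raise ValueError("y_trn length must match X_trn rows")
    if weights is None:
        if binary_fit is None:
            binary_fit = fit_binary_lasso(X_trn, X_tst, cfg, seed=seed)
        weights = compute_weights(binary_fit.beta_bin,
                                  policy=cfg.zero_coef_policy, cap=cfg.cap)
    alpha = model_alpha(model, cfg.alpha)
    cv = solver.cross_validate_lambda(X_trn, y_trn, alpha=alpha,
                                      weights=weights, k=cfg.cv_folds,
                                      seed=seed, n_lambda=cfg.n_lambda,
                                      lambda_min_ratio=cfg.lambda_min_ratio,
                                      tol=cfg.tol, max_sweeps=cfg.max_sweeps)
    lam = cv.lambda_1se if cfg.lambda_rule == "1se" else cv.lambda_min
    fit = solver.fit_weighted_enet(X_trn, y_trn, lam=lam, alpha=alpha,
                                   weights=weights, tol=cfg.tol,
                                   max_sweeps=cfg.max_sweeps)
    logger.info("%s: lambda=%.4g, %d nonzero", model, lam, fit.n_nonzero)
    return fit, solver.predict(fit, X_tst)


def fit_unweighted_model(X_trn, y_trn, X_tst, model: str = "enet",
                         config: RunConfig | None = None,
                         seed: int | None = None):
    """Conventional ENet/Lasso/Ridge counterpart on the same code path."""
    cfg = config or RunConfig()
    if seed is None:
        seed = cfg.seed
    if model not in UNWEIGHTED_MODELS:
        raise ValueError(f"model must be one of {UNWEIGHTED_MODELS}")
    alpha = model_alpha(model, cfg.alpha)
    cv = solver.cross_validate_lambda(X_trn, y_trn, alpha=alpha, weights=None,
                                      k=cfg.cv_folds, seed=seed,
                                      n_lambda=cfg.n_lambda,
                                      lambda_min_ratio=cfg.lambda_min_ratio,
                                      tol=cfg.tol, max_sweeps=cfg.max_sweeps)
    lam = cv.lambda_1se if cfg.lambda_rule == "1se" else cv.lambda_min
    fit = solver.fit_weighted_enet(X_trn, y_trn, lam=lam, alpha=alpha,
                                   tol=cfg.tol, max_sweeps=cfg.max_sweeps)
    return fit, solver.predict(fit, X_tst)
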