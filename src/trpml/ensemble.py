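"""Bayesian ensemble regression for genotype → GFP-synthesis-rate prediction.

The model is a convex combination of M diverse base regressors
g_1 … g_M with the weight vector w treated as a random variable on the
M-simplex:

    y_i ~ Normal( Σ_m w_m · g_m(x_i), σ² ),   w ~ Dirichlet(1, …, 1),
    σ ~ half-Cauchy(scale = sd(y)).

To keep the weight posterior honest, the likelihood is evaluated on
*out-of-fold* base-learner predictions (5-fold internal stacking): a
learner that merely memorizes the training set gains no weight. The
posterior is sampled with a seeded random-walk Metropolis sampler on
stick-breaking-transformed weights plus log σ (4 chains × 5000 draws,
1000 burn-in by default). Predictive mean and sd per genotype follow from
the posterior moments of w plus the noise scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_X_y, check_array


def default_learners(random_state: int | None = 0) -> list[tuple[str, BaseEstimator]]:
    """Eight deterministic base regressors spanning distinct model families.

    Linear, two regularized-linear, kernel, nearest-neighbor, single-tree
    and two tree-ensemble learners. All stochastic learners carry a fixed
    ``random_state`` so fits are reproducible.
    """
    return [
        ("linear", LinearRegression()),
        ("ridge", Ridge(alpha=1.0)),
        ("lasso", Lasso(alpha=0.5, max_iter=5000)),
        ("kernel_ridge", KernelRidge(kernel="rbf", alpha=1.0, gamma=0.1)),
        ("knn", KNeighborsRegressor(n_neighbors=5)),
        ("tree", DecisionTreeRegressor(max_depth=6, random_state=random_state)),
        (
            "random_forest",
            RandomForestRegressor(n_estimators=100, random_state=random_state, n_jobs=1),
        ),
        (
            "gbm",
            GradientBoostingRegressor(n_estimators=100, max_depth=3, random_state=random_state),
        ),
    ]


# --- stick-breaking simplex transform ------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def stick_breaking(theta: np.ndarray) -> tuple[np.ndarray, float]:
    """Map θ ∈ R^{M−1} to a weight vector on the M-simplex.

    Returns (w, log|det J|) with the Jacobian of the transform, so a flat
    Dirichlet prior on w becomes a density on θ.
    """
    M = theta.size + 1
    v = _sigmoid(theta)
    w = np.empty(M)
    log_jac = 0.0
    stick = 1.0
    log_stick = 0.0
    for i in range(M - 1):
        w[i] = v[i] * stick
        log_jac += np.log(v[i]) + np.log1p(-v[i]) + log_stick
        stick *= 1.0 - v[i]
        log_stick += np.log1p(-v[i])
    w[M - 1] = stick
    return w, log_jac


@dataclass
class McmcConfig:
    n_chains: int = 4
    n_draws: int = 5000
    n_burn: int = 1000
    proposal_scale: float = 0.25
    target_acceptance: float = 0.3


class BayesianEnsembleRegressor(RegressorMixin, BaseEstimator):
    """Probabilistic stacking ensemble with MCMC-inferred simplex weights.

    Parameters
    ----------
    learners : list of (name, estimator) or None
        Base regressors; ``None`` uses :func:`default_learners`.
    n_folds : int
        Internal folds for the out-of-fold predictions the weight
        likelihood is computed on.
    n_chains, n_draws, n_burn, proposal_scale : MCMC settings.
    random_state : int or None
        Seed for fold shuffling, learner seeds stay as configured.

    Attributes (after fit)
    ----------------------
    learners_ : fitted base learners (full training data)
    learner_names_ : names of learners that fitted successfully
    weight_samples_ : (S, M) posterior weight draws (post burn-in, pooled)
    sigma_samples_ : (S,) posterior noise-scale draws (MFI/h)
    weight_mean_, weight_cov_ : posterior moments used for prediction
    acceptance_rate_ : mean Metropolis acceptance over chains
    """

    def __init__(
        self,
        learners=None,
        n_folds: int = 5,
        n_chains: int = 4,
        n_draws: int = 5000,
        n_burn: int = 1000,
        proposal_scale: float = 0.25,
        random_state: int | None = None,
    ):
        self.learners = learners
        self.n_folds = n_folds
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.n_burn = n_burn
        self.proposal_scale = proposal_scale
        self.random_state = random_state

    # --- fitting ---------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        # canonical row order: makes the fit (fold assignment, hence the
        # whole posterior) invariant under permutation of the training rows
        order = np.lexsort([y] + [X[:, j] for j in range(X.shape[1] - 1, -1, -1)])
        X, y = X[order], y[order]
        specs = self.learners if self.learners is not None else default_learners(
            0 if self.random_state is None else self.random_state
        )
        rs = 0 if self.random_state is None else int(self.random_state)

        fitted, names, oof_cols = [], [], []
        n = len(y)
        k = min(self.n_folds, n)
        kf = KFold(n_splits=k, shuffle=True, random_state=rs)
        splits = list(kf.split(X))
        for name, est in specs:
            try:
                full = clone(est).fit(X, y)
                oof = np.empty(n)
                for tr, te in splits:
                    oof[te] = clone(est).fit(X[tr], y[tr]).predict(X[te])
            except Exception as e:  # noqa: BLE001 - any learner failure excludes it
                warnings.warn(f"base learner {name!r} failed to fit and was excluded: {e}")
                continue
            fitted.append(full)
            names.append(name)
            oof_cols.append(oof)
        if not fitted:
            raise RuntimeError("all base learners failed to fit")

        self.learners_ = fitted
        self.learner_names_ = names
        G = np.column_stack(oof_cols)  # n × M out-of-fold predictions
        self._sample_posterior(G, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _sample_posterior(self, G: np.ndarray, y: np.ndarray) -> None:
        n, M = G.shape
        sd_y = float(np.std(y)) or 1.0
        rng = np.random.default_rng(0 if self.random_state is None else self.random_state)

        def log_post(theta: np.ndarray, log_sigma: float) -> tuple[float, np.ndarray]:
            if M == 1:
                w, log_jac = np.ones(1), 0.0
            else:
                w, log_jac = stick_breaking(theta)
            sigma = np.exp(log_sigma)
            resid = y - G @ w
            loglik = -n * log_sigma - 0.5 * np.dot(resid, resid) / sigma**2
            # half-Cauchy(sd_y) prior on sigma, + log-Jacobian of log transform
            logprior = -np.log1p((sigma / sd_y) ** 2) + log_sigma
            return loglik + logprior + log_jac, w

        dim = max(M - 1, 0) + 1  # θ plus log σ
        all_w, all_sigma, acc_rates = [], [], []
        for chain in range(self.n_chains):
            crng = np.random.default_rng(rng.integers(2**31))
            theta = 0.1 * crng.standard_normal(max(M - 1, 0))
            log_sigma = np.log(sd_y) + 0.1 * crng.standard_normal()
            lp, w = log_post(theta, log_sigma)
            scale = self.proposal_scale
            accepted = 0
            ws = np.empty((self.n_draws - self.n_burn, M))
            sg = np.empty(self.n_draws - self.n_burn)
            for it in range(self.n_draws):
                prop = crng.standard_normal(dim) * scale
                theta_p = theta + prop[:-1]
                log_sigma_p = log_sigma + prop[-1]
                lp_p, w_p = log_post(theta_p, log_sigma_p)
                if np.log(crng.random()) < lp_p - lp:
                    theta, log_sigma, lp, w = theta_p, log_sigma_p, lp_p, w_p
                    accepted += 1
                if it < self.n_burn:
                    # Robbins–Monro adaptation toward the target acceptance,
                    # frozen after burn-in to preserve detailed balance
                    if (it + 1) % 100 == 0:
                        rate = accepted / (it + 1)
                        scale *= np.exp(0.5 * (rate - 0.3))
                else:
                    ws[it - self.n_burn] = w
                    sg[it - self.n_burn] = np.exp(log_sigma)
            all_w.append(ws)
            all_sigma.append(sg)
            acc_rates.append(accepted / self.n_draws)

        self.weight_samples_ = np.vstack(all_w)
        self.sigma_samples_ = np.concatenate(all_sigma)
        self.weight_mean_ = self.weight_samples_.mean(axis=0)
        self.weight_cov_ = np.cov(self.weight_samples_, rowvar=False).reshape(M, M)
        self.sigma2_mean_ = float(np.mean(self.sigma_samples_**2))
        self.acceptance_rate_ = float(np.mean(acc_rates))
        if not (0.05 <= self.acceptance_rate_ <= 0.8):
            warnings.warn(
                f"MCMC acceptance rate {self.acceptance_rate_:.2f} outside sanity band"
            )

    # --- prediction ------------------------------------------------------

    def _base_predictions(self, X) -> np.ndarray:
        X = check_array(X)
        return np.column_stack([lrn.predict(X) for lrn in self.learners_])

    def predict(self, X, return_std: bool = False):
        """Posterior predictive mean (and sd) per row.

        μ(x) = p(x)ᵀ E[w];  σ²(x) = p(x)ᵀ Cov[w] p(x) + E[σ²_noise], where
        p(x) is the vector of base-learner predictions. Both are exact
        moments over the pooled posterior draws (the mean is linear in w).
        """
        P = self._base_predictions(X)
        mu = P @ self.weight_mean_
        if not return_std:
            return mu
        var_model = np.einsum("ij,jk,ik->i", P, self.weight_cov_, P)
        sd = np.sqrt(np.maximum(var_model, 0.0) + self.sigma2_mean_)
        return mu, sd


# --- evaluation ----------------------------------------------------------


@dataclass
class CVResult:
    mae: float
    fold_maes: list[float]
    predictions: np.ndarray  # pooled held-out predictions, original row order


def cross_validate(
    estimator, X: np.ndarray, y: np.ndarray, k: int = 10, seed: int = 0
) -> CVResult:
    """k-fold cross-validated MAE (MFI/h) with random fold assignment.

    Trains a clone of ``estimator`` on k−1 folds and pools the held-out
    absolute errors; the default k=10 is the study's 90/10 protocol (use
    k=5 for the alternative 80/20 split, or k=n for leave-one-out).
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    if k < 2 or k > len(y):
        raise ValueError("need 2 <= k <= n")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.empty(len(y))
    fold_maes = []
    for tr, te in kf.split(X):
        model = clone(estimator).fit(X[tr], y[tr])
        p = model.predict(X[te])
        preds[te] = p
        fold_maes.append(float(np.mean(np.abs(p - y[te]))))
    return CVResult(float(np.mean(np.abs(preds - y))), fold_maes, preds)


def learning_curve(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    sizes: list[int],
    n_reps: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/test MAE vs dataset size, with 95% CIs over random subsamples.

    Per size and repetition a random subsample is drawn; the *train* MAE is
    computed on the whole dataset after fitting on the subsample (the
    study's convention for its train curve), the *test* MAE by
    cross-validation inside the subsample. CIs are mean ± 1.96·sd/√n_reps.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > len(y):
            raise ValueError(f"size {size} exceeds dataset ({len(y)})")
        tr_maes, te_maes = [], []
        for _ in range(n_reps):
            sub = rng.choice(len(y), size=size, replace=False)
            model = clone(estimator).fit(X[sub], y[sub])
            tr_maes.append(float(np.mean(np.abs(model.predict(X) - y))))
            k = min(cv_folds, size)
            te_maes.append(cross_validate(estimator, X[sub], y[sub], k=k, seed=int(rng.integers(2**31))).mae)
        tr, te = np.asarray(tr_maes), np.asarray(te_maes)
        half = lambda a: 1.96 * a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0
        rows.append((size, tr.mean(), half(tr), te.mean(), half(te)))
    return pd.DataFrame(
        rows, columns=["size", "train_mae", "train_ci95", "test_mae", "test_ci95"]
    )
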