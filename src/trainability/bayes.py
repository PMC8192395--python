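"""Bayesian linear regression of ∆V̇O₂max on baseline predictor panels.

A Gaussian linear model with weakly informative normal priors on the
coefficients and an inverse-gamma prior on the residual variance, reported
the ROPE+HDI way: posterior median, 89 % highest density interval, the
share of the posterior inside a standardized ROPE of ±0.01, an effect-size
label, and a split-chain convergence diagnostic.

Two backends target the *same* normal–inverse-gamma posterior:

* ``"gibbs"`` — blocked Gibbs MCMC (default 4 chains × 2000 iterations,
  warm-up 1000), matching the chain structure of the original analysis;
* ``"conjugate"`` — the analytic posterior with i.i.d. draws, whose exact
  posterior mean doubles as a deterministic oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Effect-size labels for standardized coefficients (Funder-style bands).
EFFECT_SIZE_BANDS = ((0.05, "tiny"), (0.10, "very small"), (0.20, "small"),
                     (0.30, "medium"), (0.40, "large"))
DEFAULT_ROPE = (-0.01, 0.01)


def label_effect_size(estimate: float, bands=EFFECT_SIZE_BANDS) -> str:
    """Label the magnitude of a standardized coefficient (sign ignored)."""
    mag = abs(float(estimate))
    for threshold, label in bands:
        if mag < threshold:
            return label
    return "very large"


def standardize(X: pd.DataFrame, y, mode: str = "zscore",
                condition_warn: float = 1e4):
    """Scale a design table and response for ROPE-interpretable coefficients.

    ``mode="zscore"`` (default) standardizes every predictor and the
    response to zero mean / unit SD.  ``mode="response"`` is the literal
    alternative of centring and scaling *everything* by the response's mean
    and SD.  Zero-variance predictors raise, naming the column; a large
    design condition number triggers a multicollinearity warning.

    Returns ``(Xs, ys, info)`` with the centres/scales needed to map
    coefficients back to the raw scale.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    for col in X.columns:
        if np.std(X[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"zero-variance predictor column: {col!r}")
    y_mean, y_sd = float(np.mean(y)), float(np.std(y, ddof=0))
    if y_sd == 0:
        raise ValueError("response has zero variance")
    if mode == "zscore":
        x_mean = X.mean(axis=0).to_numpy(dtype=float)
        x_sd = X.std(axis=0, ddof=0).to_numpy(dtype=float)
    elif mode == "response":
        x_mean = np.full(X.shape[1], y_mean)
        x_sd = np.full(X.shape[1], y_sd)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    Xs = (X.to_numpy(dtype=float) - x_mean) / x_sd
    ys = (y - y_mean) / y_sd
    cond = np.linalg.cond(np.column_stack([np.ones(len(ys)), Xs]))
    if cond > condition_warn:
        warnings.warn(f"design condition number {cond:.3g}: multicollinear predictors")
    info = {"x_mean": x_mean, "x_sd": x_sd, "y_mean": y_mean, "y_sd": y_sd,
            "columns": list(X.columns), "condition_number": float(cond)}
    return Xs, ys, info


def hdi_of_draws(draws, credibility: float = 0.89):
    """Narrowest interval containing ``credibility`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty draws")
    k = max(int(np.ceil(credibility * n)), 2)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential-scale-reduction diagnostic R̂.

    ``chains`` is (n_chains, n_draws); each chain is split in half before
    the between/within variance comparison.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2:
        raise ValueError("chains must be 2-D (chain, draw)")
    half = c.shape[1] // 2
    splits = np.concatenate([c[:, :half], c[:, half: 2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


@dataclass
class PosteriorSummary:
    """Per-coefficient ROPE+HDI summary of a fitted model."""

    table: pd.DataFrame      # name, estimate, hdi_lo, hdi_hi, pct_in_rope, label, rhat

    def __getitem__(self, name):
        return self.table.set_index("name").loc[name]


def summarize_rope_hdi(draws: np.ndarray, names=None, rope=DEFAULT_ROPE,
                       credibility: float = 0.89) -> PosteriorSummary:
    """ROPE+HDI summary of coefficient draws.

    ``draws`` is (n_chains, n_draws, p).  Per coefficient: posterior median,
    the ``credibility`` HDI, the share of all draws inside ``rope``, a
    significance call when the HDI excludes the ROPE, an effect-size label,
    and split-R̂.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[None, :, :]
    n_chains, n_draws, p = draws.shape
    if n_draws == 0:
        raise ValueError("empty posterior draws")
    names = names if names is not None else [f"b{j}" for j in range(p)]
    rlo, rhi = rope
    rows = []
    for j in range(p):
        flat = draws[:, :, j].ravel()
        est = float(np.median(flat))
        lo, hi = hdi_of_draws(flat, credibility)
        pct = 100.0 * float(np.mean((flat >= rlo) & (flat <= rhi)))
        rows.append({
            "name": names[j],
            "estimate": est,
            "hdi_lo": lo,
            "hdi_hi": hi,
            "pct_in_rope": pct,
            "significant": bool(lo > rhi or hi < rlo),
            "label": label_effect_size(est),
            "rhat": split_rhat(draws[:, :, j]) if n_chains > 1 else float("nan"),
        })
    return PosteriorSummary(table=pd.DataFrame(rows))


class BayesianLinearModel:
    """Bayesian Gaussian linear regression with a ROPE+HDI report.

    Model (on the standardized scale): y = α + Xβ + ε, ε ~ N(0, σ²);
    β | σ² ~ N(0, σ²·prior_scale²·I) (a wide prior on the intercept),
    σ² ~ Inv-Gamma(a₀, b₀).  ``backend="gibbs"`` runs blocked-Gibbs MCMC
    with ``chains`` seeded chains of ``iterations`` draws, discarding
    ``warmup``; ``backend="conjugate"`` draws i.i.d. from the analytic
    posterior and exposes the exact posterior mean in
    ``posterior_mean_exact_``.

    Fitted attributes: ``coef_draws_`` (chains, draws, p+1 incl. intercept),
    ``coef_`` (posterior medians, no intercept), ``intercept_``,
    ``sigma_draws_``, ``names_``, ``scaling_``.
    """

    def __init__(self, backend: str = "gibbs", chains: int = 4,
                 iterations: int = 2000, warmup: int = 1000,
                 prior_scale: float = 2.5, intercept_scale: float = 10.0,
                 sigma_prior=(2.0, 1.0), rope=DEFAULT_ROPE,
                 credibility: float = 0.89, standardize_mode: str = "zscore",
                 random_state: int | None = None):
        self.backend = backend
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.prior_scale = prior_scale
        self.intercept_scale = intercept_scale
        self.sigma_prior = sigma_prior
        self.rope = rope
        self.credibility = credibility
        self.standardize_mode = standardize_mode
        self.random_state = random_state

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "backend", "chains", "iterations", "warmup", "prior_scale",
            "intercept_scale", "sigma_prior", "rope", "credibility",
            "standardize_mode", "random_state")}

    def set_params(self, **params):
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- posterior algebra (shared by both backends) -----------------------

    def _posterior_blocks(self, X, y):
        n, p = X.shape
        A = np.column_stack([np.ones(n), X])              # intercept first
        d = np.concatenate([[1.0 / self.intercept_scale ** 2],
                            np.full(p, 1.0 / self.prior_scale ** 2)])
        prec = A.T @ A + np.diag(d)
        V = np.linalg.inv(prec)
        m = V @ (A.T @ y)
        a0, b0 = self.sigma_prior
        an = a0 + n / 2.0
        bn = b0 + 0.5 * float(y @ y - m @ prec @ m)
        return A, d, prec, V, m, an, bn

    def fit(self, X, y, names=None):
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        X = pd.DataFrame(X)
        names = names or list(X.columns)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if n <= X.shape[1] + 1:
            raise ValueError(f"need n > p + 1 observations (n={n}, p={X.shape[1]})")
        Xs, ys, info = standardize(X, y, mode=self.standardize_mode)
        self.names_ = [str(c) for c in names]
        self.scaling_ = info

        A, d, prec, V, m, an, bn = self._posterior_blocks(Xs, ys)
        self.posterior_mean_exact_ = m.copy()
        p1 = A.shape[1]
        n_keep = self.iterations - self.warmup
        ss = np.random.SeedSequence(self.random_state)
        child = ss.spawn(self.chains)
        draws = np.empty((self.chains, n_keep, p1))
        sigmas = np.empty((self.chains, n_keep))
        chol = np.linalg.cholesky(V)

        if self.backend == "conjugate":
            for c in range(self.chains):
                rng = np.random.default_rng(child[c])
                s2 = bn / rng.gamma(an, 1.0, n_keep)      # Inv-Gamma draws
                z = rng.standard_normal((n_keep, p1))
                draws[c] = m + np.sqrt(s2)[:, None] * (z @ chol.T)
                sigmas[c] = np.sqrt(s2)
        elif self.backend == "gibbs":
            a0, b0 = self.sigma_prior
            for c in range(self.chains):
                rng = np.random.default_rng(child[c])
                beta = m.copy()
                s2 = 1.0
                for it in range(self.iterations):
                    shape = a0 + (n + p1) / 2.0
                    resid = ys - A @ beta
                    rate = b0 + 0.5 * (resid @ resid + float(beta @ (d * beta)))
                    s2 = rate / rng.gamma(shape, 1.0)
                    beta = m + np.sqrt(s2) * (chol @ rng.standard_normal(p1))
                    if it >= self.warmup:
                        draws[c, it - self.warmup] = beta
                        sigmas[c, it - self.warmup] = np.sqrt(s2)
        else:
            raise ValueError(f"unknown backend {self.backend!r}")

        self.coef_draws_ = draws
        self.sigma_draws_ = sigmas
        med = np.median(draws.reshape(-1, p1), axis=0)
        self.intercept_ = float(med[0])
        self.coef_ = med[1:]

        rhats = [split_rhat(draws[:, :, j]) for j in range(p1)] if self.chains > 1 else []
        if rhats and max(rhats) > 1.01:
            warnings.warn(f"convergence diagnostic R-hat up to {max(rhats):.3f}; "
                          "inspect the chains", stacklevel=2)
        return self

    def predict(self, X):
        """Posterior-median prediction on the standardized response scale."""
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")
        info = self.scaling_
        Xs = (pd.DataFrame(X).to_numpy(dtype=float) - info["x_mean"]) / info["x_sd"]
        return self.intercept_ + Xs @ self.coef_

    def summary(self) -> PosteriorSummary:
        """ROPE+HDI coefficient table (intercept excluded)."""
        if not hasattr(self, "coef_draws_"):
            raise ValueError("model is not fitted")
        return summarize_rope_hdi(self.coef_draws_[:, :, 1:], names=self.names_,
                                  rope=self.rope, credibility=self.credibility)


def fit_predictor_panel(features: pd.DataFrame, response: str, predictors=None,
                        **model_kwargs) -> tuple[BayesianLinearModel, PosteriorSummary]:
    """Fit one predictor-domain panel and return (model, summary).

    ``features`` is a participant-level table (one row per participant);
    ``predictors`` defaults to every column except the response.
    """
    predictors = predictors or [c for c in features.columns if c != response]
    model = BayesianLinearModel(**model_kwargs)
    model.fit(features[predictors], features[response].to_numpy(), names=predictors)
    return model, model.summary()
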