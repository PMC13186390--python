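"""Likelihood evaluation and hierarchical Bayesian fitting.

Model structure
---------------
Every selection is a conditional-logit observation: in the softmax over
remaining items the class and stick/switch normalising constants cancel, so
the linear predictor of candidate ``j`` is

    eta_j = b_a*[c_j=A] + b_s*[c_j=c_prev] - rho_delta*delta_j
            + rho_psi*psi_j + sum_k theta_k*vM(phi_j)

which is linear in all parameters.  Per observer x condition the
log-likelihood is therefore concave with analytic gradient and Hessian.

The multilevel structure lets every parameter vary by condition and by
observer: core-parameter deviations (b_a, b_s, rho_delta, rho_psi across
both conditions) share a full covariance matrix, while direction-weight
deviations are independent.  Priors on the fixed effects are weakly
informative normals (b_a, b_s ~ N(0, 1.5); rho_delta ~ N(1, 0.25);
rho_psi ~ N(0, 1); theta ~ N(0, 1)); group-level SDs get Exponential(5)
priors and the correlation matrix an LKJ(2) prior.

Fitting
-------
The fit runs in two stages.  Stage one maximises each observer x condition
conditional-logit likelihood (convex; a very small ridge keeps rare
separable cases finite) and records the curvature, giving a Gaussian
summary ``beta_hat_i ~ N(beta_i, V_i)`` of each observer's evidence.  Stage
two works with the exact marginal that summary implies,
``beta_hat_i ~ N(mu, Sigma + V_i)``, whose hyperparameter posterior is
either maximised with a Laplace approximation (``backend="map"``, fast) or
sampled with an affine-invariant ensemble sampler run as four independent
chains with split-R-hat diagnostics (``backend="mcmc"``).  Both backends
return draws through the same :class:`Posterior` contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .model import (
    CoreParams,
    DataValidationError,
    DirectionParams,
    InvalidParameterError,
    ModelConfig,
    ModelVersion,
    Stimulus,
    build_model,
    feature_names,
    trial_feature_tensor,
)

__all__ = [
    "FitConfig",
    "Posterior",
    "build_model",
    "hpdi",
    "split_train_test",
    "trial_log_likelihood",
    "dataset_log_likelihood",
    "fit_hierarchical",
    "participant_params",
    "posterior_predict_next",
    "posterior_simulate_trials",
]

CORE_PRIOR_MEAN = {"b_a": 0.0, "b_s": 0.0, "rho_delta": 1.0, "rho_psi": 0.0}
CORE_PRIOR_SD = {"b_a": 1.5, "b_s": 1.5, "rho_delta": 0.25, "rho_psi": 1.0}


# ---------------------------------------------------------------------------
# HPDI
# ---------------------------------------------------------------------------

def hpdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing the requested posterior mass."""
    if not 0.0 < mass <= 1.0:
        raise InvalidParameterError(f"mass must be in (0, 1], got {mass}")
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    if n < 2:
        raise InvalidParameterError("hpdi needs at least two samples")
    k = int(np.ceil(mass * n))
    k = max(k, 2)
    widths = s[k - 1 :] - s[: n - k + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


# ---------------------------------------------------------------------------
# Trial data handling
# ---------------------------------------------------------------------------

def split_train_test(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First half of trials (by trial index, ceiling) to train, rest to test,
    per observer per condition."""
    train_idx = []
    test_idx = []
    for (obs, cond), g in trials.groupby(["observer", "condition"]):
        t = np.sort(g["trial"].unique())
        if len(t) < 2:
            warnings.warn(
                f"observer {obs}, condition {cond}: only one trial; "
                "assigned to train",
                stacklevel=2,
            )
            cut = len(t)
        else:
            cut = int(np.ceil(len(t) / 2))
        train_trials = set(t[:cut])
        mask = g["trial"].isin(train_trials)
        train_idx.extend(g.index[mask])
        test_idx.extend(g.index[~mask])
    return trials.loc[train_idx], trials.loc[test_idx]


def _trial_stimulus_order(trial_df: pd.DataFrame) -> tuple[Stimulus, list[int]]:
    stim = Stimulus.from_arrays(
        trial_df["x"].to_numpy(),
        trial_df["y"].to_numpy(),
        trial_df["item_class"].to_numpy(),
        ids=trial_df["item_id"].to_numpy(),
    )
    sel = trial_df[trial_df["order"] > 0].sort_values("order")
    order = sel["item_id"].astype(int).tolist()
    if not order:
        raise DataValidationError("trial contains no selections")
    expected = np.arange(1, len(order) + 1)
    if not np.array_equal(np.sort(sel["order"].to_numpy()), expected):
        raise DataValidationError("selection order must be 1..k without gaps")
    return stim, order


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _beta_from_params(
    cp: CoreParams, dp: DirectionParams | None, version: ModelVersion
) -> np.ndarray:
    beta = [cp.b_a, cp.b_s, cp.rho_delta]
    if version.include_rel_dir:
        beta.append(cp.rho_psi)
    if version.n_abs_directions:
        if dp is None:
            raise InvalidParameterError(
                f"version {version.id} needs direction parameters"
            )
        if dp.K != version.n_abs_directions:
            raise InvalidParameterError(
                f"version {version.id} expects {version.n_abs_directions} "
                f"direction components, got {dp.K}"
            )
        beta.extend(dp.theta)
    return np.asarray(beta, dtype=float)


def _params_from_beta(
    beta: np.ndarray, version: ModelVersion, kappa: float
) -> tuple[CoreParams, DirectionParams | None]:
    i = 3
    rho_psi = 0.0
    if version.include_rel_dir:
        rho_psi = beta[3]
        i = 4
    cp = CoreParams(beta[0], beta[1], beta[2], rho_psi)
    dp = None
    if version.n_abs_directions:
        dp = DirectionParams(
            theta=tuple(beta[i : i + version.n_abs_directions]), kappa=kappa
        )
    return cp, dp


def _step_log_probs(beta, X, mask, obs) -> np.ndarray:
    eta = X @ beta
    eta = np.where(mask, eta, -np.inf)
    lse = logsumexp(eta, axis=1)
    return eta[np.arange(len(obs)), obs] - lse


def trial_log_likelihood(
    cp: CoreParams,
    dp: DirectionParams | None,
    cfg: ModelConfig,
    stimulus: Stimulus,
    order,
) -> np.ndarray:
    """Per-selection log-probabilities of one observed trial.

    Entry ``i`` is ``log p(i-th selection | previous selections)``; the
    first entry comes from class weights alone.
    """
    version = cfg.flags
    X, mask, obs = trial_feature_tensor(
        stimulus, order, version, delta0=cfg.delta0, kappa=cfg.kappa
    )
    beta = _beta_from_params(cp, dp, version)
    return _step_log_probs(beta, X, mask, obs)


def dataset_log_likelihood(
    params: dict, trials: pd.DataFrame, cfg: ModelConfig
) -> pd.DataFrame:
    """Per-selection log-likelihood table over a dataset.

    ``params`` maps (observer, condition) to (CoreParams, DirectionParams
    or None).
    """
    rows = []
    for (obs_id, cond, trial), g in trials.groupby(
        ["observer", "condition", "trial"]
    ):
        stim, order = _trial_stimulus_order(g)
        cp, dp = params[(obs_id, cond)]
        ll = trial_log_likelihood(cp, dp, cfg, stim, order)
        for pos, (item, lp) in enumerate(zip(order, ll), start=1):
            rows.append(
                {
                    "observer": obs_id,
                    "condition": cond,
                    "trial": trial,
                    "order": pos,
                    "item_id": item,
                    "log_lik": lp,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage one: per observer x condition conditional-logit MLE
# ---------------------------------------------------------------------------

def _stack_trials(trial_tensors):
    """Stack (X, mask, obs) tuples from several trials, padding item counts."""
    n_max = max(x.shape[1] for x, _, _ in trial_tensors)
    p = trial_tensors[0][0].shape[2]
    Xs, masks, obss = [], [], []
    for X, mask, obs in trial_tensors:
        k, n, _ = X.shape
        if n < n_max:
            X = np.pad(X, ((0, 0), (0, n_max - n), (0, 0)))
            mask = np.pad(mask, ((0, 0), (0, n_max - n)))
        Xs.append(X)
        masks.append(mask)
        obss.append(obs)
    return np.concatenate(Xs), np.concatenate(masks), np.concatenate(obss)


def _logit_nll_grad(beta, X, mask, obs, ridge, ridge_center):
    eta = X @ beta
    eta = np.where(mask, eta, -np.inf)
    lse = logsumexp(eta, axis=1)
    ll = eta[np.arange(len(obs)), obs].sum() - lse.sum()
    probs = np.exp(eta - lse[:, None])
    probs[~mask] = 0.0
    x_obs = X[np.arange(len(obs)), obs]
    grad = x_obs.sum(axis=0) - np.einsum("tn,tnp->p", probs, X)
    dev = beta - ridge_center
    nll = -(ll - 0.5 * ridge * dev @ dev)
    return nll, -(grad - ridge * dev)


def _logit_firth_nll_grad(beta, X, mask, obs, ridge, ridge_center):
    """Conditional-logit objective with Jeffreys (Firth) penalty.

    The penalty +0.5*logdet I(beta) removes the O(1/n) away-from-zero bias
    of the maximum-likelihood estimates; its gradient involves the third
    central moments of the features under the model probabilities.
    """
    eta = X @ beta
    eta = np.where(mask, eta, -np.inf)
    lse = logsumexp(eta, axis=1)
    ll = eta[np.arange(len(obs)), obs].sum() - lse.sum()
    probs = np.exp(eta - lse[:, None])
    probs[~mask] = 0.0
    x_obs = X[np.arange(len(obs)), obs]
    mean_x = np.einsum("tn,tnp->tp", probs, X)
    grad_ll = x_obs.sum(axis=0) - mean_x.sum(axis=0)
    xc = X - mean_x[:, None, :]
    p = len(beta)
    flat_x = xc.reshape(-1, p)
    flat_w = (probs[:, :, None] * xc).reshape(-1, p)
    info = flat_w.T @ flat_x + ridge * np.eye(p)
    sign, logdet = np.linalg.slogdet(info)
    iinv = np.linalg.inv(info)
    # third central moments, contracted as matmuls for speed
    pair = (flat_x[:, :, None] * flat_x[:, None, :]).reshape(-1, p * p)
    m3 = (flat_w.T @ pair).reshape(p, p, p)
    grad_pen = 0.5 * np.einsum("pq,pqk->k", iinv, m3)
    dev = beta - ridge_center
    nll = -(ll + 0.5 * logdet - 0.5 * ridge * dev @ dev)
    grad = -(grad_ll + grad_pen - ridge * dev)
    return nll, grad


def _logit_hessian(beta, X, mask, obs, ridge):
    eta = X @ beta
    eta = np.where(mask, eta, -np.inf)
    lse = logsumexp(eta, axis=1)
    probs = np.exp(eta - lse[:, None])
    probs[~mask] = 0.0
    mean_x = np.einsum("tn,tnp->tp", probs, X)
    exx = np.einsum("tn,tnp,tnq->pq", probs, X, X)
    h = exx - np.einsum("tp,tq->pq", mean_x, mean_x)
    return h + ridge * np.eye(len(beta))


def _fit_observer_condition(tensors, prior_center, ridge=1e-2, firth=True):
    """Penalised conditional-logit point estimate and Laplace covariance.

    With ``firth`` the Jeffreys-penalised (bias-reduced) estimate is used;
    the covariance is the inverse observed information either way.
    """
    X, mask, obs = _stack_trials(tensors)
    objective = _logit_firth_nll_grad if firth else _logit_nll_grad
    res = minimize(
        objective,
        x0=prior_center.copy(),
        args=(X, mask, obs, ridge, prior_center),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    hess = _logit_hessian(res.x, X, mask, obs, ridge)
    cov = np.linalg.inv(hess + 1e-8 * np.eye(len(res.x)))
    return res.x, cov, bool(res.success)


# ---------------------------------------------------------------------------
# Correlation-matrix transform (Cholesky factor via canonical partial
# correlations, the standard unconstrained parameterisation)
# ---------------------------------------------------------------------------

def _chol_from_unconstrained(y: np.ndarray, dim: int):
    """Unconstrained vector -> Cholesky factor of a correlation matrix.

    Returns (L, log_jacobian, log_det_corr).
    """
    z = np.tanh(y)
    L = np.zeros((dim, dim))
    L[0, 0] = 1.0
    log_jac = float(np.sum(np.log1p(-z * z)))  # d tanh
    idx = 0
    for i in range(1, dim):
        norm2 = 0.0
        for j in range(i):
            w = z[idx]
            idx += 1
            scale2 = 1.0 - norm2
            L[i, j] = w * np.sqrt(scale2)
            log_jac += 0.5 * np.log(scale2)
            norm2 += L[i, j] ** 2
        L[i, i] = np.sqrt(max(1.0 - norm2, 1e-12))
    log_det_corr = 2.0 * float(np.sum(np.log(np.diag(L))))
    return L, log_jac, log_det_corr


def _sample_lkj_corr(dim: int, eta: float, rng) -> np.ndarray:
    """Draw a correlation matrix from the LKJ distribution (vine method)."""
    beta_par = eta + (dim - 2) / 2.0
    partials = np.zeros((dim, dim))
    corr = np.eye(dim)
    for k in range(dim - 1):
        beta_par -= 0.5
        for i in range(k + 1, dim):
            partials[k, i] = 2.0 * rng.beta(beta_par + 0.5, beta_par + 0.5) - 1.0
            p = partials[k, i]
            for l in range(k - 1, -1, -1):
                p = p * np.sqrt(
                    (1 - partials[l, i] ** 2) * (1 - partials[l, k] ** 2)
                ) + partials[l, i] * partials[l, k]
            corr[k, i] = corr[i, k] = p
    return corr


# ---------------------------------------------------------------------------
# Stage two: marginal hyperparameter posterior
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Configuration of the hierarchical fit.

    backend   "map" (penalised MAP with Laplace draws; fast, the default)
              or "mcmc" (ensemble sampler, 4 chains, split-R-hat checked).
    """

    backend: str = "map"
    n_draws: int = 1000
    seed: int = 0
    lkj_eta: float = 2.0
    theta_prior_sd: float = 1.0
    sd_prior_rate: float = 5.0
    stage1_ridge: float = 1e-2
    # Jeffreys-penalised (Firth) stage-one estimates: removes the O(1/n)
    # away-from-zero bias of per-observer maximum likelihood
    stage1_firth: bool = True
    # pool the stage-one curvature across observers (rescaled by each
    # observer's number of selection events).  Shrinkage weights then track
    # how much data an observer contributed rather than where their
    # parameters happen to sit, which removes a small-sample bias of
    # two-stage estimators (an observer with a strong stick or proximity
    # bias generates flatter likelihoods and would otherwise be
    # down-weighted, dragging the group mean toward weak-bias observers)
    pool_stage1_cov: bool = True
    mcmc_steps: int = 500
    mcmc_burn: int = 250
    n_chains: int = 4
    rhat_threshold: float = 1.01


class _HyperModel:
    """Packing/unpacking and log-posterior of the stage-two hyperparameters."""

    def __init__(self, version: ModelVersion, conditions, config: FitConfig):
        self.version = version
        self.conditions = list(conditions)
        self.config = config
        self.names = feature_names(version)
        self.p = len(self.names)
        self.core_names = [n for n in self.names if not n.startswith("theta")]
        self.n_core = len(self.core_names)
        self.k = version.n_abs_directions
        self.d = 2 * self.p  # stacked per-observer dimension
        self.n_z = (2 * self.n_core) * (2 * self.n_core - 1) // 2
        # index of core/theta positions inside the stacked vector
        self.core_pos = np.array(
            [c * self.p + i for c in range(2) for i in range(self.n_core)]
        )
        self.theta_pos = np.array(
            [c * self.p + self.n_core + k for c in range(2) for k in range(self.k)],
            dtype=int,
        )
        self.dim_psi = 2 * self.n_core + 2 * self.k + self.n_z

    # -- packing ----------------------------------------------------------
    # the sampled/optimised vector psi holds only the variance parameters:
    # (log sd_core, log sd_theta, unconstrained correlation); the fixed
    # effects mu are conjugate given psi and are integrated out analytically
    def unpack_psi(self, psi):
        nc2 = 2 * self.n_core
        nt2 = 2 * self.k
        log_sd_core = psi[:nc2]
        log_sd_theta = psi[nc2 : nc2 + nt2]
        z = psi[nc2 + nt2 :]
        return log_sd_core, log_sd_theta, z

    def sigma(self, log_sd_core, log_sd_theta, z):
        L, log_jac, log_det_corr = _chol_from_unconstrained(z, 2 * self.n_core)
        sd_core = np.exp(log_sd_core)
        corr = L @ L.T
        cov_core = np.outer(sd_core, sd_core) * corr
        sigma = np.zeros((self.d, self.d))
        sigma[np.ix_(self.core_pos, self.core_pos)] = cov_core
        if self.k:
            sd_theta = np.exp(log_sd_theta)
            sigma[self.theta_pos, self.theta_pos] = sd_theta**2
        return sigma, corr, log_jac, log_det_corr

    # -- priors -----------------------------------------------------------
    def prior_mean(self) -> np.ndarray:
        mu = np.zeros(self.d)
        for c in range(2):
            for i, name in enumerate(self.core_names):
                mu[c * self.p + i] = CORE_PRIOR_MEAN[name]
        return mu

    def prior_sd(self) -> np.ndarray:
        sd = np.full(self.d, self.config.theta_prior_sd)
        for c in range(2):
            for i, name in enumerate(self.core_names):
                sd[c * self.p + i] = CORE_PRIOR_SD[name]
        return sd

    def log_prior_psi(self, log_sd_core, log_sd_theta, log_jac, log_det_corr):
        rate = self.config.sd_prior_rate
        lp = 0.0
        for log_sd in (log_sd_core, log_sd_theta):
            if len(log_sd):
                # Exponential(rate) on the SD, with log-scale Jacobian
                lp += float(np.sum(-rate * np.exp(log_sd) + log_sd))
        lp += (self.config.lkj_eta - 1.0) * log_det_corr + log_jac
        return lp

    # -- marginal likelihood ----------------------------------------------
    def _mu_normal_equations(self, sigma, m, V):
        """Precision P and information vector b of the conjugate Gaussian
        posterior of mu given the variance parameters, plus the
        psi-dependent pieces of the integrated likelihood."""
        pm, ps = self.prior_mean(), self.prior_sd()
        P = np.diag(1.0 / ps**2)
        b = pm / ps**2
        loglik = 0.0
        total = sigma[None, :, :] + V
        chol = np.linalg.cholesky(total)  # raises LinAlgError if not PD
        eye = np.broadcast_to(np.eye(self.d), total.shape)
        inv = np.linalg.solve(total, eye)
        P = P + inv.sum(axis=0)
        b = b + np.einsum("nij,nj->i", inv, m)
        logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)))
        quad = float(np.einsum("ni,nij,nj->", m, inv, m))
        loglik = -0.5 * (logdet + quad)
        return P, b, loglik

    def log_marginal(self, psi, m, V):
        """Log posterior of psi with the fixed effects integrated out."""
        lsc, lst, z = self.unpack_psi(psi)
        if np.any(np.abs(psi) > 20):
            return -np.inf
        sigma, _, log_jac, log_det_corr = self.sigma(lsc, lst, z)
        lp = self.log_prior_psi(lsc, lst, log_jac, log_det_corr)
        if m is not None and len(m):
            try:
                P, b, loglik = self._mu_normal_equations(sigma, m, V)
            except np.linalg.LinAlgError:
                return -np.inf
            sign, logdet_p = np.linalg.slogdet(P)
            if sign <= 0:
                return -np.inf
            mu_hat = np.linalg.solve(P, b)
            lp += loglik - 0.5 * logdet_p + 0.5 * float(b @ mu_hat)
        if not np.isfinite(lp):
            return -np.inf
        return lp

    def mu_conditional(self, psi, m, V):
        """Exact Gaussian posterior of mu given psi: (mean, covariance)."""
        lsc, lst, z = self.unpack_psi(psi)
        sigma, _, _, _ = self.sigma(lsc, lst, z)
        P, b, _ = self._mu_normal_equations(sigma, m, V)
        cov = np.linalg.inv(P)
        cov = 0.5 * (cov + cov.T)
        return cov @ b, cov

    def initial_psi(self, m, V):
        psi = np.zeros(self.dim_psi)
        if m is not None and len(m) >= 3:
            # method-of-moments start: between-observer variance minus the
            # average measurement variance
            noise = np.mean(np.diagonal(V, axis1=1, axis2=2), axis=0)
            sd0 = np.sqrt(np.clip(m.var(axis=0, ddof=1) - noise, 0.01, 4.0))
        else:
            sd0 = np.full(self.d, 0.2)
        psi[: 2 * self.n_core] = np.log(sd0[self.core_pos])
        if self.k:
            psi[2 * self.n_core : 2 * self.n_core + 2 * self.k] = np.log(
                sd0[self.theta_pos]
            )
        return psi

    # -- naming -----------------------------------------------------------
    def draw_columns(self):
        cols = []
        for c, cond in enumerate(self.conditions):
            for name in self.names:
                cols.append(f"{name}[{cond}]")
        for c, cond in enumerate(self.conditions):
            for name in self.core_names:
                cols.append(f"sd_{name}[{cond}]")
        for c, cond in enumerate(self.conditions):
            for kk in range(self.k):
                cols.append(f"sd_theta_{kk + 1}[{cond}]")
        nc2 = 2 * self.n_core
        for i in range(nc2):
            for j in range(i):
                cols.append(f"corr[{i + 1},{j + 1}]")
        return cols

    def draws_to_named(
        self, mu_draws: np.ndarray, psi_draws: np.ndarray
    ) -> pd.DataFrame:
        out = np.empty((len(psi_draws), len(self.draw_columns())))
        for r, (mu, psi) in enumerate(zip(mu_draws, psi_draws)):
            lsc, lst, z = self.unpack_psi(psi)
            _, corr, _, _ = self.sigma(lsc, lst, z)
            vals = list(mu)
            vals += list(np.exp(lsc))
            vals += list(np.exp(lst))
            nc2 = 2 * self.n_core
            for i in range(nc2):
                for j in range(i):
                    vals.append(corr[i, j])
            out[r] = vals
        return pd.DataFrame(out, columns=self.draw_columns())


def _numeric_hessian(f, x, h=1e-4):
    n = len(x)
    hess = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        fpp = f(x + ei)
        fmm = f(x - ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / h**2
        for j in range(i):
            ej = np.zeros(n)
            ej[j] = h
            fpq = f(x + ei + ej)
            fmq = f(x - ei + ej)
            fpm = f(x + ei - ej)
            fm2 = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpq - fmq - fpm + fm2) / (4 * h**2)
    return hess


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class Posterior:
    """Posterior draws, summaries and everything needed for prediction."""

    draws: pd.DataFrame
    summary: pd.DataFrame
    diagnostics: dict
    participant: pd.DataFrame
    version: str
    conditions: list
    kappa: float
    delta0: float
    seed: int
    mu_hat: np.ndarray = None
    sigma_hat: np.ndarray = None
    stage1: dict = field(default_factory=dict)
    mu_draws: np.ndarray = None
    psi_draws: np.ndarray = None
    _model: object = None

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def config(self) -> ModelConfig:
        return ModelConfig(version=self.version, delta0=self.delta0, kappa=self.kappa)


def _summarise(draws: pd.DataFrame, diagnostics: dict) -> pd.DataFrame:
    rows = []
    for col in draws.columns:
        s = draws[col].to_numpy()
        lo, hi = hpdi(s, 0.95)
        rows.append(
            {
                "parameter": col,
                "mean": float(s.mean()),
                "sd": float(s.std(ddof=1)),
                "hpdi_2.5": lo,
                "hpdi_97.5": hi,
                "rhat": diagnostics.get("rhat", {}).get(col, float("nan")),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The fit
# ---------------------------------------------------------------------------

def _prepare_stage1(train, version, kappa, delta0, hm, config):
    """Per observer x condition penalised MLEs with Laplace covariances."""
    prior_center = np.array(
        [CORE_PRIOR_MEAN.get(n, 0.0) for n in hm.names], dtype=float
    )
    stage1 = {}
    ok = 0
    for (obs, cond), g in train.groupby(["observer", "condition"]):
        tensors = []
        n_events = 0
        for _, tdf in g.groupby("trial"):
            stim, order = _trial_stimulus_order(tdf)
            n_events += len(order)
            tensors.append(
                trial_feature_tensor(stim, order, version, delta0=delta0, kappa=kappa)
            )
        est, cov, success = _fit_observer_condition(
            tensors,
            prior_center,
            ridge=config.stage1_ridge,
            firth=config.stage1_firth,
        )
        stage1[(obs, cond)] = (est, cov, n_events)
        ok += success
    if config.pool_stage1_cov:
        by_cond: dict = {}
        for (obs, cond), (est, cov, n_ev) in stage1.items():
            by_cond.setdefault(cond, []).append(cov * n_ev)
        pooled = {
            cond: np.mean(np.stack(lst), axis=0) for cond, lst in by_cond.items()
        }
        stage1 = {
            (obs, cond): (est, pooled[cond] / n_ev, n_ev)
            for (obs, cond), (est, _, n_ev) in stage1.items()
        }
    return stage1, ok


def _stack_stage1(stage1, observers, conditions, p):
    d = 2 * p
    m = np.zeros((len(observers), d))
    V = np.zeros((len(observers), d, d))
    for i, obs in enumerate(observers):
        for c, cond in enumerate(conditions):
            est, cov = stage1[(obs, cond)][:2]
            sl = slice(c * p, (c + 1) * p)
            m[i, sl] = est
            V[i, sl, sl] = cov
    return m, V


def _prior_draws(hm: _HyperModel, config: FitConfig) -> pd.DataFrame:
    """Direct draws from the priors (prior-predictive mode for empty data)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_draws
    pm, ps = hm.prior_mean(), hm.prior_sd()
    mu_draws = pm + ps * rng.standard_normal((n, hm.d))
    names = hm.draw_columns()
    out = np.zeros((n, len(names)))
    out[:, : hm.d] = mu_draws
    nsd = 2 * hm.n_core + 2 * hm.k
    out[:, hm.d : hm.d + nsd] = rng.exponential(
        1.0 / config.sd_prior_rate, size=(n, nsd)
    )
    nc2 = 2 * hm.n_core
    corr_cols = []
    for r in range(n):
        corr = _sample_lkj_corr(nc2, config.lkj_eta, rng)
        corr_cols.append([corr[i, j] for i in range(nc2) for j in range(i)])
    out[:, hm.d + nsd :] = np.asarray(corr_cols)
    return pd.DataFrame(out, columns=names)


def fit_hierarchical(
    train: pd.DataFrame,
    version: str | ModelVersion = "v1.3",
    fit_config: FitConfig | None = None,
    kappa: float = 20.0,
    delta0: float = 20.0,
) -> Posterior:
    """Fit the multilevel model to a long-format training table.

    With an empty training table the fit returns draws from the priors
    (prior-predictive mode).  Reproducible under ``fit_config.seed``.
    """
    config = fit_config or FitConfig()
    if isinstance(version, str):
        version = build_model(version)
    if train is None or len(train) == 0:
        hm = _HyperModel(version, ("condition_1", "condition_2"), config)
        draws = _prior_draws(hm, config)
        diagnostics = {"backend": "prior", "converged": True}
        return Posterior(
            draws=draws,
            summary=_summarise(draws, diagnostics),
            diagnostics=diagnostics,
            participant=pd.DataFrame(),
            version=version.id,
            conditions=list(hm.conditions),
            kappa=kappa,
            delta0=delta0,
            seed=config.seed,
            _model=hm,
        )

    conditions = list(pd.unique(train["condition"]))
    if len(conditions) != 2:
        raise DataValidationError(
            f"expected exactly two conditions, found {conditions}"
        )
    hm = _HyperModel(version, conditions, config)
    stage1, n_ok = _prepare_stage1(train, version, kappa, delta0, hm, config)
    observers = sorted(train["observer"].unique())
    m, V = _stack_stage1(stage1, observers, conditions, hm.p)

    neg = lambda psi: -hm.log_marginal(psi, m, V)
    x0 = hm.initial_psi(m, V)
    res = minimize(neg, x0, method="L-BFGS-B", options={"maxiter": 1000})
    psi_hat = res.x
    rng = np.random.default_rng(config.seed)

    diagnostics = {
        "backend": config.backend,
        "stage1_converged": int(n_ok),
        "stage1_total": len(stage1),
        "map_success": bool(res.success),
    }

    if config.backend == "map":
        hess = _numeric_hessian(neg, psi_hat, h=1e-4)
        # symmetrise and regularise before inverting
        hess = 0.5 * (hess + hess.T)
        w, Q = np.linalg.eigh(hess)
        w = np.clip(w, 1e-6, None)
        cov = (Q / w) @ Q.T
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
        psis = psi_hat + rng.standard_normal((config.n_draws, hm.dim_psi)) @ chol.T
        diagnostics["converged"] = bool(res.success)
    elif config.backend == "mcmc":
        import emcee

        nwalkers = max(2 * hm.dim_psi + 2, 64)
        chains = []
        for c in range(config.n_chains):
            crng = np.random.default_rng(config.seed + 1000 * (c + 1))
            p0 = psi_hat + 0.01 * crng.standard_normal((nwalkers, hm.dim_psi))
            sampler = emcee.EnsembleSampler(
                nwalkers,
                hm.dim_psi,
                hm.log_marginal,
                args=(m, V),
            )
            sampler.random_state = np.random.RandomState(
                config.seed + 1000 * (c + 1)
            ).get_state()
            sampler.run_mcmc(p0, config.mcmc_steps, progress=False)
            flat = sampler.get_chain(discard=config.mcmc_burn, flat=True)
            chains.append(flat)
        import arviz as az

        # R-hat on the variance parameters, walkers pooled within chains
        # (the fixed effects are drawn exactly from their conjugate
        # conditional, so their mixing is governed by these)
        stacked = np.stack(chains, axis=0)
        rhat_vals = az.rhat(az.convert_to_dataset(stacked))
        rhat_arr = np.asarray(rhat_vals["x"])
        names = hm.draw_columns()[hm.d : hm.d + hm.dim_psi]
        diagnostics["rhat"] = dict(zip(names, [float(r) for r in rhat_arr]))
        diagnostics["converged"] = bool(
            np.all(rhat_arr < config.rhat_threshold)
        )
        allpsi = np.concatenate(chains, axis=0)
        take = rng.choice(len(allpsi), size=config.n_draws, replace=False)
        psis = allpsi[take]
    else:
        raise InvalidParameterError(f"unknown backend {config.backend!r}")

    if not diagnostics["converged"]:
        warnings.warn(
            "hierarchical fit did not satisfy its convergence criteria; "
            "inspect Posterior.diagnostics",
            stacklevel=2,
        )

    # exact conjugate draw of the fixed effects for every psi draw
    mus = np.empty((len(psis), hm.d))
    for r, psi in enumerate(psis):
        mean, cov_mu = hm.mu_conditional(psi, m, V)
        mus[r] = rng.multivariate_normal(mean, cov_mu)

    draws = hm.draws_to_named(mus, psis)
    mu_hat, _ = hm.mu_conditional(psi_hat, m, V)
    lsc, lst, z = hm.unpack_psi(psi_hat)
    sigma_hat, _, _, _ = hm.sigma(lsc, lst, z)

    # conditional (shrunken) per-participant point estimates at the mode
    part_rows = []
    for i, obs in enumerate(observers):
        total = sigma_hat + V[i]
        gain = sigma_hat @ np.linalg.inv(total)
        b = mu_hat + gain @ (m[i] - mu_hat)
        for c, cond in enumerate(conditions):
            row = {"observer": obs, "condition": cond}
            for j, name in enumerate(hm.names):
                row[name] = b[c * hm.p + j]
            part_rows.append(row)

    return Posterior(
        draws=draws,
        summary=_summarise(draws, diagnostics),
        diagnostics=diagnostics,
        participant=pd.DataFrame(part_rows),
        version=version.id,
        conditions=conditions,
        kappa=kappa,
        delta0=delta0,
        seed=config.seed,
        mu_hat=mu_hat,
        sigma_hat=sigma_hat,
        stage1={k: v for k, v in stage1.items()},
        mu_draws=mus,
        psi_draws=psis,
        _model=hm,
    )


# ---------------------------------------------------------------------------
# Prediction from a fitted posterior
# ---------------------------------------------------------------------------

def participant_params(posterior: Posterior) -> dict:
    """(observer, condition) -> (CoreParams, DirectionParams | None) at the
    shrunken posterior point estimates."""
    version = build_model(posterior.version)
    out = {}
    for _, row in posterior.participant.iterrows():
        beta = np.array([row[n] for n in feature_names(version)])
        out[(row["observer"], row["condition"])] = _params_from_beta(
            beta, version, posterior.kappa
        )
    return out


def _participant_beta_draws(posterior: Posterior, n_draws: int, rng) -> dict:
    """Per-observer parameter draws from the conditional normal given a
    random hyperparameter draw each time."""
    hm = posterior._model
    version = build_model(posterior.version)
    observers = sorted({k[0] for k in posterior.stage1})
    m, V = _stack_stage1(
        posterior.stage1, observers, posterior.conditions, hm.p
    )
    picks = rng.choice(len(posterior.psi_draws), size=n_draws)
    out = {obs: np.zeros((n_draws, hm.d)) for obs in observers}
    for d_i, pick in enumerate(picks):
        mu = posterior.mu_draws[pick]
        lsc, lst, z = hm.unpack_psi(posterior.psi_draws[pick])
        sigma, _, _, _ = hm.sigma(lsc, lst, z)
        for i, obs in enumerate(observers):
            total = sigma + V[i]
            gain = sigma @ np.linalg.inv(total)
            cond_mean = mu + gain @ (m[i] - mu)
            cond_cov = sigma - gain @ sigma
            cond_cov = 0.5 * (cond_cov + cond_cov.T) + 1e-10 * np.eye(hm.d)
            out[obs][d_i] = rng.multivariate_normal(cond_mean, cond_cov)
    return out


def posterior_predict_next(
    posterior: Posterior,
    trials: pd.DataFrame,
    n_draws: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Item-wise predictions (P): for each observed selection at position
    >= 2, draw the model's guess of the next item under each posterior
    parameter draw."""
    from .model import SelectionState, selection_probabilities

    rng = np.random.default_rng(seed)
    cfg = posterior.config()
    version = cfg.flags
    beta_draws = _participant_beta_draws(posterior, n_draws, rng)
    hm = posterior._model
    rows = []
    for (obs, cond, trial), g in trials.groupby(["observer", "condition", "trial"]):
        stim, order = _trial_stimulus_order(g)
        c = posterior.conditions.index(cond)
        sl = slice(c * hm.p, (c + 1) * hm.p)
        X, mask, obs_idx = trial_feature_tensor(
            stim, order, version, delta0=cfg.delta0, kappa=cfg.kappa
        )
        for d_i in range(n_draws):
            beta = beta_draws[obs][d_i, sl]
            eta = X @ beta
            eta = np.where(mask, eta, -np.inf)
            probs = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
            for pos in range(1, len(order)):
                pick = rng.choice(stim.n_items, p=probs[pos])
                rows.append(
                    {
                        "draw": d_i,
                        "observer": obs,
                        "condition": cond,
                        "trial": trial,
                        "order": pos + 1,
                        "predicted_id": int(stim.ids[pick]),
                    }
                )
    return pd.DataFrame(rows)


def posterior_simulate_trials(
    posterior: Posterior,
    trials: pd.DataFrame,
    n_draws: int = 10,
    fix_first: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Whole-trial simulations (Q, or F when ``fix_first``) on the stimuli
    of the supplied trials, one replicate per posterior draw."""
    from .simulate import simulate_trial

    rng = np.random.default_rng(seed)
    cfg = posterior.config()
    version = cfg.flags
    beta_draws = _participant_beta_draws(posterior, n_draws, rng)
    hm = posterior._model
    records = []
    for (obs, cond, trial), g in trials.groupby(["observer", "condition", "trial"]):
        stim, order = _trial_stimulus_order(g)
        c = posterior.conditions.index(cond)
        sl = slice(c * hm.p, (c + 1) * hm.p)
        first = order[0] if fix_first else None
        for d_i in range(n_draws):
            beta = beta_draws[obs][d_i, sl]
            cp, dp = _params_from_beta(beta, version, posterior.kappa)
            sim_order = simulate_trial(
                cp, dp, cfg, stim, fix_first=first,
                n_select=len(order), seed=rng,
            )
            rank = {item: r + 1 for r, item in enumerate(sim_order)}
            for idx, item_id in enumerate(stim.ids):
                records.append(
                    (
                        d_i,
                        obs,
                        cond,
                        trial,
                        rank.get(int(item_id), 0),
                        int(item_id),
                        stim.xy[idx, 0],
                        stim.xy[idx, 1],
                        stim.classes[idx],
                    )
                )
    return pd.DataFrame(
        records,
        columns=[
            "draw",
            "observer",
            "condition",
            "trial",
            "order",
            "item_id",
            "x",
            "y",
            "item_class",
        ],
    )
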