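"""Finite-mixture latent class model for mixed indicators.

The model: each patient belongs to one of K latent classes with weights
pi_k. Given the class, indicators are locally independent; a categorical
indicator j follows a class-conditional multinomial theta_jkc, a continuous
indicator a normal with class mean mu_jk and variance sigma2_j (pooled
across classes by default, class-specific on request). Missing entries are
simply skipped in the likelihood (ignorable missingness; no imputation).

Estimation is by EM from a seed-determined random initialisation, with a
probability floor on multinomial cells and a variance floor to guard
against degenerate solutions. Classes are relabelled in descending weight
before a fit is returned, which breaks label switching across restarts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .codebook import Codebook
from .dataset import Dataset, Encoded
from .errors import (
    ClassCollapseError,
    ConvergenceWarning,
    DataValidationError,
    DimensionMismatchError,
)

PROB_FLOOR = 1e-6
VAR_FLOOR_FRAC = 1e-6
_LOG_CLIP = 1e-12


@dataclass
class LCAModel:
    """Mixture parameters for a mixed-indicator latent class model."""

    codebook: Codebook
    K: int
    pi: np.ndarray  # (K,)
    cat_probs: dict[str, np.ndarray]  # name -> (K, C_j), rows sum to 1
    cont_means: dict[str, np.ndarray]  # name -> (K,)
    cont_vars: dict[str, np.ndarray]  # name -> (K,), all > 0
    variance_mode: str = "pooled"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (self.K,):
            raise DimensionMismatchError("pi must have length K")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise DimensionMismatchError("pi must be a probability vector")
        for v in self.codebook.categorical:
            tab = np.asarray(self.cat_probs[v.name], dtype=float)
            if tab.shape != (self.K, v.n_levels):
                raise DimensionMismatchError(
                    f"{v.name}: conditional table must be K x C"
                )
            if np.any(tab < 0) or np.max(np.abs(tab.sum(axis=1) - 1.0)) > 1e-9:
                raise DimensionMismatchError(f"{v.name}: rows must sum to 1")
            self.cat_probs[v.name] = tab
        for v in self.codebook.continuous:
            mu = np.asarray(self.cont_means[v.name], dtype=float)
            var = np.asarray(self.cont_vars[v.name], dtype=float)
            if mu.shape != (self.K,) or var.shape != (self.K,):
                raise DimensionMismatchError(f"{v.name}: means/variances must have length K")
            if np.any(var <= 0):
                raise DimensionMismatchError(f"{v.name}: variances must be positive")
            self.cont_means[v.name] = mu
            self.cont_vars[v.name] = var

    def permuted(self, order: np.ndarray) -> "LCAModel":
        """Return the model with classes reordered by ``order``."""
        order = np.asarray(order)
        return LCAModel(
            codebook=self.codebook,
            K=self.K,
            pi=self.pi[order],
            cat_probs={k: v[order] for k, v in self.cat_probs.items()},
            cont_means={k: v[order] for k, v in self.cont_means.items()},
            cont_vars={k: v[order] for k, v in self.cont_vars.items()},
            variance_mode=self.variance_mode,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format parameter table (variable, class, category, value)."""
        rows = []
        for k in range(self.K):
            rows.append(("_class_weight", k + 1, "", self.pi[k]))
        for v in self.codebook.categorical:
            tab = self.cat_probs[v.name]
            for k in range(self.K):
                for c, lv in enumerate(v.levels):
                    rows.append((v.name, k + 1, str(lv), tab[k, c]))
        for v in self.codebook.continuous:
            for k in range(self.K):
                rows.append((v.name, k + 1, "mean", self.cont_means[v.name][k]))
                rows.append((v.name, k + 1, "variance", self.cont_vars[v.name][k]))
        return pd.DataFrame(rows, columns=["variable", "class", "category", "value"])


@dataclass
class FitResult:
    """A fitted model with its likelihood, BIC, posteriors and assignments."""

    model: LCAModel
    loglik: float
    n_params: int
    n_obs: int
    bic: float
    posteriors: np.ndarray  # (n, K), rows sum to 1
    assignments: np.ndarray  # (n,), 1-based modal classes
    converged: bool
    n_iter: int
    seed: int
    loglik_history: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.model.K

    def class_shares(self) -> np.ndarray:
        """Modal-assignment share of the cohort per class (1..K)."""
        counts = np.bincount(self.assignments - 1, minlength=self.K)
        return counts / self.n_obs

    def metadata(self) -> dict:
        return {
            "K": self.K,
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "n_params": int(self.n_params),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "seed": int(self.seed),
        }


# ---------------------------------------------------------------------------
# likelihood machinery


def _check_aligned(model: LCAModel, data: Dataset) -> Encoded:
    if model.codebook.names != data.codebook.names:
        raise DimensionMismatchError(
            "model and dataset codebooks declare different variables"
        )
    for v in model.codebook.categorical:
        if v.levels != data.codebook[v.name].levels:
            raise DimensionMismatchError(f"{v.name}: level sets differ")
    return data.encode()


def _log_density(model: LCAModel, enc: Encoded) -> np.ndarray:
    """(n, K) matrix of per-row class-conditional log densities.

    Missing entries contribute zero. Probabilities are floored before the
    log so any model respecting the invariants yields finite values.
    """
    n = enc.n
    logf = np.zeros((n, model.K))
    for j, name in enumerate(enc.cat_names):
        logtab = np.log(np.maximum(model.cat_probs[name], _LOG_CLIP))  # (K, C)
        codes = enc.cat_codes[:, j]
        obs = codes >= 0
        safe = np.where(obs, codes, 0)
        contrib = logtab[:, safe].T  # (n, K)
        contrib[~obs] = 0.0
        logf += contrib
    for j, name in enumerate(enc.cont_names):
        y = enc.cont[:, j]
        obs = ~np.isnan(y)
        mu = model.cont_means[name]  # (K,)
        var = model.cont_vars[name]
        ysafe = np.where(obs, y, 0.0)
        contrib = -0.5 * (
            np.log(2 * np.pi * var)[None, :]
            + (ysafe[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        contrib[~obs] = 0.0
        logf += contrib
    return logf


def loglikelihood(model: LCAModel, data: Dataset) -> float:
    """Total log-likelihood of ``data`` under ``model``.

    Per-row contribution is ``log sum_k pi_k prod_{j observed} f_j(y_ij|k)``;
    missing entries are skipped.
    """
    enc = _check_aligned(model, data)
    logjoint = _log_density(model, enc) + np.log(np.maximum(model.pi, _LOG_CLIP))
    return float(logsumexp(logjoint, axis=1).sum())


def e_step(model: LCAModel, data: Dataset) -> np.ndarray:
    """Posterior class membership probabilities, one row per patient."""
    post, _ = _posteriors_and_loglik(model, _check_aligned(model, data))
    return post


def _posteriors_and_loglik(model: LCAModel, enc: Encoded) -> tuple[np.ndarray, float]:
    logjoint = _log_density(model, enc) + np.log(np.maximum(model.pi, _LOG_CLIP))
    bad = ~np.isfinite(logjoint).any(axis=1)
    if bad.any():
        raise DataValidationError(
            f"row(s) {np.flatnonzero(bad)[:5].tolist()} have no finite class density"
        )
    norm = logsumexp(logjoint, axis=1)
    post = np.exp(logjoint - norm[:, None])
    post /= post.sum(axis=1, keepdims=True)
    return post, float(norm.sum())


def m_step(posteriors: np.ndarray, data: Dataset, codebook: Codebook,
           variance_mode: str = "pooled") -> LCAModel:
    """Weighted maximum-likelihood update of all mixture parameters.

    Raises :class:`ClassCollapseError` when a class retains essentially no
    posterior weight rather than silently renormalising it.
    """
    if variance_mode not in ("pooled", "class_specific"):
        raise ValueError("variance_mode must be 'pooled' or 'class_specific'")
    post = np.asarray(posteriors, dtype=float)
    n, K = post.shape
    if np.max(np.abs(post.sum(axis=1) - 1.0)) > 1e-6:
        raise DataValidationError("posterior rows must sum to 1")
    enc = data.encode()
    if enc.n != n:
        raise DimensionMismatchError("posterior rows do not match dataset rows")

    weight = post.sum(axis=0)
    if np.any(weight < 1e-6):
        k = int(np.argmin(weight))
        raise ClassCollapseError(
            f"class {k + 1} collapsed (total weight {weight[k]:.2e}); restart advised"
        )
    pi = weight / n

    cat_probs: dict[str, np.ndarray] = {}
    for j, name in enumerate(enc.cat_names):
        C = enc.cat_sizes[j]
        codes = enc.cat_codes[:, j]
        obs = codes >= 0
        counts = np.zeros((K, C))
        w = post[obs]
        c_obs = codes[obs]
        for c in range(C):
            sel = c_obs == c
            if sel.any():
                counts[:, c] = w[sel].sum(axis=0)
        totals = counts.sum(axis=1, keepdims=True)
        # class never observed on this variable: fall back to uniform
        empty = totals[:, 0] <= 0
        counts[empty] = 1.0
        totals = counts.sum(axis=1, keepdims=True)
        tab = counts / totals
        tab = np.maximum(tab, PROB_FLOOR)
        tab /= tab.sum(axis=1, keepdims=True)
        cat_probs[name] = tab

    cont_means: dict[str, np.ndarray] = {}
    cont_vars: dict[str, np.ndarray] = {}
    for j, name in enumerate(enc.cont_names):
        y = enc.cont[:, j]
        obs = ~np.isnan(y)
        yo = y[obs]
        w = post[obs]  # (n_obs, K)
        sw = w.sum(axis=0)
        overall_mean = float(yo.mean()) if yo.size else 0.0
        sample_var = float(yo.var()) if yo.size else 1.0
        floor = max(VAR_FLOOR_FRAC * max(sample_var, 1e-12), 1e-12)
        mu = np.where(sw > 1e-12, (w * yo[:, None]).sum(axis=0) / np.maximum(sw, 1e-12),
                      overall_mean)
        sq = (yo[:, None] - mu[None, :]) ** 2
        if variance_mode == "pooled":
            var = float((w * sq).sum() / max(sw.sum(), 1e-12))
            var = np.full(K, max(var, floor))
        else:
            var = (w * sq).sum(axis=0) / np.maximum(sw, 1e-12)
            var = np.maximum(var, floor)
        cont_means[name] = mu
        cont_vars[name] = var

    return LCAModel(codebook=codebook, K=K, pi=pi, cat_probs=cat_probs,
                    cont_means=cont_means, cont_vars=cont_vars,
                    variance_mode=variance_mode)


# ---------------------------------------------------------------------------
# free-standing statistics


def n_parameters(codebook: Codebook, K: int, variance_mode: str = "pooled") -> int:
    """Free-parameter count: (K-1) class weights, K(C_j - 1) per categorical
    variable, K means plus one (pooled) or K (class-specific) variances per
    continuous variable."""
    if len(codebook) == 0:
        raise DimensionMismatchError("codebook with zero variables is invalid")
    if K < 1:
        raise ValueError("K must be >= 1")
    p = K - 1
    for v in codebook.categorical:
        p += K * (v.n_levels - 1)
    for v in codebook.continuous:
        p += 2 * K if variance_mode == "class_specific" else K + 1
    return p


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion: -2*loglik + n_params*ln(n_obs).

    Lower is better; the penalty balances model fit against parsimony.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik + n_params * math.log(n_obs)


def modal_assign(posteriors: np.ndarray) -> np.ndarray:
    """1-based class of the largest posterior per row; ties break toward
    the lowest class index."""
    post = np.asarray(posteriors, dtype=float)
    return np.argmax(post, axis=1) + 1


# ---------------------------------------------------------------------------
# EM driver


def fit_em(data: Dataset, codebook: Codebook, K: int, seed: int = 0,
           tol: float = 1e-8, max_iter: int = 1000,
           variance_mode: str = "pooled") -> FitResult:
    """Fit a K-class model by EM from a seeded random initialisation.

    Initial responsibilities are drawn per row from a symmetric Dirichlet(1)
    and turned into parameters by one M-step. Iteration stops when the
    relative log-likelihood change falls below ``tol`` or after ``max_iter``
    iterations (then ``converged=False`` with a warning). The returned
    model has classes sorted by descending weight.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > data.n:
        raise ValueError(f"K={K} exceeds the number of rows ({data.n})")
    if codebook.names != data.codebook.names:
        raise DimensionMismatchError("codebook does not match dataset")
    enc = data.encode()

    rng = np.random.default_rng(seed)
    post = rng.dirichlet(np.ones(K), size=data.n)
    model = m_step(post, data, codebook, variance_mode)

    prev = -np.inf
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        post, ll = _posteriors_and_loglik(model, enc)
        history.append(ll)
        if ll < prev - 1e-8:
            warnings.warn(
                f"log-likelihood decreased by {prev - ll:.3e} at iteration {n_iter}",
                ConvergenceWarning,
            )
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll
        model = m_step(post, data, codebook, variance_mode)
    else:
        # loop exhausted: model stems from the last M-step, refresh posteriors
        post, ll = _posteriors_and_loglik(model, enc)
        history.append(ll)
        n_iter = max_iter

    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations (K={K}, seed={seed})",
            ConvergenceWarning,
        )

    order = np.argsort(-model.pi, kind="stable")
    model = model.permuted(order)
    post = post[:, order]
    post /= post.sum(axis=1, keepdims=True)

    p = n_parameters(codebook, K, variance_mode)
    return FitResult(
        model=model,
        loglik=ll,
        n_params=p,
        n_obs=data.n,
        bic=bic(ll, p, data.n),
        posteriors=post,
        assignments=modal_assign(post),
        converged=converged,
        n_iter=n_iter,
        seed=seed,
        loglik_history=history,
    )
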