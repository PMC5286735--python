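"""Model generation and starting-model selection.

For each class count K the model is refit from several random seeds and one
fit is retained by a *BIC consistency* rule: restart BICs are rounded to two
decimals and tallied; when one rounded value recurs more often than any
other (multiplicity >= 2) the restarts agreeing on it are taken to have
found the same optimum and the best of them is retained — deliberately even
when a lone restart reports a lower BIC. Otherwise (all values distinct, or
a tie in maximal multiplicity) the minimum-BIC fit is retained.

Across class counts, the *starting model* is the last K on the walk
K=2,3,... for which the retained BIC keeps decreasing by at least 1% per
added class, capped at the global BIC argmin. Choosing a larger preferred
model is a human judgement and is left to the caller.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import contingency

from .codebook import Codebook
from .dataset import Dataset, _is_missing
from .errors import ClassCollapseError, LcasubError
from .model import FitResult, fit_em

logger = logging.getLogger(__name__)


@dataclass
class RestartSet:
    """All restarts for one class count, with the retained fit."""

    K: int
    fits: list[FitResult]
    bic_values: list[float]
    chosen: int
    rule: str  # 'consistency' or 'min_bic'
    seeds: list[int]
    data_fingerprint: str
    all_nonconverged: bool = False

    @property
    def retained(self) -> FitResult:
        return self.fits[self.chosen]


@dataclass
class SearchResult:
    """Retained fits for K = 1..K_max plus the starting-model designation."""

    per_K: dict[int, RestartSet]
    starting_K: int
    bic_table: dict[int, float]
    preferred_K: int | None = None
    errors: dict[int, str] = field(default_factory=dict)

    def retained(self, K: int) -> FitResult:
        return self.per_K[K].retained

    def bic_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"K": list(self.bic_table), "bic": list(self.bic_table.values())}
        )


def _choose_restart(fits: list[FitResult]) -> tuple[int, str]:
    """Index of the retained fit and which rule branch applied."""
    bics = [f.bic for f in fits]
    rounded = [round(b, 2) for b in bics]
    tally = Counter(rounded)
    top = tally.most_common()
    max_mult = top[0][1]
    modal_values = [v for v, m in tally.items() if m == max_mult]
    if max_mult >= 2 and len(modal_values) == 1:
        value = modal_values[0]
        candidates = [i for i, r in enumerate(rounded) if r == value]
        best = max(candidates, key=lambda i: (fits[i].loglik, -i))
        return best, "consistency"
    return int(np.argmin(bics)), "min_bic"


def fit_with_restarts(data: Dataset, codebook: Codebook, K: int,
                      n_restarts: int = 10, base_seed: int = 0,
                      tol: float = 1e-8, max_iter: int = 1000,
                      variance_mode: str = "pooled") -> RestartSet:
    """Refit K classes from ``n_restarts`` seeds (base_seed + index) and
    retain one fit by the BIC consistency rule."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    fits: list[FitResult] = []
    seeds: list[int] = []
    for r in range(n_restarts):
        seed = base_seed + r
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_em(data, codebook, K, seed=seed, tol=tol,
                             max_iter=max_iter, variance_mode=variance_mode)
        except ClassCollapseError as exc:
            logger.warning("K=%d seed=%d: %s", K, seed, exc)
            continue
        fits.append(fit)
        seeds.append(seed)
    if not fits:
        raise LcasubError(f"all {n_restarts} restarts collapsed at K={K}")
    chosen, rule = _choose_restart(fits)
    all_nonconverged = not any(f.converged for f in fits)
    if all_nonconverged:
        warnings.warn(f"no restart converged at K={K}", UserWarning)
    return RestartSet(
        K=K,
        fits=fits,
        bic_values=[f.bic for f in fits],
        chosen=chosen,
        rule=rule,
        seeds=seeds,
        data_fingerprint=data.fingerprint(),
        all_nonconverged=all_nonconverged,
    )


def select_starting_model(bic_table: dict[int, float]) -> int:
    """The lowest-BIC model reached while BIC keeps dropping by >= 1% per
    added class; capped at the global BIC argmin.

    The walk starts at K=1 and continues to K+1 while
    ``BIC(K+1) <= BIC(K) - 0.01*|BIC(K)|``; it returns 1 if the very first
    step already fails.
    """
    if not bic_table:
        raise ValueError("empty BIC table")
    ks = sorted(bic_table)
    if ks[0] != 1 or ks != list(range(1, ks[-1] + 1)):
        raise ValueError("BIC table must cover consecutive K starting at 1")
    k = 1
    while k + 1 in bic_table and bic_table[k + 1] <= bic_table[k] - 0.01 * abs(bic_table[k]):
        k += 1
    argmin = min(ks, key=lambda kk: (bic_table[kk], kk))
    return min(k, argmin)


def run_search(data: Dataset, codebook: Codebook, K_max: int = 12,
               base_seed: int = 0, n_restarts: int = 10,
               tol: float = 1e-8, max_iter: int = 1000,
               variance_mode: str = "pooled") -> SearchResult:
    """Retain one fit per K=1..K_max and designate the starting model.

    A failure at one K is logged and recorded without aborting the other
    class counts; the starting-model walk then uses the consecutive prefix
    of successful K. ``preferred_K`` is left unset — promoting a larger
    model is part of the human consensus process.
    """
    per_K: dict[int, RestartSet] = {}
    errors: dict[int, str] = {}
    for K in range(1, K_max + 1):
        try:
            per_K[K] = fit_with_restarts(
                data, codebook, K, n_restarts=n_restarts,
                base_seed=base_seed + 1000 * (K - 1), tol=tol,
                max_iter=max_iter, variance_mode=variance_mode)
        except LcasubError as exc:
            logger.error("search failed at K=%d: %s", K, exc)
            errors[K] = str(exc)
    bic_table = {K: rs.retained.bic for K, rs in per_K.items()}
    prefix = {}
    for K in range(1, K_max + 1):
        if K not in bic_table:
            break
        prefix[K] = bic_table[K]
    starting_K = select_starting_model(prefix) if prefix else 1
    return SearchResult(per_K=per_K, starting_K=starting_K,
                        bic_table=bic_table, errors=errors)


def loadings(fit: FitResult, data: Dataset) -> pd.DataFrame:
    """Association between each variable and modal class membership.

    Cramér's V for nominal variables; the correlation ratio (eta) for
    ordinal (equidistant integer scores) and continuous variables. All
    values lie in [0, 1]; a constant variable scores 0 with a warning.
    """
    if fit.n_obs != data.n:
        raise ValueError("fit and data have different numbers of rows")
    classes = fit.assignments
    rows = []
    for v in data.codebook:
        col = data.df[v.name]
        obs = ~col.map(_is_missing)
        if v.kind == "nominal":
            vals = col[obs]
            if vals.nunique() <= 1 or len(np.unique(classes[obs.to_numpy()])) <= 1:
                warnings.warn(f"{v.name}: constant variable, association set to 0")
                assoc = 0.0
            else:
                table = pd.crosstab(vals, classes[obs.to_numpy()])
                assoc = float(contingency.association(table.to_numpy(), method="cramer"))
            method = "cramers_v"
        else:
            if v.is_categorical:
                scores = {lv: i for i, lv in enumerate(v.levels)}
                y = col[obs].map(scores).to_numpy(dtype=float)
            else:
                y = col[obs].to_numpy(dtype=float)
            g = classes[obs.to_numpy()]
            if y.size == 0 or np.allclose(y, y[0]):
                warnings.warn(f"{v.name}: constant variable, association set to 0")
                assoc = 0.0
            else:
                grand = y.mean()
                ss_total = float(((y - grand) ** 2).sum())
                ss_between = 0.0
                for k in np.unique(g):
                    yk = y[g == k]
                    ss_between += len(yk) * (yk.mean() - grand) ** 2
                assoc = float(np.sqrt(ss_between / ss_total)) if ss_total > 0 else 0.0
            method = "correlation_ratio"
        rows.append((v.name, v.kind, method, min(max(assoc, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["variable", "kind", "method", "association"])
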