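"""Two-stage latent class pipeline.

Stage one fits a separate LCA within each health domain and assigns every
patient to the domain category with their largest posterior (hard, modal
assignment — the certainty of that assignment is deliberately *not*
carried forward, which is the information-loss trade-off of the design).
Stage two runs an ordinary class-count search on the resulting dataset of
one nominal variable per domain, all categorical, with far fewer
parameters than a single-stage model on the raw variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .codebook import Codebook, VariableSpec
from .dataset import Dataset
from .errors import CodebookError
from .model import FitResult
from .search import SearchResult, fit_with_restarts, run_search

logger = logging.getLogger(__name__)

#: First-stage category counts of the published six-domain template.
TEMPLATE_DOMAIN_KS = {
    "activity": 7,
    "contextual": 7,
    "pain": 7,
    "participation": 7,
    "physical_impairment": 6,
    "psychology": 8,
}


@dataclass
class DomainMembership:
    """Per-patient modal domain categories with assignment posteriors."""

    categories: pd.DataFrame  # patients x domains, 1-based category indices
    posteriors: pd.DataFrame  # patients x domains, posterior of the assigned category
    domain_Ks: dict[str, int]
    prevalences: dict[str, np.ndarray]  # domain -> category share (sums to 1)

    @property
    def domains(self) -> list[str]:
        return list(self.categories.columns)


@dataclass
class TwoStageResult:
    first_stage: dict[str, FitResult]
    first_stage_searches: dict[str, SearchResult]
    membership: DomainMembership
    second_stage: SearchResult
    second_stage_data: Dataset
    second_stage_codebook: Codebook


def fit_first_stage(data: Dataset, codebook: Codebook,
                    domain_Ks: Mapping[str, int] | str = "search",
                    base_seed: int = 0, n_restarts: int = 10,
                    K_max: int = 12, tol: float = 1e-8,
                    max_iter: int = 1000,
                    ) -> tuple[dict[str, FitResult], dict[str, SearchResult], DomainMembership]:
    """One LCA per domain, then modal category assignment.

    ``domain_Ks`` maps each domain to a fixed class count, or is the string
    ``'search'`` to run the full class-count search per domain and use its
    starting model.
    """
    partition = codebook.domain_partition
    domains = [d for d in partition if partition[d]]
    if not domains:
        raise CodebookError("codebook declares no domains")
    fits: dict[str, FitResult] = {}
    searches: dict[str, SearchResult] = {}
    cats: dict[str, np.ndarray] = {}
    posts: dict[str, np.ndarray] = {}
    for i, domain in enumerate(domains):
        sub = data.select(partition[domain])
        seed = base_seed + 100_000 * i
        if domain_Ks == "search":
            sr = run_search(sub, sub.codebook, K_max=K_max, base_seed=seed,
                            n_restarts=n_restarts, tol=tol, max_iter=max_iter)
            searches[domain] = sr
            fit = sr.retained(sr.starting_K)
        else:
            K = int(domain_Ks[domain])
            rs = fit_with_restarts(sub, sub.codebook, K, n_restarts=n_restarts,
                                   base_seed=seed, tol=tol, max_iter=max_iter)
            fit = rs.retained
        fits[domain] = fit
        cats[domain] = fit.assignments
        posts[domain] = fit.posteriors[np.arange(sub.n), fit.assignments - 1]
    index = data.row_ids
    membership = DomainMembership(
        categories=pd.DataFrame(cats, index=index),
        posteriors=pd.DataFrame(posts, index=index),
        domain_Ks={d: fits[d].K for d in domains},
        prevalences={
            d: np.bincount(cats[d] - 1, minlength=fits[d].K) / data.n for d in domains
        },
    )
    return fits, searches, membership


def build_second_stage_dataset(membership: DomainMembership) -> tuple[Dataset, Codebook]:
    """One nominal variable per domain holding the assigned category index.

    All declared categories are retained as levels even when never
    assigned (logged), and the derived dataset has no missing values.
    """
    specs = []
    for domain in membership.domains:
        K = membership.domain_Ks[domain]
        levels = tuple(range(1, K + 1))
        assigned = set(membership.categories[domain])
        empty = sorted(set(levels) - assigned)
        if empty:
            logger.info("domain %s: categories %s never assigned; levels retained",
                        domain, empty)
        specs.append(VariableSpec(name=f"{domain}_category", kind="nominal",
                                  domain=domain, levels=levels,
                                  severity_direction="none"))
    cb = Codebook(tuple(specs))
    df = membership.categories.rename(
        columns={d: f"{d}_category" for d in membership.domains})
    return Dataset(df, cb), cb


def run_two_stage(data: Dataset, codebook: Codebook,
                  domain_Ks: Mapping[str, int] | str = "search",
                  K_max: int = 12, base_seed: int = 0, n_restarts: int = 10,
                  tol: float = 1e-8, max_iter: int = 1000) -> TwoStageResult:
    """First-stage per-domain fits, derived categorical dataset, then a
    class-count search on it."""
    fits, searches, membership = fit_first_stage(
        data, codebook, domain_Ks=domain_Ks, base_seed=base_seed,
        n_restarts=n_restarts, K_max=K_max, tol=tol, max_iter=max_iter)
    ds2, cb2 = build_second_stage_dataset(membership)
    second = run_search(ds2, cb2, K_max=K_max, base_seed=base_seed + 10_000_000,
                        n_restarts=n_restarts, tol=tol, max_iter=max_iter)
    return TwoStageResult(first_stage=fits, first_stage_searches=searches,
                          membership=membership, second_stage=second,
                          second_stage_data=ds2, second_stage_codebook=cb2)
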