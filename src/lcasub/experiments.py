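"""Repeatable simulation studies over seeded synthetic cohorts.

These drive both the test suite's recovery checks and the acceptance
script. Problem sizes follow the compact six-domain design of
:func:`lcasub.simulate.compact_cohort_spec` (24 variables, identity
coupling, n = 1000, separation 0.85, 5% MCAR missingness) with a light
EM budget (5 restarts — a scaled-down version of the 10 used for real
searches — and tolerance 1e-7) so that a 20-seed study runs in minutes
on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .diagnostics import posterior_summary
from .model import fit_em
from .search import fit_with_restarts
from .simulate import CohortSpec, compact_cohort_spec, generate_cohort, with_seed
from .two_stage import run_two_stage

_TOL = 1e-7
_RESTARTS = 5


def match_classes(assignments: np.ndarray, truth: np.ndarray,
                  K: int) -> np.ndarray:
    """Permutation mapping fitted class k (1..K) to the true class that
    maximises total agreement (Hungarian on the confusion matrix)."""
    confusion = np.zeros((K, K))
    np.add.at(confusion, (assignments - 1, truth - 1), 1)
    rows, cols = linear_sum_assignment(-confusion)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm


@dataclass
class RecoveryStudy:
    n_seeds: int
    successes: int
    details: list

    @property
    def rate(self) -> float:
        return self.successes / self.n_seeds


def _spec(base: CohortSpec | None, seed: int) -> CohortSpec:
    spec = base if base is not None else compact_cohort_spec()
    return with_seed(spec, seed)


def pi_recovery_study(n_seeds: int = 20, base_seed: int = 0,
                      spec: CohortSpec | None = None,
                      tolerance: float = 0.05) -> RecoveryStudy:
    """Refit the planted class count per seed and check every mixing
    weight against the truth within ``tolerance`` after optimal label
    matching."""
    successes, details = 0, []
    for s in range(n_seeds):
        cohort_spec = _spec(spec, base_seed + s)
        data, codebook, truth = generate_cohort(cohort_spec)
        G = cohort_spec.n_classes
        rs = fit_with_restarts(data, codebook, G, n_restarts=_RESTARTS,
                               base_seed=base_seed + 777 * s, tol=_TOL)
        fit = rs.retained
        perm = match_classes(fit.assignments, truth.classes, G)
        true_pi = np.bincount(truth.classes - 1, minlength=G) / data.n
        err = float(np.max(np.abs(fit.model.pi - true_pi[perm])))
        ari = adjusted_rand_score(truth.classes, perm[fit.assignments - 1])
        ok = err <= tolerance
        successes += ok
        details.append({"seed": cohort_spec.seed, "max_pi_error": err,
                        "ari": float(ari), "ok": bool(ok)})
    return RecoveryStudy(n_seeds, successes, details)


def class_count_recovery_study(n_seeds: int = 20, base_seed: int = 0,
                               spec: CohortSpec | None = None,
                               K_range: range = range(1, 7)) -> RecoveryStudy:
    """Per seed, fit every K in ``K_range`` and check that BIC is
    minimised at the planted class count."""
    successes, details = 0, []
    for s in range(n_seeds):
        cohort_spec = _spec(spec, base_seed + s)
        data, codebook, truth = generate_cohort(cohort_spec)
        bics = {}
        for K in K_range:
            rs = fit_with_restarts(data, codebook, K, n_restarts=_RESTARTS,
                                   base_seed=base_seed + 777 * s + 31 * K,
                                   tol=_TOL)
            bics[K] = rs.retained.bic
        argmin = min(bics, key=bics.get)
        ok = argmin == cohort_spec.n_classes
        successes += ok
        details.append({"seed": cohort_spec.seed, "bic_argmin": argmin,
                        "ok": bool(ok)})
    return RecoveryStudy(n_seeds, successes, details)


@dataclass
class TwoStageStudy:
    n_seeds: int
    count_successes: int
    single_stage_medians: list[float]
    second_stage_medians: list[float]
    details: list

    @property
    def count_recovery_rate(self) -> float:
        return self.count_successes / self.n_seeds

    @property
    def certainty_ordered(self) -> bool:
        """True when every seed has second-stage median maximum posterior
        at most the single-stage median on the same cohort."""
        return all(t <= s + 1e-12 for s, t in
                   zip(self.single_stage_medians, self.second_stage_medians))


def two_stage_study(n_seeds: int = 20, base_seed: int = 0,
                    spec: CohortSpec | None = None,
                    K_range: range = range(1, 7)) -> TwoStageStudy:
    """Identity-coupled cohorts through the full two-stage pipeline.

    Per seed: (i) does the second-stage BIC over ``K_range`` recover the
    planted global class count, and (ii) how does the second-stage
    posterior certainty (median maximum posterior at the planted K)
    compare with a single-stage fit on the raw variables.
    """
    successes, details = 0, []
    ss_medians, ts_medians = [], []
    for s in range(n_seeds):
        cohort_spec = _spec(spec, base_seed + s)
        data, codebook, truth = generate_cohort(cohort_spec)
        G = cohort_spec.n_classes
        domain_Ks = {d.name: d.n_categories for d in cohort_spec.domains}
        result = run_two_stage(data, codebook, domain_Ks=domain_Ks,
                               K_max=max(K_range), base_seed=base_seed + 777 * s,
                               n_restarts=_RESTARTS, tol=_TOL)
        bics = {K: result.second_stage.bic_table[K] for K in K_range
                if K in result.second_stage.bic_table}
        argmin = min(bics, key=bics.get)
        ok = argmin == G
        successes += ok
        single = fit_em(data, codebook, G, seed=base_seed + 777 * s, tol=_TOL)
        ss_median = posterior_summary(single.posteriors).median_max_posterior
        ts_fit = result.second_stage.retained(G)
        ts_median = posterior_summary(ts_fit.posteriors).median_max_posterior
        ss_medians.append(ss_median)
        ts_medians.append(ts_median)
        details.append({"seed": cohort_spec.seed, "bic_argmin": argmin,
                        "ok": bool(ok), "single_median": ss_median,
                        "second_median": ts_median})
    return TwoStageStudy(n_seeds, successes, ss_medians, ts_medians, details)
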