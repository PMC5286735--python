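"""Synthetic cohorts with planted latent structure.

The generator emulates the design of a multi-domain low back pain cohort:
six health domains (activity, contextual factors, pain, participation,
physical impairment, psychology), ~112 mixed-type indicators, and row-wise
missingness such that at least 95% of rows are more than 86% complete.

The planted truth has two layers. Each patient carries a *global class*
(mixing weights ``weights``); each domain then derives a *domain category*
from the global class through a configurable coupling:

- ``identity``: category equals the global class (requires the domain's
  category count to equal the number of global classes) — the data are
  then an exact locally-independent latent class model;
- ``noisy``: the category distribution is a delta-weighted mixture of a
  point mass at the class-preferred category and a uniform over all
  categories;
- ``independent``: categories ignore the global class (a null regime).

Indicators are drawn conditional on the domain category. Categorical
probabilities interpolate between a shared uniform marginal and a
category-specific point mass: ``theta(delta) = (1-delta)*marginal +
delta*extreme``. Continuous indicators are normal with delta-scaled mean
offsets and common spread. Missingness is MCAR cell-by-cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codebook import Codebook, VariableSpec
from .dataset import Dataset
from .errors import LcasubError

DOMAIN_ORDER = ("activity", "contextual", "pain", "participation",
                "physical_impairment", "psychology")

#: Published first-stage category counts per domain.
TEMPLATE_CATEGORY_COUNTS = {
    "activity": 7, "contextual": 7, "pain": 7, "participation": 7,
    "physical_impairment": 6, "psychology": 8,
}


@dataclass(frozen=True)
class DomainSpec:
    """One health domain: its variables (kind + size) and planted categories.

    ``variables`` is a list of ``('nominal'|'ordinal', n_levels)`` or
    ``('continuous', (lo, hi))`` entries.
    """

    name: str
    n_categories: int
    variables: tuple = ()

    def __post_init__(self):
        if self.n_categories < 1:
            raise LcasubError(f"domain {self.name}: n_categories must be >= 1")
        for kind, size in self.variables:
            if kind in ("nominal", "ordinal"):
                if int(size) < 2:
                    raise LcasubError(f"domain {self.name}: level counts must be >= 2")
            elif kind == "continuous":
                lo, hi = size
                if not lo < hi:
                    raise LcasubError(f"domain {self.name}: bad continuous range")
            else:
                raise LcasubError(f"domain {self.name}: unknown kind {kind!r}")

    @property
    def n_variables(self) -> int:
        return len(self.variables)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort."""

    n: int = 928
    domains: tuple[DomainSpec, ...] = ()
    n_classes: int = 3
    weights: tuple[float, ...] | None = None  # None = equal
    separation: float = 0.8  # delta in [0, 1]
    coupling: str = "noisy"  # 'identity' | 'noisy' | 'independent'
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.separation <= 1.0:
            raise LcasubError("separation must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise LcasubError("missing_rate must lie in [0, 1)")
        if self.n < self.n_classes:
            raise LcasubError("n must be >= number of planted classes")
        if self.coupling not in ("identity", "noisy", "independent"):
            raise LcasubError(f"unknown coupling {self.coupling!r}")
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            if len(w) != self.n_classes:
                raise LcasubError("weights must have one entry per class")
            if any(x <= 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
                raise LcasubError("weights must be positive and sum to 1")
            object.__setattr__(self, "weights", w)
        if self.coupling == "identity":
            for d in self.domains:
                if d.n_categories != self.n_classes:
                    raise LcasubError(
                        "identity coupling requires every domain's category "
                        "count to equal the number of global classes"
                    )

    @property
    def class_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.weights)

    @property
    def n_variables(self) -> int:
        return sum(d.n_variables for d in self.domains)


@dataclass
class SyntheticTruth:
    """Planted structure behind a generated cohort."""

    classes: np.ndarray  # (n,), 1-based global class
    domain_categories: pd.DataFrame  # patients x domains, 1-based
    category_probs: dict[str, np.ndarray]  # domain -> (G, m_d) coupling table
    variable_params: dict[str, dict]  # name -> generator parameters
    spec: CohortSpec


def _binary(n: int) -> list:
    return [("nominal", 2)] * n


def default_cohort_spec(n: int = 928, seed: int = 0) -> CohortSpec:
    """The default study-scale template: six domains, 112 mixed-type
    variables apportioned to mirror a questionnaire inventory, planted
    category counts (7, 7, 7, 7, 6, 8), and MCAR missingness leaving at
    least 95% of rows more than 86% complete."""
    domains = (
        # activity limitation items plus a few graded scales
        DomainSpec("activity", 7, tuple(_binary(20) + [("ordinal", 6)] * 3)),
        # personal/contextual factors: demographics, work, comorbidity
        DomainSpec("contextual", 7, tuple(
            [("nominal", 2), ("nominal", 2), ("nominal", 3), ("nominal", 4),
             ("nominal", 5), ("nominal", 8)]
            + [("continuous", (18.0, 65.0)), ("continuous", (140.0, 210.0)),
               ("continuous", (15.0, 50.0))]
            + _binary(3))),
        # pain history and intensity
        DomainSpec("pain", 7, tuple(
            [("ordinal", 11), ("ordinal", 11), ("nominal", 3), ("nominal", 3),
             ("nominal", 4), ("nominal", 2)] + _binary(4))),
        # work and social participation
        DomainSpec("participation", 7, tuple(
            _binary(6) + [("ordinal", 11)] * 4 + [("nominal", 3)] * 2)),
        # clinical examination findings
        DomainSpec("physical_impairment", 6, tuple(
            _binary(24) + [("nominal", 3)] * 6)),
        # depression, fear-avoidance, beliefs, sleep
        DomainSpec("psychology", 8, tuple(
            [("ordinal", 4)] * 15 + _binary(8) + [("ordinal", 11)] * 2)),
    )
    return CohortSpec(n=n, domains=domains, n_classes=3, separation=0.8,
                      coupling="noisy", missing_rate=0.05, seed=seed)


def compact_cohort_spec(n: int = 1000, n_classes: int = 3,
                        separation: float = 0.85, coupling: str = "identity",
                        missing_rate: float = 0.05, seed: int = 0,
                        n_categories: int | None = None) -> CohortSpec:
    """A reduced six-domain design (4 variables per domain, 24 in total)
    used for simulation studies where many cohorts must be generated and
    refit. Planted categories per domain default to the number of global
    classes so that identity coupling yields an exact latent class model."""
    m = n_categories if n_categories is not None else n_classes
    variables = tuple(_binary(2) + [("nominal", 3), ("ordinal", 4)])
    domains = tuple(DomainSpec(name, m, variables) for name in DOMAIN_ORDER)
    return CohortSpec(n=n, domains=domains, n_classes=n_classes,
                      separation=separation, coupling=coupling,
                      missing_rate=missing_rate, seed=seed)


def _build_codebook(spec: CohortSpec) -> Codebook:
    specs = []
    for d in spec.domains:
        for idx, (kind, size) in enumerate(d.variables, start=1):
            name = f"{d.name[:4]}_{kind[:4]}_{idx:02d}"
            if kind == "continuous":
                lo, hi = size
                specs.append(VariableSpec(name=name, kind="continuous",
                                          domain=d.name, range=(lo, hi),
                                          severity_direction="higher_worse"))
            else:
                levels = tuple(range(int(size)))
                specs.append(VariableSpec(
                    name=name, kind=kind, domain=d.name, levels=levels,
                    severity_direction="higher_worse",
                    severe_level=levels[-1] if kind == "nominal" else None))
    return Codebook(tuple(specs))


def _coupling_table(spec: CohortSpec, domain: DomainSpec) -> np.ndarray:
    """(G, m) table P(category | class) for one domain."""
    G, m = spec.n_classes, domain.n_categories
    table = np.full((G, m), 1.0 / m)
    if spec.coupling == "independent":
        return table
    strength = 1.0 if spec.coupling == "identity" else spec.separation
    out = (1.0 - strength) * table
    for g in range(G):
        out[g, g % m] += strength
    return out


def generate_cohort(spec: CohortSpec) -> tuple[Dataset, Codebook, SyntheticTruth]:
    """Draw a full cohort from ``spec``; reproducible under ``spec.seed``."""
    if not spec.domains:
        raise LcasubError("cohort spec declares no domains")
    rng = np.random.default_rng(spec.seed)
    codebook = _build_codebook(spec)
    n, G, delta = spec.n, spec.n_classes, spec.separation

    classes = rng.choice(G, size=n, p=spec.class_weights) + 1

    columns: dict[str, np.ndarray] = {}
    cat_probs: dict[str, np.ndarray] = {}
    var_params: dict[str, dict] = {}
    domain_cats: dict[str, np.ndarray] = {}
    for d in spec.domains:
        table = _coupling_table(spec, d)
        cat_probs[d.name] = table
        # vectorised draw of the domain category given the class
        u = rng.random(n)
        cum = np.cumsum(table, axis=1)
        cats = (u[:, None] > cum[classes - 1]).sum(axis=1)  # 0-based
        domain_cats[d.name] = cats + 1
        for idx, (kind, size) in enumerate(d.variables, start=1):
            name = f"{d.name[:4]}_{kind[:4]}_{idx:02d}"
            if kind == "continuous":
                lo, hi = size
                center = (lo + hi) / 2.0
                half = (hi - lo) / 2.0
                sd = 0.15 * (hi - lo)
                z = (np.linspace(-1.0, 1.0, d.n_categories)
                     if d.n_categories > 1 else np.zeros(1))
                means = center + delta * 0.6 * half * z
                y = rng.normal(means[cats], sd)
                columns[name] = np.clip(y, lo, hi)
                var_params[name] = {"kind": kind, "means": means, "sd": sd}
            else:
                C = int(size)
                theta = np.full((d.n_categories, C), (1.0 - delta) / C)
                for c in range(d.n_categories):
                    theta[c, (c + idx) % C] += delta
                u = rng.random(n)
                cum = np.cumsum(theta, axis=1)
                draw = (u[:, None] > cum[cats]).sum(axis=1)
                columns[name] = draw
                var_params[name] = {"kind": kind, "theta": theta}

    df = pd.DataFrame(columns)
    # object dtype so masked cells can hold None alongside ints
    for v in codebook.categorical:
        df[v.name] = df[v.name].astype(object)
    data = Dataset(df, codebook)
    if spec.missing_rate > 0:
        data = inject_missing(data, spec.missing_rate, seed=spec.seed + 1)
    truth = SyntheticTruth(
        classes=classes,
        domain_categories=pd.DataFrame(domain_cats, index=data.row_ids),
        category_probs=cat_probs,
        variable_params=var_params,
        spec=spec,
    )
    return data, codebook, truth


def inject_missing(data: Dataset, rate: float, seed: int = 0) -> Dataset:
    """Mask each cell independently with probability ``rate`` (MCAR).

    Row masks that would leave a patient entirely missing are redrawn, so
    the result still satisfies the no-all-missing-rows invariant.
    """
    if not 0.0 <= rate < 1.0:
        raise LcasubError("rate must lie in [0, 1)")
    if rate == 0.0:
        return data
    rng = np.random.default_rng(seed)
    n, p = data.n, len(data.variables)
    mask = rng.random((n, p)) < rate
    for i in np.flatnonzero(mask.all(axis=1)):
        row = rng.random(p) < rate
        while row.all():
            row = rng.random(p) < rate
        mask[i] = row
    df = data.df.copy()
    arr = df.to_numpy(dtype=object)
    arr[mask] = None
    out = pd.DataFrame(arr, index=df.index, columns=df.columns)
    for v in data.codebook.continuous:
        out[v.name] = out[v.name].astype(float)
    return Dataset(out, data.codebook)


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    return replace(spec, seed=seed)
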