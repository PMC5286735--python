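"""Variable declarations and codebooks.

A :class:`VariableSpec` declares one indicator: its measurement kind
(nominal, ordinal or continuous), the health domain it belongs to, its
level set or range, the direction in which severity increases, and an
optional recode map applied when raw data are read.

A :class:`Codebook` is an ordered collection of variable specs together
with the induced partition of variables into health domains. Codebooks are
round-trippable through a YAML document.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .errors import CodebookError

KINDS = ("nominal", "ordinal", "continuous")
DOMAINS = (
    "activity",
    "contextual",
    "pain",
    "participation",
    "physical_impairment",
    "psychology",
    "other",
)
SEVERITY_DIRECTIONS = ("higher_worse", "lower_worse", "none")


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single indicator variable.

    Parameters
    ----------
    name : str
        Unique variable identifier.
    kind : {'nominal', 'ordinal', 'continuous'}
        Measurement kind. Ordinal variables carry an ordered level set and
        are modelled as unordered multinomials; the ordering is used only in
        summaries (conditional means, profile normalisation).
    domain : str
        Health domain (one of six study domains, or ``'other'``).
    levels : tuple, optional
        Ordered category codes; required for nominal/ordinal.
    range : (float, float), optional
        Bounds for continuous (and optionally ordinal) variables.
    severity_direction : {'higher_worse', 'lower_worse', 'none'}
        Direction in which values indicate a more severe condition.
    recode_map : mapping, optional
        Raw value -> analysis value, applied while reading data. Targets
        must be valid analysis values (declared levels for categoricals).
    severe_level : optional
        For nominal variables without a numeric scoring: the level whose
        class-conditional probability is plotted on severity profiles.
    """

    name: str
    kind: str
    domain: str = "other"
    levels: tuple | None = None
    range: tuple[float, float] | None = None
    severity_direction: str = "none"
    recode_map: Mapping[Any, Any] | None = None
    severe_level: Any = None

    def __post_init__(self) -> None:
        if not self.name:
            raise CodebookError("variable name must be non-empty")
        if self.kind not in KINDS:
            raise CodebookError(f"{self.name}: unknown kind {self.kind!r}")
        if self.domain not in DOMAINS:
            raise CodebookError(f"{self.name}: unknown domain {self.domain!r}")
        if self.severity_direction not in SEVERITY_DIRECTIONS:
            raise CodebookError(
                f"{self.name}: unknown severity_direction {self.severity_direction!r}"
            )
        if self.is_categorical:
            if not self.levels:
                raise CodebookError(f"{self.name}: {self.kind} variable needs levels")
            object.__setattr__(self, "levels", tuple(self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise CodebookError(f"{self.name}: duplicate levels")
        else:
            if self.levels is not None:
                raise CodebookError(f"{self.name}: continuous variable must not declare levels")
        if self.range is not None:
            lo, hi = self.range
            if not float(lo) < float(hi):
                raise CodebookError(f"{self.name}: range min must be < max")
            object.__setattr__(self, "range", (float(lo), float(hi)))
        if self.recode_map is not None:
            targets = set(self.recode_map.values())
            if self.is_categorical and not targets <= set(self.levels):
                raise CodebookError(
                    f"{self.name}: recode targets {targets - set(self.levels)} "
                    "are not declared levels"
                )

    @property
    def is_categorical(self) -> bool:
        return self.kind in ("nominal", "ordinal")

    @property
    def n_levels(self) -> int:
        if not self.is_categorical:
            raise CodebookError(f"{self.name}: continuous variable has no levels")
        return len(self.levels)


@dataclass(frozen=True)
class PoolingRule:
    """Declarative pooling of several source variables into one.

    ``how='any'`` produces a binary variable that is 1 when any observed
    source equals 1 (e.g. side-specific provocation tests pooled into one
    per-test variable), missing only when every source is missing.
    """

    name: str
    sources: tuple[str, ...]
    how: str = "any"
    domain: str | None = None

    def __post_init__(self) -> None:
        if self.how != "any":
            raise CodebookError(f"pooling {self.name}: unsupported rule {self.how!r}")
        if len(self.sources) < 2:
            raise CodebookError(f"pooling {self.name}: needs at least two sources")
        object.__setattr__(self, "sources", tuple(self.sources))


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of variable specs with a domain partition."""

    variables: tuple[VariableSpec, ...]
    poolings: tuple[PoolingRule, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "poolings", tuple(self.poolings))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CodebookError(f"duplicate variable names: {dupes}")
        known = set(names)
        for rule in self.poolings:
            missing = set(rule.sources) - known
            if missing:
                raise CodebookError(f"pooling {rule.name}: unknown sources {sorted(missing)}")

    # -- access -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def categorical(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.is_categorical]

    @property
    def continuous(self) -> list[VariableSpec]:
        return [v for v in self.variables if not v.is_categorical]

    @property
    def domain_partition(self) -> dict[str, list[str]]:
        """Mapping domain -> variable names, in declaration order."""
        part: dict[str, list[str]] = {}
        for v in self.variables:
            part.setdefault(v.domain, []).append(v.name)
        return part

    def subset(self, names: Iterable[str]) -> "Codebook":
        names = list(names)
        unknown = set(names) - set(self.names)
        if unknown:
            raise CodebookError(f"unknown variables: {sorted(unknown)}")
        by_name = {v.name: v for v in self.variables}
        return Codebook(tuple(by_name[n] for n in names))

    def for_domain(self, domain: str) -> "Codebook":
        names = self.domain_partition.get(domain, [])
        if not names:
            raise CodebookError(f"domain {domain!r} has no variables")
        return self.subset(names)

    def replace_variable(self, name: str, **changes) -> "Codebook":
        new = tuple(replace(v, **changes) if v.name == name else v for v in self.variables)
        return Codebook(new, self.poolings)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        out: dict[str, Any] = {"variables": []}
        for v in self.variables:
            d: dict[str, Any] = {"name": v.name, "kind": v.kind, "domain": v.domain}
            if v.levels is not None:
                d["levels"] = list(v.levels)
            if v.range is not None:
                d["range"] = list(v.range)
            if v.severity_direction != "none":
                d["severity_direction"] = v.severity_direction
            if v.recode_map is not None:
                d["recode_map"] = dict(v.recode_map)
            if v.severe_level is not None:
                d["severe_level"] = v.severe_level
            out["variables"].append(d)
        if self.poolings:
            out["poolings"] = [
                {"name": r.name, "sources": list(r.sources), "how": r.how,
                 **({"domain": r.domain} if r.domain else {})}
                for r in self.poolings
            ]
        return out

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Codebook":
        try:
            raw_vars: Sequence[Mapping] = doc["variables"]
        except (KeyError, TypeError) as exc:
            raise CodebookError("codebook document needs a 'variables' list") from exc
        variables = []
        for d in raw_vars:
            d = dict(d)
            if "levels" in d and d["levels"] is not None:
                d["levels"] = tuple(d["levels"])
            if "range" in d and d["range"] is not None:
                d["range"] = tuple(d["range"])
            variables.append(VariableSpec(**d))
        poolings = tuple(
            PoolingRule(name=p["name"], sources=tuple(p["sources"]),
                        how=p.get("how", "any"), domain=p.get("domain"))
            for p in doc.get("poolings", [])
        )
        return cls(tuple(variables), poolings)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "Codebook":
        """Load from a YAML string or a file path."""
        text = source
        try:
            import os

            if os.path.exists(str(source)):
                with open(source) as fh:
                    text = fh.read()
        except (OSError, ValueError):
            pass
        doc = yaml.safe_load(text)
        return cls.from_dict(doc)
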