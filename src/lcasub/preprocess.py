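"""Declarative variable pre-processing.

Three operations, each auditable: a rare-category screen (flag variables
where more than 85% of respondents sit in one category), declarative
recoding/pooling (severity-driven rebinning and clinically motivated
pooling of side-specific dichotomous items expressed as codebook rules —
never automated), and reverse scoring so that higher values indicate a
more severe condition. No values are ever imputed; the likelihood skips
missing entries instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import Codebook, VariableSpec
from .dataset import Dataset, _is_missing
from .errors import CodebookError

logger = logging.getLogger(__name__)


@dataclass
class ScreenReport:
    """Modal-category shares and exclusion flags per categorical variable."""

    table: pd.DataFrame  # variable, modal_category, modal_share, flagged
    threshold: float

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "variable"])


def rare_category_screen(data: Dataset, codebook: Codebook,
                         threshold: float = 0.85) -> ScreenReport:
    """Flag categorical variables whose modal category holds strictly more
    than ``threshold`` of the non-missing responses.

    Flagging is a report only; dropping flagged variables is a separate,
    explicitly confirmed transformation (:func:`drop_variables`).
    """
    rows = []
    for v in codebook.categorical:
        col = data.df[v.name]
        obs = col[~col.map(_is_missing)]
        if len(obs) == 0:
            rows.append((v.name, None, np.nan, False))
            continue
        shares = obs.value_counts(normalize=True)
        modal_share = float(shares.iloc[0])
        rows.append((v.name, shares.index[0], modal_share, modal_share > threshold))
    table = pd.DataFrame(rows, columns=["variable", "modal_category",
                                        "modal_share", "flagged"])
    return ScreenReport(table=table, threshold=threshold)


def drop_variables(data: Dataset, codebook: Codebook,
                   names: list[str]) -> tuple[Dataset, Codebook]:
    """Remove variables (e.g. those flagged by the screen) from both the
    codebook and the data; each removal is logged."""
    keep = [n for n in codebook.names if n not in set(names)]
    for n in names:
        logger.info("dropping variable %s", n)
    cb = codebook.subset(keep)
    return Dataset(data.df[keep], cb, allow_all_missing_rows=True), cb


def apply_recode(data: Dataset, codebook: Codebook) -> tuple[Dataset, Codebook]:
    """Apply declared recode maps and pooling rules.

    Recode maps replace raw values by analysis values and shrink the level
    set to the recode targets (in original level order). Pooled variables
    replace their sources: with rule ``any``, the result is 1 when any
    observed source equals 1, 0 when every observed source is 0, and
    missing only when all sources are missing. Colliding names error.
    """
    df = data.df.copy()
    new_specs: list[VariableSpec] = []
    pooled_sources = {s for rule in codebook.poolings for s in rule.sources}
    pool_names = [r.name for r in codebook.poolings]
    collisions = (set(pool_names) & set(codebook.names)) - pooled_sources
    if collisions or len(set(pool_names)) != len(pool_names):
        raise CodebookError(f"pooling name collision: {sorted(collisions) or pool_names}")

    for v in codebook:
        if v.name in pooled_sources:
            continue
        if v.recode_map and v.is_categorical:
            col = df[v.name]
            recoded = col.map(lambda x: v.recode_map.get(x, x)
                              if not _is_missing(x) else None)
            df[v.name] = recoded
            seen = []
            for lv in v.levels:
                target = v.recode_map.get(lv, lv)
                if target not in seen:
                    seen.append(target)
            new_specs.append(VariableSpec(
                name=v.name, kind=v.kind, domain=v.domain, levels=tuple(seen),
                range=v.range, severity_direction=v.severity_direction,
                severe_level=v.severe_level))
            logger.info("recoded %s onto levels %s", v.name, seen)
        else:
            new_specs.append(v)

    for rule in codebook.poolings:
        cols = [df[s] for s in rule.sources]
        pooled = []
        for i in range(len(df)):
            vals = [c.iloc[i] for c in cols]
            obs = [x for x in vals if not _is_missing(x)]
            if not obs:
                pooled.append(None)
            else:
                pooled.append(1 if any(int(x) == 1 for x in obs) else 0)
        df[rule.name] = pooled
        domain = rule.domain or codebook[rule.sources[0]].domain
        new_specs.append(VariableSpec(name=rule.name, kind="nominal",
                                      domain=domain, levels=(0, 1),
                                      severity_direction="higher_worse"))
        logger.info("pooled %s -> %s (any)", list(rule.sources), rule.name)

    cb = Codebook(tuple(new_specs))
    return Dataset(df[cb.names], cb, allow_all_missing_rows=True), cb


def reverse_score(data: Dataset, codebook: Codebook) -> tuple[Dataset, Codebook]:
    """Reverse variables declared ``lower_worse`` so that higher scores
    indicate a more severe condition; the transform is an involution on
    values and flips the severity direction to ``higher_worse``.

    Ordinal variables map level index i to index C-1-i; continuous
    variables map x to lo+hi-x over the declared range. Nominal variables
    (no intrinsic order) are left untouched.
    """
    df = data.df.copy()
    specs = []
    for v in codebook:
        if v.severity_direction != "lower_worse":
            specs.append(v)
            continue
        if v.kind == "ordinal":
            flip = {lv: v.levels[len(v.levels) - 1 - i] for i, lv in enumerate(v.levels)}
            df[v.name] = df[v.name].map(
                lambda x: None if _is_missing(x) else flip[x])
            specs.append(VariableSpec(name=v.name, kind=v.kind, domain=v.domain,
                                      levels=v.levels, range=v.range,
                                      severity_direction="higher_worse",
                                      severe_level=v.severe_level))
            logger.info("reverse scored ordinal %s", v.name)
        elif v.kind == "continuous" and v.range is not None:
            lo, hi = v.range
            df[v.name] = df[v.name].map(
                lambda x: None if _is_missing(x) else lo + hi - float(x))
            specs.append(VariableSpec(name=v.name, kind=v.kind, domain=v.domain,
                                      range=v.range,
                                      severity_direction="higher_worse"))
            logger.info("reverse scored continuous %s", v.name)
        else:
            specs.append(v)
    cb = Codebook(tuple(specs), codebook.poolings)
    return Dataset(df[cb.names], cb, allow_all_missing_rows=True), cb
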