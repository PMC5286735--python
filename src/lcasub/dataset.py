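"""Validated rectangular patient data.

A :class:`Dataset` couples a pandas DataFrame (one row per patient, one
column per variable, NaN/None = missing) with the :class:`~lcasub.codebook.Codebook`
it conforms to. Construction validates every cell: non-missing categorical
values must be declared levels, continuous values must respect declared
bounds, and no row may be entirely missing (patients with completely
missing data are excluded before analysis).

CSV convention: header row = variable names, one row per patient, empty
string = missing. Recode maps declared in the codebook are applied while
reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .codebook import Codebook, VariableSpec
from .errors import DataValidationError


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return pd.isna(value)


@dataclass(frozen=True)
class Encoded:
    """Numeric view of a dataset used by the estimation core.

    Categorical columns are integer level codes with -1 for missing;
    continuous columns are floats with NaN for missing.
    """

    cat_names: tuple[str, ...]
    cat_codes: np.ndarray  # (n, n_cat) int64, -1 = missing
    cat_sizes: tuple[int, ...]
    cont_names: tuple[str, ...]
    cont: np.ndarray  # (n, n_cont) float64, NaN = missing

    @property
    def n(self) -> int:
        return self.cat_codes.shape[0] if self.cat_names else self.cont.shape[0]


class Dataset:
    """Patients x variables table validated against a codebook."""

    def __init__(self, df: pd.DataFrame, codebook: Codebook,
                 allow_all_missing_rows: bool = False):
        missing_cols = set(codebook.names) - set(df.columns)
        if missing_cols:
            raise DataValidationError(f"data lacks declared columns: {sorted(missing_cols)}")
        extra = set(df.columns) - set(codebook.names)
        if extra:
            raise DataValidationError(f"data has undeclared columns: {sorted(extra)}")
        df = df[codebook.names].copy()
        self.codebook = codebook
        self._validate(df, codebook, allow_all_missing_rows)
        # canonicalise categorical cells to the declared level objects
        # (e.g. a float 1.0 that pandas upcast becomes the declared int 1)
        for v in codebook.categorical:
            canon = {lv: lv for lv in v.levels}
            df[v.name] = pd.Series(
                [None if _is_missing(x) else canon[x] for x in df[v.name]],
                index=df.index, dtype=object)
        self.df = df
        self._encoded: Encoded | None = None

    @staticmethod
    def _validate(df: pd.DataFrame, codebook: Codebook, allow_all_missing: bool) -> None:
        if len(df) == 0:
            raise DataValidationError("dataset has no rows")
        for v in codebook:
            col = df[v.name]
            obs = ~col.map(_is_missing)
            values = col[obs]
            if v.is_categorical:
                bad = ~values.isin(v.levels)
                if bad.any():
                    row = values.index[bad][0]
                    raise DataValidationError(
                        f"variable {v.name!r}, row {row!r}: value "
                        f"{values.loc[row]!r} not in declared levels"
                    )
            else:
                try:
                    numeric = values.astype(float)
                except (TypeError, ValueError) as exc:
                    raise DataValidationError(
                        f"variable {v.name!r}: non-numeric continuous value"
                    ) from exc
                if v.range is not None:
                    lo, hi = v.range
                    out = (numeric < lo) | (numeric > hi)
                    if out.any():
                        row = numeric.index[out][0]
                        raise DataValidationError(
                            f"variable {v.name!r}, row {row!r}: value "
                            f"{numeric.loc[row]} outside range [{lo}, {hi}]"
                        )
        if not allow_all_missing:
            all_missing = df.map(_is_missing).all(axis=1)
            if all_missing.any():
                rows = list(df.index[all_missing])
                raise DataValidationError(
                    f"{len(rows)} row(s) entirely missing: {rows[:10]}"
                )

    # -- basic access -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def variables(self) -> list[str]:
        return self.codebook.names

    @property
    def row_ids(self) -> list:
        return list(self.df.index)

    def select(self, names: Iterable[str]) -> "Dataset":
        """Column subset; rows that become all-missing are retained (they
        contribute only the class weights to a likelihood)."""
        sub_cb = self.codebook.subset(names)
        return Dataset(self.df[sub_cb.names], sub_cb, allow_all_missing_rows=True)

    def missingness_report(self) -> pd.Series:
        return self.df.map(_is_missing).mean(axis=0)

    def row_completeness(self) -> pd.Series:
        return 1.0 - self.df.map(_is_missing).mean(axis=1)

    # -- numeric encoding ---------------------------------------------------

    def encode(self) -> Encoded:
        if self._encoded is not None:
            return self._encoded
        cat_specs = self.codebook.categorical
        cont_specs = self.codebook.continuous
        n = self.n
        cat_codes = np.full((n, len(cat_specs)), -1, dtype=np.int64)
        for j, v in enumerate(cat_specs):
            level_index = {lv: i for i, lv in enumerate(v.levels)}
            col = self.df[v.name]
            for i, value in enumerate(col):
                if not _is_missing(value):
                    cat_codes[i, j] = level_index[value]
        cont = np.full((n, len(cont_specs)), np.nan)
        for j, v in enumerate(cont_specs):
            col = self.df[v.name]
            vals = [np.nan if _is_missing(x) else float(x) for x in col]
            cont[:, j] = vals
        self._encoded = Encoded(
            cat_names=tuple(v.name for v in cat_specs),
            cat_codes=cat_codes,
            cat_sizes=tuple(v.n_levels for v in cat_specs),
            cont_names=tuple(v.name for v in cont_specs),
            cont=cont,
        )
        return self._encoded

    # -- CSV I/O ------------------------------------------------------------

    def to_csv(self, path=None) -> str | None:
        out = self.df.copy()
        out = out.where(~out.map(_is_missing), "")
        return out.to_csv(path, index_label="row_id")

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_csv().encode()).hexdigest()[:16]


def _parse_cell(raw: str, spec: VariableSpec):
    """Map one CSV cell (string) to the analysis value for ``spec``."""
    if raw is None or str(raw).strip() == "":
        return None
    raw = str(raw).strip()
    if spec.recode_map is not None:
        for key, target in spec.recode_map.items():
            if str(key) == raw:
                return target
    if spec.is_categorical:
        for lv in spec.levels:
            if str(lv) == raw:
                return lv
        try:
            value = float(raw)
            for lv in spec.levels:
                if isinstance(lv, (int, float)) and float(lv) == value:
                    return lv
        except ValueError:
            pass
        raise DataValidationError(
            f"variable {spec.name!r}: value {raw!r} not in declared levels"
        )
    return float(raw)


def read_dataset(path, codebook: Codebook, on_all_missing: str = "error") -> Dataset:
    """Read a CSV into a validated :class:`Dataset`.

    Recode maps are applied cell-by-cell; empty cells are missing. Rows
    that are missing on every variable are rejected (``on_all_missing=
    'error'``, the default) or dropped with their identifiers recorded on
    the returned dataset as ``dropped_rows`` (``'drop'``).
    """
    if on_all_missing not in ("error", "drop"):
        raise ValueError("on_all_missing must be 'error' or 'drop'")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "row_id" in raw.columns:
        raw = raw.set_index("row_id")
    unknown = set(raw.columns) - set(codebook.names)
    if unknown:
        raise DataValidationError(f"unknown column(s) in CSV: {sorted(unknown)}")
    missing = set(codebook.names) - set(raw.columns)
    if missing:
        raise DataValidationError(f"CSV lacks declared column(s): {sorted(missing)}")

    parsed = {}
    for name in codebook.names:
        spec = codebook[name]
        parsed[name] = [_parse_cell(x, spec) for x in raw[name]]
    df = pd.DataFrame(parsed, index=raw.index)

    all_missing = df.map(_is_missing).all(axis=1)
    dropped: list = []
    if all_missing.any():
        rows = list(df.index[all_missing])
        if on_all_missing == "error":
            raise DataValidationError(
                f"{len(rows)} row(s) entirely missing: {rows[:10]}"
            )
        dropped = rows
        df = df[~all_missing]
    ds = Dataset(df, codebook)
    ds.dropped_rows = dropped  # type: ignore[attr-defined]
    return ds
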