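"""Solution evaluation and comparison toolkit.

Covers the descriptive apparatus used to judge and compare subgroup
solutions: posterior-certainty summaries, severity-oriented normalised
profile matrices, feature detection (the 30%-spread rule), qualitative vs
quantitative profile differences, minimum subgroup-size checks, and the
flagged cross-tabulation of modal memberships between two solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .codebook import Codebook
from .model import FitResult

_EPS = 1e-12


def round_half_up_percent(count: float, total: float) -> int:
    """Prevalence as an integer percent, rounding half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))


# ---------------------------------------------------------------------------
# posterior certainty


@dataclass
class PosteriorSummary:
    median_max_posterior: float
    iqr_max_posterior: tuple[float, float]
    n_below_070: int
    n_multi_033: int
    n_below_070_by_class: dict[int, int]
    n: int


def posterior_summary(posteriors: np.ndarray) -> PosteriorSummary:
    """Certainty-of-membership summary over a posterior matrix.

    Uses the per-patient maximum posterior (1.00 throughout would mean no
    membership uncertainty at all). Both thresholds are strict: counted are
    maxima strictly below 0.70, and patients with a posterior strictly
    above one third (conventionally printed as 0.33) for more than one
    class; boundary rows — a maximum of exactly 0.70, or posteriors of
    exactly 1/3 — fall in neither count.
    """
    post = np.asarray(posteriors, dtype=float)
    maxima = post.max(axis=1)
    modal = post.argmax(axis=1) + 1
    below = maxima < 0.70
    multi = (post > 1.0 / 3.0).sum(axis=1) > 1
    by_class = {
        int(k): int((below & (modal == k)).sum()) for k in range(1, post.shape[1] + 1)
    }
    q25, q75 = np.percentile(maxima, [25, 75])
    return PosteriorSummary(
        median_max_posterior=float(np.median(maxima)),
        iqr_max_posterior=(float(q25), float(q75)),
        n_below_070=int(below.sum()),
        n_multi_033=int(multi.sum()),
        n_below_070_by_class=by_class,
        n=post.shape[0],
    )


# ---------------------------------------------------------------------------
# normalised profiles


@dataclass
class ProfileMatrix:
    """Variables x classes matrix of severity scores normalised to [0, 1].

    Variables whose severity direction is ``lower_worse`` are reversed so
    that higher scores always indicate a more severe condition.
    """

    scores: pd.DataFrame  # index: variable, columns: 1..K
    methods: dict[str, str]
    excluded: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.scores.shape[1]

    def spread(self) -> pd.Series:
        """Per-variable max-min of the class scores."""
        if self.K < 2:
            return pd.Series(0.0, index=self.scores.index)
        return self.scores.max(axis=1) - self.scores.min(axis=1)


def normalized_profile(fit: FitResult, codebook: Codebook) -> ProfileMatrix:
    """Class-conditional severity scores per variable, scaled to [0, 1].

    Continuous variables: class means min-max scaled by the declared range
    (falling back to the span of the class means when no range is
    declared). Ordinal variables: conditional mean under equidistant
    integer scores over the level ordering, scaled by that score range.
    Nominal variables: the score-weighted mean when the recode map declares
    numeric severity scores for the levels, else the probability of the
    designated severe level; with neither, the variable is excluded with a
    warning.
    """
    model = fit.model
    K = model.K
    rows: dict[str, np.ndarray] = {}
    methods: dict[str, str] = {}
    excluded: list[str] = []
    for v in codebook:
        if v.kind == "continuous":
            mu = model.cont_means[v.name]
            if v.range is not None:
                lo, hi = v.range
            else:
                lo, hi = float(mu.min()), float(mu.max())
                if hi - lo < _EPS:
                    lo, hi = lo - 0.5, hi + 0.5
            score = (mu - lo) / (hi - lo)
            methods[v.name] = "range_scaled_mean"
        elif v.kind == "ordinal":
            tab = model.cat_probs[v.name]  # (K, C)
            idx = np.arange(tab.shape[1], dtype=float)
            mean = tab @ idx
            denom = max(tab.shape[1] - 1, 1)
            score = mean / denom
            methods[v.name] = "integer_scored_mean"
        else:  # nominal
            tab = model.cat_probs[v.name]
            numeric_scores = None
            if v.recode_map is not None:
                try:
                    numeric_scores = {lv: float(v.recode_map[lv]) for lv in v.levels}
                except (KeyError, TypeError, ValueError):
                    numeric_scores = None
            if numeric_scores is not None:
                s = np.array([numeric_scores[lv] for lv in v.levels])
                lo, hi = s.min(), s.max()
                score = (tab @ s - lo) / max(hi - lo, _EPS)
                methods[v.name] = "scored_mean"
            elif v.severe_level is not None and v.severe_level in v.levels:
                c = v.levels.index(v.severe_level)
                score = tab[:, c]
                methods[v.name] = "p_severe_level"
            else:
                warnings.warn(
                    f"{v.name}: nominal variable without severity scoring or "
                    "severe level; excluded from profile"
                )
                excluded.append(v.name)
                continue
        score = np.clip(score, 0.0, 1.0)
        if v.severity_direction == "lower_worse":
            score = 1.0 - score
        rows[v.name] = score
    frame = pd.DataFrame(rows, index=range(1, K + 1)).T
    return ProfileMatrix(scores=frame, methods=methods, excluded=excluded)


# ---------------------------------------------------------------------------
# features and profile differences


@dataclass
class FeatureGroup:
    members: list[str]
    spread: float  # minimum spread over members
    concordance: float  # minimum pairwise rank correlation (1.0 for singletons)
    classification: str  # 'quantitative' or 'qualitative'


def classify_difference(profile_a, profile_b) -> str:
    """'qualitative' when two class profiles cross (signs of the
    differences disagree across variables), 'quantitative' when one profile
    dominates (all differences of one sign or zero)."""
    d = np.asarray(profile_a, dtype=float) - np.asarray(profile_b, dtype=float)
    return "qualitative" if (d > _EPS).any() and (d < -_EPS).any() else "quantitative"


def _rank_corr(u: np.ndarray, v: np.ndarray) -> float:
    rho = spearmanr(u, v).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def _has_crossing(u: np.ndarray, v: np.ndarray) -> bool:
    """True when some pair of classes is ordered oppositely by u and v."""
    K = len(u)
    for a in range(K):
        for b in range(a + 1, K):
            if (u[a] - u[b]) * (v[a] - v[b]) < -_EPS:
                return True
    return False


def detect_features(profile: ProfileMatrix, min_spread: float = 0.30,
                    concordance_min: float = 0.6) -> list[FeatureGroup]:
    """Greedily group variables with >= ``min_spread`` between their
    highest- and lowest-scoring classes.

    Candidates are visited in descending spread; a variable joins the first
    group whose every member it rank-correlates with at >=
    ``concordance_min`` (tolerating minor profile crossings), else it opens
    a new group. A group is 'quantitative' when no pair of members orders
    any two classes oppositely, 'qualitative' when minor crossings remain.
    """
    if profile.K < 2:
        return []
    spreads = profile.spread()
    eligible = spreads[spreads >= min_spread - _EPS]
    order = sorted(eligible.index, key=lambda v: (-eligible[v], profile.scores.index.get_loc(v)))
    groups: list[list[str]] = []
    for name in order:
        vec = profile.scores.loc[name].to_numpy()
        placed = False
        for group in groups:
            if all(_rank_corr(vec, profile.scores.loc[m].to_numpy()) >= concordance_min
                   for m in group):
                group.append(name)
                placed = True
                break
        if not placed:
            groups.append([name])
    out = []
    for group in groups:
        vecs = [profile.scores.loc[m].to_numpy() for m in group]
        if len(group) == 1:
            conc, crossing = 1.0, False
        else:
            pair_corrs, crossing = [], False
            for i in range(len(vecs)):
                for j in range(i + 1, len(vecs)):
                    pair_corrs.append(_rank_corr(vecs[i], vecs[j]))
                    crossing = crossing or _has_crossing(vecs[i], vecs[j])
            conc = float(min(pair_corrs))
        out.append(FeatureGroup(
            members=list(group),
            spread=float(min(spreads[m] for m in group)),
            concordance=conc,
            classification="qualitative" if crossing else "quantitative",
        ))
    return out


# ---------------------------------------------------------------------------
# subgroup sizes


@dataclass
class SubgroupSizeReport:
    shares: np.ndarray  # per class, modal-assignment share
    status: list[str]  # 'ok' | 'conditionally_acceptable' | 'flagged'
    threshold: float
    relaxed: float


def subgroup_size_check(fit: FitResult, codebook: Codebook | None = None,
                        threshold: float = 0.05, relaxed: float = 0.03,
                        relaxed_variables: list[str] | None = None,
                        min_spread: float = 0.30) -> SubgroupSizeReport:
    """Flag classes holding less than 5% of the cohort by modal assignment.

    Classes in [3%, 5%) are conditionally acceptable when their
    distinguishing high-spread variables (where the class attains the
    extreme profile score) include any of ``relaxed_variables`` —
    characteristics known to be under-represented in the sampled
    population. Classes below 3% are always flagged.
    """
    shares = fit.class_shares()
    relaxed_variables = list(relaxed_variables or [])
    distinguishing: dict[int, set[str]] = {k: set() for k in range(1, fit.K + 1)}
    if relaxed_variables and codebook is not None and fit.K >= 2:
        profile = normalized_profile(fit, codebook)
        spreads = profile.spread()
        for name in spreads[spreads >= min_spread - _EPS].index:
            row = profile.scores.loc[name]
            distinguishing[int(row.idxmax())].add(name)
            distinguishing[int(row.idxmin())].add(name)
    status = []
    for k, share in enumerate(shares, start=1):
        if share >= threshold:
            status.append("ok")
        elif share >= relaxed and distinguishing[k] & set(relaxed_variables):
            status.append("conditionally_acceptable")
        else:
            status.append("flagged")
    return SubgroupSizeReport(shares=shares, status=status,
                              threshold=threshold, relaxed=relaxed)


# ---------------------------------------------------------------------------
# membership cross-tabulation


@dataclass
class CrossTab:
    """Joint modal-membership counts for two solutions, with per-cell flags.

    Flags (mutually exclusive, in precedence order):
      a - largest cell in its row;
      b - largest cell in its column (when not already the row maximum);
      c - more than 10% of its row total (but not a/b);
      d - more than 10% of its column total only (but not a/b/c).
    """

    counts: pd.DataFrame  # rows x columns
    flags: pd.DataFrame  # same shape, strings in {'', 'a', 'b', 'c', 'd'}
    row_margins: pd.Series
    col_margins: pd.Series
    grand_total: int

    @classmethod
    def from_counts(cls, counts: pd.DataFrame | np.ndarray,
                    row_labels=None, col_labels=None) -> "CrossTab":
        if not isinstance(counts, pd.DataFrame):
            counts = np.asarray(counts)
            counts = pd.DataFrame(
                counts,
                index=row_labels or [f"R{i+1}" for i in range(counts.shape[0])],
                columns=col_labels or [f"C{j+1}" for j in range(counts.shape[1])],
            )
        counts = counts.astype(int)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        row_tot = counts.sum(axis=1)
        col_tot = counts.sum(axis=0)
        flags = pd.DataFrame("", index=counts.index, columns=counts.columns)
        m = counts.to_numpy()
        row_max = m.max(axis=1)
        col_max = m.max(axis=0)
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                cell = m[i, j]
                if cell <= 0:
                    continue
                if cell == row_max[i]:
                    flag = "a"
                elif cell == col_max[j]:
                    flag = "b"
                elif cell > 0.10 * row_tot.iloc[i]:
                    flag = "c"
                elif cell > 0.10 * col_tot.iloc[j]:
                    flag = "d"
                else:
                    continue
                flags.iloc[i, j] = flag
        return cls(counts=counts, flags=flags, row_margins=row_tot,
                   col_margins=col_tot, grand_total=int(m.sum()))

    def prevalence_percent(self, axis: str = "columns") -> pd.Series:
        """Margin shares as integer percents (half away from zero)."""
        margins = self.col_margins if axis == "columns" else self.row_margins
        return margins.map(lambda c: round_half_up_percent(c, self.grand_total))


def crosstab(assign_a: np.ndarray, assign_b: np.ndarray,
             labels_a: list[str] | None = None,
             labels_b: list[str] | None = None) -> CrossTab:
    """Flagged cross-tabulation of two modal assignment vectors."""
    a = np.asarray(assign_a)
    b = np.asarray(assign_b)
    if a.shape != b.shape:
        raise ValueError(
            f"assignment vectors differ in length: {a.shape[0]} vs {b.shape[0]}"
        )
    ka = int(a.max())
    kb = int(b.max())
    m = np.zeros((ka, kb), dtype=int)
    np.add.at(m, (a - 1, b - 1), 1)
    return CrossTab.from_counts(
        m,
        row_labels=labels_a or [f"A{k}" for k in range(1, ka + 1)],
        col_labels=labels_b or [f"B{k}" for k in range(1, kb + 1)],
    )


def _ari_from_counts(m: np.ndarray) -> float:
    """Adjusted Rand index computed from a contingency table."""

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1) / 2.0

    n = m.sum()
    sum_cells = comb2(m).sum()
    sum_rows = comb2(m.sum(axis=1)).sum()
    sum_cols = comb2(m.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_rows * sum_cols / total if total > 0 else 0.0
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0 if sum_cells == expected else 0.0
    return float((sum_cells - expected) / (max_index - expected))


@dataclass
class CrossTabAgreement:
    row_nonzero: pd.Series
    col_nonzero: pd.Series
    row_share_largest: pd.Series
    col_share_largest: pd.Series
    percent_agreement: float  # greedy 1-1 matching of largest cells
    ari: float


def crosstab_agreement(ct: CrossTab) -> CrossTabAgreement:
    """How concentrated each subgroup of one solution is in the other,
    plus overall agreement (greedy one-to-one matching) and the adjusted
    Rand index."""
    m = ct.counts.to_numpy().astype(float)
    row_nonzero = (ct.counts > 0).sum(axis=1)
    col_nonzero = (ct.counts > 0).sum(axis=0)
    row_share = ct.counts.max(axis=1) / ct.row_margins.replace(0, 1)
    col_share = ct.counts.max(axis=0) / ct.col_margins.replace(0, 1)
    work = m.copy()
    matched = 0.0
    for _ in range(min(work.shape)):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        if work[i, j] <= 0:
            break
        matched += work[i, j]
        work[i, :] = -1
        work[:, j] = -1
    return CrossTabAgreement(
        row_nonzero=row_nonzero,
        col_nonzero=col_nonzero,
        row_share_largest=row_share,
        col_share_largest=col_share,
        percent_agreement=float(100.0 * matched / ct.grand_total),
        ari=_ari_from_counts(ct.counts.to_numpy()),
    )
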