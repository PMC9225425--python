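"""Group statistics for repeated-measures imaging biomarkers.

Implements the study's statistical layer: random-intercept linear mixed
models for the Injury x Sex x Day (and Region x Injury x Sex x Day) designs
with omnibus F tests and Bonferroni-corrected pairwise comparisons, plus
Kruskal-Wallis, the Mann-Whitney U test (exact by full enumeration, with
mid-rank tie handling, or by the tie- and continuity-corrected normal
approximation), and the bias-corrected standardized mean difference
(Hedges' g).

The mixed model is exposed statsmodels-style: build :class:`MixedAnova`
from a long-format table, call :meth:`~MixedAnova.fit`, and read the
omnibus table off the returned results object.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "StatResult",
    "results_frame",
    "MixedAnova",
    "MixedAnovaResults",
    "fit_mixed_model",
    "pairwise_bonferroni",
    "kruskal_wallis",
    "mann_whitney_u",
    "hedges_g",
]


@dataclass
class StatResult:
    """One test outcome: statistic, df, raw/adjusted p, optional effect size."""

    term: str
    statistic: float
    stat_name: str
    df: Tuple[float, ...]
    p_raw: float
    p_adj: Optional[float] = None
    adjust_method: str = "none"
    estimate: Optional[float] = None
    effect_size: Optional[float] = None
    n_per_group: Tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.p_adj is not None and self.p_adj < self.p_raw - 1e-15:
            raise ValueError("adjusted p cannot fall below raw p")


def results_frame(results: Sequence[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Linear mixed model
# ---------------------------------------------------------------------------

class MixedAnova:
    """Repeated-measures linear mixed model with a per-animal random intercept.

    Parameters
    ----------
    table : DataFrame
        Long-format measurements; must not contain rows flagged ``excluded``.
    response : str
        Response column.
    between : tuple of str
        Between-subject factors (e.g. ``("injury", "sex")``).
    within : tuple of str
        Within-subject (repeated) factors, e.g. ``("day",)`` or
        ``("region", "day")``.
    subject : str
        Subject identifier column (the random-intercept grouping).

    Fixed effects comprise all main effects and interactions up to the full
    interaction of ``between + within``.  Omnibus tests are Wald F tests
    (chi-square / numerator df) against between-within denominator degrees
    of freedom: between-subject terms use ``n_subjects - n_between_cells``;
    terms involving within factors multiply that by the product of
    ``(levels - 1)`` over the within factors in the term.
    """

    def __init__(self, table: pd.DataFrame, response: str = "value",
                 between: Sequence[str] = ("injury", "sex"),
                 within: Sequence[str] = ("day",),
                 subject: str = "animal_id"):
        if "excluded" in table.columns and table["excluded"].astype(bool).any():
            raise ValueError("table still contains excluded rows; "
                             "filter with roistats.require_clean first")
        self.between = tuple(between)
        self.within = tuple(within)
        self.factors = self.between + self.within
        self.subject = subject
        self.response = response
        cols = [subject, response, *self.factors]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks columns: {missing}")
        data = table[cols].dropna(subset=[response]).copy()
        if data.empty:
            raise ValueError("no usable rows")
        y = data[response].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("response has zero variance; model is degenerate")
        self._check_cells(data)
        self.data = data
        # sum-to-zero coding so each term's Wald block test is the Type III
        # omnibus test (with treatment coding it would be a simple effect)
        self.formula = response + " ~ " + "*".join(f"C({f}, Sum)" for f in self.factors)

    def _check_cells(self, data: pd.DataFrame) -> None:
        levels = {f: sorted(data[f].astype(str).unique()) for f in self.factors}
        counts = data.groupby([*self.factors], observed=True).size()
        for cell in itertools.product(*levels.values()):
            if cell not in counts.index or counts.loc[cell] == 0:
                named = ", ".join(f"{f}={v}" for f, v in zip(self.factors, cell))
                raise ValueError(f"design cell is empty: {named}")
        n_sub = data.groupby(list(self.between), observed=True)[self.subject].nunique()
        if (n_sub < 2).any():
            bad = n_sub.index[n_sub < 2][0]
            raise ValueError(f"fewer than 2 subjects in between-cell {bad}")

    def fit(self, reml: bool = True) -> "MixedAnovaResults":
        model = smf.mixedlm(self.formula, self.data,
                            groups=self.data[self.subject])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                res = model.fit(reml=reml, method="lbfgs")
            except Exception:
                res = model.fit(reml=reml, method="powell")
        return MixedAnovaResults(self, res)

    # denominator df bookkeeping -------------------------------------------
    def _denominator_df(self, term_factors: Sequence[str]) -> float:
        data = self.data
        n_subjects = data[self.subject].nunique()
        if self.between:
            n_cells = data.groupby(list(self.between), observed=True).ngroups
        else:
            n_cells = 1
        base = max(n_subjects - n_cells, 1)
        within_in_term = [f for f in term_factors if f in self.within]
        if not within_in_term:
            return float(base)
        q = 1
        for f in within_in_term:
            q *= max(data[f].nunique() - 1, 1)
        return float(base * q)


class MixedAnovaResults:
    """Fitted :class:`MixedAnova`; omnibus F tests plus access to the
    underlying statsmodels MixedLM results (``.mixedlm``)."""

    def __init__(self, model: MixedAnova, mixedlm_results):
        self.model = model
        self.mixedlm = mixedlm_results
        self._anova = self._build_anova()

    def _term_factors(self, term_name: str) -> List[str]:
        return [f for f in self.model.factors if f"C({f}" in term_name]

    def _build_anova(self) -> pd.DataFrame:
        res = self.mixedlm
        design_info = res.model.data.design_info
        k_fe = len(res.fe_params)
        fe = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
        rows = []
        for term, sl in design_info.term_name_slices.items():
            if term == "Intercept":
                continue
            idx = np.arange(k_fe)[sl]
            b = fe[idx]
            v = cov[np.ix_(idx, idx)]
            q = len(idx)
            chi2 = float(b @ np.linalg.solve(v, b))
            fstat = chi2 / q
            factors = self._term_factors(term)
            ddf = self.model._denominator_df(factors)
            p = float(stats.f.sf(fstat, q, ddf))
            pretty = " x ".join(factors) if factors else term
            rows.append(dict(term=pretty, num_df=q, den_df=ddf, F=fstat, p=p))
        return pd.DataFrame(rows)

    @property
    def anova_table(self) -> pd.DataFrame:
        return self._anova.copy()

    def stat_results(self) -> List[StatResult]:
        return [
            StatResult(term=r.term, statistic=r.F, stat_name="F",
                       df=(r.num_df, r.den_df), p_raw=r.p)
            for r in self._anova.itertuples()
        ]

    def pairwise(self, family: Sequence[Tuple[str, Mapping, Mapping]],
                 value: Optional[str] = None) -> List[StatResult]:
        """Bonferroni-corrected pairwise comparisons on the model's data."""
        return pairwise_bonferroni(self.model.data, family,
                                   value=value or self.model.response)

    def summary(self) -> str:
        m = self.model
        head = (f"Mixed-model ANOVA: {m.response} ~ "
                + " x ".join(m.factors)
                + f"  (random intercept: {m.subject}, "
                f"n={m.data[m.subject].nunique()} subjects, "
                f"{len(m.data)} observations)")
        lines = [head, "-" * len(head),
                 f"{'term':<28}{'num df':>7}{'den df':>9}{'F':>10}{'p':>10}"]
        for r in self._anova.itertuples():
            lines.append(f"{r.term:<28}{r.num_df:>7d}{r.den_df:>9.1f}"
                         f"{r.F:>10.3f}{r.p:>10.4f}")
        var = float(self.mixedlm.cov_re.iloc[0, 0])
        lines.append(f"Between-subject variance: {var:.4g}; "
                     f"residual variance: {float(self.mixedlm.scale):.4g}")
        return "\n".join(lines)


def fit_mixed_model(table: pd.DataFrame, response: str = "value",
                    between: Sequence[str] = ("injury", "sex"),
                    within: Sequence[str] = ("day",),
                    subject: str = "animal_id") -> MixedAnovaResults:
    """Convenience wrapper: build and fit a :class:`MixedAnova` in one call."""
    return MixedAnova(table, response=response, between=between,
                      within=within, subject=subject).fit()


# ---------------------------------------------------------------------------
# Pairwise comparisons with Bonferroni correction
# ---------------------------------------------------------------------------

def pairwise_bonferroni(table: pd.DataFrame,
                        family: Sequence[Tuple[str, Mapping, Mapping]],
                        value: str = "value") -> List[StatResult]:
    """Explicitly enumerated pairwise comparisons, Bonferroni-adjusted.

    ``family`` is a list of ``(label, filter_a, filter_b)`` where each filter
    is a ``{column: level}`` mapping selecting one group of rows.  Each
    comparison is a two-sided pooled-variance t test; adjusted p is
    ``min(1, m * p_raw)`` with m the family size.  Hedges' g is attached as
    the effect size.
    """
    if len(family) == 0:
        raise ValueError("comparison family is empty")
    m = len(family)

    def select(filt: Mapping) -> np.ndarray:
        mask = np.ones(len(table), dtype=bool)
        for col, lev in filt.items():
            mask &= (table[col] == lev).to_numpy()
        return table.loc[mask, value].dropna().to_numpy(dtype=float)

    out = []
    for label, fa, fb in family:
        x, y = select(fa), select(fb)
        if x.size < 2 or y.size < 2:
            raise ValueError(f"comparison {label!r} has a group with < 2 values")
        t, p = stats.ttest_ind(x, y, equal_var=True)
        out.append(StatResult(
            term=label, statistic=float(t), stat_name="t",
            df=(float(x.size + y.size - 2),), p_raw=float(p),
            p_adj=float(min(1.0, m * p)), adjust_method=f"bonferroni(m={m})",
            estimate=float(x.mean() - y.mean()),
            effect_size=hedges_g(x, y), n_per_group=(x.size, y.size)))
    return out


# ---------------------------------------------------------------------------
# Rank-based tests
# ---------------------------------------------------------------------------

def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def kruskal_wallis(groups: Sequence[np.ndarray]) -> StatResult:
    """Kruskal-Wallis H with tie correction, chi-square p on k-1 df.

    H = 12 / (N (N+1)) * sum n_i rbar_i^2 - 3 (N+1), divided by the tie
    correction 1 - sum(t^3 - t) / (N^3 - N).  All-identical input yields
    H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += g.size * r.mean() ** 2
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n ** 3 - n)
    if correction <= 0:  # every value identical
        return StatResult(term="kruskal_wallis", statistic=0.0, stat_name="H",
                          df=(len(groups) - 1,), p_raw=1.0,
                          n_per_group=tuple(g.size for g in groups))
    h = max(h / correction, 0.0)
    p = float(stats.chi2.sf(h, len(groups) - 1))
    return StatResult(term="kruskal_wallis", statistic=float(h), stat_name="H",
                      df=(len(groups) - 1,), p_raw=p,
                      n_per_group=tuple(g.size for g in groups))


def _u_statistics(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks under ties
    r1 = ranks[: x.size].sum()
    u1 = r1 - x.size * (x.size + 1) / 2.0
    u2 = x.size * y.size - u1
    return u1, u2, ranks


def mann_whitney_u(x: np.ndarray, y: np.ndarray, mode: str = "auto",
                   exact_limit: int = 10) -> StatResult:
    """Two-sided Mann-Whitney U test, U = min(U1, U2).

    ``mode='exact'`` enumerates all C(n1+n2, n1) assignments of the pooled
    mid-ranks to the first sample (a permutation test, so ties are handled
    exactly); the p-value is the fraction of assignments with
    min(U1, U2) <= observed U.  ``mode='asymptotic'`` uses the normal
    approximation with tie and continuity corrections.  ``'auto'`` picks
    exact when both samples are at most ``exact_limit``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    u1, u2, ranks = _u_statistics(x, y)
    u = min(u1, u2)
    if mode == "auto":
        mode = "exact" if (n1 <= exact_limit and n2 <= exact_limit) else "asymptotic"
    if mode == "exact":
        n = n1 + n2
        offset = n1 * (n1 + 1) / 2.0
        thresh = u + 1e-9
        total = comb(n, n1)
        count = 0
        for pos in itertools.combinations(range(n), n1):
            r1 = sum(ranks[i] for i in pos)
            ua = r1 - offset
            if min(ua, n1 * n2 - ua) <= thresh:
                count += 1
        p = count / total
    elif mode == "asymptotic":
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie = _tie_term(ranks)
        var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (u - mu + 0.5) / np.sqrt(var)  # continuity correction toward the mean
            p = float(min(1.0, 2.0 * stats.norm.cdf(z)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StatResult(term="mann_whitney_u", statistic=float(u), stat_name="U",
                      df=(), p_raw=float(p), n_per_group=(n1, n2))


# ---------------------------------------------------------------------------
# Effect size
# ---------------------------------------------------------------------------

def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Bias-corrected standardized mean difference,

        g = J * (mean_x - mean_y) / s_pooled,
        s_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2)),
        J = 1 - 3 / (4 (n1+n2-2) - 1).

    Returns NaN (with a warning) when the pooled SD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need >= 2 values")
    s_pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                       / (n1 + n2 - 2))
    if s_pooled == 0:
        warnings.warn("zero pooled SD: Hedges' g undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    return float(j * (x.mean() - y.mean()) / s_pooled)
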