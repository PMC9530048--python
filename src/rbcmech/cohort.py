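"""Group-comparison statistics for subject-level biomarker tables.

Three procedures: the unpaired two-sample Wilcoxon (Mann–Whitney) test,
sequential (Type I) analysis of covariance with age entered before the group
factor, and significance-filtered Spearman correlation maps computed
separately per group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .exceptions import DegenerateDataError, ValidationError

__all__ = [
    "AncovaResult",
    "CorrelationMap",
    "wilcoxon_unpaired",
    "ancova_sequential",
    "spearman_rho",
    "spearman_map",
    "correlation_strength",
]


def wilcoxon_unpaired(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-sample Wilcoxon (Mann–Whitney U) test.

    Exact enumeration of the U null distribution when the combined sample has
    at most 20 untied observations; otherwise the normal approximation with
    tie correction and continuity correction.  Returns ``(U, two-sided p)``
    with U computed for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValidationError("each sample needs >= 3 observations")
    if np.ptp(np.concatenate([x, y])) == 0:
        raise DegenerateDataError("all observations tied across both samples")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size + y.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AncovaResult:
    """Sequential ANCOVA table: one row per term plus residuals."""

    table: pd.DataFrame  # index: term; columns: Df, SumSq, MeanSq, F, p
    response: str
    n_used: int
    n_dropped: int

    def __post_init__(self) -> None:
        t = self.table
        # internal bookkeeping identities
        assert np.allclose(t["MeanSq"], t["SumSq"] / t["Df"])
        resid_ms = t.loc["Residuals", "MeanSq"]
        terms = t.index.drop("Residuals")
        assert np.allclose(t.loc[terms, "F"], t.loc[terms, "MeanSq"] / resid_ms)
        assert int(t["Df"].sum()) == self.n_used - 1

    @property
    def F(self) -> pd.Series:
        return self.table["F"].drop("Residuals")

    @property
    def p(self) -> pd.Series:
        return self.table["p"].drop("Residuals")


def ancova_sequential(
    table: pd.DataFrame,
    response: str,
    covariate: str = "age",
    factor: str = "group",
) -> AncovaResult:
    """Type I (sequential) ANCOVA, covariate entered before the group factor.

    Sums of squares are sequential: the covariate is charged with all
    variation it explains alone and the factor only with what it adds.
    Subjects missing any of the three columns are dropped from this model
    only, and the dropped count is reported.
    """
    cols = [response, covariate, factor]
    data = table[cols].dropna().copy()
    n_dropped = len(table) - len(data)
    if len(data) < 5:
        raise ValidationError(f"need >= 5 complete cases, got {len(data)}")
    if data[factor].nunique() != 2:
        raise ValidationError(f"factor '{factor}' must have exactly 2 levels")
    if np.ptp(data[covariate].to_numpy(dtype=float)) == 0:
        raise DegenerateDataError(f"covariate '{covariate}' has zero variance")
    data = data.rename(columns={response: "_y", covariate: "_x", factor: "_g"})
    # Nested OLS fits pin the sequential order (covariate enters first)
    # regardless of how the formula machinery orders design columns.
    fit0 = smf.ols("_y ~ 1", data=data).fit()
    fit1 = smf.ols("_y ~ _x", data=data).fit()
    fit2 = smf.ols("_y ~ _x + C(_g)", data=data).fit()
    out = pd.DataFrame({
        "Df": [1, 1, int(fit2.df_resid)],
        "SumSq": [fit0.ssr - fit1.ssr, fit1.ssr - fit2.ssr, fit2.ssr],
    }, index=[covariate.capitalize(), "Group", "Residuals"])
    out["MeanSq"] = out["SumSq"] / out["Df"]
    resid_ms = out.loc["Residuals", "MeanSq"]
    resid_df = out.loc["Residuals", "Df"]
    out["F"] = out["MeanSq"] / resid_ms
    out["p"] = sps.f.sf(out["F"], out["Df"], resid_df)
    out.loc["Residuals", ["F", "p"]] = np.nan
    return AncovaResult(table=out, response=response,
                        n_used=len(data), n_dropped=n_dropped)


def ancova_table_from_sums(df: Sequence[int], sumsq: Sequence[float],
                           terms: Sequence[str] = ("Age", "Group", "Residuals"),
                           ) -> pd.DataFrame:
    """Rebuild an ANCOVA table from published Df and sum-of-squares cells.

    Applies the bookkeeping identities MeanSq = SumSq/Df and
    F(term) = MeanSq(term)/MeanSq(Residuals) with the F-distribution p-value,
    so mean squares and F ratios printed alongside a table can be checked
    against its Df/SumSq columns.
    """
    out = pd.DataFrame({"Df": list(df), "SumSq": list(sumsq)}, index=list(terms))
    out["MeanSq"] = out["SumSq"] / out["Df"]
    resid_ms = out.loc["Residuals", "MeanSq"]
    out["F"] = out["MeanSq"] / resid_ms
    out["p"] = sps.f.sf(out["F"], out["Df"], out.loc["Residuals", "Df"])
    out.loc["Residuals", ["F", "p"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# Spearman correlation maps
# ---------------------------------------------------------------------------


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    The p-value is exact (full permutation enumeration) for n <= 9 untied
    samples; otherwise the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError("need >= 3 paired observations")
    rho = float(sps.spearmanr(x, y).statistic)
    if not np.isfinite(rho):
        raise DegenerateDataError("a variable is constant")
    if n <= 9:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=float)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all pairings of the observed ranks."""
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    perms = _perm_matrix(n)
    # Pearson correlation of rank vectors under every pairing of ry to rx.
    ry_perm = ry[perms.astype(int)]
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlation_strength(rho: float) -> str:
    """Strength band: strong >= 0.70, moderate 0.30–0.70, else weak."""
    a = abs(rho)
    if a > 0.70:
        return "strong"
    if a >= 0.30:
        return "moderate"
    return "weak"


@dataclass
class CorrelationMap:
    """Masked Spearman correlation map for one group."""

    rho: pd.DataFrame        # rows x cols
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean mask, p < alpha
    strength: pd.DataFrame     # weak/moderate/strong labels (significant only)
    group: str
    alpha: float
    flagged: list[str]

    def masked(self) -> pd.DataFrame:
        """Correlations with non-significant entries blanked to NaN."""
        return self.rho.where(self.significant)


def spearman_map(
    table: pd.DataFrame,
    rows: Sequence[str],
    cols: Sequence[str],
    alpha: float = 0.05,
    group: str | None = None,
    group_col: str = "group",
) -> CorrelationMap:
    """Pairwise Spearman map between ``rows`` and ``cols`` fields.

    Uses pairwise-complete observations; entries with fewer than 4 pairs or a
    constant variable are flagged (NaN), and entries with p >= ``alpha`` are
    masked.  No multiplicity adjustment is applied.
    """
    data = table if group is None else table[table[group_col] == group]
    rho = pd.DataFrame(np.nan, index=list(rows), columns=list(cols))
    pmat = pd.DataFrame(np.nan, index=list(rows), columns=list(cols))
    flagged: list[str] = []
    for r in rows:
        for c in cols:
            sub = data[[r, c]].dropna()
            if r == c:
                rho.loc[r, c], pmat.loc[r, c] = 1.0, 0.0
                continue
            if len(sub) < 4:
                flagged.append(f"{r}~{c}: <4 pairs")
                continue
            try:
                rh, p = spearman_rho(sub[r].to_numpy(), sub[c].to_numpy())
            except DegenerateDataError:
                flagged.append(f"{r}~{c}: constant variable")
                continue
            rho.loc[r, c], pmat.loc[r, c] = rh, p
    significant = pmat < alpha
    strength = rho.where(significant).map(
        lambda v: correlation_strength(v) if np.isfinite(v) else ""
    )
    return CorrelationMap(
        rho=rho, p=pmat, significant=significant, strength=strength,
        group=group or "all", alpha=alpha, flagged=flagged,
    )
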