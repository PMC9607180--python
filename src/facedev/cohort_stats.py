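"""Sex-stratified contingency summaries and rank statistics for a cohort.

Fisher's exact test is implemented from first principles (log-space
hypergeometric enumeration, two-sided by the minimum-likelihood
convention) because exact behaviour at probability ties is part of the
contract; the Friedman statistic carries the standard tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, rankdata

#: Relative slack when comparing hypergeometric probabilities to the
#: observed table's probability (minimum-likelihood two-sided method).
_TIE_SLACK = 1e-7


@dataclass
class RegionContingency:
    """2x2 flag-by-sex counts for one facial region."""

    region: str
    a: int  # men flagged
    b: int  # men not flagged
    c: int  # women flagged
    d: int  # women not flagged

    @property
    def n_men(self) -> int:
        return self.a + self.b

    @property
    def n_women(self) -> int:
        return self.c + self.d

    @property
    def n(self) -> int:
        return self.n_men + self.n_women

    @property
    def pct_men(self) -> float:
        return 100.0 * self.a / self.n_men if self.n_men else float("nan")

    @property
    def pct_women(self) -> float:
        return 100.0 * self.c / self.n_women if self.n_women else float("nan")

    @property
    def pct_total(self) -> float:
        return 100.0 * (self.a + self.c) / self.n if self.n else float("nan")


def contingency_table(
    flags: pd.DataFrame, sex: pd.Series
) -> dict[str, RegionContingency]:
    """Build per-region 2x2 tables from a subjects-by-regions flag frame.

    ``flags`` has one boolean column per region, indexed by subject;
    ``sex`` maps each subject to "M" or "F".  NaN flags (unassessable
    regions) are excluded pairwise.
    """
    sex = sex.reindex(flags.index)
    bad = set(sex.dropna().unique()) - {"M", "F"}
    if bad:
        raise ValueError(f"unknown sex label(s): {sorted(bad)}")
    out: dict[str, RegionContingency] = {}
    for region in flags.columns:
        col = flags[region]
        ok = col.notna() & sex.notna()
        f = col[ok].astype(bool)
        s = sex[ok]
        men = s == "M"
        out[region] = RegionContingency(
            region=region,
            a=int((f & men).sum()),
            b=int((~f & men).sum()),
            c=int((f & ~men).sum()),
            d=int((~f & ~men).sum()),
        )
    return out


def _log_hypergeom_pmf(k: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    """log P(X = k) for the 2x2 table cell given fixed margins."""

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logc(r1, k) + logc(n - r1, c1 - k) - logc(n, c1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value by the minimum-likelihood method.

    Sums the probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed the observed table's
    (within a tiny relative slack to absorb floating-point ties).
    """
    for v in (a, b, c, d):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError("cell counts must be nonnegative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all margins are zero")
    r1 = a + b
    c1 = a + c
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(ks, n, r1, c1)
    logp_obs = _log_hypergeom_pmf(np.array([a]), n, r1, c1)[0]
    include = logp <= logp_obs + np.log1p(_TIE_SLACK)
    p = float(np.exp(logp[include]).sum())
    return min(p, 1.0)


@dataclass
class FriedmanResult:
    mean_ranks: pd.Series  # per location, higher value -> higher rank
    statistic: float  # chi-square with tie correction
    df: int
    pvalue: float
    n_subjects: int
    n_dropped: int = 0


def friedman_test(matrix: pd.DataFrame) -> FriedmanResult:
    """Friedman rank test over k related locations per subject.

    Subjects (rows) with any missing cell are dropped listwise.  Ties get
    mean ranks; the statistic uses the general tie-corrected form
    ``(k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)``.
    """
    df_in = pd.DataFrame(matrix)
    k = df_in.shape[1]
    if k < 3:
        raise ValueError("Friedman test needs at least 3 locations")
    complete = df_in.dropna()
    n_dropped = len(df_in) - len(complete)
    n = len(complete)
    if n < 2:
        raise ValueError("Friedman test needs at least 2 complete subjects")
    values = complete.to_numpy(dtype=float)
    ranks = rankdata(values, axis=1)
    col_sums = ranks.sum(axis=0)
    expected = n * (k + 1) / 2.0
    numer = (k - 1) * float(((col_sums - expected) ** 2).sum())
    denom = float((ranks**2).sum()) - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:
        statistic = 0.0
        pvalue = 1.0
    else:
        statistic = numer / denom
        pvalue = float(chi2.sf(statistic, k - 1))
    return FriedmanResult(
        mean_ranks=pd.Series(col_sums / n, index=df_in.columns),
        statistic=statistic,
        df=k - 1,
        pvalue=pvalue,
        n_subjects=n,
        n_dropped=n_dropped,
    )


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def report_tables(
    flags: pd.DataFrame,
    sex: pd.Series,
    friedman_values: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame], Optional[FriedmanResult]]:
    """Build the per-region contingency table and the rank-ordered site table.

    Returns ``(region_table, rank_table, friedman_result)``.  Percentages
    are rounded to one decimal for reporting; exact fractions live in the
    count columns.  Significance calls are unadjusted at ``alpha`` unless
    ``holm`` is set.
    """
    tables = contingency_table(flags, sex)
    rows = []
    for region, t in tables.items():
        p = fisher_exact_two_sided(t.a, t.b, t.c, t.d) if t.n else np.nan
        rows.append(
            {
                "location": region,
                "men_flagged": t.a,
                "men_total": t.n_men,
                "women_flagged": t.c,
                "women_total": t.n_women,
                "pct_men": round(t.pct_men, 1),
                "pct_women": round(t.pct_women, 1),
                "pct_total": round(t.pct_total, 1),
                "fisher_p_2sided": p,
            }
        )
    table2 = pd.DataFrame(rows)
    if holm and len(table2):
        table2["fisher_p_adjusted"] = holm_adjust(table2["fisher_p_2sided"].to_numpy())
        table2["significant"] = table2["fisher_p_adjusted"] < alpha
    else:
        table2["significant"] = table2["fisher_p_2sided"] < alpha

    table3 = None
    friedman = None
    if friedman_values is not None:
        friedman = friedman_test(friedman_values)
        table3 = (
            friedman.mean_ranks.rename("mean_rank")
            .reset_index()
            .rename(columns={"index": "location"})
            .sort_values("mean_rank", kind="stable")  # lowest to highest rank
            .reset_index(drop=True)
        )
        table3["mean_rank"] = table3["mean_rank"].round(2)
    return table2, table3, friedman
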