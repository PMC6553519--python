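"""Group comparisons and correlations for small experimental cohorts.

The study's regime is two groups of 5 and 6 preparations, so the
Mann-Whitney U test uses the exact permutation distribution whenever
both groups have <= 8 members (ties handled by mid-ranks, which the
exact enumeration permutes directly), and the normal approximation with
tie correction above that.  Spearman correlations report a seeded
permutation p-value at small n.  All tests are two-sided and
significance is declared at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "mann_whitney",
    "spearman",
    "compare_preparations",
    "format_mean_sd",
]

ALPHA = 0.05
EXACT_MAX_N = 8


@dataclass
class GroupComparisonResult:
    """One two-group contrast: means +/- SD, test statistic and p-value."""

    variable: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str
    statistic: float
    p_value: float
    ties: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "group_a": format_mean_sd(self.mean_a, self.sd_a),
            "group_b": format_mean_sd(self.mean_b, self.sd_b),
            "n_a": self.n_a,
            "n_b": self.n_b,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def format_mean_sd(mean: float, sd: float, digits: int = 2) -> str:
    """mean +/- SD string in the conventional reporting format."""
    return f"{mean:.{digits}f}±{sd:.{digits}f}"


def _u_statistic_from_ranks(ranks: np.ndarray, idx_a: Sequence[int], n_a: int, n_b: int) -> float:
    r_a = ranks[list(idx_a)].sum()
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney(group_a, group_b, variable: str = "") -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test.

    For groups of <= 8 each, the p-value is exact: the U statistic is
    computed from mid-ranks for every one of the C(n_a+n_b, n_a) group
    labelings and the two-sided p is the fraction at least as far from
    the null mean n_a*n_b/2 as the observed U.  Larger groups use the
    normal approximation with tie correction.  Ties are noted on the
    result.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    n_a, n_b = len(a), len(b)
    if n_a < 3 or n_b < 3:
        raise ValueError("each group needs n >= 3")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks under ties
    has_ties = len(np.unique(pooled)) < len(pooled)
    u_obs = _u_statistic_from_ranks(ranks, range(n_a), n_a, n_b)
    mu = n_a * n_b / 2.0

    if max(n_a, n_b) <= EXACT_MAX_N:
        test = "Mann-Whitney U (exact)"
        n_tot = n_a + n_b
        hits = 0
        dev = abs(u_obs - mu) - 1e-12
        for idx in combinations(range(n_tot), n_a):
            u = _u_statistic_from_ranks(ranks, idx, n_a, n_b)
            if abs(u - mu) >= dev:
                hits += 1
        p = hits / comb(n_tot, n_a)
    else:
        test = "Mann-Whitney U (normal approximation)"
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)

    return GroupComparisonResult(
        variable=variable,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=n_a,
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=n_b,
        test=test, statistic=float(u_obs), p_value=float(min(p, 1.0)),
        ties=has_ties,
    )


def spearman(
    x, y, n_permutations: int = 10_000, seed: int = 0, permutation_max_n: int = 10
) -> tuple[float, float]:
    """Spearman rank correlation with a small-sample permutation p-value.

    For n <= ``permutation_max_n`` the two-sided p-value comes from
    ``n_permutations`` seeded permutations of y (add-one estimator);
    above that the asymptotic p from scipy is used.  Constant input is
    an error (rho undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 4:
        raise ValueError("need n >= 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    rho, p_asym = sps.spearmanr(x, y)
    if len(x) <= permutation_max_n:
        rng = np.random.default_rng(seed)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(ry)
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    else:
        p = float(p_asym)
    return float(rho), float(p)


def compare_preparations(
    cohort_a: list[dict],
    cohort_b: list[dict],
    group_names: tuple[str, str] = ("sham", "rtof"),
    holm: bool = False,
) -> pd.DataFrame:
    """Per-variable group comparison table for two analyzed cohorts.

    Each cohort is a list of per-preparation variable dicts (e.g.
    ``{"apd_mid_endo_ms": ..., "cv_long_cm_s": ...}``).  Variables
    missing from either cohort are reported as absent rather than
    filled with zeros.  With ``holm=True`` a Holm-adjusted p column is
    added (the multi-group ANOVA named in the source protocol reduces to
    Holm-adjusted pairwise contrasts here, since every reported contrast
    is two-group).
    """
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise ValueError("each cohort needs >= 2 analyzed preparations")
    variables = sorted(
        set().union(*(d.keys() for d in cohort_a))
        | set().union(*(d.keys() for d in cohort_b))
    )
    rows = []
    for var in variables:
        va = np.array([d[var] for d in cohort_a if var in d and np.isfinite(d[var])])
        vb = np.array([d[var] for d in cohort_b if var in d and np.isfinite(d[var])])
        if len(va) < 3 or len(vb) < 3:
            rows.append({"variable": var, "status": "absent",
                         "n_a": len(va), "n_b": len(vb)})
            continue
        res = mann_whitney(va, vb, variable=var)
        row = res.to_dict()
        row["status"] = "ok"
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["groups"] = group_names
    if holm and "p_value" in table:
        ok = table["status"] == "ok"
        if ok.any():
            adj = multipletests(table.loc[ok, "p_value"], method="holm")[1]
            table.loc[ok, "p_holm"] = adj
    return table
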