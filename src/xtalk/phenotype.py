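"""Phenotype-level statistics.

Covers the metabolic/histology readouts of a two-diet cross-sectional study:
the HOMA-IR insulin-resistance index, nonparametric HFD-vs-chow group
comparisons (Kruskal-Wallis gate followed by pairwise Mann-Whitney U), and the
quadratic regression of atherosclerotic lesion area on hepatic steatosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .io import PhenotypeTable

__all__ = [
    "homa_ir",
    "GroupComparison",
    "compare_groups",
    "compare_many",
    "QuadraticFit",
    "quadratic_r2",
    "mann_whitney_exact",
    "phenotype_report",
]

#: HOMA-IR denominator: index = insulin (ng/mL) * glucose (mM) / 22.5
HOMA_DENOMINATOR = 22.5


def homa_ir(insulin, glucose):
    """Homeostasis-model insulin-resistance index.

    Parameters
    ----------
    insulin : float or array-like
        Fasting plasma insulin in ng/mL.
    glucose : float or array-like
        Fasting blood glucose in mM.

    Returns
    -------
    float or ndarray
        ``insulin * glucose / 22.5`` (dimensionless).
    """
    insulin = np.asarray(insulin, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    if (insulin < 0).any() or (glucose < 0).any():
        raise ValueError("insulin and glucose must be >= 0")
    out = insulin * glucose / HOMA_DENOMINATOR
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_distribution(n: int, m: int) -> np.ndarray:
    """Null distribution of the Mann-Whitney U statistic (no ties).

    Returns counts c[u] = number of group-label assignments with U = u,
    u = 0..n*m, via the standard recurrence
    c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u).
    """
    # table[i][j] is the count vector for group sizes (i, j)
    table = [[None] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        table[0][j] = np.array([1], dtype=float)
    for i in range(1, n + 1):
        table[i][0] = np.array([1], dtype=float)
        for j in range(1, m + 1):
            a = np.zeros(i * j + 1)
            prev = table[i - 1][j]  # length (i-1)*j + 1, shifted by j
            a[j : j + len(prev)] += prev
            prev2 = table[i][j - 1]  # length i*(j-1) + 1
            a[: len(prev2)] += prev2
            table[i][j] = a
    return table[n][m]


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test for tie-free samples.

    Returns ``(U, p)`` where U counts pairs with a > b and
    ``p = min(1, 2 * min(P(U <= u), P(U >= u)))`` under the exact null.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if len(np.unique(pooled)) != len(pooled):
        raise ValueError("exact test requires tie-free data")
    u = float(sum((x > y) for x in a for y in b))
    counts = _u_distribution(len(a), len(b))
    total = counts.sum()
    lower = counts[: int(u) + 1].sum() / total
    upper = counts[int(u) :].sum() / total
    return u, min(1.0, 2.0 * min(lower, upper))


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    fold_change: float
    u_statistic: float
    p_value: float
    test: str


def _sem(x: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    return float(np.std(x, ddof=1) / math.sqrt(len(x)))


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variable: str = "",
    exact_max_n: int = 30,
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent groups.

    The p-value is exact (full U-distribution) for tie-free samples with
    ``n_a + n_b <= exact_max_n``, otherwise scipy's tie-corrected normal
    approximation with continuity correction is used. The fold change is the
    ratio of group means, b over a.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DesignError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) != len(pooled)
    if not has_ties and len(pooled) <= exact_max_n:
        u, p = mann_whitney_exact(a, b)
        test = "mann-whitney-exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        test = "mann-whitney-asymptotic"
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    fold = mean_b / mean_a if mean_a != 0 else math.inf if mean_b > 0 else math.nan
    return GroupComparison(
        variable=variable,
        mean_a=mean_a,
        sem_a=_sem(a),
        mean_b=mean_b,
        sem_b=_sem(b),
        fold_change=fold,
        u_statistic=u,
        p_value=min(1.0, p),
        test=test,
    )


def compare_many(
    groups: Mapping[str, Sequence[float]], variable: str = ""
) -> tuple[float | None, dict[tuple[str, str], GroupComparison]]:
    """Kruskal-Wallis gate followed by pairwise Mann-Whitney tests.

    With exactly two groups the gate is skipped (gate p is None) and only the
    pairwise Mann-Whitney test runs. With more than two groups the
    Kruskal-Wallis p is returned alongside all pairwise comparisons.
    """
    names = list(groups)
    if len(names) < 2:
        raise DesignError("need at least two groups")
    gate_p: float | None = None
    if len(names) > 2:
        gate_p = float(stats.kruskal(*[groups[n] for n in names]).pvalue)
    pairwise: dict[tuple[str, str], GroupComparison] = {}
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            pairwise[(na, nb)] = compare_groups(groups[na], groups[nb], variable)
    return gate_p, pairwise


# ---------------------------------------------------------------------------
# Quadratic fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadraticFit:
    b0: float
    b1: float
    b2: float
    r_squared: float
    p_value: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.b0 + self.b1 * x + self.b2 * x**2


def quadratic_r2(x: Sequence[float], y: Sequence[float]) -> QuadraticFit:
    """Least-squares fit of ``y = b0 + b1 x + b2 x^2`` with R^2 and F-test p.

    R^2 = 1 - SS_res / SS_tot. The p-value is the overall F-test of the
    2-degree-of-freedom regression against the intercept-only model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise DesignError("need n >= 4 paired observations")
    if np.ptp(x) == 0:
        raise DesignError("x values are all identical")
    design = np.column_stack([np.ones_like(x), x, x**2])
    if np.linalg.matrix_rank(design) < 3:
        raise DesignError("rank-deficient design (fewer than 3 distinct x values)")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    df_model, df_resid = 2, len(x) - 3
    if ss_res <= 0 or df_resid <= 0:
        p = 0.0 if r2 > 0 else 1.0
    else:
        f = ((ss_tot - ss_res) / df_model) / (ss_res / df_resid)
        p = float(stats.f.sf(f, df_model, df_resid))
    return QuadraticFit(float(coef[0]), float(coef[1]), float(coef[2]), r2, p)


# ---------------------------------------------------------------------------
# Report over a phenotype table
# ---------------------------------------------------------------------------

_VARIABLES = [
    "body_weight",
    "glucose",
    "insulin",
    "homa_ir",
    "steatosis",
    "inflammation",
    "fibrosis",
    "lesion_area",
]


def phenotype_report(table: PhenotypeTable) -> pd.DataFrame:
    """Per-variable, per-timepoint HFD vs chow comparison table.

    HOMA-IR is derived per animal from insulin and glucose before testing.
    """
    df = table.frame.copy()
    df["homa_ir"] = homa_ir(df["insulin"].to_numpy(), df["glucose"].to_numpy())
    rows = []
    for t in sorted(df["time_weeks"].unique()):
        sub = df[df["time_weeks"] == t]
        chow = sub[sub["diet"] == "chow"]
        hfd = sub[sub["diet"] == "HFD"]
        if len(chow) < 2 or len(hfd) < 2:
            continue
        for var in _VARIABLES:
            cmp = compare_groups(chow[var], hfd[var], variable=var)
            rows.append(
                {
                    "variable": var,
                    "time_weeks": t,
                    "mean_chow": cmp.mean_a,
                    "sem_chow": cmp.sem_a,
                    "mean_hfd": cmp.mean_b,
                    "sem_hfd": cmp.sem_b,
                    "fold_change": cmp.fold_change,
                    "p_value": cmp.p_value,
                    "test": cmp.test,
                }
            )
    return pd.DataFrame(rows)
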