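"""The study's inferential ladder.

Normality is screened with Shapiro-Wilk but inference proceeds
nonparametrically throughout: Wilcoxon signed-rank for two paired groups,
and a Friedman omnibus followed by pairwise signed-rank post hocs with
Bonferroni correction for more than two.  Wilcoxon uses the exact null
distribution up to n = 25 paired differences (the cohort sizes in play) and
the tie- and continuity-corrected normal approximation beyond.
"""

from __future__ import annotations

from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from chronomeal.types import ContractError, TestResult

EXACT_WILCOXON_MAX_N = 25


class ShapiroResult(NamedTuple):
    w: float
    p_value: float
    is_normal: bool
    degenerate: bool = False


def shapiro_gate(samples: Sequence[float], alpha: float = 0.05) -> ShapiroResult:
    """Shapiro-Wilk normality screen at the given alpha.

    The gate is logged, not acted on: downstream tests are nonparametric
    regardless.  Constant samples are degenerate and flagged non-normal.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ContractError("shapiro_gate: need at least 3 observations")
    if x.size > 5000:
        raise ContractError("shapiro_gate: n > 5000 unsupported")
    if np.ptp(x) == 0:
        return ShapiroResult(w=np.nan, p_value=np.nan, is_normal=False, degenerate=True)
    w, p = sps.shapiro(x)
    return ShapiroResult(w=float(w), p_value=float(p), is_normal=bool(p > alpha))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], label: str = ""
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (standard signed-rank convention).  Exact
    p-values are used when n <= 25 and the absolute differences are tie-free;
    otherwise the normal approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ContractError("wilcoxon_signed_rank: unequal lengths")
    d = x - y
    d = d[np.isfinite(d)]
    d_nz = d[d != 0]
    n = d_nz.size
    if n == 0:
        return TestResult(method="wilcoxon-signed-rank", statistic=0.0, p_value=1.0,
                          n=0, label=label, flags=("all-differences-zero",))
    flags: list[str] = []
    if n < 5:
        flags.append("n<5")
    ties = np.unique(np.abs(d_nz)).size < n
    method = "exact" if (n <= EXACT_WILCOXON_MAX_N and not ties) else "approx"
    res = sps.wilcoxon(d_nz, method=method, correction=(method == "approx"))
    return TestResult(
        method=f"wilcoxon-signed-rank-{method}",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(n),
        label=label,
        flags=tuple(flags),
    )


def _rank_matrix(m: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, m)


def friedman(matrix, label: str = "") -> TestResult:
    """Tie-corrected Friedman chi-square over a participants x conditions matrix.

    Rows with any missing cell are dropped.  Uses the general tie-robust
    form chi2 = (k-1) * [sum_j R_j^2 - n^2 k (k+1)^2 / 4] /
    [sum_ij r_ij^2 - n k (k+1)^2 / 4]; identical columns give a 0/0
    degeneracy reported as statistic 0, p 1.
    """
    m = np.asarray(matrix, dtype=float)
    if isinstance(matrix, pd.DataFrame):
        m = matrix.to_numpy(dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ContractError("friedman: need a 2-D matrix with >= 2 conditions")
    m = m[np.isfinite(m).all(axis=1)]
    n, k = m.shape
    if n < 2:
        raise ContractError("friedman: need >= 2 complete rows")
    r = _rank_matrix(m)
    rj = r.sum(axis=0)
    centre = n * k * (k + 1) ** 2 / 4.0
    num = (k - 1) * (np.sum(rj**2) - n * centre)
    den = np.sum(r**2) - centre
    if den <= 0:
        stat, p = 0.0, 1.0
    else:
        stat = num / den
        p = float(sps.chi2.sf(stat, k - 1))
    return TestResult(method="friedman", statistic=float(stat), p_value=p,
                      n=int(n), label=label)


def pairwise_wilcoxon_bonferroni(matrix, labels: Sequence[str] | None = None
                                 ) -> list[TestResult]:
    """All pairwise signed-rank tests with Bonferroni-adjusted p-values.

    Every one of the C(k, 2) raw p-values is multiplied by C(k, 2) and
    capped at 1.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(c) for c in matrix.columns]
        m = matrix.to_numpy(dtype=float)
    else:
        m = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [f"c{i}" for i in range(m.shape[1])]
    k = m.shape[1]
    n_comp = k * (k - 1) // 2
    out: list[TestResult] = []
    for i, j in combinations(range(k), 2):
        pair = m[:, [i, j]]
        pair = pair[np.isfinite(pair).all(axis=1)]
        res = wilcoxon_signed_rank(pair[:, 0], pair[:, 1],
                                   label=f"{labels[i]} vs {labels[j]}")
        out.append(
            TestResult(
                method=res.method + "+bonferroni",
                statistic=res.statistic,
                p_value=min(1.0, n_comp * res.p_value),
                n=res.n,
                adjusted=True,
                label=res.label,
                flags=res.flags,
            )
        )
    return out
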