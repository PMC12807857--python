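"""Group statistics used on morphometry and inheritance data.

Implements the two tests that gate the quantitative claims — the
unequal-variance (Welch) t-test and the nonparametric Dunn post hoc
pairwise test with Bonferroni correction — plus the linear-interpolation
percentile convention used by the stratification rule. scipy is used only
for the t and normal distribution functions; the statistics themselves are
computed here and cross-checked against independent routes in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "welch_t_test", "dunn_test", "percentile"]


@dataclass
class TestResult:
    """One comparison: statistic, degrees of freedom (if any), p, adjusted p."""

    comparison: str
    statistic: float
    p_value: float
    adjusted_p: float
    df: float | None = None
    flags: tuple[str, ...] = ()


def welch_t_test(x, y, two_sided: bool = True) -> TestResult:
    """Unequal-variance t-test with Welch-Satterthwaite degrees of freedom.

    Degenerate inputs: both samples constant with equal means -> t = 0,
    p = 1; both constant with unequal means -> p = 0, flagged
    ``zero-variance``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    dmean = x.mean() - y.mean()
    se2 = vx / nx + vy / ny
    if se2 == 0:
        if dmean == 0:
            return TestResult("x-vs-y", 0.0, 1.0, 1.0, df=float(nx + ny - 2))
        return TestResult(
            "x-vs-y", float(np.sign(dmean) * np.inf), 0.0, 0.0,
            df=float(nx + ny - 2), flags=("zero-variance",),
        )
    t = dmean / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * sps.t.sf(abs(t), df) if two_sided else sps.t.sf(t, df)
    return TestResult("x-vs-y", float(t), float(p), float(p), df=float(df))


def dunn_test(
    groups: list, labels: list[str] | None = None, correction: str = "bonferroni"
) -> list[TestResult]:
    """All pairwise Dunn comparisons on jointly ranked data.

    Observations are ranked jointly with midranks for ties. For groups i, j
    with mean ranks ``Ri``, ``Rj``:

        z_ij = (Ri - Rj) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where ``T = sum(t^3 - t)`` over tie groups. Two-sided p from the normal
    distribution; Bonferroni multiplies by the number of comparisons
    actually performed. All-tied data (zero variance) degenerates to p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)  # midranks for ties
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    k = len(groups)
    m = k * (k - 1) // 2
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            denom2 = var_core * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
            comparison = f"{labels[i]}-vs-{labels[j]}"
            if denom2 <= 0:
                results.append(
                    TestResult(comparison, 0.0, 1.0, 1.0, flags=("degenerate",))
                )
                continue
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom2)
            p = float(2 * sps.norm.sf(abs(z)))
            if correction == "bonferroni":
                adj = min(1.0, p * m)
            elif correction == "none":
                adj = p
            else:
                raise ValueError(f"unknown correction {correction!r}")
            results.append(TestResult(comparison, float(z), p, adj))
    return results


def percentile(values, q: float, method: str = "linear") -> float:
    """Percentile with linear interpolation between closest order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input has no percentile")
    if not 0 <= q <= 100:
        raise ValueError("q must be in [0, 100]")
    return float(np.percentile(values, q, method=method))
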