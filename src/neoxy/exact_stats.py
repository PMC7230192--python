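"""Significance tests for progeny count data, built from first principles.

Pearson goodness-of-fit without continuity correction (recomputation of
the published sex-ratio tests matches the uncorrected statistic), Fisher
exact tests on 2x2 and r x c tables by complete enumeration of all tables
with the observed margins, an exact two-sided binomial test, and the
two-sample t test.  All exact tests use the probability-ordering rule for
two-sidedness — the two-sided p-value is the total probability of tables
(or outcomes) no more probable than the observed one — and accumulate
probabilities in log space so tables with n of a few hundred are safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "chi2_gof",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "binomial_two_sided",
    "two_sample_t",
    "EnumerationLimitError",
]

#: relative slack when comparing table probabilities for the
#: probability-ordering rule (guards against floating-point ties)
_REL_TOL = 1e-7

#: enumeration guard for r x c tables
MAX_TABLES = 10_000_000


class EnumerationLimitError(RuntimeError):
    """Raised when full r x c enumeration would exceed :data:`MAX_TABLES`."""


def _clip_p(p: float) -> float:
    """Clamp to [0, 1]; summation of a complete support should give
    exactly 1, so anything within 1e-9 of 1 is snapped there."""
    if p >= 1.0 - 1e-9:
        return 1.0
    return max(p, 0.0)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one test: statistic (None for exact tests), degrees of
    freedom where applicable, two-sided or requested-tail p-value."""

    p_value: float
    statistic: float | None = None
    df: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value out of range: {self.p_value}")


def _validate_counts(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{name} must be a 1-d vector of length >= 2")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{name} must be non-negative integers")
    return arr


def chi2_gof(
    observed: Sequence[float], expected_probs: Sequence[float]
) -> TestResult:
    """Pearson chi-square goodness of fit, no continuity correction.

    ``statistic = sum (O - E)^2 / E`` with ``E = n * p``; ``df = k - 1``;
    p from the chi-square survival function.
    """
    obs = _validate_counts(observed, "observed")
    probs = np.asarray(expected_probs, dtype=float)
    if probs.shape != obs.shape:
        raise ValueError("observed and expected_probs must have equal length")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("expected_probs must be non-negative and sum to 1")
    expected = obs.sum() * probs
    if np.any(expected == 0):
        raise ValueError("zero expected count; drop the empty category")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(p_value=p, statistic=stat, df=df, method="chi2_gof")


def fisher_exact_2x2(
    table: Sequence[Sequence[int]], alternative: str = "two-sided"
) -> TestResult:
    """Fisher's exact test on a 2x2 table by hypergeometric enumeration.

    Conditions on both margins; the two-sided p-value sums the
    probabilities of all tables no more probable than the observed one.
    A zero margin makes the table degenerate and p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    _validate_counts(t.ravel(), "table")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    t = t.astype(int)
    n = int(t.sum())
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return TestResult(p_value=1.0, method="fisher_exact_2x2")
    x = int(t[0, 0])
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = sps.hypergeom.logpmf(support, n, c1, r1)
    log_obs = float(sps.hypergeom.logpmf(x, n, c1, r1))
    if alternative == "greater":
        p = float(np.exp(logpmf[support >= x]).sum())
    elif alternative == "less":
        p = float(np.exp(logpmf[support <= x]).sum())
    else:
        keep = logpmf <= log_obs + math.log1p(_REL_TOL)
        p = float(np.exp(logpmf[keep]).sum())
    return TestResult(p_value=_clip_p(p), method="fisher_exact_2x2")


def _row_fills(total: int, caps: Sequence[int]) -> Iterator[tuple[int, ...]]:
    """All ways to write ``total`` as a sum over cells with per-cell caps."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    first_max = min(total, caps[0])
    first_min = max(0, total - sum(caps[1:]))
    for v in range(first_min, first_max + 1):
        for rest in _row_fills(total - v, caps[1:]):
            yield (v,) + rest


def _enumerate_tables(
    row_sums: Sequence[int], col_sums: Sequence[int]
) -> Iterator[tuple[tuple[int, ...], ...]]:
    """All contingency tables with the given margins, depth-first by row."""

    def recurse(rows_left: Sequence[int], cols_left: list[int]):
        if len(rows_left) == 1:
            yield (tuple(cols_left),)
            return
        for fill in _row_fills(rows_left[0], cols_left):
            remaining = [c - f for c, f in zip(cols_left, fill)]
            for rest in recurse(rows_left[1:], remaining):
                yield (fill,) + rest

    yield from recurse(list(row_sums), list(col_sums))


def _log_table_prob(
    cells: np.ndarray, log_margin_const: float
) -> float:
    return log_margin_const - float(sum(math.lgamma(v + 1) for v in cells.ravel()))


def fisher_exact_rxc(
    table: Sequence[Sequence[int]],
    monte_carlo: int | None = None,
    seed: int | None = None,
) -> TestResult:
    """Fisher's exact test on an r x c table by complete enumeration.

    Sums the multivariate-hypergeometric probabilities of every table
    with the observed margins that is no more probable than the observed
    table.  If the number of candidate tables would exceed
    :data:`MAX_TABLES`, raises :class:`EnumerationLimitError` unless
    ``monte_carlo`` (a replicate count, with ``seed``) requests the
    seeded permutation fallback.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2x2")
    _validate_counts(t.ravel(), "table")
    t = t.astype(int)
    row_sums = [int(v) for v in t.sum(axis=1)]
    col_sums = [int(v) for v in t.sum(axis=0)]
    n = int(t.sum())
    if n == 0 or min(v for v in row_sums) < 0:
        return TestResult(p_value=1.0, method="fisher_exact_rxc")
    if all(v == 0 for v in row_sums[1:]) or all(v == 0 for v in col_sums[1:]):
        return TestResult(p_value=1.0, method="fisher_exact_rxc")

    log_const = (
        sum(math.lgamma(v + 1) for v in row_sums)
        + sum(math.lgamma(v + 1) for v in col_sums)
        - math.lgamma(n + 1)
    )
    log_obs = _log_table_prob(t, log_const)
    cutoff = log_obs + math.log1p(_REL_TOL)

    if monte_carlo is None:
        log_terms = []
        count = 0
        for cand in _enumerate_tables(row_sums, col_sums):
            count += 1
            if count > MAX_TABLES:
                raise EnumerationLimitError(
                    f"more than {MAX_TABLES} tables share these margins; "
                    "pass monte_carlo=<replicates> (with seed) to use the "
                    "seeded permutation fallback"
                )
            lp = _log_table_prob(np.asarray(cand), log_const)
            if lp <= cutoff:
                log_terms.append(lp)
        if not log_terms:
            return TestResult(p_value=0.0, method="fisher_exact_rxc")
        m = max(log_terms)
        p = math.exp(m) * sum(math.exp(v - m) for v in log_terms)
        return TestResult(p_value=_clip_p(p), method="fisher_exact_rxc")

    # seeded permutation Monte Carlo (R-style simulated p-value)
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(col_sums)), col_sums)
    hits = 0
    for _ in range(int(monte_carlo)):
        rng.shuffle(labels)
        sim = np.zeros_like(t)
        start = 0
        for i, r in enumerate(row_sums):
            chunk = labels[start : start + r]
            sim[i] = np.bincount(chunk, minlength=len(col_sums))
            start += r
        if _log_table_prob(sim, log_const) <= cutoff:
            hits += 1
    p = (hits + 1) / (int(monte_carlo) + 1)
    return TestResult(p_value=p, method="fisher_exact_rxc_mc")


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test by the probability-ordering rule."""
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        return TestResult(p_value=1.0, method="binomial_two_sided")
    support = np.arange(n + 1)
    logpmf = sps.binom.logpmf(support, n, p0)
    keep = logpmf <= logpmf[k] + math.log1p(_REL_TOL)
    p = float(np.exp(logpmf[keep]).sum())
    return TestResult(p_value=_clip_p(p), method="binomial_two_sided")


def two_sample_t(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sample t test (pooled Student by default, Welch optional)."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must contain at least 2 observations")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("both samples have zero variance")
    n1, n2 = a.size, b.size
    diff = a.mean() - b.mean()
    if welch:
        se2 = v1 / n1 + v2 / n2
        stat = diff / math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        method = "welch_t"
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        stat = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        method = "student_t"
    p = float(2.0 * sps.t.sf(abs(stat), df))
    return TestResult(p_value=min(p, 1.0), statistic=float(stat), df=float(df), method=method)
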