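"""Overlap statistics for gene-set enrichment.

Implements the asymmetric fixed-set / comparator-set overlap analysis used to
compare stem-cell gene signatures against disease interactomes and phenotype
annotation sets: expected overlap under uniform sampling, its finite-population
standard deviation, an enrichment Z-score, exact Fisher p-values, and odds
ratios (sample or conditional-MLE under the noncentral hypergeometric) with
confidence intervals.

Notation, throughout: a universe of ``N`` genes, a fixed set of size ``K``, a
comparator set of size ``n``, and an observed overlap ``a``. Under the null
hypothesis that the comparator is a uniform draw of ``n`` genes, ``a`` follows
a (central) hypergeometric distribution with mean ``n*K/N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "OverlapResult",
    "OddsRatioResult",
    "expected_overlap",
    "overlap_sd",
    "enrichment_z",
    "fisher_p",
    "odds_ratio",
    "bh_adjust",
    "enrich",
    "results_to_frame",
    "write_results_tsv",
]

# Below this universe size, Fisher tails are summed with exact integer
# combinatorics; above it, in log space (gammaln).
_EXACT_N = 500

RESULT_COLUMNS = [
    "fixed_set", "comparator_set", "N", "K", "n",
    "observed", "expected", "sd", "z",
    "p_greater", "p_two_sided",
    "or", "or_lo", "or_hi",
    "sd_model", "or_method", "or_flags",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of a fixed set vs a comparator set over a shared universe.

    ``a`` in both, ``b`` fixed only, ``c`` comparator only, ``d`` neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"cell {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"cell {name} must be >= 0, got {v}")
        if self.N < 1:
            raise ValueError("universe size N = a+b+c+d must be >= 1")

    @property
    def N(self) -> int:
        return int(self.a) + int(self.b) + int(self.c) + int(self.d)

    @property
    def K(self) -> int:
        """Fixed-set size (first row margin)."""
        return int(self.a) + int(self.b)

    @property
    def n(self) -> int:
        """Comparator size (first column margin)."""
        return int(self.a) + int(self.c)


@dataclass(frozen=True)
class OddsRatioResult:
    point: float
    ci_low: float
    ci_high: float
    method: str
    open_lower: bool = False
    open_upper: bool = False
    degenerate: bool = False
    corrected: bool = False  # Haldane-Anscombe +0.5 applied (sample method)

    def flags(self) -> str:
        out = []
        if self.open_lower:
            out.append("open_lower")
        if self.open_upper:
            out.append("open_upper")
        if self.degenerate:
            out.append("degenerate")
        if self.corrected:
            out.append("haldane")
        return ",".join(out) if out else "-"


@dataclass(frozen=True)
class OverlapResult:
    """Full report for one fixed-vs-comparator overlap test."""

    fixed_name: str
    comparator_name: str
    N: int
    K: int
    n: int
    observed: int
    expected: float
    sd: float
    z: float
    p_greater: float
    p_two_sided: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    sd_model: str
    or_method: str
    or_result: OddsRatioResult = field(repr=False, compare=False, default=None)

    def to_row(self) -> dict:
        return {
            "fixed_set": self.fixed_name,
            "comparator_set": self.comparator_name,
            "N": self.N, "K": self.K, "n": self.n,
            "observed": self.observed,
            "expected": self.expected, "sd": self.sd, "z": self.z,
            "p_greater": self.p_greater, "p_two_sided": self.p_two_sided,
            "or": self.odds_ratio,
            "or_lo": self.or_ci_low, "or_hi": self.or_ci_high,
            "sd_model": self.sd_model, "or_method": self.or_method,
            "or_flags": self.or_result.flags() if self.or_result else "-",
        }


# ---------------------------------------------------------------------------
# Moments of the null overlap distribution
# ---------------------------------------------------------------------------

def expected_overlap(K: int, n: int, N: int) -> float:
    """Expected overlap ``(K/N) * n``: fixed-set frequency times comparator size."""
    if N < 1:
        raise ValueError("universe size N must be >= 1")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    return (K / N) * n


def overlap_sd(K: int, n: int, N: int, model: str = "hypergeometric") -> float:
    """SD of the null overlap count.

    hypergeometric (default): sqrt(n p (1-p) (N-n)/(N-1)) with p = K/N — the
    finite-population SD matching the hypergeometric mean used by
    :func:`expected_overlap`. binomial: sqrt(n p (1-p)), sampling with
    replacement.
    """
    if N < 1:
        raise ValueError("universe size N must be >= 1")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    p = K / N
    if model == "hypergeometric":
        if N == 1:
            return 0.0
        var = n * p * (1.0 - p) * (N - n) / (N - 1)
    elif model == "binomial":
        var = n * p * (1.0 - p)
    else:
        raise ValueError(f"unknown SD model {model!r}")
    return math.sqrt(max(var, 0.0))


def enrichment_z(observed: float, expected: float, sd: float) -> float:
    """Standardized deviation (observed - expected) / SD(observed).

    With sd == 0 the statistic is degenerate: returns 0.0 when observed equals
    expected, otherwise a signed infinity.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    diff = observed - expected
    if sd == 0.0:
        if diff == 0:
            return 0.0
        return math.inf if diff > 0 else -math.inf
    return diff / sd


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def _support(N: int, K: int, n: int) -> tuple[int, int]:
    return max(0, n + K - N), min(K, n)


def _fisher_exact_int(table: ContingencyTable, sidedness: str) -> float:
    """Exact-rational tail sums via integer combinatorics (small N)."""
    N, K, n, a = table.N, table.K, table.n, int(table.a)
    kmin, kmax = _support(N, K, n)
    counts = [math.comb(K, k) * math.comb(N - K, n - k)
              for k in range(kmin, kmax + 1)]
    total = math.comb(N, n)
    if sidedness == "greater":
        num = sum(counts[a - kmin:])
    elif sidedness == "less":
        num = sum(counts[: a - kmin + 1])
    elif sidedness == "two_sided":
        point = counts[a - kmin]
        num = sum(c for c in counts if c <= point)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return float(Fraction(num, total))


def _fisher_log(table: ContingencyTable, sidedness: str) -> float:
    """Log-space tail sums for large universes."""
    N, K, n, a = table.N, table.K, table.n, int(table.a)
    ks, base = _log_weights(N, K, n)
    logpmf = base - _log_binom(N, n)
    i = a - ks[0]
    if sidedness == "greater":
        return float(min(1.0, math.exp(logsumexp(logpmf[i:]))))
    if sidedness == "less":
        return float(min(1.0, math.exp(logsumexp(logpmf[: i + 1]))))
    if sidedness == "two_sided":
        # minimum-likelihood rule with a relative tie tolerance
        cutoff = logpmf[i] + math.log1p(1e-7)
        sel = logpmf[logpmf <= cutoff]
        return float(min(1.0, math.exp(logsumexp(sel))))
    raise ValueError(f"unknown sidedness {sidedness!r}")


def fisher_p(table: ContingencyTable, sidedness: str = "greater") -> float:
    """Exact Fisher p-value for a 2x2 table.

    ``greater``/``less`` are the hypergeometric tails of the overlap count;
    ``two_sided`` sums all tables (same margins) whose point probability does
    not exceed that of the observed one.
    """
    if table.N <= _EXACT_N:
        return _fisher_exact_int(table, sidedness)
    return _fisher_log(table, sidedness)


# ---------------------------------------------------------------------------
# Noncentral hypergeometric machinery (odds-ratio inference)
# ---------------------------------------------------------------------------

def _log_binom(m, k):
    m = np.asarray(m, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)


@lru_cache(maxsize=256)
def _log_weights(N: int, K: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Support ks and log[C(K,k) C(N-K,n-k)] over it (cached per margins)."""
    kmin, kmax = _support(N, K, n)
    ks = np.arange(kmin, kmax + 1)
    base = _log_binom(K, ks) + _log_binom(N - K, n - ks)
    ks.setflags(write=False)
    base.setflags(write=False)
    return ks, base


def nchg_pmf(N: int, K: int, n: int, log_odds: float) -> tuple[np.ndarray, np.ndarray]:
    """Fisher noncentral hypergeometric pmf over its support, given log(odds)."""
    ks, base = _log_weights(N, K, n)
    w = base + ks * log_odds
    w = w - logsumexp(w)
    return ks, np.exp(w)


def _nchg_mean(N, K, n, log_odds):
    ks, p = nchg_pmf(N, K, n, log_odds)
    return float(np.dot(ks, p))


def _nchg_sf(a, N, K, n, log_odds):
    """P(A >= a) under the noncentral hypergeometric."""
    ks, p = nchg_pmf(N, K, n, log_odds)
    return float(p[ks >= a].sum())


def _nchg_cdf(a, N, K, n, log_odds):
    ks, p = nchg_pmf(N, K, n, log_odds)
    return float(p[ks <= a].sum())


def _solve_increasing(fn, target, lo=-40.0, hi=40.0, limit=700.0):
    """Root of fn(t) = target for fn monotone increasing in t (expanding bracket)."""
    while fn(lo) > target and lo > -limit:
        lo *= 2
    while fn(hi) < target and hi < limit:
        hi *= 2
    if fn(lo) > target or fn(hi) < target:
        raise ArithmeticError("bracket expansion failed")
    return brentq(lambda t: fn(t) - target, lo, hi, xtol=1e-12, rtol=1e-12)


def odds_ratio(table: ContingencyTable, method: str = "cmle",
               alpha: float = 0.05) -> OddsRatioResult:
    """Odds ratio with a 100(1-alpha)% confidence interval.

    ``sample``: (a d)/(b c), with a Haldane–Anscombe +0.5 on every cell when
    any cell is zero, and a Wald CI on the log odds ratio.

    ``cmle``: conditional maximum likelihood under the Fisher noncentral
    hypergeometric (margins fixed), CI by inverting one-sided exact tests at
    alpha/2 per side. Overlap at its margin-feasible maximum (minimum) gives an
    open upper (lower) bound.
    """
    a, b, c, d = int(table.a), int(table.b), int(table.c), int(table.d)
    if table.K == 0 or table.n == 0 or (b + d) == 0 or (c + d) == 0:
        # a zero margin: the association is undefined whatever the method
        return OddsRatioResult(math.nan, math.nan, math.nan, method,
                               degenerate=True)
    if method == "sample":
        corrected = 0 in (a, b, c, d)
        if corrected:
            af, bf, cf, df = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            af, bf, cf, df = float(a), float(b), float(c), float(d)
        point = (af * df) / (bf * cf)
        se = math.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
        from scipy.stats import norm
        zq = norm.ppf(1 - alpha / 2)
        lo = point * math.exp(-zq * se)
        hi = point * math.exp(zq * se)
        return OddsRatioResult(point, lo, hi, "sample", corrected=corrected)

    if method != "cmle":
        raise ValueError(f"unknown odds-ratio method {method!r}")

    N, K, n = table.N, table.K, table.n
    kmin, kmax = _support(N, K, n)
    if kmin == kmax:
        return OddsRatioResult(math.nan, 0.0, math.inf, "cmle", degenerate=True)

    at_min, at_max = a == kmin, a == kmax
    # point estimate: odds at which E[A] = a
    if at_min:
        point = 0.0
    elif at_max:
        point = math.inf
    else:
        t = _solve_increasing(lambda t: _nchg_mean(N, K, n, t), float(a))
        point = math.exp(t)

    # lower limit: odds with P(A >= a) = alpha/2 (sf increases with odds)
    if at_min:
        lo = 0.0
    else:
        t = _solve_increasing(lambda t: _nchg_sf(a, N, K, n, t), alpha / 2)
        lo = math.exp(t)
    # upper limit: odds with P(A <= a) = alpha/2 (cdf decreases with odds)
    if at_max:
        hi = math.inf
    else:
        t = _solve_increasing(lambda t: -_nchg_cdf(a, N, K, n, t), -(alpha / 2))
        hi = math.exp(t)
    return OddsRatioResult(point, lo, hi, "cmle",
                           open_lower=at_min, open_upper=at_max)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    pvals = list(pvalues)
    if not pvals:
        return []
    arr = np.asarray(pvals, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in adj]


# ---------------------------------------------------------------------------
# One-pass enrichment
# ---------------------------------------------------------------------------

def enrich(fixed, comparator, universe, *, sd_model: str = "hypergeometric",
           or_method: str = "cmle", alpha: float = 0.05) -> OverlapResult:
    """Full overlap report for a fixed set vs a comparator over a universe.

    Both sets must already be restricted to ``universe``
    (see :func:`hscnet.core_sets.restrict_universe`).
    """
    from .core_sets import overlap_counts  # deferred: avoids import cycle

    table = overlap_counts(fixed, comparator, universe)
    return enrich_table(table, fixed_name=fixed.name,
                        comparator_name=comparator.name,
                        sd_model=sd_model, or_method=or_method, alpha=alpha)


def enrich_table(table: ContingencyTable, *, fixed_name: str = "fixed",
                 comparator_name: str = "comparator",
                 sd_model: str = "hypergeometric", or_method: str = "cmle",
                 alpha: float = 0.05) -> OverlapResult:
    """As :func:`enrich` but starting from a ready 2x2 table."""
    N, K, n, a = table.N, table.K, table.n, int(table.a)
    exp = expected_overlap(K, n, N)
    sd = overlap_sd(K, n, N, model=sd_model)
    z = enrichment_z(a, exp, sd)
    orr = odds_ratio(table, method=or_method, alpha=alpha)
    return OverlapResult(
        fixed_name=fixed_name, comparator_name=comparator_name,
        N=N, K=K, n=n, observed=a, expected=exp, sd=sd, z=z,
        p_greater=fisher_p(table, "greater"),
        p_two_sided=fisher_p(table, "two_sided"),
        odds_ratio=orr.point, or_ci_low=orr.ci_low, or_ci_high=orr.ci_high,
        sd_model=sd_model, or_method=or_method, or_result=orr,
    )


def results_to_frame(results: Iterable[OverlapResult]) -> pd.DataFrame:
    rows = [r.to_row() for r in results]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_tsv(results: Iterable[OverlapResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
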