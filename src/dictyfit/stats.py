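"""Rank statistics and interval summaries used throughout the pipeline.

Self-contained implementations of Spearman correlation, Kruskal-Wallis
("ANOVA on ranks"), Dunn's pairwise post-hoc test, the Mann-Whitney U test
and highest-posterior-density intervals.  All rank procedures use average
ranks for ties and tie-corrected variances; every test offers an exact
(enumeration) p-value at small sample sizes in addition to the usual
large-sample approximation.  Exact enumeration keeps these functions
verifiable against brute-force oracles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined for the data (e.g. all values tied)."""


@dataclass(frozen=True)
class CorrelationResult:
    """Rank-correlation outcome: coefficient, p-value and sample size."""

    rho: float
    p_value: float
    n: int
    method: str = "spearman"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho out of [-1, 1]: {self.rho}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a rank-based hypothesis test."""

    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    tie_correction: float
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if not 0.0 < self.tie_correction <= 1.0:
            raise ValueError(f"tie correction out of (0, 1]: {self.tie_correction}")


def _rankdata(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    return _sps.rankdata(np.asarray(x, dtype=float), method="average")


def _tie_sum(ranks_source: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled values."""
    _, counts = np.unique(np.asarray(ranks_source, dtype=float), return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman_rho(x, y, method: str = "auto") -> CorrelationResult:
    """Spearman rank-order correlation with tie handling.

    rho is the Pearson correlation of average ranks.  The p-value comes from
    the t approximation with n - 2 degrees of freedom, or from exact
    enumeration of all rank permutations for n <= 8 (``method='auto'``).

    Parameters
    ----------
    x, y : array-like, equal length n >= 3.
    method : {'auto', 'exact', 'approx'}

    Raises
    ------
    DegenerateDataError
        If either vector is constant (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a Spearman p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input vector: rho is undefined")

    rx, ry = _rankdata(x), _rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = min(1.0, max(-1.0, rho))

    exact = method == "exact" or (method == "auto" and n <= 8)
    if exact:
        p = _spearman_exact_p(rx, ry, rho)
        used = "spearman-exact"
    else:
        p = _spearman_t_p(rho, n)
        used = "spearman-t"
    return CorrelationResult(rho=rho, p_value=p, n=n, method=used)


def _spearman_t_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * _sps.t.sf(abs(t), df=n - 2))


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p: share of y-rank permutations with |rho| >= |obs|."""
    n = rx.size
    sx = rx - rx.mean()
    denom_x = math.sqrt(float(sx @ sx))
    hits = 0
    total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        yp = ry[list(perm)]
        sy = yp - yp.mean()
        denom = denom_x * math.sqrt(float(sy @ sy))
        r = float(sx @ sy) / denom
        if abs(r) >= thresh:
            hits += 1
        total += 1
    return hits / total


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _kw_h(pooled: np.ndarray, sizes: list[int]) -> tuple[float, float]:
    """Tie-corrected H for pooled values split consecutively by sizes."""
    N = pooled.size
    ranks = _rankdata(pooled)
    h = 0.0
    start = 0
    for n_i in sizes:
        rbar = ranks[start:start + n_i].mean()
        h += n_i * (rbar - (N + 1) / 2.0) ** 2
        start += n_i
    h *= 12.0 / (N * (N + 1))
    correction = 1.0 - _tie_sum(pooled) / (N**3 - N)
    return h, correction


def kruskal_wallis(groups, method: str = "auto") -> RankTestResult:
    """Kruskal-Wallis H test ("ANOVA on ranks") with tie correction.

    p comes from the chi-square approximation (df = k - 1); for total
    N <= 10 an exact permutation p is computed instead when
    ``method='auto'`` or ``'exact'``.

    Raises
    ------
    DegenerateDataError
        If all values across all groups are identical.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [a.size for a in arrays]
    if min(sizes) < 1:
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate(arrays)
    N = pooled.size
    if N < 3:
        raise ValueError("need total N >= 3")
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical across groups")

    h_obs, corr = _kw_h(pooled, sizes)
    h_obs /= corr
    df = len(sizes) - 1

    exact = method == "exact" or (method == "auto" and N <= 10)
    if exact:
        p = _kw_exact_p(pooled, sizes, h_obs)
        used = "kruskal-wallis-exact"
    else:
        p = float(_sps.chi2.sf(h_obs, df))
        used = "kruskal-wallis-chi2"
    return RankTestResult(statistic=h_obs, p_value=p,
                          n_per_group=tuple(sizes), tie_correction=corr,
                          method=used)


def _partitions(indices: tuple[int, ...], sizes: list[int]):
    """Yield all distinct splits of `indices` into ordered groups of `sizes`."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for head in itertools.combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in set(head))
        for tail in _partitions(rest, sizes[1:]):
            yield (head,) + tail


def _kw_exact_p(pooled: np.ndarray, sizes: list[int], h_obs: float) -> float:
    hits = 0
    total = 0
    thresh = h_obs - 1e-9
    for split in _partitions(tuple(range(pooled.size)), sizes):
        perm = np.concatenate([pooled[list(part)] for part in split])
        h, corr = _kw_h(perm, sizes)
        if h / corr >= thresh:
            hits += 1
        total += 1
    return hits / total


# ---------------------------------------------------------------------------
# Dunn's pairwise post-hoc test
# ---------------------------------------------------------------------------

def dunn_pairwise(groups, adjust: str = "none") -> np.ndarray:
    """Dunn's z tests on pooled tie-corrected ranks for every pair of groups.

    Returns a symmetric (k x k) matrix of two-sided p-values with unit
    diagonal.  ``adjust='holm'`` applies a Holm step-down correction over the
    k(k-1)/2 comparisons.
    """
    if adjust not in ("none", "holm"):
        raise ValueError("adjust must be 'none' or 'holm'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = _rankdata(pooled)
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(ranks[start:start + n_i].mean())
        start += n_i
    var_term = N * (N + 1) / 12.0 - _tie_sum(pooled) / (12.0 * (N - 1))

    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        se = math.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0.0:
            raw.append(1.0)
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw.append(float(2.0 * _sps.norm.sf(abs(z))))
    if adjust == "holm":
        raw = list(holm_adjust(raw))

    out = np.ones((k, k))
    for (i, j), p in zip(pairs, raw):
        out[i, j] = out[j, i] = p
    return out


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment; monotone and >= the raw p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(a, b, method: str = "auto") -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    U is the number of (a, b) pairs with a > b (ties count 1/2).  The p-value
    is exact (enumeration of all group assignments) for n_a + n_b <= 12,
    otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    N = n1 + n2
    pooled = np.concatenate([a, b])
    u_obs = _u_stat(pooled, n1)
    mid = n1 * n2 / 2.0

    exact = method == "exact" or (method == "auto" and N <= 12)
    if exact:
        thresh = abs(u_obs - mid) - 1e-9
        hits = total = 0
        idx = tuple(range(N))
        for pick in itertools.combinations(idx, n1):
            sel = np.zeros(N, dtype=bool)
            sel[list(pick)] = True
            u = _u_stat(np.concatenate([pooled[sel], pooled[~sel]]), n1)
            if abs(u - mid) >= thresh:
                hits += 1
            total += 1
        p = hits / total
        used = "mann-whitney-exact"
        corr = 1.0
    else:
        tie = _tie_sum(pooled)
        var = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
        if var == 0.0:
            raise DegenerateDataError("all values identical: U variance is zero")
        corr = 1.0 - tie / (N**3 - N)
        dev = max(0.0, abs(u_obs - mid) - 0.5)  # continuity correction
        z = dev / math.sqrt(var)
        p = float(min(1.0, 2.0 * _sps.norm.sf(z)))
        used = "mann-whitney-normal"
    return RankTestResult(statistic=u_obs, p_value=p, n_per_group=(n1, n2),
                          tie_correction=corr, method=used)


def _u_stat(pooled: np.ndarray, n1: int) -> float:
    a, b = pooled[:n1], pooled[n1:]
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


# ---------------------------------------------------------------------------
# Highest posterior density interval
# ---------------------------------------------------------------------------

def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ceil(mass * n) sorted samples.

    Width ties are broken toward the smallest lower bound.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    m = int(math.ceil(mass * n))
    widths = s[m - 1:] - s[:n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first, i.e. lowest lower bound
    return float(s[i]), float(s[i + m - 1])
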