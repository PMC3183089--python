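"""Exact and approximate null distributions for the Wilcoxon tests.

The paired signed-rank test and the two-sample rank-sum (Mann–Whitney)
test are the workhorses of the discordant-twin analysis, so they are
implemented here with explicit control over the branch taken:

* ``exact`` — the full null distribution, computed by dynamic programming
  (equivalent to enumerating every sign assignment / rank arrangement),
  valid only for tie-free data.
* ``approx`` — midrank statistic, normal approximation with tie-corrected
  variance and a 0.5 continuity correction.
* ``auto`` — exact when the sample is small and tie-free (n <= 25 for the
  signed-rank test, min(n1, n2) <= 10 for the rank-sum test), otherwise
  approx.

All functions are deterministic and vectorised variants operate row-wise
on (probes x samples) arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import ndtr  # standard normal CDF, vectorised

__all__ = [
    "signed_rank_test",
    "signed_rank_p_matrix",
    "rank_sum_test",
    "rank_sum_p_matrix",
    "SignedRankResult",
]

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_MIN_N = 10

_ALTERNATIVES = ("two-sided", "greater", "less")


# ---------------------------------------------------------------------------
# exact null distributions (dynamic programming)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _signed_rank_counts(n: int) -> np.ndarray:
    """counts[w] = number of the 2**n sign assignments with W+ == w."""
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        new = counts.copy()
        new[r:] += counts[:-r]
        counts = new
    return counts


@lru_cache(maxsize=None)
def _signed_rank_tails(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(P(W <= w), P(W >= w)) indexed by w, under the tie-free null."""
    counts = _signed_rank_counts(n)
    total = counts.sum()  # == 2**n
    lower = np.cumsum(counts) / total
    upper = np.cumsum(counts[::-1])[::-1] / total
    return lower, upper


@lru_cache(maxsize=None)
def _mann_whitney_counts(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of rank arrangements with U == u (tie-free null)."""
    if n1 == 0 or n2 == 0:
        return np.ones(1)
    out = np.zeros(n1 * n2 + 1)
    a = _mann_whitney_counts(n1 - 1, n2)
    out[n2 : n2 + a.size] += a
    b = _mann_whitney_counts(n1, n2 - 1)
    out[: b.size] += b
    return out


@lru_cache(maxsize=None)
def _mann_whitney_tails(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    counts = _mann_whitney_counts(n1, n2)
    total = counts.sum()  # == C(n1+n2, n1)
    lower = np.cumsum(counts) / total
    upper = np.cumsum(counts[::-1])[::-1] / total
    return lower, upper


def _two_sided(lower: float | np.ndarray, upper: float | np.ndarray):
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


# ---------------------------------------------------------------------------
# signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignedRankResult:
    p_value: float
    statistic: float  # W+ (sum of midranks of positive differences)
    n_used: int  # differences remaining after zeros are dropped
    method: str  # "exact", "approx" or "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _validate_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def _midranks(a: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) of a 1-D array."""
    order = np.argsort(a, kind="stable")
    ranks = np.empty(a.size)
    ranks[order] = np.arange(1, a.size + 1)
    # average over tied groups
    s = a[order]
    i = 0
    while i < s.size:
        j = i
        while j + 1 < s.size and s[j + 1] == s[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def signed_rank_full(
    diffs,
    alternative: str = "two-sided",
    method: str = "auto",
) -> SignedRankResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (classical Wilcoxon
    zero handling); if every difference is zero the test is degenerate
    and p = 1 is returned with ``method == "degenerate"``.
    """
    _validate_alternative(alternative)
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1:
        raise ValueError("diffs must be one-dimensional")
    if d.size < 6:
        raise ValueError("signed-rank test requires at least 6 differences")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return SignedRankResult(1.0, 0.0, 0, "degenerate")
    absd = np.abs(d)
    ranks = _midranks(absd)
    w = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    if method == "exact" and has_ties:
        raise ValueError("exact signed-rank distribution requires tie-free |differences|")
    use_exact = method == "exact" or (
        method == "auto" and n <= EXACT_SIGNED_RANK_MAX_N and not has_ties
    )
    if use_exact:
        lower_t, upper_t = _signed_rank_tails(n)
        wi = int(round(w))
        lower, upper = lower_t[wi], upper_t[wi]
        branch = "exact"
    else:
        mu = n * (n + 1) / 4.0
        # tie correction: subtract sum(t^3 - t)/48 from the tie-free variance
        _, counts = np.unique(absd, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            ((counts**3 - counts).sum()) / 48.0
        )
        if var <= 0:
            return SignedRankResult(1.0, w, n, "degenerate")
        sd = np.sqrt(var)
        # continuity correction of 0.5 toward the mean
        lower = float(ndtr((w - mu + 0.5) / sd))
        upper = float(1.0 - ndtr((w - mu - 0.5) / sd))
        branch = "approx"
    if alternative == "greater":
        p = upper
    elif alternative == "less":
        p = lower
    else:
        p = float(_two_sided(lower, upper))
    return SignedRankResult(min(1.0, float(p)), w, n, branch)


def signed_rank_test(diffs, alternative: str = "two-sided", method: str = "auto") -> float:
    """p-value of :func:`signed_rank_full` (degenerate all-zero input -> 1.0)."""
    return signed_rank_full(diffs, alternative=alternative, method=method).p_value


# ---------------------------------------------------------------------------
# vectorised signed-rank over rows of a (probes x pairs) matrix
# ---------------------------------------------------------------------------

def _rankdata_rows(a: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(a, axis=1)


def _row_tie_sums(a: np.ndarray) -> np.ndarray:
    """sum over tied groups of (t^3 - t), per row.

    Uses the identity sum_g t^3 = sum_j c_j^2 where c_j is the number of
    entries in row equal to entry j. O(n^2) per row, fine for small n.
    """
    eq = a[:, :, None] == a[:, None, :]
    c = eq.sum(axis=2).astype(float)
    return (c**2).sum(axis=1) - a.shape[1]


@dataclass
class _SignedRankRows:
    """Precomputed per-row structures for repeated sign-flip evaluation."""

    ranks: np.ndarray  # midranks of |d| among nonzero entries; 0 at zeros
    nonzero: np.ndarray  # bool mask of d != 0
    n_eff: np.ndarray  # nonzero count per row
    exact_rows: np.ndarray  # bool: tie-free and n_eff in [1, EXACT...]
    mu: np.ndarray
    sd: np.ndarray  # tie-corrected approx sd (0 where degenerate)


def _prepare_signed_rank_rows(d: np.ndarray, method: str = "auto") -> _SignedRankRows:
    d = np.asarray(d, dtype=float)
    nonzero = d != 0.0
    n_eff = nonzero.sum(axis=1)
    absd = np.abs(d)
    # push zeros beyond every real value so they occupy the top ranks,
    # then zero their ranks out
    big = absd.max() + 1.0 if absd.size else 1.0
    masked = np.where(nonzero, absd, big)
    ranks = _rankdata_rows(masked)
    ranks[~nonzero] = 0.0
    # ties among the nonzero |d| of each row: c_j = multiplicity of |d_j|,
    # sum_g t^3 = sum_j c_j^2 (over nonzero j), so sum(t^3 - t) = sum c^2 - n
    both = nonzero[:, :, None] & nonzero[:, None, :]
    eq = (absd[:, :, None] == absd[:, None, :]) & both
    c = eq.sum(axis=2).astype(float)
    ties = (c**2).sum(axis=1) - n_eff
    tie_free = (c <= 1.0).all(axis=1)
    n = n_eff.astype(float)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ties / 48.0
    sd = np.sqrt(np.maximum(var, 0.0))
    if method == "approx":
        exact_rows = np.zeros(d.shape[0], dtype=bool)
    else:
        exact_rows = tie_free & (n_eff >= 1) & (n_eff <= EXACT_SIGNED_RANK_MAX_N)
    return _SignedRankRows(ranks, nonzero, n_eff, exact_rows, mu, sd)


def _signed_rank_p_from_w(
    rows: _SignedRankRows, w: np.ndarray, alternative: str
) -> np.ndarray:
    """Per-row p-values given W+ values (possibly from flipped signs)."""
    p = np.ones(w.shape[0])
    # exact rows, grouped by effective n so each table is indexed once
    for n in np.unique(rows.n_eff[rows.exact_rows]):
        sel = rows.exact_rows & (rows.n_eff == n)
        lower_t, upper_t = _signed_rank_tails(int(n))
        wi = np.rint(w[sel]).astype(int)
        lower, upper = lower_t[wi], upper_t[wi]
        p[sel] = _pick_alternative(lower, upper, alternative)
    # approx rows
    sel = ~rows.exact_rows & (rows.sd > 0)
    if sel.any():
        mu, sd = rows.mu[sel], rows.sd[sel]
        ws = w[sel]
        lower = ndtr((ws - mu + 0.5) / sd)
        upper = 1.0 - ndtr((ws - mu - 0.5) / sd)
        p[sel] = _pick_alternative(lower, upper, alternative)
    return np.minimum(p, 1.0)


def _pick_alternative(lower, upper, alternative: str):
    if alternative == "greater":
        return upper
    if alternative == "less":
        return lower
    return _two_sided(lower, upper)


def signed_rank_p_matrix(
    d: np.ndarray,
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise signed-rank p-values for a (probes x pairs) difference matrix.

    Returns ``(p, degenerate)`` where ``degenerate`` flags rows whose test
    carried no information (all differences zero, or zero approx variance).
    """
    _validate_alternative(alternative)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2:
        raise ValueError("expected a 2-D (probes x pairs) array")
    rows = _prepare_signed_rank_rows(d, method=method)
    w = np.where(d > 0, rows.ranks, 0.0).sum(axis=1)
    p = _signed_rank_p_from_w(rows, w, alternative)
    degenerate = (rows.n_eff == 0) | (~rows.exact_rows & (rows.sd == 0))
    p[degenerate] = 1.0
    return p, degenerate


# ---------------------------------------------------------------------------
# rank-sum (Mann–Whitney) test
# ---------------------------------------------------------------------------

def rank_sum_test(
    x,
    y,
    alternative: str = "two-sided",
    method: str = "auto",
) -> float:
    """Wilcoxon rank-sum / Mann–Whitney test of x vs y.

    ``alternative="greater"`` tests the alternative that x tends to exceed y.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    return float(rank_sum_p_matrix(x, y, alternative=alternative, method=method)[0])


def rank_sum_p_matrix(
    x: np.ndarray,
    y: np.ndarray,
    alternative="two-sided",
    method: str = "auto",
) -> np.ndarray:
    """Row-wise rank-sum p-values.

    Parameters
    ----------
    x, y
        Arrays of shape (rows, n1) and (rows, n2).
    alternative
        Either a single string, or a sequence of per-row strings drawn
        from {"two-sided", "greater", "less"} (used for per-probe
        directional alternatives).
    method
        "auto", "exact" or "approx" (see module docstring).
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("x and y must be 2-D with matching row counts")
    rows, n1 = x.shape
    n2 = y.shape[1]
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if isinstance(alternative, str):
        alts = np.full(rows, alternative)
    else:
        alts = np.asarray(alternative)
        if alts.shape != (rows,):
            raise ValueError("per-row alternatives must match the row count")
    for a in np.unique(alts):
        _validate_alternative(str(a))

    combined = np.concatenate([x, y], axis=1)
    ranks = _rankdata_rows(combined)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0

    tie_sums = _row_tie_sums(combined)
    tie_free = tie_sums == 0.0
    if method == "exact" and not tie_free.all():
        raise ValueError("exact rank-sum distribution requires tie-free data")
    if method == "approx":
        exact_rows = np.zeros(rows, dtype=bool)
    else:
        exact_rows = tie_free & (min(n1, n2) <= EXACT_RANK_SUM_MAX_MIN_N)
        if method == "exact":
            exact_rows = np.ones(rows, dtype=bool)

    p = np.ones(rows)
    lower = np.empty(rows)
    upper = np.empty(rows)
    if exact_rows.any():
        lower_t, upper_t = _mann_whitney_tails(n1, n2)
        ui = np.rint(u[exact_rows]).astype(int)
        lower[exact_rows] = lower_t[ui]
        upper[exact_rows] = upper_t[ui]
    approx_rows = ~exact_rows
    if approx_rows.any():
        n = n1 + n2
        mu = n1 * n2 / 2.0
        var = (n1 * n2 / 12.0) * (n + 1 - tie_sums[approx_rows] / (n * (n - 1)))
        ok = var > 0
        sd = np.sqrt(np.where(ok, var, 1.0))
        ua = u[approx_rows]
        lo = np.where(ok, ndtr((ua - mu + 0.5) / sd), 1.0)
        hi = np.where(ok, 1.0 - ndtr((ua - mu - 0.5) / sd), 1.0)
        lower[approx_rows] = lo
        upper[approx_rows] = hi
    for a in np.unique(alts):
        sel = alts == a
        p[sel] = _pick_alternative(lower[sel], upper[sel], str(a))
    return np.minimum(p, 1.0)
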