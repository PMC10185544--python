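"""Nonparametric association statistics for grade/feature integration.

The clinical question — does the 0–3 MRI compression grade separate patients
by evoked-potential abnormality? — is answered here with the four classical
rank/exact procedures used throughout the neurophysiology literature:

* :func:`fisher_exact_2x2` — exact two-sided test on a 2×2 contingency table
  (per-grade amplitude-reduction × power-loss cross-classification), computed
  with rational hypergeometric arithmetic rather than asymptotics.
* :func:`kendall_tau_b` — tie-corrected rank correlation between compression
  indices (CCR, MSCC) and evoked-potential features.
* :func:`kruskal_wallis_h` — k-sample rank test across the four MRI grades.
* :func:`mann_whitney_u` — two-sample rank test, exact for small samples.

All p-values are two-sided. Standard distribution functions (normal,
chi-square) and midranking come from :mod:`scipy.stats`; the test statistics
themselves are computed here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "fisher_exact_2x2",
    "kendall_tau_b",
    "kruskal_wallis_h",
    "mann_whitney_u",
    "correlation_band",
    "grade_association_summary",
    "benjamini_hochberg",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]`` with optional row/column labels.

    The integration layer fills this with, per MRI grade, the cross-counts of
    amplitude reduction (< cut, >= cut) against TFA power loss (< cut, >= cut).
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError(f"counts must be non-negative integers, got {v!r}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class AssociationResult:
    """A named test statistic with its two-sided p-value and sample size."""

    name: str
    statistic: float
    p_value: float
    n: int
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


# --------------------------------------------------------------------------
# Fisher's exact test
# --------------------------------------------------------------------------

def _hypergeom_pmf(k: int, r1: int, c1: int, n: int) -> Fraction:
    """Exact P(top-left cell = k) for fixed margins, as a rational number."""
    return Fraction(
        math.comb(r1, k) * math.comb(n - r1, c1 - k), math.comb(n, c1)
    )


def fisher_exact_2x2(table: ContingencyTable2x2, rel_tol: float = 1e-7) -> AssociationResult:
    """Two-sided Fisher exact test by the probability-mass rule.

    Conditional on both margins, the top-left cell follows a hypergeometric
    distribution. The two-sided p-value sums the probabilities of every
    admissible table whose probability does not exceed that of the observed
    table (the rule used by most statistical packages). All arithmetic is
    exact rational; ``rel_tol`` loosens the <= comparison so that tables tied
    with the observed one up to a relative rounding slack are included.

    A zero margin admits no alternative tables and returns p = 1.

    Returns an :class:`AssociationResult` whose statistic is the sample odds
    ratio ``(a*d)/(b*c)`` (``inf`` when ``b*c == 0`` and ``a*d > 0``).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    r1, _ = table.row_margins
    c1, _ = table.col_margins

    if a * d == 0 and b * c == 0:
        odds: float = math.nan
    elif b * c == 0:
        odds = math.inf
    else:
        odds = (a * d) / (b * c)

    if min(*table.row_margins, *table.col_margins) == 0:
        return AssociationResult("fisher_exact", odds, 1.0, n)

    k_min = max(0, c1 - (n - r1))
    k_max = min(r1, c1)
    pmf = {k: _hypergeom_pmf(k, r1, c1, n) for k in range(k_min, k_max + 1)}
    total = sum(pmf.values())
    if total != 1:  # internal normalization invariant of the exact pmf
        raise AssertionError("hypergeometric pmf does not normalize")

    p_obs = pmf[a]
    cutoff = p_obs * (1 + Fraction(rel_tol))
    p = sum(prob for prob in pmf.values() if prob <= cutoff)
    p_value = min(1.0, float(p))
    return AssociationResult("fisher_exact", odds, p_value, n)


# --------------------------------------------------------------------------
# Kendall's tau-b
# --------------------------------------------------------------------------

def _tie_sizes(v: np.ndarray) -> np.ndarray:
    _, counts = np.unique(v, return_counts=True)
    return counts[counts > 1]


def kendall_tau_b(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "asymptotic",
) -> AssociationResult:
    """Tie-corrected Kendall rank correlation with a two-tailed p-value.

    tau_b = (C - D) / sqrt((n0 - Tx) (n0 - Ty)) with n0 = n(n-1)/2 and
    Tx, Ty the number of tied pairs within x and y. The default p-value uses
    the tie-adjusted normal approximation for C - D; ``method="permutation"``
    enumerates all permutations of ``y`` (exact, restricted to n <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values are not allowed")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b undefined: one input is entirely tied")

    iu = np.triu_indices(n, k=1)
    sx = np.sign(x[:, None] - x[None, :])[iu]
    sy = np.sign(y[:, None] - y[None, :])[iu]
    c_minus_d = int(np.sum(sx * sy))

    n0 = n * (n - 1) // 2
    tx_sizes = _tie_sizes(x)
    ty_sizes = _tie_sizes(y)
    tx = int(np.sum(tx_sizes * (tx_sizes - 1) // 2))
    ty = int(np.sum(ty_sizes * (ty_sizes - 1) // 2))
    tau = c_minus_d / math.sqrt((n0 - tx) * (n0 - ty))

    if method == "permutation":
        if n > 10:
            raise ValueError("exact permutation p-value restricted to n <= 10")
        hits = 0
        total = 0
        ref = abs(tau) - 1e-12
        for perm in itertools.permutations(y):
            sp = np.sign(np.asarray(perm)[:, None] - np.asarray(perm)[None, :])[iu]
            cd = int(np.sum(sx * sp))
            t = cd / math.sqrt((n0 - tx) * (n0 - ty))
            if abs(t) >= ref:
                hits += 1
            total += 1
        p_value = hits / total
    elif method == "asymptotic":
        # tie-adjusted variance of C - D (same form as SPSS / scipy ASE)
        v0 = n * (n - 1) * (2 * n + 5)
        vt = float(np.sum(tx_sizes * (tx_sizes - 1) * (2 * tx_sizes + 5)))
        vu = float(np.sum(ty_sizes * (ty_sizes - 1) * (2 * ty_sizes + 5)))
        v1 = (
            float(np.sum(tx_sizes * (tx_sizes - 1)))
            * float(np.sum(ty_sizes * (ty_sizes - 1)))
            / (2.0 * n * (n - 1))
        )
        v2 = 0.0
        if n > 2:
            v2 = (
                float(np.sum(tx_sizes * (tx_sizes - 1) * (tx_sizes - 2)))
                * float(np.sum(ty_sizes * (ty_sizes - 1) * (ty_sizes - 2)))
                / (9.0 * n * (n - 1) * (n - 2))
            )
        var = (v0 - vt - vu) / 18.0 + v1 + v2
        if var <= 0:
            p_value = 1.0
        else:
            z = c_minus_d / math.sqrt(var)
            p_value = min(1.0, 2.0 * norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")

    return AssociationResult(
        "kendall_tau_b", tau, p_value, n, extra={"concordant_minus_discordant": c_minus_d}
    )


def correlation_band(tau: float) -> str:
    """Interpretation band for |tau|: low < 0.3 <= moderate <= 0.7 < high."""
    a = abs(tau)
    if a < 0.3:
        return "low"
    if a <= 0.7:
        return "moderate"
    return "high"


# --------------------------------------------------------------------------
# Kruskal-Wallis H
# --------------------------------------------------------------------------

def kruskal_wallis_h(groups: Sequence[Sequence[float]]) -> AssociationResult:
    """Kruskal-Wallis H across k independent samples, midranks for ties.

    H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi-square with k-1 df.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if g.size == 0:
            raise ValueError("groups must be non-empty")
        if np.isnan(g).any():
            raise ValueError("NaN values are not allowed")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = rankdata(pooled)

    h = 0.0
    start = 0
    for g in arrays:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - (n_total + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n_total * (n_total + 1))

    tie_sizes = _tie_sizes(pooled)
    correction = 1.0 - float(np.sum(tie_sizes**3 - tie_sizes)) / (n_total**3 - n_total)
    if correction == 0.0:
        raise ValueError("all pooled observations identical: H undefined")
    h /= correction
    df = len(arrays) - 1
    p_value = float(chi2.sf(h, df))
    return AssociationResult("kruskal_wallis_h", h, p_value, n_total, extra={"df": df})


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
) -> AssociationResult:
    """Two-sample Mann-Whitney U with midranks; reports min(U_x, U_y).

    ``method="exact"`` enumerates all rank assignments (permutation-exact,
    valid under ties); ``"asymptotic"`` uses the tie-corrected normal
    approximation with a 0.5 continuity correction; ``"auto"`` picks exact
    when n_x + n_y <= 12.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values are not allowed")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rx = float(ranks[:nx].sum())
    u_x = rx - nx * (nx + 1) / 2.0
    u_y = nx * ny - u_x
    u = min(u_x, u_y)

    if method == "auto":
        method = "exact" if n <= 12 else "asymptotic"

    if method == "exact":
        total = math.comb(n, nx)
        hits = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, nx):
            ux = float(ranks[list(comb)].sum()) - nx * (nx + 1) / 2.0
            if min(ux, nx * ny - ux) <= u + 1e-9:
                hits += 1
        p_value = hits / total
    elif method == "asymptotic":
        mu = nx * ny / 2.0
        tie_sizes = _tie_sizes(pooled)
        tie_term = float(np.sum(tie_sizes**3 - tie_sizes)) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p_value = 1.0
        else:
            z = (u - mu + 0.5) / math.sqrt(var)  # u <= mu, shift toward the mean
            p_value = min(1.0, 2.0 * norm.cdf(z))
    else:
        raise ValueError(f"unknown method {method!r}")

    return AssociationResult(
        "mann_whitney_u", u, p_value, n, extra={"u_x": u_x, "u_y": u_y}
    )


# --------------------------------------------------------------------------
# multiple testing (optional, not part of the source analysis)
# --------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional extra column).

    The source analysis reports raw p-values only; this adjustment is offered
    as a clearly separate, opt-in column for users who test many pairs.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_i in range(m - 1, -1, -1):
        i = order[rank_i]
        running = min(running, p[i] * m / (rank_i + 1))
        adj[i] = running
    return adj


# --------------------------------------------------------------------------
# integration summary (Table 1/2/3-style report blocks)
# --------------------------------------------------------------------------

def grade_association_summary(
    data: pd.DataFrame,
    grade_col: str = "grade",
    variables: Sequence[str] | None = None,
    grade_tables: Mapping[int, ContingencyTable2x2] | None = None,
    include_bh: bool = False,
) -> dict:
    """Assemble the full association report for one aligned patient table.

    Parameters
    ----------
    data:
        One row per patient; must contain ``grade_col`` plus the continuous
        variables (typically CCR, MSCC and the six evoked-potential features).
    variables:
        Columns to correlate; defaults to every numeric column except the
        grade.
    grade_tables:
        Optional per-grade 2×2 amplitude × power tables to test exactly.

    Returns a JSON-serialisable dict with a pairwise Kendall tau-b matrix
    (with interpretation bands), per-variable Kruskal-Wallis tests across
    grades, and per-grade Fisher exact tests.
    """
    if grade_col not in data.columns:
        raise ValueError(f"missing grade column {grade_col!r}")
    if data[grade_col].isna().any():
        raise ValueError("every patient needs a grade")
    if variables is None:
        variables = [
            c
            for c in data.columns
            if c != grade_col and pd.api.types.is_numeric_dtype(data[c])
        ]
    variables = list(variables)
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")

    k = len(variables)
    tau = np.full((k, k), np.nan)
    tau_p = np.full((k, k), np.nan)
    bands: list[list[str | None]] = [[None] * k for _ in range(k)]
    for i in range(k):
        tau[i, i] = 1.0
        bands[i][i] = "high"
        for j in range(i + 1, k):
            res = kendall_tau_b(data[variables[i]].to_numpy(), data[variables[j]].to_numpy())
            tau[i, j] = tau[j, i] = res.statistic
            tau_p[i, j] = tau_p[j, i] = res.p_value
            bands[i][j] = bands[j][i] = correlation_band(res.statistic)

    kw = {}
    grouped = [g for _, g in data.groupby(grade_col)]
    for v in variables:
        if len(grouped) >= 2:
            res = kruskal_wallis_h([g[v].to_numpy() for g in grouped])
            kw[v] = {"H": res.statistic, "p_value": res.p_value, "df": res.extra["df"]}
        else:
            kw[v] = {"H": None, "p_value": None, "df": None}

    fisher = {}
    if grade_tables:
        for grade, table in sorted(grade_tables.items()):
            res = fisher_exact_2x2(table)
            fisher[int(grade)] = {
                "counts": table.as_array().tolist(),
                "odds_ratio": None if not math.isfinite(res.statistic) else res.statistic,
                "p_value": res.p_value,
                "n": res.n,
            }

    out = {
        "variables": variables,
        "kendall_tau_b": {
            "tau": tau.tolist(),
            "p_value": tau_p.tolist(),
            "band": bands,
        },
        "kruskal_wallis": kw,
        "fisher_by_grade": fisher,
        "band_rule": "|tau| < 0.3 low; 0.3-0.7 moderate; > 0.7 high",
    }
    if include_bh:
        iu = np.triu_indices(k, k=1)
        raw = tau_p[iu]
        adj = benjamini_hochberg(raw)
        adj_m = np.full((k, k), np.nan)
        adj_m[iu] = adj
        adj_m.T[iu] = adj
        out["kendall_tau_b"]["p_value_bh"] = adj_m.tolist()
        out["bh_note"] = "Benjamini-Hochberg column is an optional extra; the primary report uses raw p-values."
    return out
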