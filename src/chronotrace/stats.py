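"""Categorical statistics: exact tests, enrichment, corrections, proportions.

These primitives back the perturbation-screen analysis (Fisher's exact tests
with Bonferroni correction within phenotype families and a BH summary FDR),
reporter-assay proportions with binomial standard errors, motif-set
hypergeometric enrichment, and the ordered log-odds "causality chain" linking
perturbation, division geometry, tissue contact and gene expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._utils import round_half_up

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "ProportionStat",
    "fisher_exact",
    "hypergeom_enrichment",
    "adjust_pvalues",
    "proportion_se",
    "odds_ratio",
    "chain_association",
    "screen_family_tests",
    "reconstruct_count",
]

# Relative slack when comparing point probabilities in the two-sided test;
# point probabilities that are equal as exact rationals must compare equal
# in floating point.
_TWO_SIDED_SLACK = 1e-12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class EnrichmentResult:
    """Outcome of a 2x2 or hypergeometric enrichment test."""

    odds_ratio: float
    log2_odds_ratio: float
    p: float
    p_adjusted: float | None = None
    method: str = "fisher_two_sided"
    correction: str = "none"
    or_continuity_corrected: bool = False
    or_defined: bool = True
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ProportionStat:
    """k successes of n with binomial SE and normal-approximation 95% CI."""

    k: int
    n: int
    p_hat: float
    se: float
    ci95: tuple[float, float]

    @property
    def percent(self) -> float:
        return round_half_up(100 * self.p_hat, 1)

    @property
    def se_percent(self) -> float:
        return round_half_up(100 * self.se, 1)


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return ContingencyTable2x2(*(int(v) for v in arr.ravel()))


def odds_ratio(table) -> tuple[float, float, bool, bool]:
    """Sample odds ratio ad/bc with Haldane–Anscombe continuity correction.

    +0.5 is added to *all* cells only when any cell is zero.  Returns
    (odds_ratio, log2_odds_ratio, continuity_applied, defined).  The OR is
    flagged undefined when a margin is empty (a whole row or column is zero),
    in which case nan is returned.
    """
    t = _as_table(table)
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return math.nan, math.nan, False, False
    cont = min(a, b, c, d) == 0
    if cont:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    return orr, math.log2(orr), cont, True


def _hypergeom_pmf_support(n_total: int, row1: int, col1: int):
    """PMF of table cell ``a`` over its support for fixed margins.

    Computed from log-gamma binomial coefficients; exact enumeration of the
    conditional (hypergeometric) distribution underlying Fisher's test.
    """
    lo = max(0, col1 - (n_total - row1))
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)

    def logc(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    logpmf = (
        logc(row1, ks)
        + logc(n_total - row1, col1 - ks)
        - logc(n_total, col1)
    )
    return ks, np.exp(logpmf)


def fisher_exact(table, alternative: str = "two_sided") -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p-value sums the point probabilities of all tables (with
    the observed margins) whose probability does not exceed the observed
    one, allowing a 1e-12 relative slack so that exact rational ties are
    honored in floating point.  One-sided alternatives sum the upper
    (``greater``: group 1 more in column 1) or lower tail.

    A table with an empty margin carries no information: p = 1 and the odds
    ratio is flagged undefined.
    """
    if alternative not in {"greater", "less", "two_sided"}:
        raise ValueError(f"unknown alternative: {alternative!r}")
    t = _as_table(table)
    orr, log2or, cont, defined = odds_ratio(t)
    method = f"fisher_{alternative}" if alternative != "two_sided" else "fisher_two_sided"
    row1, col1, n_total = t.a + t.b, t.a + t.c, t.total
    if row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        return EnrichmentResult(orr, log2or, 1.0, method=method,
                                or_continuity_corrected=cont, or_defined=defined)
    ks, pmf = _hypergeom_pmf_support(n_total, row1, col1)
    p_obs = pmf[ks == t.a][0]
    if alternative == "greater":
        p = float(pmf[ks >= t.a].sum())
    elif alternative == "less":
        p = float(pmf[ks <= t.a].sum())
    else:
        p = float(pmf[pmf <= p_obs * (1 + _TWO_SIDED_SLACK)].sum())
    p = min(1.0, p)
    return EnrichmentResult(orr, log2or, p, method=method,
                            or_continuity_corrected=cont, or_defined=defined)


def hypergeom_enrichment(
    overlap: int, set_a: int, set_b: int, universe: int
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment P(X >= overlap).

    ``set_a`` and ``set_b`` are the sizes of two subsets of ``universe``;
    ``overlap`` their observed intersection.  Equivalent to
    ``fisher_exact(greater)`` on the induced 2x2 table
    [[overlap, set_a - overlap], [set_b - overlap, universe - set_a - set_b
    + overlap]]; the log2 odds ratio is computed from that table with the
    same continuity handling.
    """
    if not (0 <= overlap <= min(set_a, set_b) <= universe):
        raise ValueError("inconsistent counts: need 0 <= overlap <= min(set_a, set_b) <= universe")
    if set_a + set_b - overlap > universe:
        raise ValueError("set union exceeds universe")
    induced = ContingencyTable2x2(
        overlap, set_a - overlap, set_b - overlap, universe - set_a - set_b + overlap
    )
    orr, log2or, cont, defined = odds_ratio(induced)
    if not defined:
        # empty-margin induced tables are legitimate here (e.g. target =
        # background): continuity on all cells yields the uninformative OR 1
        a, b = induced.a + 0.5, induced.b + 0.5
        c, d = induced.c + 0.5, induced.d + 0.5
        orr = (a * d) / (b * c)
        log2or = math.log2(orr)
        cont, defined = True, True
    p = float(hypergeom.sf(overlap - 1, universe, set_b, set_a))
    p = min(1.0, max(0.0, p))
    return EnrichmentResult(orr, log2or, p, method="hypergeometric_upper",
                            or_continuity_corrected=cont, or_defined=defined)


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, m*p).  ``bh``: Benjamini–Hochberg step-up with
    enforced monotonicity (statsmodels' ``fdr_bh``).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction method: {method!r}")
    return multipletests(p, method=key)[1]


def proportion_se(k: int, n: int) -> ProportionStat:
    """Binomial proportion with SE = sqrt(p(1-p)/n) and normal 95% CI."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p_hat = k / n
    se = math.sqrt(p_hat * (1 - p_hat) / n)
    half = 1.959963984540054 * se
    return ProportionStat(k, n, p_hat, se, (max(0.0, p_hat - half), min(1.0, p_hat + half)))


def reconstruct_count(percent_value: float, n: int, audit: list | None = None) -> int:
    """Recover an integer count from a printed percentage: round(p*n).

    Figures often print proportions as percentages; the underlying count is
    reconstructed as the nearest integer, with an audit entry recording the
    reconstruction and its residual.
    """
    k = int(round(percent_value / 100 * n))
    if audit is not None:
        audit.append({
            "percent_printed": percent_value,
            "n": n,
            "count_reconstructed": k,
            "percent_recomputed": round_half_up(100 * k / n, 1),
        })
    return k


def chain_association(
    observations: pd.DataFrame,
    links: Sequence[tuple[str, str]],
    correction: str = "bh",
) -> pd.DataFrame:
    """Ordered log-odds association chain over binary per-unit variables.

    Each link (upstream, downstream) names two boolean-codable columns of
    ``observations`` (one row per unit, e.g. half-embryo).  For every link
    the 2x2 cross-tabulation is tested with the two-sided Fisher exact test
    and summarized by the continuity-corrected log2 odds ratio; p-values are
    adjusted across links.  A constant variable yields an undefined OR and
    p = 1 (an empty margin carries no evidence).
    """
    rows = []
    for up, down in links:
        for col in (up, down):
            if col not in observations.columns:
                raise KeyError(f"variable {col!r} missing from observations")
        u = observations[up].astype(bool).to_numpy()
        d = observations[down].astype(bool).to_numpy()
        if u.size == 0:
            raise ValueError("no observations for link")
        tab = ContingencyTable2x2(
            int(np.sum(u & d)), int(np.sum(u & ~d)),
            int(np.sum(~u & d)), int(np.sum(~u & ~d)),
        )
        res = fisher_exact(tab, "two_sided")
        rows.append({
            "upstream": up, "downstream": down,
            "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
            "odds_ratio": res.odds_ratio,
            "log2_odds_ratio": res.log2_odds_ratio,
            "or_defined": res.or_defined,
            "p": res.p,
        })
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p"].to_numpy(), correction)
    return out


def screen_family_tests(
    counts: pd.DataFrame,
    control: str,
    positive_category: str | Iterable[str],
    condition_col: str = "condition",
    category_col: str = "category",
    count_col: str = "count",
    correction: str = "bonferroni",
    alternative: str = "two_sided",
) -> pd.DataFrame:
    """Per-condition Fisher tests against a control within a phenotype family.

    ``counts`` is long-format (condition, category, count).  Categories in
    ``positive_category`` are collapsed to "outcome yes"; each non-control
    condition is compared to ``control`` on the induced 2x2.  The correction
    (Bonferroni by default, matching screen-figure conventions) is applied
    within the family; a BH column is also reported for summary FDR displays.
    """
    if isinstance(positive_category, str):
        positive = {positive_category}
    else:
        positive = set(positive_category)
    piv = counts.pivot_table(index=condition_col, columns=category_col,
                             values=count_col, aggfunc="sum", fill_value=0)
    if control not in piv.index:
        raise KeyError(f"control condition {control!r} not in table")
    missing = positive - set(piv.columns)
    if missing:
        raise KeyError(f"positive categories not in table: {sorted(missing)}")
    pos = piv[sorted(positive)].sum(axis=1)
    tot = piv.sum(axis=1)
    ck, cn = int(pos[control]), int(tot[control])
    rows = []
    for cond in piv.index:
        if cond == control:
            continue
        k, n = int(pos[cond]), int(tot[cond])
        tab = ContingencyTable2x2(k, n - k, ck, cn - ck)
        res = fisher_exact(tab, alternative)
        stat = proportion_se(k, n)
        rows.append({
            "condition": cond, "k": k, "n": n,
            "proportion": stat.p_hat, "se": stat.se,
            "odds_ratio": res.odds_ratio,
            "log2_odds_ratio": res.log2_odds_ratio,
            "p": res.p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = adjust_pvalues(out["p"].to_numpy(), correction)
        out["fdr"] = adjust_pvalues(out["p"].to_numpy(), "bh")
    return out
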