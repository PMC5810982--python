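"""Case-control association testing for extended haplotypes.

Implements the conditional carrier odds-ratio framework: 2x2 carrier
tables with Wald confidence intervals, motif-exclusion rules (carriers of
a dominant risk motif are removed before testing other haplotypes),
z-tests on differences of log odds ratios, Fisher/chi-square tests of
Class I x Class II combinations, Bonferroni and Benjamini-Hochberg
multiplicity handling, and covariate-adjusted logistic dose regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .haplotypes import CEH, Diplotype, MotifPattern, as_pattern

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedORError(ValueError):
    """The odds ratio is undefined (structural zero margin or empty stratum)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier-status cross-tabulation: (exposed/unexposed) x (case/control)."""

    a: int  # exposed cases
    b: int  # unexposed cases
    c: int  # exposed controls
    d: int  # unexposed controls

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    """Odds ratio with Wald CI and p-value for a carrier comparison."""

    target: str
    copies: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: ContingencyTable2x2
    exclusion: Optional[str] = None
    corrected: bool = False  # Haldane-Anscombe 0.5 applied

    @property
    def log_se(self) -> float:
        return (np.log(self.ci_high) - np.log(self.ci_low)) / (2.0 * Z_95)


@dataclass
class MultiplicityContext:
    """How a family of tests is corrected for multiplicity."""

    m: int
    method: str = "benjamini-hochberg"  # or "bonferroni"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("bonferroni", "benjamini-hochberg"):
            raise ValueError(f"unknown method {self.method!r}")


def carrier_or(
    table: ContingencyTable2x2,
    target: str = "",
    copies: int = 1,
    exclusion: Optional[str] = None,
) -> AssociationResult:
    """Wald odds ratio for a 2x2 carrier table.

    ``OR = ad/bc`` with the Haldane-Anscombe correction (0.5 added to every
    cell) when any cell is zero; the 95% CI is ``exp(ln OR +/- 1.96 SE)``
    with ``SE = sqrt(1/a + 1/b + 1/c + 1/d)`` and the two-sided p-value is
    normal on ``|ln OR| / SE``.
    """
    a, b, c, d = table.cells
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise UndefinedORError(f"structural zero margin in table {table.cells}")
    corrected = 0 in table.cells
    if corrected:
        a, b, c, d = (x + 0.5 for x in table.cells)
    orr = (a * d) / (b * c)
    se = float(np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d))
    log_or = float(np.log(orr))
    lo, hi = np.exp(log_or - Z_95 * se), np.exp(log_or + Z_95 * se)
    p = float(2.0 * stats.norm.sf(abs(log_or) / se))
    p = min(p, 1.0) if p > 0 else np.nextafter(0, 1)
    return AssociationResult(
        target, copies, float(orr), float(lo), float(hi), p, table, exclusion, corrected
    )


def carrier_table(
    diplotypes: Sequence[Diplotype],
    phenotypes: Sequence[int],
    target: "CEH | MotifPattern | str",
    copies: int = 1,
    exclusion: "CEH | MotifPattern | str | None" = None,
) -> tuple[ContingencyTable2x2, int]:
    """Build the carrier table for ``copies`` copies of the target versus 0.

    Exclusion rule: an individual is removed whenever any of their
    haplotypes matches the exclusion motif without matching the target —
    so when the target itself carries the motif, carriers of the target
    stay while all *other* motif carriers are excluded. Individuals whose
    target copy count is neither 0 nor ``copies`` are left out of the table.
    Returns the table and the number of excluded individuals.
    """
    if copies not in (1, 2):
        raise ValueError("copies must be 1 or 2")
    pat = as_pattern(target)
    excl = as_pattern(exclusion) if exclusion is not None else None
    a = b = c = d = 0
    n_excluded = 0
    for dip, pheno in zip(diplotypes, phenotypes):
        if excl is not None and any(
            excl.matches(h) and not pat.matches(h) for h in dip
        ):
            n_excluded += 1
            continue
        t = pat.carried_by(dip)
        if t == copies:
            if pheno:
                a += 1
            else:
                c += 1
        elif t == 0:
            if pheno:
                b += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c, d), n_excluded


def conditional_carrier_or(
    diplotypes: Sequence[Diplotype],
    phenotypes: Sequence[int],
    target: "CEH | MotifPattern | str",
    copies: int = 1,
    exclusion: "CEH | MotifPattern | str | None" = None,
) -> AssociationResult:
    """Carrier OR for a target CEH or motif under a motif-exclusion rule."""
    table, _ = carrier_table(diplotypes, phenotypes, target, copies, exclusion)
    if table.a + table.c == 0 or table.b + table.d == 0:
        raise UndefinedORError("empty exposure stratum after exclusion")
    pat = as_pattern(target)
    excl_str = str(as_pattern(exclusion)) if exclusion is not None else None
    return carrier_or(table, target=str(pat), copies=copies, exclusion=excl_str)


def compare_or_z(
    result1: AssociationResult, result2: AssociationResult
) -> tuple[float, float]:
    """z-test on the difference of log odds ratios of two associations.

    Each SE is recovered from the 95% CI as ``(ln hi - ln lo) / (2 * 1.96)``.
    Returns (z, two-sided p).
    """
    for r in (result1, result2):
        if not (np.isfinite(r.odds_ratio) and r.odds_ratio > 0):
            raise ValueError("both odds ratios must be finite and positive")
        if r.ci_high <= r.ci_low:
            raise ValueError("degenerate confidence interval")
    se1, se2 = result1.log_se, result2.log_se
    z = float(
        (np.log(result1.odds_ratio) - np.log(result2.odds_ratio))
        / np.sqrt(se1**2 + se2**2)
    )
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return z, p


from functools import lru_cache


@lru_cache(maxsize=100_000)
def _hypergeom_pmf(n: int, col1: int, row1: int) -> tuple[int, np.ndarray]:
    """Hypergeometric pmf over the support of a 2x2 table's margins."""
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    return lo, stats.hypergeom.pmf(support, n, col1, row1)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric tables with
    probability not exceeding that of the observed table (with a 1+1e-7
    relative slack against floating-point ties)."""
    a, b, c, d = table.cells
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    row1 = a + b
    col1 = a + c
    lo, pmf = _hypergeom_pmf(n, col1, row1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def class1_class2_association(table: ContingencyTable2x2) -> tuple[float, str]:
    """Association p-value for a Class I x Class II combination cross-table.

    Uses the Fisher exact test when any expected cell frequency is 5 or
    less, and the Pearson chi-square test otherwise. Returns (p, method).
    """
    arr = table.as_array()
    n = arr.sum()
    if n == 0:
        raise ValueError("empty table")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    if np.any(expected <= 5.0):
        return fisher_exact_two_sided(table), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(p), "chi-square"


@dataclass
class AdjustedPvalues:
    """Multiplicity-adjusted p-values and per-test significance calls."""

    method: str
    alpha: float
    m: int
    raw: np.ndarray
    adjusted: np.ndarray
    significant: np.ndarray
    threshold: Optional[float] = None  # Bonferroni per-test threshold alpha/m


def adjust_pvalues(
    pvals: Sequence[float], context: MultiplicityContext
) -> AdjustedPvalues:
    """Bonferroni threshold or Benjamini-Hochberg step-up adjustment."""
    raw = np.asarray(pvals, dtype=float)
    if raw.size == 0:
        raise ValueError("empty p-value list")
    if np.any((raw <= 0) | (raw > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if context.method == "bonferroni":
        threshold = context.alpha / context.m
        adjusted = np.minimum(1.0, raw * context.m)
        significant = raw < threshold
        return AdjustedPvalues(
            context.method, context.alpha, context.m, raw, adjusted, significant, threshold
        )
    reject, adjusted, _, _ = multipletests(
        raw, alpha=context.alpha, method="fdr_bh"
    )
    return AdjustedPvalues(
        context.method, context.alpha, context.m, raw, adjusted, reject, None
    )


class RankDeficientDesignError(ValueError):
    """The regression design matrix is rank deficient."""


def dose_regression(
    phenotypes: Sequence[int],
    doses: "pd.DataFrame | Mapping[str, Sequence[int]]",
    covariates: Optional[pd.DataFrame] = None,
    regions: Optional[Sequence[str]] = None,
    interactions: bool = False,
) -> pd.DataFrame:
    """Logistic regression of case status on per-CEH dose (0/1/2).

    Covariates (principal components, sex, ...) enter as given; region
    labels are dummy-coded with the first (sorted) region dropped. With
    ``interactions=True``, pairwise products of the dose columns are added.
    Returns a coefficient table (term, coef, se, z, p, OR with 95% CI,
    estimable flag); separation is flagged, not raised, while a rank
    deficient design raises :class:`RankDeficientDesignError` naming the
    collinear columns.
    """
    import statsmodels.api as sm

    y = np.asarray(phenotypes, dtype=float)
    X = pd.DataFrame(doses).astype(float).copy()
    dose_cols = list(X.columns)
    if interactions and len(dose_cols) > 1:
        for i, u in enumerate(dose_cols):
            for v in dose_cols[i + 1 :]:
                X[f"{u}:{v}"] = X[u] * X[v]
    if covariates is not None:
        for col in covariates.columns:
            v = np.asarray(covariates[col], dtype=float)
            if np.ptp(v) == 0.0:
                continue  # constant covariates are absorbed by the intercept
            X[col] = v
    if regions is not None:
        dummies = pd.get_dummies(pd.Series(list(regions), name="region"), prefix="region")
        dummies = dummies.iloc[:, 1:]  # drop first level
        for col in dummies.columns:
            X[col] = dummies[col].astype(float).to_numpy()
    X.insert(0, "const", 1.0)

    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        bad = []
        kept: list[int] = []
        for j in range(mat.shape[1]):
            cand = kept + [j]
            if np.linalg.matrix_rank(mat[:, cand]) == len(cand):
                kept.append(j)
            else:
                bad.append(X.columns[j])
        raise RankDeficientDesignError(f"collinear design columns: {bad}")

    separated = False
    params = se = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = fit.params
            se = fit.bse
            if not np.all(np.isfinite(se)) or np.any(se > 1e3):
                separated = True
        except Exception:
            separated = True

    rows = []
    for term in X.columns:
        if separated or params is None:
            rows.append(
                {"term": term, "coef": np.nan, "se": np.nan, "z": np.nan,
                 "p": np.nan, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "estimable": False}
            )
            continue
        coef, s = float(params[term]), float(se[term])
        z = coef / s
        rows.append(
            {
                "term": term,
                "coef": coef,
                "se": s,
                "z": z,
                "p": float(2.0 * stats.norm.sf(abs(z))),
                "or": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - Z_95 * s)),
                "ci_high": float(np.exp(coef + Z_95 * s)),
                "estimable": True,
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["separated"] = separated
    return out


def dose_vector(
    diplotypes: Sequence[Diplotype], target: "CEH | MotifPattern | str"
) -> np.ndarray:
    """Per-individual copy count (0/1/2) of a CEH or motif."""
    pat = as_pattern(target)
    return np.array([pat.carried_by(d) for d in diplotypes], dtype=int)
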