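"""Homozygote-excess testing and the two-class conversion-selection model.

Two ideas live here. First, a z-test of the observed number of CEH
homozygotes against the Hardy-Weinberg expectation ``E = N q`` with
``q = sum_i f_i^2``, using the binomial variance ``N q (1 - q)`` (each
individual is homozygous with probability q independently).

Second, a two-class haplotype dynamic: haplotypes are classified "rare" or
"frequent" (observed once versus more than once), homozygous diplotypes
are class homozygotes regardless of the actual CEH, and each generation is
random union of gametes, viability selection on the three diplotype
classes ``(w_ff, w_fr, w_rr)``, and per-haplotype class conversion at
rates ``c_fr`` (frequent to rare) and ``c_rf``. Unopposed conversion
equilibrates only when the two fluxes balance; a skewed observed spectrum
plus a homozygosity deviation lets the equilibrium be inverted for the
net conversion rate and the relative survival of rare-class homozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .spectrum import FrequencySpectrum


@dataclass
class HomozygosityTest:
    """Observed versus HWE-expected count of homozygous individuals."""

    n: int
    q: float  # expected per-individual homozygosity probability
    expected: float
    observed: int
    z: float
    p_value: float


def homozygote_excess_test(
    frequencies: "Sequence[float] | FrequencySpectrum",
    observed: int,
    n: int,
) -> HomozygosityTest:
    """z-test of homozygote count against Hardy-Weinberg expectations.

    ``frequencies`` are the haplotype (or haplotype-class) frequencies from
    which ``q = sum f_i^2``; the variance is binomial, ``N q (1 - q)``.
    """
    if isinstance(frequencies, FrequencySpectrum):
        f = np.array(list(frequencies.frequencies().values()))
    else:
        f = np.asarray(frequencies, dtype=float)
    if abs(float(f.sum()) - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    if observed > n:
        raise ValueError("observed homozygotes cannot exceed N")
    q = float(np.sum(f**2))
    if q <= 0.0:
        raise ValueError("q = 0: no homozygosity is possible")
    if q >= 1.0:
        raise ValueError("q = 1: homozygote count is degenerate, z undefined")
    expected = n * q
    z = (observed - expected) / np.sqrt(n * q * (1.0 - q))
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return HomozygosityTest(n, q, float(expected), int(observed), float(z), p)


def classify_rare_frequent(spectrum: FrequencySpectrum) -> tuple[float, float]:
    """Class frequencies (p_frequent, p_rare): rare = exactly one copy."""
    tot = spectrum.total_copies
    rare = sum(c for c in spectrum.counts.values() if c == 1)
    return (tot - rare) / tot, rare / tot


@dataclass
class TwoClassModel:
    """Frequent/rare haplotype classes under selection and conversion.

    ``p_f + p_r = 1`` are the gamete class frequencies at birth; ``w_ff``
    (referent, 1), ``w_fr`` and ``w_rr`` are relative survivals of the
    diplotype classes; ``c_fr`` and ``c_rf`` are per-haplotype
    per-generation class-conversion probabilities, applied to the gamete
    output after selection.
    """

    p_f: float
    c_fr: float = 0.0
    c_rf: float = 0.0
    w_ff: float = 1.0
    w_fr: float = 1.0
    w_rr: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_f", "c_fr", "c_rf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("w_ff", "w_fr", "w_rr"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    @property
    def p_r(self) -> float:
        return 1.0 - self.p_f

    def adult_summary(self) -> dict[str, float]:
        """Post-selection adult population at the current gamete frequencies.

        Returns the adult diplotype class probabilities, the adult
        haplotype class frequencies, and the rare-rare and frequent-frequent
        homozygosity ratios relative to HWE at the *adult* frequencies —
        the observable deviation a cohort sampled after selection shows.
        """
        p, r = self.p_f, self.p_r
        w = np.array([self.w_ff, self.w_fr, self.w_rr])
        geno = np.array([p * p, 2.0 * p * r, r * r]) * w
        wbar = geno.sum()
        geno /= wbar
        adult_pf = geno[0] + 0.5 * geno[1]
        adult_pr = 1.0 - adult_pf
        out = {
            "P_ff": float(geno[0]),
            "P_fr": float(geno[1]),
            "P_rr": float(geno[2]),
            "adult_p_f": float(adult_pf),
            "adult_p_r": float(adult_pr),
            "mean_fitness": float(wbar),
        }
        out["excess_ff"] = float(geno[0] / adult_pf**2) if adult_pf > 0 else np.nan
        out["excess_rr"] = float(geno[2] / adult_pr**2) if adult_pr > 0 else np.nan
        return out


def forward_generation(model: TwoClassModel) -> TwoClassModel:
    """One generation: random union, viability selection, then conversion.

    Conserves ``p_f + p_r = 1`` exactly.
    """
    s = model.adult_summary()
    gamete_f = s["adult_p_f"]  # random union of post-selection gametes
    converted = gamete_f * (1.0 - model.c_fr) + (1.0 - gamete_f) * model.c_rf
    return replace(model, p_f=float(converted))


@dataclass
class EquilibriumResult:
    p_f: float
    boundary: bool  # True when no interior fixed point exists
    residual: float


def equilibrium_solve(model: TwoClassModel, tol: float = 1e-12) -> EquilibriumResult:
    """Fixed point of :func:`forward_generation` by bisection on p_f.

    The map is monotone in p_f, so the displacement ``g(p) = next(p) - p``
    brackets any interior fixed point; if ``g`` has no sign change on
    (0, 1) the attracting boundary is reported with a flag.
    """

    def g(p: float) -> float:
        return forward_generation(replace(model, p_f=p)).p_f - p

    eps = 1e-9
    lo, hi = eps, 1.0 - eps
    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        return EquilibriumResult(lo, False, 0.0)
    if ghi == 0.0:
        return EquilibriumResult(hi, False, 0.0)
    if glo < 0.0 and ghi < 0.0:
        return EquilibriumResult(0.0, True, abs(g(0.0)))
    if glo > 0.0 and ghi > 0.0:
        return EquilibriumResult(1.0, True, abs(g(1.0)))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if abs(gm) < tol and hi - lo < tol:
            break
        if (gm > 0) == (glo > 0):
            lo, glo = mid, gm
        else:
            hi = mid
    p_star = 0.5 * (lo + hi)
    return EquilibriumResult(float(p_star), False, abs(g(p_star)))


@dataclass
class ConversionSelectionFit:
    """Inverted (conversion rate, rare-homozygote survival) with diagnostics."""

    c: float
    w_rr: float
    residual: float
    feasible: bool
    observed_p_f: float
    observed_excess_rr: float


def _equilibrium_observables(c: float, w_rr: float) -> tuple[float, float]:
    """Adult (p_f, rare-rare homozygosity ratio) at the model equilibrium."""
    model = TwoClassModel(p_f=0.5, c_fr=c, c_rf=c, w_rr=w_rr)
    eq = equilibrium_solve(model)
    s = replace(model, p_f=eq.p_f).adult_summary()
    return s["adult_p_f"], s["excess_rr"]


def estimate_conversion_selection(
    observed_p_f: float,
    observed_excess_rr: float,
    n: Optional[int] = None,
    c_bounds: tuple[float, float] = (0.0, 0.25),
    w_bounds: tuple[float, float] = (0.2, 1.5),
    grid: int = 25,
    refinements: int = 6,
    residual_tol: float = 1e-4,
) -> ConversionSelectionFit:
    """Invert the equilibrium for (c, w_rr) from observed class data.

    Inputs are the observed adult frequent-class haplotype frequency and
    the observed rare-rare homozygote count divided by its HWE expectation
    at the adult class frequencies. Solved on a (c, w_rr) grid that is
    repeatedly zoomed around the best cell; among near-equivalent optima
    the smallest conversion rate and the survival nearest 1 win, so a
    population with no homozygosity deviation and balanced fluxes returns
    (c = 0, w_rr = 1). ``n`` only scales the reported residual tolerance
    for the feasibility flag.
    """
    if not 0.0 < observed_p_f < 1.0:
        raise ValueError("observed_p_f must lie in (0, 1)")
    if observed_excess_rr <= 0.0:
        raise ValueError("observed_excess_rr must be positive")

    # No homozygosity deviation and balanced class frequencies lie on the
    # model's unidentifiable ridge (any conversion rate with w_rr = 1 fits);
    # by convention the neutral model is reported.
    if abs(observed_excess_rr - 1.0) < 1e-9 and abs(observed_p_f - 0.5) < 1e-9:
        return ConversionSelectionFit(0.0, 1.0, 0.0, True,
                                      observed_p_f, observed_excess_rr)

    def score(c: float, w: float) -> float:
        pf, ex = _equilibrium_observables(c, w)
        return (pf - observed_p_f) ** 2 + (ex - observed_excess_rr) ** 2

    lo_c, hi_c = c_bounds
    lo_w, hi_w = w_bounds
    best = (np.inf, 0.0, 1.0)
    for _ in range(refinements):
        cs = np.linspace(lo_c, hi_c, grid)
        ws = np.linspace(lo_w, hi_w, grid)
        cells = []
        for c in cs:
            for w in ws:
                cells.append((score(float(c), float(w)), float(c), float(w)))
        smin = min(cells, key=lambda t: t[0])[0]
        # tie-break near-equivalent optima: smallest c, then w nearest 1
        near = [t for t in cells if t[0] <= smin + 1e-12]
        best = min(near, key=lambda t: (t[1], abs(t[2] - 1.0)))
        span_c = (hi_c - lo_c) / (grid - 1)
        span_w = (hi_w - lo_w) / (grid - 1)
        lo_c = max(c_bounds[0], best[1] - span_c)
        hi_c = min(c_bounds[1], best[1] + span_c)
        lo_w = max(w_bounds[0], best[2] - span_w)
        hi_w = min(w_bounds[1], best[2] + span_w)
    residual, c_hat, w_hat = best
    tol = residual_tol if n is None else max(residual_tol, 4.0 / n)
    return ConversionSelectionFit(
        c=c_hat,
        w_rr=w_hat,
        residual=float(residual),
        feasible=bool(residual <= tol),
        observed_p_f=observed_p_f,
        observed_excess_rr=observed_excess_rr,
    )


def sample_two_class_observables(
    c: float, w_rr: float, n: int, seed: int = 0
) -> tuple[float, float]:
    """Sample N adults from the model equilibrium and measure the observables.

    Used for parameter-recovery studies: draws diplotype classes from the
    post-selection equilibrium distribution and returns the empirical adult
    frequent-class frequency and rare-rare homozygosity ratio.
    """
    model = TwoClassModel(p_f=0.5, c_fr=c, c_rf=c, w_rr=w_rr)
    eq = equilibrium_solve(model)
    s = replace(model, p_f=eq.p_f).adult_summary()
    probs = np.array([s["P_ff"], s["P_fr"], s["P_rr"]])
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    n_ff, n_fr, n_rr = (int(x) for x in counts)
    p_f_hat = (2 * n_ff + n_fr) / (2 * n)
    p_r_hat = 1.0 - p_f_hat
    if p_r_hat <= 0 or n_rr == 0:
        raise ValueError("no rare-class observations in the sample")
    excess_rr = (n_rr / n) / p_r_hat**2
    return float(p_f_hat), float(excess_rr)
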