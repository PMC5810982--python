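"""Probabilistic haplotype phasing by expectation-maximization.

Unphased multi-locus genotypes (unordered allele pairs per locus) are
resolved by the classic EM estimator of haplotype frequencies: the E-step
weights each haplotype pair compatible with a genotype by
``2^[h1 != h2] * f(h1) * f(h2)`` normalized within the individual, and the
M-step re-estimates frequencies as expected haplotype dose over ``2N``.
Each individual is then assigned the most probable compatible pair, with
its posterior probability reported alongside.

The machinery is generic over loci: it phases the 11-SNP Class II window
(biallelic loci), and, after collapsing that window to one multi-allelic
"SNP-haplotype locus", the joint 6-locus extended haplotype over
HLA-A, -C, -B, -DRB1, -DQB1 and the SNP haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .haplotypes import CEH, Diplotype, HLA_LOCI, HaplotypeError

#: a genotype is one sorted unordered allele pair per locus
Genotype = tuple[tuple[str, str], ...]
#: a haplotype is one allele per locus
Hap = tuple[str, ...]


def _pair_key(h: Hap) -> str:
    return "~".join(h)


def canonical_pair(h1: Hap, h2: Hap) -> tuple[Hap, Hap]:
    """Order a haplotype pair lexicographically on the '~'-joined encoding."""
    return (h1, h2) if _pair_key(h1) <= _pair_key(h2) else (h2, h1)


def enumerate_compatible_pairs(genotype: Genotype) -> list[tuple[Hap, Hap]]:
    """All unordered haplotype pairs whose locus-wise union is the genotype.

    For k heterozygous loci there are ``max(1, 2**(k-1))`` pairs. The first
    heterozygous locus is anchored to remove the mirror-image duplicates.
    """
    for pair in genotype:
        if len(pair) != 2:
            raise HaplotypeError(f"each locus needs exactly two alleles, got {pair!r}")
    het = [i for i, (x, y) in enumerate(genotype) if x != y]
    h1 = [x for x, _ in genotype]
    h2 = [y for _, y in genotype]
    if not het:
        hom = tuple(h1)
        return [(hom, hom)]
    pairs = []
    for bits in product((0, 1), repeat=len(het) - 1):
        a, b = list(h1), list(h2)
        for locus, bit in zip(het[1:], bits):
            if bit:
                a[locus], b[locus] = b[locus], a[locus]
        pairs.append(canonical_pair(tuple(a), tuple(b)))
    return sorted(set(pairs), key=lambda p: (_pair_key(p[0]), _pair_key(p[1])))


@dataclass
class PhasingResult:
    """EM frequency estimates with per-iteration log-likelihood trace."""

    frequencies: dict[Hap, float]
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    n_individuals: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def frequency_array(self, haps: Sequence[Hap]) -> np.ndarray:
        return np.array([self.frequencies.get(h, 0.0) for h in haps])


@dataclass
class Assignment:
    """Most-likely haplotype pair for one genotype, with its posterior."""

    pair: Optional[tuple[Hap, Hap]]
    posterior: float
    assignable: bool = True


def _collapse(genotypes: Iterable[Genotype]) -> tuple[list[Genotype], np.ndarray]:
    counts: dict[Genotype, int] = {}
    for g in genotypes:
        counts[g] = counts.get(g, 0) + 1
    distinct = list(counts)
    return distinct, np.array([counts[g] for g in distinct], dtype=float)


def em_haplotype_frequencies(
    genotypes: Sequence[Genotype],
    tol: float = 1e-6,
    max_iter: int = 200,
    prune_threshold: Optional[float] = None,
    prune_after: int = 5,
) -> PhasingResult:
    """Estimate haplotype frequencies from unphased genotypes by EM.

    Haplotypes whose estimated frequency falls below ``prune_threshold``
    (default ``1/(4N)``) are dropped after iteration ``prune_after``, except
    where that would leave a genotype with no compatible pair. Stops when
    the largest frequency change is below ``tol`` or after ``max_iter``
    iterations (then flagged non-converged).
    """
    if len(genotypes) == 0:
        raise HaplotypeError("at least one genotype is required")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = len(genotypes)
    if prune_threshold is None:
        prune_threshold = 1.0 / (4.0 * n)

    distinct, g_counts = _collapse(genotypes)
    pair_lists = [enumerate_compatible_pairs(g) for g in distinct]

    hap_index: dict[Hap, int] = {}
    for pairs in pair_lists:
        for h1, h2 in pairs:
            for h in (h1, h2):
                hap_index.setdefault(h, len(hap_index))

    def build_arrays(active_pairs):
        i1 = np.array([hap_index[p[0]] for pairs in active_pairs for p in pairs])
        i2 = np.array([hap_index[p[1]] for pairs in active_pairs for p in pairs])
        gi = np.array([g for g, pairs in enumerate(active_pairs) for _ in pairs])
        mult = np.where(i1 == i2, 1.0, 2.0)
        return i1, i2, gi, mult

    active_pairs = [list(p) for p in pair_lists]
    i1, i2, gi, mult = build_arrays(active_pairs)
    k = len(hap_index)
    haps = list(hap_index)

    f = np.zeros(k)
    used = np.unique(np.concatenate([i1, i2]))
    f[used] = 1.0 / len(used)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mult * f[i1] * f[i2]
        tots = np.bincount(gi, weights=w, minlength=len(distinct))
        if np.any(tots[g_counts > 0] <= 0):
            raise HaplotypeError("zero-probability genotype during EM")
        trace.append(float(np.sum(g_counts * np.log(tots))))
        contrib = g_counts[gi] * w / tots[gi]
        dose = np.bincount(i1, weights=contrib, minlength=k) + np.bincount(
            i2, weights=contrib, minlength=k
        )
        f_new = dose / (2.0 * n)
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new

        if it == prune_after and prune_threshold > 0:
            doomed = set(np.nonzero((f > 0) & (f < prune_threshold))[0])
            if doomed:
                for g, pairs in enumerate(active_pairs):
                    alive = [
                        p
                        for p in pairs
                        if hap_index[p[0]] not in doomed and hap_index[p[1]] not in doomed
                    ]
                    if alive:
                        active_pairs[g] = alive
                    else:
                        # rescue: keep the currently most probable pair
                        best = max(
                            pairs,
                            key=lambda p: (2 - (p[0] == p[1]))
                            * f[hap_index[p[0]]]
                            * f[hap_index[p[1]]],
                        )
                        active_pairs[g] = [best]
                        doomed.discard(hap_index[best[0]])
                        doomed.discard(hap_index[best[1]])
                f[list(doomed)] = 0.0
                if f.sum() > 0:
                    f /= f.sum()
                i1, i2, gi, mult = build_arrays(active_pairs)

        if delta < tol:
            converged = True
            # record the likelihood at the final estimate as well
            w = mult * f[i1] * f[i2]
            tots = np.bincount(gi, weights=w, minlength=len(distinct))
            trace.append(float(np.sum(g_counts * np.log(tots))))
            break

    freqs = {haps[i]: float(f[i]) for i in range(k) if f[i] > 0}
    return PhasingResult(freqs, trace, converged, it, n)


def assign_best_pair(
    genotype: Genotype, frequencies: Mapping[Hap, float]
) -> Assignment:
    """Most probable compatible pair under the given frequencies.

    Pair weight is ``2^[het] * f(h1) * f(h2)``; the posterior is the weight
    normalized over all compatible pairs. Ties break lexicographically on
    the canonical pair encoding. If every compatible pair has zero weight
    the genotype is flagged unassignable.
    """
    pairs = enumerate_compatible_pairs(genotype)
    weights = []
    for h1, h2 in pairs:
        mult = 1.0 if h1 == h2 else 2.0
        weights.append(mult * frequencies.get(h1, 0.0) * frequencies.get(h2, 0.0))
    total = float(sum(weights))
    if total <= 0.0:
        return Assignment(None, 0.0, assignable=False)
    best = max(range(len(pairs)), key=lambda i: weights[i])  # first max wins ties
    return Assignment(pairs[best], weights[best] / total)


def posterior_coverage_summary(
    posteriors: Sequence[float], thresholds: Sequence[float] = (0.5, 0.6, 0.7)
) -> dict[float, float]:
    """Fraction of assignments with posterior strictly above each threshold."""
    if len(posteriors) == 0:
        raise ValueError("at least one assignment is required")
    arr = np.asarray(posteriors, dtype=float)
    return {t: float(np.mean(arr > t)) for t in thresholds}


@dataclass
class WindowScanResult:
    """Per-window association scan over EM-phased SNP windows."""

    #: (start, width, min p-value, best haplotype) per evaluated window
    windows: list[tuple[int, int, float, Optional[Hap]]]
    #: selected (start, width): smallest p, ties to smaller width then leftmost
    selected: tuple[int, int]

    @property
    def selected_p(self) -> float:
        for s, w, p, _ in self.windows:
            if (s, w) == self.selected:
                return p
        raise KeyError(self.selected)


def _carrier_min_p(
    assignments: list[Assignment], phenotype: np.ndarray, min_copies: int
) -> tuple[float, Optional[Hap]]:
    """Smallest carrier chi-square p over haplotypes with enough copies."""
    copies: dict[Hap, int] = {}
    carriers: dict[Hap, list[int]] = {}
    for i, a in enumerate(assignments):
        if not a.assignable:
            continue
        h1, h2 = a.pair
        copies[h1] = copies.get(h1, 0) + 1
        copies[h2] = copies.get(h2, 0) + 1
        carriers.setdefault(h1, []).append(i)
        if h2 != h1:
            carriers.setdefault(h2, []).append(i)
    best_p, best_h = np.inf, None
    n_cases = int(phenotype.sum())
    n_ctrl = len(phenotype) - n_cases
    for h in sorted(copies, key=_pair_key):
        if copies[h] < min_copies:
            continue
        idx = carriers[h]
        a = int(phenotype[idx].sum())  # carrier cases
        c = len(idx) - a  # carrier controls
        table = np.array([[a, n_cases - a], [c, n_ctrl - c]])
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            continue
        p = float(chi2_contingency(table, correction=False)[1])
        if p < best_p:
            best_p, best_h = p, h
    return best_p, best_h


def scan_snp_windows(
    snp_genotypes: Sequence[Genotype],
    phenotype: Sequence[int],
    widths: Sequence[int] = tuple(range(2, 16)),
    min_copies: int = 5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> WindowScanResult:
    """Slide windows of 2-15 SNPs, phase each by EM and rank by association.

    Each window is phased independently; per phased haplotype with at least
    ``min_copies`` assigned copies, a carrier-versus-noncarrier chi-square
    against case/control status is computed, and the window is scored by its
    smallest p-value. The window with the smallest score is selected, ties
    going to the smaller width and then the leftmost start.
    """
    phenotype = np.asarray(phenotype, dtype=int)
    n_snps = len(snp_genotypes[0])
    widths = [w for w in widths if w <= n_snps]
    if not widths:
        raise HaplotypeError("no window width fits the SNP list")
    results = []
    for width in sorted(widths):
        for start in range(0, n_snps - width + 1):
            sub = [g[start : start + width] for g in snp_genotypes]
            em = em_haplotype_frequencies(sub, tol=tol, max_iter=max_iter)
            assigns = [assign_best_pair(g, em.frequencies) for g in sub]
            p, hap = _carrier_min_p(assigns, phenotype, min_copies)
            results.append((start, width, p, hap))
    selected = min(results, key=lambda r: (r[2], r[1], r[0]))
    return WindowScanResult(results, (selected[0], selected[1]))


# ---------------------------------------------------------------------------
# staged extended-haplotype phasing of GenotypeRecord datasets


@dataclass
class ExtendedPhasingResult:
    """Joint 6-locus phasing of HLA loci plus the collapsed SNP haplotype."""

    snp_result: PhasingResult
    extended_result: PhasingResult
    #: sample id -> (diplotype, posterior) for assignable individuals
    assignments: dict[str, tuple[Diplotype, float]]
    #: sample ids dropped for missing calls or unassignable genotypes
    excluded: list[str]

    def ceh_frequencies(self) -> dict[CEH, float]:
        return {
            CEH(h[:5], h[5]): f for h, f in self.extended_result.frequencies.items()
        }

    def posteriors(self) -> list[float]:
        return [p for _, p in self.assignments.values()]


def snp_genotype_of(record) -> Optional[Genotype]:
    if record.snps is None:
        return None
    return tuple(tuple(pair) for pair in record.snps)


def phase_dataset(
    records: Sequence,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ExtendedPhasingResult:
    """Two-stage phasing of a GenotypeRecord dataset.

    Stage 1 phases the 11-SNP window by EM and assigns each individual its
    most probable SNP-haplotype pair. Stage 2 collapses that pair into one
    multi-allelic locus and runs EM jointly over the five HLA loci plus the
    SNP-haplotype locus. Individuals with any missing call at the loci being
    phased are excluded from that stage.
    """
    excluded: list[str] = []
    snp_gts: dict[str, Genotype] = {}
    for rec in records:
        g = snp_genotype_of(rec)
        if g is None:
            excluded.append(rec.sample_id)
        else:
            snp_gts[rec.sample_id] = g
    if not snp_gts:
        raise HaplotypeError("no individuals with complete SNP genotypes")
    snp_em = em_haplotype_frequencies(list(snp_gts.values()), tol=tol, max_iter=max_iter)

    ext_gts: dict[str, Genotype] = {}
    for rec in records:
        if rec.sample_id not in snp_gts:
            continue
        hla = rec.hla_genotype()
        if hla is None:
            excluded.append(rec.sample_id)
            continue
        snp_assign = assign_best_pair(snp_gts[rec.sample_id], snp_em.frequencies)
        if not snp_assign.assignable:
            excluded.append(rec.sample_id)
            continue
        s1, s2 = snp_assign.pair
        snp_pair = tuple(sorted(("".join(s1), "".join(s2))))
        ext_gts[rec.sample_id] = hla + (snp_pair,)
    if not ext_gts:
        raise HaplotypeError("no individuals with complete HLA + SNP data")
    ext_em = em_haplotype_frequencies(list(ext_gts.values()), tol=tol, max_iter=max_iter)

    assignments: dict[str, tuple[Diplotype, float]] = {}
    for sid, g in ext_gts.items():
        a = assign_best_pair(g, ext_em.frequencies)
        if not a.assignable:
            excluded.append(sid)
            continue
        h1, h2 = a.pair
        dip = Diplotype(CEH(h1[:5], h1[5]), CEH(h2[:5], h2[5]))
        assignments[sid] = (dip, a.posterior)
    return ExtendedPhasingResult(snp_em, ext_em, assignments, excluded)
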