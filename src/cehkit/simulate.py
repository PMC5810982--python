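"""Synthetic diploid case-control populations drawn from a CEH pool.

The generator emulates the salient structure of a large European
case-control cohort typed across the MHC: a strongly skewed CEH frequency
spectrum (a handful of very common haplotypes plus a long tail of
singletons), tight linkage between Class II HLA motifs and 11-SNP
haplotype alleles, per-haplotype disease effects that are dominant /
dose-dependent or recessive, and optional mating substructure that
produces a Wahlund-type homozygote excess.

Every stochastic draw flows from a single :class:`numpy.random.Generator`
so a run is fully replayable from one seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import catalog
from .haplotypes import CEH, Diplotype, HLA_LOCI, N_SNPS, HaplotypeError

FREQ_TOL = 1e-12

#: loci accepted by the missingness configuration ("SNP" masks the whole
#: 11-SNP genotype of an individual, mirroring cohorts where the SNP
#: haplotype data were unavailable for some samples)
MASKABLE_LOCI = HLA_LOCI + ("SNP",)


class PoolValidationError(ValueError):
    """Invalid haplotype pool, scheme or risk configuration."""


def _check_simplex(freqs: np.ndarray, what: str) -> None:
    if np.any(freqs < 0):
        raise PoolValidationError(f"{what} must be non-negative")
    if abs(float(freqs.sum()) - 1.0) > 1e-9:
        raise PoolValidationError(
            f"{what} must sum to 1 (got {float(freqs.sum()):.12f})"
        )


@dataclass
class HaplotypePool:
    """A population pool of CEHs with frequencies and per-CEH risk triples.

    ``risk`` maps a CEH to its genotype relative risks ``(rr1, rr2)`` for 1
    and 2 copies; the 0-copy referent is 1 for every CEH. A recessive CEH is
    encoded ``rr1 = 1, rr2 > 1``; a dose-dependent one ``rr1 = r, rr2 = r**2``.
    """

    haplotypes: list[CEH]
    frequencies: np.ndarray
    risk: dict[CEH, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.haplotypes) == 0:
            raise PoolValidationError("haplotype pool is empty")
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) != len(self.haplotypes):
            raise PoolValidationError("frequencies and haplotypes differ in length")
        _check_simplex(self.frequencies, "pool frequencies")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise PoolValidationError("duplicate haplotypes in pool")
        for hap, (rr1, rr2) in self.risk.items():
            if rr1 <= 0 or rr2 <= 0:
                raise PoolValidationError(f"non-positive relative risk for {hap.key}")

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def homozygosity(self) -> float:
        """Expected per-individual homozygote probability q = sum(f_i^2)."""
        return float(np.sum(self.frequencies**2))

    def frequency_of(self, hap: CEH) -> float:
        return float(self.frequencies[self.haplotypes.index(hap)])

    def risk_of(self, hap: CEH) -> tuple[float, float]:
        return self.risk.get(hap, (1.0, 1.0))

    def top_share(self, k: int) -> float:
        """Share of total haplotype mass carried by the k most frequent CEHs."""
        return float(np.sort(self.frequencies)[::-1][:k].sum())


@dataclass
class SubpopulationScheme:
    """Subpopulation mixing with per-subpopulation CEH frequencies.

    An individual's subpopulation is drawn from ``mixing_weights`` and both
    haplotypes are then drawn from that subpopulation's frequencies — the
    classic Wahlund construction in which divergent subpopulation
    frequencies inflate pooled homozygosity above HWE expectations.
    """

    mixing_weights: np.ndarray
    frequencies: np.ndarray  # shape (n_subpops, n_haplotypes)

    def __post_init__(self) -> None:
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        self.frequencies = np.atleast_2d(np.asarray(self.frequencies, dtype=float))
        _check_simplex(self.mixing_weights, "mixing weights")
        if self.frequencies.shape[0] != len(self.mixing_weights):
            raise PoolValidationError("one frequency row per subpopulation required")
        for i, row in enumerate(self.frequencies):
            _check_simplex(row, f"subpopulation {i} frequencies")

    @property
    def n_subpops(self) -> int:
        return len(self.mixing_weights)

    @property
    def pooled_frequencies(self) -> np.ndarray:
        return self.mixing_weights @ self.frequencies

    @property
    def expected_homozygosity(self) -> float:
        """Pooled homozygote probability sum_j w_j sum_i f_ij^2 (>= HWE value)."""
        return float(np.sum(self.mixing_weights @ (self.frequencies**2)))


@dataclass
class PoolRecipe:
    """Generator recipe for a skewed CEH pool.

    ``n_common`` haplotypes carry ``common_mass`` of the total frequency
    (Zipf-decreasing within the set, exponent ``common_skew``); ``n_rare``
    tail haplotypes share the rest with truncated power-law weights
    (exponent ``tail_exponent``). Defaults emulate a cohort in which the 10
    most common CEHs carry ~22% of all haplotype copies and the tail is
    singleton-dominated.
    """

    n_common: int = 10
    n_rare: int = 6000
    common_mass: float = 0.22
    common_skew: float = 1.0
    tail_exponent: float = 0.3
    seed: int = 0
    risk: Mapping[str, tuple[float, float]] = field(default_factory=dict)


# allele alphabets used to label generated haplotypes (well-formed two-field
# names; common European alleles first so generated pools look plausible)
_ALLELE_POOLS = {
    "A": ["01:01", "02:01", "03:01", "11:01", "24:02", "25:01", "26:01", "29:02",
          "31:01", "32:01", "68:01", "23:01", "30:02", "66:01", "68:02"],
    "C": ["01:02", "03:03", "03:04", "04:01", "05:01", "06:02", "07:01", "07:02",
          "07:04", "08:02", "12:03", "15:02", "16:01", "17:01"],
    "B": ["07:02", "08:01", "13:02", "14:02", "15:01", "18:01", "27:05", "35:01",
          "37:01", "39:06", "40:01", "41:02", "44:02", "44:03", "49:01", "51:01",
          "55:01", "57:01"],
    "DRB1": ["01:01", "03:01", "04:01", "07:01", "08:01", "09:01", "11:01",
             "13:01", "13:03", "15:01"],
    "DQB1": ["02:01", "02:02", "03:01", "03:03", "04:02", "05:01", "05:02",
             "06:02", "06:03"],
}


def _random_cehs(rng: np.random.Generator, count: int, taken: set[str]) -> list[CEH]:
    """Draw ``count`` distinct well-formed CEHs not already in ``taken``."""
    out: list[CEH] = []
    names = {
        locus: [f"{locus}*{a}" for a in _ALLELE_POOLS[locus]] for locus in HLA_LOCI
    }
    while len(out) < count:
        m = int((count - len(out)) * 1.2) + 8
        cols = [
            rng.integers(0, len(names[locus]), size=m) for locus in HLA_LOCI
        ]
        bits = rng.integers(0, 2, size=(m, N_SNPS))
        for i in range(m):
            if len(out) >= count:
                break
            alleles = tuple(names[locus][cols[j][i]] for j, locus in enumerate(HLA_LOCI))
            snp = "".join("1" if b else "0" for b in bits[i])
            hap = CEH(alleles, snp)
            if hap.key not in taken:
                taken.add(hap.key)
                out.append(hap)
    return out


def _random_ceh(rng: np.random.Generator, taken: set[str]) -> CEH:
    """Draw one fresh well-formed CEH not already in ``taken`` (keyed)."""
    return _random_cehs(rng, 1, taken)[0]


def build_pool(spec: "PoolRecipe | Mapping | None" = None,
               haplotypes: Optional[Sequence[CEH]] = None,
               frequencies: Optional[Sequence[float]] = None,
               risk: Optional[Mapping[CEH, tuple[float, float]]] = None) -> HaplotypePool:
    """Build a haplotype pool from an explicit list or a generator recipe.

    Either pass ``haplotypes`` + ``frequencies`` (+ optional ``risk``) for an
    explicit pool, or a :class:`PoolRecipe` (or mapping of its fields) to
    generate a skewed spectrum.
    """
    if haplotypes is not None:
        if frequencies is None:
            raise PoolValidationError("explicit pools need frequencies")
        return HaplotypePool(list(haplotypes), np.asarray(frequencies, float),
                             dict(risk or {}))
    if spec is None:
        raise PoolValidationError("either a recipe or an explicit haplotype list is required")
    if isinstance(spec, Mapping):
        spec = PoolRecipe(**spec)

    rng = np.random.default_rng(spec.seed)
    taken: set[str] = set()
    commons = _random_cehs(rng, spec.n_common, taken)
    rares = _random_cehs(rng, spec.n_rare, taken)

    ranks_c = np.arange(1, spec.n_common + 1, dtype=float)
    w_c = ranks_c ** (-spec.common_skew)
    w_c *= spec.common_mass / w_c.sum()
    if spec.n_rare:
        ranks_r = np.arange(1, spec.n_rare + 1, dtype=float)
        w_r = ranks_r ** (-spec.tail_exponent)
        w_r *= (1.0 - spec.common_mass) / w_r.sum()
        freqs = np.concatenate([w_c, w_r])
        haps = commons + rares
    else:
        freqs = w_c / w_c.sum()
        haps = commons
    risk_map: dict[CEH, tuple[float, float]] = {}
    for i, (tagname, rr) in enumerate(spec.risk.items()):
        # recipe risks are attached to the i-th common haplotype in order
        if i < len(commons):
            risk_map[commons[i]] = tuple(rr)
    return HaplotypePool(haps, freqs, risk_map)


def default_pool(n_rare: int = 10_030, tail_exponent: float = 0.42,
                 seed: int = 0) -> HaplotypePool:
    """The catalogue-backed default pool emulating a large European cohort.

    The named catalogue CEHs keep their observed cohort frequencies
    (copies / total copies) and their reported risk patterns (dose risk at
    the reported per-copy odds ratio; recessive where flagged); the rest of
    the mass goes to a generated power-law tail of rare haplotypes.
    """
    named = [e.ceh for e in catalog.CEH_CATALOG]
    named_f = np.array([e.copies for e in catalog.CEH_CATALOG], float)
    named_f /= catalog.COHORT_TOTAL_COPIES
    tail_mass = 1.0 - named_f.sum()

    rng = np.random.default_rng(seed)
    taken = {h.key for h in named}
    rares = _random_cehs(rng, n_rare, taken)
    # enforce the tight SNP-tag <-> Class II motif linkage: a rare haplotype
    # whose SNP string matches a known tag carries that tag's DRB1~DQB1 motif
    tag_motif = {
        catalog.SNP_TAGS[t]: m for t, m in catalog.TAG_CLASS2_MOTIF.items()
    }
    for i, hap in enumerate(rares):
        motif = tag_motif.get(hap.snp)
        if motif is None:
            continue
        drb1, dqb1 = motif.split("~")
        cand = CEH(hap.alleles[:3] + (drb1, dqb1), hap.snp)
        if cand.key not in taken:
            taken.discard(hap.key)
            taken.add(cand.key)
            rares[i] = cand
        else:
            rares[i] = _random_cehs(rng, 1, taken)[0]
    ranks = np.arange(1, n_rare + 1, dtype=float)
    w = ranks**-tail_exponent
    w *= tail_mass / w.sum()

    risk: dict[CEH, tuple[float, float]] = {}
    for e in catalog.CEH_CATALOG:
        if e.pattern == "recessive":
            risk[e.ceh] = (1.0, e.rr2 if e.rr2 is not None else e.odds_ratio)
        else:
            risk[e.ceh] = (e.odds_ratio, e.odds_ratio**2)
    return HaplotypePool(named + rares, np.concatenate([named_f, w]), risk)


def sample_diplotypes(pool: HaplotypePool, n: int,
                      scheme: Optional[SubpopulationScheme] = None,
                      seed: "int | np.random.Generator" = 0,
                      return_subpops: bool = False):
    """Draw ``n`` diplotypes from the pool.

    Without a scheme each individual is two independent multinomial draws
    from the pool frequencies (HWE). With a scheme, the subpopulation is
    drawn first and both haplotypes come from its frequencies.
    """
    if n < 0:
        raise PoolValidationError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(pool)
    if scheme is None:
        idx = rng.choice(k, size=(n, 2), p=pool.frequencies)
        subpops = np.zeros(n, dtype=int)
    else:
        if scheme.frequencies.shape[1] != k:
            raise PoolValidationError("scheme frequencies must cover the pool")
        subpops = rng.choice(scheme.n_subpops, size=n, p=scheme.mixing_weights)
        idx = np.empty((n, 2), dtype=int)
        for s in range(scheme.n_subpops):
            mask = subpops == s
            m = int(mask.sum())
            if m:
                idx[mask] = rng.choice(k, size=(m, 2), p=scheme.frequencies[s])
    dips = [Diplotype(pool.haplotypes[i], pool.haplotypes[j]) for i, j in idx]
    if return_subpops:
        return dips, subpops
    return dips


def assign_phenotypes(diplotypes: Sequence[Diplotype], pool: HaplotypePool,
                      baseline_odds: float = 0.25,
                      seed: "int | np.random.Generator" = 0) -> np.ndarray:
    """Bernoulli case/control labels from multiplicative per-CEH odds.

    Disease odds for an individual are ``baseline_odds`` times the product,
    over the CEHs they carry, of the relative risk for their copy count.
    Returns an int array (1 = case, 0 = control).
    """
    if baseline_odds <= 0:
        raise PoolValidationError("baseline_odds must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.empty(len(diplotypes), dtype=int)
    for i, dip in enumerate(diplotypes):
        odds = baseline_odds
        if dip.is_homozygous:
            odds *= pool.risk_of(dip.hap1)[1]
        else:
            odds *= pool.risk_of(dip.hap1)[0] * pool.risk_of(dip.hap2)[0]
        p = odds / (1.0 + odds)
        labels[i] = int(rng.random() < p)
    return labels


@dataclass
class GenotypeRecord:
    """Unphased observable data for one individual."""

    sample_id: str
    #: locus -> unordered allele pair (sorted), or None if masked
    hla: dict[str, Optional[tuple[str, str]]]
    #: 11 unordered SNP allele pairs ('0'/'1'), or None if masked
    snps: Optional[tuple[tuple[str, str], ...]]
    phenotype: Optional[int] = None  # 1 = case, 0 = control
    region: Optional[str] = None
    sex: Optional[int] = None  # 1 = male, 0 = female
    covariates: tuple[float, ...] = ()

    def hla_genotype(self) -> Optional[tuple[tuple[str, str], ...]]:
        pairs = tuple(self.hla.get(locus) for locus in HLA_LOCI)
        if any(p is None for p in pairs):
            return None
        return pairs  # type: ignore[return-value]


def unphase(diplotypes: Sequence[Diplotype],
            masking: Optional[Mapping[str, float]] = None,
            seed: "int | np.random.Generator" = 0,
            sample_ids: Optional[Sequence[str]] = None) -> list[GenotypeRecord]:
    """Destroy phase: per-locus unordered allele pairs, with optional masking.

    ``masking`` maps a locus name (``A``, ``C``, ``B``, ``DRB1``, ``DQB1`` or
    ``SNP`` for the whole SNP genotype) to a per-individual missingness rate.
    """
    masking = dict(masking or {})
    for locus in masking:
        if locus not in MASKABLE_LOCI:
            raise HaplotypeError(f"unknown locus {locus!r} in missingness config")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for i, dip in enumerate(diplotypes):
        sid = sample_ids[i] if sample_ids is not None else f"S{i + 1:06d}"
        hla: dict[str, Optional[tuple[str, str]]] = {}
        for j, locus in enumerate(HLA_LOCI):
            pair = tuple(sorted((dip.hap1.alleles[j], dip.hap2.alleles[j])))
            if masking.get(locus, 0.0) > rng.random():
                pair = None
            hla[locus] = pair
        snps: Optional[tuple[tuple[str, str], ...]]
        snps = tuple(
            tuple(sorted((dip.hap1.snp[s], dip.hap2.snp[s]))) for s in range(N_SNPS)
        )
        if masking.get("SNP", 0.0) > rng.random():
            snps = None
        records.append(GenotypeRecord(sid, hla, snps))
    return records


@dataclass
class DatasetConfig:
    """Configuration for a full synthetic case-control dataset."""

    pool: Optional[HaplotypePool] = None
    recipe: Optional[PoolRecipe] = None
    n: int = 2000
    scheme: Optional[SubpopulationScheme] = None
    baseline_odds: float = 0.25
    masking: Mapping[str, float] = field(default_factory=dict)
    n_regions: int = 14
    n_pcs: int = 0

    def resolve_pool(self) -> HaplotypePool:
        if self.pool is not None:
            return self.pool
        if self.recipe is not None:
            return build_pool(self.recipe)
        return default_pool()


def generate_dataset(config: DatasetConfig, seed: int = 0):
    """Generate (records, truth) for a synthetic case-control cohort.

    ``records`` is the unphased observable dataset; ``truth`` is a pandas
    DataFrame with the true diplotypes, subpopulation and region labels for
    parameter-recovery tests. Deterministic for a fixed seed.
    """
    import pandas as pd

    pool = config.resolve_pool()
    rng = np.random.default_rng(seed)
    dips, subpops = sample_diplotypes(pool, config.n, config.scheme, rng,
                                      return_subpops=True)
    phenotypes = assign_phenotypes(dips, pool, config.baseline_odds, rng)
    records = unphase(dips, config.masking, rng)
    regions = rng.integers(0, config.n_regions, size=config.n)
    sexes = rng.integers(0, 2, size=config.n)
    pcs = rng.standard_normal((config.n, config.n_pcs)) if config.n_pcs else None
    for i, rec in enumerate(records):
        rec.phenotype = int(phenotypes[i])
        rec.region = f"R{regions[i] + 1:02d}"
        rec.sex = int(sexes[i])
        rec.covariates = tuple(pcs[i]) if pcs is not None else ()
    truth = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "hap1": [d.hap1.key for d in dips],
            "hap2": [d.hap2.key for d in dips],
            "subpop": subpops,
            "region": [r.region for r in records],
            "phenotype": phenotypes,
        }
    )
    return records, truth


def truth_diplotypes(truth) -> list[Diplotype]:
    """Rebuild Diplotype objects from a truth table."""
    return [
        Diplotype(CEH.from_string(h1), CEH.from_string(h2))
        for h1, h2 in zip(truth["hap1"], truth["hap2"])
    ]
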