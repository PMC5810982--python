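"""Core domain types for MHC conserved extended haplotypes (CEHs).

A CEH is a specific combination of alleles at the five classical HLA loci
HLA-A, HLA-C, HLA-B, HLA-DRB1 and HLA-DQB1 together with an 11-SNP
haplotype from the Class II region, inherited as a unit across >2.7 Mb.
The 11-SNP haplotype is treated as one multi-allelic "haplotype locus":
two CEHs that share all five HLA alleles but differ in their SNP string
are distinct haplotypes.

Canonical text encoding joins the six fields with "~" in locus order
A~C~B~DRB1~DQB1~SNP, e.g.::

    A*03:01~C*07:02~B*07:02~DRB1*15:01~DQB1*06:02~10110100010

Partial patterns ("motifs") use the same encoding with "*" for an
unconstrained locus; the SNP field of a pattern may be a binary string
or a named tag (``a1``, ``a2``, ...) resolved through a tag table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

HLA_LOCI: tuple[str, ...] = ("A", "C", "B", "DRB1", "DQB1")
N_SNPS: int = 11

SEP = "~"
WILDCARD = "*"


class HaplotypeError(ValueError):
    """Malformed haplotype, genotype or pattern input."""


def validate_snp_string(snp: str, n_snps: int = N_SNPS) -> str:
    if len(snp) != n_snps or any(ch not in "01" for ch in snp):
        raise HaplotypeError(
            f"SNP haplotype must be a length-{n_snps} string over {{0,1}}, got {snp!r}"
        )
    return snp


def normalize_allele(locus: str, allele: str) -> str:
    """Normalize an HLA allele name to two-field resolution with locus prefix.

    ``"15:01"`` at DRB1 becomes ``"DRB1*15:01"``; ``"DRB1*15:01:01:02"`` is
    truncated to ``"DRB1*15:01"``.
    """
    allele = allele.strip()
    if "*" in allele:
        prefix, fields = allele.split("*", 1)
        if prefix and prefix != locus:
            raise HaplotypeError(f"allele {allele!r} does not belong to locus {locus}")
    else:
        fields = allele
    parts = fields.split(":")
    if not parts or not parts[0]:
        raise HaplotypeError(f"malformed allele name {allele!r}")
    fields = ":".join(parts[:2])
    return f"{locus}*{fields}"


@dataclass(frozen=True)
class CEH:
    """A conserved extended haplotype: five HLA alleles plus an 11-SNP string."""

    alleles: tuple[str, str, str, str, str]
    snp: str

    def __post_init__(self) -> None:
        if len(self.alleles) != len(HLA_LOCI):
            raise HaplotypeError(f"expected {len(HLA_LOCI)} HLA alleles, got {self.alleles!r}")
        validate_snp_string(self.snp)

    @property
    def key(self) -> str:
        return SEP.join(self.alleles + (self.snp,))

    def allele(self, locus: str) -> str:
        return self.alleles[HLA_LOCI.index(locus)]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key

    def __lt__(self, other: "CEH") -> bool:
        return self.key < other.key

    @classmethod
    def from_fields(
        cls,
        a: str,
        c: str,
        b: str,
        drb1: str,
        dqb1: str,
        snp: str,
        snp_tags: Optional[Mapping[str, str]] = None,
    ) -> "CEH":
        alleles = tuple(
            normalize_allele(locus, allele)
            for locus, allele in zip(HLA_LOCI, (a, c, b, drb1, dqb1))
        )
        snp = resolve_snp_field(snp, snp_tags)
        return cls(alleles, snp)

    @classmethod
    def from_string(cls, text: str, snp_tags: Optional[Mapping[str, str]] = None) -> "CEH":
        parts = text.split(SEP)
        if len(parts) != 6:
            raise HaplotypeError(f"expected 6 '~'-joined fields, got {text!r}")
        return cls.from_fields(*parts, snp_tags=snp_tags)


def resolve_snp_field(snp: str, snp_tags: Optional[Mapping[str, str]] = None) -> str:
    """Resolve a SNP field that may be a binary string or a named tag."""
    snp = snp.strip()
    if set(snp) <= {"0", "1"} and snp:
        return validate_snp_string(snp)
    if snp_tags is None:
        from .catalog import SNP_TAGS as snp_tags  # default tag table
    if snp in snp_tags:
        return snp_tags[snp]
    raise HaplotypeError(f"unknown SNP haplotype tag {snp!r}")


@dataclass(frozen=True)
class Diplotype:
    """An individual's unordered pair of CEHs, stored in canonical order."""

    hap1: CEH
    hap2: CEH

    def __post_init__(self) -> None:
        if self.hap1.key > self.hap2.key:
            h1, h2 = self.hap1, self.hap2
            object.__setattr__(self, "hap1", h2)
            object.__setattr__(self, "hap2", h1)

    @property
    def is_homozygous(self) -> bool:
        return self.hap1 == self.hap2

    def copies_of(self, hap: CEH) -> int:
        return int(self.hap1 == hap) + int(self.hap2 == hap)

    @property
    def key(self) -> str:
        return f"{self.hap1.key}/{self.hap2.key}"

    def __iter__(self):
        return iter((self.hap1, self.hap2))


@dataclass(frozen=True)
class MotifPattern:
    """A partial CEH pattern: one constraint (or wildcard) per locus plus SNP.

    ``hla`` holds one entry per HLA locus in order (None = wildcard); ``snp``
    is a binary string or None. Parsed from the "~"-joined encoding, e.g.
    ``"*~*~*~DRB1*15:01~DQB1*06:02~a1"``.
    """

    hla: tuple[Optional[str], ...]
    snp: Optional[str]

    def __post_init__(self) -> None:
        if len(self.hla) != len(HLA_LOCI):
            raise HaplotypeError("pattern must constrain exactly the five HLA loci")
        if self.snp is not None:
            validate_snp_string(self.snp)

    @classmethod
    def parse(cls, text: str, snp_tags: Optional[Mapping[str, str]] = None) -> "MotifPattern":
        parts = [p.strip() for p in text.split(SEP)]
        if len(parts) != 6:
            raise HaplotypeError(
                f"pattern must have 6 '~'-joined fields (use '*' for wildcards): {text!r}"
            )
        hla = tuple(
            None if p == WILDCARD else normalize_allele(locus, p)
            for locus, p in zip(HLA_LOCI, parts[:5])
        )
        snp = None if parts[5] == WILDCARD else resolve_snp_field(parts[5], snp_tags)
        return cls(hla, snp)

    def matches(self, hap: CEH) -> bool:
        for want, have in zip(self.hla, hap.alleles):
            if want is not None and want != have:
                return False
        return self.snp is None or self.snp == hap.snp

    def carried_by(self, dip: Diplotype) -> int:
        """Number of haplotypes in the pair matching this pattern (0, 1 or 2)."""
        return int(self.matches(dip.hap1)) + int(self.matches(dip.hap2))

    def __str__(self) -> str:
        parts = [a if a is not None else WILDCARD for a in self.hla]
        parts.append(self.snp if self.snp is not None else WILDCARD)
        return SEP.join(parts)


def as_pattern(
    target: "CEH | MotifPattern | str", snp_tags: Optional[Mapping[str, str]] = None
) -> MotifPattern:
    """Coerce a CEH, pattern or pattern string to a MotifPattern."""
    if isinstance(target, MotifPattern):
        return target
    if isinstance(target, CEH):
        return MotifPattern(tuple(target.alleles), target.snp)
    return MotifPattern.parse(target, snp_tags)


def sort_haplotypes(haps: Iterable[CEH]) -> list[CEH]:
    return sorted(haps, key=lambda h: h.key)
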