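"""Catalogue of MHC conserved extended haplotypes for European populations.

Holds the 11-SNP Class II haplotype tags (``a1``, ``a2``, ...) with their
binary strings and classical Class II HLA motif associations, and a table
of named CEHs (``c1``, ``c2``, ...) with their cohort copy counts and
reported single-copy disease odds ratios for multiple sclerosis. These are
the well-replicated haplotypes of the European MHC and serve as the
realistic default configuration of the synthetic-population generator and
as fixtures in examples and tests.

The 11 SNPs span ~246 kb around HLA-DRB1 (rs2395173, rs2395174, rs3129871,
rs7192, rs3129890, rs9268832, rs532098, rs17533090, rs2187668, rs1063355,
rs9275141); "0" denotes the major and "1" the minor allele in controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .haplotypes import CEH

#: 11-SNP haplotype tag -> binary string. Tags ``a16`` and ``a18`` appear in
#: the CEH table but their strings are not published at this resolution; the
#: strings given for them here are synthetic stand-ins (distinct from all
#: published strings) so that the catalogue haplotypes are fully specified.
SNP_TAGS: dict[str, str] = {
    "a1": "10110100010",
    "a2": "00000000100",
    "a3": "00000010001",
    "a4": "00000000001",
    "a5": "10100010001",
    "a6": "01011100100",
    "a8": "10110100011",
    "a9": "01000001010",
    "a11": "00000010010",
    "a14": "10111111001",
    "a27": "10100100011",
    "a34": "10111100010",
    "a36": "10100100010",
    "a43": "00000100010",
    "a16": "01000100100",  # synthetic stand-in
    "a18": "00000011010",  # synthetic stand-in
}

#: Class II HLA motif (DRB1~DQB1) most strongly tied to each SNP tag.
TAG_CLASS2_MOTIF: dict[str, str] = {
    "a1": "DRB1*15:01~DQB1*06:02",
    "a2": "DRB1*03:01~DQB1*02:01",
    "a4": "DRB1*11:01~DQB1*03:01",
    "a5": "DRB1*07:01~DQB1*02:02",
    "a6": "DRB1*03:01~DQB1*02:01",
    "a8": "DRB1*15:01~DQB1*05:02",
    "a9": "DRB1*01:01~DQB1*05:01",
    "a11": "DRB1*13:01~DQB1*06:03",
    "a14": "DRB1*13:03~DQB1*03:01",
    "a34": "DRB1*15:01~DQB1*06:02",
    "a36": "DRB1*15:01~DQB1*06:02",
    "a43": "DRB1*15:01~DQB1*06:02",
}

#: The strongest MS-risk Class II motif, which rides almost exclusively on a1.
RISK_MOTIF = "*~*~*~DRB1*15:01~DQB1*06:02~a1"


@dataclass(frozen=True)
class CatalogEntry:
    """One named CEH with cohort copy count and reported 1-copy odds ratio."""

    name: str
    a: str
    c: str
    b: str
    drb1: str
    dqb1: str
    snp_tag: str
    copies: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    #: disease-risk pattern: "dose" (per-copy multiplicative) or "recessive"
    pattern: str = "dose"
    #: homozygote relative risk where the pattern is recessive
    rr2: Optional[float] = None

    @property
    def ceh(self) -> CEH:
        return CEH.from_fields(
            self.a, self.c, self.b, self.drb1, self.dqb1, SNP_TAGS[self.snp_tag]
        )


def _e(name, a, c, b, drb1, dqb1, tag, n, orr, lo, hi, pattern="dose", rr2=None):
    return CatalogEntry(name, a, c, b, drb1, dqb1, tag, n, orr, lo, hi, pattern, rr2)


#: Named CEHs with >= ~50 cohort copies, carrying the a1 risk motif or the
#: a2/a6/a14 Class II motifs, plus other significantly associated haplotypes.
CEH_CATALOG: tuple[CatalogEntry, ...] = (
    # DRB1*15:01~DQB1*06:02~a1 haplotypes (dose-dependent risk)
    _e("c2", "03:01", "07:02", "07:02", "15:01", "06:02", "a1", 2961, 3.2, 3.0, 3.5),
    _e("c3", "02:01", "07:02", "07:02", "15:01", "06:02", "a1", 1465, 2.2, 2.0, 2.5),
    _e("c6", "24:02", "07:02", "07:02", "15:01", "06:02", "a1", 728, 2.8, 2.4, 3.3),
    _e("c11", "25:01", "12:03", "18:01", "15:01", "06:02", "a1", 440, 3.9, 3.1, 4.8),
    _e("c13", "01:01", "07:02", "07:02", "15:01", "06:02", "a1", 405, 3.4, 2.7, 4.2),
    _e("c16", "01:01", "07:01", "08:01", "15:01", "06:02", "a1", 320, 3.7, 2.9, 4.8),
    _e("c19", "02:01", "05:01", "44:02", "15:01", "06:02", "a1", 289, 2.1, 1.6, 2.7),
    _e("c22", "11:01", "07:02", "07:02", "15:01", "06:02", "a1", 229, 2.5, 1.9, 3.4),
    _e("c28", "01:01", "06:02", "37:01", "15:01", "06:02", "a1", 178, 4.5, 3.2, 6.3),
    _e("c44", "31:01", "07:01", "18:01", "15:01", "06:02", "a1", 135, 2.9, 2.0, 4.2),
    _e("c50", "02:01", "03:04", "40:01", "15:01", "06:02", "a1", 124, 3.1, 2.0, 4.7),
    _e("c58", "02:01", "03:03", "15:01", "15:01", "06:02", "a1", 105, 3.2, 2.1, 5.0),
    _e("c78", "29:02", "16:01", "44:03", "15:01", "06:02", "a1", 84, 3.7, 2.2, 6.1),
    _e("c87", "31:01", "07:02", "07:02", "15:01", "06:02", "a1", 73, 3.4, 2.0, 5.6),
    _e("c91", "26:01", "07:02", "07:02", "15:01", "06:02", "a1", 71, 2.6, 1.6, 4.3),
    _e("c108", "32:01", "07:02", "07:02", "15:01", "06:02", "a1", 64, 3.1, 1.8, 5.4),
    _e("c116", "31:01", "15:02", "51:01", "15:01", "06:02", "a1", 60, 4.3, 2.4, 7.9),
    _e("c120", "03:01", "04:01", "35:01", "15:01", "06:02", "a1", 58, 4.5, 2.5, 8.1),
    _e("c125", "11:01", "03:03", "55:01", "15:01", "06:02", "a1", 57, 1.9, 1.1, 3.3),
    _e("c128", "68:01", "07:04", "44:02", "15:01", "06:02", "a1", 55, 2.9, 1.6, 5.1),
    _e("c132", "01:01", "06:02", "57:01", "15:01", "06:02", "a1", 54, 1.8, 1.0, 3.3),
    _e("c139", "02:01", "03:04", "15:01", "15:01", "06:02", "a1", 52, 3.2, 1.6, 6.3),
    _e("c140", "11:01", "15:02", "51:01", "15:01", "06:02", "a1", 52, 3.3, 1.7, 6.4),
    _e("c143", "68:01", "07:02", "07:02", "15:01", "06:02", "a1", 51, 3.0, 1.6, 5.6),
    _e("c173", "23:01", "07:01", "49:01", "15:01", "06:02", "a1", 43, 5.5, 2.8, 10.9),
    _e("c282", "03:01", "15:02", "51:01", "15:01", "06:02", "a1", 29, 20.3, 6.1, 67.3),
    # DRB1*03:01~DQB1*02:01~a2 haplotypes (dominant / dose-dependent risk)
    _e("c23", "30:02", "05:01", "18:01", "03:01", "02:01", "a2", 212, 2.0, 1.4, 2.7),
    _e("c46", "01:01", "07:01", "08:01", "03:01", "02:01", "a2", 128, 2.1, 1.5, 3.0),
    _e("c85", "02:01", "05:01", "18:01", "03:01", "02:01", "a2", 75, 1.7, 1.0, 2.9),
    # DRB1*03:01~DQB1*02:01~a6 haplotypes (largely recessive risk)
    _e("c1", "01:01", "07:01", "08:01", "03:01", "02:01", "a6", 3782, 1.1, 1.0, 1.2,
       pattern="recessive", rr2=2.1),
    _e("c14", "02:01", "07:01", "08:01", "03:01", "02:01", "a6", 397, 0.9, 0.7, 1.2,
       pattern="recessive", rr2=2.1),
    _e("c27", "03:01", "07:01", "08:01", "03:01", "02:01", "a6", 181, 1.7, 1.2, 2.3),
    _e("c51", "68:01", "07:01", "08:01", "03:01", "02:01", "a6", 121, 0.6, 0.4, 1.0,
       pattern="recessive", rr2=2.1),
    _e("c68", "24:02", "07:01", "08:01", "03:01", "02:01", "a6", 91, 3.0, 1.8, 4.9),
    _e("c90", "03:01", "07:02", "07:02", "03:01", "02:01", "a6", 71, 1.6, 0.9, 2.6,
       pattern="recessive", rr2=2.1),
    _e("c97", "32:01", "07:01", "08:01", "03:01", "02:01", "a6", 68, 1.1, 0.6, 2.0,
       pattern="recessive", rr2=2.1),
    _e("c110", "25:01", "07:01", "08:01", "03:01", "02:01", "a6", 63, 1.3, 0.7, 2.3,
       pattern="recessive", rr2=2.1),
    # DRB1*13:03~DQB1*03:01~a14 haplotypes (dose-dependent risk)
    _e("c34", "68:02", "08:02", "14:02", "13:03", "03:01", "a14", 161, 1.9, 1.3, 2.8),
    _e("c96", "66:01", "17:01", "41:02", "13:03", "03:01", "a14", 69, 2.6, 1.5, 4.5),
    _e("c107", "02:01", "17:01", "41:02", "13:03", "03:01", "a14", 64, 1.9, 1.1, 3.4),
    # other associated haplotypes, mostly protective
    _e("c5", "02:01", "05:01", "44:02", "04:01", "03:01", "a3", 906, 0.5, 0.4, 0.6),
    _e("c15", "02:01", "06:02", "13:02", "07:01", "02:02", "a3", 361, 0.5, 0.3, 0.6),
    _e("c18", "02:01", "06:02", "57:01", "07:01", "03:03", "a5", 293, 0.5, 0.3, 0.7),
    _e("c24", "02:01", "01:02", "27:05", "01:01", "05:01", "a9", 211, 0.5, 0.3, 0.7),
    _e("c30", "02:01", "05:01", "44:02", "11:01", "03:01", "a4", 173, 0.6, 0.4, 0.9),
    _e("c32", "03:01", "07:02", "07:02", "13:01", "06:03", "a18", 166, 0.6, 0.4, 0.9),
    _e("c73", "02:01", "15:02", "51:01", "09:01", "03:03", "a4", 87, 0.4, 0.2, 0.8),
    _e("c81", "24:02", "07:02", "39:06", "08:01", "04:02", "a16", 79, 3.1, 1.8, 5.5),
)

#: Total haplotype copies in the reference cohort (2 per phased individual).
COHORT_TOTAL_COPIES = 59_884
#: Phased individuals in the reference cohort.
COHORT_INDIVIDUALS = 29_942
#: Unique CEHs observed in the reference cohort.
COHORT_UNIQUE_CEHS = 10_078


def entry(name: str) -> CatalogEntry:
    for e in CEH_CATALOG:
        if e.name == name:
            return e
    raise KeyError(name)
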