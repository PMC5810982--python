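"""Hamming-distance profiling of SNP haplotypes and HLA-motif carriage.

Given the phased pool of extended haplotypes, this module asks how
carriage of a Class II HLA motif (e.g. DRB1*15:01~DQB1*06:02) varies with
the Hamming distance of the 11-SNP haplotype from an anchor string: if
motif assignments at short distances were typing or phasing artifacts,
carriage would decay smoothly with distance, whereas haplotype-specific
carriage shows up as individual SNP haplotypes that carry the motif at
high rates even several steps away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .haplotypes import CEH, MotifPattern, as_pattern, validate_snp_string


def hamming(h1: str, h2: str) -> int:
    """Number of differing positions between two equal-length SNP strings."""
    if len(h1) != len(h2):
        raise ValueError(f"length mismatch: {len(h1)} vs {len(h2)}")
    return sum(a != b for a, b in zip(h1, h2))


@dataclass
class DistanceProfile:
    """Motif carriage as a function of Hamming distance from an anchor.

    ``by_distance`` has one row per distance with total copies, motif
    carrier copies and the copy-weighted carriage proportion, plus the
    unweighted mean over unique SNP haplotypes at that distance;
    ``by_haplotype`` has one row per unique SNP haplotype with its own
    carriage proportion and a subgroup label splitting haplotypes that
    carry the motif in fewer than 10% of their copies from the rest.
    """

    anchor: str
    motif: str
    by_distance: pd.DataFrame
    by_haplotype: pd.DataFrame

    def proportion_at(self, d: int) -> float:
        row = self.by_distance[self.by_distance["distance"] == d]
        if row.empty:
            raise KeyError(f"no haplotypes at distance {d}")
        return float(row["proportion"].iloc[0])


def carriage_by_distance(
    haplotype_counts: Mapping[CEH, int],
    anchor: str,
    motif: "MotifPattern | str",
    subgroup_threshold: float = 0.10,
) -> DistanceProfile:
    """Profile HLA-motif carriage against SNP-haplotype Hamming distance.

    ``haplotype_counts`` maps extended haplotypes to copy counts (e.g. a
    spectrum's counts). Copies are grouped by the Hamming distance of their
    SNP part from ``anchor``; at each distance both the copy-weighted
    carriage proportion and the mean over unique SNP haplotypes are
    reported. Distance 0 contains the anchor SNP haplotype only.
    """
    anchor = validate_snp_string(anchor)
    pat = as_pattern(motif) if not isinstance(motif, MotifPattern) else motif

    # per unique SNP haplotype: total copies and motif-carrying copies
    per_snp: dict[str, list[int]] = {}
    for hap, count in haplotype_counts.items():
        tot_car = per_snp.setdefault(hap.snp, [0, 0])
        tot_car[0] += count
        if pat.matches(hap):
            tot_car[1] += count

    hap_rows = []
    for snp in sorted(per_snp):
        copies, carriers = per_snp[snp]
        prop = carriers / copies
        hap_rows.append(
            {
                "snp_haplotype": snp,
                "distance": hamming(snp, anchor),
                "copies": copies,
                "carriers": carriers,
                "proportion": prop,
                "subgroup": "low" if prop < subgroup_threshold else "high",
            }
        )
    by_hap = pd.DataFrame(hap_rows)

    dist_rows = []
    for d in sorted(by_hap["distance"].unique()):
        sub = by_hap[by_hap["distance"] == d]
        copies = int(sub["copies"].sum())
        carriers = int(sub["carriers"].sum())
        row = {
            "distance": int(d),
            "n_unique": int(len(sub)),
            "copies": copies,
            "carriers": carriers,
            "proportion": carriers / copies,
            "mean_haplotype_proportion": float(sub["proportion"].mean()),
        }
        for grp in ("low", "high"):
            g = sub[sub["subgroup"] == grp]
            row[f"proportion_{grp}"] = (
                float(g["carriers"].sum() / g["copies"].sum()) if len(g) else float("nan")
            )
        dist_rows.append(row)
    by_dist = pd.DataFrame(dist_rows)
    return DistanceProfile(anchor, str(pat), by_dist, by_hap)
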