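"""CEH copy-count spectra: coverage summaries, cumulative curves, group ranks.

A spectrum counts haplotype copies (two per phased individual) per unique
CEH. From it come the headline descriptors of MHC haplotype structure: how
much of the total mass the top-k CEHs carry, how many unique CEHs are
singletons, the cumulative coverage curve over descending-frequency ranks,
and per-region rank orders of the globally most common CEHs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .haplotypes import CEH, Diplotype


@dataclass
class FrequencySpectrum:
    """CEH -> copy count, with deterministic descending-count rank order."""

    counts: dict[CEH, int]
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("copy counts must be positive")

    @property
    def total_copies(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def ranked(self) -> list[tuple[CEH, int]]:
        """CEHs by descending count, ties broken by canonical haplotype string."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0].key))

    def rank_of(self, hap: CEH) -> Optional[int]:
        for r, (h, _) in enumerate(self.ranked(), start=1):
            if h == hap:
                return r
        return None

    def frequencies(self) -> dict[CEH, float]:
        tot = self.total_copies
        return {h: c / tot for h, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        cum = 0
        tot = self.total_copies
        for rank, (hap, count) in enumerate(self.ranked(), start=1):
            cum += count
            rows.append(
                {
                    "haplotype": hap.key,
                    "count": count,
                    "rank": rank,
                    "percent": 100.0 * count / tot,
                    "cumulative_percent": 100.0 * cum / tot,
                    "group": self.group if self.group is not None else "",
                }
            )
        return pd.DataFrame(rows)


def build_spectrum(
    pairs: Iterable[Diplotype],
    group_labels: Optional[Sequence[str]] = None,
) -> "FrequencySpectrum | dict[str, FrequencySpectrum]":
    """Count both haplotypes of each individual's pair.

    With ``group_labels`` (one per individual), returns one spectrum per
    group; the group spectra partition the global one.
    """
    pairs = list(pairs)
    if group_labels is None:
        counts: Counter = Counter()
        for dip in pairs:
            counts[dip.hap1] += 1
            counts[dip.hap2] += 1
        return FrequencySpectrum(dict(counts))
    if len(group_labels) != len(pairs):
        raise ValueError("one group label per individual is required")
    by_group: dict[str, Counter] = {}
    for dip, g in zip(pairs, group_labels):
        c = by_group.setdefault(str(g), Counter())
        c[dip.hap1] += 1
        c[dip.hap2] += 1
    return {
        g: FrequencySpectrum(dict(c), group=g) for g, c in sorted(by_group.items())
    }


@dataclass
class SpectrumSummary:
    """Coverage of top-k CEHs and of low-multiplicity (rare) CEHs."""

    total_copies: int
    n_unique: int
    #: k -> (copies in top-k, raw percent of total copies)
    top_k: dict[int, tuple[int, float]]
    #: multiplicity cutoff m -> (n unique CEHs with count <= m,
    #:   raw percent of unique CEHs, copies they carry, raw percent of copies)
    multiplicity: dict[int, tuple[int, float, int, float]]

    def top_k_percent(self, k: int, rounded: bool = True) -> float:
        pct = self.top_k[k][1]
        return round(pct) if rounded else pct

    def multiplicity_percent_unique(self, m: int, rounded: bool = True) -> float:
        pct = self.multiplicity[m][1]
        return round(pct) if rounded else pct


def spectrum_summary(
    spectrum: FrequencySpectrum,
    top_k: Sequence[int] = (10, 25, 146, 810),
    multiplicity_cutoffs: Sequence[int] = (1, 2),
) -> SpectrumSummary:
    """Coverage summary: top-k copy shares and rare-CEH multiplicity shares.

    Percentages are reported rounded to the nearest integer for display,
    with the raw values retained.
    """
    if spectrum.n_unique == 0:
        raise ValueError("empty spectrum")
    ranked = spectrum.ranked()
    tot = spectrum.total_copies
    top = {}
    for k in top_k:
        copies = sum(c for _, c in ranked[:k])
        top[int(k)] = (copies, 100.0 * copies / tot)
    mult = {}
    for m in multiplicity_cutoffs:
        rare = [(h, c) for h, c in ranked if c <= m]
        n_rare = len(rare)
        copies = sum(c for _, c in rare)
        mult[int(m)] = (
            n_rare,
            100.0 * n_rare / spectrum.n_unique,
            copies,
            100.0 * copies / tot,
        )
    return SpectrumSummary(tot, spectrum.n_unique, top, mult)


def coverage_curve(spectrum: FrequencySpectrum) -> list[tuple[int, float]]:
    """Cumulative percent of copies against unique-CEH count, descending rank."""
    if spectrum.n_unique == 0:
        raise ValueError("empty spectrum")
    tot = spectrum.total_copies
    curve = []
    cum = 0
    for i, (_, count) in enumerate(spectrum.ranked(), start=1):
        cum += count
        curve.append((i, 100.0 * cum / tot))
    return curve


def rank_by_group(
    spectra: Mapping[str, FrequencySpectrum],
    reference: Optional[Sequence[CEH]] = None,
    global_spectrum: Optional[FrequencySpectrum] = None,
    order_by: Optional[CEH] = None,
) -> pd.DataFrame:
    """Per-group ranks of the reference CEHs (global top-10 by default).

    Returns a DataFrame indexed by reference haplotype key with one column
    per group; a CEH absent from a group gets a missing value rather than a
    rank. With ``order_by``, the group columns are ordered by the descending
    frequency of that CEH across groups.
    """
    if not spectra:
        raise ValueError("at least one group is required")
    if reference is None:
        if global_spectrum is None:
            merged: Counter = Counter()
            for sp in spectra.values():
                merged.update(sp.counts)
            global_spectrum = FrequencySpectrum(dict(merged))
        reference = [h for h, _ in global_spectrum.ranked()[:10]]
    groups = list(spectra)
    if order_by is not None:
        def freq_in(g: str) -> float:
            sp = spectra[g]
            return sp.counts.get(order_by, 0) / sp.total_copies
        groups = sorted(groups, key=freq_in, reverse=True)
    data = {}
    for g in groups:
        sp = spectra[g]
        data[g] = [sp.rank_of(h) for h in reference]
    return pd.DataFrame(data, index=[h.key for h in reference]).astype("Int64")
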