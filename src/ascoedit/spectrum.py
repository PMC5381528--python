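"""The 12-type substitution spectrum and its per-condition statistics.

Because sites live in sense-strand gene space, A→G is the direct A-to-I
editing signature and is never collapsed with its reverse-strand alias
T→C; all 12 ordered ref→alt types are kept distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = ["SUBSTITUTION_TYPES", "SpectrumCounts", "substitution_type", "spectrum"]

SUBSTITUTION_TYPES = (
    "AC", "AG", "AT",
    "CA", "CG", "CT",
    "GA", "GC", "GT",
    "TA", "TC", "TG",
)

_BASES = set("ACGT")


def substitution_type(ref: str, alt: str) -> str:
    """Ordered ref→alt pair label, e.g. ``("A","G") → "AG"``."""
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}→{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}")
    return ref + alt


@dataclass
class SpectrumCounts:
    """Counts of sites over the 12 substitution types for one condition."""

    condition: str
    counts: dict[str, int]
    covered_bases: float

    def __post_init__(self) -> None:
        full = {t: 0 for t in SUBSTITUTION_TYPES}
        for t, n in self.counts.items():
            if t not in full:
                raise ValueError(f"unknown substitution type {t!r}")
            full[t] = n
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def rates(self) -> dict[str, float]:
        """Events per million covered bases, per type."""
        if self.covered_bases <= 0:
            if self.total:
                raise ValueError("covered_bases must be positive with nonzero sites")
            return {t: 0.0 for t in SUBSTITUTION_TYPES}
        return {t: 1e6 * n / self.covered_bases for t, n in self.counts.items()}

    @property
    def fractions(self) -> Optional[dict[str, float]]:
        """Share of each type among all classified sites (None if empty)."""
        tot = self.total
        if tot == 0:
            return None
        return {t: n / tot for t, n in self.counts.items()}


def spectrum(sites: Iterable, covered_bases: float, condition: str = "") -> SpectrumCounts:
    """Classify sites (anything with ref_base/alt_base) into the 12 types."""
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    for s in sites:
        counts[substitution_type(s.ref_base, s.alt_base)] += 1
    sc = SpectrumCounts(condition=condition, counts=counts, covered_bases=covered_bases)
    sc.rates  # validates covered_bases against nonzero totals
    return sc


def plot_spectrum(spectra: list[SpectrumCounts], path: str) -> None:
    """Grouped bar chart of per-million rates across conditions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    x = np.arange(len(SUBSTITUTION_TYPES))
    width = 0.8 / max(len(spectra), 1)
    fig, ax = plt.subplots(figsize=(10, 4))
    for i, sc in enumerate(spectra):
        rates = sc.rates
        ax.bar(x + i * width, [rates[t] for t in SUBSTITUTION_TYPES], width, label=sc.condition)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([f"{t[0]}-to-{t[1]}" for t in SUBSTITUTION_TYPES], rotation=45)
    ax.set_ylabel("events / million covered bases")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
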