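"""Replicate intersection, condition specificity and normalised summaries.

Each condition has exactly two independent biological replicates.  Only
sites called in both replicates with an identical (gene, position, ref,
alt) key are considered reproducible and analysed further.  Summary
rows normalise call counts to events per million covered bases and
report the "both" count as a percentage of the mean of the two
replicates' normalised counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from ascoedit.detection import VariantSite
from ascoedit.spectrum import substitution_type

__all__ = [
    "SiteEvidence",
    "EditingSiteRecord",
    "ReplicateSummary",
    "intersect_replicates",
    "condition_specific",
    "normalize_per_million",
    "pct_both",
    "summarize_condition",
]


@dataclass(frozen=True)
class SiteEvidence:
    """Depth / alternative-base evidence for one site in one sample."""

    depth: int
    alt_count: int

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class EditingSiteRecord:
    """A replicate-reproducible site with provenance and annotation."""

    gene_id: str
    position: int
    ref_base: str
    alt_base: str
    samples: dict[str, SiteEvidence] = field(default_factory=dict)
    conditions_reproducible: set[str] = field(default_factory=set)
    specific_to: Optional[str] = None
    consequence: object = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene_id, self.position, self.ref_base, self.alt_base)

    @property
    def substitution_type(self) -> str:
        return substitution_type(self.ref_base, self.alt_base)

    def pooled_fraction(self, samples: Sequence[str] | None = None) -> float:
        """Alt reads / depth summed over (a subset of) the sample evidence."""
        names = samples if samples is not None else list(self.samples)
        depth = sum(self.samples[n].depth for n in names if n in self.samples)
        alt = sum(self.samples[n].alt_count for n in names if n in self.samples)
        return alt / depth if depth else 0.0


@dataclass
class ReplicateSummary:
    """One condition's replicate-reproducibility row.

    Normalised values are events per million covered bases; ``pct_both``
    is ``100 × norm_both / mean(norm_rep1, norm_rep2)`` (None when the
    denominator is zero).
    """

    condition: str
    covered_bases_mean: float
    n_rep1: int
    n_rep2: int
    n_both: int
    norm_rep1: float
    norm_rep2: float
    norm_both: float
    pct_both: Optional[float]

    def as_table_row(self) -> dict:
        """Rounded presentation row (1 decimal, matching published tables)."""
        return {
            "condition": self.condition,
            "covered_bases": round(self.covered_bases_mean),
            "rep1": round(self.norm_rep1, 1),
            "rep2": round(self.norm_rep2, 1),
            "both": round(self.norm_both, 1),
            "pct_both": round(self.pct_both, 1) if self.pct_both is not None else None,
        }


def intersect_replicates(
    rep1: Sequence[VariantSite],
    rep2: Sequence[VariantSite],
    sample_names: tuple[str, str] = ("rep1", "rep2"),
) -> list[EditingSiteRecord]:
    """Sites called in both replicates with identical (gene, pos, ref, alt).

    Per-replicate depth/alt evidence is carried forward under
    ``sample_names``.  Output is sorted by (gene_id, position).
    """
    by_key = {s.key: s for s in rep2}
    records = []
    for s1 in rep1:
        s2 = by_key.get(s1.key)
        if s2 is None:
            continue
        records.append(
            EditingSiteRecord(
                s1.gene_id,
                s1.position,
                s1.ref_base,
                s1.alt_base,
                samples={
                    sample_names[0]: SiteEvidence(s1.depth, s1.alt_count),
                    sample_names[1]: SiteEvidence(s2.depth, s2.alt_count),
                },
            )
        )
    records.sort(key=lambda r: (r.gene_id, r.position))
    return records


def condition_specific(
    by_condition: Mapping[str, Sequence[EditingSiteRecord]],
    raw_calls: Mapping[str, Sequence[VariantSite]] | None = None,
) -> dict[str, list[EditingSiteRecord]]:
    """Partition reproducible sites into condition-specific sets.

    A site is specific to condition *c* iff it is reproducible in *c* and
    its key appears in no other condition's reproducible set.  Each
    record's ``conditions_reproducible`` and ``specific_to`` fields are
    filled in place.

    When ``raw_calls`` maps conditions to their single-replicate raw call
    lists, a stricter rule applies: the key must also be absent from every
    other condition's raw (pre-intersection) calls.
    """
    keys_by_condition = {
        c: {r.key for r in recs} for c, recs in by_condition.items()
    }
    raw_keys = (
        {c: {s.key for s in sites} for c, sites in raw_calls.items()}
        if raw_calls is not None
        else None
    )
    specific: dict[str, list[EditingSiteRecord]] = {c: [] for c in by_condition}
    for cond, recs in by_condition.items():
        for rec in recs:
            present = {
                c for c, keys in keys_by_condition.items() if rec.key in keys
            }
            rec.conditions_reproducible = present
            others = present - {cond}
            if raw_keys is not None:
                others |= {
                    c for c, keys in raw_keys.items()
                    if c != cond and rec.key in keys
                }
            if not others:
                rec.specific_to = cond
                specific[cond].append(rec)
            else:
                rec.specific_to = None
    return specific


def normalize_per_million(count: int, covered_bases: float) -> float:
    """Events per million covered bases: ``1e6 × count / covered_bases``."""
    if covered_bases <= 0:
        raise ValueError("covered_bases must be positive")
    return 1e6 * count / covered_bases


def pct_both(norm_rep1: float, norm_rep2: float, norm_both: float) -> Optional[float]:
    """"Both" as percent of the mean of the two replicate values."""
    denom = (norm_rep1 + norm_rep2) / 2
    if denom == 0:
        return None
    return 100.0 * norm_both / denom


def _filter_type(sites: Sequence[VariantSite], type_filter: str | None):
    if type_filter is None:
        return list(sites)
    return [s for s in sites if s.ref_base + s.alt_base == type_filter]


def summarize_condition(
    rep1: Sequence[VariantSite],
    rep2: Sequence[VariantSite],
    covered_rep1: float,
    covered_rep2: float,
    condition: str = "",
    type_filter: str | None = None,
) -> ReplicateSummary:
    """Build a replicate-reproducibility summary row for one condition.

    Per-replicate counts are normalised by their own covered bases; the
    intersection count by the mean of the two.  ``type_filter`` (e.g.
    ``"AG"``) restricts all counts to one substitution type.
    """
    if covered_rep1 <= 0 or covered_rep2 <= 0:
        raise ValueError("covered base counts must be positive")
    s1 = _filter_type(rep1, type_filter)
    s2 = _filter_type(rep2, type_filter)
    n_both = len({s.key for s in s1} & {s.key for s in s2})
    covered_mean = (covered_rep1 + covered_rep2) / 2
    norm1 = normalize_per_million(len(s1), covered_rep1)
    norm2 = normalize_per_million(len(s2), covered_rep2)
    norm_both = normalize_per_million(n_both, covered_mean)
    return ReplicateSummary(
        condition=condition,
        covered_bases_mean=covered_mean,
        n_rep1=len(s1),
        n_rep2=len(s2),
        n_both=n_both,
        norm_rep1=norm1,
        norm_rep2=norm2,
        norm_both=norm_both,
        pct_both=pct_both(norm1, norm2, norm_both),
    )
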