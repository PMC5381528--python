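"""Single-sample variant detection from per-base counts.

Thresholds follow the editing-survey convention for filamentous
ascomycetes: a candidate site needs a minimum read depth (default 5),
exactly one alternative base with at least two supporting reads, an
alternative-base fraction of at least 3%, and no qualifying
insertion/deletion evidence at the position.  A separate screen flags
positions where essentially every sample shows the same near-fixed
alternative base (≥95% by default) — these are genome-sequence errors or
strain differences, not editing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ascoedit.io_formats import BaseCountColumn

__all__ = [
    "DetectionParams",
    "VariantSite",
    "ReferenceDiscrepancy",
    "call_variants",
    "count_covered_bases",
    "flag_reference_discrepancies",
]

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for candidate-variant detection.

    min_depth
        Minimum A+C+G+T read depth for a position to be considered (also
        the "covered base" threshold for normalisation denominators).
    min_alt_fraction
        Minimum alternative-base fraction of depth.
    min_alt_reads
        Minimum reads supporting the alternative base; also the veto
        threshold for indel evidence at the position.
    genome_error_fraction
        Alternative-base fraction above which a position counts as
        near-fixed in a sample, for the genome-error screen.
    strict_single_alt
        If True, any second alternative base with ≥1 read voids the
        position.  The default requires a second alternative to reach
        ``min_alt_reads`` before the position is discarded, so a single
        stray error read does not kill a deep position.
    """

    min_depth: int = 5
    min_alt_fraction: float = 0.03
    min_alt_reads: int = 2
    genome_error_fraction: float = 0.95
    strict_single_alt: bool = False

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be ≥ 1")
        if not 0 < self.min_alt_fraction <= 1:
            raise ValueError("min_alt_fraction must be in (0, 1]")
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be ≥ 1")
        if not 0 < self.genome_error_fraction <= 1:
            raise ValueError("genome_error_fraction must be in (0, 1]")


@dataclass(frozen=True)
class VariantSite:
    """A position whose single alternative base passed all thresholds."""

    gene_id: str
    position: int
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")
        if self.alt_count > self.depth:
            raise ValueError("alt_count cannot exceed depth")

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene_id, self.position, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class ReferenceDiscrepancy:
    """A position near-fixed for the same alternative base in every sample."""

    gene_id: str
    position: int
    ref_base: str
    alt_base: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene_id, self.position, self.ref_base, self.alt_base)


def call_variants(
    columns: Iterable[BaseCountColumn], params: DetectionParams = DetectionParams()
) -> list[VariantSite]:
    """Apply the detection thresholds to one sample's count columns.

    A site is emitted iff depth ≥ ``min_depth``, exactly one alternative
    base reaches ``min_alt_reads``, that base's fraction is ≥
    ``min_alt_fraction``, and indel evidence at the column is below
    ``min_alt_reads``.  Positions where two or more distinct alternative
    bases each reach ``min_alt_reads`` are discarded entirely.
    """
    sites = []
    for col in columns:
        depth = col.depth
        if depth < params.min_depth:
            continue
        if col.ref_base not in col.counts:
            continue
        qualifying = [
            b for b in BASES
            if b != col.ref_base and col.counts.get(b, 0) >= params.min_alt_reads
        ]
        if len(qualifying) != 1:
            continue
        alt = qualifying[0]
        if params.strict_single_alt:
            stray = sum(
                col.counts.get(b, 0) for b in BASES if b not in (col.ref_base, alt)
            )
            if stray > 0:
                continue
        alt_count = col.counts[alt]
        if alt_count / depth < params.min_alt_fraction:
            continue
        if col.indel_reads >= params.min_alt_reads:
            continue
        sites.append(
            VariantSite(col.gene_id, col.position, col.ref_base, alt, depth, alt_count)
        )
    return sites


def count_covered_bases(columns: Iterable[BaseCountColumn], min_depth: int = 5) -> int:
    """Number of positions with depth ≥ ``min_depth`` (the "covered bases")."""
    return sum(1 for col in columns if col.depth >= min_depth)


def flag_reference_discrepancies(
    per_sample_columns: Mapping[str, Sequence[BaseCountColumn]],
    params: DetectionParams = DetectionParams(),
) -> list[ReferenceDiscrepancy]:
    """Flag candidate genome-sequence errors / strain differences.

    A position is flagged when, in *every* sample that covers it with
    depth ≥ ``min_depth``, one and the same alternative base has a
    fraction ≥ ``genome_error_fraction``.  Samples that do not cover the
    position abstain; a position covered by no sample is skipped.
    """
    if len(per_sample_columns) < 2:
        raise ValueError("the genome-error screen needs at least two samples")
    by_pos: dict[tuple[str, int], list[BaseCountColumn]] = {}
    for cols in per_sample_columns.values():
        for col in cols:
            by_pos.setdefault((col.gene_id, col.position), []).append(col)
    flagged = []
    for (gene_id, position), cols in sorted(by_pos.items()):
        covered = [c for c in cols if c.depth >= params.min_depth]
        if not covered:
            continue
        candidate: str | None = None
        ok = True
        for col in covered:
            best_alt, best_n = None, -1
            for b in BASES:
                if b != col.ref_base and col.counts.get(b, 0) > best_n:
                    best_alt, best_n = b, col.counts.get(b, 0)
            if best_alt is None or best_n / col.depth < params.genome_error_fraction:
                ok = False
                break
            if candidate is None:
                candidate = best_alt
            elif best_alt != candidate:
                ok = False
                break
        if ok and candidate is not None:
            flagged.append(
                ReferenceDiscrepancy(gene_id, position, covered[0].ref_base, candidate)
            )
    return flagged
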