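"""End-to-end orchestration: pileups in, annotated editing sites out.

The canonical run parses each sample's mpileup, calls candidate
variants under the detection thresholds, screens genome-reference
discrepancies across all samples, intersects replicates per condition,
derives condition-specific sets, classifies substitution types and
codon consequences, and produces replicate summary rows and spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ascoedit.consequences import annotate_sites, consequence_summary
from ascoedit.detection import (
    DetectionParams,
    ReferenceDiscrepancy,
    VariantSite,
    call_variants,
    count_covered_bases,
    flag_reference_discrepancies,
)
from ascoedit.io_formats import BaseCountColumn, GeneModel, parse_mpileup
from ascoedit.replicates import (
    EditingSiteRecord,
    ReplicateSummary,
    condition_specific,
    intersect_replicates,
    summarize_condition,
)
from ascoedit.simulate import SimulatedStudy, SimulationConfig, simulate_study
from ascoedit.spectrum import SpectrumCounts, spectrum

__all__ = ["PipelineResult", "run_pipeline", "run_simulated_study", "RecoveryReport", "evaluate_recovery"]


@dataclass
class PipelineResult:
    """Everything the discovery pipeline computes for one study."""

    params: DetectionParams
    raw_calls: dict[tuple[str, int], list[VariantSite]]
    covered: dict[tuple[str, int], int]
    reference_discrepancies: list[ReferenceDiscrepancy]
    reproducible: dict[str, list[EditingSiteRecord]]
    specific: dict[str, list[EditingSiteRecord]]
    summaries: dict[str, ReplicateSummary] = field(default_factory=dict)
    summaries_ag: dict[str, ReplicateSummary] = field(default_factory=dict)
    spectra: dict[str, SpectrumCounts] = field(default_factory=dict)

    def all_records(self) -> list[EditingSiteRecord]:
        seen: dict[tuple, EditingSiteRecord] = {}
        for recs in self.reproducible.values():
            for r in recs:
                seen.setdefault(r.key, r)
        return sorted(seen.values(), key=lambda r: (r.gene_id, r.position))

    def consequence_counts(self, condition: str, ag_only: bool = True) -> dict:
        recs = self.specific.get(condition, [])
        if ag_only:
            recs = [r for r in recs if r.substitution_type == "AG"]
        return consequence_summary(recs)


def run_pipeline(
    samples: Mapping[tuple[str, int], Sequence[BaseCountColumn] | str],
    params: DetectionParams = DetectionParams(),
    models: Sequence[GeneModel] | None = None,
    exclude_reference_errors: bool = True,
) -> PipelineResult:
    """Run discovery on per-sample pileups or pre-parsed count columns.

    ``samples`` maps (condition, replicate index) to either mpileup text
    or parsed columns.  Positions flagged by the genome-error screen are
    excluded from all editing calls.  When gene models are given,
    consequences are annotated on every reproducible record.
    """
    columns: dict[tuple[str, int], list[BaseCountColumn]] = {}
    for key, value in samples.items():
        columns[key] = (
            list(value) if not isinstance(value, str) else parse_mpileup(value)
        )
    per_sample_for_screen = {f"{c}_{r}": cols for (c, r), cols in columns.items()}
    discrepancies = (
        flag_reference_discrepancies(per_sample_for_screen, params)
        if len(per_sample_for_screen) >= 2
        else []
    )
    bad_positions = {(d.gene_id, d.position) for d in discrepancies}

    raw_calls: dict[tuple[str, int], list[VariantSite]] = {}
    covered: dict[tuple[str, int], int] = {}
    for key, cols in columns.items():
        calls = call_variants(cols, params)
        if exclude_reference_errors:
            calls = [s for s in calls if (s.gene_id, s.position) not in bad_positions]
        raw_calls[key] = calls
        covered[key] = count_covered_bases(cols, params.min_depth)

    conditions = sorted({c for c, _ in columns}, key=lambda c: str(c))
    reproducible: dict[str, list[EditingSiteRecord]] = {}
    summaries: dict[str, ReplicateSummary] = {}
    summaries_ag: dict[str, ReplicateSummary] = {}
    spectra: dict[str, SpectrumCounts] = {}
    for cond in conditions:
        reps = sorted(r for c, r in columns if c == cond)
        if len(reps) != 2:
            raise ValueError(f"condition {cond!r} needs exactly two replicates")
        r1, r2 = raw_calls[(cond, reps[0])], raw_calls[(cond, reps[1])]
        names = (f"{cond}_rep{reps[0]}", f"{cond}_rep{reps[1]}")
        reproducible[cond] = intersect_replicates(r1, r2, names)
        c1, c2 = covered[(cond, reps[0])], covered[(cond, reps[1])]
        summaries[cond] = summarize_condition(r1, r2, c1, c2, condition=cond)
        summaries_ag[cond] = summarize_condition(
            r1, r2, c1, c2, condition=cond, type_filter="AG"
        )
        spectra[cond] = spectrum(reproducible[cond], (c1 + c2) / 2, condition=cond)

    specific = condition_specific(reproducible)

    result = PipelineResult(
        params=params,
        raw_calls=raw_calls,
        covered=covered,
        reference_discrepancies=discrepancies,
        reproducible=reproducible,
        specific=specific,
        summaries=summaries,
        summaries_ag=summaries_ag,
        spectra=spectra,
    )
    if models is not None:
        by_id = {m.gene_id: m for m in models}
        annotate_sites(result.all_records(), by_id)
    return result


@dataclass
class RecoveryReport:
    """Truth-vs-called comparison for a simulated study."""

    n_truth_specific: int
    n_recovered_specific: int
    recovery_rate: float
    n_called_focal: int
    n_false_focal: int
    false_discovery_rate: float
    n_reference_errors_planted: int
    n_reference_errors_flagged: int
    n_consequence_checked: int
    n_consequence_matched: int


def run_simulated_study(
    config: SimulationConfig, seed: int, params: DetectionParams = DetectionParams()
) -> tuple[SimulatedStudy, PipelineResult]:
    """Simulate a study and run the full discovery pipeline on it."""
    study = simulate_study(config, seed)
    result = run_pipeline(study.pileups, params, models=study.models)
    return study, result


def evaluate_recovery(study: SimulatedStudy, result: PipelineResult) -> RecoveryReport:
    """Score the pipeline against the planted truth.

    Recovery: share of planted focal-condition-specific sites that come
    out condition-specific to the focal condition.  False discoveries:
    reproducible calls in the focal condition whose key matches no
    planted site, as a fraction of all focal-condition reproducible
    calls (after reference-error exclusion).  Consequence agreement is
    checked on recovered planted sites with a truth category.
    """
    focal = study.config.focal_condition
    truth_specific = {s.key: s for s in study.truth.specific_sites(focal)}
    called_specific = {r.key: r for r in result.specific.get(focal, [])}
    recovered = set(truth_specific) & set(called_specific)

    focal_calls = {r.key for r in result.reproducible.get(focal, [])}
    truth_keys = study.truth.site_keys()
    false_calls = focal_calls - truth_keys

    flagged = {d.key for d in result.reference_discrepancies}
    planted_errors = {e.key for e in study.truth.reference_errors}

    truth_by_key = {s.key: s for s in study.truth.sites}
    n_checked = n_matched = 0
    for r in result.all_records():
        t = truth_by_key.get(r.key)
        if t is None or t.region != "cds" or t.category is None:
            continue
        if r.consequence is None:
            continue
        n_checked += 1
        if r.consequence.category == t.category:
            n_matched += 1

    return RecoveryReport(
        n_truth_specific=len(truth_specific),
        n_recovered_specific=len(recovered),
        recovery_rate=len(recovered) / len(truth_specific) if truth_specific else 1.0,
        n_called_focal=len(focal_calls),
        n_false_focal=len(false_calls),
        false_discovery_rate=len(false_calls) / len(focal_calls) if focal_calls else 0.0,
        n_reference_errors_planted=len(planted_errors),
        n_reference_errors_flagged=len(planted_errors & flagged),
        n_consequence_checked=n_checked,
        n_consequence_matched=n_matched,
    )
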