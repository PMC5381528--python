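"""Synthetic study generator with known ground truth.

Emulates the study design the pipeline targets: gene-space transcript
models (UTR/CDS/intron structure), three conditions (vegetative, sexual
mycelium, protoperithecia) with two independent biological replicates
each, negative-binomial per-base coverage with a smooth positional
profile (and an optional 3'-bias ramp mimicking linearly amplified
libraries), uniform sequencing error, planted editing sites with
per-condition editing fractions, planted genome-reference errors
(near-fixed alternative base in every sample), cDNA-clone matrices and
expression tables.

Seed discipline: one master seed; every stochastic operation derives a
child seed deterministically from (master, purpose, condition,
replicate), so replicates differ only by derivation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ascoedit.consequences import translate_codon
from ascoedit.io_formats import GeneModel, Segment
from ascoedit.clones import CloneMatrix
from ascoedit.expression import ExpressionTable

__all__ = [
    "SimulationConfig",
    "PlantedSite",
    "PlantedError",
    "TruthTable",
    "SimulatedStudy",
    "child_seed",
    "generate_genes",
    "plant_editing",
    "simulate_sample",
    "simulate_study",
    "simulate_clone_set",
    "generate_expression",
    "ortholog_pairs_from_models",
    "models_to_fasta",
    "models_to_tsv",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))
NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def child_seed(master: int, *tokens) -> int:
    """Deterministic child seed from a master seed and purpose tokens."""
    key = "|".join([str(int(master)), *map(str, tokens)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little")  # < 2**32


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic data.

    Defaults describe the reference simulation: 50 genes, three
    conditions × two replicates, 50× mean coverage, 0.5% sequencing
    error, 100 planted sites (20 A→G specific to the focal condition,
    5 of them stop-loss, plus 80 background variants spread over the 12
    substitution types and present in every condition) and 3 planted
    reference errors.
    """

    n_genes: int = 50
    n_noncoding_genes: int = 0
    conditions: tuple[str, ...] = ("veg", "sex", "proto")
    focal_condition: str = "proto"
    n_replicates: int = 2
    mean_coverage: float = 50.0
    nb_dispersion: float = 20.0  # negative-binomial size parameter
    error_rate: float = 0.005
    profile_amplitude: float = 0.3  # smooth sinusoidal coverage modulation
    three_prime_bias: float = 0.0  # 0 = flat, 1 = strong ramp toward the 3' end
    n_specific_sites: int = 20
    n_stop_loss_sites: int = 5
    n_background_sites: int = 80
    n_reference_errors: int = 3
    specific_fraction_range: tuple[float, float] = (0.15, 0.9)
    background_fraction_range: tuple[float, float] = (0.10, 0.5)
    utr5_range: tuple[int, int] = (40, 120)
    n_internal_codons_range: tuple[int, int] = (80, 200)
    utr3_range: tuple[int, int] = (80, 200)
    intron_prob: float = 0.5
    intron_len_range: tuple[int, int] = (50, 90)
    decorate_reads: bool = True  # sprinkle ^X / $ marks into pileup strings

    def __post_init__(self) -> None:
        if self.focal_condition not in self.conditions:
            raise ValueError("focal_condition must be one of conditions")
        if self.n_stop_loss_sites > self.n_specific_sites:
            raise ValueError("stop-loss sites are a subset of specific sites")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be ≥ 0")
        for lo, hi in (self.specific_fraction_range, self.background_fraction_range):
            if not 0 <= lo <= hi <= 1:
                raise ValueError("fraction ranges must satisfy 0 ≤ lo ≤ hi ≤ 1")


@dataclass
class PlantedSite:
    """Ground truth for one planted editing site."""

    gene_id: str
    position: int
    ref_base: str
    alt_base: str
    fractions: dict[str, float]  # condition → editing fraction
    specific_to: Optional[str]
    region: str
    category: Optional[str] = None  # codon consequence, CDS sites only

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene_id, self.position, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class PlantedError:
    """A planted genome-sequence error (near-fixed alt in all samples)."""

    gene_id: str
    position: int
    ref_base: str
    alt_base: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene_id, self.position, self.ref_base, self.alt_base)


@dataclass
class TruthTable:
    """All planted sites and reference errors for one simulated study."""

    sites: list[PlantedSite] = field(default_factory=list)
    reference_errors: list[PlantedError] = field(default_factory=list)

    def specific_sites(self, condition: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.specific_to == condition]

    def site_keys(self) -> set[tuple]:
        return {s.key for s in self.sites}

    def variants_in(self, condition: str) -> dict[tuple[str, int], tuple[str, float]]:
        """(gene, pos) → (alt, fraction) for sites edited in a condition,
        with reference errors overlaid at fraction 1."""
        out = {
            (s.gene_id, s.position): (s.alt_base, s.fractions.get(condition, 0.0))
            for s in self.sites
            if s.fractions.get(condition, 0.0) > 0
        }
        for e in self.reference_errors:
            out[(e.gene_id, e.position)] = (e.alt_base, 1.0)
        return out


@dataclass
class _GeneLayout:
    """Generator-side bookkeeping: where the CDS codons live in gene space."""

    utr5: int
    n_codons: int  # total codons incl. start and stop
    intron_after_offset: Optional[int]  # spliced-CDS offset after which the intron sits
    intron_len: int
    codons: list[str]

    def gene_position(self, spliced_offset: int) -> int:
        """Map a 1-based spliced-CDS offset to a gene-space position."""
        pos = self.utr5 + spliced_offset
        if self.intron_after_offset is not None and spliced_offset > self.intron_after_offset:
            pos += self.intron_len
        return pos


def generate_genes(
    config: SimulationConfig, seed: int
) -> tuple[list[GeneModel], dict[str, "_GeneLayout"]]:
    """Generate gene models with UTR/CDS/intron structure.

    CDS begins with ATG, internal codons are non-stop, and the CDS ends
    with a stop codon; the 3'UTR provides downstream sequence for
    stop-loss read-through.  Reproducible: a fixed seed yields
    byte-identical sequences.
    """
    rng = np.random.default_rng(child_seed(seed, "genes"))
    models: list[GeneModel] = []
    layouts: dict[str, _GeneLayout] = {}
    total = config.n_genes + config.n_noncoding_genes
    for i in range(total):
        gene_id = f"g{i + 1:03d}"
        if i >= config.n_genes:
            length = int(rng.integers(200, 501))
            seq = "".join(rng.choice(_BASES, size=length))
            models.append(GeneModel(gene_id, seq, (Segment("five_utr", 1, length),)))
            continue
        utr5 = int(rng.integers(*config.utr5_range, endpoint=True))
        n_internal = int(rng.integers(*config.n_internal_codons_range, endpoint=True))
        utr3 = int(rng.integers(*config.utr3_range, endpoint=True))
        codons = (
            ["ATG"]
            + [NONSTOP_CODONS[j] for j in rng.integers(0, len(NONSTOP_CODONS), n_internal)]
            + [STOP_CODONS[int(rng.integers(0, 3))]]
        )
        cds = "".join(codons)
        has_intron = rng.random() < config.intron_prob
        intron_len = int(rng.integers(*config.intron_len_range, endpoint=True))
        segments: list[Segment]
        if has_intron:
            # intron between two codons, away from the CDS ends
            split_codon = int(rng.integers(10, len(codons) - 10))
            split = 3 * split_codon  # spliced-CDS offset before the intron
            intron_seq = "".join(rng.choice(_BASES, size=intron_len))
            seq = (
                "".join(rng.choice(_BASES, size=utr5))
                + cds[:split]
                + intron_seq
                + cds[split:]
                + "".join(rng.choice(_BASES, size=utr3))
            )
            segments = [
                Segment("five_utr", 1, utr5),
                Segment("cds", utr5 + 1, utr5 + split),
                Segment("intron", utr5 + split + 1, utr5 + split + intron_len),
                Segment("cds", utr5 + split + intron_len + 1, utr5 + intron_len + len(cds)),
                Segment("three_utr", utr5 + intron_len + len(cds) + 1, utr5 + intron_len + len(cds) + utr3),
            ]
            layout = _GeneLayout(utr5, len(codons), split, intron_len, codons)
        else:
            seq = (
                "".join(rng.choice(_BASES, size=utr5))
                + cds
                + "".join(rng.choice(_BASES, size=utr3))
            )
            segments = [
                Segment("five_utr", 1, utr5),
                Segment("cds", utr5 + 1, utr5 + len(cds)),
                Segment("three_utr", utr5 + len(cds) + 1, utr5 + len(cds) + utr3),
            ]
            layout = _GeneLayout(utr5, len(codons), None, 0, codons)
        models.append(GeneModel(gene_id, seq, tuple(segments)))
        layouts[gene_id] = layout
    return models, layouts


def models_to_fasta(models: Sequence[GeneModel], width: int = 70) -> str:
    chunks = []
    for m in models:
        chunks.append(f">{m.gene_id}")
        for i in range(0, len(m.sequence), width):
            chunks.append(m.sequence[i : i + width])
    return "\n".join(chunks) + "\n"


def models_to_tsv(models: Sequence[GeneModel]) -> str:
    lines = ["gene_id\tkind\tstart\tend"]
    for m in models:
        for s in m.segments:
            lines.append(f"{m.gene_id}\t{s.kind}\t{s.start}\t{s.end}")
    return "\n".join(lines) + "\n"


def _draw_fraction(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    lo, hi = lo_hi
    return float(rng.uniform(lo, hi))


def plant_editing(
    models: Sequence[GeneModel],
    layouts: dict[str, _GeneLayout],
    config: SimulationConfig,
    seed: int,
) -> TruthTable:
    """Plant editing sites and reference errors with known consequences.

    Condition-specific A→G sites are edited only in the focal condition
    (fraction 0 elsewhere); the requested number of them sits on
    annotated TGA/TAG stop codons to guarantee stop-loss cases, and
    their codon consequences are recorded from the generator's own codon
    bookkeeping.  Background sites cycle through the 12 substitution
    types and carry the same editing fraction in every condition.
    """
    rng = np.random.default_rng(child_seed(seed, "truth"))
    truth = TruthTable()
    used: set[tuple[str, int]] = set()
    coding = [m for m in models if not m.noncoding]

    def claim(gene_id: str, pos: int) -> bool:
        if (gene_id, pos) in used:
            return False
        used.add((gene_id, pos))
        return True

    def focal_fractions() -> dict[str, float]:
        f = _draw_fraction(rng, config.specific_fraction_range)
        return {c: (f if c == config.focal_condition else 0.0) for c in config.conditions}

    # stop-loss sites: the editable A of a TGA (3rd base) or TAG (2nd base) stop
    editable = [m for m in coding if layouts[m.gene_id].codons[-1] in ("TGA", "TAG")]
    if len(editable) < config.n_stop_loss_sites:
        raise ValueError("not enough TGA/TAG-terminated genes for stop-loss sites")
    picked = rng.choice(len(editable), size=config.n_stop_loss_sites, replace=False)
    for idx in sorted(picked):
        m = editable[idx]
        lay = layouts[m.gene_id]
        stop = lay.codons[-1]
        within = 3 if stop == "TGA" else 2
        spliced_offset = 3 * (lay.n_codons - 1) + within
        pos = lay.gene_position(spliced_offset)
        assert m.sequence[pos - 1] == "A"
        claim(m.gene_id, pos)
        truth.sites.append(
            PlantedSite(
                m.gene_id, pos, "A", "G", focal_fractions(),
                specific_to=config.focal_condition, region="cds", category="stop_loss",
            )
        )

    # remaining condition-specific A→G sites: 2/3 in CDS codons (consequence
    # known from the codon), the rest in UTR/intron regions
    n_rest = config.n_specific_sites - config.n_stop_loss_sites
    n_cds = (2 * n_rest + 2) // 3
    for k in range(n_rest):
        in_cds = k < n_cds
        for _ in range(10000):
            m = coding[int(rng.integers(0, len(coding)))]
            lay = layouts[m.gene_id]
            if in_cds:
                ci = int(rng.integers(1, lay.n_codons))  # excludes the stop codon
                codon = lay.codons[ci - 1]
                a_positions = [j + 1 for j, b in enumerate(codon) if b == "A"]
                if not a_positions:
                    continue
                cp = a_positions[int(rng.integers(0, len(a_positions)))]
                pos = lay.gene_position(3 * (ci - 1) + cp)
                if not claim(m.gene_id, pos):
                    continue
                alt_codon = codon[: cp - 1] + "G" + codon[cp:]
                ref_aa, alt_aa = translate_codon(codon), translate_codon(alt_codon)
                category = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
                truth.sites.append(
                    PlantedSite(
                        m.gene_id, pos, "A", "G", focal_fractions(),
                        specific_to=config.focal_condition, region="cds",
                        category=category,
                    )
                )
                break
            else:
                seg = m.segments[int(rng.integers(0, len(m.segments)))]
                if seg.kind == "cds":
                    continue
                pos = int(rng.integers(seg.start, seg.end + 1))
                if m.sequence[pos - 1] != "A" or not claim(m.gene_id, pos):
                    continue
                truth.sites.append(
                    PlantedSite(
                        m.gene_id, pos, "A", "G", focal_fractions(),
                        specific_to=config.focal_condition, region=seg.kind,
                    )
                )
                break
        else:
            raise ValueError("could not place a condition-specific site")

    # background sites: cycle over the 12 types, present in all conditions
    types = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
    for k in range(config.n_background_sites):
        ref, alt = types[k % len(types)]
        for _ in range(10000):
            m = models[int(rng.integers(0, len(models)))]
            pos = int(rng.integers(1, len(m.sequence) + 1))
            if m.sequence[pos - 1] != ref or not claim(m.gene_id, pos):
                continue
            f = _draw_fraction(rng, config.background_fraction_range)
            region, _ = _region_of(m, pos)
            truth.sites.append(
                PlantedSite(
                    m.gene_id, pos, ref, alt,
                    {c: f for c in config.conditions},
                    specific_to=None, region=region,
                )
            )
            break
        else:
            raise ValueError(f"could not place a {ref}→{alt} background site")

    # reference errors: near-fixed alternative base in every sample
    for _ in range(config.n_reference_errors):
        for _ in range(10000):
            m = models[int(rng.integers(0, len(models)))]
            pos = int(rng.integers(1, len(m.sequence) + 1))
            ref = m.sequence[pos - 1]
            if ref == "N" or not claim(m.gene_id, pos):
                continue
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            truth.reference_errors.append(PlantedError(m.gene_id, pos, ref, alt))
            break
        else:
            raise ValueError("could not place a reference error")
    return truth


def _region_of(model: GeneModel, position: int) -> tuple[str, Optional[Segment]]:
    if model.noncoding:
        return "noncoding_gene", None
    for seg in model.segments:
        if seg.start <= position <= seg.end:
            return seg.kind, seg
    raise ValueError("position outside gene")


def _depth_means(
    length: int, config: SimulationConfig, phase: float
) -> np.ndarray:
    i = np.arange(length)
    profile = 1.0 + config.profile_amplitude * np.sin(2 * np.pi * i / length + phase)
    if config.three_prime_bias > 0:
        profile = profile * (1.0 + config.three_prime_bias * (2 * i / length - 1.0))
    return np.clip(config.mean_coverage * profile, 0.0, None)


def simulate_sample(
    models: Sequence[GeneModel],
    truth: TruthTable,
    condition: str,
    replicate_index: int,
    config: SimulationConfig,
    seed: int,
) -> str:
    """Simulate one sample's mpileup text.

    Depth is negative-binomial around a smooth per-gene coverage profile
    (profile phase is a property of the gene, shared by all samples).
    Each read shows the template base with probability 1−e and each of
    the three other bases with probability e/3; at a planted variant
    with fraction f, the template is the alternative base with
    probability f.  Replicates differ only by seed derivation.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(child_seed(seed, "pileup", condition, replicate_index))
    variants = truth.variants_in(condition)
    e = config.error_rate
    k = config.nb_dispersion
    lines: list[str] = []
    for m in models:
        L = len(m.sequence)
        phase_rng = np.random.default_rng(child_seed(seed, "profile", m.gene_id))
        means = _depth_means(L, config, float(phase_rng.uniform(0, 2 * np.pi)))
        if config.mean_coverage > 0:
            depths = rng.negative_binomial(k, k / (k + np.maximum(means, 1e-9)))
        else:
            depths = np.zeros(L, dtype=int)
        # error reads at non-variant positions, vectorised
        err_totals = rng.binomial(depths, e) if e > 0 else np.zeros(L, dtype=int)
        decorate = (
            rng.random(L) < 0.05 if config.decorate_reads else np.zeros(L, dtype=bool)
        )
        for pos0 in range(L):
            depth = int(depths[pos0])
            ref = m.sequence[pos0]
            gene_pos = pos0 + 1
            if depth == 0:
                lines.append(f"{m.gene_id}\t{gene_pos}\t{ref}\t0\t*\t*")
                continue
            var = variants.get((m.gene_id, gene_pos))
            counts = {"A": 0, "C": 0, "G": 0, "T": 0}
            if var is None:
                n_err = int(err_totals[pos0])
                counts[ref] = depth - n_err
                if n_err:
                    split = rng.multinomial(n_err, [1 / 3] * 3)
                    for b, c in zip([b for b in "ACGT" if b != ref], split):
                        counts[b] += int(c)
            else:
                alt, f = var
                probs = []
                for b in "ACGT":
                    p = 0.0
                    if b == alt:
                        p += f * (1 - e)
                    else:
                        p += f * (e / 3)
                    if b == ref:
                        p += (1 - f) * (1 - e)
                    else:
                        p += (1 - f) * (e / 3)
                    probs.append(p)
                draw = rng.multinomial(depth, probs)
                for b, c in zip("ACGT", draw):
                    counts[b] = int(c)
            parts = []
            n_ref = counts.pop(ref) if ref in counts else 0
            parts.append("." * ((n_ref + 1) // 2) + "," * (n_ref // 2))
            for b, c in counts.items():
                parts.append(b * ((c + 1) // 2) + b.lower() * (c // 2))
            bases = "".join(parts)
            if decorate[pos0] and bases:
                bases = "^]" + bases + "$"
            lines.append(f"{m.gene_id}\t{gene_pos}\t{ref}\t{depth}\t{bases}\t{'I' * depth}")
    return "\n".join(lines) + "\n"


@dataclass
class SimulatedStudy:
    """A complete synthetic study: models, ground truth, per-sample pileups."""

    config: SimulationConfig
    models: list[GeneModel]
    layouts: dict[str, _GeneLayout]
    truth: TruthTable
    pileups: dict[tuple[str, int], str]  # (condition, replicate) → mpileup text


def simulate_study(config: SimulationConfig, seed: int) -> SimulatedStudy:
    """Generate models, plant truth and simulate every sample's pileup."""
    models, layouts = generate_genes(config, seed)
    truth = plant_editing(models, layouts, config, seed)
    pileups = {}
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            pileups[(cond, rep)] = simulate_sample(models, truth, cond, rep, config, seed)
    return SimulatedStudy(config, models, layouts, truth, pileups)


def simulate_clone_set(
    site_positions: Sequence[int],
    probabilities: Sequence[float],
    dependence: float,
    n_clones: int,
    seed: int,
    gene_id: str = "g001",
    sample: str = "3d",
) -> CloneMatrix:
    """Simulate a cDNA-clone editing matrix with tunable site coupling.

    ``dependence`` interpolates between fully independent sites (0) and
    full coupling through a shared per-clone latent state (1): with
    probability ``dependence`` a clone uses one shared uniform draw for
    all its sites (comonotone coupling), otherwise independent draws.
    Marginal frequencies equal ``probabilities`` for any dependence.
    """
    if not 0 <= dependence <= 1:
        raise ValueError("dependence must be in [0, 1]")
    p = np.asarray(probabilities, dtype=float)
    if len(p) != len(site_positions):
        raise ValueError("need one probability per site")
    rng = np.random.default_rng(child_seed(seed, "clones", gene_id, sample))
    coupled = rng.random(n_clones) < dependence
    shared = rng.random(n_clones)
    indep = rng.random((n_clones, len(p)))
    u = np.where(coupled[:, None], shared[:, None], indep)
    matrix = (u < p).astype(int)
    return CloneMatrix(gene_id, tuple(site_positions), matrix, sample)


def generate_expression(
    models: Sequence[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
    seed: int,
    focal_upshift: float = 2.0,
    min_edit_fraction: float = 0.10,
) -> ExpressionTable:
    """Per-gene expression with an upshift for product-changing edited genes.

    Baseline abundance is log-normal per gene with mild per-condition
    noise; genes carrying a focal-condition-specific, product-changing
    planted site edited at ≥ ``min_edit_fraction`` get ``focal_upshift``×
    expression in the focal condition (the association the expression-
    group analysis is meant to detect).
    """
    import pandas as pd

    rng = np.random.default_rng(child_seed(seed, "expression"))
    upshifted = {
        s.gene_id
        for s in truth.sites
        if s.specific_to == config.focal_condition
        and s.category in ("nonsynonymous", "stop_loss")
        and s.fractions.get(config.focal_condition, 0.0) >= min_edit_fraction
    }
    rows = []
    for m in models:
        base = float(rng.lognormal(np.log(100.0), 0.7))
        for cond in config.conditions:
            value = base * float(rng.lognormal(0.0, 0.3))
            if cond == config.focal_condition and m.gene_id in upshifted:
                value *= focal_upshift
            rows.append({"gene_id": m.gene_id, "condition": cond, "value": value})
    return ExpressionTable(pd.DataFrame(rows))


def ortholog_pairs_from_models(
    models_a: Sequence[GeneModel], models_b: Sequence[GeneModel]
):
    """Pair coding genes of two simulated species one-to-one by rank.

    Proteins are the reference translations of the spliced CDS.  A
    stand-in for a reciprocal-BLAST ortholog table when both species are
    synthetic.
    """
    from ascoedit.conservation import OrthologPair
    from ascoedit.consequences import _translate_until_stop

    pairs = []
    coding_a = [m for m in models_a if not m.noncoding and m.complete]
    coding_b = [m for m in models_b if not m.noncoding and m.complete]
    for ma, mb in zip(coding_a, coding_b):
        prot_a, _ = _translate_until_stop(ma.spliced_cds)
        prot_b, _ = _translate_until_stop(mb.spliced_cds)
        if prot_a and prot_b:
            pairs.append(OrthologPair(ma.gene_id, mb.gene_id, prot_a, prot_b))
    return pairs
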