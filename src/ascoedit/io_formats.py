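"""Readers and writers for the formats the pipeline touches.

Coordinates are 1-based inclusive in *gene space*: positions along a
single gene's unspliced sense-strand sequence (5'UTR + CDS exons +
introns + 3'UTR).  Mapping to gene space rather than the genome means an
A-to-G change is observed directly as A→G regardless of the gene's
genomic strand (on the genome, reverse-strand A→G would alias to T→C).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FastaFormatError",
    "GeneModelError",
    "PileupParseError",
    "Segment",
    "GeneModel",
    "BaseCountColumn",
    "read_fasta",
    "read_gene_models",
    "parse_mpileup",
    "write_site_table",
    "read_site_table",
    "write_vcf",
]

SEGMENT_KINDS = ("five_utr", "cds", "intron", "three_utr")

# full IUPAC nucleotide set accepted on input; models restrict further
_IUPAC = set("ACGTNRYSWKMBDHV")


class FastaFormatError(ValueError):
    """Malformed FASTA input (duplicate ids, non-IUPAC characters)."""


class GeneModelError(ValueError):
    """Gene structure annotation inconsistent with the sequence."""


class PileupParseError(ValueError):
    """Malformed samtools-mpileup line."""


@dataclass(frozen=True)
class Segment:
    """One gene-space structural segment (1-based inclusive coordinates)."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise GeneModelError(f"unknown segment kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise GeneModelError(
                f"bad segment coordinates {self.start}-{self.end} for kind {self.kind}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """A gene's unspliced sense-strand sequence plus its segment structure.

    Invariants enforced at construction: segments tile ``[1, len(sequence)]``
    without gaps or overlap, and the sequence alphabet is A/C/G/T/N.  A
    model without CDS segments is flagged noncoding; a model whose
    concatenated CDS length is not divisible by three is flagged
    incomplete (kept, but codon arithmetic refuses it).
    """

    gene_id: str
    sequence: str
    segments: tuple[Segment, ...]
    complete: bool = field(init=False)
    noncoding: bool = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise GeneModelError(f"{self.gene_id}: non-ACGTN characters {bad}")
        segs = tuple(sorted(self.segments, key=lambda s: s.start))
        expected = 1
        for s in segs:
            if s.start < expected:
                raise GeneModelError(
                    f"{self.gene_id}: segment {s.kind} {s.start}-{s.end} overlaps previous"
                )
            if s.start > expected:
                raise GeneModelError(
                    f"{self.gene_id}: gap before {s.kind} at {expected}-{s.start - 1}"
                )
            expected = s.end + 1
        if expected != len(self.sequence) + 1:
            raise GeneModelError(
                f"{self.gene_id}: segments cover 1-{expected - 1} of a "
                f"{len(self.sequence)}-base gene"
            )
        self.segments = segs
        self.noncoding = not any(s.kind == "cds" for s in segs)
        self.complete = (not self.noncoding) and self.cds_length % 3 == 0

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "cds")

    @property
    def cds_length(self) -> int:
        return sum(len(s) for s in self.cds_segments)

    @property
    def spliced_cds(self) -> str:
        """CDS segments concatenated in order (introns excised)."""
        return "".join(self.sequence[s.start - 1 : s.end] for s in self.cds_segments)

    def base_at(self, position: int) -> str:
        if not 1 <= position <= len(self.sequence):
            raise GeneModelError(f"{self.gene_id}: position {position} out of range")
        return self.sequence[position - 1]


@dataclass
class BaseCountColumn:
    """Per-position base counts for one sample (one mpileup column).

    ``depth`` counts A/C/G/T calls only; N calls, deletions (``*``) and
    reference skips are excluded from the thresholding denominator.
    """

    gene_id: str
    position: int
    ref_base: str
    counts: dict[str, int]
    indel_reads: int = 0

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: uppercase sequence}`` map.

    Raises :class:`FastaFormatError` on duplicate record ids or characters
    outside the IUPAC nucleotide alphabet.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FastaFormatError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not set(seq) <= _IUPAC:
            bad = sorted(set(seq) - _IUPAC)
            raise FastaFormatError(f"{rec.id}: non-IUPAC characters {bad}")
        out[rec.id] = seq
    return out


_GFF_KIND_MAP = {
    "five_prime_UTR": "five_utr",
    "three_prime_UTR": "three_utr",
    "CDS": "cds",
    "intron": "intron",
}


def _iter_annotation_rows(path: Path) -> Iterator[tuple[str, str, int, int]]:
    """Yield (gene_id, kind, start, end) rows from TSV or GFF3 annotation.

    The canonical dialect is a 4-column TSV (gene_id, kind, start, end,
    optional header).  GFF3 files (by .gff/.gff3 suffix) are accepted with
    the seqid column holding the gene id and coordinates already in gene
    space; feature types other than CDS/UTR/intron are ignored.
    """
    if path.suffix.lower() in {".gff", ".gff3"}:
        from gffutils.feature import feature_from_line

        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                feat = feature_from_line(line)
                kind = _GFF_KIND_MAP.get(feat.featuretype)
                if kind is None:
                    continue
                yield feat.seqid, kind, feat.start, feat.end
        return
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0] == "gene_id":
                continue
            if len(parts) < 4:
                raise GeneModelError(f"{path}: expected 4 columns, got {len(parts)}")
            yield parts[0], parts[1], int(parts[2]), int(parts[3])


def read_gene_models(path: str | Path, sequences: Mapping[str, str]) -> list[GeneModel]:
    """Read gene structure annotation and validate against the sequences.

    Every annotated gene must have a sequence; segments must tile the
    sequence exactly.  Models lacking CDS come out flagged ``noncoding``,
    models with CDS length not divisible by 3 flagged not ``complete``.
    """
    by_gene: dict[str, list[Segment]] = {}
    for gene_id, kind, start, end in _iter_annotation_rows(Path(path)):
        by_gene.setdefault(gene_id, []).append(Segment(kind, start, end))
    models = []
    for gene_id, segs in by_gene.items():
        if gene_id not in sequences:
            raise GeneModelError(f"annotated gene {gene_id!r} has no sequence")
        models.append(GeneModel(gene_id, sequences[gene_id], tuple(segs)))
    return models


def parse_mpileup(source: str | Path | io.TextIOBase | Iterable[str]) -> list[BaseCountColumn]:
    """Parse samtools-mpileup 6-column text into per-base count columns.

    Read-bases symbols are consumed per the mpileup dialect: ``.``/``,``
    count toward the reference base, letter calls toward their base
    (case-folded), ``+N``/``-N`` indel runs are consumed and tallied into
    ``indel_reads``, and ``^`` (with its mapping-quality byte), ``$``,
    ``*``, ``>``, ``<`` and N calls contribute to no base count.
    """
    if isinstance(source, (str, Path)) and "\t" not in str(source):
        fh: Iterable[str] = open(source)
    elif isinstance(source, str):
        fh = io.StringIO(source)
    else:
        fh = source
    columns = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise PileupParseError(f"line {lineno}: expected ≥5 columns, got {len(parts)}")
        gene_id, pos_s, ref = parts[0], parts[1], parts[2].upper()
        bases = parts[4] if len(parts) > 4 else ""
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        indel_reads = 0
        i = 0
        n = len(bases)
        while i < n:
            c = bases[i]
            if c == "^":
                i += 2  # caret plus mapping-quality byte
                continue
            if c == "$":
                i += 1
                continue
            if c in "+-":
                j = i + 1
                while j < n and bases[j].isdigit():
                    j += 1
                if j == i + 1:
                    raise PileupParseError(
                        f"line {lineno}: indel run without length at offset {i}"
                    )
                run = int(bases[i + 1 : j])
                i = j + run
                indel_reads += 1
                continue
            if c in ".,":
                if ref in counts:
                    counts[ref] += 1
            elif c.upper() in counts:
                counts[c.upper()] += 1
            elif c in "*><Nn":
                pass  # deletions, ref skips and N calls carry no base evidence
            else:
                raise PileupParseError(f"line {lineno}: unexpected symbol {c!r}")
            i += 1
        columns.append(BaseCountColumn(gene_id, int(pos_s), ref, counts, indel_reads))
    if isinstance(source, (str, Path)) and "\t" not in str(source):
        fh.close()  # type: ignore[union-attr]
    return columns


def _site_rows(sites: Sequence) -> tuple[list[str], list[dict]]:
    sample_names: list[str] = []
    for s in sites:
        for name in s.samples:
            if name not in sample_names:
                sample_names.append(name)
    rows = []
    for s in sorted(sites, key=lambda s: (s.gene_id, s.position)):
        row = {
            "gene_id": s.gene_id,
            "position": s.position,
            "ref": s.ref_base,
            "alt": s.alt_base,
            "substitution_type": s.substitution_type,
            "conditions": ",".join(sorted(s.conditions_reproducible)),
            "specific_to": s.specific_to or ".",
        }
        cons = getattr(s, "consequence", None)
        row["region"] = cons.region if cons else "."
        row["category"] = (cons.category or ".") if cons else "."
        row["ref_aa"] = (cons.ref_aa or ".") if cons else "."
        row["alt_aa"] = (cons.alt_aa or ".") if cons else "."
        for name in sample_names:
            ev = s.samples.get(name)
            row[f"{name}_depth"] = ev.depth if ev else 0
            row[f"{name}_alt"] = ev.alt_count if ev else 0
            row[f"{name}_frac"] = f"{ev.alt_fraction:.4f}" if ev else f"{0:.4f}"
        rows.append(row)
    return sample_names, rows


def write_site_table(sites: Sequence, path: str | Path) -> None:
    """Write editing-site records as a TSV, sorted by (gene_id, position).

    Alt fractions are formatted with 4 decimals; per-sample evidence is
    flattened into ``<sample>_depth/_alt/_frac`` columns.
    """
    sample_names, rows = _site_rows(sites)
    base_cols = [
        "gene_id", "position", "ref", "alt", "substitution_type",
        "conditions", "specific_to", "region", "category", "ref_aa", "alt_aa",
    ]
    cols = base_cols + [f"{n}_{f}" for n in sample_names for f in ("depth", "alt", "frac")]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a site table written by :func:`write_site_table`."""
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def write_vcf(sites: Sequence, path: str | Path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Export sites as minimal VCF 4.2 with the gene id as CHROM.

    POS is the gene-space position, not a genomic coordinate; the header
    says so.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=ascoedit",
        '##INFO=<ID=COND,Number=.,Type=String,Description="Conditions with reproducible evidence">',
        "##comment=POS is a 1-based position in unspliced gene space, not a genomic coordinate",
    ]
    if contig_lengths:
        for cid, clen in contig_lengths.items():
            lines.append(f"##contig=<ID={cid},length={clen}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for s in sorted(sites, key=lambda s: (s.gene_id, s.position)):
        cond = ",".join(sorted(s.conditions_reproducible)) or "."
        lines.append(
            f"{s.gene_id}\t{s.position}\t.\t{s.ref_base}\t{s.alt_base}\t.\t.\tCOND={cond}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
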