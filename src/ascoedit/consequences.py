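"""Codon-consequence classification of edited positions.

A site is located within its gene model (5'UTR / CDS / intron / 3'UTR);
CDS sites are mapped through the spliced CDS to a codon and classified
by translating the reference and edited codon with the standard nuclear
genetic code.  Editing away an annotated stop codon (stop-loss) extends
translation: read-through continues in frame through the *unspliced*
downstream gene sequence (annotation beyond the stop is untrusted —
mis-annotated introns are exactly where such extensions are
biologically real) until the next stop or the transcript end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from ascoedit.io_formats import GeneModel

__all__ = [
    "Consequence",
    "ConsistencyError",
    "locate",
    "classify_site",
    "edited_protein",
    "translate_codon",
]

PRODUCT_CHANGING = ("nonsynonymous", "stop_loss", "stop_gain")


class ConsistencyError(ValueError):
    """Site and gene model disagree (sequence/annotation desync)."""


def translate_codon(codon: str) -> str:
    """Standard-code translation of a single codon; stop is ``*``."""
    if len(codon) != 3:
        raise ValueError(f"codon must have 3 bases, got {codon!r}")
    return str(Seq(codon).translate(table=1))


@dataclass
class Consequence:
    """Where an edited position falls and what it does to the product."""

    region: str  # five_utr | cds | intron | three_utr | noncoding_gene
    codon_index: Optional[int] = None  # 1-based codon number in the spliced CDS
    codon_position: Optional[int] = None  # 1-3 within the codon
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    category: Optional[str] = None  # synonymous | nonsynonymous | stop_loss | stop_retained | stop_gain
    extension_aa: Optional[int] = None  # residues gained (stop_loss only)

    @property
    def changes_product(self) -> bool:
        """True for categories predicted to yield a different gene product.

        stop_retained counts with synonymous as "no product change".
        """
        return self.category in PRODUCT_CHANGING


def locate(position: int, model: GeneModel) -> tuple[str, Optional[int]]:
    """Containing segment kind and, for CDS, the 1-based spliced-CDS offset.

    The offset counts through the CDS segments concatenated in order with
    introns excised.  Noncoding models return ``("noncoding_gene", None)``.
    """
    if not 1 <= position <= len(model.sequence):
        raise ValueError(f"position {position} outside gene {model.gene_id}")
    if model.noncoding:
        return "noncoding_gene", None
    cds_before = 0
    for seg in model.segments:
        if seg.start <= position <= seg.end:
            if seg.kind == "cds":
                return "cds", cds_before + (position - seg.start + 1)
            return seg.kind, None
        if seg.kind == "cds":
            cds_before += len(seg)
    raise AssertionError("segments tile the gene; unreachable")


def classify_site(site, model: GeneModel) -> Consequence:
    """Classify one site's coding consequence against its gene model.

    ``site`` needs gene_id / position / ref_base / alt_base.  The model
    sequence must carry the site's reference base at the position,
    otherwise a :class:`ConsistencyError` signals annotation desync.
    CDS sites on models flagged incomplete get region only.
    """
    if site.gene_id != model.gene_id:
        raise ConsistencyError(f"site gene {site.gene_id} vs model {model.gene_id}")
    if model.base_at(site.position) != site.ref_base:
        raise ConsistencyError(
            f"{model.gene_id}:{site.position} model has "
            f"{model.base_at(site.position)}, site claims ref {site.ref_base}"
        )
    region, offset = locate(site.position, model)
    if region != "cds":
        return Consequence(region=region)
    if not model.complete:
        return Consequence(region="cds")
    assert offset is not None
    codon_index = (offset - 1) // 3 + 1
    codon_position = (offset - 1) % 3 + 1
    spliced = model.spliced_cds
    ref_codon = spliced[3 * (codon_index - 1) : 3 * codon_index]
    alt_codon = (
        ref_codon[: codon_position - 1] + site.alt_base + ref_codon[codon_position:]
    )
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == "*" and alt_aa == "*":
        category = "stop_retained"
    elif ref_aa == "*":
        category = "stop_loss"
    elif alt_aa == "*":
        category = "stop_gain"
    elif ref_aa == alt_aa:
        category = "synonymous"
    else:
        category = "nonsynonymous"
    cons = Consequence(
        region="cds",
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        category=category,
    )
    if category == "stop_loss" and (site.ref_base, site.alt_base) == ("A", "G"):
        _, extension, _ = edited_protein(model, [site.position])
        cons.extension_aa = extension
    return cons


def _translate_until_stop(seq: str) -> tuple[str, bool]:
    """Translate in frame until a stop codon; returns (protein, stopped)."""
    aas = []
    for i in range(0, len(seq) - 2, 3):
        aa = translate_codon(seq[i : i + 3])
        if aa == "*":
            return "".join(aas), True
        aas.append(aa)
    return "".join(aas), False


def edited_protein(
    model: GeneModel, applied_sites: Sequence[int]
) -> tuple[str, int, bool]:
    """Protein predicted after applying A→G edits at the given positions.

    Returns ``(protein, extension_aa, overran)``.  The spliced CDS is
    translated with all edits applied; if the annotated stop has been
    edited away, translation continues in frame through the literal
    (unspliced) gene sequence downstream of the last CDS segment until
    the next stop.  ``extension_aa`` counts the residues translated
    beyond the annotated CDS (the recoded stop codon itself is not
    counted as gained); ``overran`` flags translation running off the
    transcript end without meeting a stop.
    """
    seq = list(model.sequence)
    for pos in applied_sites:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {pos} outside gene {model.gene_id}")
        if seq[pos - 1] != "A":
            raise ValueError(
                f"{model.gene_id}:{pos} is {seq[pos - 1]}, A→G edits only"
            )
        seq[pos - 1] = "G"
    edited = "".join(seq)
    if model.noncoding or not model.complete:
        raise ValueError(f"{model.gene_id} has no complete CDS to translate")
    spliced = "".join(edited[s.start - 1 : s.end] for s in model.cds_segments)
    ref_protein, _ = _translate_until_stop(model.spliced_cds)
    protein, stopped = _translate_until_stop(spliced)
    overran = False
    if not stopped:
        # annotated stop lost: read through the unspliced downstream sequence
        downstream_start = model.cds_segments[-1].end  # 0-based index just past CDS
        tail, stopped_tail = _translate_until_stop(edited[downstream_start:])
        extension = len(tail)
        protein += tail
        overran = not stopped_tail
    else:
        extension = len(protein) - len(ref_protein)
    return protein, extension, overran


def annotate_sites(records: Sequence, models: dict[str, GeneModel]) -> None:
    """Fill ``record.consequence`` in place for every record with a model."""
    for rec in records:
        model = models.get(rec.gene_id)
        if model is None:
            continue
        rec.consequence = classify_site(rec, model)


def product_changing_percent(
    n_nonsynonymous: int, n_stop_loss: int, n_total: int, n_stop_gain: int = 0
) -> float:
    """Share of sites predicted to yield a different gene product.

    The counting identity behind "different product" summaries:
    ``100 × (nonsynonymous + stop_loss [+ stop_gain]) / total sites``.
    Synonymous and stop-retained sites count as "no product change".
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * (n_nonsynonymous + n_stop_loss + n_stop_gain) / n_total


def consequence_summary(records: Sequence) -> dict:
    """Counting identity over annotated sites.

    cds sites = synonymous + nonsynonymous + stop_loss + stop_retained
    (+ stop_gain for non-A→G types); "different product" share =
    (nonsynonymous + stop_loss + stop_gain) / all sites.  Both
    conventions for stop_retained (with/without the coding total) are
    derivable from the returned counts.
    """
    counts = {
        "total": 0,
        "cds": 0,
        "synonymous": 0,
        "nonsynonymous": 0,
        "stop_loss": 0,
        "stop_retained": 0,
        "stop_gain": 0,
        "noncoding_regions": 0,
    }
    for rec in records:
        cons = rec.consequence
        if cons is None:
            continue
        counts["total"] += 1
        if cons.region == "cds" and cons.category is not None:
            counts["cds"] += 1
            counts[cons.category] += 1
        else:
            counts["noncoding_regions"] += 1
    changed = counts["nonsynonymous"] + counts["stop_loss"] + counts["stop_gain"]
    counts["product_changing"] = changed
    counts["pct_product_changing"] = (
        100.0 * changed / counts["total"] if counts["total"] else None
    )
    return counts
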