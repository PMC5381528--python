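import numpy as np
import pytest

from ascoedit.consequences import (
    ConsistencyError,
    classify_site,
    edited_protein,
    locate,
    translate_codon,
)
from ascoedit.detection import VariantSite
from ascoedit.io_formats import GeneModel, Segment

STOPS = {"TAA", "TAG", "TGA"}
CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def model_with_codon(codon, stop="TAA"):
    """5'UTR CCT + CDS (ATG <codon> <stop>) + 3'UTR with an in-frame stop."""
    cds = "ATG" + codon + stop
    seq = "CCT" + cds + "AAATAAGGG"
    return GeneModel(
        "g1", seq,
        (Segment("five_utr", 1, 3), Segment("cds", 4, 3 + len(cds)),
         Segment("three_utr", 4 + len(cds), len(seq))),
    )


def site_at(model, pos, alt="G"):
    ref = model.base_at(pos)
    return VariantSite(model.gene_id, pos, ref, alt, 50, 10)


class TestLocate:
    def test_cds_offset(self, simple_model):
        assert locate(5, simple_model) == ("cds", 2)

    def test_utr(self, simple_model):
        assert locate(2, simple_model) == ("five_utr", None)

    def test_spliced_offset_skips_intron(self, spliced_model):
        assert locate(11, spliced_model) == ("cds", 5)
        assert locate(8, spliced_model) == ("intron", None)

    def test_out_of_range(self, simple_model):
        with pytest.raises(ValueError):
            locate(13, simple_model)

    def test_noncoding_gene(self):
        m = GeneModel("n1", "ACGTACGT", (Segment("five_utr", 1, 8),))
        assert locate(3, m) == ("noncoding_gene", None)


class TestClassifySite:
    def test_stop_loss_tga_to_tgg(self):
        m = model_with_codon("AAA", stop="TGA")
        # stop codon TGA occupies CDS positions 7-9 → gene pos 10-12; A at 12
        cons = classify_site(site_at(m, 12), m)
        assert cons.category == "stop_loss"
        assert cons.alt_codon == "TGG" and cons.alt_aa == "W"

    def test_tag_position_two_stop_loss(self):
        m = model_with_codon("AAA", stop="TAG")
        cons = classify_site(site_at(m, 11), m)
        assert cons.category == "stop_loss" and cons.alt_codon == "TGG"

    def test_taa_stays_stop(self):
        m = model_with_codon("AAA", stop="TAA")
        cons = classify_site(site_at(m, 11), m)
        assert cons.category == "stop_retained"

    def test_synonymous_gca_to_gcg(self):
        m = model_with_codon("GCA")
        cons = classify_site(site_at(m, 9), m)
        assert cons.category == "synonymous"
        assert (cons.ref_aa, cons.alt_aa) == ("A", "A")

    def test_nonsynonymous_aaa_to_aga(self):
        m = model_with_codon("AAA")
        cons = classify_site(site_at(m, 8), m)
        assert cons.category == "nonsynonymous"
        assert (cons.ref_aa, cons.alt_aa) == ("K", "R")
        assert cons.codon_index == 2 and cons.codon_position == 2

    def test_intron_site_has_region_only(self, spliced_model):
        cons = classify_site(site_at(spliced_model, 9, alt="G"), spliced_model)
        assert cons.region == "intron" and cons.category is None

    def test_ref_mismatch_signals_desync(self, simple_model):
        bad = VariantSite("g1", 5, "C", "G", 50, 10)  # model has T at 5
        with pytest.raises(ConsistencyError):
            classify_site(bad, simple_model)


class TestEditedProtein:
    def test_stop_loss_readthrough(self):
        # CDS ATG TGA, downstream AAA TAA → MWK with one gained residue
        m = GeneModel(
            "g1", "ATGTGAAAATAA",
            (Segment("cds", 1, 6), Segment("three_utr", 7, 12)),
        )
        protein, extension, overran = edited_protein(m, [6])
        assert (protein, extension, overran) == ("MWK", 1, False)

    def test_no_edits_identity(self):
        m = model_with_codon("AAA")
        protein, extension, overran = edited_protein(m, [])
        assert protein == "MK" and extension == 0 and not overran

    def test_readthrough_does_not_splice_downstream_intron(self):
        # annotation places an intron right after the stop; read-through
        # translates the literal transcript, intron included
        m = GeneModel(
            "g1", "ATGTGA" + "CCC" + "TAA",
            (Segment("cds", 1, 6), Segment("intron", 7, 9), Segment("three_utr", 10, 12)),
        )
        protein, extension, overran = edited_protein(m, [6])
        assert protein == "MWP" and extension == 1 and not overran

    def test_transcript_end_overrun_flagged(self):
        m = GeneModel(
            "g1", "ATGTGAAAAAAA",
            (Segment("cds", 1, 6), Segment("three_utr", 7, 12)),
        )
        protein, extension, overran = edited_protein(m, [6])
        assert overran and protein.startswith("MW")

    def test_rejects_non_a_positions(self):
        m = model_with_codon("AAA")
        with pytest.raises(ValueError, match="A→G"):
            edited_protein(m, [1])


class TestStopGainImpossible:
    def test_no_ag_edit_creates_a_stop(self):
        """Exhaustive: no non-stop codon becomes a stop via a single A→G."""
        for codon in CODONS:
            for i, base in enumerate(codon):
                if base != "A":
                    continue
                alt = codon[:i] + "G" + codon[i + 1 :]
                if codon not in STOPS:
                    assert alt not in STOPS, f"{codon}→{alt}"

    def test_classifier_never_emits_stop_gain_for_ag(self):
        for codon in CODONS:
            m = model_with_codon(codon, stop="TAA")
            for i, base in enumerate(codon):
                if base != "A":
                    continue
                cons = classify_site(site_at(m, 7 + i), m)
                assert cons.category != "stop_gain"

    def test_stop_gain_exists_for_other_types(self):
        # sanity: the category is reachable, just not via A→G
        m = model_with_codon("CAA")
        cons = classify_site(site_at(m, 7, alt="T"), m)
        assert cons.category == "stop_gain"


def translation_diff_category(model, pos, alt):
    """Oracle: classify by translating full ref and alt spliced CDS and diffing."""
    from Bio.Seq import Seq

    seq = list(model.sequence)
    seq[pos - 1] = alt
    alt_spliced = "".join(
        "".join(seq[s.start - 1 : s.end]) for s in model.cds_segments
    )
    ref_p = str(Seq(model.spliced_cds).translate(table=1))
    alt_p = str(Seq(alt_spliced).translate(table=1))
    if ref_p == alt_p:
        diffs = []
    else:
        diffs = [i for i, (a, b) in enumerate(zip(ref_p, alt_p)) if a != b]
    if not diffs:
        # unchanged protein: synonymous, or a stop staying a stop
        region, offset = locate(pos, model)
        ci = (offset - 1) // 3 + 1
        codon = model.spliced_cds[3 * (ci - 1) : 3 * ci]
        return "stop_retained" if translate_codon(codon) == "*" else "synonymous"
    (i,) = diffs
    if ref_p[i] == "*":
        return "stop_loss"
    if alt_p[i] == "*":
        return "stop_gain"
    return "nonsynonymous"


class TestFullCdsDiffOracle:
    def test_random_models_agree_with_translation_diff(self):
        from ascoedit.simulate import SimulationConfig, generate_genes

        cfg = SimulationConfig(n_genes=150)
        models, _ = generate_genes(cfg, seed=11)
        rng = np.random.default_rng(17)
        checked = 0
        for m in models:
            for _ in range(4):
                # random CDS position edited to a random other base
                seg = [s for s in m.segments if s.kind == "cds"]
                s = seg[int(rng.integers(0, len(seg)))]
                pos = int(rng.integers(s.start, s.end + 1))
                ref = m.base_at(pos)
                alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
                cons = classify_site(site_at(m, pos, alt=alt), m)
                assert cons.category == translation_diff_category(m, pos, alt), (m.gene_id, pos, alt)
                checked += 1
        assert checked >= 500
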