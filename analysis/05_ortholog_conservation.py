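"""Cross-species comparison of edited orthologs.

Simulates a second species with its own independently planted editing
sites, pairs genes one-to-one as a stand-in ortholog table, and asks
whether any shared amino-acid changes fall at orthologous alignment
positions.  With independently planted sites, positional orthology
should essentially never occur.
"""

import pandas as pd
from common import SEED, get_study, outdirs

from ascoedit.consequences import classify_site
from ascoedit.conservation import shared_editing
from ascoedit.detection import VariantSite
from ascoedit.replicates import EditingSiteRecord, SiteEvidence
from ascoedit.simulate import (
    SimulationConfig,
    generate_genes,
    ortholog_pairs_from_models,
    plant_editing,
)


def truth_records(models, truth, focal):
    """Annotated site records built from a truth table (depth 100 stand-in)."""
    by_id = {m.gene_id: m for m in models}
    records = []
    for s in truth.sites:
        f = s.fractions.get(focal, 0.0)
        if f <= 0 or (s.ref_base, s.alt_base) != ("A", "G"):
            continue
        alt = round(100 * f)
        rec = EditingSiteRecord(
            s.gene_id, s.position, s.ref_base, s.alt_base,
            samples={"rep1": SiteEvidence(100, alt), "rep2": SiteEvidence(100, alt)},
            conditions_reproducible={focal}, specific_to=s.specific_to,
        )
        rec.consequence = classify_site(
            VariantSite(s.gene_id, s.position, s.ref_base, s.alt_base, 100, alt),
            by_id[s.gene_id],
        )
        records.append(rec)
    return records


def main() -> None:
    results, _ = outdirs()
    study, result, _ = get_study()
    focal = study.config.focal_condition

    config_b = SimulationConfig()
    models_b, layouts_b = generate_genes(config_b, seed=SEED + 1000)
    truth_b = plant_editing(models_b, layouts_b, config_b, seed=SEED + 1000)

    pairs = ortholog_pairs_from_models(study.models, models_b)
    sites_a = [r for r in result.specific[focal] if r.substitution_type == "AG"]
    sites_b = truth_records(models_b, truth_b, config_b.focal_condition)

    report = shared_editing(pairs, sites_a, sites_b, min_edit_fraction=0.10)
    print(f"{len(pairs)} ortholog pairs; "
          f"{report.n_edited_genes_a} edited genes in species A "
          f"({report.n_sites_a} aa-changing sites at >=10% editing), "
          f"{report.n_edited_genes_b} in species B ({report.n_sites_b} sites)")
    print(f"pairs with both orthologs edited: {len(report.pairs_both_edited)}")
    print(f"shared amino-acid changes: {len(report.shared_aa_changes)}; "
          f"at orthologous alignment positions: {report.n_positionally_orthologous}")

    pd.DataFrame(
        report.shared_aa_changes
        or [{"gene_a": None, "gene_b": None, "pos_a": None, "pos_b": None,
             "aa_change": None, "mapped_pos_b": None, "positionally_orthologous": None}]
    ).to_csv(results / "conservation_report.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
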