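"""Codon consequences of focal-specific A→I sites, incl. stop-loss read-through.

Counts synonymous / nonsynonymous / stop-loss / stop-retained among the
condition-specific A→G sites, reports the "different gene product"
share, and shows the predicted protein extensions for stop-loss sites.
"""

import pandas as pd
from common import get_study, outdirs

from ascoedit.consequences import edited_protein


def main() -> None:
    results, _ = outdirs()
    study, result, report = get_study()
    focal = study.config.focal_condition

    counts = result.consequence_counts(focal, ag_only=True)
    pd.DataFrame([counts]).to_csv(results / "consequence_counts.tsv", sep="\t", index=False)
    print(f"focal-specific A-to-G sites: {counts['total']} "
          f"({counts['cds']} in coding sequence)")
    for cat in ("synonymous", "nonsynonymous", "stop_loss", "stop_retained"):
        print(f"  {cat}: {counts[cat]}")
    print(f"predicted to change the gene product: {counts['product_changing']} "
          f"({counts['pct_product_changing']:.0f}%)")
    print(f"planted consequence categories reproduced: "
          f"{report.n_consequence_matched}/{report.n_consequence_checked}")

    by_id = {m.gene_id: m for m in study.models}
    print("\nstop-loss read-through predictions:")
    for rec in result.specific[focal]:
        cons = rec.consequence
        if cons is None or cons.category != "stop_loss":
            continue
        protein, extension, overran = edited_protein(by_id[rec.gene_id], [rec.position])
        tail = protein[-min(12, len(protein)):]
        print(f"  {rec.gene_id}:{rec.position} {cons.ref_codon}->{cons.alt_codon} "
              f"extends protein by {extension} aa"
              f"{' (runs off transcript end)' if overran else ''} ...{tail}")


if __name__ == "__main__":
    main()
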