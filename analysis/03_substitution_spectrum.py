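"""Per-condition 12-type substitution spectra of reproducible sites.

The A→G excess should appear only in the focal (protoperithecia)
condition; the other conditions show the flat error-driven background.
Writes the spectrum table to results/ and a bar chart to scratch/.
"""

import pandas as pd
from common import get_study, outdirs

from ascoedit.spectrum import SUBSTITUTION_TYPES, plot_spectrum


def main() -> None:
    results, scratch = outdirs()
    study, result, _ = get_study()

    rows = []
    for cond in study.config.conditions:
        sc = result.spectra[cond]
        rates = sc.rates
        for t in SUBSTITUTION_TYPES:
            rows.append(
                {"condition": cond, "type": t, "count": sc.counts[t],
                 "rate_per_million": round(rates[t], 2)}
            )
    df = pd.DataFrame(rows)
    df.to_csv(results / "spectrum.tsv", sep="\t", index=False)

    wide = df.pivot(index="type", columns="condition", values="count")
    print(wide.to_string())
    focal = study.config.focal_condition
    for cond in study.config.conditions:
        sc = result.spectra[cond]
        share = 100 * sc.counts["AG"] / sc.total if sc.total else 0
        marker = " <-- A-to-G dominated" if cond == focal else ""
        print(f"{cond}: {sc.total} reproducible sites, A-to-G share {share:.0f}%{marker}")

    plot_spectrum([result.spectra[c] for c in study.config.conditions],
                  str(scratch / "spectrum.png"))
    print(f"figure written to {scratch / 'spectrum.png'}")


if __name__ == "__main__":
    main()
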