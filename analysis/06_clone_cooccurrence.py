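"""Clone-level co-editing: penetrance, histograms, independence, timepoints.

Simulates Sanger-sequenced cDNA clone sets for five multi-site genes at
an early (3d) and later (5d) stage of sexual development — per-site
editing probabilities rise between stages — then summarises per-site
penetrance, the edits-per-clone histograms, the Monte-Carlo test
against the site-independence expectation, and the 5d−3d shift.
Clone counts (8–14 per sample) match what cDNA cloning typically yields,
so the independence test is descriptive rather than decisive.
"""

import numpy as np
import pandas as pd
from common import SEED, outdirs

from ascoedit.clones import (
    compare_timepoints,
    edits_per_clone,
    independence_fit,
    site_frequencies,
)
from ascoedit.simulate import child_seed, simulate_clone_set

GENES = {  # gene → per-site 3d editing probabilities (5d adds +0.4, capped)
    "g003": (0.2, 0.35),
    "g007": (0.15, 0.3, 0.5),
    "g012": (0.1, 0.25, 0.4, 0.55),
    "g021": (0.3, 0.3),
    "g034": (0.2, 0.4, 0.6),
}


def main() -> None:
    results, _ = outdirs()
    rng = np.random.default_rng(child_seed(SEED, "clone-counts"))
    rows = []
    for gene, p3 in GENES.items():
        p5 = tuple(min(p + 0.4, 0.95) for p in p3)
        positions = tuple(range(1, len(p3) + 1))
        n3, n5 = int(rng.integers(8, 15)), int(rng.integers(8, 15))
        early = simulate_clone_set(positions, p3, dependence=0.0, n_clones=n3,
                                   seed=SEED, gene_id=gene, sample="3d")
        late = simulate_clone_set(positions, p5, dependence=0.0, n_clones=n5,
                                  seed=SEED, gene_id=gene, sample="5d")
        delta = compare_timepoints(early, late)
        fit = independence_fit(late, n_mc=5000, seed=SEED)
        rows.append({
            "gene": gene, "n_sites": len(p3),
            "clones_3d": n3, "clones_5d": n5,
            "mean_penetrance_3d": round(float(site_frequencies(early).mean()), 3),
            "mean_penetrance_5d": round(float(site_frequencies(late).mean()), 3),
            "mean_edits_delta": round(delta.mean_edits_delta, 3),
            "independence_tv_5d": round(fit.tv_distance, 3),
            "independence_p_5d": round(fit.p_value, 4),
        })
        hist3 = ", ".join(f"{int(100 * h)}%" for h in edits_per_clone(early))
        hist5 = ", ".join(f"{int(100 * h)}%" for h in edits_per_clone(late))
        print(f"{gene} [{len(p3)} sites] 3d({n3} clones) edits/clone: {hist3}")
        print(f"{'':>4} {'':>9} 5d({n5} clones) edits/clone: {hist5}")
    df = pd.DataFrame(rows)
    df.to_csv(results / "clones_summary.tsv", sep="\t", index=False)
    print("\n", df.to_string(index=False), sep="")
    print("\nall independence p-values are unremarkable: with 8-14 clones the "
          "edits-per-clone histogram cannot distinguish independent from "
          "weakly coupled editing")


if __name__ == "__main__":
    main()
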