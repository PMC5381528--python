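"""Generate the reference synthetic study and materialise its input files.

Writes gene FASTA, gene-model TSV, per-sample mpileups and the planted
truth table under scratch/sim/ (pileups are tens of MB, hence scratch).
"""

from common import SEED, get_study, outdirs

from ascoedit.simulate import models_to_fasta, models_to_tsv


def main() -> None:
    _, scratch = outdirs()
    study, result, report = get_study()
    simdir = scratch / "sim"
    simdir.mkdir(parents=True, exist_ok=True)
    (simdir / "genes.fa").write_text(models_to_fasta(study.models))
    (simdir / "genes.tsv").write_text(models_to_tsv(study.models))
    for (cond, rep), text in study.pileups.items():
        (simdir / f"{cond}_rep{rep}.pileup").write_text(text)
    with open(simdir / "truth.tsv", "w") as fh:
        fh.write("gene_id\tposition\tref\talt\tspecific_to\tregion\tcategory\tfractions\n")
        for s in study.truth.sites:
            fr = ";".join(f"{c}={f:.3f}" for c, f in s.fractions.items())
            fh.write(
                f"{s.gene_id}\t{s.position}\t{s.ref_base}\t{s.alt_base}\t"
                f"{s.specific_to or '.'}\t{s.region}\t{s.category or '.'}\t{fr}\n"
            )
    n_bases = sum(len(m.sequence) for m in study.models)
    print(f"seed {SEED}: {len(study.models)} genes, {n_bases} transcript bases")
    print(
        f"planted: {len(study.truth.sites)} editing sites "
        f"({len(study.truth.specific_sites(study.config.focal_condition))} "
        f"specific to {study.config.focal_condition}), "
        f"{len(study.truth.reference_errors)} reference errors"
    )
    print(f"inputs written to {simdir}")


if __name__ == "__main__":
    main()
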