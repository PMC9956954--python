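"""Score the simulated screen and triage candidate genes.

Runs the full screen arm (RPM -> enrichment -> NTC baseline -> Z and t/FDR
hit calling -> gene prioritisation), then intersects the per-treatment FDR
hit lists and checks recovery of the planted suppressors.  Expects the
outputs of 01_simulate_screen.py.
"""

from pathlib import Path

from birscreen import io as bio
from birscreen import pipeline as pl
from birscreen import screen_enrichment as se

IN = Path("results/screen")
OUT = Path("results/screen/scored")


def main() -> None:
    cfg = pl.RunConfig(
        pipeline="screen",
        inputs={"library": str(IN / "library.tsv"), "counts": str(IN / "counts.tsv")},
        outdir=str(OUT),
    )
    report = pl.run_screen_pipeline(cfg)
    st = report.stages["hits"]
    print(f"FDR (q<=0.001) guide hits: {st['n_fdr_hits']}; "
          f"Z (>=2 in >=3 reps) guide hits: {st['n_z_hits']}; "
          f"genes with a hit: {st['n_genes_with_hit']} "
          f"({st['n_genes_multi_shrna']} with >=2 distinct guides)")

    library = bio.read_library_tsv(IN / "library.tsv")
    counts, design = bio.read_counts_tsv(IN / "counts.tsv")
    import pandas as pd

    baseline = pd.Series({g: library.input_rpm[g] for g in counts.index})
    screen = se.ScreenCounts(counts=counts, baseline_rpm=baseline, design=design)
    table = se.enrichment_from_counts(screen)
    calls = se.call_hits_ttest_fdr(table, library)
    sig = calls.is_hit()
    gene_of = library.gene_of
    per_treatment = {
        t: {gene_of[g] for g in sig.index[sig[t]] if gene_of[g]}
        for t in design.treatments
    }
    inter = se.intersect_lists(per_treatment)
    inter.to_csv(OUT / "treatment_intersections.tsv", sep="\t")
    all_four = inter.loc["&".join(sorted(design.treatments)), "count"]
    print(f"genes significant in all four treatments: {all_four}")

    truth = set((IN / "true_suppressors.txt").read_text().split())
    recovered = truth & set().union(*per_treatment.values())
    print(f"planted suppressors recovered by the t/FDR route: "
          f"{len(recovered)}/{len(truth)}")
    print(f"wrote {OUT}/ (guide_hits.tsv, gene_table.tsv, "
          f"treatment_intersections.tsv, report.json)")


if __name__ == "__main__":
    main()
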