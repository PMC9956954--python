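"""Simulate iPCR long reads for two conditions at the ATTCT ectopic site.

Condition A emulates a control knockdown: two-thirds of reads carry a single
template switch to chr2/chr3/chr17, breakpoints recur at six domains, and
HiFi-scale errors are implanted (ins 1e-3, del 1.15e-3, mm 2e-4 per bp).
Condition B emulates a suppressor knockdown: more switching (77% single +
10% double), template switching now also reaches chr12 — always paired with
a second switch to chr17 — a new breakpoint domain appears, and mutations
are spiked 10-fold around one poly-dT tract.
"""

from pathlib import Path

from birscreen import io as bio
from birscreen.synthetic_data import (
    build_reference_panel,
    default_domain_centers,
    simulate_ipcr_reads,
)

OUT = Path("results/ipcr")
SEED = 40230
N_READS = 2000
DUP_FACTOR = 1.3


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = build_reference_panel(repeat_variant="ATTCT47", seed=SEED)
    bio.write_panel(panel, OUT / "panel.fasta", OUT / "features.bed")
    centers = default_domain_centers(panel)

    reads_a, truth_a = simulate_ipcr_reads(
        panel,
        n_reads=N_READS,
        p_single_switch=0.67,
        switch_domain_centers=centers,
        dup_factor=DUP_FACTOR,
        seed=SEED + 1,
    )
    bio.write_fastq(reads_a, OUT / "reads_control.fastq")
    bio.write_truth_tsv(truth_a, OUT / "truth_control.tsv")

    _, start, end, _ = panel.ectopic.feature("dT_run_1")
    extra_domain = int(0.05 * len(panel.ectopic.amplicon))
    reads_b, truth_b = simulate_ipcr_reads(
        panel,
        n_reads=N_READS,
        p_single_switch=0.77,
        p_double_switch=0.10,
        switch_domain_centers=sorted(centers + [extra_domain]),
        decoy_weights={"chr2": 1, "chr3": 1, "chr12": 1, "chr17": 1},
        pair_rule=("chr12", "chr17"),
        hotspot_center=(start + end) // 2,
        hotspot_multiplier=10.0,
        dup_factor=DUP_FACTOR,
        seed=SEED + 2,
    )
    bio.write_fastq(reads_b, OUT / "reads_knockdown.fastq")
    bio.write_truth_tsv(truth_b, OUT / "truth_knockdown.tsv")

    for tag, truths in (("control", truth_a), ("knockdown", truth_b)):
        uniq = [t for t in truths if t.duplicate_of is None]
        singles = sum(t.n_switches == 1 for t in uniq) / len(uniq)
        doubles = sum(t.n_switches >= 2 for t in uniq) / len(uniq)
        print(f"{tag}: {len(truths)} reads ({len(uniq)} unique templates), "
              f"true single-switch fraction {singles:.3f}, double {doubles:.3f}")
    print(f"wrote {OUT}/ (panel.fasta, features.bed, reads_*.fastq, truth_*.tsv)")


if __name__ == "__main__":
    main()
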