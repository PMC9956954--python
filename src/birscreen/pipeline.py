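"""End-to-end pipelines tying the stages together, plus run configuration
and reporting.

Two arms: the screen arm (counts -> enrichment -> NTC baseline -> Z and
t/FDR hit calling -> gene prioritisation) and the iPCR arm (reads -> primer
filter -> dedup -> align -> switches -> domains -> mutations -> spectrum ->
hotspots).  Every run writes TSV artifacts, a parameter echo, and a
machine-readable JSON report whose counts reconcile with the artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from birscreen import __version__
from birscreen import io as bio
from birscreen import ipcr_core, screen_enrichment as se, switch_caller as sw
from birscreen.synthetic_data.panel import ECTOPIC_NAME


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


@dataclass
class ScreenParams:
    fdr_q: float = 0.001
    z_min: float = 2.0
    min_replicates: int = 3
    pooled_ntc: bool = False

    def validate(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ConfigError("fdr_q must be in (0, 1)")
        if self.min_replicates < 1:
            raise ConfigError("min_replicates must be >= 1")


@dataclass
class IpcrParams:
    max_primer_mismatches: int = 1
    end_window: int | None = None
    min_block: int = 50
    band: int = 32
    min_segment: int = 100
    domain_bandwidth: int = 100
    domain_min_support: int = 5
    hotspot_window: int = 50
    n_perm: int = 1000
    t_run_min: int = 20
    hotspot_q: float = 0.05

    def validate(self) -> None:
        if self.min_segment < 1 or self.domain_bandwidth < 1:
            raise ConfigError("min_segment and domain_bandwidth must be >= 1")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")


@dataclass
class RunConfig:
    pipeline: str
    inputs: dict[str, str] = field(default_factory=dict)
    outdir: str = "results"
    seed: int = 0
    screen: ScreenParams = field(default_factory=ScreenParams)
    ipcr: IpcrParams = field(default_factory=IpcrParams)

    def validate(self) -> None:
        if self.pipeline not in {"screen", "ipcr", "simulate"}:
            raise ConfigError(f"unknown pipeline {self.pipeline!r}")
        self.screen.validate()
        self.ipcr.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        screen = ScreenParams(**data.pop("screen", {}))
        ipcr = IpcrParams(**data.pop("ipcr", {}))
        try:
            cfg = cls(screen=screen, ipcr=ipcr, **data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
        return cls.from_dict(data)


@dataclass
class RunReport:
    pipeline: str
    parameters: dict
    stages: dict[str, dict] = field(default_factory=dict)
    version: str = __version__
    wall_time_s: float = 0.0

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_json_default)
            fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _require_inputs(config: RunConfig, *names: str) -> list[Path]:
    paths = []
    for name in names:
        if name not in config.inputs:
            raise ConfigError(f"pipeline {config.pipeline!r} requires input {name!r}")
        p = Path(config.inputs[name])
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
        paths.append(p)
    return paths


def run_screen_pipeline(config: RunConfig) -> RunReport:
    """Counts + library -> hit tables (guide- and gene-level) + report."""
    t0 = time.monotonic()
    config.validate()
    library_path, counts_path = _require_inputs(config, "library", "counts")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    library = bio.read_library_tsv(library_path)
    counts_df, design = bio.read_counts_tsv(counts_path)
    missing = set(g for g in library.guide_ids()) - set(counts_df.index)
    if missing:
        raise bio.InputFormatError(
            f"{counts_path}: {len(missing)} library guides missing from counts"
        )
    baseline = pd.Series(
        {g: library.input_rpm[g] for g in counts_df.index}, name="input_rpm"
    )
    screen = se.ScreenCounts(counts=counts_df, baseline_rpm=baseline, design=design)

    table = se.enrichment_from_counts(screen)
    baseline_ntc = se.ntc_baseline(table, library, pooled=config.screen.pooled_ntc)
    zcalls = se.call_hits_z(
        table,
        baseline_ntc,
        z_min=config.screen.z_min,
        min_replicates=config.screen.min_replicates,
    )
    tcalls = se.call_hits_ttest_fdr(table, library, fdr_q=config.screen.fdr_q)
    significant = tcalls.is_hit().reindex(table.fold.index, fill_value=False)
    gene_table = se.prioritize_genes(significant, library, fold=table.fold)

    guide_out = tcalls.table.reset_index()
    guide_out.to_csv(outdir / "guide_hits.tsv", sep="\t", index=False)
    zcalls.z.to_csv(outdir / "z_scores.tsv", sep="\t", index_label="guide_id")
    z_flags = zcalls.is_hit.copy()
    z_flags["is_hit_z"] = zcalls.is_hit_any
    z_flags.to_csv(outdir / "z_hits.tsv", sep="\t", index_label="guide_id")
    gene_table.to_csv(outdir / "gene_table.tsv", sep="\t")
    with open(outdir / "run_metadata.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "config": config.to_dict(),
                "scales": {"z": "natural ratio", "t_test": "log2"},
                "version": __version__,
            },
            fh,
        )

    report = RunReport(pipeline="screen", parameters=config.to_dict())
    report.stages["counts"] = {
        "n_guides": int(counts_df.shape[0]),
        "n_samples": int(counts_df.shape[1]),
        "n_excluded_zero_baseline": int(table.excluded.sum()),
    }
    report.stages["hits"] = {
        "n_fdr_hits": int(tcalls.table["is_hit"].sum()),
        "n_z_hits": int(zcalls.is_hit_any.sum()),
        "n_genes_with_hit": int(gene_table.shape[0]),
        "n_genes_multi_shrna": int(gene_table["multi_shrna"].sum()),
    }
    report.wall_time_s = time.monotonic() - t0
    report.write(outdir / "report.json")
    return report


def _analyze_read_set(
    reads: list[tuple[str, str]],
    panel,
    index: sw.PanelIndex,
    params: IpcrParams,
    seed: int,
) -> dict:
    """filter -> dedup -> align -> switches -> domains -> mutations ->
    spectrum -> hotspots for one condition; returns all intermediates."""
    primers = panel.ectopic.primers
    kept = ipcr_core.filter_reads_by_primers(
        reads,
        primers,
        max_mismatches=params.max_primer_mismatches,
        end_window=params.end_window,
    )
    if not kept:
        raise ValueError(
            "primer filter kept zero reads: inputs do not look like iPCR products"
        )
    unique, dup_map = ipcr_core.deduplicate(kept)
    chains = sw.align_reads(unique, index, min_block=params.min_block, band=params.band)
    if all(len(c) == 0 for c in chains.values()):
        raise ValueError("alignment failed: no read produced any aligned block")
    events = {
        rid: sw.call_switches(chain, read_id=rid, min_segment=params.min_segment)
        for rid, chain in chains.items()
    }
    fractions, per_contig = sw.switch_stats(events)
    breakpoints = [
        bp
        for evs in events.values()
        for e in evs
        for bp in (e.departure, e.return_)
        if bp is not None
    ]
    domains = sw.cluster_domains(
        breakpoints,
        bandwidth=params.domain_bandwidth,
        min_support=params.domain_min_support,
    )
    mutations, rates = sw.call_mutations(chains)
    spectrum, c_to_a, skipped = sw.trinucleotide_spectrum(
        mutations, panel.ectopic.sequence
    )
    motifs = sw.find_motifs(panel.ectopic.sequence, t_run_min=params.t_run_min)
    # coverage-weighted eligible positions: the null re-places mutations in
    # proportion to how often each reference base was actually sequenced
    aligned_positions = np.concatenate(
        [
            np.arange(b.ref_start, b.ref_end)
            for chain in chains.values()
            for b in chain
            if b.contig == ECTOPIC_NAME
        ]
    )
    hotspots = sw.hotspot_test(
        [m.pos for m in mutations],
        motifs,
        aligned_positions,
        window=params.hotspot_window,
        n_perm=params.n_perm,
        seed=seed,
        q_threshold=params.hotspot_q,
    )
    return {
        "n_input": len(reads),
        "kept": kept,
        "unique": unique,
        "dup_map": dup_map,
        "chains": chains,
        "events": events,
        "fractions": fractions,
        "per_contig": per_contig,
        "domains": domains,
        "mutations": mutations,
        "rates": rates,
        "spectrum": spectrum,
        "c_to_a": c_to_a,
        "spectrum_skipped": skipped,
        "hotspots": hotspots,
    }


def _write_condition(outdir: Path, tag: str, res: dict) -> None:
    prefix = f"{tag}_" if tag else ""
    pd.DataFrame(
        [
            {
                "read_id": e.read_id,
                "departure": e.departure if e.departure is not None else "",
                "return": e.return_ if e.return_ is not None else "",
                "target": e.target,
                "segment_length": e.segment_length,
                "order_index": e.order_index,
            }
            for evs in res["events"].values()
            for e in evs
        ]
    ).to_csv(outdir / f"{prefix}switch_events.tsv", sep="\t", index=False)
    bio.write_domains_bed(res["domains"], outdir / f"{prefix}domains.bed")
    pd.DataFrame(
        [
            {
                "contig": m.contig,
                "pos": m.pos,
                "ref": m.ref,
                "alt": m.alt,
                "type": m.type,
                "read_id": m.read_id,
            }
            for m in res["mutations"]
        ]
    ).to_csv(outdir / f"{prefix}mutations.tsv", sep="\t", index=False)
    res["spectrum"].rename("count").to_csv(
        outdir / f"{prefix}spectrum.tsv", sep="\t", index_label="channel"
    )
    res["rates"].table.to_csv(
        outdir / f"{prefix}rates.tsv", sep="\t", index_label="type"
    )
    res["hotspots"].to_csv(outdir / f"{prefix}hotspots.tsv", sep="\t", index=False)


def run_ipcr_pipeline(config: RunConfig) -> RunReport:
    """Reads + panel -> switch/mutation/hotspot artifacts + report.

    With a second read set (input ``reads_b``) the report gains a comparison
    block: domains present in condition B but not A, and rate percent
    differences.
    """
    t0 = time.monotonic()
    config.validate()
    panel_fa, panel_bed, reads_path = _require_inputs(config, "panel_fasta", "panel_bed", "reads")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = bio.read_panel(panel_fa, panel_bed)
    index = sw.PanelIndex(panel)
    reads = bio.read_fastq(reads_path)
    two_condition = "reads_b" in config.inputs
    res_a = _analyze_read_set(reads, panel, index, config.ipcr, config.seed)
    _write_condition(outdir, "condition_a" if two_condition else "", res_a)

    report = RunReport(pipeline="ipcr", parameters=config.to_dict())

    def stage_counts(res: dict) -> dict:
        return {
            "reads_in": res["n_input"],
            "reads_kept": len(res["kept"]),
            "reads_unique": len(res["unique"]),
            "reads_no_ectopic_alignment": res["rates"].n_reads_no_ectopic,
            "switch_fractions": res["fractions"],
            "reads_per_target_contig": res["per_contig"],
            "n_domains": len(res["domains"]),
            "rates_per_bp": res["rates"].table["rate"].to_dict(),
            "c_to_a_fraction": res["c_to_a"],
            "n_hotspots": int(res["hotspots"]["hotspot"].sum())
            if not res["hotspots"].empty
            else 0,
        }

    report.stages["condition_a" if two_condition else "reads"] = stage_counts(res_a)

    if two_condition:
        reads_b = bio.read_fastq(Path(config.inputs["reads_b"]))
        res_b = _analyze_read_set(reads_b, panel, index, config.ipcr, config.seed + 1)
        _write_condition(outdir, "condition_b", res_b)
        report.stages["condition_b"] = stage_counts(res_b)
        new = sw.new_domains(
            res_a["domains"], res_b["domains"], slack=config.ipcr.domain_bandwidth
        )
        report.stages["comparison"] = {
            "new_domains_in_b": [
                {"label": d.label, "start": d.start, "end": d.end, "support": d.support}
                for d in new
            ],
            "rate_percent_difference": sw.rate_percent_difference(
                res_a["rates"], res_b["rates"]
            ).to_dict(),
        }

    report.wall_time_s = time.monotonic() - t0
    report.write(outdir / "report.json")
    return report
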