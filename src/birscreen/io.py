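"""Readers and writers for the package's plain-text interchange formats.

TSV for tables, FASTA/FASTQ (via Biopython) for sequence, BED (0-based
half-open) for features, one-gene-per-line text for gene sets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from birscreen.ipcr_core import PrimerPair
from birscreen.switch_caller import SwitchDomain
from birscreen.synthetic_data.library import GuideLibrary, GuideRecord, ScreenDesign
from birscreen.synthetic_data.panel import ECTOPIC_NAME, EctopicConstruct, ReferencePanel
from birscreen.synthetic_data.reads import ImplantedMutation, ReadTruth, Segment


class InputFormatError(ValueError):
    """A malformed input file (message names file and, where known, line)."""


# ---------------------------------------------------------------- library

def write_library_tsv(library: GuideLibrary, path: str | Path) -> None:
    rows = [
        {
            "guide_id": r.guide_id,
            "gene": r.gene if r.gene is not None else "",
            "category": r.category,
            "sequence": r.sequence,
            "input_rpm": library.input_rpm[r.guide_id],
        }
        for r in library.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | Path) -> GuideLibrary:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene": str}, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001
        raise InputFormatError(f"{path}: cannot parse library TSV ({exc})") from exc
    required = {"guide_id", "gene", "category", "sequence", "input_rpm"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                GuideRecord(
                    guide_id=row.guide_id,
                    gene=row.gene or None,
                    category=row.category,
                    sequence=row.sequence,
                )
            )
        except ValueError as exc:
            raise InputFormatError(f"{path}: line {i}: {exc}") from exc
    input_rpm = dict(zip(df["guide_id"], df["input_rpm"].astype(float)))
    return GuideLibrary(records=records, input_rpm=input_rpm)


# ----------------------------------------------------------------- counts

def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="guide_id")


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, ScreenDesign]:
    try:
        df = pd.read_csv(path, sep="\t", index_col="guide_id")
    except Exception as exc:  # noqa: BLE001
        raise InputFormatError(f"{path}: cannot parse counts TSV ({exc})") from exc
    treatments: list[str] = []
    reps: set[int] = set()
    for col in df.columns:
        if ":" not in col:
            raise InputFormatError(
                f"{path}: column {col!r} is not of the form treatment:replicate"
            )
        t, _, r = col.rpartition(":")
        if not r.isdigit():
            raise InputFormatError(f"{path}: bad replicate in column {col!r}")
        if t not in treatments:
            treatments.append(t)
        reps.add(int(r))
    design = ScreenDesign(
        treatments=tuple(treatments), replicates_per_treatment=max(reps)
    )
    return df, design


# ------------------------------------------------------------------ panel

def write_panel(panel: ReferencePanel, fasta_path: str | Path, bed_path: str | Path) -> None:
    ect = panel.ectopic
    desc = (
        f"repeat_variant={ect.repeat_variant} amplicon_length={ect.amplicon_length} "
        f"xba_cuts={ect.xba_cuts[0]},{ect.xba_cuts[1]} "
        f"fwd_primer={ect.primers.forward} rev_primer={ect.primers.reverse}"
    )
    records = [SeqRecord(Seq(ect.sequence), id=ECTOPIC_NAME, description=desc)]
    records += [
        SeqRecord(Seq(seq), id=name, description="decoy")
        for name, seq in panel.decoys.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(bed_path, "w") as fh:
        for name, start, end, strand in ect.features:
            fh.write(f"{ECTOPIC_NAME}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def read_panel(fasta_path: str | Path, bed_path: str | Path, anchor_k: int = 21) -> ReferencePanel:
    seqs: dict[str, str] = {}
    meta: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        if rec.id == ECTOPIC_NAME:
            for tok in rec.description.split():
                if "=" in tok:
                    key, _, val = tok.partition("=")
                    meta[key] = val
    if ECTOPIC_NAME not in seqs:
        raise InputFormatError(f"{fasta_path}: no contig named {ECTOPIC_NAME!r}")
    for key in ("repeat_variant", "amplicon_length", "xba_cuts"):
        if key not in meta:
            raise InputFormatError(f"{fasta_path}: ectopic header lacks {key}=")
    features = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise InputFormatError(f"{bed_path}: line {lineno}: expected 6 BED columns")
            features.append((parts[3], int(parts[1]), int(parts[2]), parts[5]))
    c1, _, c2 = meta["xba_cuts"].partition(",")
    primers = PrimerPair(
        forward=meta.get("fwd_primer", PrimerPair().forward),
        reverse=meta.get("rev_primer", PrimerPair().reverse),
    )
    ectopic = EctopicConstruct(
        sequence=seqs.pop(ECTOPIC_NAME),
        features=features,
        repeat_variant=meta["repeat_variant"],
        amplicon_length=int(meta["amplicon_length"]),
        xba_cuts=(int(c1), int(c2)),
        primers=primers,
    )
    return ReferencePanel(ectopic=ectopic, decoys=seqs, anchor_k=anchor_k)


# ------------------------------------------------------------------ reads

def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: int = 40) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    try:
        return [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")
        ]
    except Exception as exc:  # noqa: BLE001
        raise InputFormatError(f"{path}: cannot parse FASTQ ({exc})") from exc


# ------------------------------------------------------------------ truth

def write_truth_tsv(truths: list[ReadTruth], path: str | Path) -> None:
    rows = []
    for t in truths:
        rows.append(
            {
                "read_id": t.read_id,
                "duplicate_of": t.duplicate_of or "",
                "n_switches": t.n_switches,
                "segments": ";".join(
                    f"{s.contig}:{s.start}-{s.end}:{s.strand}" for s in t.segments
                ),
                "mutations": ";".join(
                    f"{m.type}@{m.template_offset}/{m.read_pos}:{m.bases}"
                    for m in t.mutations
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[ReadTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        segments = []
        for tok in str(row.segments).split(";"):
            if not tok:
                continue
            loc, _, strand = tok.rpartition(":")
            contig, _, span = loc.rpartition(":")
            start, _, end = span.partition("-")
            segments.append(Segment(contig, int(start), int(end), strand))
        mutations = []
        for tok in str(row.mutations).split(";"):
            if not tok:
                continue
            head, _, bases = tok.partition(":")
            mtype, _, pos = head.partition("@")
            tpos, _, rpos = pos.partition("/")
            mutations.append(ImplantedMutation(mtype, int(tpos), int(rpos), bases))
        out.append(
            ReadTruth(
                read_id=row.read_id,
                segments=segments,
                mutations=mutations,
                duplicate_of=row.duplicate_of or None,
            )
        )
    return out


# ------------------------------------------------------------- misc text

def read_geneset(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_domains_bed(domains: list[SwitchDomain], path: str | Path, contig: str = ECTOPIC_NAME) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{contig}\t{d.start}\t{d.end}\t{d.label}\t{d.support}\t+\n")
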