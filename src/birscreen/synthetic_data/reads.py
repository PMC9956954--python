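"""Ground-truthed chimeric long reads from in-silico iPCR products.

Each read is the unrearranged amplicon (forward primer ... body ...
reverse-complemented reverse primer) into which 0, 1 or 2 nonallelic
template-switch segments are spliced: the replication fork departs the
ectopic template near a recurrent breakpoint domain, copies 250 bp - 1 kb
from a decoy chromosome, and returns to the ectopic site.  HiFi-scale
errors are implanted per template base (insertions ~1e-3/bp, deletions
~1.15e-3/bp, mismatches ~2e-4/bp by default) and PCR duplicates are emitted
as verbatim copies.  The truth log records segments, every implanted
mutation, and duplicate provenance, so callers can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from birscreen._seq import ALPHABET
from birscreen.synthetic_data.panel import ECTOPIC_NAME, ReferencePanel

_BASE_IDX = {b: i for i, b in enumerate(ALPHABET)}

#: Breakpoint-domain jitter (bp, 1 sd) around each domain center.
DOMAIN_JITTER_SD = 12.0
_JITTER_CLIP = 36  # 3 sd

#: Ectopic bases skipped between departure and return of one switch.
SKIP_RANGE = (20, 100)


@dataclass(frozen=True)
class Segment:
    """One source piece of a simulated read (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ImplantedMutation:
    """type in {insertion, deletion, mismatch}; offsets are 0-based.

    ``template_offset`` indexes the concatenated clean template;
    ``read_pos`` is the position in the final read (for deletions, the
    position the base would have occupied). ``bases`` is the inserted or
    deleted base, or "X>Y" for a mismatch.
    """

    type: str
    template_offset: int
    read_pos: int
    bases: str


@dataclass
class ReadTruth:
    read_id: str
    segments: list[Segment]
    mutations: list[ImplantedMutation]
    duplicate_of: str | None = None

    @property
    def n_switches(self) -> int:
        return sum(1 for s in self.segments if s.contig != ECTOPIC_NAME)

    @property
    def switch_contigs(self) -> list[str]:
        return [s.contig for s in self.segments if s.contig != ECTOPIC_NAME]


def default_domain_centers(panel: ReferencePanel, n: int = 6) -> list[int]:
    """Evenly spread breakpoint-domain centers, in amplicon coordinates."""
    length = panel.ectopic.amplicon_length
    return [int(length * (0.15 + 0.75 * i / max(n - 1, 1))) for i in range(n)]


def _pick_events(
    rng: np.random.Generator,
    n_switches: int,
    centers: list[int],
    amplicon_len: int,
) -> list[tuple[int, int]]:
    """Departure/return positions (amplicon coords) for each switch event."""
    for _ in range(100):
        if n_switches == 1:
            idx = [int(rng.integers(0, len(centers)))]
        else:
            idx = sorted(rng.choice(len(centers), size=n_switches, replace=False).tolist())
        events = []
        for i in idx:
            jitter = int(np.clip(round(rng.normal(0.0, DOMAIN_JITTER_SD)), -_JITTER_CLIP, _JITTER_CLIP))
            a_dep = centers[i] + jitter
            a_ret = a_dep + int(rng.integers(SKIP_RANGE[0], SKIP_RANGE[1] + 1))
            events.append((a_dep, a_ret))
        ok = all(0 < d < r < amplicon_len for d, r in events) and all(
            events[i][1] < events[i + 1][0] for i in range(len(events) - 1)
        )
        if ok:
            return events
    raise RuntimeError("could not place non-overlapping switch events; check domain centers")


def _choose_contig(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = sorted(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    if w.sum() <= 0:
        raise ValueError("decoy weights must have positive mass")
    return names[int(rng.choice(len(names), p=w / w.sum()))]


def _mutate(
    template: str,
    rate: np.ndarray,  # per-position multiplier-adjusted base rates, shape (T, 3)
    rng: np.random.Generator,
) -> tuple[str, list[ImplantedMutation]]:
    t = len(template)
    u = rng.random((t, 3))
    del_mask = u[:, 0] < rate[:, 0]
    mm_mask = (u[:, 1] < rate[:, 1]) & ~del_mask
    ins_mask = u[:, 2] < rate[:, 2]
    hot = np.flatnonzero(del_mask | mm_mask | ins_mask)

    out: list[str] = []
    muts: list[ImplantedMutation] = []
    read_pos = 0
    prev = 0
    for pos in hot.tolist():
        chunk = template[prev:pos]
        out.append(chunk)
        read_pos += len(chunk)
        base = template[pos]
        if del_mask[pos]:
            muts.append(ImplantedMutation("deletion", pos, read_pos, base))
        else:
            emit = base
            if mm_mask[pos]:
                emit = ALPHABET[(_BASE_IDX[base] + int(rng.integers(1, 4))) % 4]
                muts.append(ImplantedMutation("mismatch", pos, read_pos, f"{base}>{emit}"))
            out.append(emit)
            read_pos += 1
        if ins_mask[pos]:
            ins_base = ALPHABET[int(rng.integers(0, 4))]
            muts.append(ImplantedMutation("insertion", pos, read_pos, ins_base))
            out.append(ins_base)
            read_pos += 1
        prev = pos + 1
    out.append(template[prev:])
    return "".join(out), muts


def simulate_ipcr_reads(
    panel: ReferencePanel,
    n_reads: int,
    p_single_switch: float = 0.67,
    p_double_switch: float = 0.0,
    switch_domain_centers: list[int] | None = None,
    switch_len_range: tuple[int, int] = (250, 1000),
    decoy_weights: dict[str, float] | None = None,
    ins_rate: float = 1e-3,
    del_rate: float = 1.15e-3,
    mm_rate: float = 2e-4,
    dup_factor: float = 1.0,
    seed: int = 0,
    pair_rule: tuple[str, str] | None = None,
    hotspot_center: int | None = None,
    hotspot_halfwidth: int = 50,
    hotspot_multiplier: float = 10.0,
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Simulate iPCR long reads and their truth log.

    ``switch_domain_centers`` are amplicon coordinates of recurrent
    breakpoint domains (default: six evenly spread).  With ``pair_rule``
    = (X, Y), double-switch reads visit X then Y and single switches avoid
    X — emulating strictly co-occurring nonallelic targets.  A hotspot
    (``hotspot_center`` in construct coordinates) multiplies all three
    mutation rates within ``hotspot_halfwidth`` of the center.

    Returns ``(reads, truths)`` with reads as (read_id, sequence), ordered
    unique templates first, then duplicates.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if p_single_switch < 0 or p_double_switch < 0 or p_single_switch + p_double_switch > 1:
        raise ValueError("switch probabilities must be non-negative and sum to <= 1")
    for name, r in (("ins_rate", ins_rate), ("del_rate", del_rate), ("mm_rate", mm_rate)):
        if not 0 <= r <= 0.1:
            raise ValueError(f"{name} must lie in [0, 0.1]")
    if dup_factor < 1:
        raise ValueError("dup_factor must be >= 1")

    ect = panel.ectopic
    amplicon_len = len(ect.amplicon)
    centers = switch_domain_centers or default_domain_centers(panel)
    for c in centers:
        if not 0 < c < amplicon_len:
            raise ValueError(f"domain center {c} outside amplicon [0, {amplicon_len})")
    if decoy_weights is None:
        decoy_weights = {n: 1.0 for n in panel.decoys if n != "chr12"}
    unknown = set(decoy_weights) - set(panel.decoys)
    if unknown:
        raise ValueError(f"decoy_weights name unknown contigs: {sorted(unknown)}")
    single_weights = dict(decoy_weights)
    if pair_rule is not None:
        if not all(c in panel.decoys for c in pair_rule):
            raise ValueError("pair_rule contigs must be decoys")
        single_weights.pop(pair_rule[0], None)

    rng = np.random.default_rng(seed)
    contig_seqs = panel.contigs()
    n_unique = max(1, int(round(n_reads / dup_factor)))

    reads: list[tuple[str, str]] = []
    truths: list[ReadTruth] = []
    p0 = 1.0 - p_single_switch - p_double_switch
    for i in range(n_unique):
        n_sw = int(rng.choice(3, p=[p0, p_single_switch, p_double_switch]))
        segments: list[Segment] = []
        if n_sw == 0:
            segments.extend(
                Segment(ECTOPIC_NAME, a, b)
                for a, b in ect.amplicon_interval_to_construct(0, amplicon_len)
            )
        else:
            events = _pick_events(rng, n_sw, centers, amplicon_len)
            if pair_rule is not None and n_sw == 2:
                targets = list(pair_rule)
            else:
                targets = [
                    _choose_contig(rng, single_weights if pair_rule else decoy_weights)
                    for _ in range(n_sw)
                ]
            prev_a = 0
            lo, hi = switch_len_range
            for (a_dep, a_ret), contig in zip(events, targets):
                segments.extend(
                    Segment(ECTOPIC_NAME, a, b)
                    for a, b in ect.amplicon_interval_to_construct(prev_a, a_dep)
                )
                decoy = contig_seqs[contig]
                seg_len = int(rng.integers(lo, min(hi, len(decoy)) + 1))
                start = int(rng.integers(0, len(decoy) - seg_len + 1))
                segments.append(Segment(contig, start, start + seg_len))
                prev_a = a_ret
            segments.extend(
                Segment(ECTOPIC_NAME, a, b)
                for a, b in ect.amplicon_interval_to_construct(prev_a, amplicon_len)
            )

        template = "".join(contig_seqs[s.contig][s.start : s.end] for s in segments)
        rate = np.tile(
            np.array([del_rate, mm_rate, ins_rate]), (len(template), 1)
        )
        if hotspot_center is not None:
            offset = 0
            for s in segments:
                if s.contig == ECTOPIC_NAME:
                    pos = np.arange(s.start, s.end)
                    mask = np.abs(pos - hotspot_center) <= hotspot_halfwidth
                    rate[offset : offset + s.length][mask] *= hotspot_multiplier
                offset += s.length
        seq, muts = _mutate(template, rate, rng)
        read_id = f"read{i + 1:06d}"
        reads.append((read_id, seq))
        truths.append(ReadTruth(read_id, segments, muts))

    for j in range(n_reads - n_unique):
        src = int(rng.integers(0, n_unique))
        read_id = f"read{n_unique + j + 1:06d}"
        reads.append((read_id, reads[src][1]))
        truths.append(
            replace(truths[src], read_id=read_id, duplicate_of=truths[src].read_id)
        )
    return reads, truths


def reconstruct_read(truth: ReadTruth, panel: ReferencePanel) -> str:
    """Replay truth segments and mutations into the read sequence.

    Exact reconstruction is the generator's conservation invariant: the
    truth log fully determines every simulated read.
    """
    contig_seqs = panel.contigs()
    template = "".join(
        contig_seqs[s.contig][s.start : s.end] for s in truth.segments
    )
    # mismatches/deletions act on the base itself, insertions follow it
    order = {"mismatch": 0, "deletion": 0, "insertion": 1}
    muts = sorted(truth.mutations, key=lambda m: (m.template_offset, order[m.type]))
    out: list[str] = []
    prev = 0
    for m in muts:
        if m.type == "insertion":
            out.append(template[prev : m.template_offset + 1])
            out.append(m.bases)
        elif m.type == "deletion":
            out.append(template[prev : m.template_offset])
        else:  # mismatch
            out.append(template[prev : m.template_offset])
            out.append(m.bases.split(">")[1])
        prev = m.template_offset + 1
    out.append(template[prev:])
    return "".join(out)
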