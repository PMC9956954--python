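"""Template-switch calling and hypermutation analysis of iPCR long reads.

Reads (oriented, deduplicated) are aligned to the reference panel by unique
k-mer anchor chaining: because the panel is built k-mer-disjoint, every
anchor places a read position unambiguously on one contig.  Co-linear anchor
runs become aligned blocks; block boundaries are extended by exact matching
into anchor-free gaps and per-block edits come from a global edit-distance
alignment of each block span.  A template switch is a maximal non-ectopic
block run between ectopic-aligned sequence — the molecular signature of the
replication fork leaving the ectopic template for a nonallelic donor and
returning.  Downstream: breakpoint-domain clustering, per-bp mutation rates,
96-channel trinucleotide spectra, motif scans (poly-dT runs, G-quadruplex
consensus) and a permutation test for motif-proximal mutation hotspots.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from string import ascii_lowercase

import edlib
import numpy as np
import pandas as pd

from birscreen.synthetic_data.panel import ECTOPIC_NAME, ReferencePanel

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class Edit:
    """One edit within an aligned block; ``ref_pos`` is a contig coordinate.

    For mismatches ``bases`` is "ref>alt"; insertions carry the inserted
    bases (extra in the read), deletions the deleted reference bases.
    """

    type: str
    read_pos: int
    ref_pos: int
    bases: str


@dataclass
class AlignedBlock:
    read_start: int
    read_end: int
    contig: str
    ref_start: int
    ref_end: int
    strand: str = "+"
    edits: list[Edit] = field(default_factory=list)

    @property
    def read_length(self) -> int:
        return self.read_end - self.read_start

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class SwitchEvent:
    """One template switch: ectopic departure/return breakpoints (None at a
    read end) and the nonallelic donor segment."""

    read_id: str
    departure: int | None
    return_: int | None
    target: str
    segment_length: int
    order_index: int


@dataclass(frozen=True)
class SwitchDomain:
    label: str
    start: int
    end: int
    support: int


@dataclass(frozen=True)
class MutationCall:
    read_id: str
    contig: str
    pos: int
    type: str
    ref: str
    alt: str


class PanelIndex:
    """Unique k-mer anchor index over all panel contigs (forward strands)."""

    def __init__(self, panel: ReferencePanel, k: int | None = None):
        self.panel = panel
        self.k = k or panel.anchor_k
        self.contigs = panel.contigs()
        index: dict[str, tuple[str, int]] = {}
        dupes: set[str] = set()
        for name, seq in self.contigs.items():
            for i in range(len(seq) - self.k + 1):
                kmer = seq[i : i + self.k]
                if kmer in dupes:
                    continue
                if kmer in index:
                    del index[kmer]
                    dupes.add(kmer)
                else:
                    index[kmer] = (name, i)
        self._index = index

    def lookup(self, kmer: str) -> tuple[str, int] | None:
        return self._index.get(kmer)


def _cigar_edits(
    cigar: str, query: str, target: str, read_offset: int, ref_offset: int
) -> list[Edit]:
    """Convert an extended CIGAR (query=read, target=reference) to edits."""
    edits: list[Edit] = []
    q = r = 0
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        if op in "=M":
            q += n
            r += n
        elif op == "X":
            for j in range(n):
                edits.append(
                    Edit(
                        "mismatch",
                        read_offset + q + j,
                        ref_offset + r + j,
                        f"{target[r + j]}>{query[q + j]}",
                    )
                )
            q += n
            r += n
        elif op == "I":  # extra bases in the read
            edits.append(
                Edit("insertion", read_offset + q, ref_offset + r, query[q : q + n])
            )
            q += n
        elif op == "D":  # bases missing from the read
            edits.append(
                Edit("deletion", read_offset + q, ref_offset + r, target[r : r + n])
            )
            r += n
    return edits


def _chain_anchors(
    anchors: list[tuple[int, str, int]], k: int, band: int
) -> list[list[tuple[int, str, int]]]:
    """Split read-ordered anchors into co-linear same-contig runs."""
    runs: list[list[tuple[int, str, int]]] = []
    for a in anchors:
        if runs:
            pi, pc, pp = runs[-1][-1]
            same = a[1] == pc and a[2] > pp
            diag_ok = same and abs((a[2] - a[0]) - (pp - pi)) <= band
            if diag_ok:
                runs[-1].append(a)
                continue
        runs.append([a])
    return runs


def _prefix_costs(g: str, ref: str) -> tuple[list[int], list[int]]:
    """best[i] = min over j of edit distance(g[:i], ref[:j]), with the
    smallest minimising j; plain O(len(g) * len(ref)) DP on tiny strings."""
    n, m = len(g), len(ref)
    best = [0] * (n + 1)
    arg = [0] * (n + 1)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (g[i - 1] != ref[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        b = min(cur)
        best[i] = b
        arg[i] = cur.index(b)
        prev = cur
    return best, arg


#: Gaps longer than this are left to exact extension only (they are not
#: boundary noise but unanchored sequence, e.g. a dropped short block).
_GAP_RESOLVE_LIMIT = 120


def _resolve_gap(read: str, spans: list[list[int]], idx: int, contigs: dict[str, str]) -> None:
    """Distribute the anchor-free read gap after span ``idx`` (idx == -1 for
    the read-start gap) between the flanking blocks by minimal edit cost,
    so mutations near block boundaries stay inside an aligned block."""
    left = spans[idx] if idx >= 0 else None
    right = spans[idx + 1] if idx + 1 < len(spans) else None
    g_start = left[1] if left else 0
    g_end = right[0] if right else len(read)
    gap = read[g_start:g_end]
    if not gap:
        return
    if len(gap) > _GAP_RESOLVE_LIMIT:
        _exact_extend(read, spans, idx, contigs)
        return
    pad = len(gap) + 8
    if left is not None:
        ref_l = contigs[left[2]][left[4] : left[4] + pad]
        best_l, arg_l = _prefix_costs(gap, ref_l)
    else:
        best_l, arg_l = [0] + [10**9] * len(gap), [0] * (len(gap) + 1)
    if right is not None:
        seq_r = contigs[right[2]]
        ref_r = seq_r[max(0, right[3] - pad) : right[3]][::-1]
        best_r, arg_r = _prefix_costs(gap[::-1], ref_r)
    else:
        best_r, arg_r = [0] + [10**9] * len(gap), [0] * (len(gap) + 1)
    # split gap[:i] to the left block, gap[i:] to the right block
    totals = [best_l[i] + best_r[len(gap) - i] for i in range(len(gap) + 1)]
    cost = min(totals)
    if cost > max(3, len(gap) // 3):
        _exact_extend(read, spans, idx, contigs)
        return
    i = totals.index(cost)
    if left is not None and i > 0:
        left[1] += i
        left[4] += arg_l[i]
    if right is not None and i < len(gap):
        right[0] -= len(gap) - i
        right[3] -= arg_r[len(gap) - i]


def _exact_extend(read: str, spans: list[list[int]], idx: int, contigs: dict[str, str]) -> None:
    """Fallback gap handling: extend flanking blocks by exact base matches."""
    left = spans[idx] if idx >= 0 else None
    right = spans[idx + 1] if idx + 1 < len(spans) else None
    if left is not None:
        seq = contigs[left[2]]
        limit = right[0] if right else len(read)
        while left[1] < limit and left[4] < len(seq) and read[left[1]] == seq[left[4]]:
            left[1] += 1
            left[4] += 1
    if right is not None:
        seq = contigs[right[2]]
        limit = left[1] if left else 0
        while right[0] > limit and right[3] > 0 and read[right[0] - 1] == seq[right[3] - 1]:
            right[0] -= 1
            right[3] -= 1


def align_read(
    read: str,
    index: PanelIndex,
    min_block: int = 50,
    band: int = 32,
) -> list[AlignedBlock]:
    """Align one oriented read against the panel; returns the block chain.

    Every read base belongs to at most one block; reads with no anchors at
    all return an empty chain (unalignable).
    """
    k = index.k
    if len(read) < k:
        raise ValueError(f"read shorter than anchor size k={k}")
    anchors = []
    for i in range(len(read) - k + 1):
        hit = index.lookup(read[i : i + k])
        if hit is not None:
            anchors.append((i, hit[0], hit[1]))
    if not anchors:
        return []
    runs = [
        r
        for r in _chain_anchors(anchors, k, band)
        if (r[-1][0] + k - r[0][0]) >= min_block
    ]
    if not runs:
        return []

    spans = []  # [read_start, read_end, contig, ref_start, ref_end]
    for run in runs:
        i0, contig, p0 = run[0]
        i1, _, p1 = run[-1]
        spans.append([i0, i1 + k, contig, p0, p1 + k])

    # merge collinear same-contig spans separated by anchor deserts (tandem
    # repeats have no unique k-mers, so anchors vanish for the whole tract);
    # the merged span is realigned globally, which handles the desert exactly
    merged: list[list[int]] = []
    for span in spans:
        if merged:
            prev = merged[-1]
            ref_gap = span[3] - prev[4]
            read_gap = span[0] - prev[1]
            if (
                span[2] == prev[2]
                and ref_gap >= 0
                and read_gap >= 0
                and abs(ref_gap - read_gap) <= band
            ):
                prev[1], prev[4] = span[1], span[4]
                continue
        merged.append(span)
    spans = merged

    # microhomology at a junction (e.g. the religated XbaI site on the
    # circle) lets both flanking blocks anchor the same read bases; keep the
    # upstream block and trim the downstream one, so a switch is placed as
    # late as the homology allows
    trimmed = []
    for span in spans:
        if trimmed and span[0] < trimmed[-1][1]:
            d = trimmed[-1][1] - span[0]
            span[0] += d
            span[3] += d
            if span[0] >= span[1]:
                continue
        trimmed.append(span)
    spans = trimmed

    # distribute anchor-free gaps (read ends, switch junctions, the circle
    # junction) between flanking blocks by minimal edit cost
    for gap_idx in range(-1, len(spans)):
        _resolve_gap(read, spans, gap_idx, index.contigs)

    blocks = []
    for read_start, read_end, contig, ref_start, ref_end in spans:
        query = read[read_start:read_end]
        target = index.contigs[contig][ref_start:ref_end]
        if query == target:
            edits: list[Edit] = []
        else:
            aln = edlib.align(query, target, task="path", mode="NW")
            edits = _cigar_edits(aln["cigar"], query, target, read_start, ref_start)
        blocks.append(
            AlignedBlock(
                read_start=read_start,
                read_end=read_end,
                contig=contig,
                ref_start=ref_start,
                ref_end=ref_end,
                edits=edits,
            )
        )
    return blocks


def align_reads(
    reads: list[tuple[str, str]],
    index: PanelIndex,
    min_block: int = 50,
    band: int = 32,
) -> dict[str, list[AlignedBlock]]:
    return {
        read_id: align_read(seq, index, min_block=min_block, band=band)
        for read_id, seq in reads
    }


def deduplicate_by_mutations(
    chains: dict[str, list[AlignedBlock]],
) -> tuple[list[str], dict[str, str]]:
    """Post-alignment deduplication: reads whose aligned blocks and edit
    sets are identical are PCR copies of one template even if raw sequences
    were already collapsed upstream.  Returns kept read ids (first by input
    order) and a removed-id -> representative map."""
    kept: list[str] = []
    rep_of: dict[tuple, str] = {}
    dup_map: dict[str, str] = {}
    for read_id, chain in chains.items():
        key = tuple(
            (b.contig, b.ref_start, b.ref_end, tuple(b.edits)) for b in chain
        )
        rep = rep_of.get(key)
        if rep is None:
            rep_of[key] = read_id
            kept.append(read_id)
        else:
            dup_map[read_id] = rep
    return kept, dup_map


def call_switches(
    chain: list[AlignedBlock], read_id: str = "", min_segment: int = 100
) -> list[SwitchEvent]:
    """Template switches: maximal non-ectopic block runs (per donor contig)
    of total reference length >= min_segment, with the flanking ectopic
    block boundaries as departure/return breakpoints."""
    events: list[SwitchEvent] = []
    i = 0
    order = 0
    n = len(chain)
    while i < n:
        if chain[i].contig == ECTOPIC_NAME:
            i += 1
            continue
        j = i
        while j < n and chain[j].contig == chain[i].contig:
            j += 1
        seg_len = sum(b.ref_length for b in chain[i:j])
        if seg_len >= min_segment:
            departure = chain[i - 1].ref_end if i > 0 and chain[i - 1].contig == ECTOPIC_NAME else None
            nxt = chain[j].ref_start if j < n and chain[j].contig == ECTOPIC_NAME else None
            events.append(
                SwitchEvent(
                    read_id=read_id,
                    departure=departure,
                    return_=nxt,
                    target=chain[i].contig,
                    segment_length=seg_len,
                    order_index=order,
                )
            )
            order += 1
        i = j
    return events


def switch_stats(
    events_per_read: dict[str, list[SwitchEvent]],
) -> tuple[dict[str, float], dict[str, int]]:
    """Fractions of reads with 0 / 1 / >=2 switches, and per-donor-contig
    read tallies (a read counts once per contig it switches to)."""
    n_reads = len(events_per_read)
    if n_reads == 0:
        raise ValueError("no reads")
    frac = {"0": 0, "1": 0, "2+": 0}
    per_contig: Counter[str] = Counter()
    for events in events_per_read.values():
        n = len(events)
        frac["0" if n == 0 else "1" if n == 1 else "2+"] += 1
        for contig in {e.target for e in events}:
            per_contig[contig] += 1
    return {key: v / n_reads for key, v in frac.items()}, dict(per_contig)


def cluster_domains(
    breakpoints: list[int], bandwidth: int = 100, min_support: int = 1
) -> list[SwitchDomain]:
    """Single-linkage 1-D clustering of switch breakpoints.

    Breakpoints within ``bandwidth`` of a cluster member merge; clusters with
    support >= min_support become domains labelled a, b, c, ... in coordinate
    order (read order never matters).
    """
    if not breakpoints:
        return []
    pts = sorted(breakpoints)
    clusters: list[list[int]] = [[pts[0]]]
    for p in pts[1:]:
        if p - clusters[-1][-1] <= bandwidth:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    kept = [c for c in clusters if len(c) >= min_support]
    labels = list(ascii_lowercase) + [
        a + b for a in ascii_lowercase for b in ascii_lowercase
    ]
    return [
        SwitchDomain(label=labels[i], start=c[0], end=c[-1] + 1, support=len(c))
        for i, c in enumerate(kept)
    ]


def new_domains(
    reference_condition: list[SwitchDomain],
    other_condition: list[SwitchDomain],
    slack: int = 100,
) -> list[SwitchDomain]:
    """Domains of ``other_condition`` absent from ``reference_condition``
    (no overlap within ``slack`` bp) — new-domain detection between, e.g.,
    control and knockdown read sets."""
    out = []
    for d in other_condition:
        if not any(
            d.start - slack < r.end and r.start - slack < d.end
            for r in reference_condition
        ):
            out.append(d)
    return out


@dataclass
class RateSummary:
    """Mutation rates over ectopic-aligned sequence.

    Rates use aligned reference bp as denominator; ``rate`` counts events
    (a multi-base indel is one event), ``rate_bases`` counts affected bases.
    """

    table: pd.DataFrame
    aligned_bp: int
    n_reads: int
    n_reads_no_ectopic: int

    def rate(self, mutation_type: str) -> float:
        return float(self.table.loc[mutation_type, "rate"])


def call_mutations(
    chains: dict[str, list[AlignedBlock]],
) -> tuple[list[MutationCall], RateSummary]:
    """Collect edits over ectopic-aligned blocks and summarise per-bp rates.

    Reads without any ectopic-aligned base are excluded from the denominator
    and counted in the summary.
    """
    calls: list[MutationCall] = []
    aligned_bp = 0
    n_no_ectopic = 0
    counts = {t: [0, 0] for t in ("insertion", "deletion", "mismatch")}  # events, bases
    for read_id, chain in chains.items():
        ect_blocks = [b for b in chain if b.contig == ECTOPIC_NAME]
        if not ect_blocks:
            n_no_ectopic += 1
            continue
        for block in ect_blocks:
            aligned_bp += block.ref_length
            for e in block.edits:
                if e.type == "mismatch":
                    ref, alt = e.bases.split(">")
                    counts["mismatch"][0] += 1
                    counts["mismatch"][1] += 1
                else:
                    ref, alt = (
                        ("-", e.bases) if e.type == "insertion" else (e.bases, "-")
                    )
                    counts[e.type][0] += 1
                    counts[e.type][1] += len(e.bases)
                calls.append(
                    MutationCall(read_id, block.contig, e.ref_pos, e.type, ref, alt)
                )
    if aligned_bp == 0:
        raise ValueError("zero ectopic-aligned bp across all reads")
    table = pd.DataFrame(
        {
            "n_events": {t: v[0] for t, v in counts.items()},
            "n_bases": {t: v[1] for t, v in counts.items()},
        }
    )
    table["rate"] = table["n_events"] / aligned_bp
    table["rate_bases"] = table["n_bases"] / aligned_bp
    summary = RateSummary(
        table=table,
        aligned_bp=aligned_bp,
        n_reads=len(chains),
        n_reads_no_ectopic=n_no_ectopic,
    )
    return calls, summary


def rate_percent_difference(a: RateSummary, b: RateSummary) -> pd.Series:
    """Percent change of each rate from condition a to condition b."""
    return (b.table["rate"] - a.table["rate"]) / a.table["rate"] * 100.0


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def spectrum_channels() -> list[str]:
    out = []
    for sub in SUBSTITUTION_CLASSES:
        ref = sub[0]
        for left in "ACGT":
            for right in "ACGT":
                out.append(f"{left}[{sub}]{right}")
    return out


def fold_substitution(ref: str, alt: str, left: str, right: str) -> str:
    """Fold a substitution to the pyrimidine reference strand and return its
    96-channel label. Folding twice returns the original channel."""
    if ref in "AG":
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
        left, right = right.translate(_COMPLEMENT), left.translate(_COMPLEMENT)
    return f"{left}[{ref}>{alt}]{right}"


def trinucleotide_spectrum(
    mutations: list[MutationCall], reference: str
) -> tuple[pd.Series, float | None, int]:
    """96-channel folded substitution counts, the C>A fraction (None when
    there are no countable mismatches), and the number of edge-skipped
    mismatches (no flanking context)."""
    channels = pd.Series(0, index=spectrum_channels(), dtype=int)
    skipped = 0
    for m in mutations:
        if m.type != "mismatch":
            continue
        if m.pos <= 0 or m.pos >= len(reference) - 1:
            skipped += 1
            continue
        label = fold_substitution(
            m.ref, m.alt, reference[m.pos - 1], reference[m.pos + 1]
        )
        channels[label] += 1
    total = int(channels.sum())
    if total == 0:
        return channels, None, skipped
    c_to_a = int(channels[[c for c in channels.index if "[C>A]" in c]].sum())
    return channels, c_to_a / total, skipped


G4_PATTERN = r"G{3,}(?:[ACGT]{1,7}G{3,}){3}"
_G4_FWD = re.compile(G4_PATTERN)
_G4_REV = re.compile(r"C{3,}(?:[ACGT]{1,7}C{3,}){3}")


def _merged_pattern_intervals(reference: str, pattern: re.Pattern) -> list[tuple[int, int]]:
    """All pattern occurrences, including overlapping starts, merged to
    maximal intervals."""
    hits = []
    for start in range(len(reference)):
        m = pattern.match(reference, start)
        if m:
            hits.append((m.start(), m.end()))
    merged: list[list[int]] = []
    for s, e in sorted(hits):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def find_motifs(
    reference: str, t_run_min: int = 20
) -> list[tuple[str, int, int, str]]:
    """Poly-dT runs (>= t_run_min, either strand) and G-quadruplex consensus
    occurrences (both strands, overlapping matches merged).

    Returns (kind, start, end, strand) in forward-strand coordinates; an
    A-run on the forward strand is a T-run on the reverse strand.
    """
    motifs: list[tuple[str, int, int, str]] = []
    for m in re.finditer(rf"T{{{t_run_min},}}", reference):
        motifs.append(("T_run", m.start(), m.end(), "+"))
    for m in re.finditer(rf"A{{{t_run_min},}}", reference):
        motifs.append(("T_run", m.start(), m.end(), "-"))
    for s, e in _merged_pattern_intervals(reference, _G4_FWD):
        motifs.append(("G4", s, e, "+"))
    for s, e in _merged_pattern_intervals(reference, _G4_REV):
        motifs.append(("G4", s, e, "-"))
    return sorted(motifs, key=lambda x: (x[1], x[2], x[0], x[3]))


def hotspot_test(
    mutation_positions: list[int],
    motifs: list[tuple[str, int, int, str]],
    eligible_positions: np.ndarray,
    window: int = 50,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Permutation test for mutation enrichment within ``window`` bp of each
    motif.

    The null re-places the observed mutations uniformly over
    ``eligible_positions`` (the aligned reference positions) ``n_perm``
    times; p = (1 + #null >= observed) / (1 + n_perm), BH-adjusted across
    motifs. Motifs with q <= q_threshold are flagged hotspots — recurrent
    mutagenesis next to a structural element rather than uniform background.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(motifs) == 0:
        return pd.DataFrame(
            columns=["kind", "start", "end", "strand", "observed", "expected", "p_value", "q_value", "hotspot"]
        )
    eligible = np.asarray(eligible_positions)
    obs = np.asarray(mutation_positions)
    rng = np.random.default_rng(seed)
    samples = eligible[rng.integers(0, eligible.size, size=(n_perm, obs.size))] if obs.size else np.empty((n_perm, 0), dtype=int)
    rows = []
    for kind, start, end, strand in motifs:
        lo, hi = start - window, end + window
        observed = int(((obs >= lo) & (obs < hi)).sum())
        null_counts = ((samples >= lo) & (samples < hi)).sum(axis=1)
        p = (1.0 + float((null_counts >= observed).sum())) / (1.0 + n_perm)
        rows.append(
            {
                "kind": kind,
                "start": start,
                "end": end,
                "strand": strand,
                "observed": observed,
                "expected": float(null_counts.mean()),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["q_value"] = q
    out["hotspot"] = out["q_value"] <= q_threshold
    return out
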