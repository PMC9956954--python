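"""Ectopic-site construct and decoy reference panel.

The construct emulates the engineered integration locus: a c-myc replication
origin flanked by a structure-prone microsatellite (hairpin-forming CTG,
quadruplex/triplex Pu/Py, or AT-rich ATTCT), fluorescent and thymidine-kinase
reporters, AluYA5 recombination targets, two XbaI sites delimiting the iPCR
fragment and an outward-facing primer pair whose unrearranged circular
product has a configured length (default 4 kb).

Decoys are random sequences labelled with chromosome names; they share no
k-mer (anchor size, either strand) with the construct, so template-switch
segments have unambiguous truth without a real genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from birscreen._seq import random_dna, random_dna_avoiding, revcomp
from birscreen.ipcr_core import XBAI_SITE, PrimerPair

REPEAT_UNITS: dict[str, tuple[str, int]] = {
    "CTG100": ("CTG", 100),
    # the Pu/Py tract is modelled as a homopurine 12-mer tandem (synthetic
    # stand-in; the construct's actual mirror-repeat sequence is not modelled)
    "PuPy58": ("AAGGGAGGGAGG", 58),
    "ATTCT47": ("ATTCT", 47),
}

ECTOPIC_NAME = "ectopic"
DEFAULT_DECOY_LENGTHS = {"chr2": 6000, "chr3": 6000, "chr12": 6000, "chr17": 6000}

_FLANK = 400  # construct sequence outside the XbaI fragment, per side

# fragment-local layout constants (0-based; fragment starts at the left cut)
_MARKER = (50, 580)
_REV_SITE = 600
_SPACER = 200  # unamplified gap between the primer sites
_ALU_A = (900, 1200)
_REPEAT_START = 1250
_GAP = 50
_ORIGIN_LEN = 300
_DTOMATO_LEN = 700
_ALU_LEN = 300

# structure-prone elements implanted downstream of the second Alu: two
# poly-dT tracts (one on each strand) and two G-quadruplex consensus
# elements (one on each strand) — candidate hotspot-associated motifs
G4_ELEMENT = "GGGTTAGGGTTAGGGTTAGGG"
_MOTIF_ELEMENTS = [
    ("dT_run_1", "T" * 29),
    ("dT_run_2", "A" * 29),  # T-run on the reverse strand
    ("G4_1", G4_ELEMENT),
    ("G4_2", G4_ELEMENT.translate(str.maketrans("ACGT", "TGCA"))[::-1]),
]
# spacing keeps the +/-50 bp hotspot windows of adjacent elements disjoint
_MOTIF_SPACING = 150


@dataclass
class EctopicConstruct:
    """Linear construct sequence with annotated features.

    Features are (name, start, end, strand) in 0-based half-open construct
    coordinates. ``xba_cuts`` are the two cut positions; the fragment between
    them, circularized, is the iPCR template.
    """

    sequence: str
    features: list[tuple[str, int, int, str]]
    repeat_variant: str
    amplicon_length: int
    xba_cuts: tuple[int, int]
    primers: PrimerPair = field(default_factory=PrimerPair)

    def feature(self, name: str) -> tuple[str, int, int, str]:
        hits = [f for f in self.features if f[0] == name]
        if len(hits) != 1:
            raise KeyError(f"feature {name!r} found {len(hits)} times")
        return hits[0]

    @property
    def fragment(self) -> str:
        c1, c2 = self.xba_cuts
        return self.sequence[c1:c2]

    @property
    def _fwd_local(self) -> int:
        c1, _ = self.xba_cuts
        _, start, _, _ = self.feature("primer_fwd")
        return start - c1

    @property
    def _rev_end_local(self) -> int:
        c1, _ = self.xba_cuts
        _, _, end, _ = self.feature("primer_rev")
        return end - c1

    @property
    def amplicon(self) -> str:
        """Unrearranged iPCR product, forward-primer-first."""
        frag = self.fragment
        return frag[self._fwd_local :] + frag[: self._rev_end_local]

    def amplicon_to_construct(self, pos: int) -> int:
        """Map an amplicon coordinate to a construct coordinate."""
        c1, c2 = self.xba_cuts
        arc1 = (c2 - c1) - self._fwd_local
        if not 0 <= pos <= len(self.amplicon):
            raise ValueError("position outside amplicon")
        if pos < arc1:
            return c1 + self._fwd_local + pos
        return c1 + (pos - arc1)

    def amplicon_interval_to_construct(self, a0: int, a1: int) -> list[tuple[int, int]]:
        """Construct intervals covering amplicon[a0:a1] (1 or 2 pieces —
        the circle junction splits intervals that span it)."""
        if not 0 <= a0 <= a1 <= len(self.amplicon):
            raise ValueError("interval outside amplicon")
        if a0 == a1:
            return []
        c1, c2 = self.xba_cuts
        arc1 = (c2 - c1) - self._fwd_local
        pieces = []
        if a0 < arc1:
            hi = min(a1, arc1)
            pieces.append((c1 + self._fwd_local + a0, c1 + self._fwd_local + hi))
        if a1 > arc1:
            lo = max(a0, arc1)
            pieces.append((c1 + (lo - arc1), c1 + (a1 - arc1)))
        return pieces


@dataclass
class ReferencePanel:
    """The ectopic construct plus decoy chromosome contigs."""

    ectopic: EctopicConstruct
    decoys: dict[str, str]
    anchor_k: int = 21

    def __post_init__(self) -> None:
        if ECTOPIC_NAME in self.decoys:
            raise ValueError(f"decoy may not be named {ECTOPIC_NAME!r}")
        self.validate_kmer_disjoint()

    def contigs(self) -> dict[str, str]:
        return {ECTOPIC_NAME: self.ectopic.sequence, **self.decoys}

    def validate_kmer_disjoint(self) -> None:
        k = self.anchor_k
        ect = self.ectopic.sequence
        ect_kmers = _strand_kmers(ect, k)
        for name, seq in self.decoys.items():
            if _strand_kmers(seq, k) & ect_kmers:
                raise ValueError(f"decoy {name} shares a {k}-mer with the ectopic contig")


def _strand_kmers(seq: str, k: int) -> set[str]:
    rc = revcomp(seq)
    return {seq[i : i + k] for i in range(len(seq) - k + 1)} | {
        rc[i : i + k] for i in range(len(rc) - k + 1)
    }


def _build_construct(
    repeat_variant: str, amplicon_length: int, rng: np.random.Generator
) -> EctopicConstruct:
    primers = PrimerPair()
    fwd = primers.forward
    rc_rev = revcomp(primers.reverse)
    forbidden = [XBAI_SITE, fwd, revcomp(fwd), primers.reverse, rc_rev]

    unit, copies = REPEAT_UNITS[repeat_variant]
    repeat = unit * copies
    rep_len = len(repeat)

    rev_end = _REV_SITE + len(primers.reverse)
    fwd_start = rev_end + _SPACER
    frag_len = amplicon_length + _SPACER

    # sequential layout after the forward primer
    rep_start = _REPEAT_START
    origin = (rep_start + rep_len + _GAP, rep_start + rep_len + _GAP + _ORIGIN_LEN)
    dtomato = (origin[1] + _GAP, origin[1] + _GAP + _DTOMATO_LEN)
    alu_b = (dtomato[1] + _GAP, dtomato[1] + _GAP + _ALU_LEN)
    motif_layout = []
    cursor = alu_b[1] + _MOTIF_SPACING
    for name, motif_seq in _MOTIF_ELEMENTS:
        motif_layout.append((name, cursor, motif_seq))
        cursor += len(motif_seq) + _MOTIF_SPACING
    layout_end = motif_layout[-1][1] + len(motif_layout[-1][2])
    if layout_end > frag_len - _GAP:
        raise ValueError(
            f"amplicon_length={amplicon_length} too small for the "
            f"{repeat_variant} feature layout (needs >= {layout_end + _GAP - _SPACER})"
        )

    marker_name = "CMV_TK" if repeat_variant == "PuPy58" else "eGFP_TK"

    for attempt in range(20):
        m = list(random_dna_avoiding(frag_len - 6, rng, forbidden))

        def overwrite(local_start: int, text: str) -> None:
            # fragment-local position i maps to m[i - 5]
            m[local_start - 5 : local_start - 5 + len(text)] = list(text)

        overwrite(_REV_SITE, rc_rev)
        overwrite(fwd_start, fwd)
        overwrite(rep_start, repeat)
        for _, local, motif_seq in motif_layout:
            overwrite(local, motif_seq)
        fragment = "CTAGA" + "".join(m) + "T"

        flank_a = random_dna_avoiding(_FLANK, rng, forbidden)
        flank_b = random_dna_avoiding(_FLANK, rng, forbidden)
        seq = flank_a + XBAI_SITE + fragment[5:-1] + XBAI_SITE + flank_b
        c1 = _FLANK + 1
        c2 = c1 + frag_len
        assert seq[c1:c2] == fragment

        ok = (
            seq.count(XBAI_SITE) == 2
            and seq.count(fwd) == 1
            and seq.count(rc_rev) == 1
            and seq.count(revcomp(fwd)) == 0
            and seq.count(primers.reverse) == 0
        )
        if not ok:
            continue

        g = lambda local: c1 + local  # noqa: E731 - fragment-local to construct
        features = [
            ("XbaI_site", _FLANK, _FLANK + len(XBAI_SITE), "+"),
            (marker_name, g(_MARKER[0]), g(_MARKER[1]), "+"),
            ("primer_rev", g(_REV_SITE), g(rev_end), "-"),
            ("primer_fwd", g(fwd_start), g(fwd_start + len(fwd)), "+"),
            ("AluYA5_a", g(_ALU_A[0]), g(_ALU_A[1]), "+"),
            ("repeat_tract", g(rep_start), g(rep_start + rep_len), "+"),
            ("c_myc_origin", g(origin[0]), g(origin[1]), "+"),
            ("dTomato", g(dtomato[0]), g(dtomato[1]), "+"),
            ("AluYA5_b", g(alu_b[0]), g(alu_b[1]), "+"),
            *(
                (name, g(local), g(local + len(motif_seq)), "-" if name in ("dT_run_2", "G4_2") else "+")
                for name, local, motif_seq in motif_layout
            ),
            ("XbaI_site", c2 - 1, c2 - 1 + len(XBAI_SITE), "+"),
        ]
        construct = EctopicConstruct(
            sequence=seq,
            features=features,
            repeat_variant=repeat_variant,
            amplicon_length=amplicon_length,
            xba_cuts=(c1, c2),
            primers=primers,
        )
        if len(construct.amplicon) != amplicon_length:
            raise AssertionError("internal layout error: amplicon length mismatch")
        return construct
    raise RuntimeError("could not build a clean construct within the retry budget")


def build_reference_panel(
    repeat_variant: str = "CTG100",
    decoy_lengths: dict[str, int] | None = None,
    amplicon_length: int = 4000,
    seed: int = 0,
    anchor_k: int = 21,
) -> ReferencePanel:
    """Build the ectopic construct plus k-mer-disjoint decoy contigs."""
    if repeat_variant not in REPEAT_UNITS:
        raise ValueError(f"unknown repeat_variant {repeat_variant!r}")
    if decoy_lengths is None:
        decoy_lengths = dict(DEFAULT_DECOY_LENGTHS)
    rng = np.random.default_rng(seed)
    ectopic = _build_construct(repeat_variant, amplicon_length, rng)

    taken = _strand_kmers(ectopic.sequence, anchor_k)
    decoys: dict[str, str] = {}
    for name, length in decoy_lengths.items():
        for attempt in range(20):
            seq = random_dna(length, rng)
            km = _strand_kmers(seq, anchor_k)
            if not (km & taken):
                decoys[name] = seq
                taken |= km
                break
        else:
            raise RuntimeError(f"could not generate k-mer-disjoint decoy {name}")
    return ReferencePanel(ectopic=ectopic, decoys=decoys, anchor_k=anchor_k)
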