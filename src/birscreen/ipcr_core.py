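"""In-silico inverse PCR (iPCR).

The wet assay: digest genomic DNA with XbaI (T^CTAGA), dilute and
self-ligate so each fragment becomes a circle, then amplify outward from a
primer pair inside the fragment. On an unrearranged locus the product has a
fixed, predictable size; rearrangements change product sizes and junctions.
This module mirrors each step on strings: digestion, circularization with
rotation-invariant identity, amplicon prediction, primer-based filtering and
orientation of long reads, exact-sequence deduplication, and the
nonsense-mutation target size of a reporter CDS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from birscreen._seq import revcomp, validate_dna

XBAI_SITE = "TCTAGA"
XBAI_CUT_OFFSET = 1  # T^CTAGA

# Outward-facing iPCR primer pair at the ectopic site (Gfp-Rev / Nhe-For).
GFP_REV = "GTCCATGCCGAGAGTGATC"
NHE_FOR = "AAGCTTGCCTTGAGTGCTTC"

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primers (5'->3' on their annealing strands)."""

    forward: str = GFP_REV
    reverse: str = NHE_FOR

    def __post_init__(self) -> None:
        validate_dna(self.forward, "forward primer")
        validate_dna(self.reverse, "reverse primer")


@dataclass(frozen=True)
class Fragment:
    """A digestion product; ``start``/``end`` map linear fragments to the parent."""

    sequence: str
    start: int | None = None
    end: int | None = None
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)

    def canonical(self) -> str:
        """Rotation-invariant key: lexicographically minimal rotation.

        Only meaningful for circular fragments; linear fragments return the
        sequence unchanged.
        """
        if not self.circular:
            return self.sequence
        s = self.sequence
        doubled = s + s
        n = len(s)
        return min(doubled[i : i + n] for i in range(n))

    def equivalent(self, other: "Fragment") -> bool:
        if self.circular != other.circular:
            return False
        return self.canonical() == other.canonical()


def _site_positions(sequence: str, site: str, circular: bool) -> list[int]:
    search_in = sequence + sequence[: len(site) - 1] if circular else sequence
    positions = []
    start = search_in.find(site)
    while start != -1:
        if start < len(sequence):
            positions.append(start)
        start = search_in.find(site, start + 1)
    return positions


def digest(
    sequence: str,
    site: str = XBAI_SITE,
    cut_offset: int = XBAI_CUT_OFFSET,
    circular_input: bool = False,
) -> list[Fragment]:
    """Cut at every site occurrence at ``site_start + cut_offset``.

    Linear input with n sites yields n+1 fragments (in parent order, 5'->3');
    circular input yields n fragments, the one spanning the origin first.
    Total length is conserved.
    """
    if len(site) < 4:
        raise ValueError("restriction site must be at least 4 bp")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset must lie within the site")
    validate_dna(sequence)
    n = len(sequence)
    cuts = sorted((p + cut_offset) % n for p in _site_positions(sequence, site, circular_input))
    if circular_input:
        if not cuts:
            return [Fragment(sequence, circular=True)]
        frags = []
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            if nxt > c:
                seq = sequence[c:nxt]
            else:  # wraps the origin
                seq = sequence[c:] + sequence[:nxt]
            frags.append(Fragment(seq, start=c, end=nxt))
        # parent order, fragment spanning the origin first
        frags.sort(key=lambda f: f.start)
        return frags
    bounds = [0] + cuts + [n]
    return [
        Fragment(sequence[a:b], start=a, end=b)
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]


def circularize(fragment: Fragment) -> Fragment:
    """Self-ligate a linear fragment; rotations compare equal afterwards."""
    if fragment.circular:
        raise ValueError("fragment is already circular")
    return Fragment(fragment.sequence, circular=True)


def _find_once(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def predict_ipcr_product(circle: Fragment, primers: PrimerPair | None = None) -> str | None:
    """Predicted amplicon of outward PCR on a circle, or None.

    The forward primer must match the circle (either strand representation);
    from its 3' end the polymerase proceeds 5'->3' around the circle until it
    reaches the reverse complement of the reverse primer. The returned
    amplicon includes both primer sites. Multiple forward-primer matches on
    one strand raise an ambiguity error.
    """
    if primers is None:
        primers = PrimerPair()
    if not circle.circular:
        raise ValueError("predict_ipcr_product requires a circular fragment")
    n = len(circle.sequence)
    rc_rev = revcomp(primers.reverse)
    if n < len(primers.forward) or n < len(rc_rev):
        return None
    for strand_seq in (circle.sequence, revcomp(circle.sequence)):
        doubled = strand_seq + strand_seq
        starts = [p for p in _find_once(doubled, primers.forward) if p < n]
        if not starts:
            continue
        if len(starts) > 1:
            raise ValueError("ambiguous iPCR: forward primer matches the circle more than once")
        a = starts[0]
        # first reverse-primer complement reached going around the circle
        arc = doubled[a : a + n]
        hits = [p for p in _find_once(arc, rc_rev) if p + len(rc_rev) <= n]
        if not hits:
            continue
        b = hits[0]
        return arc[: b + len(rc_rev)]
    return None


def _matches_within(read: str, primer: str, max_mismatches: int, window: tuple[int, int]) -> bool:
    lo, hi = window
    plen = len(primer)
    region = read[lo:hi]
    for off in range(0, len(region) - plen + 1):
        mm = 0
        seg = region[off : off + plen]
        for x, y in zip(seg, primer):
            if x != y:
                mm += 1
                if mm > max_mismatches:
                    break
        if mm <= max_mismatches:
            return True
    return False


def _is_forward_read(read: str, primers: PrimerPair, max_mismatches: int, end_window: int) -> bool:
    n = len(read)
    if n < 2 * max(len(primers.forward), len(primers.reverse)):
        return False
    fwd_ok = _matches_within(read, primers.forward, max_mismatches, (0, min(end_window, n)))
    rev_ok = _matches_within(
        read, revcomp(primers.reverse), max_mismatches, (max(0, n - end_window), n)
    )
    return fwd_ok and rev_ok


def filter_reads_by_primers(
    reads: Iterable[tuple[str, str]],
    primers: PrimerPair | None = None,
    max_mismatches: int = 1,
    end_window: int | None = None,
) -> list[tuple[str, str]]:
    """Keep reads with the forward primer at the 5' end and the reverse
    primer's complement at the 3' end (substitutions only, no indels).

    Reads that match in the opposite overall orientation are
    reverse-complemented; kept reads are emitted forward-primer-first.
    """
    if primers is None:
        primers = PrimerPair()
    if end_window is None:
        end_window = max(len(primers.forward), len(primers.reverse)) + 5
    if end_window < max(len(primers.forward), len(primers.reverse)):
        raise ValueError("end_window must be at least the primer length")
    kept: list[tuple[str, str]] = []
    for read_id, seq in reads:
        if _is_forward_read(seq, primers, max_mismatches, end_window):
            kept.append((read_id, seq))
            continue
        rc = revcomp(seq)
        if _is_forward_read(rc, primers, max_mismatches, end_window):
            kept.append((read_id, rc))
    return kept


def deduplicate(
    reads: Sequence[tuple[str, str]],
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Collapse exact-sequence duplicates (PCR copies of one template).

    Returns the unique reads (first occurrence by input order is the
    representative) and a map removed-read-id -> representative-id.
    """
    unique: list[tuple[str, str]] = []
    rep_of_seq: dict[str, str] = {}
    duplicate_map: dict[str, str] = {}
    for read_id, seq in reads:
        rep = rep_of_seq.get(seq)
        if rep is None:
            rep_of_seq[seq] = read_id
            unique.append((read_id, seq))
        else:
            duplicate_map[read_id] = rep
    return unique, duplicate_map


def count_stop_convertible_codons(cds: str) -> int:
    """Number of in-frame sense codons one substitution away from a stop.

    This is the reporter's nonsense-mutation target size: each such codon is
    a site where a single base change can truncate the protein.
    """
    validate_dna(cds, "cds")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    count = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            continue
        if any(
            codon[:j] + base + codon[j + 1 :] in STOP_CODONS
            for j in range(3)
            for base in "ACGT"
            if base != codon[j]
        ):
            count += 1
    return count
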