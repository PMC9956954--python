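"""Small DNA-string helpers shared across modules.

Sequences are plain upper-case ``str`` over {A,C,G,T}; coordinates are
0-based half-open throughout the package.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(np.array(list(ALPHABET))[rng.integers(0, 4, size=length)])


def random_dna_avoiding(
    length: int,
    rng: np.random.Generator,
    forbidden: list[str],
    max_rounds: int = 100,
) -> str:
    """Random DNA containing none of the forbidden substrings.

    Offending occurrences are re-randomised locally; raises if the string
    cannot be cleaned within ``max_rounds`` passes.
    """
    seq = list(random_dna(length, rng))
    for _ in range(max_rounds):
        dirty = False
        s = "".join(seq)
        for motif in forbidden:
            start = s.find(motif)
            while start != -1:
                dirty = True
                for i in range(start, start + len(motif)):
                    seq[i] = ALPHABET[rng.integers(0, 4)]
                s = "".join(seq)
                start = s.find(motif)
        if not dirty:
            return "".join(seq)
    raise RuntimeError("could not scrub forbidden motifs from random sequence")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def validate_dna(seq: str, name: str = "sequence") -> None:
    if not seq or set(seq) - set(ALPHABET):
        raise ValueError(f"{name} must be a non-empty string over ACGT")
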