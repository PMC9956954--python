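"""Pooled shRNA guide library and screen design containers.

The library emulates an ultracomplex lentiviral pool: every gene covered by
several distinct guides, plus two control classes — non-targeting controls
(NTCs, no genomic target; they define the null enrichment distribution) and
guides against non-essential genes. Input abundances are reads-per-million
(RPM) in the pre-selection pool, drawn from a log-normal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from birscreen._seq import ALPHABET, validate_dna

CATEGORIES = ("targeting", "ntc", "nonessential")

DEFAULT_TREATMENTS = ("untreated", "HU", "DOX", "HU+DOX")


@dataclass(frozen=True)
class GuideRecord:
    """One shRNA guide: id, target gene (None for NTCs), category, sequence."""

    guide_id: str
    gene: str | None
    category: str
    sequence: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "ntc" and self.gene is not None:
            raise ValueError("NTC guides must have gene=None")
        validate_dna(self.sequence, f"guide {self.guide_id}")


@dataclass
class GuideLibrary:
    """Guide records plus pre-selection abundances (RPM, summing to 1e6)."""

    records: list[GuideRecord]
    input_rpm: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        ids = [r.guide_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("guide_id values must be unique")
        if set(self.input_rpm) != set(ids):
            raise ValueError("input_rpm must cover exactly the library guides")
        total = sum(self.input_rpm.values())
        if abs(total - 1e6) > 1.0:
            raise ValueError(f"input RPM must sum to 1e6 (got {total:.3f})")

    def __len__(self) -> int:
        return len(self.records)

    def guides(self, category: str | None = None) -> list[GuideRecord]:
        if category is None:
            return list(self.records)
        return [r for r in self.records if r.category == category]

    def guide_ids(self, category: str | None = None) -> list[str]:
        return [r.guide_id for r in self.guides(category)]

    @property
    def gene_of(self) -> dict[str, str | None]:
        return {r.guide_id: r.gene for r in self.records}

    @property
    def guide_length(self) -> int:
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError("library has variable guide lengths")
        return lengths.pop()

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.records if r.gene is not None}


@dataclass(frozen=True)
class ScreenDesign:
    """Treatment labels and replicate count of the selection screen."""

    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    replicates_per_treatment: int = 4

    def __post_init__(self) -> None:
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatment labels must be unique")
        if not self.treatments:
            raise ValueError("design needs at least one treatment")
        if self.replicates_per_treatment < 1:
            raise ValueError("replicates_per_treatment must be >= 1")

    @property
    def samples(self) -> list[tuple[str, int]]:
        return [
            (t, r)
            for t in self.treatments
            for r in range(1, self.replicates_per_treatment + 1)
        ]

    @staticmethod
    def sample_label(treatment: str, replicate: int) -> str:
        return f"{treatment}:{replicate}"


def _random_guide_sequences(
    n: int, length: int, rng: np.random.Generator, max_tries: int | None = None
) -> list[str]:
    """Distinct random guide sequences; raises after the retry budget."""
    if max_tries is None:
        max_tries = 20 * n + 1000
    seen: set[str] = set()
    out: list[str] = []
    alphabet = np.array(list(ALPHABET))
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not draw {n} distinct guide sequences of length {length}"
            )
        seq = "".join(alphabet[rng.integers(0, 4, size=length)])
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def build_library(
    n_genes: int = 1200,
    guides_per_gene: tuple[int, int] = (5, 8),
    n_ntc: int = 125,
    n_nonessential: int = 272,
    guide_length: int = 19,
    seed: int = 0,
    rpm_sigma: float = 1.0,
) -> GuideLibrary:
    """Build a synthetic guide library.

    Each of ``n_genes`` genes receives a uniform-random number of guides in
    the closed ``guides_per_gene`` range; control counts are met exactly.
    Pre-selection abundances are log-normal (``rpm_sigma`` on the natural-log
    scale) and normalised to 1e6 RPM.
    """
    lo, hi = guides_per_gene
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not (1 <= lo <= hi <= 20):
        raise ValueError("guides_per_gene range must lie within [1, 20]")
    rng = np.random.default_rng(seed)

    per_gene = rng.integers(lo, hi + 1, size=n_genes)
    n_total = int(per_gene.sum()) + n_ntc + n_nonessential
    if n_total < 1:
        raise ValueError("library would be empty")
    seqs = iter(_random_guide_sequences(n_total, guide_length, rng))

    records: list[GuideRecord] = []
    for g in range(n_genes):
        gene = f"GENE{g + 1:05d}"
        for i in range(per_gene[g]):
            records.append(
                GuideRecord(f"{gene}_sh{i + 1}", gene, "targeting", next(seqs))
            )
    for i in range(n_ntc):
        records.append(GuideRecord(f"NTC{i + 1:04d}", None, "ntc", next(seqs)))
    for i in range(n_nonessential):
        gene = f"NESS{i + 1:04d}"
        records.append(GuideRecord(f"{gene}_sh1", gene, "nonessential", next(seqs)))

    raw = rng.lognormal(mean=0.0, sigma=rpm_sigma, size=len(records))
    rpm = raw / raw.sum() * 1e6
    input_rpm = {r.guide_id: float(v) for r, v in zip(records, rpm)}
    return GuideLibrary(records=records, input_rpm=input_rpm)
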