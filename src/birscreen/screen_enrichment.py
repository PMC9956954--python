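"""Pooled-screen scoring: RPM normalisation, fold enrichment, hit calling.

Enrichment of a guide is its post-selection reads-per-million divided by its
pre-selection (input) RPM.  Two hit-calling routes are provided, both anchored
on the non-targeting controls (NTCs) as the empirical null:

* a Z-score route — fold enrichment standardised against the per-sample NTC
  mean/SD on the natural ratio scale, a guide passing when Z >= z_min in at
  least ``min_replicates`` replicates of one treatment;
* a t-test/FDR route — per treatment, a Student two-sample two-tailed t of
  the guide's replicate log2 folds against the pooled NTC log2 folds, with
  Benjamini-Hochberg correction across guides and a directional requirement
  (only enrichment above the NTC mean can be a hit).

Gene-level prioritisation, exclusive list intersections and hypergeometric
gene-set overlaps support the downstream candidate triage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from birscreen._seq import revcomp

if TYPE_CHECKING:  # pragma: no cover
    from birscreen.synthetic_data.library import GuideLibrary, ScreenDesign


@dataclass
class ScreenCounts:
    """Per-sample guide counts plus the pre-selection baseline RPM.

    ``counts`` is guides x samples with column labels "treatment:replicate".
    """

    counts: pd.DataFrame
    baseline_rpm: pd.Series
    design: "ScreenDesign"

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.baseline_rpm.index):
            raise ValueError("counts and baseline must share the guide universe")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        expected = {
            self.design.sample_label(t, r) for t, r in self.design.samples
        }
        if set(self.counts.columns) != expected:
            raise ValueError("count columns do not match the design samples")

    def treatment_columns(self, treatment: str) -> list[str]:
        return [
            self.design.sample_label(treatment, r)
            for r in range(1, self.design.replicates_per_treatment + 1)
        ]


@dataclass
class EnrichmentTable:
    """Fold enrichment per guide and sample; ``excluded`` flags guides with
    zero baseline RPM, which carry no fold values and enter no statistics."""

    fold: pd.DataFrame
    excluded: pd.Series
    design: "ScreenDesign"

    def treatment_columns(self, treatment: str) -> list[str]:
        return [
            self.design.sample_label(treatment, r)
            for r in range(1, self.design.replicates_per_treatment + 1)
        ]


@dataclass
class NtcBaseline:
    """Per-sample mean/SD of NTC fold enrichment (natural ratio scale)."""

    mean: pd.Series
    sd: pd.Series
    n_ntc: pd.Series
    pooled: bool = False


@dataclass
class ZCalls:
    z: pd.DataFrame  # guides x samples
    pass_count: pd.DataFrame  # guides x treatments
    is_hit: pd.DataFrame  # guides x treatments
    is_hit_any: pd.Series
    z_min: float
    min_replicates: int


@dataclass
class TtestCalls:
    """Long-format results: one row per (guide, treatment)."""

    table: pd.DataFrame  # columns: p_value, q_value, mean_log2fc, is_hit, zero_variance
    fdr_q: float

    def is_hit(self) -> pd.DataFrame:
        return self.table["is_hit"].unstack("treatment")


def to_rpm(counts: Mapping[str, int] | pd.Series) -> pd.Series:
    """Reads-per-million: count * 1e6 / total (total must be positive)."""
    series = pd.Series(counts, dtype=float)
    total = series.sum()
    if total <= 0:
        raise ValueError("cannot normalise a sample with zero total count")
    return series * 1e6 / total


def enrichment(
    rpm_post: pd.DataFrame, baseline_rpm: pd.Series, design: "ScreenDesign"
) -> EnrichmentTable:
    """Fold enrichment = post-selection RPM / input RPM per guide and sample."""
    if not rpm_post.index.equals(baseline_rpm.index):
        raise ValueError("post and baseline must share the guide universe")
    excluded = baseline_rpm == 0
    fold = rpm_post.div(baseline_rpm, axis=0)
    fold[excluded] = np.nan
    return EnrichmentTable(fold=fold, excluded=excluded, design=design)


def enrichment_from_counts(screen: ScreenCounts) -> EnrichmentTable:
    rpm_post = screen.counts.apply(to_rpm, axis=0)
    return enrichment(rpm_post, screen.baseline_rpm, screen.design)


def ntc_baseline(
    table: EnrichmentTable, library: "GuideLibrary", pooled: bool = False
) -> NtcBaseline:
    """Mean and sample SD of the NTC fold enrichments, per sample.

    With ``pooled=True`` the NTC folds of all samples are pooled into one
    baseline applied to every sample.
    """
    ntc_ids = [g for g in library.guide_ids("ntc") if g in table.fold.index]
    ntc = table.fold.loc[ntc_ids].dropna(how="all")
    counts = ntc.notna().sum(axis=0)
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 non-excluded NTC guides per sample; short in {bad}")
    if pooled:
        flat = ntc.to_numpy().ravel()
        flat = flat[~np.isnan(flat)]
        mean = pd.Series(flat.mean(), index=ntc.columns)
        sd = pd.Series(flat.std(ddof=1), index=ntc.columns)
        n = pd.Series(flat.size, index=ntc.columns)
        return NtcBaseline(mean=mean, sd=sd, n_ntc=n, pooled=True)
    return NtcBaseline(
        mean=ntc.mean(axis=0), sd=ntc.std(axis=0, ddof=1), n_ntc=counts, pooled=False
    )


def call_hits_z(
    table: EnrichmentTable,
    baseline: NtcBaseline,
    z_min: float = 2.0,
    min_replicates: int = 3,
    epsilon_guard: bool = False,
) -> ZCalls:
    """Z = (fold - NTC mean) / NTC SD per sample; a guide is a hit when it
    passes Z >= z_min in at least ``min_replicates`` replicates of one
    treatment.  Zero NTC SD is an error unless the epsilon guard is enabled.
    """
    sd = baseline.sd.copy()
    if (sd == 0).any():
        if not epsilon_guard:
            raise ValueError("NTC SD is zero in at least one sample (enable epsilon_guard to proceed)")
        sd = sd.replace(0.0, 1e-12)
    z = table.fold.sub(baseline.mean, axis=1).div(sd, axis=1)
    design = table.design
    pass_count = pd.DataFrame(
        {
            t: (z[table.treatment_columns(t)] >= z_min).sum(axis=1)
            for t in design.treatments
        }
    )
    is_hit = pass_count >= min_replicates
    # excluded guides can never pass
    is_hit[table.excluded] = False
    return ZCalls(
        z=z,
        pass_count=pass_count,
        is_hit=is_hit,
        is_hit_any=is_hit.any(axis=1),
        z_min=z_min,
        min_replicates=min_replicates,
    )


def _log2_with_floor(fold: pd.DataFrame) -> pd.DataFrame:
    """log2 fold with zeros floored at half the smallest positive fold per
    sample (keeps fully-depleted guides finite without dropping them)."""
    floored = fold.copy()
    for col in floored.columns:
        col_vals = floored[col]
        positive = col_vals[col_vals > 0]
        floor = positive.min() / 2.0 if not positive.empty else 1e-9
        floored[col] = col_vals.clip(lower=floor)
    return np.log2(floored)


def student_t_vs_pool(
    group: np.ndarray, pool: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Student's two-sample two-tailed t (pooled variance) of each
    row of ``group`` (shape n x r) against the 1-D ``pool``.

    Returns (t, df, p); rows where the pooled variance is zero get p = 1.
    With a large control pool the degrees of freedom are dominated by the
    pool, so a single consistently enriched guide can reach small p despite
    having only a handful of replicates.
    """
    n1 = group.shape[1]
    n2 = pool.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per group")
    m1 = group.mean(axis=1)
    v1 = group.var(axis=1, ddof=1)
    m2 = pool.mean()
    v2 = pool.var(ddof=1)
    df = float(n1 + n2 - 2)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se2 = sp2 * (1.0 / n1 + 1.0 / n2)
    zero = se2 == 0
    t = np.zeros_like(m1)
    np.divide(m1 - m2, np.sqrt(se2), out=t, where=~zero)
    p = np.where(zero, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, np.full_like(m1, df), p


def call_hits_ttest_fdr(
    table: EnrichmentTable,
    library: "GuideLibrary",
    fdr_q: float = 0.001,
) -> TtestCalls:
    """Per-treatment Student t (pooled variance) of guide replicate log2 folds
    vs pooled NTC log2 folds, Benjamini-Hochberg across guides within the
    treatment.

    A guide is a hit when q <= fdr_q and its mean log2 fold exceeds the NTC
    mean (enrichment-directional; depletion is reported, never flagged).
    NTC guides define the null and are not themselves tested.
    """
    design = table.design
    if design.replicates_per_treatment < 2:
        raise ValueError("t-test route needs >= 2 replicates per treatment")
    log2fold = _log2_with_floor(table.fold)
    ntc_ids = [g for g in library.guide_ids("ntc") if g in log2fold.index]
    ntc_set = set(ntc_ids)
    excluded_set = set(table.excluded.index[table.excluded])
    test_ids = [
        g for g in log2fold.index if g not in ntc_set and g not in excluded_set
    ]
    rows = []
    for treatment in design.treatments:
        cols = table.treatment_columns(treatment)
        pool = log2fold.loc[ntc_ids, cols].to_numpy().ravel()
        pool = pool[~np.isnan(pool)]
        group = log2fold.loc[test_ids, cols].to_numpy()
        t, df, p = student_t_vs_pool(group, pool)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        mean_l2 = group.mean(axis=1)
        zero_var = (group.var(axis=1, ddof=1) == 0) & (pool.var(ddof=1) == 0)
        is_hit = (q <= fdr_q) & (mean_l2 > pool.mean())
        rows.append(
            pd.DataFrame(
                {
                    "guide_id": test_ids,
                    "treatment": treatment,
                    "t_stat": t,
                    "p_value": p,
                    "q_value": q,
                    "mean_log2fc": mean_l2,
                    "ntc_mean_log2fc": pool.mean(),
                    "zero_variance": zero_var,
                    "is_hit": is_hit,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True).set_index(["guide_id", "treatment"])
    return TtestCalls(table=out, fdr_q=fdr_q)


def null_fdr_calibration(
    n_screens: int = 500,
    n_guides: int = 5000,
    n_ntc: int = 500,
    n_replicates: int = 4,
    fdr_q: float = 0.001,
    log2_sigma: float = 1.0,
    seed: int = 0,
) -> dict[str, float]:
    """Calibration of the t/FDR stage under the global null.

    Each simulated screen draws every guide and NTC enrichment i.i.d. from
    the same log-normal (log2 folds normal with sd ``log2_sigma``), runs
    :func:`call_hits_ttest_fdr` at ``fdr_q``, and records the fraction of
    guides flagged (every flag is a false discovery) and the false-discovery
    proportion V / max(R, 1).  Returns the means over screens plus their
    Monte-Carlo standard errors.
    """
    from birscreen.synthetic_data.library import ScreenDesign

    if n_screens < 1:
        raise ValueError("n_screens must be >= 1")
    rng = np.random.default_rng(seed)
    design = ScreenDesign(treatments=("null",), replicates_per_treatment=n_replicates)
    cols = [design.sample_label("null", r) for r in range(1, n_replicates + 1)]
    guide_ids = [f"g{i}" for i in range(n_guides)]
    ntc_ids = [f"NTC{i}" for i in range(n_ntc)]
    library = _NullLibrary(guide_ids, ntc_ids)
    index = pd.Index(guide_ids + ntc_ids, name="guide_id")
    excluded = pd.Series(False, index=index)
    flagged, fdp = [], []
    for _ in range(n_screens):
        fold = np.exp2(rng.normal(0.0, log2_sigma, size=(n_guides + n_ntc, n_replicates)))
        table = EnrichmentTable(
            fold=pd.DataFrame(fold, index=index, columns=cols),
            excluded=excluded,
            design=design,
        )
        calls = call_hits_ttest_fdr(table, library, fdr_q=fdr_q)
        n_hits = int(calls.table["is_hit"].sum())
        flagged.append(n_hits / n_guides)
        fdp.append(1.0 if n_hits > 0 else 0.0)
    flagged_arr = np.array(flagged)
    fdp_arr = np.array(fdp)

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0

    return {
        "n_screens": float(n_screens),
        "mean_flagged_fraction": float(flagged_arr.mean()),
        "se_flagged_fraction": se(flagged_arr),
        "mean_fdp": float(fdp_arr.mean()),
        "se_fdp": se(fdp_arr),
    }


class _NullLibrary:
    """Minimal guide-library facade for calibration runs: ids + categories
    only (no sequences needed by the hit callers)."""

    def __init__(self, targeting_ids: list[str], ntc_ids: list[str]):
        self._targeting = list(targeting_ids)
        self._ntc = list(ntc_ids)

    def guide_ids(self, category: str | None = None) -> list[str]:
        if category == "ntc":
            return list(self._ntc)
        if category == "targeting":
            return list(self._targeting)
        return self._targeting + self._ntc

    @property
    def gene_of(self) -> dict[str, str | None]:
        out: dict[str, str | None] = {g: g for g in self._targeting}
        out.update({g: None for g in self._ntc})
        return out


def benjamini_hochberg(p_values: Iterable[float], q: float) -> np.ndarray:
    """Boolean discovery mask of the BH step-up procedure at level q."""
    rejected, _, _, _ = multipletests(np.asarray(list(p_values)), alpha=q, method="fdr_bh")
    return rejected


@dataclass
class GeneTable:
    table: pd.DataFrame = field(repr=False)


def prioritize_genes(
    significant: pd.DataFrame,
    library: "GuideLibrary",
    fold: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Gene-level prioritisation from a guides x treatments significance mask.

    Per gene: number of distinct significant guides, treatments in which any
    guide is significant, max fold enrichment (if folds given), and flags
    ``multi_shrna`` (>= 2 distinct significant guides) and ``all_treatments``.
    """
    gene_of = library.gene_of
    treatments = list(significant.columns)
    records: dict[str, dict] = {}
    for guide_id, row in significant.iterrows():
        gene = gene_of.get(guide_id)
        if gene is None or not row.any():
            continue
        rec = records.setdefault(
            gene, {"guides": set(), "treatments": set()}
        )
        rec["guides"].add(guide_id)
        rec["treatments"].update(t for t in treatments if row[t])
    rows = []
    for gene, rec in sorted(records.items()):
        max_fold = np.nan
        if fold is not None:
            guide_rows = fold.loc[sorted(rec["guides"])]
            if not guide_rows.empty:
                max_fold = np.nanmax(guide_rows.to_numpy())
        rows.append(
            {
                "gene": gene,
                "n_significant_guides": len(rec["guides"]),
                "treatments": ",".join(t for t in treatments if t in rec["treatments"]),
                "n_treatments": len(rec["treatments"]),
                "max_fold": max_fold,
                "multi_shrna": len(rec["guides"]) >= 2,
                "all_treatments": len(rec["treatments"]) == len(treatments),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_significant_guides",
            "treatments",
            "n_treatments",
            "max_fold",
            "multi_shrna",
            "all_treatments",
        ],
    ).set_index("gene")


def intersect_lists(lists: Mapping[str, set]) -> pd.DataFrame:
    """Exclusive intersection cells over every non-empty label subset.

    Each union member is assigned to exactly one cell (the subset of lists
    containing it), so cell counts partition the union.
    """
    if len(lists) < 2:
        raise ValueError("need at least 2 lists")
    labels = sorted(lists)
    membership: dict[frozenset, set] = {}
    union = set().union(*lists.values())
    for item in union:
        sig = frozenset(l for l in labels if item in lists[l])
        membership.setdefault(sig, set()).add(item)
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            sig = frozenset(combo)
            members = membership.get(sig, set())
            rows.append(
                {
                    "subset": "&".join(combo),
                    "n_lists": r,
                    "count": len(members),
                    "members": ",".join(sorted(members)),
                }
            )
    return pd.DataFrame(rows).set_index("subset")


def geneset_overlap(
    hits: set, reference_set: set, universe_size: int
) -> tuple[int, float]:
    """Overlap count and upper-tail hypergeometric p-value.

    Models drawing |hits| genes from a universe containing |reference| marked
    genes; p = P(overlap >= observed).
    """
    if universe_size < len(hits) or universe_size < len(reference_set):
        raise ValueError("universe smaller than one of the sets")
    k = len(hits & reference_set)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(reference_set), len(hits)))
    return k, p


def assign_guides(
    reads: Iterable[tuple[str, str]] | Iterable[str],
    library: "GuideLibrary",
    max_mismatches: int = 0,
) -> tuple[dict[str, int], int]:
    """Assign amplicon reads to guides by best Hamming match on either strand.

    A read counts for the guide with the unique minimal distance <=
    ``max_mismatches`` over all offsets and both strands; ties between
    distinct guides are left unassigned (never double-counted).
    """
    if max_mismatches > 2:
        raise ValueError("max_mismatches must be <= 2")
    length = library.guide_length  # raises on variable lengths
    guide_ids = library.guide_ids()
    seq_to_guide = {r.sequence: r.guide_id for r in library.records}
    mat = np.frombuffer(
        "".join(r.sequence for r in library.records).encode(), dtype=np.uint8
    ).reshape(len(guide_ids), length)
    counts = {g: 0 for g in guide_ids}
    unassigned = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        best_guides: set[str] = set()
        best_d = max_mismatches + 1
        for strand_seq in (seq, revcomp(seq)):
            arr = np.frombuffer(strand_seq.encode(), dtype=np.uint8)
            for off in range(len(strand_seq) - length + 1):
                if max_mismatches == 0:
                    exact = seq_to_guide.get(strand_seq[off : off + length])
                    if exact is not None:
                        best_d = 0
                        best_guides.add(exact)
                    continue
                d = (mat != arr[off : off + length]).sum(axis=1)
                dmin = int(d.min())
                if dmin < best_d:
                    best_d = dmin
                    best_guides = {guide_ids[i] for i in np.flatnonzero(d == dmin)}
                elif dmin == best_d:
                    best_guides |= {guide_ids[i] for i in np.flatnonzero(d == dmin)}
        if best_d <= max_mismatches and len(best_guides) == 1:
            counts[best_guides.pop()] += 1
        else:
            unassigned += 1
    return counts, unassigned
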