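"""Screen scoring: normalisation, baselines, hit calling, set utilities.

Independent oracles: brute-force BH step-up over all prefixes, exhaustive
hypergeometric enumeration, and a literal Hamming scan for guide assignment.
"""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birscreen import screen_enrichment as se
from birscreen._seq import revcomp
from birscreen.synthetic_data import GuideLibrary, GuideRecord, ScreenDesign

DESIGN2 = ScreenDesign(treatments=("A", "B"), replicates_per_treatment=2)


def _table(fold_rows: dict[str, list[float]], design=DESIGN2, baseline=None):
    cols = [design.sample_label(t, r) for t, r in design.samples]
    fold = pd.DataFrame.from_dict(fold_rows, orient="index", columns=cols)
    if baseline is None:
        baseline = pd.Series(1.0, index=fold.index)
    excluded = baseline == 0
    fold = fold.copy()
    fold[excluded] = np.nan
    return se.EnrichmentTable(fold=fold, excluded=excluded, design=design)


def _mini_library(ntc_ids, targeting):
    """targeting: dict guide_id -> gene."""
    rng = np.random.default_rng(0)
    records = []
    seqs = iter(
        "".join("ACGT"[b] for b in rng.integers(0, 4, size=19))
        for _ in range(len(ntc_ids) + len(targeting))
    )
    for g in ntc_ids:
        records.append(GuideRecord(g, None, "ntc", next(seqs)))
    for g, gene in targeting.items():
        records.append(GuideRecord(g, gene, "targeting", next(seqs)))
    rpm = {r.guide_id: 1e6 / len(records) for r in records}
    total = sum(rpm.values())
    rpm = {k: v * 1e6 / total for k, v in rpm.items()}
    return GuideLibrary(records=records, input_rpm=rpm)


class TestRpmAndEnrichment:
    def test_rpm_arithmetic(self):
        rpm = se.to_rpm({"a": 1, "b": 3})
        assert rpm["a"] == pytest.approx(250_000)
        assert rpm.sum() == pytest.approx(1e6)

    def test_rpm_zero_total_is_error(self):
        with pytest.raises(ValueError):
            se.to_rpm({"a": 0})

    def test_fold_arithmetic_and_exclusion(self):
        design = ScreenDesign(treatments=("A",), replicates_per_treatment=1)
        post = pd.DataFrame({"A:1": [4.0, 0.0, 7.0]}, index=["g1", "g2", "g3"])
        baseline = pd.Series([2.0, 5.0, 0.0], index=post.index)
        table = se.enrichment(post, baseline, design)
        assert table.fold.loc["g1", "A:1"] == 2.0
        assert table.fold.loc["g2", "A:1"] == 0.0
        assert table.excluded.loc["g3"]
        assert np.isnan(table.fold.loc["g3", "A:1"])


class TestNtcBaseline:
    def test_mean_and_sample_sd(self):
        lib = _mini_library(["n1", "n2"], {"t1": "G1"})
        table = _table(
            {"n1": [0.5] * 4, "n2": [1.5] * 4, "t1": [2.0] * 4}
        )
        base = se.ntc_baseline(table, lib)
        assert base.mean.iloc[0] == pytest.approx(1.0)
        assert base.sd.iloc[0] == pytest.approx(0.7071, abs=1e-4)

    def test_zero_sd_guarded_downstream(self):
        lib = _mini_library(["n1", "n2"], {"t1": "G1"})
        table = _table({"n1": [1.0] * 4, "n2": [1.0] * 4, "t1": [9.0] * 4})
        base = se.ntc_baseline(table, lib)
        with pytest.raises(ValueError, match="SD is zero"):
            se.call_hits_z(table, base)
        calls = se.call_hits_z(table, base, epsilon_guard=True, min_replicates=2)
        assert calls.is_hit_any.loc["t1"]

    def test_estimates_recover_sampling_distribution(self):
        rng = np.random.default_rng(1)
        n = 10_000
        ntc_ids = [f"n{i}" for i in range(n)]
        lib = _mini_library(ntc_ids, {})
        design = ScreenDesign(treatments=("A",), replicates_per_treatment=1)
        folds = rng.normal(1.0, 0.25, size=n)
        table = _table({g: [f] for g, f in zip(ntc_ids, folds)}, design=design)
        base = se.ntc_baseline(table, lib)
        assert base.mean.iloc[0] == pytest.approx(1.0, abs=3 * 0.25 / np.sqrt(n))
        assert base.sd.iloc[0] == pytest.approx(0.25, abs=3 * 0.25 / np.sqrt(2 * n))


class TestZCalls:
    def test_threshold_boundary_exact(self):
        """A fold exactly 2 SD above the NTC mean passes; just below fails."""
        lib = _mini_library(["n1", "n2", "n3"], {"t1": "G1", "t2": "G2"})
        design = ScreenDesign(treatments=("A",), replicates_per_treatment=4)
        table = _table(
            {
                "n1": [0.75] * 4,
                "n2": [1.0] * 4,
                "n3": [1.25] * 4,
                "t1": [1.5] * 4,
                "t2": [1.49] * 4,
            },
            design=design,
        )
        base = se.ntc_baseline(table, lib)
        assert base.mean.iloc[0] == pytest.approx(1.0)
        assert base.sd.iloc[0] == pytest.approx(0.25)
        calls = se.call_hits_z(table, base)
        assert calls.z.loc["t1"].iloc[0] == pytest.approx(2.0)
        assert calls.is_hit_any.loc["t1"]
        assert not calls.is_hit_any.loc["t2"]
        flagged_z = calls.z[calls.is_hit.to_numpy().any(axis=1)].min().min()
        assert flagged_z == pytest.approx(2.0)

    def test_two_of_four_replicates_is_not_enough(self):
        lib = _mini_library(["n1", "n2", "n3"], {"t1": "G1"})
        design = ScreenDesign(treatments=("A",), replicates_per_treatment=4)
        table = _table(
            {
                "n1": [0.75] * 4,
                "n2": [1.0] * 4,
                "n3": [1.25] * 4,
                "t1": [1.6, 1.6, 1.0, 1.0],
            },
            design=design,
        )
        calls = se.call_hits_z(table, se.ntc_baseline(table, lib), min_replicates=3)
        assert calls.pass_count.loc["t1", "A"] == 2
        assert not calls.is_hit_any.loc["t1"]


class TestTtestFdr:
    def test_strong_enrichment_is_significant(self):
        rng = np.random.default_rng(2)
        ntc_ids = [f"n{i}" for i in range(100)]
        lib = _mini_library(ntc_ids, {"t1": "G1"})
        design = ScreenDesign(treatments=("A",), replicates_per_treatment=4)
        rows = {g: rng.normal(1.0, 0.1, size=4).tolist() for g in ntc_ids}
        rows["t1"] = [4.0, 4.1, 3.9, 4.2]
        table = _table(rows, design=design)
        calls = se.call_hits_ttest_fdr(table, lib)
        assert calls.table.loc[("t1", "A"), "p_value"] < 1e-6
        assert calls.table.loc[("t1", "A"), "is_hit"]

    def test_bh_against_brute_force_oracle(self):
        """BH step-up agrees with direct enumeration of every cut-off."""

        def bh_oracle(ps, q):
            m = len(ps)
            order = np.argsort(ps)
            k_star = 0
            for rank, idx in enumerate(order, start=1):
                if ps[idx] <= q * rank / m:
                    k_star = rank
            rejected = np.zeros(m, dtype=bool)
            rejected[order[:k_star]] = True
            return rejected

        rng = np.random.default_rng(3)
        cases = [
            [1e-6, 0.5, 0.9],
            [0.001, 0.001, 0.001],
            [1.0, 1.0],
        ] + [rng.uniform(0, 1, size=rng.integers(2, 13)).tolist() for _ in range(50)]
        for ps in cases:
            got = se.benjamini_hochberg(ps, q=0.05)
            want = bh_oracle(np.array(ps), 0.05)
            assert np.array_equal(got, want), ps
        assert se.benjamini_hochberg([1e-6, 0.5, 0.9], q=0.001).sum() == 1

    def test_all_p_one_yields_no_discoveries(self):
        lib = _mini_library(["n1", "n2", "n3"], {"t1": "G1"})
        design = ScreenDesign(treatments=("A",), replicates_per_treatment=4)
        table = _table(
            {"n1": [1.0] * 4, "n2": [1.0] * 4, "n3": [1.0] * 4, "t1": [1.0] * 4},
            design=design,
        )
        calls = se.call_hits_ttest_fdr(table, lib)
        assert calls.table["zero_variance"].all()
        assert (calls.table["p_value"] == 1.0).all()
        assert not calls.table["is_hit"].any()


class TestGeneLevel:
    def test_prioritisation_flags(self):
        lib = _mini_library(
            ["n1", "n2"],
            {"a1": "GA", "a2": "GA", "b1": "GB", "c1": "GC"},
        )
        sig = pd.DataFrame(
            {
                "A": [True, True, True, False],
                "B": [False, False, True, False],
            },
            index=["a1", "a2", "b1", "c1"],
        )
        out = se.prioritize_genes(sig, lib)
        assert out.loc["GA", "multi_shrna"]
        assert not out.loc["GB", "multi_shrna"]
        assert out.loc["GB", "all_treatments"]
        assert "GC" not in out.index

    def test_intersections_exclusive_cells(self):
        out = se.intersect_lists({"A": {"x", "y"}, "B": {"y", "z"}})
        assert out.loc["A", "count"] == 1 and out.loc["A", "members"] == "x"
        assert out.loc["B", "members"] == "z"
        assert out.loc["A&B", "members"] == "y"

    def test_identical_lists_only_full_cell(self):
        lists = {k: {"p", "q"} for k in "ABCD"}
        out = se.intersect_lists(lists)
        nonzero = out[out["count"] > 0]
        assert list(nonzero.index) == ["A&B&C&D"]
        assert nonzero.iloc[0]["count"] == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sets(st.integers(0, 30).map(str), max_size=12),
            min_size=2,
            max_size=4,
        )
    )
    def test_cells_partition_the_union(self, sets):
        lists = {f"L{i}": s for i, s in enumerate(sets)}
        out = se.intersect_lists(lists)
        union = set().union(*lists.values())
        assert out["count"].sum() == len(union)
        members = [m for ms in out["members"] if ms for m in ms.split(",")]
        assert sorted(members) == sorted(union)

    def test_hypergeometric_against_enumeration(self):
        """Upper-tail p equals exhaustive counting of draw outcomes."""

        def oracle(universe, n_ref, n_hits, k_obs):
            total = comb(universe, n_hits)
            favourable = sum(
                comb(n_ref, k) * comb(universe - n_ref, n_hits - k)
                for k in range(k_obs, min(n_ref, n_hits) + 1)
            )
            return favourable / total

        universe = [f"g{i}" for i in range(20)]
        hits = set(universe[:5])
        ref = set(universe[2:6])
        k, p = se.geneset_overlap(hits, ref, 20)
        assert k == 3
        assert p == pytest.approx(oracle(20, 4, 5, 3), rel=1e-12)

    def test_overlap_degenerate_cases(self):
        full = {"a", "b"}
        k, p = se.geneset_overlap(full, full, 2)
        assert (k, p) == (2, pytest.approx(1.0))
        k, _ = se.geneset_overlap({"a"}, {"b"}, 3)
        assert k == 0
        with pytest.raises(ValueError):
            se.geneset_overlap({"a", "b"}, {"a"}, 1)


@pytest.fixture(scope="module")
def tiny_library():
    return _mini_library(["n1"], {"g1": "GA", "g2": "GB", "g3": "GC"})


class TestAssignGuides:

    def test_exact_containment(self, tiny_library):
        g1 = tiny_library.records[1]
        read = "AAAA" + g1.sequence + "TTTT"
        counts, unassigned = se.assign_guides([read], tiny_library)
        assert counts[g1.guide_id] == 1 and unassigned == 0

    def test_reverse_strand_containment(self, tiny_library):
        g1 = tiny_library.records[1]
        read = revcomp("AAAA" + g1.sequence + "TTTT")
        counts, _ = se.assign_guides([read], tiny_library)
        assert counts[g1.guide_id] == 1

    def test_no_match_is_unassigned(self, tiny_library):
        counts, unassigned = se.assign_guides(["A" * 40], tiny_library, max_mismatches=1)
        assert unassigned == 1
        assert sum(counts.values()) == 0

    def test_one_mismatch_against_brute_force(self, tiny_library):
        """Best-hit assignment agrees with a literal all-offsets Hamming scan."""
        rng = np.random.default_rng(4)

        def brute(read, lib, max_mm):
            best = {}
            for rec in lib.records:
                d_best = 99
                for strand in (read, revcomp(read)):
                    for off in range(len(strand) - 19 + 1):
                        d = sum(
                            a != b for a, b in zip(strand[off : off + 19], rec.sequence)
                        )
                        d_best = min(d_best, d)
                best[rec.guide_id] = d_best
            dmin = min(best.values())
            winners = [g for g, d in best.items() if d == dmin]
            if dmin <= max_mm and len(winners) == 1:
                return winners[0]
            return None

        for _ in range(20):
            rec = tiny_library.records[rng.integers(0, 4)]
            seq = list(rec.sequence)
            if rng.random() < 0.7:
                seq[rng.integers(0, 19)] = "ACGT"[rng.integers(0, 4)]
            flank = "".join("ACGT"[b] for b in rng.integers(0, 4, size=8))
            read = flank + "".join(seq) + flank
            counts, unassigned = se.assign_guides([read], tiny_library, max_mismatches=1)
            want = brute(read, tiny_library, 1)
            if want is None:
                assert unassigned == 1
            else:
                assert counts[want] == 1
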