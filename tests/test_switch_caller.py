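"""Read alignment, template-switch calling, domains, mutations, motifs,
hotspots.

The full-DP edit-distance oracle here is written independently of the
aligner's block refinement: a plain Needleman-Wunsch matrix with unit costs.
"""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birscreen import switch_caller as sc
from birscreen.synthetic_data import simulate_ipcr_reads
from birscreen.synthetic_data.panel import ECTOPIC_NAME


def full_dp_edit_distance(a: str, b: str) -> int:
    """Textbook O(nm) edit distance, the oracle for block refinement."""
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev[-1])


class TestAlignRead:
    def test_exact_substring_single_block(self, panel, panel_index):
        read = panel.ectopic.sequence[100:900]
        chain = sc.align_read(read, panel_index)
        assert len(chain) == 1
        b = chain[0]
        assert (b.contig, b.ref_start, b.ref_end) == (ECTOPIC_NAME, 100, 900)
        assert (b.read_start, b.read_end) == (0, 800)
        assert b.edits == []

    def test_three_block_chimera(self, panel, panel_index):
        ect = panel.ectopic.sequence
        chr3 = panel.decoys["chr3"]
        read = ect[0:500] + chr3[1000:1400] + ect[500:900]
        chain = sc.align_read(read, panel_index)
        assert [b.contig for b in chain] == [ECTOPIC_NAME, "chr3", ECTOPIC_NAME]
        assert chain[1].ref_start == 1000 and chain[1].ref_end == 1400

    def test_single_substitution_reported_at_reference_offset(self, panel, panel_index):
        ref = panel.ectopic.sequence[100:900]
        pos = 250
        alt = "A" if ref[pos] != "A" else "C"
        read = ref[:pos] + alt + ref[pos + 1 :]
        chain = sc.align_read(read, panel_index)
        assert len(chain) == 1
        assert len(chain[0].edits) == 1
        e = chain[0].edits[0]
        assert e.type == "mismatch"
        assert e.ref_pos == 100 + pos
        assert e.bases == f"{ref[pos]}>{alt}"

    def test_unalignable_read_gives_empty_chain(self, panel_index):
        chain = sc.align_read("ACGT" * 30, panel_index)
        assert chain == []

    def test_read_bases_never_overlap_between_blocks(self, panel, panel_index):
        reads, _ = simulate_ipcr_reads(panel, n_reads=25, p_double_switch=0.15, seed=21)
        for _, seq in reads:
            chain = sc.align_read(seq, panel_index)
            for left, right in zip(chain, chain[1:]):
                assert left.read_end <= right.read_start
            assert sum(b.read_length for b in chain) <= len(seq)

    def test_block_edit_count_equals_full_dp_distance(self, panel, panel_index):
        """Block refinement is edit-optimal: per-block edit counts (bases for
        multi-base indels) equal the independent full-DP distance."""
        rng = np.random.default_rng(5)
        reads, _ = simulate_ipcr_reads(
            panel, n_reads=8, p_single_switch=0.5, ins_rate=3e-3, del_rate=3e-3,
            mm_rate=2e-3, seed=22,
        )
        checked = 0
        for _, seq in reads:
            for b in sc.align_read(seq, panel_index):
                if b.read_length > 2000:
                    continue
                query = seq[b.read_start : b.read_end]
                target = panel_index.contigs[b.contig][b.ref_start : b.ref_end]
                cost = sum(
                    len(e.bases) if e.type in ("insertion", "deletion") else 1
                    for e in b.edits
                )
                assert cost == full_dp_edit_distance(query, target)
                checked += 1
        assert checked >= 8


class TestCallSwitches:
    def test_fully_ectopic_chain_has_no_events(self, panel, panel_index):
        chain = sc.align_read(panel.ectopic.sequence[0:1500], panel_index)
        assert sc.call_switches(chain) == []

    def test_chimera_event_geometry(self, panel, panel_index):
        ect = panel.ectopic.sequence
        read = ect[0:500] + panel.decoys["chr3"][1000:1400] + ect[500:900]
        events = sc.call_switches(sc.align_read(read, panel_index), read_id="r")
        assert len(events) == 1
        e = events[0]
        assert e.target == "chr3"
        assert e.segment_length == 400
        assert e.departure == 500 and e.return_ == 500

    def test_two_ordered_events(self, panel, panel_index):
        ect = panel.ectopic.sequence
        read = (
            ect[0:400]
            + panel.decoys["chr12"][100:400]
            + ect[450:900]
            + panel.decoys["chr17"][2000:2350]
            + ect[950:1400]
        )
        events = sc.call_switches(sc.align_read(read, panel_index), read_id="r")
        assert [e.target for e in events] == ["chr12", "chr17"]
        assert [e.order_index for e in events] == [0, 1]

    def test_short_segment_below_min_is_ignored(self, panel, panel_index):
        ect = panel.ectopic.sequence
        read = ect[0:500] + panel.decoys["chr2"][500:580] + ect[520:1100]
        events = sc.call_switches(
            sc.align_read(read, panel_index), min_segment=100
        )
        assert events == []

    def test_switch_stats_counting(self):
        ev = lambda tgt: sc.SwitchEvent("r", 1, 2, tgt, 300, 0)  # noqa: E731
        events = {
            "r1": [ev("chr2")],
            "r2": [ev("chr3")],
            "r3": [],
            "r4": [ev("chr12"), ev("chr17")],
        }
        frac, per_contig = sc.switch_stats(events)
        assert frac == {"0": 0.25, "1": 0.5, "2+": 0.25}
        assert per_contig == {"chr2": 1, "chr3": 1, "chr12": 1, "chr17": 1}
        with pytest.raises(ValueError):
            sc.switch_stats({})


class TestMutationSetDedup:
    def test_identical_alignments_collapse(self, panel, panel_index):
        reads, _ = simulate_ipcr_reads(panel, n_reads=20, dup_factor=2.0, seed=33)
        chains = sc.align_reads(reads, panel_index)
        kept, dup_map = sc.deduplicate_by_mutations(chains)
        # raw-sequence duplicates have identical alignments, so the counts
        # agree with exact-sequence dedup
        from birscreen.ipcr_core import deduplicate

        unique_seq, _ = deduplicate(reads)
        assert len(kept) == len(unique_seq)
        assert all(dup_map[r] in kept for r in dup_map)


class TestClusterDomains:
    def test_two_well_separated_clusters(self):
        rng = np.random.default_rng(6)
        pts = (
            (100 + rng.integers(-5, 6, size=50)).tolist()
            + (900 + rng.integers(-5, 6, size=40)).tolist()
        )
        domains = sc.cluster_domains(pts, bandwidth=100, min_support=10)
        assert [d.label for d in domains] == ["a", "b"]
        assert domains[0].support == 50 and domains[1].support == 40
        assert 90 <= domains[0].start <= domains[0].end <= 111

    def test_empty_input(self):
        assert sc.cluster_domains([]) == []

    def test_permutation_invariance(self):
        pts = [100, 105, 110, 900, 905, 2000]
        rng = np.random.default_rng(7)
        base = sc.cluster_domains(pts, min_support=2)
        for _ in range(5):
            shuffled = list(pts)
            rng.shuffle(shuffled)
            assert sc.cluster_domains(shuffled, min_support=2) == base

    def test_min_support_filters(self):
        domains = sc.cluster_domains([100, 101, 5000], min_support=2)
        assert len(domains) == 1 and domains[0].label == "a"

    def test_new_domain_detection(self):
        a = [sc.SwitchDomain("a", 100, 150, 20), sc.SwitchDomain("b", 900, 950, 15)]
        b = [
            sc.SwitchDomain("a", 110, 140, 25),
            sc.SwitchDomain("b", 2000, 2080, 30),
        ]
        new = sc.new_domains(a, b)
        assert [d.start for d in new] == [2000]


class TestMutationsAndSpectrum:
    def test_rate_arithmetic(self, panel, panel_index):
        ref = panel.ectopic.sequence[100:1100]
        read = ref[:400] + "A" + ref[400:]  # one inserted base over 1000 bp
        chains = {"r1": sc.align_read(read, panel_index)}
        calls, rates = sc.call_mutations(chains)
        assert rates.aligned_bp == 1000
        assert rates.rate("insertion") == pytest.approx(1e-3)
        assert rates.rate("deletion") == 0.0

    def test_perfect_alignment_all_rates_zero(self, panel, panel_index):
        chains = {"r1": sc.align_read(panel.ectopic.sequence[0:2000], panel_index)}
        _, rates = sc.call_mutations(chains)
        assert (rates.table["rate"] == 0).all()

    def test_zero_aligned_bp_is_error(self):
        with pytest.raises(ValueError):
            sc.call_mutations({"r1": []})

    def test_spectrum_channels_and_folding(self):
        ref = "TACAG"  # C at pos 2 in context A_A
        m = sc.MutationCall("r", ECTOPIC_NAME, 2, "mismatch", "C", "A")
        channels, frac, skipped = sc.trinucleotide_spectrum([m], ref)
        assert channels["A[C>A]A"] == 1 and channels.sum() == 1
        assert frac == 1.0 and skipped == 0

    def test_purine_site_folds_to_pyrimidine_strand(self):
        ref = "ATGTA"  # G at pos 2, context T_T; G>T folds to A[C>A]A
        m = sc.MutationCall("r", ECTOPIC_NAME, 2, "mismatch", "G", "T")
        channels, frac, _ = sc.trinucleotide_spectrum([m], ref)
        assert channels["A[C>A]A"] == 1

    def test_folding_is_involution(self):
        for ref, alt in (("C", "A"), ("G", "T"), ("T", "G"), ("A", "C")):
            for left in "ACGT":
                for right in "ACGT":
                    once = sc.fold_substitution(ref, alt, left, right)
                    m = re.match(r"(.)\[(.)>(.)\](.)", once)
                    twice = sc.fold_substitution(
                        m.group(2), m.group(3), m.group(1), m.group(4)
                    )
                    assert once == twice

    def test_no_mismatches_reports_null_fraction(self):
        channels, frac, _ = sc.trinucleotide_spectrum([], "ACGT")
        assert channels.sum() == 0 and frac is None

    def test_edge_mismatch_skipped_with_count(self):
        m = sc.MutationCall("r", ECTOPIC_NAME, 0, "mismatch", "A", "C")
        channels, frac, skipped = sc.trinucleotide_spectrum([m], "ACGT")
        assert skipped == 1 and frac is None


class TestMotifs:
    def test_embedded_t29_run_found(self):
        rng = np.random.default_rng(8)
        left = "".join("ACG"[i] for i in rng.integers(0, 3, size=200))
        right = "".join("ACG"[i] for i in rng.integers(0, 3, size=200))
        seq = left + "T" * 29 + right
        runs = [m for m in sc.find_motifs(seq) if m[0] == "T_run"]
        assert runs == [("T_run", 200, 229, "+")]

    def test_g4_consensus_found(self):
        seq = "ATAT" + "GGGTTGGGTTGGGTTGGG" + "ATAT"
        g4s = [m for m in sc.find_motifs(seq) if m[0] == "G4"]
        assert g4s == [("G4", 4, 22, "+")]

    def test_reverse_strand_motifs(self):
        seq = "AT" + "A" * 25 + "CCCTTCCCTTCCCTTCCC" + "GT"
        kinds = {(m[0], m[3]) for m in sc.find_motifs(seq)}
        assert ("T_run", "-") in kinds and ("G4", "-") in kinds

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_agrees_with_naive_regex_oracle(self, seed):
        """Independent oracle: per-position re.match scan, intervals merged."""
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1000))
        # bias towards Gs and Ts so motifs actually occur sometimes
        seq = seq.replace("A", "G", 200).replace("C", "T", 100)

        def oracle():
            out = set()
            for pat, kind, strand in (
                (re.compile(r"T{20,}"), "T_run", "+"),
                (re.compile(r"A{20,}"), "T_run", "-"),
            ):
                for m in pat.finditer(seq):
                    out.add((kind, m.start(), m.end(), strand))
            for pat, strand in (
                (re.compile(sc.G4_PATTERN), "+"),
                (re.compile(r"C{3,}(?:[ACGT]{1,7}C{3,}){3}"), "-"),
            ):
                ivs = []
                for start in range(len(seq)):
                    m = pat.match(seq, start)
                    if m:
                        ivs.append((m.start(), m.end()))
                merged = []
                for s, e in sorted(ivs):
                    if merged and s <= merged[-1][1]:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                    else:
                        merged.append((s, e))
                out |= {("G4", s, e, strand) for s, e in merged}
            return out

        assert set(sc.find_motifs(seq)) == oracle()


class TestHotspots:
    def test_zero_mutations_nothing_flagged(self):
        motifs = [("T_run", 100, 129, "+")]
        out = sc.hotspot_test([], motifs, np.arange(1000), seed=0)
        assert not out["hotspot"].any()

    def test_no_motifs_empty_result(self):
        out = sc.hotspot_test([1, 2, 3], [], np.arange(100), seed=0)
        assert out.empty

    def test_spiked_motif_flagged_others_not(self):
        rng = np.random.default_rng(9)
        background = rng.integers(0, 4000, size=400).tolist()
        spike = rng.integers(1950, 2050, size=120).tolist()
        motifs = [
            ("G4", 1975, 2005, "+"),
            ("G4", 500, 530, "+"),
            ("T_run", 3000, 3029, "+"),
        ]
        out = sc.hotspot_test(
            background + spike, motifs, np.arange(4000), window=50, seed=1
        )
        assert bool(out.loc[0, "hotspot"])
        assert not out.loc[1, "hotspot"] and not out.loc[2, "hotspot"]
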