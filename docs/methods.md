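# Methods

`birscreen` models two linked assays used to find suppressors of
break-induced replication (BIR): a pooled shRNA selection screen read out by
amplicon sequencing, and single-molecule inverse-PCR (iPCR) long-read
sequencing across an engineered ectopic locus carrying structure-prone
(non-B) DNA. This note records the models, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
decisions a maintainer would want to know.

## Screen arm

### Enrichment model

Counts are normalised within each sample to reads per million (RPM).
Fold enrichment of guide *g* in sample *s* is

    E(g, s) = RPM_post(g, s) / RPM_input(g),

with the input taken from the pre-selection pool. Guides with zero input
RPM are flagged `excluded` and enter no statistics (the screen cannot say
anything about a guide that was never present).

### Hit calling

Two routes, both using the non-targeting controls (NTCs) as the empirical
null:

* **Z route** (natural ratio scale). Per sample, Z(g, s) =
  (E(g, s) − μ_NTC(s)) / σ_NTC(s), with μ/σ the mean and sample SD
  (ddof = 1) over non-excluded NTC folds. A guide is a hit when Z ≥ 2 in at
  least 3 replicates of one treatment. The threshold comparison is ≥, so a
  guide sitting exactly at Z = 2 passes. σ_NTC = 0 raises an error unless an
  explicit epsilon guard (1e−12) is enabled. A pooled-NTC baseline (all
  samples' NTC folds pooled) is available as a flag; per-replicate baselines
  are the default.
* **t/FDR route** (log2 scale, variance stabilisation). Per treatment, a
  Student's two-sample two-tailed t with pooled variance compares the
  guide's replicate log2 folds (n = 4) against the pooled NTC log2 folds of
  that treatment (125 NTCs × 4 replicates = 500 values). p-values are
  Benjamini–Hochberg corrected across guides within the treatment and a
  guide is a hit when q ≤ 0.001 **and** its mean log2 fold exceeds the NTC
  mean — only enrichment can be a hit; depletion is reported but never
  flagged. Zero variance in both groups sets p = 1 with a `zero_variance`
  flag.

The pooled-variance form (rather than Welch) is a deliberate choice: with
four replicates the Welch degrees of freedom collapse to ≈3, which makes a
q ≤ 0.001 discovery essentially unreachable for any single guide and breaks
the internal consistency one expects between the two routes. With the
pooled form the degrees of freedom are dominated by the large NTC pool, and
a guide with Z ≥ 6 in every replicate is always also an FDR hit — a
property the test suite asserts. Fold values of 0 are floored at half the
smallest positive fold in the sample before taking log2.

### Gene-level triage and set statistics

Per gene: the number of distinct significant guides, the treatments in
which any guide is significant, the maximum fold, and flags `multi_shrna`
(≥ 2 distinct guides) and `all_treatments`. List comparison uses exclusive
intersection cells (every gene assigned to exactly the subset of lists
containing it, so cells partition the union). Gene-set overlap against
user-supplied reference lists uses the upper-tail hypergeometric p-value.

### Read-to-guide assignment

Reads are assigned by best Hamming match of the guide (either strand, any
offset) with at most `max_mismatches` (≤ 2) substitutions; ties between
distinct guides at the minimal distance are left unassigned and never
double-counted. This is a deliberately simple, exhaustive matcher meant for
amplicon reads; the primary input path is a pre-tabulated count matrix.

## Synthetic screen generator

Each guide's log2 selection effect in sample *s* is

    eff(g, s) = m_g + b_g + e_{g,s},
    b_g ~ N(0, effect_sd),   e_{g,s} ~ N(0, replicate_sd),

with m_g = `suppressor_log2fc` (default +5) for guides targeting a planted
suppressor and m_g = `ntc_log2fc_mean` (default −1.852) for everything
else, NTCs and non-essential controls included. `b_g` is a guide-level
effect that reproduces across replicates (clonal history, integration
position, spontaneous pre-selection events); `e` is replicate noise.
Defaults: effect_sd = 1.0, replicate_sd = 0.25. Counts are Poisson–gamma
(negative-binomial-style) draws centred on depth × RPM_input × 2^eff / 1e6
with one overdispersion scalar (default 0.05); sequencing depth defaults to
1e7.

Sequencing is compositional: observed enrichment equals 2^eff times a
global factor C = 1e6 / Σ_g RPM_g·2^eff_g. When suppressor guides soak up
read share, every null guide is pushed below 1 — this is exactly how strong
selection depletes the controls. `expected_fraction_below` gives the
closed-form expectation of the fraction of a category's enrichments below a
threshold including C; at the analysis defaults (1,200 genes, 20
suppressors at log2 fold 5) about 95–97% of NTC enrichments fall below 1.0,
and the simulation is checked against this analytic value, not against a
tuned constant. The default null mean −1.852 places Φ(1.852) = 96.8% of the
null effect distribution below zero when C ≈ 1.

What the generator does **not** emulate: infection multiplicity and
guide-per-cell statistics, cell growth and bottleneck dynamics during
selection, PCR jackpotting, and any correlation between guides of the same
gene beyond the shared mean. Passing tests therefore show that the scoring
machinery is calibrated and recovers planted effects under an explicit
noise model — not that it would be calibrated under every real screen's
noise structure.

## iPCR arm

### Construct and reference panel

The ectopic construct is a linear sequence with annotated features: two
XbaI sites (T^CTAGA) delimiting a fragment that, circularized, is the iPCR
template; an outward-facing primer pair (Gfp-Rev
5'-GTCCATGCCGAGAGTGATC-3', Nhe-For 5'-AAGCTTGCCTTGAGTGCTTC-3') whose
unrearranged product is exactly `amplicon_length` (default 4,000 bp); a
microsatellite tract ((CTG)₁₀₀ = 300 bp, (ATTCT)₄₇ = 235 bp, or a
homopurine 12-mer × 58 standing in for the Pu/Py mirror repeat, whose true
sequence is not modelled); the c-myc origin, dTomato and eGFP/TK (or
CMV-TK) reporters and AluYA5 flanks as labelled intervals; and four
implanted structure-prone elements — two poly-dT tracts (d(T)₂₉, one per
strand) and two G-quadruplex consensus elements — spaced so that their
±50 bp hotspot windows do not overlap. Decoy contigs (default chr2, chr3,
chr12, chr17, 6 kb each) are random sequences sharing no 21-mer (either
strand) with the construct, enforced at generation with a retry budget, so
template-switch segments have unambiguous truth without downloading a
genome. Coordinates are 0-based half-open everywhere.

### Read simulator

Each unique template is the amplicon with 0, 1 or 2 decoy segments spliced
in. A switch departs the ectopic template at a breakpoint-domain center
(default six, evenly spread in amplicon coordinates) plus N(0, 12 bp)
jitter, copies 250–1,000 bp from a decoy chosen by weight, and returns
20–100 bp downstream. With `pair_rule = (chr12, chr17)` every double switch
visits chr12 then chr17 and single switches avoid chr12 — strict
co-occurrence of two donors. Errors are implanted per template base:
insertions 1e−3/bp, deletions 1.15e−3/bp, mismatches 2e−4/bp; an optional
hotspot multiplies all three rates (default 10×) within ±50 bp of a chosen
construct position. PCR duplicates are verbatim copies appended after the
unique templates and flagged in the truth log. The truth log (segments +
every implanted mutation with template and read offsets) reconstructs each
read exactly; this conservation is asserted in the tests. Base quality is a
constant placeholder; homopolymer-aware HiFi error profiles, chimeric PCR
artifacts and strand-switched (inverted) segments are not modelled.

### Alignment

Reads are filtered for the forward primer within the first
`end_window` bases (default primer length + 5) and the reverse-primer
complement within the last window, substitutions only, ≤ 1 mismatch;
opposite-orientation reads are reverse-complemented so everything
downstream sees forward-primer-first reads. Exact-sequence duplicates
collapse to the first representative; an optional post-alignment
deduplication collapses reads with identical block/edit sets.

Alignment is unique-k-mer anchor chaining (k = 21): every k-mer occurring
exactly once in the panel places a read position on one contig. Anchors are
grouped into co-linear same-contig runs (monotone reference positions,
diagonal drift ≤ 32); runs shorter than 50 bp of read are dropped. Three
repairs make the block decomposition exact enough for rate estimation:

1. **Anchor deserts.** Tandem repeats contain no unique k-mers, so anchors
   vanish across the whole tract. Collinear same-contig runs separated by a
   gap whose read and reference lengths agree within the band are merged
   and realigned globally.
2. **Junction microhomology.** At a junction where both flanking blocks can
   anchor the same read bases (e.g. the religated XbaI site at the circle
   junction contributes 6 bp of exact homology), the upstream block wins
   and the downstream block is trimmed — a switch is placed as late as the
   homology allows.
3. **Boundary gaps.** Mutations within ~k of a junction destroy the
   anchors around themselves; the anchor-free gap (≤ 120 bp) is split
   between the flanking blocks at the point minimising total edit cost
   (small O(gap²) DP per side, accepted only if the cost is plausible),
   so boundary-adjacent mutations stay inside an aligned block. Longer
   gaps fall back to exact-match extension.

Per-block edits come from a global edit-distance alignment of the block
span (edlib), parsed from the extended CIGAR; tests assert the per-block
edit cost equals an independently written full-DP edit distance. Edits
inside a tandem repeat are reported at the canonical (edit-minimal)
position, which for repeat indels is a register convention, not a physical
location.

### Switch calling and domains

A template switch is a maximal same-contig run of non-ectopic blocks with
total reference length ≥ `min_segment` (default 100 bp — the simulated
segments are ≥ 250 bp, so the margin tolerates boundary noise without
calling alignment artifacts). Departure/return breakpoints are the
flanking ectopic block boundaries (absent at read ends). Read-level
statistics count reads with 0 / 1 / ≥ 2 switches and reads per donor
contig. Breakpoint domains are single-linkage 1-D clusters (bandwidth
100 bp, labelled a, b, c, … in coordinate order; the paper-style domain
picture is visual, so the clustering rule and bandwidth are this package's
choices and are echoed into the output metadata). Comparison mode reports
domains of one condition that overlap no domain of the other within the
bandwidth — new-domain detection.

### Mutation rates, spectra, hotspots

Rates are computed over ectopic-aligned blocks only, with aligned
*reference* bp as denominator; reads with no ectopic-aligned base are
excluded and counted. Both event counts and affected-base counts are
reported: insertions and mismatches are quoted as events, deletion depth as
deleted nucleotides (adjacent deleted bases merge into one called event).
Mismatches are folded to the pyrimidine reference strand into the standard
96 trinucleotide channels; the C>A fraction summarises the signature
associated with oxidative-lesion repair loss (folding is an involution,
asserted in tests). Mismatches at contig edges (no flanking context) are
skipped with a count. The simulator implants substitutions uniformly, so
the synthetic C>A fraction is ≈ 1/6; no signature skew is modelled.

Motifs are maximal poly-dT runs (≥ 20 nt, either strand — an A-run on the
forward strand is a T-run on the reverse) and G-quadruplex consensus
matches G₃₊(N₁₋₇G₃₊)₃ on both strands with overlapping matches merged. The
hotspot statistic per motif is the mutation count within ±50 bp. The null
re-places the observed mutations over the aligned reference positions
`n_perm` times (default 1,000) and p = (1 + #null ≥ obs) / (1 + n_perm),
BH-adjusted across motifs at q ≤ 0.05. In the pipeline the eligible
positions are the coverage-weighted multiset of aligned positions — mutation
opportunity scales with how often a base was sequenced, and a
uniform-over-positions null would systematically flag high-coverage
regions. With only a handful of motifs, an occasional marginal flag at
q ≈ 0.05 in a null condition is the expected 5% false-flag rate.

### Reporter target size

`count_stop_convertible_codons` counts in-frame sense codons at Hamming
distance 1 from TAA/TAG/TGA — the reporter's nonsense-mutation target
size. Of the 64 codons, 18 are stop-convertible; a random stop-free ORF is
therefore ≈ 28% convertible, and the absolute count scales with reporter
length (a TK-only reporter presents roughly half the target of an
eGFP-TK-sized fusion).

## Problem sizes and determinism

Default analysis and test scales: screens of ~8,200 guides × 16 samples;
calibration over 500–1,000 simulated null screens of 5,500 guides;
2,000 iPCR reads of ~4–4.7 kb per condition. All generators and tests take
explicit integer seeds (numpy `default_rng`); identical seeds give
byte-identical outputs, which the pipeline tests assert on re-runs.

## Known limitations

* Decoys are random sequences, not human chromosomes; mapping ambiguity of
  real nonallelic donors (segmental duplications, repeats) is designed away
  by k-mer disjointness.
* The aligner assumes donor segments in the forward orientation;
  inverted-segment switches would need reverse-strand anchoring.
* Indel positions inside microsatellites are reported in a canonical
  register; per-position hotspot claims inside a repeat tract are not
  meaningful at single-base resolution.
* The t/FDR route under the global null is conservative (observed false
  flag rate ≪ 0.001) because an isolated guide cannot reach the BH
  threshold without many co-discoveries; calibration numbers are computed,
  not assumed, by `analysis/05_calibration.py` and the acceptance script.
* Gene-set overlap takes user-supplied lists; no pathway databases are
  bundled or fetched.
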