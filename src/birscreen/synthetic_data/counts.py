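"""Selection-screen count simulation.

Model: each guide g in sample s carries a log2 selection effect

    eff(g, s) = m_g + b_g + e_{g,s},
    b_g ~ Normal(0, effect_sd),  e_{g,s} ~ Normal(0, replicate_sd),

with ``m_g = suppressor_log2fc`` for guides targeting a true suppressor and
``m_g = ntc_log2fc_mean`` (negative: depletion under selection) for every
other guide, NTCs and non-essential controls included.  ``b_g`` is a fixed
guide-level effect (clonal and integration-site effects that reproduce
across replicates); ``e`` is replicate noise.  Post-selection reads
are negative-binomial-style draws (Poisson-gamma mixture, one overdispersion
scalar) centred on ``depth x input_rpm x 2^eff / 1e6``.

Because sequencing is compositional, observed fold enrichment equals
``2^eff`` times a global factor C = 1e6 / sum_g(input_rpm_g * 2^eff_g): when
suppressor guides soak up read share, everything else is pushed below 1.
``expected_fraction_below`` gives the closed-form expectation of the
fraction of a category's enrichments below a threshold, including C, so
simulations can be checked against the generator's own analytics.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from birscreen.synthetic_data.library import GuideLibrary, ScreenDesign

#: Default mean log2 effect of null guides under selection. At effect_sd=1
#: and a composition factor near 1 this places ~96.8% of NTC enrichments
#: below 1.0 (Phi(1.852) = 0.968), the depletion level the screen emulates.
DEFAULT_NTC_LOG2FC = -1.852


def _effect_means(
    library: GuideLibrary,
    true_suppressors: frozenset[str] | set[str],
    suppressor_log2fc: float,
    ntc_log2fc_mean: float,
) -> np.ndarray:
    gene_of = library.gene_of
    return np.array(
        [
            suppressor_log2fc
            if gene_of[r.guide_id] in true_suppressors
            else ntc_log2fc_mean
            for r in library.records
        ]
    )


def simulate_screen_counts(
    library: GuideLibrary,
    design: ScreenDesign | None = None,
    true_suppressors: set[str] | frozenset[str] = frozenset(),
    suppressor_log2fc: float = 5.0,
    ntc_log2fc_mean: float = DEFAULT_NTC_LOG2FC,
    dispersion: float = 0.05,
    depth: int = 10_000_000,
    seed: int = 0,
    effect_sd: float = 1.0,
    replicate_sd: float = 0.25,
):
    """Simulate per-sample guide counts plus the pre-selection baseline.

    Returns a :class:`birscreen.screen_enrichment.ScreenCounts`.  One count
    vector is drawn per (treatment, replicate); the guide-level effect is
    drawn once and shared across samples, replicate noise is redrawn per
    sample.  Deterministic for a fixed seed.
    """
    from birscreen.screen_enrichment import ScreenCounts

    if design is None:
        design = ScreenDesign()
    if not design.treatments:
        raise ValueError("empty design")
    if depth < 10_000:
        raise ValueError("depth must be >= 1e4")
    unknown = set(true_suppressors) - library.genes
    if unknown:
        raise ValueError(f"true_suppressors not in library: {sorted(unknown)[:5]}")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")

    rng = np.random.default_rng(seed)
    guide_ids = [r.guide_id for r in library.records]
    rpm = np.array([library.input_rpm[g] for g in guide_ids])
    means = _effect_means(library, true_suppressors, suppressor_log2fc, ntc_log2fc_mean)

    guide_effect = rng.normal(0.0, effect_sd, size=len(means))
    columns: dict[str, np.ndarray] = {}
    for treatment, rep in design.samples:
        eff = means + guide_effect + rng.normal(0.0, replicate_sd, size=len(means))
        mu = depth * (rpm / 1e6) * np.exp2(eff)
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        else:
            lam = mu
        columns[ScreenDesign.sample_label(treatment, rep)] = rng.poisson(lam)

    counts = pd.DataFrame(columns, index=pd.Index(guide_ids, name="guide_id"))
    baseline = pd.Series(rpm, index=counts.index, name="input_rpm")
    return ScreenCounts(counts=counts, baseline_rpm=baseline, design=design)


def expected_fraction_below(
    library: GuideLibrary,
    true_suppressors: set[str] | frozenset[str] = frozenset(),
    suppressor_log2fc: float = 5.0,
    ntc_log2fc_mean: float = DEFAULT_NTC_LOG2FC,
    effect_sd: float = 1.0,
    replicate_sd: float = 0.25,
    threshold: float = 1.0,
    category: str = "ntc",
) -> float:
    """Closed-form P(observed enrichment < threshold) for one guide category.

    Uses the normal tail of the log2-effect distribution shifted by the
    analytic compositional factor C (count noise is ignored, appropriate at
    high sequencing depth).
    """
    guide_ids = [r.guide_id for r in library.records]
    rpm = np.array([library.input_rpm[g] for g in guide_ids])
    means = _effect_means(library, true_suppressors, suppressor_log2fc, ntc_log2fc_mean)
    ln2 = math.log(2.0)
    sd = math.hypot(effect_sd, replicate_sd)
    # E[2^eff] = exp(m*ln2 + (sd*ln2)^2 / 2) per guide
    e2 = np.exp(means * ln2 + (sd * ln2) ** 2 / 2.0)
    log2_c = math.log2(1e6 / float(np.dot(rpm, e2)))
    if category == "targeting_null":
        m = ntc_log2fc_mean
    elif category == "suppressor":
        m = suppressor_log2fc
    else:
        m = ntc_log2fc_mean  # ntc / nonessential share the null effect
    return float(norm.cdf((math.log2(threshold) - log2_c - m) / sd))
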