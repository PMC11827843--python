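# Methods

## Scoring model

For one contrast (ordered control and treated samples) each column is
normalised to a fixed sequencing depth with a pseudocount,

    c'_i = pseudocount + c_i · scale / Σ c,

with defaults `pseudocount = 5` (stabilises low counts) and
`scale = 1e7`. For every control/treated pair (paired contrasts match the
k-th columns; unpaired contrasts use every control × treated pair — the
screens this package targets have one column per arm, so the two coincide)
the guide statistic is the log2 fold change `fc = log2(c'_t / c'_c)`.

Fold-change variance in a pooled screen depends mainly on abundance, so
the null spread is estimated empirically: guides are ranked by normalised
control count (descending, ties broken by guide id so results are
permutation-invariant) and the standard deviation for the guide at rank
`r` is the sample sd (denominator n−1) of `fc` over ranks
`[r−w, r+w]`, clamped at the table boundaries and floored at
`min_std = 1e-6` (an all-equal window would otherwise produce a zero
divisor). The half-window default is `w = min(500, max(50, ⌊n/4⌋))`:
a fixed 500 would span a quarter of a 2,000-guide custom library and
destroy the locality the estimator exists for, so the window adapts to
library size while keeping at least ~100 guides of context. Guide
z-scores are `z = fc / sd`.

Per scored unit (gene, or NTC pseudogene), `sumZ = Σ z` over its
guide-pair observations, `rawZ = sumZ / √numObs`, and normZ is rawZ
re-standardised across units (mean 0, population sd 1). If the raw scores
are constant across units (e.g. treated ≡ control) the contrast carries no
ordering information and all normZ are set to 0 with p = 0.5. One-tailed
p-values are `p_left = Φ(normZ)` (depletion/sensitizer) and
`p_right = Φ(−normZ)` (enrichment/suppressor), computed with scipy's
normal CDF/SF and clipped into the open interval (0, 1); the analytic
identity `p_left + p_right = 1` therefore holds to float precision rather
than bitwise for |normZ| ≳ 8. Benjamini–Hochberg correction (statsmodels)
is applied within each tail separately — depletion and enrichment calls
are distinct hypothesis families.

## NTC-pseudogene resampling

Non-targeting controls anchor the null but have no gene structure. They
are randomly partitioned into pseudogenes of `group_size = 4` guides
(shuffle, consecutive blocks; a remainder that cannot fill a block is
dropped from that repetition with a warning), scored like genes, and the
whole run is repeated `n_rep = 100` times. Real genes' counts never
change across repetitions — per-rep variation enters only through the
aggregated NTCs' influence on the empirical-Bayes windows and the final
re-standardisation — so a gene's averaged normZ is a stable, slightly
de-noised version of its single-run score. p-values are taken from the
standard normal applied to the averaged normZ; because the averaged
statistic has variance slightly below 1, this is mildly conservative and
is documented rather than corrected. BH runs over real genes only: NTC
pseudogene membership changes each repetition, so cross-rep averaging is
undefined for them and they are reported per repetition as diagnostics
(mean, sd, 5th/95th percentiles, fraction beyond |1.645|).

Child seeds are derived from the master seed with a counter-based
`SeedSequence(entropy=seed, spawn_key=(rep,))` rule, so repetitions are
independent, order-insensitive, and any single repetition can be rebuilt
in isolation (`build_rep_table`); for fixed (seed, n_rep) the output is
bit-reproducible.

## Essential-control exclusion

Essential genes are excluded from drug-vs-vehicle contrasts before
scoring: their near-complete dropout would otherwise dominate the
fold-change variance windows and the re-standardisation. Exclusion is a
per-contrast switch, and the pipeline's default keeps essentials **in**
the vehicle-vs-T0 fitness contrast. This is a deliberate design choice:
with essentials present, the re-standardisation scale is set by their
strong depletion, so genes without a fitness effect sit well inside the
[−1, +1] fitness window (as in published fitness-axis scatters); with
essentials excluded the fitness scores of an effect-free library are
forced to sd 1 and ~32% of genes would leave the window by construction,
which would make the window a lottery rather than a tolerability gate.

## Hit nomination

Nominated ⇔ fitness normZ ∈ [−1, +1] (closed interval, plain reading of
"between") in every cell line with data, and drug normZ < −1 (strict) in
at least `min_cell_lines = 1` cell line. The FDR < 0.1 clause is an
annotation flag by default and a hard gate in `require_fdr` mode, because
the original selection combined it "and/or" with a visual per-guide
consistency check that cannot be formalised; that check is quantified
here as `guide_concordance` — the fraction of a gene's guides whose
normalised treated count falls below their normalised control count.
Genes with drug data but no fitness score in that cell line are listed as
unevaluable and never nominated. Known-sensitizer annotation matches gene
symbols case-insensitively.

## Synthetic screens

The generator reproduces what the downstream statistics actually see —
counts — rather than the wet-lab mechanics. Per guide: efficiency
`u ~ Beta(α, β)` (defaults α = 5, β = 1: most guides cut well), baseline
abundance `b ~ LogNormal(0, σ)` with σ = 0.5 (plasmid-pool skew; together
these absorb MOI, infection and selection, which are not modelled
mechanistically). Initial proportions `p ∝ b` give T0. A grown arm with
`D` doublings multiplies each guide by `2^{D·u·(f + s·[drug arm])}` and
renormalises (compositional closure: essential dropout inflates the rest
of the library, a real artifact the scorer must tolerate). Each count is
gamma-Poisson with mean `depth · proportion` and dispersion θ — drawn per
guide, not multinomially, so column totals are random around the depth,
as in sequencing.

Defaults mirror the emulated design: 15 doublings per grown arm (the
design's 15–18 range, exposed per arm), depth 300× per guide (600,000
reads for the 2,000-guide library), θ = 100, essential fitness −0.5
log2/doubling, sensitizer effect −0.5 log2/doubling under drug. With
u averaging ~0.83, an essential or sensitizer guide is expected to drop
~6 log2 units over the screen — a strong, unambiguous signal. What the
generator does **not** emulate: guide off-target effects, clonal Cas9
activity variation, PCR jackpotting beyond gamma-Poisson overdispersion,
replicate sequencing of the same arm, and correlated guide behaviour
within genes. Tests passing on these simulations therefore demonstrate
the statistics are implemented and calibrated correctly, not that real
screens will show effects this clean.

## Problem sizes

Unit tests run on a 60-guide toy library; calibration, recovery and
reproducibility checks run at the full design scale (2,000 guides, 4
arms, 100 resampling repetitions), which completes in a few seconds — the
engine is vectorised (a centered rolling window for the empirical-Bayes
sd, grouped aggregation for gene scores). The variance-shrinkage check
uses 20 master seeds at n_rep = 10 vs 1.

## Known limitations

- Exact numerical parity with external scoring tools is out of scope; the
  contract is internal consistency plus an independent straight-line
  oracle (tested to 1e-9 per field).
- The HSA score is the plain mean excess in percentage points with ±10
  classification bands; no baseline correction or response-surface
  smoothing, so scores from web tools that apply either will differ.
- Replicate-aware variance moderation beyond the rank-window scheme is
  not implemented (single column per arm is the target design).
- p-values from averaged normZ are conservative (see above); FDRs are
  correspondingly conservative.
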