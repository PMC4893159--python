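# Methods

## The statistical model

Each proteomic screen is treated as an independent noisy sensor of the same
underlying set of UV-damage-response factors. Within one screen the
log2(UV/control) ratio of a non-responding protein is modelled as symmetric
noise around the screen median; a responding protein carries an additive
positive shift. No distributional assumption is imposed at analysis time:
standardization uses the median and the median absolute deviation
(`z = (x − median) / (1.4826·MAD)`), which is consistent with a Normal
sigma but insensitive to the heavy tails and outlier hits that SILAC ratio
distributions always carry. When the MAD degenerates to 0 the sample SD is
used; if that is also 0 all Z-scores are 0 and a warning is logged.

Hits are directional. Each screen has a response-tail policy ("+" for
recruitment/increase, "−" for loss, "both"); the default for every screen is
the "+" tail (recruitment to CSB/RNAPII, chromatin gain, increased
ubiquitylation/phosphorylation, RNAi low-transcription — the RNAi statistic
is oriented so its response is positive). The threshold (default |z| ≥ 2)
is inclusive and configurable; no single threshold is claimed to be optimal,
which is exactly why the aggregate and weighted schemes below do not depend
on it alone.

±MG132 conditions of the same screen are merged before integration: a
protein is a screen-level hit if it passes in either condition, and the
condition entry with maximum |z| carries the screen Z. This keeps the
integration at exactly six screens, and retains MG132-dependent events
(e.g. degradation-coupled losses) without doubling the screen count.

PTM site tables are Z-scored across all sites of one modification and
rolled up to protein level by the maximum-|z| site (ties break to the
smaller residue position, making output deterministic). The rollup
preserves the protein count: one record per protein with ≥ 1 site.

## RNAi low/high-transcriber statistics

The post-UV EU-intensity distribution is bimodal: a lowly transcribing
subpopulation appears next to the main population. The screen statistic
formalizes the visual call:

1. **Boundary** — per plate, the 25th percentile (linear interpolation) of
   the pooled per-cell intensities of UV-treated negative-control wells
   (non-targeting and RISC-free siRNAs). The quantile is configurable.
2. **Well statistic** — `fraction_low` = share of the well's cells below
   the boundary, plus the well median. Wells with < 50 cells are excluded,
   not scored (a lethality/toxicity guard).
3. **Plate normalization** — robust Z of `fraction_low` (and of the
   median) against the same plate's scored negative controls, MAD with SD
   fallback; plates whose controls are fully degenerate are rejected.
4. **Calls** — `low` if `z_low ≥ 2`; otherwise `high` if `z_median ≥ 2`;
   low takes precedence when both trigger, because the low-transcriber
   phenotype is the screen's primary axis and its positive controls are
   low. Gene-level calls take the median z over a gene's wells, and with
   replicates require at least two concordant wells.

Only per-plate normalization is performed; no B-score row/column polish.
Plate-geometry artefacts are therefore out of scope (a documented
limitation of the statistic, acceptable because the generator plants no
such artefacts and real runs should inspect control heat-maps separately).

The boundary construction pins the negative-control `fraction_low` mean at
the chosen quantile (0.25), so `z_low` is centred at 0 on every plate by
construction, and all statistics are invariant under rescaling a plate's
intensities by any positive constant.

## Integration

Per-screen Z-scores are not commensurable across technologies (an MS
interactome Z and an RNAi plate Z live on very different scales), so each
screen's evidence is reduced to a fractional rank in the response
direction: best = 1.0, worst = 1/n, ties share the mean rank, proteins not
quantified in the screen score 0 (absence of evidence, never imputed).

- **Count score**: number of screens passed; integer 0–6.
- **Aggregate score**: unweighted sum of the normalized scores (0–6).
- **Weighted score**: Σ wᵢ·sᵢ ∈ [0, 1]. The weight of screen *i* is the
  −log10 one-sided hypergeometric upper-tail p-value of the overlap
  between the screen's hit set and the gold training category within the
  screen's own quantified universe, capped at 300 and normalized to sum 1.
  If no screen shows any gold enrichment the weights fall back to uniform
  with a warning. A leave-one-out variant was considered and rejected as a
  default: with gold categories of realistic size (tens of members) the
  direct computation is stable, and the benchmark median is reported on
  the same direct weights.

With uniform weights the weighted ranking equals the aggregate ranking
exactly (the weighted score is aggregate/6); this identity is tested.

Ranking is descending by score, ties share the minimum rank, and the listing
order among ties is count score (descending) then protein id, so output is
fully deterministic under input permutation.

The **benchmark median** is the median score of the training-category
members under a scheme (missing members enter as 0). Because the gold
standard is also what drives the weights, the weighted-vs-unweighted gold
median comparison is a self-benchmark: it demonstrates that the weighting
extracts real heterogeneity between screens, which is why the test suite
also includes a negative control (a random gold set must show no
systematic gain).

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k), computed from the log survival function for numerical stability
(tails below ~1e−308 are clamped to the smallest positive double so
p ∈ (0, 1] always holds), with Benjamini–Hochberg adjustment across the
tested categories. Categories are tested when their size within the
universe is in [3, 2000] (configurable). The universe defaults to every
protein quantified in ≥ 1 screen; since the universe materially changes
p-values, it is recorded (as N) in every output row. Overlapping categories
mean Σk across categories may exceed the number of hits; no conservation is
implied.

The category × screen coverage matrix counts, per category, the members
hitting each screen and the distinct members hitting any screen. The
kinase-neighborhood summary reports, for each queried kinase, the fraction
of its network interactors carrying ≥ 1 UV-increased phosphosite, with
per-interactor cross-screen flags; a kinase with no interactors yields
fraction 0 with an explicit `undefined` flag.

## Synthetic data: what it emulates and what it does not

Defaults (the study conditions): 5,000 proteins, 100 true factors,
per-screen sensitivities csb 0.7 / rnapii 0.6 / chromatin 0.4 /
ubiquitylome 0.5 / phosphoproteome 0.5 / rnai 0.35, effect size 2.0 (log2
units), background noise SD 0.5, gold fraction 0.3. Sensitivities are
deliberately heterogeneous so the weighting scheme has signal to exploit.
Background MS coverage is 0.9 (PTM 0.6) per screen; a screen's responders
are always quantified in that screen, on the reasoning that a genuinely
responding protein is detectable in the screen it responds in.

PTM tables carry 1–5 sites per covered protein; a responding protein has
one shifted site. Phospho residue composition is S:T:Y = 86:13:1 and 15%
of phospho windows carry the S/T-Q consensus (windows are length 7,
random elsewhere). Ubiquitin sites sit on K.

RNAi wells draw 300 cells from a two-component log-normal mixture
(log-means 5 and 7, log-SD 0.5); the low-component weight is 0.15 for
controls and background genes and 0.6 for planted knockdowns. Plates hold
320 test wells, 16 non-targeting + 16 RISC-free negative controls (32 per
plate, enough for stable per-plate median/MAD estimation) and 8 positive
controls.

All randomness flows from one integer seed through a fixed
`SeedSequence.spawn` order (truth, RNAi, categories, one stream per
screen), so the bundle is byte-identical across runs and each table is
reproducible in isolation.

The generator does **not** emulate: correlated noise between screens,
plate-position effects, MS missingness that depends on abundance,
peptide-level quantification, off-target RNAi effects, or cell images.
Passing tests therefore demonstrate the pipeline's statistical correctness
under the declared model, not robustness to these real-data pathologies.

## Null expectations used in calibration tests

With no planted factors, the expected hit rate at z ≥ 2 is the Normal
upper tail q = Φ̄(2) transformed by each screen's procedure: 1−(1−q)² for
merged two-condition screens, E[1−(1−q)^k] over the site-count distribution
for PTM screens (max-|z| rollup), and, for the RNAi screen, a Monte Carlo
expectation over the plate structure, because standardizing against 32
finite negative controls inflates and correlates the per-plate tail mass.
These are Normal-theory consequences of the declared procedures, computed
from structure — not fitted numbers.

## Problem sizes

The default bundle (5,000 proteins, ~1.9M simulated cells) generates in
≈0.3 s and runs through the full pipeline in ≈2 s. The test suite runs the
acceptance-level checks at this default size and exercises
replicate-heavy properties (e.g. the 50-replicate weighted-vs-unweighted
directional check) on a reduced bundle of 600 proteins with 100 cells per
well, which preserves the statistical structure while keeping the suite
fast.

## Known limitations

- Identifier harmonization is trim/upper-case plus a user-supplied alias
  table; no ortholog or accession-level mapping.
- The weighting formula (−log10 hypergeometric enrichment) is one
  reasonable operationalization of "information value"; recall-based
  weights are a plausible alternative and the weights object is pluggable.
- The enrichment universe choice dominates p-values; only the
  quantified-in-≥1-screen default is tested.
- BH adjustment is not idempotent (re-applying the step-up to already
  adjusted values can only raise them); tests assert the true dominance
  and monotonicity properties.
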