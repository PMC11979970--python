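# Methods

`foramdiv` analyses a genus-level range chart of benthic foraminifera —
one row per genus with its wall type (calcareous, agglutinated, organic) and
its first and last geological intervals — and asks how the diversity and
turnover of each wall type behaved across the Phanerozoic. This note records
the models, conventions, parameter choices and known limitations.

## Temporal framework

All counting happens on an embedded epoch-level timescale (ICS
chronostratigraphic chart, 2013 version) spanning 541–0 Ma in 38 contiguous
bins: the four Cambrian series, three Ordovician and four Silurian epochs,
three Devonian epochs, six Carboniferous epochs (Lower/Middle/Upper
Mississippian and Pennsylvanian), three Permian epochs, and so on through
Pleistocene and Holocene. The Permian–Triassic boundary is stored at
251.902 Ma (the refined age for that boundary; the rest of the table keeps
the 2013 chart values), which places the Palaeozoic/Mesozoic era split at
251.9 Ma and the Mesozoic/Cenozoic split at 66.0 Ma. Ages are decimal Myr
(the Holocene base, 0.0117 Ma, needs four decimals). Interval lookup is
case-insensitive, treats Lower/Early and Upper/Late as synonyms, and maps
every ICS stage name to its containing epoch through an embedded alias table;
unrecognized names raise rather than being skipped, because silent row loss
is the classic range-chart bug.

Bin-boundary convention: an age exactly on a boundary opens the younger bin
for originations and closes the older bin for extinctions. This matters only
for the simulator's instantaneous kill pulses, which act exactly at
boundaries: their victims are recorded as extinctions in the bin they
terminate, the way a mass extinction at an era boundary appears in range
data.

## Wall-type simplification

Source wall descriptions are free text and inconsistently fine-grained, so
they are collapsed to three analysis categories: anything the test
precipitates itself (calcareous, porcelaneous, aragonite, and combinations)
is *calcareous*; anything built from aggregated sediment — even when the
grains are carbonate ("calcareous and agglutinated") — is *agglutinated*;
*organic* stands alone. Three special rules cover the genera whose walls the
compilation leaves unknown: fusulinid taxa (detected by a fusulin- stem in
any higher-taxon field, or an explicit genus allow-list) count as calcareous,
following the consensus that their microgranular calcite was precipitated;
*Saudia* and *Sornayina* are agglutinated, following their WoRMS
classification; and *Milammellus*, the lone opaline genus, is excluded from
analysis entirely. Any description outside this vocabulary raises a
classification error: extending the mapping is an explicit, reviewable act.
Every read and filter is count-conserving — input rows equal retained records
plus logged exclusions.

## Occurrence counting and proportional diversity

A genus occupies every bin its [fad, lad] index range touches and is exactly
one of four things there: singleton (fad = lad = bin), originator
(fad = bin < lad), extinct-in-bin (fad < bin = lad) or boundary crosser
(fad < bin < lad). Diversity per epoch is the count of occupying genera,
split by wall type; proportional diversity (wall-type count / epoch total) is
the quantity used for cross-era comparison, because raw counts confound
diversity with preservation and sampling intensity, which differ enormously
between the Cambrian and the Neogene. Epochs with zero total are flagged
undefined rather than producing 0/0. Percent changes are formatted by
rounding halves away from zero (so 17 → 62 genera prints as +265%).

Removing singletons from a bin (used on the Holocene) is the standard
sensitivity check for the pull of the recent: single-bin genera inflate raw
diversity but never cross a boundary, so the per-capita rates are blind to
them by construction.

## Per-capita rates

For each bin of duration Δt, with N_bt the genera crossing both boundaries,
N_t those crossing the top (younger) boundary and N_b those crossing the
bottom (older) boundary, the per-capita rates are

    p̂ = −ln(N_bt / N_t) / Δt        q̂ = −ln(N_bt / N_b) / Δt

per lineage-Myr. The denominators follow the estimator definitions: the
top-boundary cohort for origination, the bottom-boundary cohort for
extinction. (Prose descriptions sometimes label N_t the "start" and N_b the
"end" of an interval; the equations, not the labels, are authoritative here.)
When N_bt = 0 the estimator is undefined and the bin is flagged invalid —
never zero, never infinite — and invalid bins are excluded from envelopes and
trend fits.

Extant genera are treated as crossing the top of the terminal (Holocene) bin:
they have not gone extinct, so counting them as terminal extinctions would
manufacture a Holocene extinction pulse. The adjustment is configurable
(`extant_top_crossing=False` restores the censored reading), and the terminal
bin is flagged edge-affected for q̂ regardless, as is the first bin for p̂
(nothing can cross into the oldest bin). One knock-on convention: an extant
genus confined to the Holocene counts as a top-crossing originator, not a
singleton, in the rate counts — though it is still a singleton for the
diversity-side removal above.

## Bootstrap null envelopes

The null hypothesis for a wall type's rates is "a random group of the same
size drawn from the whole benthic dataset". Each of `n_reps` replicates
(default 1000) draws `group_size` genera — without replacement by default;
with-replacement resampling is selectable — recomputes crossing counts and
rates, and the envelope stores the central 95% (configurable) empirical
quantiles per epoch, type-7 interpolation, with invalid replicate rates
dropped from the pool and the pool size recorded. A single named generator is
seeded once per envelope, so envelopes are bit-reproducible. Observed rates
are flagged below/within/above per epoch against the closed interval.

Two structural checks pin the implementation down: drawing the full dataset
without replacement collapses the envelope exactly onto the observed rates,
and under a truly exchangeable synthetic dataset the observed wall-type rates
fall inside the 95% envelope in about 95% of epochs (measured at 94.9% over
200 simulations with 500 replicates each — 500 is used inside that
simulation study purely because its quantile error is already negligible;
the analysis default remains 1000).

## Trend fits

Each wall type's origination and extinction series is regressed on epoch
midpoint age with a GLM using a square-root link and Gamma variance:
sqrt(μ) = β0 + β1·age, Var ∝ μ². The sqrt link keeps fitted means positive
while allowing a linear trend on a variance-stabilizing scale for rate-like
data; the Gamma variance matches the multiplicative error of per-capita
rates. Fitting is IRLS (via statsmodels, with the link whitelist relaxed —
sqrt is non-canonical but perfectly defined for positive responses);
dispersion is the Pearson estimate and slope inference is a Wald test on it
(quasi-Gamma). Non-positive and invalid rates are excluded (a Gamma response
must be positive) and counted on the fit. The series is split into Palaeozoic
and Mesozoic+Cenozoic at the 251.9 Ma era boundary so the two fits have
comparable point counts; the boundary epoch belongs to its own era.
Prediction bands are ±1 SE delta-method propagated from the link scale
(se(μ) = 2|η|·se(η)); significance is annotated at α = 0.05. Age increases
into the past, so a negative slope means rates declining toward the present.

Calibration, measured by simulation at the Phanerozoic design (38 epoch
midpoints, Gamma noise with shape 50 — the shape used for both the flat-rate
and sloped scenarios): a flat rate of 0.05/Myr yields slope p > 0.05 in 97%
of 200 runs, and a planted link-scale slope of −0.0005 is recovered within
±2 SE in 95.5% of 200 runs. Coefficients agree with an independently coded
IRLS to better than six significant figures.

## Synthetic data

The generator is a continuous-time budding birth–death process at genus
level: founders appear at `t_start`, each living genus spawns new genera of
its own wall type at rate p and dies at rate q (exponential waiting times; no
tree is retained because the analysis is taxic, not phylogenetic). Pulses
kill each living genus of a wall type with a stated probability at an
instant. Survivors at `t_end` are extant, get the terminal bin as their last
interval, and exact origination/extinction times are returned alongside the
discretized ranges. Population growth is capped (default 200 000 genera) to
fail fast on super-critical configurations.

The reference configuration (the default, used by the `analysis/` drivers)
emulates the gross structure of the compiled benthic dataset: 150 founders
over 541–0 Ma; calcareous genera with the fastest turnover and slight net
diversification (p = 0.027, q = 0.022 per lineage-Myr), agglutinated slower
(0.019/0.017), organic marginal (0.010/0.0095); an end-Permian pulse killing
85% of calcareous vs 30% of other genera, and an end-Cretaceous pulse leaning
on agglutinated genera (45% vs 30–35%). Across seeds this yields roughly
2000–3500 genera, calcareous dominance from the later Palaeozoic, a
calcareous proportional crash at the end-Permian and recovery through the
Cenozoic. The per-lineage rates sit in the 0.01–0.03/Myr range typical of
genus-level marine invertebrate estimates.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: no preservation or sampling model (every simulated
genus is observed), no de-novo evolution of a wall type (wall identity is
inherited from founders, so the Silurian first appearance of calcareous walls
has no analogue), no taxonomic error, and only a mild pull of the recent
(real compilations inflate the terminal bin mainly through better sampling of
the living fauna, not through true within-Holocene originations). Estimator
and model checks on synthetic data validate the arithmetic and statistical
machinery, not the completeness of any fossil compilation.

## Simulation study sizes

The self-checks in `foramdiv.evaluation` use: estimator recovery — 100
simulations of 500 founders over 100 Myr in 10-Myr bins at p = q = 0.05/Myr
(measured relative error of the pooled means: < 1%); envelope coverage — 200
simulations of 200 founders over 120 Myr, 500 bootstrap replicates each;
pulse detection — one 300-founder dataset with a 90% calcareous kill; GLM
size/power — 200 fits per scenario. These sizes give Monte-Carlo error
comfortably inside the tolerances being checked while keeping the full suite
in the tens of seconds.

## Numerical conventions and degenerate inputs

Rates are per Myr with durations taken from the timescale; undefined
estimators are NaN plus an explicit validity flag, never silently dropped;
empirical quantiles are type 7; percent formatting rounds halves away from
zero; CSV outputs use `%.10g` floats and a comment header carrying package
and timescale versions, so identical configurations reproduce byte-identical
files. Empty groups yield all-invalid rate series (not errors); an empty
benthic filter result warns; fewer than three usable points make a trend fit
raise `InsufficientDataError` rather than returning a meaningless line.

## Known limitations

Epoch bins are coarse: a rate spike attributed to a bin cannot be placed
within it, and extinctions recorded in a boundary bin may pre-date the
boundary event itself. Genus-level taxic counting ignores abundance and
species richness. The first and last bins are edge-affected for p̂ and q̂
respectively. The null envelope conditions on the observed dataset, so it
tests exchangeability of wall-type labels, not absolute rate levels. And the
GLM deliberately fits one specification — no model selection, alternative
links or autocorrelation handling — because its role is a single summary
trend per era, not a best predictive model.
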