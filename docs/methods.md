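# Methods

## Overview

`pandaniche` couples a micro model of household resource-utilization
decisions with a macro, village-level ecological-niche evaluation of giant
panda habitat condition, and asks how the age structure of the dominant
household labor force (old-age group, OAG, primary laborer ≥ 55 years, vs
young-adult group, YAG) shifts both. Because the underlying questionnaire
data are not public, the pipeline is driven by a synthetic survey
generator whose marginals are calibrated to the published summary
statistics of that survey; the scientific claims the test suite checks are
therefore *structural* (conservation laws, oracle equivalence,
direction-of-effect recovery), not numerical reproductions of any
field-data value.

## Synthetic survey generator

The generator emulates a stratified household survey: `n_households`
(default 538) spread as evenly as possible over `n_communities` (default
35) grouped into `n_reserves` (default 9) — the community count is not a
multiple of the household count, so community sizes are 15 or 16; an
explicit `households_per_community` enforces the exact product instead.

Variable marginals (`ScenarioConfig.variable_specs`):

* **Bounded continuous** variables are truncated normals with
  *post-truncation* moment matching: the underlying (μ, σ) are found by
  nested root-finding (σ bracketed in log space; for each σ, μ solved so
  the truncated mean is exact). The truncated mean is monotone in μ and
  the truncated sd monotone in σ, so both brackets are safe; in the
  large-σ limit the truncated density becomes log-linear with slope μ/σ²,
  which dictates a μ bracket widening like σ².
* **Infeasible printed sds.** Several published sds exceed what any
  distribution (or any truncated normal) on the stated support can attain
  — e.g. sd 1.507 for a fraction in [0, 1], or sd 0.887 for a 3-level
  ordinal with mean 1.271. The calibration then matches the mean exactly,
  clips the sd to the feasible supremum (the log-linear limit for
  truncated normals; the two-point extreme for ordinals) and emits a
  warning. The mean is the reproducible quantity; the sd is reported
  honestly as clipped.
* **3-level ordinals** use the closed form: with the mean fixed,
  Var = (4·mean − 3 − mean²) − p₂, so the middle-category probability is
  solved directly and clipped to its feasible interval.
* **5-level perception scales** (regulation-intensity perceptions, no
  published moments) use fixed categorical probabilities with means ≈ 3.8
  — most households perceive regulation as strengthening, matching the
  policy environment the survey describes (quota cutting limits,
  ecological public-welfare forest expansion).
* **Quantities and revenues** (cropland area in mu, fuelwood in kg/yr,
  revenues in CNY/yr) are not tabulated in the published summary; defaults
  are realistic magnitudes for smallholder mountain agriculture (cropland
  ≈ 5 mu, fuelwood ≈ 1.5 t/yr). Only their *relative* sizes matter
  downstream (value shares and max-normalized scales).

Two injected structures: non-agricultural households (livelihood type 3,
~20 % of the sample by the calibrated ordinal) have zero quantities and
revenues — valid non-utilizing observations, not errors; and OAG
households have quantities (and hence proportional revenues) multiplied by
`1 − aging_effect` (default 0.3), the labor-capacity reduction whose
downstream recovery the acceptance tests check.

Randomness: one root seed; each variable and table draws from an
independent substream keyed by CRC-32 of its name, so adding or removing a
variable never perturbs the others and all outputs are byte-reproducible.

What the generator does **not** emulate: within-household correlation
between attributes (age is independent of education, health, perceptions),
spatial autocorrelation between neighboring communities, and any
behavioral feedback from regulation onto quantities. Passing tests
therefore demonstrate that the *pipeline* recovers an injected effect of
known size under clean conditions — not that the effect is identifiable in
real survey data with confounding.

## Household decision model

Per household j, with two utilization patterns k ∈ {cropland, fuelwood}:

1. **Belief update.** `Belief_{t+1} = s·P_t + (1−s)·Belief_t` with
   smoothing s = 0.5, prior belief 0.5 and P_t the mean of the two
   regulation perceptions rescaled from [1, 5] to [0, 1]. The pipeline is
   cross-sectional, so exactly one update step is taken: the *state*
   decision uses the prior belief, the *next* decision the updated one,
   and their difference is the decision potential.
2. **Importance.** `D_jk = UA_jk·I_jk / Σ_k UA_jk·I_jk` — the value share
   of pattern k. Shares sum to 1 whenever any value is positive; a zero
   total is flagged, not raised.
3. **Factor scores** in [0, 1]: ecological value identity = the belief;
   social pressure = mean rescaled regulation perceptions; environmental
   constraints = mean of inverted soil quality, fragmentation, slope,
   restriction flag and distance/16 km; labor literacy = mean rescaled
   education and health.
4. **Final decision.** The literal weighted sum Σ w_x·D with Σ w_x = 1
   returns D unchanged, which carries no information; the factors are
   therefore read as multiplicative modulations of the importance:
   `final_k = (Σ_x w_x·m_x)·D_k`, with m_x = 1 − score for the suppressing
   factors (identity, pressure, constraints) and m_x = score for labor
   literacy, and w_x = a_x/Σa_x from the configurable salience a (default
   equal). With all m_x = 1 this reduces to the literal form, and
   weakening any factor weakly lowers every final intensity. Signs and
   saliences are configurable (`DecisionConfig.modulation_signs`,
   `salience`); the saliences are not estimated from data.
5. **Micro → macro.** The community × age-group utilization decision x1
   (cropland) / x2 (fuelwood) is the unweighted mean over the group's
   households of `final_k · UA_k / max(UA_k)`. The max-normalized quantity
   factor is the deliberate design choice here: the importance D_k is a
   *within-household share*, invariant to a uniform reduction of
   quantities, so a pure share aggregation could not express the central
   mechanism — aging lowering the physical intensity of use. Scaling by
   the household's relative quantity preserves [0, 1] bounds, keeps the
   mean interpretation, and lets the OAG quantity reduction propagate to
   x1/x2. (`scale_by_quantity=False` restores the share-only reading; a
   value-weighted mean is available via `weighted_aggregation`.)

Communities without members of a group yield missing values and are
excluded from that group's evaluation with a warning.

## Niche evaluation

**Index system.** 14 indexes in 4 dimensions — X1 utilization strength
(x1, x2), X2 support (x3 available/total cultivated land, x4 available
fuelwood/total forestland, x5 practitioners/population), X3 constraints
(x6–x7 community mean regulation perceptions on [1, 5], x8–x10 five-year
change rates), X4 panda sustainable-habitat level (x11 habitat-area change
rate between the 3rd and 4th national surveys, x12 population change rate,
x13 bamboo/reserve area, x14 bamboo area per panda) — broadcast from
reserves to member communities. Evaluation units are community ×
age-group rows; only x1/x2 differ between the two group rows of a
community, so group contrasts are X1-driven by construction.

**State and potential.** State = the 2013-baseline value; potential = the
2013→2018 increment, annualized by `period_years` (5) and combined as
`R = S + A·(P/period_years)` with conversion coefficient A = 1 per index
(both configurable). Indexes observed only once (perceptions, the panda
survey ratios, which are themselves inter-survey change rates) have zero
potential.

**Weights.** Coefficient-of-variation weights on the raw adjusted columns:
`V_j = δ_j/|x̄_j|`, `W_j = V_j/ΣV`, dimension weight w_d = Σ of member
W_j. CV weights cannot be computed on z-scored columns (mean 0), so they
use the raw adjusted values; a near-zero column mean raises an error
rather than producing a silently huge weight. Dimension weights are
nowhere separately defined, so they inherit the member sums (already
normalized over all 14 indexes).

**Standardization.** Classical z-scores are computed and reported, but the
niche algebra requires strictly positive values in (0, 1]: each adjusted
column is min–max rescaled to [ε, 1] with ε = 10⁻⁶ (a monotone transform,
so orderings are preserved; `standardization: zscore_shifted` selects
min-shifted z-scores instead). A constant column is an error at the
operation level; the pipeline neutralizes it to all-ones with a warning,
which is harmless because its CV weight is zero (this arises only in
degenerate scenarios, e.g. a single community).

**Orientation.** x1 and x2 are cost-type for habitat (more utilization =
lower habitat level) and are inverted in the *habitat-oriented* scaling
used for widths; all other indexes are benefit-type. Overlap, by
contrast, measures competition over *resource utilization*, where more
use means more competition, so overlap profiles use the non-inverted
scaling. This orientation split is the package's resolution of an
ambiguity the evaluation leaves open, and it is what makes both headline
directions emerge from the same mechanism: lower OAG utilization → higher
inverted X1 values → higher OAG widths; and smaller OAG x1/x2 components
→ a weaker common component in the profile cosine → lower OAG overlaps.

**Widths.** Per index, each unit's share of the column total across *all*
units (both groups pooled — per-group normalization would cancel exactly
the level difference the comparison measures); per dimension,
`N_d = Σ_{k∈d} (W_k/w_d)·share_k`; comprehensive `M = Σ_d w_d·N_d`.
Conservation holds by construction: N_d and M each sum to 1 over units.

**Overlaps.** Pianka (cosine) overlap of row-normalized 14-index profiles,
`O_jk = Σ p_ij p_ik / √(Σp_ij²·Σp_ik²)` — the square root in the
denominator is required for the stated [0, 1] range and symmetry. Pairs
default to the community adjacency list (a ring within each reserve);
`--all-pairs` computes the full matrix. The OAG/YAG ratio per pair is
classified positive in (0, 1), negative above 1, undefined at exactly 1
or when the YAG overlap is 0 or missing.

## Numerical choices and degenerate inputs

* Root-finding tolerances: 10⁻¹³ on μ (mean match ≪ 10⁻⁶), 10⁻¹² on
  log σ; σ capped at 10× the support span, where the sd has converged to
  its supremum to ~10⁻⁴.
* Zero denominators in index construction (total land, population, survey
  baselines) raise a `DataError` naming the index and offending units.
* A household with zero utilization value propagates zeros (flagged);
  all-zero salience raises; smoothing and belief bounds are validated.
* Widths require strictly positive adjusted values; min–max ε = 10⁻⁶
  keeps the smallest unit's share positive without distorting shares.
* The run manifest records the config hash, seed, per-file SHA-256
  checksums and collected warnings; the timestamp is the only
  non-reproducible field, so reproducibility checks compare the table
  files and checksum map, not the manifest file itself.

## Problem sizes

Default runs use the survey-scale scenario (538 households, 35
communities, 9 reserves) and complete in a few seconds; moment-recovery
checks use 5,000 households, and the direction-of-effect check aggregates
10 independent seeds at the default scale. These sizes give standard
errors small enough to resolve the calibrated means (SE ≈ printed
sd/√5000) and the injected 30 % intensity effect.

## Known limitations

* The four factor modulations and their saliences are interpretive
  defaults, not estimates; only the qualitative monotonicity (weakening
  suppresses utilization) is load-bearing and tested.
* The belief/aspiration structure is collapsed to a single smoothing
  update; no multi-period dynamics.
* Overlap magnitudes are dominated by the shared community-level indexes
  (x3–x14), so group contrasts in overlap are small (ratios near 1);
  only their direction, not their size, is meaningful at the default
  effect size.
* No spatial processes: adjacency is topological (ring within reserve),
  centroids are decorative, and no interpolation or map products are
  produced.
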