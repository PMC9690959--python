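# pandaniche

Household resource-use decisions and ecological-niche evaluation of giant
panda habitat under labor-force aging.

Villages around the Sichuan giant panda nature reserves disturb panda
habitat mainly through two household activities: cultivated-land use and
fuelwood cutting. As the rural labor force ages (out-migration leaves
laborers ≥ 55 dominating many households), the intensity of both
activities falls. `pandaniche` implements, as a tested and reproducible
pipeline, a socio-ecological model of this mechanism for conservation
ecologists and social-ecological-systems researchers:

1. a **synthetic survey generator** that emulates a 538-household
   questionnaire across 35 communities and 9 reserves, with every marginal
   moment-matched to published survey summary statistics (truncated normals
   calibrated post-truncation, exact-mean ordinals, Bernoulli constraints)
   and a configurable multiplicative *aging effect* on the resource-use
   quantities of old-age-group (OAG) households;
2. a **household decision model**: belief update
   `Belief_{t+1} = s·P_t + (1−s)·Belief_t`, per-pattern importance
   `D_k = UA_k·I_k / Σ_k UA_k·I_k` (quantity × revenue value shares over
   the k = 2 patterns), and a final intensity damped by four
   salience-weighted factors (ecological value identity, social pressure,
   environmental constraints, labor literacy), aggregated to community ×
   age-group utilization decisions x1, x2;
3. a **niche evaluation**: a 4-dimension, 14-index matrix per community ×
   age group with *state* (baseline) and *potential* (five-year increment)
   layers combined as `S + A·P`, coefficient-of-variation index weights
   `W_j = (δ_j/x̄_j) / Σ(δ/x̄)`, relative niche widths
   `N_i = W_k·R_ik / Σ_j R_jk` (shares summing to 1 across units),
   comprehensive widths `M_i = Σ_d N_id·w_d`, and Pianka niche overlaps
   `O_jk = Σ p_ij p_ik / √(Σ p_ij² Σ p_ik²)` between neighboring
   communities;
4. an **OAG/YAG comparison**: per-community width differences and
   per-pair overlap ratios `O_OAG / O_YAG`, classified as *positive
   differences* (ratio in (0, 1): aging relaxes ecological competition) or
   *negative differences* (ratio > 1).

Everything flows from one root seed and is byte-reproducible.

## Worked example

```sh
pandaniche run-all --seed 42 --out out/
```

runs simulate → decide → evaluate → compare and prints the manifest.
`out/summary.json` from that run:

```json
{
 "median_overlap_ratio": 0.9981837888400105,
 "n_communities": 35,
 "n_pairs": 35,
 "n_pairs_negative": 15,
 "n_pairs_positive": 20,
 "n_pairs_undefined": 0,
 "n_width_oag_higher": 26,
 "n_width_yag_higher": 9
}
```

Reading: in 26 of 35 communities the OAG comprehensive niche width `M`
exceeds the YAG width — the weakened resource use of aging households
leaves habitat-relevant conditions in a better state — and 20 of 35
neighbor pairs show an overlap ratio below 1 (median 0.998), i.e. less
ecological competition under OAG-dominated use. Per-community and
per-pair detail lands in `comparison_communities.csv` and `overlaps.csv`:

```
community_id    M_OAG    M_YAG  difference
         C01 0.014605 0.014984   -0.000379
         C04 0.016277 0.015407    0.000870

community_a community_b  O_OAG  O_YAG  ratio classification
        C01         C02 0.9202 0.9265 0.9932       positive
        C02         C03 0.8811 0.8754 1.0065       negative
```

Widths are shares of the weighted evaluation space: they sum to 1 over
all 70 community × age-group units, so a width of 0.0146 is roughly the
average unit's share (1/70 ≈ 0.0143).

The same pipeline is scriptable:

```python
from pandaniche import PipelineConfig, run_all

cfg = PipelineConfig()
cfg.scenario.aging_effect = 0.3   # OAG quantities scaled by 0.7
manifest = run_all(cfg, seed=42, out_dir="out")
```

Stages can be run individually (`pandaniche simulate|decide|evaluate|
compare`), each reading and writing plain CSV, with a JSON/YAML config
file for every parameter (see `docs/methods.md`).

## Layout

- `src/pandaniche/core.py` — the whole implementation, sectioned in
  pipeline order (calibration → generators → decision model → niche
  evaluation → orchestration); `__main__.py` is the thin CLI.
- `docs/methods.md` — model description, parameter defaults and the
  reasoning behind the open design choices.
- `tests/` — unit, property and acceptance tests.
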