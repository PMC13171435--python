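# hoiforest

Pairwise and higher-order neighbourhood interactions in mapped forest
census data.

## The problem

Conspecific negative density dependence (CNDD) — conspecific neighbours
hurting a focal tree more than heterospecific ones — is a leading candidate
mechanism behind the latitudinal tree diversity gradient, but estimates of
it usually assume trees interact only in pairs. When a third tree modifies a
pairwise interaction (a **higher-order interaction**, HOI), pairwise
coefficients estimated from pair-only models silently absorb those
modifications, and latitudinal patterns in CNDD can be distorted.
`hoiforest` implements the full neighbourhood-analysis pipeline needed to
separate the two: it is written for ecologists working with two-census
mapped stem data (ForestGEO-style plots) and for method studies on synthetic
forests with known truth.

## The model

For a focal tree *f* of species *i*, growth and interval survival are

    Growth_if   = G_i · DBH_if^γ · e^Pair_if · e^HOI_if
    Survival_if = logistic(λ_i + γ₁/DBH + γ₂·DBH + γ₃·DBH² + Pair_if + HOI_if)

with neighbourhood terms

    Pair_if = α_ii·n_i  + α_ih·n_h
    HOI_if  = β_iii·n_ii + β_iih·n_ih + β_ihi·n_hi + β_ihh·n_hh

where `n_i`, `n_h` are conspecific/heterospecific crowding indices (each
neighbour contributes `DBH/d` within a fixed radius) and the four
higher-order indices additionally weight each neighbour by its own crowding
from initiators of the focal species (`n_ii`, `n_hi`) or other species
(`n_ih`, `n_hh`). Negative coefficients are competitive, positive
facilitative. Three nested classes are fitted per species — null (size
only), pair-only (α's; these are α_modified), HOI-inclusive (α_true + β's) —
and a class is *supported* when its AIC undercuts every simpler class by ≥2.
Downstream analyses relate coefficient magnitudes and plot richness to
absolute latitude with exponential regressions, and summarize cumulative
neighbourhood effects per species as the multipliers
`RC_Pair = mean(e^Pair)` and `RC_HOI = mean(e^HOI)`, regressed on log
abundance × latitude to test for stabilization (rare species benefiting).

## Worked example

`examples/02_growth_model_recovery.py` simulates one plot from the
generative model, fits the three growth-model classes for the most abundant
species and prints:

```
species sp001: 423 interior surviving trees
  true alpha_ii          = -0.00722
  alpha_ii,true (HOI)    = -0.00429
  alpha_ii,mod  (pair)   = -0.02888
  AIC: null 539.0, pair 263.4, hoi 205.5 -> best: hoi
```

The HOI-inclusive estimate (−0.0043) targets the generative intraspecific
coefficient (−0.0072); the pair-only estimate (−0.029) is several times too
negative because it absorbs the species' higher-order effects — precisely
the bias the method is built to expose. The AIC line applies the ΔAIC ≥ 2
rule: here the HOI-inclusive model wins by ~58 units.

The other examples cover the crowding indices on a tiny stem map (`01`),
latitudinal gradient fits (`03`), RC stabilization (`04`) and the one-shot
pipeline (`05`). The same pipeline is scriptable from the shell:

```bash
hoiforest run-all --config config.yaml --out out/
```

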