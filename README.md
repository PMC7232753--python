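# probene

Statistical toolkit for decomposing the health effects of host-associated
microbes into **proliferation** (how dense the microbe grows in the host) and
**benevolence** (how much good or harm it does per unit density), and the
mirror-image host traits **resistance** and **tolerance**.

## Who this is for

Experimental groups doing infection or colonisation experiments that record,
per host, a health outcome and a microbial density (cfu counts), typically
comparing host genotypes, microbial strains, or a wild-type strain against an
isogenic gene knockout. The package answers: does the variation in outcome
come from the microbe growing to different densities, from a different
health-per-density relationship, or both — and, for a knockout contrast, what
kind of effector molecule the deleted gene encodes.

## The model

For one (host type, strain) group, host health is modelled as a line in
microbial density *c*:

    health = a + b·c

* *a* — baseline health of uninfected hosts ("vigour");
* *b* — slope of health on density: **tolerance** when compared across host
  types, **benevolence** when compared across strains (*b* > 0 benevolent,
  *b* < 0 malevolent);
* *c̄* — group mean density: (inverse) **resistance** across host types,
  **proliferation** across strains;
* *b·c̄* — the signed **virulence** of a malevolent microbe.

Variation in *c̄* is tested with a one-way model `density ~ group`; variation
in *b* with the slope-comparison ANCOVA
`health ~ group + density + group:density`, where the interaction term is
tested by an extra-sum-of-squares F against the additive model (a binomial
GLM with a likelihood-ratio test replaces this for 0/1 survival outcomes).
A fully factorial design (`≥2 host types × ≥2 strains`) is handled by a
combined model with both density interactions, plus a screen for a
host × strain interaction in the density model.

From a wild-type/knockout contrast the factor is classified as:

| significant difference | direction | call |
|---|---|---|
| slope | b_wt > b_ko | benevolence factor |
| slope | b_wt < b_ko | malevolence factor |
| mean density | c̄_wt > c̄_ko | proliferation factor (microbial gene) |
| mean density | c̄_wt < c̄_ko | resistance factor (host gene) |
| slope | b_wt > b_ko (harmful infection) | tolerance factor (host gene) |

A factor is *pure* when exactly one of the two tests is significant.
Built-in diagnostics implement the field's two standard caveats: slope
comparisons between groups with poor density-range overlap are flagged
unreliable, and a quadratic-extension fit checks that the relationship is
actually linear. Densities are analysed on log10(cfu+1) by default.

## Worked example

Simulate a knockout experiment in which the deleted gene both raises the
strain's density (by 1 log10 unit) and makes its slope more negative (by
0.8), then classify it:

```bash
$ probene simulate --preset knockout_mixed --seed 42 --out demo.csv
wrote 100 records to demo.csv (truth: demo.truth.json)

$ probene classify demo.csv
malevolence_factor + proliferation_factor (mixed)
  b_wt       -1.29484
  b_ko       -0.535278
  c_bar_wt   4.94877
  c_bar_ko   4.09121
  p_slope    0.000371418
  p_density  5.77414e-06

$ probene diagnose demo.csv
density overlap (threshold 0.5):
  ko ~ wt: 0.558
linearity: curvature p = 0.8431
  no evidence of curvature; the linear model is adequate
```

The wild type's slope of health on log density (−1.29) is significantly
steeper than the knockout's (−0.54), so the molecule worsens health per unit
density — a malevolence factor; the wild type also reaches a significantly
higher mean log density (4.95 vs 4.09) — a proliferation factor. Both tests
fire, so the factor is *mixed*, not pure: inhibiting it would both reduce
per-density harm and push the microbe's density (and fitness) down. The
diagnostics confirm the two density ranges overlap adequately (0.56) and that
the linear model is appropriate.

The same pipeline is available as a library (`probene.classify_microbial_factor`,
`probene.test_slope_variation`, …), and `probene plot` renders the
health-vs-density scatter with per-group fitted lines.

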