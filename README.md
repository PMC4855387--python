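# reefcomposite

Community-level seascape genetics for island archipelagos: who holds the
genetic diversity of a reef community, and which features of the seascape
predict it?

Conservation planning for reefs increasingly asks about the genetic
diversity of *whole assemblages*, not single exemplar species. This package
implements that community-level analysis for many co-distributed species
genotyped across an island chain:

* **Rarefied allelic richness (AR)** per species × island — the expected
  number of distinct alleles in a standardized subsample of `g` gene
  copies, computed exactly by hypergeometric rarefaction
  `AR_g = Σ_i [1 − C(N−N_i, g)/C(N, g)]`;
* **Composite AR** — the per-island multi-species mean, standardized by
  repeatedly drawing 12 species without replacement (500 draws) so islands
  with different species pools are comparable;
* **Congruence** — Pearson r of each species's spatial AR pattern against
  the composite, with a one-sided t-test for a community-wide tendency,
  plus a leave-one-out mode that removes self-correlation bias;
* **Seascape model selection** — exhaustive small-sample AICc comparison
  (`ΔAICc`, Akaike weights `w_i`, adjusted r²) of 1–3-term OLS models of
  composite AR on habitat area, historical (last-glacial-maximum) habitat
  loss, coral/CCA cover and thermal stress, with a greedy colinearity
  screen, regional subsets, and a parallel random-intercept mixed-model
  path on the species-level records;
* **RDA / partial RDA** of the species × driver correlation profile on
  species traits, and **Moran's I** spatial autocorrelation screening;
* a **stepping-stone Wright–Fisher simulator** with per-deme effective
  sizes and infinite-alleles mutation, validated against the Ewens sampling
  formula `E[K_n] = Σ θ/(θ+i)`, used to test whether large marginal habitats
  produce the observed excess diversity at the chain's ends;
* a **synthetic archipelago generator** with known ground truth (habitat
  areas spanning 6.6–470 km² with maxima at the margins, correlated
  predictors, occupancy, realistic sample sizes) so every stage of the
  pipeline has a recovery test.

It is aimed at population geneticists and spatial ecologists who want the
community-level composite-diversity workflow as a tested, scriptable
library rather than a chain of one-off spreadsheet and GUI steps.

## Worked example

Generate a synthetic archipelago whose only causal driver of diversity is
habitat area, run the core pipeline, and ask which seascape model wins:

```python
import reefcomposite as rc

seascape, genetic, traits, truth = rc.generate_scenario("habitat_driver", seed=7)
ar = rc.species_island_ar(genetic, g_haploid=6, g_diploid=12)
comp = rc.composite_ar(ar, k_species=12, n_resamples=500, seed=7)
print(comp.data.head(4).to_string(index=False))

prof = rc.species_congruence(ar, comp, min_islands=6)
test = rc.congruence_ttest(prof)
print(f"congruence: t = {test.t:.2f}, df = {test.df}, p = {test.p:.4f}")

retained, corr = rc.colinearity_screen(
    seascape, ["habitat_area_t", "lgm_loss", "coral_cover",
               "cca_cover", "thermal_stress"])
y = comp.series()
sel = rc.ModelSelection(y, seascape.data.loc[y.index, retained], max_terms=3).fit()
print(sel.table.head(4)[["model", "K", "aicc", "delta_aicc", "w", "adj_r2"]]
      .to_string(index=False))
```

Output:

```
island  composite    mc_sd  n_species_available  included
   I01   4.224255 0.317638                   36      True
   I02   3.041498 0.320245                   40      True
   I03   3.513332 0.329819                   37      True
   I04   2.737836 0.237283                   39      True
congruence: t = 24.22, df = 46, p = 0.0000
                                      model  K      aicc  delta_aicc        w   adj_r2
                             habitat_area_t  3 23.080251    0.000000 0.257808 0.533858
            habitat_area_t + thermal_stress  4 23.278887    0.198636 0.233434 0.626937
                 habitat_area_t + cca_cover  4 24.222355    1.142105 0.145644 0.598855
habitat_area_t + cca_cover + thermal_stress  5 24.311160    1.230909 0.139318 0.707653
```

Reading this: each island's composite is the resampled 12-species mean AR
(in alleles per 6 gene copies) with its Monte-Carlo spread; the strongly
positive congruence t says species' spatial patterns track the shared
pattern (as built into this scenario); and every ΔAICc < 2 model contains
`habitat_area_t` — the generator's one causal driver — with the single-term
model ranked first and explaining ~53% of the variance (adjusted).

The same stages are available from the shell via the `reefcomposite` CLI
(`generate`, `ingest`, `ar`, `composite`, `run`, `report`, `simulate`), and
`rc.run_pipeline({"scenario": "habitat_driver", "seed": 7}, "out/")` runs
everything end to end with a manifest recording every exclusion decision.

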