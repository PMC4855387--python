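"""Replicated validation experiments on synthetic data with known truth.

Each function runs a self-contained experiment — generation, analysis,
measurement — and returns plain numbers. They back both the test suite and
the reproduction script, so the quantities reported there are always
recomputed through the same code path as the pipeline itself.

Problem sizes are chosen to give stable Monte-Carlo estimates on a single
CPU in minutes; every function takes an explicit seed.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .composite import composite_ar
from .congruence import congruence_ttest, species_congruence
from .rarefaction import rarefied_allele_count, species_island_ar
from .seascape_models import ModelSelection
from .simulate import (SimConfig, crp_sample, expected_alleles_ewens,
                       hawaii_like_sizes, simulate_stepping_stone)
from .synthetic import generate_scenario, scenario_presets


# ---------------------------------------------------------------------------
# rarefaction vs exhaustive enumeration
# ---------------------------------------------------------------------------

def _enumeration_ar(counts: list[int], g: int) -> float:
    """Exhaustive oracle: mean distinct alleles over all C(N, g) subsets of
    the individually labelled gene copies."""
    labels: list[int] = []
    for a, c in enumerate(counts):
        labels.extend([a] * c)
    ks = [len({labels[i] for i in sub})
          for sub in combinations(range(len(labels)), g)]
    return float(np.mean(ks))


def rarefaction_oracle_error(n_vectors: int = 500, max_copies: int = 12,
                             seed: int = 0) -> float:
    """Max |hypergeometric AR - enumeration mean| over random count vectors
    (N <= max_copies) at every feasible depth g."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        k = int(rng.integers(1, 6))
        counts = list(rng.integers(1, 7, size=k))
        while sum(counts) > max_copies:
            counts = counts[:-1] if len(counts) > 1 else [max_copies]
        n = sum(counts)
        for g in range(1, n + 1):
            err = abs(rarefied_allele_count(counts, g)
                      - _enumeration_ar(counts, g))
            worst = max(worst, err)
    return worst


# ---------------------------------------------------------------------------
# Ewens sampling formula agreements
# ---------------------------------------------------------------------------

def crp_ewens_agreement(theta: float, n: int = 6, n_draws: int = 20000,
                        seed: int = 0) -> dict:
    """Mean distinct alleles from the equilibrium sampler vs the closed form."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    ks = np.fromiter((len(crp_sample(theta, n, rng)) for _ in range(n_draws)),
                     dtype=float, count=n_draws)
    expected = expected_alleles_ewens(theta, n)
    se = float(ks.std(ddof=1) / np.sqrt(n_draws))
    return {"mean": float(ks.mean()), "expected": expected, "se": se,
            "z": float((ks.mean() - expected) / se)}


def panmictic_limit(theta: float = 1.0, deme_size: int = 100,
                    n_sample: int = 6, replicates: int = 600,
                    seed: int = 0) -> dict:
    """Single-deme Wright-Fisher run at 2 N mu = theta vs the Ewens E[K]."""
    mu = theta / (2 * deme_size)
    cfg = SimConfig(deme_sizes=[deme_size], m=0.0, mu=mu,
                    n_sample=n_sample, replicates=replicates, seed=seed)
    res = simulate_stepping_stone(cfg)
    ks = res.ar["ar"].to_numpy(dtype=float)
    expected = expected_alleles_ewens(theta, n_sample)
    se = float(ks.std(ddof=1) / np.sqrt(len(ks)))
    return {"mean": float(ks.mean()), "expected": expected, "se": se,
            "z": float((ks.mean() - expected) / se)}


def margin_diversity_experiment(n_demes: int = 15, base: int = 50,
                                margin_factor: float = 3.0, m: float = 0.05,
                                mu: float = 5e-3, replicates: int = 100,
                                seed: int = 0) -> dict:
    """Chain with ~3x larger marginal demes: do margins carry more sampled
    diversity than the smallest central demes?

    Returns per-replicate paired contrast (margin mean AR - mean AR of the
    three smallest central demes) with a one-sided paired t-test.
    """
    sizes = hawaii_like_sizes(n_demes, base=base, margin_factor=margin_factor)
    cfg = SimConfig(deme_sizes=sizes, m=m, mu=mu, n_sample=6,
                    replicates=replicates, seed=seed)
    res = simulate_stepping_stone(cfg)
    margins = [0, n_demes - 1]
    interior = np.arange(1, n_demes - 1)
    central = interior[np.argsort(np.asarray(sizes)[interior])[:3]]
    per_rep = res.ar.pivot(index="replicate", columns="deme", values="ar")
    contrast = (per_rep[margins].mean(axis=1)
                - per_rep[list(central)].mean(axis=1)).to_numpy()
    t = stats.ttest_1samp(contrast, 0.0, alternative="greater")
    return {"margin_mean_ar": float(per_rep[margins].to_numpy().mean()),
            "central_mean_ar": float(per_rep[list(central)].to_numpy().mean()),
            "mean_contrast": float(contrast.mean()),
            "p_one_sided": float(t.pvalue), "replicates": replicates}


# ---------------------------------------------------------------------------
# composite unbiasedness
# ---------------------------------------------------------------------------

def composite_unbiasedness(n_species: int = 13, k_species: int = 12,
                           n_resamples: int = 500, seed: int = 0) -> dict:
    """500-draw composite vs the exhaustive mean over all 13 subsets of 12
    (which equals the plain mean), plus the exact k==n case."""
    from .rarefaction import ARMatrix
    rng = np.random.default_rng(seed)
    vals = rng.uniform(1.0, 5.0, n_species)
    wide = pd.DataFrame({"isl": vals},
                        index=[f"sp{i:02d}" for i in range(n_species)])
    mat = ARMatrix(wide=wide, per_locus=pd.DataFrame(), g_haploid=6, g_diploid=12)
    subset_means = [np.mean(vals[list(c)])
                    for c in combinations(range(n_species), k_species)]
    exact = float(np.mean(subset_means))
    comp = composite_ar(mat, k_species=k_species, n_resamples=n_resamples,
                        seed=seed)
    mc_se = float(comp.data["mc_sd"].iloc[0] / np.sqrt(n_resamples))
    # exact case: matrix of exactly k species
    wide12 = wide.iloc[:k_species]
    mat12 = ARMatrix(wide=wide12, per_locus=pd.DataFrame(), g_haploid=6,
                     g_diploid=12)
    comp12 = composite_ar(mat12, k_species=k_species, n_resamples=n_resamples,
                          seed=seed)
    return {"composite": float(comp.series()["isl"]), "exhaustive_mean": exact,
            "mc_se": mc_se,
            "z": float((comp.series()["isl"] - exact) / mc_se),
            "exact_case_error": float(abs(comp12.series()["isl"]
                                          - wide12["isl"].mean()))}


# ---------------------------------------------------------------------------
# model-selection recovery
# ---------------------------------------------------------------------------

RECOVERY_PREDICTORS = ["habitat_area_t", "lgm_loss", "coral_cover",
                       "cca_cover", "thermal_stress"]


def _one_selection(scenario: str, seed: int):
    seascape, table, traits, truth = generate_scenario(scenario, seed=seed)
    ar = species_island_ar(table)
    comp = composite_ar(ar, seed=seed)
    s = comp.series()
    X = seascape.data.loc[s.index, RECOVERY_PREDICTORS]
    return ModelSelection(s, X, max_terms=3).fit(), s, seascape


def model_selection_recovery(n_reps: int = 200, seed: int = 0) -> dict:
    """habitat_driver: how often is habitat area in the dAICc < 2 top set?
    null: how often does the intercept-only reference stay within 2 of the
    best predictor model?"""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_reps)
    hits = 0
    for i in range(n_reps):
        res, _, _ = _one_selection("habitat_driver", int(seeds[i]))
        hits += res.term_in_top_set("habitat_area_t")
    null_ok = 0
    for i in range(n_reps):
        res, _, _ = _one_selection("null", int(seeds[n_reps + i]))
        null_ok += res.reference_delta < 2.0
    return {"habitat_recovery_rate": hits / n_reps,
            "null_reference_within_2_rate": null_ok / n_reps,
            "replicates": n_reps}


# ---------------------------------------------------------------------------
# congruence calibration and power
# ---------------------------------------------------------------------------

def _one_congruence(scenario: str, seed: int, leave_one_out: bool):
    seascape, table, traits, truth = generate_scenario(scenario, seed=seed)
    ar = species_island_ar(table)
    comp = composite_ar(ar, seed=seed)
    prof = species_congruence(ar, comp, min_islands=6,
                              leave_one_out=leave_one_out)
    return congruence_ttest(prof)


def congruence_calibration(n_reps: int = 1000, seed: int = 0,
                           alpha: float = 0.05) -> dict:
    """Type-I error of the one-sided congruence t-test under the null
    scenario, with the self-correlation-free leave-one-out composite."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    rejections = 0
    df_ok = True
    for s in seeds:
        res = _one_congruence("null", int(s), leave_one_out=True)
        rejections += res.p < alpha
        df_ok &= res.df == res.n_species - 1
    return {"rejection_rate": rejections / n_reps, "alpha": alpha,
            "replicates": n_reps, "df_always_n_minus_1": bool(df_ok),
            "binomial_3se": 3 * float(np.sqrt(alpha * (1 - alpha) / n_reps))}


def congruence_power(n_reps: int = 200, seed: int = 0,
                     alpha: float = 0.05) -> dict:
    """Power of the congruence test under the shared habitat driver, with the
    study's include-all composite."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    rejections = 0
    for s in seeds:
        res = _one_congruence("shared_congruence", int(s), leave_one_out=False)
        rejections += res.p < alpha
    return {"power": rejections / n_reps, "alpha": alpha, "replicates": n_reps}
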