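"""Forward-time stepping-stone Wright-Fisher simulator with infinite-alleles
mutation, plus exact Ewens-sampling-formula tools.

Demes form a linear chain with per-deme haploid effective sizes N_i (scaled
to island habitat area in the margin-diversity experiment). Each generation
every new copy picks a parent deme — its own with probability 1 - m, each
adjacent deme with m/2 (edge demes send the full m to their single
neighbour) — then a uniform parent copy there, and mutates to a brand-new
allele with probability mu. After burn-in, n_sample copies per deme are
drawn without replacement and the distinct-allele count is the sampled AR
(identical to hypergeometric rarefaction at g = n_sample).

For a single deme at stationarity the sample follows the Ewens sampling
formula with theta = 2 N mu, giving the exact check
E[K] = sum_{i=0}^{n-1} theta / (theta + i). The Chinese-restaurant sampler
draws from that equilibrium directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


def expected_alleles_ewens(theta: float, n: int) -> float:
    """Exact expected number of distinct alleles in an Ewens sample of size n."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    return float(np.sum(theta / (theta + i)))


def crp_sample(theta: float, n: int, seed=None) -> np.ndarray:
    """Draw allele counts from the Ewens sampling formula (Chinese restaurant).

    Copy j (1-indexed) founds a new allele with probability
    theta/(theta + j - 1), otherwise joins an existing allele proportionally
    to its count. Returns the vector of allele counts (sums to n).

    ``seed`` may be an int, a Generator, or None.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    v = rng.random(n)
    counts: list[int] = []
    for j in range(n):
        if j == 0 or u[j] < theta / (theta + j):
            counts.append(1)
        else:
            # join existing copy uniformly == join allele w.p. proportional to count
            target = int(v[j] * j)  # index over existing copies
            acc = 0
            for a, c in enumerate(counts):
                acc += c
                if target < acc:
                    counts[a] += 1
                    break
    return np.asarray(counts, dtype=int)


@dataclass
class SimConfig:
    """Stepping-stone simulation settings.

    deme_sizes : haploid effective sizes N_i along the chain.
    m : per-generation migration probability (split between neighbours).
    mu : per-copy per-generation mutation probability (infinite alleles).
    burn_in : generations before sampling; default 10 * max(N_i).
    n_sample : copies sampled per deme (default 6, the AR unit).
    replicates : independent runs, each with its own seeded stream.
    """

    deme_sizes: Sequence[int]
    m: float = 0.1
    mu: float = 1e-3
    burn_in: int | None = None
    n_sample: int = 6
    replicates: int = 1
    seed: int = 0
    plateau_check: bool = False

    def __post_init__(self):
        self.deme_sizes = [int(x) for x in self.deme_sizes]
        if any(n < 2 for n in self.deme_sizes):
            raise ValueError("all deme sizes must be >= 2")
        if not (0 <= self.m < 1):
            raise ValueError("m must lie in [0, 1)")
        if not (0 < self.mu <= 1):
            raise ValueError("mu must lie in (0, 1]")
        if self.n_sample > min(self.deme_sizes):
            raise ValueError("n_sample exceeds the smallest deme size")
        if self.burn_in is None:
            self.burn_in = 10 * max(self.deme_sizes)


@dataclass
class SimResult:
    """Sampled allele counts and AR per deme per replicate."""

    samples: pd.DataFrame      # replicate, deme, allele, count
    ar: pd.DataFrame           # replicate, deme, ar (distinct alleles at g=n_sample)
    config: SimConfig
    metadata: dict = field(default_factory=dict)

    def mean_ar(self) -> pd.Series:
        """Mean sampled AR per deme across replicates."""
        return self.ar.groupby("deme")["ar"].mean()

    def to_allele_table(self, species: str = "sim", marker_type: str = "sim_locus"):
        """Expose one replicate set as an AlleleCountTable (demes = islands).

        Replicates become loci so simulator output feeds the rarefaction /
        composite pipeline unchanged.
        """
        from .io_formats import AlleleCountTable, GENETIC_COLUMNS
        df = self.samples.copy()
        df["species"] = species
        df["marker_type"] = marker_type
        df["ploidy"] = 1
        df["locus"] = "rep" + df["replicate"].astype(str)
        df["island"] = "deme" + df["deme"].astype(str).str.zfill(2)
        df["allele"] = df["allele"].astype(str)
        return AlleleCountTable(df[GENETIC_COLUMNS])


def _evolve(cfg: SimConfig, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Evolve one replicate; returns (population, sizes, offsets, plateau_ok)."""
    sizes = np.asarray(cfg.deme_sizes, dtype=np.int64)
    L = len(sizes)
    total = int(sizes.sum())
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    deme_of = np.repeat(np.arange(L), sizes)
    # per-deme migration split: interior demes m/2 each side, edges full m to
    # their single neighbour (conserves total emigrant mass m)
    p_left = np.full(L, cfg.m / 2)
    p_right = np.full(L, cfg.m / 2)
    if L == 1:
        p_left[:] = p_right[:] = 0.0
    else:
        p_left[0] = 0.0
        p_right[0] = cfg.m
        p_right[-1] = 0.0
        p_left[-1] = cfg.m
    pop = np.arange(total, dtype=np.int64)  # maximal initial diversity
    counter = total
    window: list[float] = []
    half = max(cfg.burn_in // 4, 1)
    for gen in range(cfg.burn_in):
        r = rng.random(total)
        src = np.where(r < p_left[deme_of], deme_of - 1,
                       np.where(r < p_left[deme_of] + p_right[deme_of],
                                deme_of + 1, deme_of))
        parent = offsets[src] + (rng.random(total) * sizes[src]).astype(np.int64)
        pop = pop[parent]
        mut = rng.random(total) < cfg.mu
        k = int(mut.sum())
        if k:
            pop[mut] = np.arange(counter, counter + k)
            counter += k
        if cfg.plateau_check and gen >= cfg.burn_in - 2 * half:
            window.append(len(np.unique(pop)))
    plateau_ok = True
    if cfg.plateau_check and len(window) >= 2:
        a = np.mean(window[: len(window) // 2])
        b = np.mean(window[len(window) // 2:])
        plateau_ok = abs(a - b) <= 0.05 * max(a, 1.0)
    return pop, sizes, offsets, plateau_ok


def _run_once(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[np.ndarray], bool]:
    """One replicate: per-deme sampled allele arrays (without replacement)."""
    pop, sizes, offsets, plateau_ok = _evolve(cfg, rng)
    samples = []
    for d in range(len(sizes)):
        idx = offsets[d] + rng.choice(sizes[d], size=cfg.n_sample, replace=False)
        samples.append(pop[idx].copy())
    return samples, plateau_ok


def simulate_stepping_stone(cfg: SimConfig) -> SimResult:
    """Run the chain simulator for ``cfg.replicates`` independent replicates.

    Each replicate uses its own stream spawned from the master seed, so
    results for replicate r never depend on how many replicates were asked
    for after it.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    sample_rows, ar_rows = [], []
    plateau_all = True
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        samples, plateau_ok = _run_once(cfg, rng)
        plateau_all &= plateau_ok
        for d, alleles in enumerate(samples):
            vals, counts = np.unique(alleles, return_counts=True)
            ar_rows.append({"replicate": rep, "deme": d, "ar": len(vals)})
            for v, c in zip(vals, counts):
                sample_rows.append({"replicate": rep, "deme": d,
                                    "allele": int(v), "count": int(c)})
    samples_df = pd.DataFrame(sample_rows, columns=["replicate", "deme", "allele", "count"])
    ar_df = pd.DataFrame(ar_rows, columns=["replicate", "deme", "ar"])
    meta = {
        "edge_handling": "full migrant mass m to the single neighbour",
        "burn_in": cfg.burn_in,
        "plateau_ok": plateau_all,
        "theta_per_deme": [2 * n * cfg.mu for n in cfg.deme_sizes],
    }
    return SimResult(samples=samples_df, ar=ar_df, config=cfg, metadata=meta)


def hawaii_like_sizes(n_demes: int = 15, base: int = 50, margin_factor: float = 3.0
                      ) -> list[int]:
    """U-shaped deme-size profile: ~``margin_factor`` larger at both margins.

    Mimics the island chain's habitat-area profile (large areas at the two
    ends, small in the middle) on a smooth quadratic in chain position.
    """
    pos = np.linspace(-1, 1, n_demes)
    scale = 1.0 + (margin_factor - 1.0) * pos ** 2
    return [int(round(base * s)) for s in scale]
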