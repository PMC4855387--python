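"""Congruence of species' spatial AR patterns with the composite, and the
species x seascape-driver correlation profile.

Congruence is the Pearson correlation of one species's island AR vector with
the composite AR vector over the islands where both are defined; a one-sided
one-sample t-test on those r values asks whether species tend, as a
community, to track the composite pattern. Because the focal species
contributes to the all-species composite, the include-all r carries a
positive self-correlation bias of order 1/sqrt(n_species); the leave-one-out
mode removes it by correlating against the composite of the remaining
species (the exact expectation of the without-replacement resampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composite import CompositeAR
from .io_formats import SeascapeTable, SEASCAPE_PREDICTORS
from .rarefaction import ARMatrix


@dataclass
class CorrelationProfile:
    """Per-species congruence and driver correlations.

    ``data`` is indexed by species with columns ``r_congruence``,
    ``n_islands_used`` and one ``r_<driver>`` column per seascape predictor.
    ``reasons`` records why a cell is missing.
    """

    data: pd.DataFrame
    reasons: dict[tuple[str, str], str]

    def defined_congruence(self) -> pd.Series:
        return self.data["r_congruence"].dropna()

    def driver_matrix(self) -> pd.DataFrame:
        cols = [c for c in self.data.columns if c.startswith("r_") and c != "r_congruence"]
        return self.data[cols].rename(columns=lambda c: c[2:])

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


@dataclass
class CongruenceTest:
    """One-sided one-sample t-test of mean congruence r > 0."""

    t: float
    df: int
    p: float
    n_species: int
    mean_r: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    r, _ = stats.pearsonr(x, y)
    return float(r)


def species_congruence(ar: ARMatrix, comp: CompositeAR, min_islands: int = 6,
                       leave_one_out: bool = False) -> CorrelationProfile:
    """Correlate each species's AR pattern with the composite pattern.

    Species qualify when AR and the composite are jointly defined at
    ``min_islands`` or more islands ("more than five" -> default 6).
    ``leave_one_out`` correlates against the composite of the other species
    (plain mean of their AR at each island, the resampling expectation),
    removing self-correlation inflation.
    """
    comp_series = comp.series()
    if len(comp_series) < min_islands:
        raise ValueError(
            f"composite defined on {len(comp_series)} islands; need >= {min_islands}"
        )
    wide = ar.wide
    reasons: dict[tuple[str, str], str] = {}
    rows = {}
    for species in wide.index:
        sp = wide.loc[species].dropna()
        islands = sp.index.intersection(comp_series.index)
        n_used = len(islands)
        if n_used < min_islands:
            reasons[(species, "r_congruence")] = (
                f"only {n_used} islands overlap the composite (< {min_islands})"
            )
            rows[species] = (np.nan, n_used)
            continue
        x = sp[islands].to_numpy()
        if leave_one_out:
            others = wide.drop(index=species)
            y = others[islands].mean(axis=0, skipna=True).to_numpy()
        else:
            y = comp_series[islands].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            reasons[(species, "r_congruence")] = "constant AR or composite over overlap"
            rows[species] = (np.nan, n_used)
            continue
        rows[species] = (_pearson(x, y), n_used)
    data = pd.DataFrame(
        {"r_congruence": {s: v[0] for s, v in rows.items()},
         "n_islands_used": {s: v[1] for s, v in rows.items()}}
    )
    data.index.name = "species"
    return CorrelationProfile(data=data, reasons=reasons)


def congruence_ttest(profile: CorrelationProfile | pd.Series) -> CongruenceTest:
    """Test for a community-level tendency towards positive congruence.

    One-sample t of mean r against 0, upper tail; df = n - 1.
    """
    r = profile.defined_congruence() if isinstance(profile, CorrelationProfile) else profile.dropna()
    n = len(r)
    if n < 2:
        raise ValueError("need at least 2 defined congruence values")
    if np.ptp(r.to_numpy()) == 0:
        raise ValueError("congruence values have zero variance; t undefined")
    res = stats.ttest_1samp(r, 0.0, alternative="greater")
    return CongruenceTest(t=float(res.statistic), df=n - 1, p=float(res.pvalue),
                          n_species=n, mean_r=float(r.mean()))


def driver_correlations(ar: ARMatrix, seascape: SeascapeTable,
                        min_islands: int = 5,
                        predictors: list[str] | None = None) -> CorrelationProfile:
    """Pearson r of each species's AR against each seascape predictor.

    Each correlation uses the islands where both the species AR and the
    predictor are present; pairs with fewer than ``min_islands`` overlapping
    islands ("more than four" -> default 5) are missing.
    """
    predictors = predictors or [p for p in SEASCAPE_PREDICTORS
                                if p in seascape.data.columns]
    wide = ar.wide
    env = seascape.data
    reasons: dict[tuple[str, str], str] = {}
    out = pd.DataFrame(index=wide.index, dtype=float)
    out.index.name = "species"
    for pred in predictors:
        col = env[pred]
        vals = []
        for species in wide.index:
            sp = wide.loc[species].dropna()
            islands = sp.index.intersection(col.dropna().index)
            if len(islands) < min_islands:
                reasons[(species, pred)] = (
                    f"only {len(islands)} islands overlap (< {min_islands})"
                )
                vals.append(np.nan)
                continue
            x = sp[islands].to_numpy()
            y = col[islands].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                reasons[(species, pred)] = "species AR constant over overlap"
                vals.append(np.nan)
            elif np.ptp(y) == 0:
                reasons[(species, pred)] = "predictor constant over overlap"
                vals.append(np.nan)
            else:
                vals.append(_pearson(x, y))
        out[f"r_{pred}"] = vals
    return CorrelationProfile(data=out, reasons=reasons)
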