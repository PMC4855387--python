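"""Rarefied allelic richness (AR) per species x island, and inclusion filters.

AR at depth ``g`` is the expected number of distinct alleles in a random
subsample of ``g`` gene copies drawn without replacement from the observed
sample — the hypergeometric rarefaction

    AR_g = sum_i [ 1 - C(N - N_i, g) / C(N, g) ],   N = sum_i N_i,

where N_i are allele copy counts. Each term is the probability that allele i
appears at least once in the subsample. Multi-locus species values are the
unweighted mean of per-locus AR over loci deep enough to rarefy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import AlleleCountTable


class InsufficientSampleError(ValueError):
    """Requested rarefaction depth exceeds the available gene copies."""


def rarefied_allele_count(counts: Sequence[int], g: int) -> float:
    """Expected distinct alleles in a without-replacement subsample of ``g`` copies.

    Exact (no Monte Carlo). Each allele's retention probability
    1 - C(N-N_i, g)/C(N, g) is evaluated as a product of ratios
    prod_{j=0}^{g-1} (N - N_i - j)/(N - j), which never overflows.

    Parameters
    ----------
    counts : copy counts per allele, all >= 1.
    g : rarefaction depth in gene copies, 1 <= g <= N.
    """
    counts = list(counts)
    if len(counts) == 0:
        raise ValueError("empty allele count vector")
    if any(c < 1 for c in counts):
        raise ValueError("all allele counts must be >= 1")
    n_total = sum(counts)
    if g < 1:
        raise ValueError("rarefaction depth g must be >= 1")
    if g > n_total:
        raise InsufficientSampleError(
            f"insufficient sample: g={g} exceeds N={n_total} gene copies"
        )
    total = 0.0
    for n_i in counts:
        if n_total - n_i < g:
            total += 1.0  # allele cannot be missed
            continue
        p_absent = 1.0
        for j in range(g):
            p_absent *= (n_total - n_i - j) / (n_total - j)
        total += 1.0 - p_absent
    return total


@dataclass
class ARMatrix:
    """Species x island rarefied allelic richness with per-locus detail.

    ``wide`` is the species x island AR matrix (NaN = cell not rarefiable,
    explicitly absent rather than zero). ``per_locus`` keeps the per-locus
    values and gene-copy numbers behind each cell.
    """

    wide: pd.DataFrame
    per_locus: pd.DataFrame
    g_haploid: int
    g_diploid: int

    @property
    def species(self) -> list[str]:
        return list(self.wide.index)

    @property
    def islands(self) -> list[str]:
        return list(self.wide.columns)

    def islands_sampled(self) -> pd.Series:
        """Number of islands with a defined AR value, per species."""
        return self.wide.notna().sum(axis=1)

    def to_long(self) -> pd.DataFrame:
        long = self.wide.stack().rename("ar").reset_index()
        long.columns = ["species", "island", "ar"]
        return long


def species_island_ar(table: AlleleCountTable, g_haploid: int = 6,
                      g_diploid: int = 12) -> ARMatrix:
    """Rarefy every (species, locus, island) cell and average over loci.

    Haploid loci rarefy to ``g_haploid`` gene copies (the "per six
    individuals" scale for mtDNA), diploid loci to ``g_diploid``. A locus
    with fewer copies than its depth is excluded from that cell's mean; a
    cell with no qualifying locus is absent.
    """
    if g_haploid < 2 or g_diploid < 2:
        raise ValueError("rarefaction depths must be >= 2")
    df = table.data
    rows = []
    for (species, marker, ploidy, locus, island), grp in df.groupby(
            ["species", "marker_type", "ploidy", "locus", "island"], sort=True):
        counts = grp["count"].to_numpy()
        n = int(counts.sum())
        g = g_haploid if ploidy == 1 else g_diploid
        if n < g:
            rows.append({"species": species, "marker_type": marker, "locus": locus,
                         "island": island, "n_copies": n, "g": g, "ar": np.nan,
                         "included": False})
            continue
        rows.append({"species": species, "marker_type": marker, "locus": locus,
                     "island": island, "n_copies": n, "g": g,
                     "ar": rarefied_allele_count(counts, g), "included": True})
    per_locus = pd.DataFrame(rows, columns=["species", "marker_type", "locus",
                                            "island", "n_copies", "g", "ar",
                                            "included"])
    kept = per_locus[per_locus["included"]]
    if len(per_locus):
        wide = (kept.pivot_table(index="species", columns="island", values="ar",
                                 aggfunc="mean")
                .reindex(index=sorted(per_locus["species"].unique()),
                         columns=sorted(per_locus["island"].unique())))
    else:
        wide = pd.DataFrame(dtype=float)
    wide.index.name = "species"
    wide.columns.name = "island"
    return ARMatrix(wide=wide, per_locus=per_locus,
                    g_haploid=g_haploid, g_diploid=g_diploid)


@dataclass
class ExclusionReport:
    """Every sample or species dropped by the inclusion filters, with reason."""

    records: list[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        self.records.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["level", "species", "island",
                                                   "specimens", "reason"])


def apply_inclusion_filters(table: AlleleCountTable, min_specimens: int = 6,
                            min_islands: int = 2,
                            strict_min: int | None = None
                            ) -> tuple[AlleleCountTable, ExclusionReport]:
    """Apply the study inclusion rules to the raw allele counts.

    Drops species-island samples with fewer than ``min_specimens``
    individuals (default 6), then species left on fewer than ``min_islands``
    islands (default 2). ``strict_min`` (e.g. 10) additionally applies the
    sensitivity rule that discards samples of ``min_specimens``..
    ``strict_min - 1`` individuals.
    """
    if min_specimens < 1:
        raise ValueError("min_specimens must be >= 1")
    report = ExclusionReport()
    df = table.data
    if len(df) == 0:
        return table, report
    spec = table.specimens().set_index(["species", "island"])["specimens"]
    threshold = strict_min if strict_min is not None else min_specimens
    keep_keys = set()
    for (species, island), n in spec.items():
        if n < min_specimens:
            report.add(level="sample", species=species, island=island, specimens=int(n),
                       reason=f"fewer than {min_specimens} specimens")
        elif n < threshold:
            report.add(level="sample", species=species, island=island, specimens=int(n),
                       reason=f"strict sensitivity filter: fewer than {threshold} specimens")
        else:
            keep_keys.add((species, island))
    mask = df.set_index(["species", "island"]).index.isin(keep_keys)
    kept = df[mask]
    island_counts = (kept.groupby("species")["island"].nunique()
                     .reindex(df["species"].unique(), fill_value=0))
    thin_species = set(island_counts[island_counts < min_islands].index)
    for s in sorted(thin_species):
        report.add(level="species", species=s, island=None,
                   specimens=None,
                   reason=f"sampled at fewer than {min_islands} islands after sample filter")
    kept = kept[~kept["species"].isin(thin_species)]
    if len(kept) == 0:
        import logging
        logging.getLogger(__name__).warning("inclusion filters removed every sample")
    return AlleleCountTable(kept.reset_index(drop=True)), report
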