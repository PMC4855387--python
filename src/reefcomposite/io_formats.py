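"""Readers/writers for the three input tables and the genetic file dialects.

The genetic input is a long-form allele count table: one row per
(species, marker, locus, island, allele) with the number of gene copies
carrying that allele. Three on-disk dialects feed it: a long CSV (counted
rows or one row per gene copy), FASTA haplotype files (one file per
species x locus x island; identical sequences collapse to one allele), and
GENEPOP files for diploid multi-locus nuclear data.

Island-level seascape predictors and species-level traits arrive as plain
CSVs keyed by ``island`` / ``species``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

GENETIC_COLUMNS = ["species", "marker_type", "ploidy", "locus", "island", "allele", "count"]
KEY_COLUMNS = ["species", "locus", "island", "allele"]

#: seascape predictor columns usable in models (region/lat/lon/chain_order are metadata)
SEASCAPE_PREDICTORS = [
    "habitat_area_t", "lgm_loss", "coral_cover", "cca_cover", "thermal_stress",
    "fish_richness_ln", "coral_richness", "immigration", "nn_distance", "wave",
]

TRAIT_COLUMNS = [
    "fish", "endemic", "pld_log", "length_log", "min_depth_log",
    "depth_range_log", "habitat_specialist", "theta_ST", "F_CT", "herbivore",
]
SAMPLING_COVARIATES = ["n_islands", "marker_type_code", "total_marker_diversity"]


class SchemaError(ValueError):
    """A required column or field is missing or unmappable."""


class ValidationError(ValueError):
    """Table content violates an invariant (duplicate keys, bad counts...)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AlleleCountTable:
    """Long-form allele counts per species x marker x locus x island.

    ``data`` columns: species, marker_type, ploidy (1 or 2), locus, island,
    allele, count (gene copies carrying that allele). The total gene copies
    for a (species, locus, island) cell is the sum of its counts; for diploid
    loci that is twice the number of genotyped individuals.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        missing = [c for c in GENETIC_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"allele count table missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        if (df["count"] < 1).any():
            bad = df.loc[df["count"] < 1].iloc[0]
            raise ValidationError(
                f"count < 1 for {tuple(bad[k] for k in KEY_COLUMNS)}"
            )
        if not df["ploidy"].isin([1, 2]).all():
            raise ValidationError("ploidy must be 1 or 2")
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), KEY_COLUMNS])
            raise ValidationError(f"duplicate (species,locus,island,allele) key: {key}")
        ploidies = df.groupby(["species", "locus"])["ploidy"].nunique()
        if (ploidies > 1).any():
            key = ploidies[ploidies > 1].index[0]
            raise ValidationError(f"ploidy varies within species/locus {key}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def islands(self) -> list[str]:
        return sorted(self.data["island"].unique())

    def n_copies(self) -> pd.DataFrame:
        """Total gene copies N per (species, marker_type, ploidy, locus, island)."""
        return (
            self.data.groupby(["species", "marker_type", "ploidy", "locus", "island"],
                              as_index=False)["count"]
            .sum()
            .rename(columns={"count": "n_copies"})
        )

    def specimens(self) -> pd.DataFrame:
        """Specimens (individuals) per (species, island): max over loci of N/ploidy."""
        nc = self.n_copies()
        nc["individuals"] = np.ceil(nc["n_copies"] / nc["ploidy"]).astype(int)
        return (
            nc.groupby(["species", "island"], as_index=False)["individuals"]
            .max()
            .rename(columns={"individuals": "specimens"})
        )

    @staticmethod
    def concat(tables: Iterable["AlleleCountTable"]) -> "AlleleCountTable":
        frames = [t.data for t in tables]
        if not frames:
            return AlleleCountTable(pd.DataFrame(columns=GENETIC_COLUMNS))
        return AlleleCountTable(pd.concat(frames, ignore_index=True))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class SeascapeTable:
    """Island-level seascape predictors plus metadata (region, lat/lon, chain_order)."""

    data: pd.DataFrame
    excluded: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if "island" not in df.columns:
            raise SchemaError("seascape table needs an 'island' column")
        if "region" not in df.columns:
            raise SchemaError(
                "seascape table needs a 'region' column (NWHI/MHI); region is "
                "metadata and is never inferred from longitude"
            )
        bad_region = ~df["region"].isin(["NWHI", "MHI"])
        if bad_region.any():
            raise ValidationError(f"unknown region values: {df.loc[bad_region, 'region'].unique()}")
        if df["island"].duplicated().any():
            raise ValidationError("duplicate island rows in seascape table")
        if "habitat_area" in df.columns:
            if (df["habitat_area"] <= 0).any():
                raise ValidationError("habitat_area must be > 0")
            if "habitat_area_t" not in df.columns:
                df["habitat_area_t"] = np.log10(df["habitat_area"] + 1.0)
        for cover in ("coral_cover", "cca_cover"):
            if cover in df.columns:
                vals = df[cover].dropna()
                if ((vals < 0) | (vals > 100)).any():
                    raise ValidationError(f"{cover} must lie in [0, 100] percent")
        if "lgm_loss" in df.columns:
            vals = df["lgm_loss"].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError("lgm_loss must lie in [0, 1]")
        if "fish_richness" in df.columns and "fish_richness_ln" not in df.columns:
            df["fish_richness_ln"] = np.log(df["fish_richness"])
        self.data = df.set_index("island", drop=False) if df.index.name != "island" else df

    @property
    def islands(self) -> list[str]:
        return list(self.data["island"])

    def require(self, predictors: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
        """Subset with complete cases for ``predictors``; also returns excluded islands.

        Mirrors the study design of dropping islands that miss key seascape
        factors rather than imputing them.
        """
        missing_cols = [p for p in predictors if p not in self.data.columns]
        if missing_cols:
            raise SchemaError(f"seascape table lacks predictor columns: {missing_cols}")
        ok = self.data[list(predictors)].notna().all(axis=1)
        excluded = list(self.data.loc[~ok, "island"])
        for isl in excluded:
            self.excluded.setdefault(isl, []).append(
                f"missing value in one of {list(predictors)}"
            )
        return self.data.loc[ok], excluded

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class TraitTable:
    """Species-level life-history/genetic traits plus sampling covariates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "species" not in df.columns:
            raise SchemaError("trait table needs a 'species' column")
        if df["species"].duplicated().any():
            raise ValidationError("duplicate species rows in trait table")
        for b in ("fish", "endemic", "habitat_specialist", "herbivore"):
            if b in df.columns and not df[b].dropna().isin([0, 1]).all():
                raise ValidationError(f"trait '{b}' must be 0/1")
        for g in ("theta_ST", "F_CT"):
            if g in df.columns and (df[g].dropna() < -0.05).any():
                # estimator-derived differentiation can dip slightly below zero
                raise ValidationError(f"{g} has values below -0.05; not an estimator artefact")
        self.data = df.set_index("species", drop=False) if df.index.name != "species" else df

    @property
    def species(self) -> list[str]:
        return list(self.data["species"])

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# long CSV
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {c: c for c in GENETIC_COLUMNS}


def read_long_genotypes(path: str | Path,
                        schema: Mapping[str, str] | None = None) -> AlleleCountTable:
    """Read the long genetic CSV into an :class:`AlleleCountTable`.

    ``schema`` maps our field names to the file's column names. Two layouts
    are accepted: counted rows (a ``count`` column; duplicate keys are an
    error, never silently summed) and per-copy rows (no count column; one row
    per observed gene copy, aggregated here). Rows with a missing allele code
    are dropped and the number dropped is logged.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype={colmap["allele"]: str})
    have_count = colmap["count"] in df.columns
    required = [colmap[c] for c in GENETIC_COLUMNS if c != "count" or have_count]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    n0 = len(df)
    df = df.dropna(subset=["allele"])
    df = df[df["allele"].astype(str).str.strip() != ""]
    if len(df) < n0:
        logger.info("read_long_genotypes(%s): dropped %d rows with missing allele", path, n0 - len(df))
    if len(df) == 0:
        return AlleleCountTable(pd.DataFrame(columns=GENETIC_COLUMNS))
    if have_count:
        if df.duplicated(subset=KEY_COLUMNS).any():
            dup = df[df.duplicated(subset=KEY_COLUMNS, keep=False)].iloc[0]
            raise ValidationError(
                "duplicate keyed rows with explicit counts for "
                f"{tuple(dup[k] for k in KEY_COLUMNS)}; merge them upstream"
            )
    else:
        df = (
            df.groupby(["species", "marker_type", "ploidy", "locus", "island", "allele"],
                       as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )
    df["ploidy"] = df["ploidy"].astype(int)
    df["count"] = df["count"].astype(int)
    return AlleleCountTable(df[GENETIC_COLUMNS])


# ---------------------------------------------------------------------------
# FASTA haplotypes
# ---------------------------------------------------------------------------

def read_fasta_haplotypes(path: str | Path, species: str, island: str,
                          locus: str, marker_type: str | None = None) -> AlleleCountTable:
    """Collapse aligned FASTA sequences into haploid allele counts.

    Sequences must be pre-aligned to equal length. Identical strings
    (case-insensitive, terminal whitespace stripped) are one allele;
    IUPAC ambiguity codes are treated literally, so sequences differing only
    at an N site remain distinct alleles (a warning is logged because such
    splits can inflate diversity).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: empty FASTA file")
    seqs = [str(r.seq).strip().upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValidationError(
            f"{path}: sequences have unequal lengths {sorted(lengths)}; "
            "align them before haplotype collapsing"
        )
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    haps = list(counts)
    for i, a in enumerate(haps):
        for b in haps[i + 1:]:
            diffs = [k for k in range(len(a)) if a[k] != b[k]]
            if diffs and all("N" in (a[k], b[k]) for k in diffs):
                logger.warning(
                    "%s: haplotypes differ only at N-containing sites; kept distinct", path
                )
    marker = marker_type or locus
    rows = [
        {"species": species, "marker_type": marker, "ploidy": 1, "locus": locus,
         "island": island, "allele": f"h{i + 1:03d}", "count": c}
        for i, (s, c) in enumerate(sorted(counts.items()))
    ]
    return AlleleCountTable(pd.DataFrame(rows, columns=GENETIC_COLUMNS))


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

def _parse_genepop_loci(lines: list[str]) -> tuple[list[str], int]:
    """Locus names follow the title line, one per line or comma-separated,
    until the first 'Pop'. Returns (loci, index of first Pop line)."""
    loci: list[str] = []
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        if line.lower() == "pop":
            break
        if line:
            loci.extend(x.strip() for x in line.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ValidationError("GENEPOP file has no 'Pop' line")
    return loci, i


def read_genepop(path: str | Path, species: str,
                 island_order: Sequence[str] | None = None,
                 marker_type: str = "microsatellite") -> AlleleCountTable:
    """Parse a GENEPOP file into diploid allele counts per island per locus.

    Populations are named by the label of their last individual (the usual
    GENEPOP convention) unless ``island_order`` supplies names positionally.
    Allele codes 00/000 are missing data: that individual contributes nothing
    to that locus's copy number.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty GENEPOP file")
    loci, first_pop = _parse_genepop_loci(lines)
    pops: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for lineno, raw in enumerate(lines[first_pop:], start=first_pop + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            current = []
            pops.append(current)
            continue
        if current is None:
            raise ValidationError(f"{path}:{lineno}: sample line before first Pop")
        if "," in line:
            label, geno = line.split(",", 1)
        else:
            label, geno = "", line
        genos = geno.split()
        if len(genos) != len(loci):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(loci)} genotypes, got {len(genos)}"
            )
        for g in genos:
            if len(g) % 2 != 0 or len(g) not in (4, 6):
                raise ValidationError(
                    f"{path}:{lineno}: genotype '{g}' is not a 2x2- or 2x3-digit code"
                )
        current.append((label.strip(), genos))

    rows = []
    for p, samples in enumerate(pops):
        if not samples:
            continue
        if island_order is not None:
            island = island_order[p]
        else:
            island = samples[-1][0] or f"pop{p + 1}"
        counts: dict[tuple[str, str], int] = {}
        for _, genos in samples:
            for locus, g in zip(loci, genos):
                half = len(g) // 2
                for allele in (g[:half], g[half:]):
                    if set(allele) == {"0"}:
                        continue
                    counts[(locus, allele)] = counts.get((locus, allele), 0) + 1
        for (locus, allele), c in sorted(counts.items()):
            rows.append({"species": species, "marker_type": marker_type, "ploidy": 2,
                         "locus": locus, "island": island, "allele": allele, "count": c})
    return AlleleCountTable(pd.DataFrame(rows, columns=GENETIC_COLUMNS))


def write_genepop(table: AlleleCountTable, path: str | Path,
                  title: str = "reefcomposite export", digits: int = 3) -> None:
    """Write diploid counts as a GENEPOP file (inverse of :func:`read_genepop`).

    Copies are paired arbitrarily into pseudo-individuals; an odd copy pairs
    with a missing code. Counts round-trip exactly; individuals do not.
    """
    df = table.data
    if (df["ploidy"] != 2).any():
        raise ValidationError("write_genepop requires diploid data")
    loci = sorted(df["locus"].unique())
    missing = "0" * digits
    out = [title]
    out.extend(loci)
    for island in sorted(df["island"].unique()):
        sub = df[df["island"] == island]
        per_locus: dict[str, list[str]] = {}
        for locus in loci:
            alleles: list[str] = []
            for _, row in sub[sub["locus"] == locus].iterrows():
                alleles.extend([str(row["allele"]).zfill(digits)] * int(row["count"]))
            per_locus[locus] = alleles
        n_ind = max(
            (math.ceil(len(v) / 2) for v in per_locus.values()), default=0
        )
        out.append("Pop")
        for i in range(n_ind):
            genos = []
            for locus in loci:
                alleles = per_locus[locus]
                a = alleles[2 * i] if 2 * i < len(alleles) else missing
                b = alleles[2 * i + 1] if 2 * i + 1 < len(alleles) else missing
                genos.append(a + b)
            out.append(f"{island}, " + " ".join(genos))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# seascape / traits CSV
# ---------------------------------------------------------------------------

def read_seascape(path: str | Path) -> SeascapeTable:
    """Read the island-level predictor CSV.

    Applies the standard transforms where raw values are stored:
    ``habitat_area_t = log10(habitat_area + 1)`` and, when a raw
    ``habitat_area_lgm`` column is present, ``lgm_loss`` via
    :func:`reefcomposite.seascape_models.lgm_loss`.
    """
    df = pd.read_csv(path)
    if "habitat_area_lgm" in df.columns and "lgm_loss" not in df.columns:
        from .seascape_models import lgm_loss as _lgm
        df["lgm_loss"] = [
            _lgm(l, p) for l, p in zip(df["habitat_area_lgm"], df["habitat_area"])
        ]
    return SeascapeTable(df)


def read_traits(path: str | Path) -> TraitTable:
    return TraitTable(pd.read_csv(path))
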