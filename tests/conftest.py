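import numpy as np
import pandas as pd
import pytest

from reefcomposite import (
    AlleleCountTable,
    composite_ar,
    generate_scenario,
    species_island_ar,
)
from reefcomposite.io_formats import GENETIC_COLUMNS


def make_table(rows):
    """Build an AlleleCountTable from (species, marker, ploidy, locus, island,
    allele, count) tuples."""
    return AlleleCountTable(pd.DataFrame(rows, columns=GENETIC_COLUMNS))


@pytest.fixture
def tiny_table():
    """One haploid species on three islands with known allele counts."""
    rows = []
    for island, counts in {"A": {"h1": 5, "h2": 3}, "B": {"h1": 8},
                           "C": {"h1": 4, "h2": 4, "h3": 2}}.items():
        for allele, c in counts.items():
            rows.append(("sp1", "COI", 1, "COI", island, allele, c))
    return make_table(rows)


@pytest.fixture(scope="session")
def habitat_run():
    """One habitat_driver scenario taken through AR and the composite."""
    seascape, table, traits, truth = generate_scenario("habitat_driver", seed=11)
    ar = species_island_ar(table)
    comp = composite_ar(ar, seed=11)
    return {"seascape": seascape, "table": table, "traits": traits,
            "truth": truth, "ar": ar, "comp": comp}


def enumeration_ar(counts, g):
    """Independent oracle: exhaustive mean distinct alleles over all C(N, g)
    subsets of the labelled gene copies."""
    from itertools import combinations
    labels = []
    for a, c in enumerate(counts):
        labels.extend([a] * c)
    vals = [len(set(sub)) for sub in combinations(range(len(labels)), g)]
    labelled = [tuple(labels[i] for i in sub)
                for sub in combinations(range(len(labels)), g)]
    return float(np.mean([len(set(t)) for t in labelled])) if vals else 0.0
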