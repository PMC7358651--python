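import numpy as np
import pandas as pd
import pytest

import haplodyn as hd
from haplodyn.alignment_io import HaplotypeTable


@pytest.fixture(scope="session")
def study():
    """The eight-population synthetic study: alignment, table, truth."""
    aln, pops, truth = hd.make_study_dataset(seed=11)
    return aln, pops, truth


@pytest.fixture(scope="session")
def study_table(study):
    aln, pops, _ = study
    return hd.collapse_haplotypes(aln, pops)


@pytest.fixture(scope="session")
def study_distances(study_table):
    hap = hd.pairwise_distances(study_table.haplotypes)
    ind = hd.individual_distance_matrix(study_table, hap)
    return hap, ind


def make_haplotype_table(counts: pd.DataFrame) -> HaplotypeTable:
    """Build a HaplotypeTable directly from a population x haplotype
    count frame (dummy sequences; callers supply distances)."""
    assignments = {}
    for pop in counts.index:
        i = 0
        for hap in counts.columns:
            for _ in range(int(counts.loc[pop, hap])):
                assignments[f"{pop}_{i}"] = hap
                i += 1
    return HaplotypeTable(
        haplotypes={h: "" for h in counts.columns},
        counts=counts,
        assignments=pd.Series(assignments),
        S=0,
        n_indel_chars=0,
    )


def random_symmetric_distances(k: int, rng: np.random.Generator) -> np.ndarray:
    d = rng.integers(1, 10, size=(k, k)).astype(float)
    d = np.triu(d, 1)
    d = d + d.T
    return d
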