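"""Shared fixtures: small populations, toy plot tables and kinships."""

import numpy as np
import pandas as pd
import pytest

from sparsegp.genotypes import GenotypeMatrix, KinshipMatrix
from sparsegp.synthetic_data import (
    PopulationSpec,
    simulate_families,
    simulate_founder_genotypes,
)


@pytest.fixture(scope="session")
def small_population():
    """~60 lines from 12 crosses of 20 founders, 500 markers."""
    pop = PopulationSpec(
        n_founders=20, n_markers=500, n_crosses=12, family_size_range=(3, 7), seed=42
    )
    founders = simulate_founder_genotypes(pop)
    geno, ped = simulate_families(founders, pop)
    return pop, founders, geno, ped


@pytest.fixture
def toy_kinship():
    lines = [f"L{i}" for i in range(4)]
    K = np.eye(4) + 0.25 * (np.ones((4, 4)) - np.eye(4))
    return KinshipMatrix(lines, K, "genomic")


def make_plot_table(n_lines=6, envs=("SE1", "SE2"), n_reps=2, n_blocks=2, seed=0,
                    values=None):
    """Minimal balanced plot table: one trial per env, lines x reps."""
    rng = np.random.default_rng(seed)
    lines = [f"L{i}" for i in range(n_lines)]
    rows = []
    for e in envs:
        i = 0
        for rep in range(1, n_reps + 1):
            perm = rng.permutation(n_lines)
            for j, li in enumerate(perm):
                block = 1 + j * n_blocks // n_lines
                rows.append((lines[li], e, 1, "T1", rep, block, 1, i + 1, 0.0))
                i += 1
    df = pd.DataFrame(
        rows,
        columns=["line", "env", "year", "trial", "rep", "block", "row", "col", "value"],
    )
    if values is not None:
        df["value"] = values
    else:
        df["value"] = rng.standard_normal(len(df))
    return df


@pytest.fixture
def toy_plot_table():
    return make_plot_table()


def simple_genotypes(dosages, lines=None, markers=None):
    dosages = np.asarray(dosages, dtype=float)
    lines = lines or [f"L{i}" for i in range(dosages.shape[0])]
    markers = markers or [f"M{j}" for j in range(dosages.shape[1])]
    return GenotypeMatrix(lines, markers, dosages)
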