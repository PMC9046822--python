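"""Shared fixtures: a small simulated population reused across test modules.

Everything is generated programmatically from fixed seeds; session scope
keeps the suite fast without coupling tests (fixtures are treated as
read-only inputs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from salmogs import SimulationConfig
from salmogs.containers import Pedigree, TraitModel
from salmogs.simulate import (make_progeny, mate_partial_factorial,
                              simulate_founders, simulate_genome)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        n_chromosomes=1, chromosome_length_bp=10_000_000, n_markers=300,
        n_qtl=60, n_founders=80, families_per_year=20,
        pooled_progeny_per_year=400, progeny_genotyped_per_year=200, seed=42)


@pytest.fixture(scope="session")
def tiny_map(tiny_config):
    return simulate_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_founders(tiny_config, tiny_map):
    return simulate_founders(tiny_map, tiny_config)


@pytest.fixture(scope="session")
def family_population(tiny_config, tiny_map, tiny_founders):
    """Founders + one generation of full-sib families with known pedigree."""
    rng = np.random.default_rng(7)
    sires = tiny_founders.ids[:10]
    dams = tiny_founders.ids[40:50]
    matings = mate_partial_factorial(sires, dams, 20, rng)
    offspring, rows = make_progeny(matings, tiny_founders, tiny_map, 10, rng)
    ped_rows = pd.DataFrame({
        "id": tiny_founders.ids, "sire": None, "dam": None,
        "sex": ["M"] * 40 + ["F"] * 40, "year_class": 0})
    off_rows = rows.assign(sex="M", year_class=1)[
        ["id", "sire", "dam", "sex", "year_class"]]
    pedigree = Pedigree(pd.concat([ped_rows, off_rows], ignore_index=True))
    return {
        "matings": matings,
        "founders": tiny_founders,
        "offspring": offspring,
        "all_haplotypes": tiny_founders.concat(offspring),
        "pedigree": pedigree,
        "marker_map": tiny_map,
    }


@pytest.fixture(scope="session")
def univariate_model() -> TraitModel:
    return TraitModel(("weight_marine",), [[0.44]], [[0.10]], [[0.46]])
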