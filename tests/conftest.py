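"""Shared fixtures: synthetic batches exercised by several test modules.

Expensive preprocessed batches are session-scoped; all generation is
seeded so the suite is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

import spartakit as sk
from spartakit.simulate import (
    PopulationSpec,
    et_cargo,
    generate_blanks,
    generate_particle_set,
    polymersome_carrier,
)


@pytest.fixture(scope="session")
def grid() -> sk.WavenumberGrid:
    return sk.WavenumberGrid.default()


@pytest.fixture(scope="session")
def config() -> sk.AnalysisConfig:
    return sk.AnalysisConfig()


def make_processed_batch(
    config: sk.AnalysisConfig,
    grid: sk.WavenumberGrid,
    seed: int,
    loading_mode: str = "membrane",
    loading_strength: float = 0.8,
    n_particles: int = 300,
    outlier_fraction: float = 0.0,
    **spec_kwargs,
):
    """Generate, preprocess and return (processed, truth-aligned-to-kept, report)."""
    spec = PopulationSpec(
        n_particles=n_particles,
        loading_mode=loading_mode,
        loading_strength=loading_strength,
        outlier_fraction=outlier_fraction,
        seed=seed,
        **spec_kwargs,
    )
    raw, truth = generate_particle_set(
        spec, polymersome_carrier(), et_cargo(), grid, cargo_window=config.cargo_window
    )
    blanks = generate_blanks(grid=grid, seed=seed + 10_000)
    processed, report = sk.run_preprocess(raw, blanks, config)
    return processed, truth[report.mask].reset_index(drop=True), report


@pytest.fixture(scope="session")
def et_two_pop(config, grid):
    """Membrane-loaded batch with a planted 10% highly loaded subpopulation."""
    return make_processed_batch(config, grid, seed=1, outlier_fraction=0.10)


@pytest.fixture(scope="session")
def et_one_pop(config, grid):
    """Matched single-population batch (same settings, no outliers)."""
    return make_processed_batch(config, grid, seed=51, outlier_fraction=0.0)


@pytest.fixture(scope="session")
def core_batch(config, grid):
    """Size-independent core-loaded batch (flat scatter)."""
    return make_processed_batch(
        config, grid, seed=13, loading_mode="core_empirical", loading_strength=5.0
    )


@pytest.fixture(scope="session")
def two_pop_nnmf(et_two_pop, config):
    processed, _truth, _report = et_two_pop
    result = sk.nnmf_two_factor(processed, config)
    result = sk.order_factors(result, config.carrier_window, config.cargo_window, processed.grid)
    sk.assign_clusters(result)
    return result


@pytest.fixture(scope="session")
def one_pop_nnmf(et_one_pop, config):
    processed, _truth, _report = et_one_pop
    result = sk.nnmf_two_factor(processed, config)
    result = sk.order_factors(result, config.carrier_window, config.cargo_window, processed.grid)
    sk.assign_clusters(result)
    return result


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
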