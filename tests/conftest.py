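"""Shared fixtures: small simulated designs, panels and cohorts."""

import pytest

import twindmr as t


@pytest.fixture(scope="session")
def design500():
    """A 500-region design at realistic tiling density (~5200 probes)."""
    return t.generate_array_design(500, (8, 12), 0.05, seed=11)


@pytest.fixture(scope="session")
def panel500(design500):
    """Sorted-cell panel on design500 with 40 planted marker regions."""
    return t.generate_cell_reference(
        design500, n_marker_regions=40, n_replicates=3, noise_sd=0.02, seed=12
    )


@pytest.fixture(scope="session")
def planted_cohort(design500, panel500):
    """5 twin pairs with one planted DMR (delta 0.15) and noise 0.05."""
    _, _, truth = panel500
    cfg = t.SimulationConfig(
        n_pairs=5, n_regions=500, planted_dmrs=[t.PlantedDMR(7, 0.15)], noise_sd=0.05, seed=13
    )
    return t.simulate_twin_cohort(design500, truth.profiles, cfg)


@pytest.fixture(scope="session")
def null_cohort(design500, panel500):
    """All-null cohort: no planted DMRs, mixture + noise only."""
    _, _, truth = panel500
    cfg = t.SimulationConfig(n_pairs=5, n_regions=500, noise_sd=0.05, seed=14)
    return t.simulate_twin_cohort(design500, truth.profiles, cfg)


@pytest.fixture(scope="session")
def small_exact():
    """Mixture-free, noiseless cohort for exact-identity checks."""
    design = t.generate_array_design(30, (10, 10), 0.1, seed=21)
    _, _, truth = t.generate_cell_reference(
        design, n_marker_regions=0, n_replicates=1, noise_sd=0.0,
        baseline_range=(0.25, 0.65), seed=22,
    )
    cfg = t.SimulationConfig(
        n_pairs=5, n_regions=30, dirichlet_alpha=None, noise_sd=0.0,
        planted_dmrs=[t.PlantedDMR(4, 0.15)], seed=23,
    )
    meth, cohort, gt = t.simulate_twin_cohort(design, truth.profiles, cfg)
    return design, meth, cohort, gt
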