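import numpy as np
import pytest

from msocc import (
    DetectionData,
    FamilyLayout,
    HyperParams,
    McmcConfig,
    PriorConfig,
    SpeciesParams,
    StudyDesign,
    run_mcmc,
    simulate_dataset,
)


def toy_design(n_species=1, n_sites=1, n_years=1, n_visits=3,
               treatment=None, district=None, date=150.0) -> StudyDesign:
    """Minimal hand-built design with constant dates (scaled date = 0)."""
    treatment = np.zeros(n_sites, int) if treatment is None else np.asarray(treatment)
    district = np.zeros(n_sites, int) if district is None else np.asarray(district)
    return StudyDesign(
        n_species=n_species, treatment=treatment, district=district,
        date_raw=np.full((n_sites, n_years, n_visits), float(date)),
    )


def toy_data(design: StudyDesign, y=None) -> DetectionData:
    shape = (design.n_species, design.n_sites, design.n_years, design.n_visits)
    if y is None:
        y = np.zeros(shape, dtype=int)
    return DetectionData(y=np.asarray(y).reshape(shape), design=design)


@pytest.fixture(scope="session")
def small_fit():
    """A quick 2-chain fit on a small simulated dataset, shared by the
    sampler/diagnostics/stats tests."""
    data, truth = simulate_dataset(
        seed=5, n_species=8, n_sites_per_cell=2, n_years=2, n_visits=3
    )
    cfg = McmcConfig(n_chains=2, n_iter=900, n_burnin=450, thin=3, seed=5)
    draws = run_mcmc(data, PriorConfig(), cfg)
    return data, truth, draws
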