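import numpy as np
import pytest

from histospat.geometry import SetCovariance, Window, rasterize_window
from histospat.pipeline import run_pipeline
from histospat.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_window():
    return Window()


@pytest.fixture(scope="session")
def default_set_cov(default_window):
    mask = rasterize_window(default_window, 1.0)
    return SetCovariance(mask, 1.0)


@pytest.fixture(scope="session")
def holed_window():
    holes = (
        np.array([[100.0, 100.0], [220.0, 110.0], [200.0, 230.0], [110.0, 210.0]]),
        np.array([[500.0, 400.0], [560.0, 420.0], [540.0, 480.0], [495.0, 460.0]]),
    )
    return Window(holes=holes)


@pytest.fixture(scope="session")
def regime_interaction_means():
    """Per-pattern mean interaction distances for CSR vs clustered regimes.

    Six patterns per regime, each augmented with CSR 'random cells' and
    resampled into 15 Cochran-sized realizations per mark, profile-fitted.
    """
    from histospat.geyer import GeyerParams, make_dummy_grid, simulate_geyer
    from histospat.geometry import simulate_csr
    from histospat.randomization import (
        augment_with_random_cells,
        fit_realization_set,
        make_realizations,
        mean_interaction_distance,
    )

    w = Window()
    dg = make_dummy_grid(w)
    prm = GeyerParams(beta=5.4e-4, gamma=1.6, r=9.0, sat=2)
    out = {"random": [], "clustered": [], "random_rc": [], "clustered_rc": []}
    rng = np.random.default_rng(22)
    for _ in range(6):
        for regime in ("random", "clustered"):
            if regime == "random":
                p = simulate_csr(w, 7e-4, rng, mark="tumor")
            else:
                p = simulate_geyer(w, prm, seed=int(rng.integers(2**31)))
            aug = augment_with_random_cells(p, rng)
            for mark, key in (("cells", regime), ("random_cells", regime + "_rc")):
                rs = make_realizations(aug, mark, n_real=15, seed=rng)
                fit_realization_set(rs, dummy_grid=dg)
                out[key].append(mean_interaction_distance(rs))
    return out


@pytest.fixture(scope="session")
def cohort_pipeline_runs():
    """Full pipeline results for five master seeds (shared across tests)."""
    runs = []
    for seed in range(1, 6):
        records, truth = generate_cohort(CohortConfig(master_seed=seed))
        result = run_pipeline(records, seed=seed)
        runs.append({"seed": seed, "records": records, "truth": truth, "result": result})
    return runs
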