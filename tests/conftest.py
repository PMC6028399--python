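import numpy as np
import pandas as pd
import pytest

import scalediv as sd


@pytest.fixture(scope="session")
def toy_tree():
    """((A:1,B:1):1,C:2) — the hand-evaluated FD example tree."""
    return sd.FunctionalDendrogram.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_traits():
    return sd.generate_trait_table(12, seed=42)


@pytest.fixture(scope="session")
def small_routes():
    return sd.generate_routes(n_routes=25, n_bcrs=2, extent_km=600, seed=7, years=[1969, 1970, 1971])


@pytest.fixture(scope="session")
def fitted_occupancy():
    """One moderate occupancy fit shared across tests (15 species x 100 routes)."""
    routes = sd.generate_routes(100, 3, seed=3, years=[2000])
    hp = {"mu_beta0": -0.5, "sd_beta0": 1.0, "mu_beta1": 0.0, "sd_beta1": 0.5,
          "mu_alpha0": 0.3, "sd_alpha0": 0.5}
    params = sd.generate_species_params(15, hp, seed=4)
    dets = sd.simulate_detection_histories(params, routes, [2000], seed=5)[0]
    cfg = sd.OccupancyConfig(chains=3, draws=1500, warmup=800)
    res = sd.fit_multispecies_occupancy(dets, routes, cfg, seed=11)
    return {"routes": routes, "params": params, "detections": dets, "results": res}
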