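import numpy as np
import pytest
from hypothesis import settings

from bstmap import ModelSpec, generate_area_graph, simulate_panel

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid9():
    graph, polygons = generate_area_graph(9, layout="grid", seed=0)
    return graph, polygons


@pytest.fixture(scope="session")
def small_panel():
    """A 10-area × 6-year panel with BYM + RW2 + type I structure and 2 covariates."""
    graph, _ = generate_area_graph(10, seed=1)
    spec = ModelSpec(covariate_names=("x1", "x2"))
    panel, covariates, truth = simulate_panel(
        graph, n_years=6, spec=spec, effect_sizes=np.array([0.4, -0.2]), seed=11
    )
    return graph, panel, covariates, truth
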