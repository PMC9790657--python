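import numpy as np
import pandas as pd
import pytest

from tmmp import ModelConfig, ObservationTable, TimeGrid, TMMPModel


@pytest.fixture
def grid10():
    return TimeGrid(T=10)


@pytest.fixture
def conjugate_toy():
    """1-population, T=5, identity transform, IID smoother with fixed
    scale, normal data with known sds: fully conjugate."""
    T = 5
    grid = TimeGrid(T=T)
    cfg = ModelConfig({
        "transform": "identity",
        "smoothing": {"basis": "identity", "kernel": "iid",
                      "kernel_params": {"sigma": 1.0}, "r": 0,
                      "constraint": "none"},
        "data_model": {"family": "normal", "variance": "fixed"},
        "hierarchy": {"kernel_scale": {"strategy": "fixed"}},
    })
    rng = np.random.default_rng(3)
    truth = rng.normal(0, 1, T)
    sd = 0.5
    rows = [
        {"population": "A", "time": t, "value": rng.normal(truth[t - 1], sd),
         "sampling_sd": sd, "source": "s"}
        for t in range(1, T + 1) for _ in range(2)
    ]
    df = pd.DataFrame(rows)
    data = ObservationTable(df.copy(), grid)
    model = TMMPModel(cfg, grid, ["A"])
    # analytic posterior: prior N(0,1), two obs per cell with sd 0.5
    prec = 1.0 + 2.0 / sd**2
    post_mean = df.groupby("time")["value"].sum().values / sd**2 / prec
    return model, data, post_mean, 1.0 / prec
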