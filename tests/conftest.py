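import numpy as np
import pandas as pd
import pytest

import dsempanel as dp


@pytest.fixture
def tiny_scores_csv(tmp_path):
    """2 participants x 3 weeks, week 2 missing for participant 2."""
    rows = [
        # id, week, bd2, female, age55, rapid, dep, ins, hypo
        (1, 1, 0, 1, 0, 0, 5.0, 2.0, 1.0),
        (1, 2, 0, 1, 0, 0, 6.0, 3.0, 0.0),
        (1, 3, 0, 1, 0, 0, 4.0, 1.0, 2.0),
        (2, 1, 1, 0, 1, 1, 10.0, 4.0, 3.0),
        (2, 3, 1, 0, 1, 1, 11.0, 5.0, 2.0),
    ]
    df = pd.DataFrame(rows, columns=["id", "week", "bd2", "female", "age55", "rapid",
                                     "dep", "ins", "hypo"])
    path = tmp_path / "panel.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def small_univariate_fit():
    """Shared small univariate fit on a calibrated synthetic panel."""
    spec = dp.calibrated_spec(("dep",))
    panel, truth = dp.simulate_panel(
        dp.GeneratorConfig(spec=spec, n=50, n_weeks=70, seed=101)
    )
    res = dp.DsemModel(panel, processes=("dep",)).fit(
        chains=2, iterations=400, burn=400, seed=202
    )
    return spec, panel, truth, res
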