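import numpy as np
import pandas as pd
import pytest

import darkmir as dm


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """Small but fully featured study design for fast pipeline tests."""
    return dm.SimulationConfig(
        n_mirna=6,
        n_targets=24,
        n_edges_per_mirna=4,
        n_normal=15,
        n_cancer=30,
        n_driver_edges=4,
        n_dm_mirna=2,
        n_diff_mirna=2,
        seed=7,
    )


@pytest.fixture
def tiny_sim(tiny_config):
    return dm.simulate(tiny_config)


def _expr(values, molecule_class="miRNA", prefix="f", cohort="c",
          is_log=False):
    values = np.asarray(values, dtype=float)
    idx = [f"{prefix}{i}" for i in range(values.shape[0])]
    cols = [f"s{i}" for i in range(values.shape[1])]
    return dm.ExpressionMatrix(
        pd.DataFrame(values, index=idx, columns=cols),
        molecule_class, cohort, is_log=is_log,
    )


@pytest.fixture
def make_expr():
    return _expr


@pytest.fixture(scope="session")
def default_run():
    """One fit of the default study design, shared by the slower tests.

    Simulates the default cohorts (seed 0), fits the perturbation model for
    both target classes, and computes miRNA differential expression.
    """
    sim = dm.simulate(dm.SimulationConfig(seed=0))
    results = {
        tclass: dm.SampleNetworkModel.from_simulation(sim, tclass).fit()
        for tclass in ("mRNA", "lncRNA")
    }
    de = dm.differential_expression(
        sim.expr_mirna_cancer, sim.expr_mirna_normal
    )
    return {"sim": sim, "results": results, "de": de}
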