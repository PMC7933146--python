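import numpy as np
import pandas as pd
import pytest

from regact import synthetic
from regact.containers import ExpressionMatrix


@pytest.fixture
def small_network():
    return synthetic.make_truth_network(
        n_regulators=2,
        n_targets_per_regulator=3,
        n_genes=20,
        overlap_fraction=0.0,
        seed=1,
        effect_range=(1.0, 1.0),
    )


@pytest.fixture
def dev_cohort():
    """Developmental-style cohort: one population, per-sample activity jitter."""
    net = synthetic.make_truth_network(4, 10, 120, seed=3)
    expr, truth = synthetic.simulate_expression_cohort(
        net,
        groups={"dev": 60},
        activity_profiles={"dev": {r: 0.0 for r in net.regulators}},
        noise_sd=0.4,
        seed=4,
        activity_sd=1.0,
    )
    return net, expr, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_expression(rng, n_genes=30, n_samples=12, unit="log2fpkm"):
    values = rng.standard_normal((n_genes, n_samples))
    if unit in ("counts", "fpkm"):
        values = np.abs(values) * 10
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i:03d}" for i in range(n_genes)],
            columns=[f"s{i:02d}" for i in range(n_samples)],
        ),
        unit=unit,
    )
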