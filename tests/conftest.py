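import logging

import numpy as np
import pytest

import hiscom_mimi as hm

logging.getLogger("hiscom_mimi").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def s1_spec():
    return hm.make_scenario(1)


@pytest.fixture(scope="session")
def s1_null_data(s1_spec):
    """One Scenario-1 null replicate (n = 114, all effects zero)."""
    return hm.simulate_dataset(s1_spec, 20250901)


@pytest.fixture(scope="session")
def s1_net(s1_spec, s1_null_data):
    return hm.scenario_network(s1_spec, s1_null_data)


@pytest.fixture(scope="session")
def strong_signal():
    """Scenario-1 data with a large causal effect, plus its fixed layout."""
    import dataclasses

    spec = dataclasses.replace(hm.make_scenario(1), effect_beta=1.0)
    data = hm.simulate_dataset(spec, 77)
    return spec, data, hm.scenario_network(spec)


def singleton_net(mirna_ids):
    """Direct-effect-only components (one miRNA each, no mRNAs)."""
    return hm.SubnetworkMap(
        entries=[
            hm.SubnetworkEntry(mirna_id=m, mrna_ids=[], r=np.empty(0), p=np.empty(0))
            for m in mirna_ids
        ]
    )


def random_logistic_dataset(rng, n=80, j=4, beta_scale=0.8):
    """Small dataset whose phenotype depends only on the miRNA columns."""
    Z = rng.standard_normal((n, j))
    X = rng.standard_normal((n, 2))
    coefs = beta_scale * rng.standard_normal(j)
    y = (rng.random(n) < 1 / (1 + np.exp(-(Z @ coefs)))).astype(int)
    if y.min() == y.max():  # re-draw pathological single-class labels
        y[: n // 2] = 1 - y[: n // 2]
    return hm.ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        mirna_ids=[f"m{k}" for k in range(j)],
        mrna_ids=["gA", "gB"],
        Z=Z,
        X=X,
        y=y,
    )
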