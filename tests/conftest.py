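import numpy as np
import pandas as pd
import pytest

import crashmix as cm


@pytest.fixture(scope="session")
def preset_dataset() -> cm.SyntheticDataset:
    """One mid-sized dataset from the default scenario, shared read-only."""
    return cm.preset_scenario(n=2000, seed=20160101).generate()


@pytest.fixture(scope="session")
def mnl_truth() -> cm.TrueParameters:
    """Fixed-coefficient truth: the generating process is plain MNL."""
    return cm.TrueParameters(
        constants={"NI": 1.2},
        fixed_coefs={
            ("rollover", "SI"): 1.1,
            ("rural", "SI"): -0.6,
            ("fatigue", "MIN"): 0.7,
            ("rear_end", "NI"): -0.5,
        },
    )


@pytest.fixture(scope="session")
def mnl_dataset(mnl_truth) -> cm.SyntheticDataset:
    design = cm.generate_design(
        2500,
        {"rollover": 0.14, "rural": 0.45, "fatigue": 0.02, "rear_end": 0.19},
        seed=99,
    )
    return cm.simulate_outcomes(design, mnl_truth, seed=100)


def mnl_loglik_oracle(data: pd.DataFrame, truth: cm.TrueParameters) -> float:
    """Closed-form multinomial-logit log-likelihood, computed directly.

    Independent of the package's likelihood path: utilities are assembled
    from the truth's coefficient dictionaries and softmaxed by hand.
    """
    alts = list(truth.alternatives)
    n = len(data)
    util = np.zeros((n, len(alts)))
    for a, c in truth.constants.items():
        util[:, alts.index(a)] += c
    for (v, a), b in truth.fixed_coefs.items():
        util[:, alts.index(a)] += b * data[v].to_numpy(dtype=float)
    for (v, a), b in truth.random_means.items():  # means only: sigma == 0 case
        util[:, alts.index(a)] += b * data[v].to_numpy(dtype=float)
    e = np.exp(util - util.max(axis=1, keepdims=True))
    p = e / e.sum(axis=1, keepdims=True)
    idx = data["severity"].map({a: i for i, a in enumerate(alts)}).to_numpy()
    return float(np.log(p[np.arange(n), idx]).sum())
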