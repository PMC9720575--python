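"""Monte-Carlo validation studies for the estimator and the LR test.

These are the package's self-checks on synthetic data with known truth:
parameter recovery (does the root-mean-square error of the random
coefficient's mean and standard deviation shrink as the sample grows?)
and the empirical size of the likelihood-ratio transferability test under
the null of a shared data-generating process.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from . import model as m
from . import posthoc
from .synth import Scenario, preset_scenario

logger = logging.getLogger(__name__)


def recovery_study(
    ns: tuple[int, ...] = (1000, 2500, 5000),
    n_seeds: int = 20,
    n_draws: int = 100,
    base_seed: int = 1,
) -> pd.DataFrame:
    """RMSE of the random coefficient's mean and sigma across sample sizes.

    Per replication one dataset of size max(ns) is generated from the
    preset scenario (one normally distributed random coefficient with one
    mean and one variance shifter) and the model is refitted on its first
    n rows for every n — a nested-sample (common random numbers) design,
    standard for consistency studies: the per-seed estimation errors at
    different n are positively correlated, so the RMSE comparison across
    n is far less noisy than with independent datasets, while each RMSE
    remains an honest average over ``n_seeds`` independent replications.
    Consistency of simulated maximum likelihood shows as RMSE decreasing
    in n.
    """
    n_max = max(ns)
    errors: dict[int, tuple[list, list]] = {n: ([], []) for n in ns}
    for s in range(n_seeds):
        seed = (base_seed * 100003 + 1009 * s) % (2**31)
        scenario = preset_scenario(n=n_max, seed=seed)
        ds = scenario.generate()
        spec = scenario.truth.to_model_spec(n_draws=n_draws)
        (var, alt), = scenario.truth.random_terms
        true_mean = scenario.truth.random_means[(var, alt)]
        true_sd = scenario.truth.random_sds[(var, alt)]
        for n in ns:
            res = m.fit(ds.data.head(n), spec)
            if not res.converged:
                logger.warning("recovery fit (n=%d, seed=%d) not converged",
                               n, seed)
            est = res.estimates.as_dict()
            errors[n][0].append(est[f"beta:{var}[{alt}]"] - true_mean)
            errors[n][1].append(abs(est[f"sigma:{var}[{alt}]"]) - true_sd)
    rows = []
    for n in ns:
        err_mean, err_sd = errors[n]
        rows.append({
            "n": n,
            "rmse_random_mean": float(np.sqrt(np.mean(np.square(err_mean)))),
            "rmse_random_sd": float(np.sqrt(np.mean(np.square(err_sd)))),
            "n_seeds": n_seeds,
            "n_draws": n_draws,
        })
    return pd.DataFrame(rows)


def lr_null_size_study(
    scenario: Scenario | None = None,
    reps: int = 30,
    n_group: int = 1200,
    confidence: float = 0.90,
    base_seed: int = 1,
) -> dict:
    """Empirical size of the transferability test under a shared truth.

    Two groups are simulated from one data-generating process per
    replication; pooled and separate models are fitted and the LR test
    applied.  The separate-model support (rejection) rate should not
    exceed the nominal size 1 - confidence beyond Monte-Carlo noise.
    Fixed-coefficient specs keep each replication cheap; the test statistic
    only consumes the three converged log-likelihoods.
    """
    if scenario is None:
        base = preset_scenario(n=n_group, seed=0)
        truth = replace(base.truth, random_means={}, random_sds={},
                        mean_shifters={}, variance_shifters={},
                        fixed_coefs={**base.truth.fixed_coefs,
                                     ("rural", "SI"): -1.0})
        scenario = Scenario(n=n_group, prevalences=base.prevalences,
                            truth=truth, seed=0)
    spec = scenario.truth.to_model_spec()
    df = m.n_parameters(spec)
    rejections = 0
    for rep in range(reps):
        seed = (base_seed * 90007 + 101 * rep) % (2**31 - 10)
        s1 = replace(scenario, seed=seed)
        s2 = replace(scenario, seed=seed + 5)
        g1, g2 = s1.generate(), s2.generate()
        pooled = pd.concat([g1.data, g2.data], ignore_index=True)
        ll_all = m.fit(pooled, spec).ll_converged
        ll_1 = m.fit(g1.data, spec).ll_converged
        ll_2 = m.fit(g2.data, spec).ll_converged
        res = posthoc.lr_transferability(ll_all, ll_1, ll_2, df=df,
                                         confidence=confidence)
        rejections += res.separate_models_supported
    nominal = 1.0 - confidence
    mc_se = float(np.sqrt(nominal * (1 - nominal) / reps))
    return {
        "reps": reps,
        "confidence": confidence,
        "nominal_size": nominal,
        "rejection_rate": rejections / reps,
        "mc_standard_error": mc_se,
        "within_three_se": rejections / reps <= nominal + 3 * mc_se,
    }
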