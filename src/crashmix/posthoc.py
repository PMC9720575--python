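"""Post-estimation: marginal effects and the transferability LR test.

Marginal effects for indicator covariates are average discrete changes:
for each indicator X, the model probability of every severity alternative
is evaluated with X forced to 1 and to 0 (other covariates at their
observed values) and the difference is averaged over the estimation
sample.  Random coefficients are evaluated at their estimated means.
Since probabilities sum to one in both counterfactuals, each variable's
effects sum to zero across the three alternatives.

The likelihood-ratio transferability test asks whether separately
estimated group models (e.g. in-state vs out-of-state drivers) fit better
than one pooled model:

    LR = -2 [ LL(pooled) - LL(group1) - LL(group2) ]  ~  chi^2(df),

with df the excess parameters of the pair of group models over the pooled
model; the pooled specification is rejected (separate models supported)
when LR exceeds the chi-square critical value at the chosen confidence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    CONST,
    FitResult,
    ModelSpec,
    ParameterVector,
    mean_coefficient_probabilities,
)

logger = logging.getLogger(__name__)


@dataclass
class MarginalEffectsTable:
    """Variable x alternative average discrete-change effects.

    One row per model indicator: the alternative whose utility it enters,
    and its average effect on each alternative's probability.  Effects are
    raw; ``rounded_frame`` reports them to 4 decimals in the style of
    published severity-model tables.
    """

    frame: pd.DataFrame  # variable, defined_for, me_<alt>...
    alternatives: tuple[str, ...]

    def rounded_frame(self, decimals: int = 4) -> pd.DataFrame:
        out = self.frame.copy()
        cols = [f"me_{a}" for a in self.alternatives]
        out[cols] = out[cols].round(decimals)
        return out

    def to_csv(self, path: str | Path, decimals: int = 4) -> None:
        self.rounded_frame(decimals).to_csv(path, index=False)


def marginal_effects(
    fit: FitResult | ParameterVector,
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    respect_mean_shifters: bool = True,
) -> MarginalEffectsTable:
    """Average discrete-change marginal effects of every model indicator.

    For each indicator the whole sample is evaluated at X=1 and X=0 with
    the other covariates untouched (a covariate serving double duty as a
    mean or variance shifter is flipped everywhere, keeping the
    counterfactual coherent).  Random coefficients enter at their
    estimated means — including the delta'z mean shifts per observation by
    default; ``respect_mean_shifters=False`` uses the overall mean only.
    The noise term is always dropped.
    """
    if isinstance(fit, FitResult):
        spec = spec or fit.spec
        theta = fit.estimates
    else:
        if spec is None:
            raise ValueError("spec is required when passing a bare vector")
        theta = fit
    if not respect_mean_shifters:
        logger.info("marginal effects at overall means (delta shifts ignored)")

    variables: list[tuple[str, str]] = []
    for t in spec.terms:
        if t.variable != CONST and (t.variable, t.alternative) not in variables:
            variables.append((t.variable, t.alternative))
    for var, _alt in variables:
        vals = np.unique(data[var].to_numpy())
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(
                f"marginal effects require binary indicators; column "
                f"{var!r} takes values outside {{0, 1}}"
            )

    rows = []
    for var, alt in variables:
        on = data.copy()
        on[var] = 1
        off = data.copy()
        off[var] = 0
        p_on = mean_coefficient_probabilities(
            on, spec, theta, respect_mean_shifters)
        p_off = mean_coefficient_probabilities(
            off, spec, theta, respect_mean_shifters)
        effect = (p_on - p_off).mean(axis=0)
        row = {"variable": var, "defined_for": alt}
        row.update({f"me_{a}": effect[i]
                    for i, a in enumerate(spec.alternatives)})
        rows.append(row)
    return MarginalEffectsTable(frame=pd.DataFrame(rows),
                                alternatives=spec.alternatives)


def chi2_quantile(df: int, p: float) -> float:
    """Inverse chi-square CDF (the critical value at confidence p)."""
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {p}")
    return float(stats.chi2.ppf(p, df))


@dataclass
class TransferabilityResult:
    """Outcome of the pooled-vs-separate likelihood-ratio test."""

    lr_statistic: float
    degrees_of_freedom: int
    confidence: float
    critical_value: float
    separate_models_supported: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def lr_transferability(
    ll_all: float,
    ll_group1: float,
    ll_group2: float,
    df: int,
    confidence: float = 0.9999,
) -> TransferabilityResult:
    """Likelihood-ratio test of separate group models against a pooled one.

    The statistic -2[LL(pooled) - LL(group1) - LL(group2)] is compared to
    the chi-square quantile at ``confidence`` with ``df`` degrees of
    freedom (the extra parameters the pair of group models spends).  A
    slightly negative statistic can arise from simulation noise in the
    separate fits; it is reported as-is with a warning.
    """
    if df <= 0:
        raise ValueError(
            f"degrees of freedom must be positive, got {df}; the pair of "
            f"group models must spend more parameters than the pooled model"
        )
    lr = -2.0 * (ll_all - ll_group1 - ll_group2)
    if lr < 0:
        logger.warning(
            "negative LR statistic (%.4f): pooled fit beat the separate "
            "fits, typically simulation noise", lr,
        )
    crit = chi2_quantile(df, confidence)
    return TransferabilityResult(
        lr_statistic=float(lr),
        degrees_of_freedom=int(df),
        confidence=float(confidence),
        critical_value=crit,
        separate_models_supported=bool(lr > crit),
    )
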