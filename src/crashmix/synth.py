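"""Synthetic crash-severity data with known ground truth.

Real statewide crash databases are restricted, so estimator behaviour is
demonstrated on data generated with exactly the structure the model
assumes: independent (or one-hot) Bernoulli indicator covariates,
normally distributed random coefficients whose means shift with
z-attributes and whose standard deviations scale as sigma * exp(omega'w),
and three-alternative outcomes chosen by argmax of utilities with
independent standard Gumbel errors.  The generating parameters are stored
with every dataset so recovery tests can compare estimates to truth.

Generation is a deterministic function of (truth, design, seed); Gumbel
errors come from the inverse CDF -ln(-ln u) applied to a seeded uniform
stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import CONST, ModelSpec, ParameterVector, Term
from .schema import CrashRecord

_ALT_TO_KABCO = {"SI": "A", "MIN": "C", "NI": "O"}


@dataclass(frozen=True)
class TrueParameters:
    """Generating parameters of the three-alternative utility system.

    ``fixed_coefs`` maps (variable, alternative) to its coefficient;
    ``constants`` maps an alternative to its alternative-specific constant.
    Random coefficients are declared through ``random_means`` and
    ``random_sds`` (strictly positive), with optional mean shifters
    (delta vectors over z-attributes) and variance shifters (omega vectors
    over w-attributes) keyed by the same (variable, alternative) pair.
    """

    constants: Mapping[str, float] = field(default_factory=dict)
    fixed_coefs: Mapping[tuple[str, str], float] = field(default_factory=dict)
    random_means: Mapping[tuple[str, str], float] = field(default_factory=dict)
    random_sds: Mapping[tuple[str, str], float] = field(default_factory=dict)
    mean_shifters: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=dict)
    variance_shifters: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=dict)
    alternatives: tuple[str, ...] = ("SI", "MIN", "NI")
    reference: str = "NI"

    def __post_init__(self) -> None:
        if set(self.random_means) != set(self.random_sds):
            raise ValueError(
                "random_means and random_sds must declare the same terms"
            )
        for key, sd in self.random_sds.items():
            if sd <= 0:
                raise ValueError(
                    f"random coefficient sd must be strictly positive, "
                    f"got {sd} for {key}"
                )
        for name, shifters in (("mean_shifters", self.mean_shifters),
                               ("variance_shifters", self.variance_shifters)):
            unknown = set(shifters) - set(self.random_means)
            if unknown:
                raise ValueError(
                    f"{name} reference non-random terms: {sorted(unknown)}"
                )

    @property
    def random_terms(self) -> tuple[tuple[str, str], ...]:
        return tuple(self.random_means)

    @property
    def variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        keys = list(self.fixed_coefs) + list(self.random_means)
        for var, _alt in keys:
            if var != CONST and var not in seen:
                seen.append(var)
        for shifters in (self.mean_shifters, self.variance_shifters):
            for vec in shifters.values():
                for var in vec:
                    if var not in seen:
                        seen.append(var)
        return tuple(seen)

    def to_model_spec(self, n_draws: int = 1000) -> ModelSpec:
        """The estimation spec matching this truth (same terms, same shape)."""
        terms = [Term(variable=CONST, alternative=a)
                 for a in self.constants]
        terms += [Term(variable=v, alternative=a)
                  for (v, a) in self.fixed_coefs]
        terms += [
            Term(
                variable=v, alternative=a, random=True,
                mean_shifters=tuple(self.mean_shifters.get((v, a), {})),
                variance_shifters=tuple(self.variance_shifters.get((v, a), {})),
            )
            for (v, a) in self.random_means
        ]
        return ModelSpec(
            terms=tuple(terms), alternatives=self.alternatives,
            reference=self.reference, n_draws=n_draws,
            allow_reference_constant=self.reference in self.constants,
        )

    def to_theta(self, spec: ModelSpec | None = None) -> ParameterVector:
        """The packed true parameter vector under ``to_model_spec`` layout."""
        spec = spec or self.to_model_spec()
        values: dict[str, float] = {}
        for a, c in self.constants.items():
            values[f"beta:{CONST}[{a}]"] = c
        for (v, a), b in self.fixed_coefs.items():
            values[f"beta:{v}[{a}]"] = b
        for (v, a), b in self.random_means.items():
            values[f"beta:{v}[{a}]"] = b
            values[f"sigma:{v}[{a}]"] = self.random_sds[(v, a)]
            for z, d in self.mean_shifters.get((v, a), {}).items():
                values[f"delta:{v}[{a}]<-{z}"] = d
            for w, o in self.variance_shifters.get((v, a), {}).items():
                values[f"omega:{v}[{a}]<-{w}"] = o
        return ParameterVector.from_dict(spec, values)


def generate_design(
    n: int,
    prevalences: Mapping[str, float],
    seed: int,
    exclusive_groups: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Draw an n-row table of 0/1 indicator covariates.

    ``prevalences`` gives independent Bernoulli probabilities per column.
    ``exclusive_groups`` optionally adds one-hot blocks: within a group
    the level probabilities must sum to at most 1 and at most one level
    indicator is set per row (the remainder is the all-zero baseline),
    mimicking mutually exclusive categories such as a one-hot primary
    contributing factor.
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    for name, p in prevalences.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(
                f"prevalence for {name!r} must lie in [0, 1], got {p}"
            )
    rng = np.random.default_rng(seed)
    data = {
        name: (rng.random(n) < p).astype(np.int64)
        for name, p in prevalences.items()
    }
    if exclusive_groups:
        for group, levels in exclusive_groups.items():
            probs = np.array(list(levels.values()), dtype=float)
            if (probs < 0).any() or probs.sum() > 1.0 + 1e-12:
                raise ValueError(
                    f"one-hot group {group!r} level probabilities must be "
                    f"non-negative and sum to at most 1"
                )
            cut = np.concatenate([[0.0], np.cumsum(probs)])
            u = rng.random(n)
            for i, name in enumerate(levels):
                data[name] = ((u >= cut[i]) & (u < cut[i + 1])).astype(np.int64)
    return pd.DataFrame(data)


def realize_coefficients(
    truth: TrueParameters,
    design: pd.DataFrame,
    noise: Mapping[tuple[str, str], np.ndarray] | np.ndarray,
) -> pd.DataFrame:
    """Per-observation coefficients under the heterogeneity structure.

    Each random coefficient is beta + delta'z + sigma * exp(omega'w) * v
    with the supplied standard-normal ``noise`` (one column or array entry
    per random term); fixed coefficients pass through unchanged.  Returns
    one column per (variable, alternative) coefficient.
    """
    n = len(design)
    if isinstance(noise, np.ndarray):
        noise_arr = np.atleast_2d(noise.T).T.reshape(n, -1)
        noise = {key: noise_arr[:, i]
                 for i, key in enumerate(truth.random_terms)}
    missing = set(truth.random_terms) - set(noise)
    if missing:
        raise ValueError(f"noise missing for random terms: {sorted(missing)}")
    out: dict[str, np.ndarray] = {}
    for a, c in truth.constants.items():
        out[f"{CONST}[{a}]"] = np.full(n, float(c))
    for (v, a), b in truth.fixed_coefs.items():
        out[f"{v}[{a}]"] = np.full(n, float(b))
    for (v, a), b in truth.random_means.items():
        mean = np.full(n, float(b))
        for z, d in truth.mean_shifters.get((v, a), {}).items():
            mean = mean + d * design[z].to_numpy(dtype=float)
        log_scale = np.zeros(n)
        for w, o in truth.variance_shifters.get((v, a), {}).items():
            log_scale = log_scale + o * design[w].to_numpy(dtype=float)
        sd = truth.random_sds[(v, a)] * np.exp(log_scale)
        out[f"{v}[{a}]"] = mean + sd * np.asarray(noise[(v, a)], dtype=float)
    return pd.DataFrame(out, index=design.index)


@dataclass
class SyntheticDataset:
    """Generated records plus the truth and realizations that produced them."""

    data: pd.DataFrame            # covariates + 'severity' outcome column
    truth: TrueParameters
    seed: int
    realized_params: pd.DataFrame  # per-observation coefficients used

    @property
    def n(self) -> int:
        return len(self.data)

    def outcome_shares(self) -> pd.Series:
        return (self.data["severity"].value_counts(normalize=True)
                .reindex(self.truth.alternatives, fill_value=0.0))

    def to_records(self, license_state: str = "AL") -> list[CrashRecord]:
        """View as crash records (severity mapped back into KABCO codes)."""
        recs = []
        indicator_cols = [c for c in self.data.columns if c != "severity"]
        for _, row in self.data.iterrows():
            attrs = {c: str(int(row[c])) for c in indicator_cols}
            recs.append(CrashRecord(
                severity_kabco=_ALT_TO_KABCO[row["severity"]],
                license_state=license_state,
                attributes=attrs,
            ))
        return recs

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def simulate_outcomes(
    design: pd.DataFrame,
    truth: TrueParameters,
    seed: int | None,
) -> SyntheticDataset:
    """Generate outcomes from Gumbel-error utilities under the truth.

    Per row, utility of each alternative is the systematic part (realized
    coefficients times covariates) plus an independent standard Gumbel
    draw; the outcome is the argmax alternative.  A seed is mandatory:
    regeneration with the same (design, truth, seed) is bit-for-bit
    identical.
    """
    if seed is None:
        raise ValueError("simulate_outcomes requires an explicit seed")
    missing = [v for v in truth.variables if v not in design.columns]
    if missing:
        raise KeyError(f"design is missing variables the truth references: "
                       f"{missing}")
    n = len(design)
    rng = np.random.default_rng(seed)
    noise = {key: rng.standard_normal(n) for key in truth.random_terms}
    coefs = realize_coefficients(truth, design, noise)

    alts = truth.alternatives
    util = np.zeros((n, len(alts)))
    alt_pos = {a: i for i, a in enumerate(alts)}
    for col in coefs.columns:
        var = col[:col.index("[")]
        alt = col[col.index("[") + 1:-1]
        x = (np.ones(n) if var == CONST
             else design[var].to_numpy(dtype=float))
        util[:, alt_pos[alt]] += x * coefs[col].to_numpy()
    u = rng.random((n, len(alts)))
    gumbel = -np.log(-np.log(u))
    total = util + gumbel
    outcome = np.asarray(alts)[total.argmax(axis=1)]

    data = design.copy()
    data["severity"] = outcome
    return SyntheticDataset(data=data, truth=truth, seed=seed,
                            realized_params=coefs)


# ---------------------------------------------------------------------------
# Scenarios


@dataclass(frozen=True)
class Scenario:
    """Declarative recipe: design size, prevalences, truth, seed."""

    n: int
    prevalences: Mapping[str, float]
    truth: TrueParameters
    seed: int
    exclusive_groups: Mapping[str, Mapping[str, float]] | None = None

    def generate(self) -> SyntheticDataset:
        design = generate_design(self.n, self.prevalences, self.seed,
                                 self.exclusive_groups)
        return simulate_outcomes(design, self.truth, self.seed + 1)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        t = self.truth
        return {
            "n": self.n,
            "seed": self.seed,
            "prevalences": dict(self.prevalences),
            "exclusive_groups": (
                {g: dict(l) for g, l in self.exclusive_groups.items()}
                if self.exclusive_groups else None
            ),
            "truth": {
                "alternatives": list(t.alternatives),
                "reference": t.reference,
                "constants": dict(t.constants),
                "fixed_coefs": [
                    {"variable": v, "alternative": a, "value": c}
                    for (v, a), c in t.fixed_coefs.items()
                ],
                "random_coefs": [
                    {
                        "variable": v,
                        "alternative": a,
                        "mean": t.random_means[(v, a)],
                        "sd": t.random_sds[(v, a)],
                        "mean_shifters": dict(t.mean_shifters.get((v, a), {})),
                        "variance_shifters": dict(
                            t.variance_shifters.get((v, a), {})),
                    }
                    for (v, a) in t.random_terms
                ],
            },
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "Scenario":
        n = int(raw["n"])
        if n < 1:
            raise ValueError(f"scenario n must be positive, got {n}")
        tr = raw["truth"]
        fixed = {(e["variable"], e["alternative"]): float(e["value"])
                 for e in tr.get("fixed_coefs", [])}
        rand = tr.get("random_coefs", [])
        truth = TrueParameters(
            constants={a: float(c) for a, c in tr.get("constants", {}).items()},
            fixed_coefs=fixed,
            random_means={(e["variable"], e["alternative"]): float(e["mean"])
                          for e in rand},
            random_sds={(e["variable"], e["alternative"]): float(e["sd"])
                        for e in rand},
            mean_shifters={
                (e["variable"], e["alternative"]): dict(e.get("mean_shifters", {}))
                for e in rand if e.get("mean_shifters")
            },
            variance_shifters={
                (e["variable"], e["alternative"]): dict(
                    e.get("variance_shifters", {}))
                for e in rand if e.get("variance_shifters")
            },
            alternatives=tuple(tr.get("alternatives", ("SI", "MIN", "NI"))),
            reference=tr.get("reference", "NI"),
        )
        return cls(
            n=n,
            prevalences=dict(raw.get("prevalences", {})),
            truth=truth,
            seed=int(raw["seed"]),
            exclusive_groups=raw.get("exclusive_groups") or None,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def preset_scenario(n: int = 7000, seed: int = 20160101) -> Scenario:
    """Default scenario mirroring the scale of a statewide 5-year extract.

    Roughly 7000 crashes, one normally distributed random coefficient on a
    rural indicator in the severe-injury utility with one mean shifter
    (interstate) and one variance shifter (tree collision), a handful of
    fixed indicators, and a no-injury constant — the structural shape of
    the published in-state model at loosely similar magnitudes.
    """
    truth = TrueParameters(
        constants={"NI": 2.0},
        fixed_coefs={
            ("rollover", "SI"): 1.3,
            ("fatigue", "MIN"): 0.5,
            ("rear_end", "NI"): -0.7,
        },
        random_means={("rural", "SI"): -1.0},
        random_sds={("rural", "SI"): 2.2},
        mean_shifters={("rural", "SI"): {"interstate": -0.6}},
        variance_shifters={("rural", "SI"): {"tree_collision": 0.6}},
    )
    prevalences = {
        "rural": 0.45,
        "interstate": 0.22,
        "tree_collision": 0.02,
        "rollover": 0.14,
        "fatigue": 0.02,
        "rear_end": 0.19,
    }
    return Scenario(n=n, prevalences=prevalences, truth=truth, seed=seed)
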