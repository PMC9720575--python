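"""Mixed multinomial logit with heterogeneity in means and variances.

The three-alternative injury-severity model.  Each crash n has a severity
function per alternative k,

    S_kn = beta_k' X_kn + eps_kn,

with eps_kn i.i.d. extreme value type I (Gumbel), giving multinomial-logit
choice probabilities conditional on the coefficients.  Selected
coefficients are random across crashes with heterogeneity in both moments:

    beta_kn = beta + delta' z_n + sigma * exp(omega' w_n) * v_n,

where z shifts the mean, w scales the standard deviation multiplicatively,
and v is a standard disturbance (normal by default).  Unconditional
probabilities integrate over the mixing distribution; estimation maximises
the simulated log-likelihood, the integral being approximated by averaging
over quasi-random (Halton) draws.

The module provides the declarative :class:`ModelSpec`, the packed
:class:`ParameterVector`, the simulated log-likelihood and its analytic
gradient, the quasi-Newton :func:`fit`, and the fit statistics
(null log-likelihood, McFadden pseudo-rho^2, sign shares of normally
distributed random coefficients).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .draws import DEFAULT_DISCARD, DrawsCube, normal_cube

logger = logging.getLogger(__name__)

CONST = "const"

#: Observation block size for the chunked likelihood/gradient evaluation.
_CHUNK = 2048

#: Floor applied to a simulated probability before taking the log.
PROB_FLOOR = 1e-300

DISTRIBUTIONS = ("normal", "lognormal", "uniform", "triangular")


# ---------------------------------------------------------------------------
# Specification


@dataclass(frozen=True)
class Term:
    """One utility term: a variable attached to exactly one alternative.

    ``variable=="const"`` denotes an alternative-specific constant.  Random
    terms carry a distribution label plus the attribute lists that shift
    the coefficient mean (``mean_shifters``, the z variables) and scale its
    standard deviation (``variance_shifters``, the w variables).
    """

    variable: str
    alternative: str
    random: bool = False
    distribution: str = "normal"
    mean_shifters: tuple[str, ...] = ()
    variance_shifters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"unknown mixing distribution {self.distribution!r}; "
                f"choose from {', '.join(DISTRIBUTIONS)}"
            )
        if not self.random and (self.mean_shifters or self.variance_shifters):
            raise ValueError(
                f"term {self.variable!r} is fixed but declares heterogeneity "
                f"shifters; mark it random"
            )

    @property
    def label(self) -> str:
        return f"{self.variable}[{self.alternative}]"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative three-alternative utility system.

    ``alternatives`` is the ordered outcome list, ``reference`` the
    baseline alternative whose utility carries no constant unless
    ``allow_reference_constant`` is set (the published crash models place
    their single constant on the no-injury baseline, which requires the
    override).  Estimation options ride along so a spec file fully
    reproduces a fit.
    """

    terms: tuple[Term, ...]
    alternatives: tuple[str, ...] = ("SI", "MIN", "NI")
    reference: str = "NI"
    n_draws: int = 1000
    discard: int = DEFAULT_DISCARD
    allow_reference_constant: bool = False
    tol: float = 1e-11
    gtol: float = 1e-5
    max_iter: int = 500
    #: Box half-width for every parameter during optimisation.  Indicator
    #: coefficients of this magnitude are already absurd (odds factors of
    #: e^50), so the bound never binds on a well-posed problem; it exists
    #: to stop quasi-Newton steps running off along weakly identified,
    #: simulation-flat ridges of the likelihood.
    param_bound: float = 50.0

    def __post_init__(self) -> None:
        if self.reference not in self.alternatives:
            raise ValueError(
                f"reference {self.reference!r} not among alternatives "
                f"{self.alternatives}"
            )
        for t in self.terms:
            if t.alternative not in self.alternatives:
                raise ValueError(
                    f"term {t.label} attaches to unknown alternative "
                    f"{t.alternative!r}"
                )
            if (t.variable == CONST and t.alternative == self.reference
                    and not self.allow_reference_constant):
                raise ValueError(
                    f"the reference alternative {self.reference!r} carries no "
                    f"constant; set allow_reference_constant=True to override"
                )
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate term (variable, alternative) pairs")

    @property
    def random_terms(self) -> tuple[Term, ...]:
        return tuple(t for t in self.terms if t.random)

    @property
    def n_random(self) -> int:
        return len(self.random_terms)

    @property
    def variables(self) -> tuple[str, ...]:
        """All data columns the spec references (utilities and shifters)."""
        seen: list[str] = []
        for t in self.terms:
            for v in (t.variable, *t.mean_shifters, *t.variance_shifters):
                if v != CONST and v not in seen:
                    seen.append(v)
        return tuple(seen)

    def with_draws(self, n_draws: int) -> "ModelSpec":
        return replace(self, n_draws=n_draws)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alternatives": list(self.alternatives),
            "reference": self.reference,
            "n_draws": self.n_draws,
            "discard": self.discard,
            "allow_reference_constant": self.allow_reference_constant,
            "terms": [
                {
                    "variable": t.variable,
                    "alternative": t.alternative,
                    "random": t.random,
                    **(
                        {
                            "distribution": t.distribution,
                            "mean_shifters": list(t.mean_shifters),
                            "variance_shifters": list(t.variance_shifters),
                        }
                        if t.random
                        else {}
                    ),
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ModelSpec":
        terms = tuple(
            Term(
                variable=t["variable"],
                alternative=t["alternative"],
                random=t.get("random", False),
                distribution=t.get("distribution", "normal"),
                mean_shifters=tuple(t.get("mean_shifters", ())),
                variance_shifters=tuple(t.get("variance_shifters", ())),
            )
            for t in raw["terms"]
        )
        return cls(
            terms=terms,
            alternatives=tuple(raw.get("alternatives", ("SI", "MIN", "NI"))),
            reference=raw.get("reference", "NI"),
            n_draws=raw.get("n_draws", 1000),
            discard=raw.get("discard", DEFAULT_DISCARD),
            allow_reference_constant=raw.get("allow_reference_constant", False),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Parameter packing


@dataclass(frozen=True)
class ParameterVector:
    """Packed parameter vector with a named layout.

    Order: one beta per term (spec order; constants are the betas of
    ``const`` terms), then per random term its delta block (one entry per
    mean shifter), its sigma, and its omega block (one entry per variance
    shifter).  Sigma is stored unconstrained; the likelihood uses its
    absolute value and reports report the positive scale.
    """

    spec: ModelSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = n_parameters(self.spec)
        if self.values.shape != (expected,):
            raise ValueError(
                f"parameter vector has length {self.values.shape}, spec "
                f"requires {expected}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return parameter_names(self.spec)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    @classmethod
    def from_dict(cls, spec: ModelSpec, values: dict[str, float],
                  default: float = 0.0) -> "ParameterVector":
        names = parameter_names(spec)
        missing = [k for k in values if k not in names]
        if missing:
            raise KeyError(f"unknown parameter names: {missing}")
        vec = np.full(len(names), default, dtype=float)
        for i, name in enumerate(names):
            if name in values:
                vec[i] = values[name]
        return cls(spec=spec, values=vec)


def parameter_names(spec: ModelSpec) -> tuple[str, ...]:
    names = [f"beta:{t.label}" for t in spec.terms]
    for t in spec.random_terms:
        names.extend(f"delta:{t.label}<-{z}" for z in t.mean_shifters)
        names.append(f"sigma:{t.label}")
        names.extend(f"omega:{t.label}<-{w}" for w in t.variance_shifters)
    return tuple(names)


def n_parameters(spec: ModelSpec) -> int:
    return len(parameter_names(spec))


@dataclass(frozen=True)
class _Layout:
    """Index bookkeeping between the packed vector and the spec's terms."""

    beta: np.ndarray          # index of beta per term (spec order)
    delta: tuple[np.ndarray, ...]  # per random term, delta indices
    sigma: np.ndarray         # index of sigma per random term
    omega: tuple[np.ndarray, ...]  # per random term, omega indices


def _layout(spec: ModelSpec) -> _Layout:
    pos = len(spec.terms)
    beta = np.arange(len(spec.terms))
    delta, sigma, omega = [], [], []
    for t in spec.random_terms:
        delta.append(np.arange(pos, pos + len(t.mean_shifters)))
        pos += len(t.mean_shifters)
        sigma.append(pos)
        pos += 1
        omega.append(np.arange(pos, pos + len(t.variance_shifters)))
        pos += len(t.variance_shifters)
    return _Layout(beta=beta, delta=tuple(delta),
                   sigma=np.array(sigma, dtype=int), omega=tuple(omega))


# ---------------------------------------------------------------------------
# Data marshalling


@dataclass(frozen=True)
class _Design:
    """Numeric arrays extracted once from the data frame for a spec."""

    x: np.ndarray            # (n_terms, n_obs) covariate per term
    z: tuple[np.ndarray, ...]  # per random term, (n_obs, n_z)
    w: tuple[np.ndarray, ...]  # per random term, (n_obs, n_w)
    alt_index: np.ndarray    # alternative index per term
    chosen: np.ndarray       # (n_obs,) chosen alternative index
    n_obs: int
    n_alts: int


def _build_design(data: pd.DataFrame, spec: ModelSpec,
                  choice_col: str = "severity") -> _Design:
    missing = [v for v in spec.variables if v not in data.columns]
    if missing:
        raise KeyError(f"data is missing model columns: {missing}")
    if choice_col not in data.columns:
        raise KeyError(f"data is missing the outcome column {choice_col!r}")
    n_obs = len(data)
    alt_pos = {a: i for i, a in enumerate(spec.alternatives)}
    bad = set(data[choice_col].unique()) - set(spec.alternatives)
    if bad:
        raise ValueError(f"outcome column contains unknown levels: {sorted(bad)}")
    chosen = data[choice_col].map(alt_pos).to_numpy(dtype=np.int64)

    def col(v: str) -> np.ndarray:
        if v == CONST:
            return np.ones(n_obs)
        arr = data[v].to_numpy(dtype=np.float64)
        if not np.isfinite(arr).all():
            raise ValueError(f"column {v!r} contains non-finite values")
        return arr

    x = np.stack([col(t.variable) for t in spec.terms])
    z = tuple(
        np.column_stack([col(v) for v in t.mean_shifters])
        if t.mean_shifters else np.empty((n_obs, 0))
        for t in spec.random_terms
    )
    w = tuple(
        np.column_stack([col(v) for v in t.variance_shifters])
        if t.variance_shifters else np.empty((n_obs, 0))
        for t in spec.random_terms
    )
    alt_index = np.array([alt_pos[t.alternative] for t in spec.terms])
    return _Design(x=x, z=z, w=w, alt_index=alt_index, chosen=chosen,
                   n_obs=n_obs, n_alts=len(spec.alternatives))


# ---------------------------------------------------------------------------
# Probabilities and likelihood


def choice_probabilities(utilities: np.ndarray) -> np.ndarray:
    """Softmax over the last axis with max-shift overflow guarding.

    ``utilities[..., k]`` is the systematic utility of alternative k; the
    result sums to one over the last axis.
    """
    u = np.asarray(utilities, dtype=float)
    if np.isnan(u).any():
        raise ValueError("utilities contain NaN")
    shifted = u - u.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _coef_transform(distribution: str, mean: np.ndarray, sd: np.ndarray,
                    v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-draw coefficient and its derivatives w.r.t. (mean, sd).

    ``mean``/``sd`` are (chunk,), ``v`` is (chunk, n_draws); returns the
    coefficient plus d(coef)/d(mean) and d(coef)/d(sd), all (chunk, draws).
    The underlying disturbance is standard normal; the uniform and
    triangular mixing densities are reached through its probability
    transform, keeping one Halton stream per random coefficient.
    """
    m = mean[:, None]
    s = sd[:, None]
    if distribution == "normal":
        coef = m + s * v
        return coef, np.ones_like(coef), v
    if distribution == "lognormal":
        coef = np.exp(m + s * v)
        return coef, coef, coef * v
    u = stats.norm.cdf(v)
    if distribution == "uniform":
        t = 2.0 * u - 1.0
    else:  # triangular on (-1, 1) with mode 0
        t = np.where(u < 0.5, np.sqrt(2.0 * u) - 1.0,
                     1.0 - np.sqrt(2.0 * (1.0 - u)))
    coef = m + s * t
    return coef, np.ones_like(coef), t


def _chunk_eval(theta: np.ndarray, design: _Design, spec: ModelSpec,
                cube: DrawsCube, lo: int, hi: int, want_scores: bool):
    """Simulated probability (and scores) for observations [lo, hi)."""
    lay = _layout(spec)
    rterms = spec.random_terms
    n = hi - lo
    R = cube.n_draws
    J = design.n_alts
    chosen = design.chosen[lo:hi]

    # Per-term coefficients: fixed -> (n, 1); random -> (n, R)
    coefs: list[np.ndarray] = []
    dmeans: list[np.ndarray | None] = [None] * len(spec.terms)
    dsds: list[np.ndarray | None] = [None] * len(spec.terms)
    sds: list[np.ndarray | None] = [None] * len(spec.terms)
    expw: list[np.ndarray | None] = [None] * len(spec.terms)
    r = 0
    for ti, term in enumerate(spec.terms):
        if not term.random:
            coefs.append(np.full((n, 1), theta[lay.beta[ti]]))
            continue
        mean = np.full(n, theta[lay.beta[ti]])
        if len(lay.delta[r]):
            mean = mean + design.z[r][lo:hi] @ theta[lay.delta[r]]
        scale = np.ones(n)
        if len(lay.omega[r]):
            scale = np.exp(design.w[r][lo:hi] @ theta[lay.omega[r]])
        sd = np.abs(theta[lay.sigma[r]]) * scale
        v = cube.values[lo:hi, :, r]
        coef, dmean, dsd = _coef_transform(term.distribution, mean, sd, v)
        coefs.append(coef)
        dmeans[ti], dsds[ti], sds[ti], expw[ti] = dmean, dsd, sd, scale
        r += 1

    # Utilities (n, R, J)
    util = np.zeros((n, R, J))
    for ti, term in enumerate(spec.terms):
        xi = design.x[ti, lo:hi]
        util[:, :, design.alt_index[ti]] += xi[:, None] * coefs[ti]
    prob = choice_probabilities(util)            # (n, R, J)
    p_chosen = prob[np.arange(n), :, chosen]     # (n, R)
    p_bar = p_chosen.mean(axis=1)                # (n,)
    floored = p_bar < PROB_FLOOR
    if floored.any():
        logger.warning(
            "%d simulated probabilities fell below the %.0e floor",
            int(floored.sum()), PROB_FLOOR,
        )
        p_bar = np.maximum(p_bar, PROB_FLOOR)
    ll = np.log(p_bar)
    if not want_scores:
        return ll, None

    # Scores: d ll_n / d theta_p, shape (n, n_params)
    scores = np.zeros((n, len(theta)))
    inv = 1.0 / (R * p_bar)                      # (n,)
    r = 0
    for ti, term in enumerate(spec.terms):
        a = design.alt_index[ti]
        xi = design.x[ti, lo:hi]
        ind = (chosen == a).astype(float)
        # (n, R): p_chosen * (1[y=a] - P_a) * x
        base = p_chosen * (ind[:, None] - prob[:, :, a]) * xi[:, None]
        if not term.random:
            scores[:, lay.beta[ti]] = inv * base.sum(axis=1)
            continue
        dmean, dsd, sd, scale = dmeans[ti], dsds[ti], sds[ti], expw[ti]
        scores[:, lay.beta[ti]] = inv * (base * dmean).sum(axis=1)
        if len(lay.delta[r]):
            core = inv * (base * dmean).sum(axis=1)
            scores[:, lay.delta[r]] = core[:, None] * design.z[r][lo:hi]
        sgn = np.sign(theta[lay.sigma[r]]) or 1.0
        scores[:, lay.sigma[r]] = inv * (base * dsd).sum(axis=1) * sgn * scale
        if len(lay.omega[r]):
            core_w = inv * (base * dsd * sd[:, None]).sum(axis=1)
            scores[:, lay.omega[r]] = core_w[:, None] * design.w[r][lo:hi]
        r += 1
    return ll, scores


def _loglik_core(theta: np.ndarray, design: _Design, spec: ModelSpec,
                 cube: DrawsCube, want_scores: bool):
    lls = []
    score_blocks = []
    for lo in range(0, design.n_obs, _CHUNK):
        hi = min(lo + _CHUNK, design.n_obs)
        ll, sc = _chunk_eval(theta, design, spec, cube, lo, hi, want_scores)
        lls.append(ll)
        if want_scores:
            score_blocks.append(sc)
    ll_total = float(np.concatenate(lls).sum())
    if want_scores:
        return ll_total, np.vstack(score_blocks)
    return ll_total, None


def simulated_loglik(
    theta: ParameterVector | np.ndarray,
    data: pd.DataFrame,
    spec: ModelSpec,
    cube: DrawsCube | None = None,
    choice_col: str = "severity",
) -> float:
    """Simulated log-likelihood at ``theta``.

    Sum over observations of the log of the draw-averaged probability of
    the chosen alternative, coefficients realized per draw through the
    heterogeneity-in-means-and-variances structure.  With no random terms
    this is the exact multinomial-logit log-likelihood.
    """
    vec = theta.values if isinstance(theta, ParameterVector) else np.asarray(theta, float)
    design = _build_design(data, spec, choice_col)
    cube = _ensure_cube(spec, design.n_obs, cube)
    ll, _ = _loglik_core(vec, design, spec, cube, want_scores=False)
    return ll


def _ensure_cube(spec: ModelSpec, n_obs: int,
                 cube: DrawsCube | None) -> DrawsCube:
    dims = max(spec.n_random, 1)
    if cube is None:
        cube = normal_cube(n_obs, spec.n_draws if spec.n_random else 1,
                           dims, discard=spec.discard)
    if cube.n_obs != n_obs:
        raise ValueError(
            f"draws cube covers {cube.n_obs} observations, data has {n_obs}"
        )
    if spec.n_random and cube.n_dims < spec.n_random:
        raise ValueError(
            f"draws cube has {cube.n_dims} dimensions, spec needs "
            f"{spec.n_random}"
        )
    return cube


# ---------------------------------------------------------------------------
# Fit statistics


def null_loglik(n: int, mode: str = "equal_shares",
                shares: Sequence[float] | None = None,
                n_alts: int = 3) -> float:
    """Null ("at zero") log-likelihood for n observations.

    ``equal_shares`` is -n ln(n_alts): every alternative equally likely,
    all parameters zero.  ``constants_only`` is the constants-only maximum
    n * sum(s_k ln s_k) at the supplied empirical shares; a zero share
    contributes nothing (the 0 ln 0 -> 0 convention).
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    if mode == "equal_shares":
        if shares is not None:
            raise ValueError("shares are only used with mode='constants_only'")
        return -n * float(np.log(n_alts))
    if mode == "constants_only":
        if shares is None:
            raise ValueError("mode='constants_only' requires empirical shares")
        s = np.asarray(shares, dtype=float)
        if abs(s.sum() - 1.0) > 1e-9 or (s < 0).any():
            raise ValueError("shares must be non-negative and sum to one")
        if (s == 0).any():
            logger.info("zero empirical share encountered; 0*ln0 taken as 0")
        pos = s[s > 0]
        return float(n * (pos * np.log(pos)).sum())
    raise ValueError(f"unknown null mode {mode!r}")


def pseudo_r2(ll_converged: float, ll_zero: float) -> float:
    """McFadden pseudo-rho^2, 1 - LL(converged)/LL(zero)."""
    if ll_zero == 0:
        raise ValueError("null log-likelihood of zero is degenerate")
    return 1.0 - ll_converged / ll_zero


def share_sign(mean: float, sd: float, sign: str = "positive") -> float:
    """Population share (percent) of a normal random coefficient's sign.

    For a coefficient ~ N(mean, sd^2), the positive share is
    100 * Phi(mean/sd) and the negative share 100 * Phi(-mean/sd).
    """
    if sd <= 0:
        raise ValueError(f"standard deviation must be positive, got {sd}")
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    z = mean / sd
    return float(100.0 * stats.norm.cdf(z if sign == "positive" else -z))


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    """Packed estimates with inference and fit statistics.

    ``estimates`` holds the raw packed vector (sigma unconstrained);
    ``summary_frame`` reports sigma on the positive scale.  Standard errors
    come from the inverted numerical Hessian at the optimum, falling back
    to the BHHH outer product of scores; entries are NaN when neither is
    positive definite (never fabricated).
    """

    spec: ModelSpec
    estimates: ParameterVector
    std_errors: np.ndarray
    ll_converged: float
    ll_zero: float
    ll_zero_mode: str
    pseudo_r2: float
    n_obs: int
    n_draws: int
    converged: bool
    n_iter: int
    se_method: str
    message: str = ""

    @property
    def t_stats(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.reported_values / self.std_errors

    @property
    def reported_values(self) -> np.ndarray:
        """Estimates with sigma mapped to the positive scale."""
        vals = self.estimates.values.copy()
        lay = _layout(self.spec)
        vals[lay.sigma] = np.abs(vals[lay.sigma])
        return vals

    def summary_frame(self, significance_level: float = 0.90) -> pd.DataFrame:
        crit = stats.norm.ppf(0.5 + significance_level / 2)
        names = self.estimates.names
        alt = []
        for name in names:
            label = name.split(":", 1)[1].split("<-")[0]
            alt.append(label[label.index("[") + 1:-1])
        t = self.t_stats
        return pd.DataFrame(
            {
                "parameter": list(names),
                "alternative": alt,
                "estimate": self.reported_values,
                "std_error": self.std_errors,
                "t_stat": t,
                "significant": np.abs(t) > crit,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.summary_frame().to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            "n_obs": self.n_obs,
            "n_draws": self.n_draws,
            "ll_converged": self.ll_converged,
            "ll_zero": self.ll_zero,
            "ll_zero_mode": self.ll_zero_mode,
            "mcfadden_pseudo_r2": self.pseudo_r2,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "se_method": self.se_method,
            "discard": self.spec.discard,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2))


def _finite_diff_grad(fun, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient with shared draws (the cube is
    fixed across evaluations, so common random numbers apply)."""
    g = np.zeros_like(theta)
    for i in range(theta.size):
        step = h * max(1.0, abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += step
        dn[i] -= step
        g[i] = (fun(up) - fun(dn)) / (2 * step)
    return g


def _numerical_hessian(grad_fun, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    p = theta.size
    H = np.zeros((p, p))
    for i in range(p):
        step = h * max(1.0, abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += step
        dn[i] -= step
        H[:, i] = (grad_fun(up) - grad_fun(dn)) / (2 * step)
    return 0.5 * (H + H.T)


def _try_se_from(matrix: np.ndarray) -> np.ndarray | None:
    """Standard errors from an information-matrix candidate, or None."""
    try:
        cov = np.linalg.inv(matrix)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if (diag <= 0).any() or not np.isfinite(diag).all():
        return None
    return np.sqrt(diag)


def fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    start: ParameterVector | np.ndarray | None = None,
    choice_col: str = "severity",
    cube: DrawsCube | None = None,
    ll_zero_mode: str = "equal_shares",
    gradient: str = "analytic",
) -> FitResult:
    """Estimate the model by simulated maximum likelihood.

    The simulated log-likelihood is maximised by L-BFGS-B with the
    analytic gradient (``gradient="finite"`` switches to central
    differences over the shared draws) inside a wide non-binding box
    (``spec.param_bound``) that stops runaway steps along
    simulation-flat ridges.  When no start is given and the spec has random
    terms, the plain-MNL analogue (every term fixed) is fitted first — its
    likelihood is globally concave — and the mixed model starts from those
    coefficients with sigma at 0.5; this two-stage start avoids the flat
    region around sigma = 0.  Non-convergence is flagged on the result,
    not raised; standard errors that cannot be computed are NaN.
    """
    design = _build_design(data, spec, choice_col)
    if design.n_obs < n_parameters(spec):
        raise ValueError(
            f"{design.n_obs} observations cannot identify "
            f"{n_parameters(spec)} parameters"
        )
    cube = _ensure_cube(spec, design.n_obs, cube)
    lay = _layout(spec)

    if start is None:
        theta0 = np.zeros(n_parameters(spec))
        if spec.n_random:
            mnl = replace(
                spec,
                terms=tuple(Term(t.variable, t.alternative) for t in spec.terms),
                n_draws=1,
            )
            warm = fit(data, mnl, start=np.zeros(len(spec.terms)),
                       choice_col=choice_col, ll_zero_mode=ll_zero_mode,
                       gradient=gradient)
            theta0[lay.beta] = warm.estimates.values
            theta0[lay.sigma] = 0.5
    else:
        theta0 = (start.values if isinstance(start, ParameterVector)
                  else np.asarray(start, float)).copy()

    def negll(v: np.ndarray) -> float:
        ll, _ = _loglik_core(v, design, spec, cube, want_scores=False)
        return -ll

    if gradient == "analytic":
        def neggrad(v: np.ndarray) -> np.ndarray:
            _, sc = _loglik_core(v, design, spec, cube, want_scores=True)
            return -sc.sum(axis=0)
    elif gradient == "finite":
        def neggrad(v: np.ndarray) -> np.ndarray:
            return _finite_diff_grad(negll, v)
    else:
        raise ValueError(f"unknown gradient mode {gradient!r}")

    b = spec.param_bound
    res = optimize.minimize(
        negll, theta0, jac=neggrad, method="L-BFGS-B",
        bounds=[(-b, b)] * theta0.size,
        options={"ftol": spec.tol, "gtol": spec.gtol,
                 "maxiter": spec.max_iter},
    )
    theta_hat = res.x
    ll_hat = -res.fun
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm < 10 * spec.gtol
    if (np.abs(theta_hat) >= b - 1e-6).any():
        converged = False
        logger.warning("estimate hit the +/-%g optimisation bound", b)
    if not converged:
        logger.warning("optimizer did not converge: %s", res.message)

    # Standard errors: inverse numerical Hessian of -LL, BHHH fallback.
    se_method = "hessian"
    H = _numerical_hessian(neggrad, theta_hat)
    se = _try_se_from(H)
    if se is None:
        _, scores = _loglik_core(theta_hat, design, spec, cube, want_scores=True)
        se = _try_se_from(scores.T @ scores)
        se_method = "bhhh"
    if se is None:
        se = np.full(theta_hat.size, np.nan)
        se_method = "unavailable"
        logger.warning("information matrix singular; standard errors unavailable")

    if ll_zero_mode == "constants_only":
        counts = np.bincount(design.chosen, minlength=design.n_alts)
        ll0 = null_loglik(design.n_obs, "constants_only",
                          shares=counts / design.n_obs, n_alts=design.n_alts)
    else:
        ll0 = null_loglik(design.n_obs, "equal_shares", n_alts=design.n_alts)

    return FitResult(
        spec=spec,
        estimates=ParameterVector(spec=spec, values=theta_hat),
        std_errors=se,
        ll_converged=ll_hat,
        ll_zero=ll0,
        ll_zero_mode=ll_zero_mode,
        pseudo_r2=pseudo_r2(ll_hat, ll0),
        n_obs=design.n_obs,
        n_draws=cube.n_draws if spec.n_random else 0,
        converged=converged,
        n_iter=int(res.nit),
        se_method=se_method,
        message=str(res.message),
    )


def mean_coefficient_probabilities(
    data: pd.DataFrame,
    spec: ModelSpec,
    theta: ParameterVector | np.ndarray,
    respect_mean_shifters: bool = True,
) -> np.ndarray:
    """Per-observation choice probabilities at the mean coefficients.

    Random coefficients are evaluated at beta + delta'z (per observation)
    when ``respect_mean_shifters`` is set, else at the overall mean beta;
    the simulation noise term is dropped either way.  Returns an
    (n_obs, n_alts) array.  Used by the marginal-effects computation.
    """
    vec = theta.values if isinstance(theta, ParameterVector) else np.asarray(theta, float)
    work = data.copy()
    if "severity" not in work.columns:
        work["severity"] = spec.alternatives[0]  # outcome unused here
    design = _build_design(work, spec, "severity")
    lay = _layout(spec)
    util = np.zeros((design.n_obs, design.n_alts))
    r = 0
    for ti, term in enumerate(spec.terms):
        coef = np.full(design.n_obs, vec[lay.beta[ti]])
        if term.random:
            if respect_mean_shifters and len(lay.delta[r]):
                coef = coef + design.z[r] @ vec[lay.delta[r]]
            if term.distribution == "lognormal":
                coef = np.exp(coef)
            r += 1
        util[:, design.alt_index[ti]] += design.x[ti] * coef
    return choice_probabilities(util)
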