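"""Quasi-random draw machinery for simulated maximum likelihood.

Mixing integrals over random coefficients are approximated by averaging
over draws.  Halton sequences (radical-inverse sequences in a prime base)
cover the unit interval far more evenly than pseudo-random numbers, so the
same accuracy is reached with many fewer draws.  This module builds the
per-observation, per-draw cube of standard-normal values that the
simulated likelihood consumes.

Conventions
-----------
* Prime bases are assigned to random-coefficient dimensions in order
  (2, 3, 5, ...).
* The first ``discard`` points of each sequence are dropped (default 10)
  to remove the degenerate prefix near zero.
* Each observation receives its own contiguous, non-overlapping block of
  draws per dimension, which is the standard layout for simulated
  likelihood on cross-sectional data.
* Everything is a pure function of ``(bases, discard, shape)`` — there is
  no hidden randomness, so cubes are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Prime bases available for random-coefficient dimensions, in assignment
#: order.  Plain Halton degrades in high dimensions; models here use 1-3
#: random coefficients, so a short list is a feature, not a limit.
PRIME_BASES: tuple[int, ...] = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29)

#: Default number of leading sequence points dropped.
DEFAULT_DISCARD = 10


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    if n < 4:
        return True
    if n % 2 == 0:
        return False
    f = 3
    while f * f <= n:
        if n % f == 0:
            return False
        f += 2
    return True


def halton_sequence(base: int, n: int, discard: int = 0) -> np.ndarray:
    """Radical-inverse (Halton) sequence in a prime base.

    The k-th point is the base-``base`` digit reversal of k mirrored about
    the radix point, for k = 1, 2, ...; the first ``discard`` points are
    dropped.  Returns ``n`` reals in (0, 1).

    >>> halton_sequence(2, 3)
    array([0.5 , 0.25, 0.75])
    """
    if not _is_prime(base):
        raise ValueError(f"Halton base must be prime, got {base}")
    if n < 1:
        raise ValueError(f"need at least one point, got n={n}")
    if discard < 0:
        raise ValueError(f"discard must be non-negative, got {discard}")
    idx = np.arange(discard + 1, discard + n + 1, dtype=np.int64)
    out = np.zeros(n, dtype=np.float64)
    f = 1.0 / base
    while idx.any():
        out += f * (idx % base)
        idx //= base
        f /= base
    return out


@dataclass(frozen=True)
class DrawsCube:
    """Standard-normal quasi-random draws, observations x draws x dimensions.

    ``values[i, r, d]`` is the r-th draw for observation i in random
    dimension d.  ``bases`` records the prime used per dimension and
    ``discard`` the number of leading Halton points dropped, which together
    with the shape fully determine the contents.
    """

    values: np.ndarray
    bases: tuple[int, ...]
    discard: int = DEFAULT_DISCARD
    scrambled: bool = False
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("draws cube must be 3-dimensional (obs, draws, dims)")
        if self.values.shape[2] != len(self.bases):
            raise ValueError("one prime base required per random dimension")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    @property
    def n_dims(self) -> int:
        return self.values.shape[2]


def normal_cube(
    n_obs: int,
    n_draws: int,
    dims: int,
    discard: int = DEFAULT_DISCARD,
    scramble: bool = False,
    seed: int | None = None,
) -> DrawsCube:
    """Build the standard-normal draws cube for ``dims`` random coefficients.

    Per dimension d, a single Halton sequence of length ``n_obs * n_draws``
    in base ``PRIME_BASES[d]`` is generated (after dropping ``discard``
    leading points) and cut into consecutive non-overlapping blocks of
    ``n_draws`` points, one block per observation, then mapped through the
    inverse standard-normal CDF.

    ``scramble=True`` switches to randomly digit-scrambled Halton points
    (useful above ~5 dimensions where plain Halton points correlate); it
    requires a ``seed`` and delegates the scrambling to scipy's QMC engine.
    """
    if dims < 1:
        raise ValueError("need at least one random dimension")
    if dims > len(PRIME_BASES):
        raise ValueError(
            f"{dims} random dimensions requested but only {len(PRIME_BASES)} "
            f"prime bases are configured; reduce the number of random "
            f"coefficients or extend PRIME_BASES"
        )
    bases = PRIME_BASES[:dims]
    total = n_obs * n_draws
    uniforms = np.empty((total, dims), dtype=np.float64)
    if scramble:
        if seed is None:
            raise ValueError("scrambled Halton draws require a seed")
        engine = stats.qmc.Halton(d=dims, scramble=True, seed=seed)
        if discard:
            engine.fast_forward(discard)
        uniforms[:] = engine.random(total)
    else:
        for d, base in enumerate(bases):
            uniforms[:, d] = halton_sequence(base, total, discard=discard)
    normals = stats.norm.ppf(uniforms)
    values = np.ascontiguousarray(
        normals.reshape(n_obs, n_draws, dims)
    )
    return DrawsCube(values=values, bases=bases, discard=discard,
                     scrambled=scramble, seed=seed)


def star_discrepancy_1d(points: np.ndarray) -> float:
    """Exact star discrepancy of a 1-D point set in [0, 1).

    D*_n = max_i max( i/n - x_(i), x_(i) - (i-1)/n ) over the sorted
    points; used to verify that Halton points are more uniform than
    pseudo-random points of the same length.
    """
    x = np.sort(np.asarray(points, dtype=float))
    n = x.size
    i = np.arange(1, n + 1)
    return float(np.maximum(i / n - x, x - (i - 1) / n).max())
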