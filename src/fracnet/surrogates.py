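"""Surrogate time-series benchmarks with known dependence structure.

Two families are provided for validating edge measures before they
touch real data:

* **Logistic-map pairs** — orbits of x(n+1) = A x(n) (1 - x(n)) at a
  shared control parameter A in (3, 4).  Raising A drives the map
  through the period-doubling cascade into chaos, producing pairs of
  increasing complexity (wider spread of points in the joint phase
  portrait) and decreasing mutual similarity.
* **Randomization pairs** — a white-noise series mixed with fresh
  noise, (x, (1 - alpha) x + alpha eps), so that the expected linear
  correlation (1 - alpha) / sqrt((1 - alpha)^2 + alpha^2) decays
  monotonically along a schedule of mixing fractions.

Every stochastic routine takes an explicit seed; there is no hidden
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .similarity import get_measure

__all__ = [
    "LogisticParams",
    "logistic_series",
    "logistic_pair",
    "random_logistic_pair",
    "similarity_schedule",
    "randomization_pairs",
    "expected_mixture_correlation",
    "complexity_sweep",
    "trend_summary",
    "DEFAULT_A_GRID",
    "DEFAULT_BURN_IN",
]

#: control-parameter grid spanning the period-doubling route to chaos
DEFAULT_A_GRID = tuple(np.round(np.arange(3.05, 4.0, 0.10), 2))


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of one logistic-map orbit."""

    a: float
    x0: float
    length: int
    discard: int = 0

    def __post_init__(self):
        if not (3.0 < self.a < 4.0):
            raise ValueError(f"control parameter A must lie in (3, 4), got {self.a}")
        if not (0.0 < self.x0 < 1.0):
            raise ValueError(f"initial condition must lie in (0, 1), got {self.x0}")
        if self.length < 1:
            raise ValueError("length must be positive")
        if self.discard < 0:
            raise ValueError("discard must be nonnegative")


def logistic_series(p: LogisticParams) -> np.ndarray:
    """Iterate the logistic map, discarding ``p.discard`` burn-in steps.

    Deterministic given (A, x0, length, discard).
    """
    n = p.length + p.discard
    out = np.empty(n, dtype=float)
    x = p.x0
    for i in range(n):
        out[i] = x
        x = p.a * x * (1.0 - x)
    return out[p.discard :]


#: default burn-in so orbits reach the attractor before sampling
DEFAULT_BURN_IN = 100


def logistic_pair(
    a: float, x0_a: float, x0_b: float, length: int, discard: int = DEFAULT_BURN_IN
) -> tuple[np.ndarray, np.ndarray]:
    """Two orbits of the same map started from distinct initial points.

    Near A = 3 both orbits settle onto the same low-period cycle and
    phase-lock, so the pair is highly similar; deep in the chaotic
    regime the orbits decorrelate and the joint phase portrait fills
    out.  The default burn-in discards the transient approach to the
    attractor.
    """
    if x0_a == x0_b:
        xa = logistic_series(LogisticParams(a, x0_a, length, discard))
        return xa, xa.copy()
    xa = logistic_series(LogisticParams(a, x0_a, length, discard))
    xb = logistic_series(LogisticParams(a, x0_b, length, discard))
    return xa, xb


def random_logistic_pair(
    a: float, length: int, rng: np.random.Generator, discard: int = DEFAULT_BURN_IN
) -> tuple[np.ndarray, np.ndarray]:
    """Logistic pair with initial conditions drawn uniformly from (0, 1)."""
    x0_a, x0_b = rng.uniform(0.01, 0.99, size=2)
    return logistic_pair(a, float(x0_a), float(x0_b), length, discard)


# ---------------------------------------------------------------------------
# Randomization (similarity-decay) surrogates
# ---------------------------------------------------------------------------

def expected_mixture_correlation(alpha) -> np.ndarray:
    """Closed-form correlation of x with (1-alpha) x + alpha eps for
    independent unit-variance x and eps."""
    a = np.asarray(alpha, dtype=float)
    return (1.0 - a) / np.sqrt((1.0 - a) ** 2 + a**2)


def similarity_schedule(n_levels: int = 8, terminal: float = 0.3) -> np.ndarray:
    """Mixing fractions whose expected correlations fall linearly from
    1 down to ``terminal`` (default 30%, the conventional floor).

    The first level is always alpha = 0 (an identical pair); alphas are
    strictly increasing.
    """
    if n_levels < 2:
        raise ValueError("a schedule needs at least 2 levels")
    if not (0.0 < terminal < 1.0):
        raise ValueError("terminal similarity must lie in (0, 1)")
    rho = np.linspace(1.0, terminal, n_levels)
    t = np.sqrt(np.clip(1.0 / rho**2 - 1.0, 0.0, None))
    return t / (1.0 + t)


def randomization_pairs(
    length: int, schedule, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One noise-mixture pair per mixing fraction in ``schedule``.

    Each pair is (x, (1 - alpha) x + alpha eps) with x white Gaussian
    and eps fresh noise matched to x's standard deviation, so the pair
    at alpha = 0 is identical and similarity decays along the schedule.
    """
    alphas = np.asarray(schedule, dtype=float)
    if alphas.ndim != 1 or alphas.size < 1:
        raise ValueError("schedule must be a non-empty 1-D sequence")
    if alphas[0] != 0.0:
        raise ValueError("schedule must start at alpha = 0 (identical pair)")
    if np.any(np.diff(alphas) <= 0.0) and alphas.size > 1:
        raise ValueError("schedule must be strictly increasing after the start")
    if np.any((alphas < 0.0) | (alphas > 1.0)):
        raise ValueError("mixing fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = []
    for alpha in alphas:
        x = rng.standard_normal(length)
        eps = rng.standard_normal(length) * x.std()
        y = (1.0 - alpha) * x + alpha * eps
        pairs.append((x, y))
    return pairs


# ---------------------------------------------------------------------------
# Complexity sweep (logistic benchmark)
# ---------------------------------------------------------------------------

def complexity_sweep(
    measures=("lc", "mi", "bcfd"),
    a_grid=DEFAULT_A_GRID,
    replicates: int = 50,
    seed: int = 0,
    length: int = 256,
    discard: int = DEFAULT_BURN_IN,
    measure_params: dict | None = None,
) -> pd.DataFrame:
    """Evaluate measures on logistic pairs across a complexity grid.

    Returns a tidy table with columns ``level`` (the A value),
    ``measure``, ``replicate`` and ``value``.  Replicates share the
    same pair of series across measures so the measures see identical
    inputs.
    """
    a_grid = [float(a) for a in a_grid]
    if len(a_grid) < 3:
        raise ValueError("the complexity grid needs at least 3 levels")
    measure_params = measure_params or {}
    fns = {name: get_measure(name, **measure_params.get(name, {})) for name in measures}
    rng = np.random.default_rng(seed)
    rows = []
    for a in a_grid:
        for rep in range(replicates):
            x, y = random_logistic_pair(a, length, rng, discard=discard)
            for name, fn in fns.items():
                rows.append(
                    {"level": a, "measure": name, "replicate": rep, "value": fn(x, y)}
                )
    return pd.DataFrame(rows)


def trend_summary(table: pd.DataFrame, absolute: bool = False) -> pd.DataFrame:
    """Per-(level, measure) median of the sweep values.

    ``absolute=True`` takes medians of |value| — appropriate for the
    signed correlation measure, whose sign flips with the relative
    phase of the two orbits.
    """
    t = table.copy()
    if absolute:
        t["value"] = t["value"].abs()
    return (
        t.groupby(["measure", "level"], as_index=False)["value"]
        .median()
        .rename(columns={"value": "median"})
    )
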