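"""Deterministic selection model for selfing lineages under a changing environment.

A population is a set of *lineages* — genome-wide haploid haplotypes of a fully
selfing, homozygous organism, which therefore behave as asexual clones. Each
lineage ``k`` is a tuple of region-wide haplotypes (RWHs), one per genomic
region. Its log fitness reaction norm is additive over regions,

    xi_k(x) = sum_{l in S_k} f(x | theta_l),      lambda_k(x) = exp(xi_k(x)),

where ``x`` is the environmental value (NaCl concentration in mM) and
``f(x | theta_l)`` is a linear or quadratic per-RWH norm. Under viability
selection with discrete non-overlapping generations and infinite population
size, lineage frequencies follow

    g_k(t+1) = lambda_k(x(t+1)) g_k(t) / sum_j lambda_j(x(t+1)) g_j(t).

Frequencies are carried in log space so that strongly disfavored lineages decay
smoothly toward zero without ever being clipped (the infinite-population model
never loses a lineage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ReactionNormParams",
    "Lineage",
    "AncestralState",
    "EnvironmentSchedule",
    "FrequencyState",
    "rwh_log_fitness",
    "lineage_log_fitness",
    "step",
    "propagate_epoch",
    "predict_trajectories",
    "mean_fitness",
    "fitness_variance",
    "crossing_points",
    "selfing_effective_size",
    "EPOCH_GENERATIONS",
]

#: Generations at which populations were genotyped (T_0 .. T_3).
EPOCH_GENERATIONS: tuple[int, ...] = (0, 10, 35, 50)

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class ReactionNormParams:
    """Per-RWH log-fitness reaction norm f(x | theta).

    Parameters
    ----------
    form:
        ``"linear"`` for ``a*x + b`` or ``"quadratic"`` for ``a*x**2 + b*x + c``.
    coefficients:
        ``(a, b)`` or ``(a, b, c)``; ``x`` in mM NaCl, ``f`` in log offspring
        per capita per generation.
    """

    form: str
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        n_expected = {"linear": 2, "quadratic": 3}.get(self.form)
        if n_expected is None:
            raise ValueError(f"unknown reaction norm form {self.form!r}")
        if len(self.coefficients) != n_expected:
            raise ValueError(
                f"{self.form} norm needs {n_expected} coefficients, "
                f"got {len(self.coefficients)}"
            )
        if not all(math.isfinite(c) for c in self.coefficients):
            raise ValueError("reaction norm coefficients must be finite")

    def __call__(self, x: float) -> float:
        return rwh_log_fitness(x, self)

    def as_quadratic(self) -> tuple[float, float, float]:
        """Coefficients (a2, a1, a0) of the norm viewed as a quadratic in x."""
        if self.form == "linear":
            a, b = self.coefficients
            return (0.0, a, b)
        a, b, c = self.coefficients
        return (a, b, c)


@dataclass(frozen=True)
class Lineage:
    """A selfing lineage: one RWH per genomic region."""

    lineage_id: str
    rwh_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rwh_ids) == 0:
            raise ValueError("lineage must carry at least one RWH")


@dataclass
class AncestralState:
    """Ancestral lineage set A with its frequency vector g^[0]."""

    lineages: list[Lineage]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.lineages) != self.frequencies.shape[0]:
            raise ValueError("lineages and frequencies differ in length")
        _check_simplex(self.frequencies)

    def as_state(self) -> "FrequencyState":
        return FrequencyState.from_frequencies(0, self.frequencies)


@dataclass
class FrequencyState:
    """Lineage frequencies at one generation, stored as log frequencies."""

    generation: int
    log_frequencies: np.ndarray

    @classmethod
    def from_frequencies(cls, generation: int, frequencies) -> "FrequencyState":
        f = np.asarray(frequencies, dtype=float)
        _check_simplex(f)
        with np.errstate(divide="ignore"):
            return cls(generation, np.log(f))

    @property
    def frequencies(self) -> np.ndarray:
        return np.exp(self.log_frequencies)


def _check_simplex(f: np.ndarray) -> None:
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(float(f.sum()) - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {f.sum()!r}")


class EnvironmentSchedule:
    """Per-generation environmental value x(t) for one regime.

    Stored as sorted breakpoints with piecewise-constant forward fill, so a
    sparse schedule file row ``(regime, generation, env_mM)`` defines the value
    from that generation until the next breakpoint.
    """

    def __init__(self, regime_name: str, generations: Sequence[int], values: Sequence[float]):
        gens = np.asarray(generations, dtype=int)
        vals = np.asarray(values, dtype=float)
        if gens.size == 0:
            raise ValueError("schedule needs at least one breakpoint")
        order = np.argsort(gens)
        self.regime_name = regime_name
        self._gens = gens[order]
        self._vals = vals[order]
        if np.any(np.diff(self._gens) == 0):
            raise ValueError("duplicate generations in schedule")
        if np.any(self._vals < 0):
            raise ValueError("environmental values must be >= 0")

    def value_at(self, t: int) -> float:
        idx = np.searchsorted(self._gens, t, side="right") - 1
        if idx < 0:
            raise KeyError(
                f"schedule {self.regime_name!r} undefined at generation {t}"
            )
        return float(self._vals[idx])

    def values(self, from_gen: int, to_gen: int) -> np.ndarray:
        """x(t) for t in (from_gen, to_gen], vectorized."""
        ts = np.arange(from_gen + 1, to_gen + 1)
        idx = np.searchsorted(self._gens, ts, side="right") - 1
        if np.any(idx < 0):
            missing = int(ts[idx < 0][0])
            raise KeyError(
                f"schedule {self.regime_name!r} undefined at generation {missing}"
            )
        return self._vals[idx]

    # -- built-in study regimes ------------------------------------------------

    @classmethod
    def sudden(cls, high_mM: float = 305.0) -> "EnvironmentSchedule":
        """305 mM NaCl from generation 1 onwards."""
        return cls("sudden", [1], [high_mM])

    @classmethod
    def gradual(
        cls,
        start_mM: float = 33.0,
        step_mM: float = 8.0,
        plateau_generation: int = 35,
    ) -> "EnvironmentSchedule":
        """33 mM at generation 1, +8 mM per generation, 305 mM from generation 35."""
        gens = np.arange(1, plateau_generation + 1)
        vals = start_mM + step_mM * (gens - 1)
        return cls("gradual", gens, vals)

    @classmethod
    def control(cls, ancestral_mM: float = 25.0) -> "EnvironmentSchedule":
        """Constant ancestral conditions (25 mM NaCl)."""
        return cls("control", [1], [ancestral_mM])

    @classmethod
    def builtin(cls, regime_name: str) -> "EnvironmentSchedule":
        try:
            return {"sudden": cls.sudden, "gradual": cls.gradual, "control": cls.control}[
                regime_name
            ]()
        except KeyError:
            raise KeyError(f"no built-in schedule named {regime_name!r}") from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> dict[str, "EnvironmentSchedule"]:
        """Parse a schedules table (columns regime, generation, env_mM)."""
        out = {}
        for regime, grp in df.groupby("regime"):
            out[str(regime)] = cls(str(regime), grp["generation"].to_numpy(), grp["env_mM"].to_numpy())
        return out

    def to_frame(self, horizon: int | None = None) -> pd.DataFrame:
        if horizon is None:
            gens, vals = self._gens, self._vals
        else:
            gens = np.arange(1, horizon + 1)
            vals = self.values(0, horizon)
        return pd.DataFrame(
            {"regime": self.regime_name, "generation": gens, "env_mM": vals}
        )


# -- fitness evaluation --------------------------------------------------------


def rwh_log_fitness(x: float, theta: ReactionNormParams) -> float:
    """Evaluate one RWH's log-fitness norm f(x | theta)."""
    if not math.isfinite(x):
        raise ValueError("environmental value must be finite")
    a2, a1, a0 = theta.as_quadratic()
    return a2 * x * x + a1 * x + a0


def lineage_log_fitness(
    x: float,
    lineage: Lineage,
    params: Mapping[str, ReactionNormParams],
) -> float:
    """Additive lineage log fitness xi_k(x) = sum over its RWHs of f(x|theta_l)."""
    total = 0.0
    for rwh_id in lineage.rwh_ids:
        try:
            theta = params[rwh_id]
        except KeyError:
            raise KeyError(f"no reaction-norm parameters for RWH {rwh_id!r}") from None
        total += rwh_log_fitness(x, theta)
    return total


def _xi_vector(
    x: float, lineages: Sequence[Lineage], params: Mapping[str, ReactionNormParams]
) -> np.ndarray:
    return np.array([lineage_log_fitness(x, k, params) for k in lineages])


# -- dynamics ------------------------------------------------------------------


def step(
    state: FrequencyState,
    x: float,
    lineages: Sequence[Lineage],
    params: Mapping[str, ReactionNormParams],
) -> FrequencyState:
    """One generation of viability selection at environment x (log-space update)."""
    logg = state.log_frequencies + _xi_vector(x, lineages, params)
    return FrequencyState(state.generation + 1, logg - logsumexp(logg))

def propagate_epoch(
    state: FrequencyState,
    schedule: EnvironmentSchedule,
    from_gen: int,
    to_gen: int,
    lineages: Sequence[Lineage],
    params: Mapping[str, ReactionNormParams],
) -> FrequencyState:
    """Propagate over generations from_gen+1 .. to_gen in a single product update.

    Equivalent to composing :func:`step` generation by generation: the log
    selection increments sum, so the epoch update applies their cumulative sum
    followed by one renormalization.
    """
    if from_gen >= to_gen:
        raise ValueError("from_gen must be < to_gen")
    xs = schedule.values(from_gen, to_gen)
    cum = np.zeros(len(lineages))
    for x in xs:
        cum += _xi_vector(float(x), lineages, params)
    logg = state.log_frequencies + cum
    return FrequencyState(to_gen, logg - logsumexp(logg))


def predict_trajectories(
    ancestral: AncestralState,
    schedule: EnvironmentSchedule,
    horizon: int,
    params: Mapping[str, ReactionNormParams],
) -> list[FrequencyState]:
    """Deterministic per-generation trajectory of length horizon+1 (incl. t=0)."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    states = [ancestral.as_state()]
    for t in range(1, horizon + 1):
        states.append(step(states[-1], schedule.value_at(t), ancestral.lineages, params))
    return states


def mean_fitness(
    state: FrequencyState,
    x: float,
    lineages: Sequence[Lineage],
    params: Mapping[str, ReactionNormParams],
) -> float:
    """Population mean absolute fitness sum_k g_k lambda_k(x)."""
    lam = np.exp(_xi_vector(x, lineages, params))
    return float(state.frequencies @ lam)


def fitness_variance(
    state: FrequencyState,
    x: float,
    lineages: Sequence[Lineage],
    params: Mapping[str, ReactionNormParams],
) -> float:
    """Population variance in absolute fitness at environment x."""
    lam = np.exp(_xi_vector(x, lineages, params))
    g = state.frequencies
    m = float(g @ lam)
    return float(g @ (lam - m) ** 2)


# -- reaction-norm geometry ----------------------------------------------------


def crossing_points(
    lineage_a: Lineage,
    lineage_b: Lineage,
    params: Mapping[str, ReactionNormParams],
    x_range: tuple[float, float],
) -> list[float]:
    """Environmental values where two lineages' log-fitness norms cross.

    Solves xi_a(x) - xi_b(x) = 0 in closed form (the difference is at most
    quadratic in x) and returns roots inside ``x_range``, sorted.
    """
    lo, hi = x_range
    if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
        raise ValueError("x_range must be a finite interval")

    d2 = d1 = d0 = 0.0
    for rwh_id in lineage_a.rwh_ids:
        a2, a1, a0 = params[rwh_id].as_quadratic()
        d2, d1, d0 = d2 + a2, d1 + a1, d0 + a0
    for rwh_id in lineage_b.rwh_ids:
        a2, a1, a0 = params[rwh_id].as_quadratic()
        d2, d1, d0 = d2 - a2, d1 - a1, d0 - a0

    eps = 1e-14
    if abs(d2) < eps and abs(d1) < eps:
        if abs(d0) < eps:
            raise ValueError("norms coincide: infinitely many crossing points")
        return []
    if abs(d2) < eps:
        roots = [-d0 / d1]
    else:
        disc = d1 * d1 - 4.0 * d2 * d0
        if disc < 0:
            return []
        sq = math.sqrt(disc)
        roots = [(-d1 - sq) / (2 * d2), (-d1 + sq) / (2 * d2)]
    return sorted(r for r in roots if lo <= r <= hi)


def selfing_effective_size(ne_outcrossing: float) -> float:
    """Effective population size under complete self-fertilization.

    Full selfing halves the effective size relative to the (partially)
    outcrossing value, since the two homologous genomes of an individual are
    copies of a single parental genome.
    """
    if ne_outcrossing <= 0:
        raise ValueError("effective size must be positive")
    return ne_outcrossing / 2.0
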