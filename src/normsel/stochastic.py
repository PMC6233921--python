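"""Finite-population forward simulation of selfing lineage dynamics.

With complete self-fertilization and no recombination, lineages reproduce as
asexual clones, so genetic drift is exact multinomial resampling of N lineage
labels each generation, applied after the deterministic viability-selection
update. Frequencies live on the lattice {0, 1/N, ..., 1}; 0 and 1 are
absorbing (no mutation). Founder-effect bottlenecks (freeze/revive) are a
single multinomial draw of a small founder number.

This is the in-silico counterpart of the second evolution experiment: gradual
populations restarted at generation 35 into constant high salt at large
(N = 1e4) or small (N = 2e3) census sizes, asking whether the lineage best at
305 mM is stochastically lost on the way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .model import (
    AncestralState,
    EnvironmentSchedule,
    Lineage,
    ReactionNormParams,
    _xi_vector,
)

__all__ = [
    "WfConfig",
    "SweepCall",
    "wf_step",
    "bottleneck",
    "simulate_wf",
    "sweep_probability",
    "founder_experiment",
]


@dataclass
class WfConfig:
    """Configuration of a replicated Wright-Fisher forward run."""

    census_N: int
    n_generations: int
    schedule: EnvironmentSchedule
    n_replicates: int = 1
    bottleneck_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.census_N < 2:
            raise ValueError("census_N must be >= 2")
        if self.bottleneck_size is not None and self.bottleneck_size > self.census_N:
            raise ValueError("bottleneck_size cannot exceed census_N")


@dataclass
class SweepCall:
    """Replicate-level sweep/loss summary for one target lineage."""

    target_lineage_id: str
    threshold: float
    by_generation: int
    n_replicates: int
    n_sweep: int
    n_lost: int

    @property
    def sweep_fraction(self) -> float:
        return self.n_sweep / self.n_replicates

    @property
    def loss_fraction(self) -> float:
        return self.n_lost / self.n_replicates

    def binomial_se(self, fraction: float) -> float:
        return float(np.sqrt(fraction * (1 - fraction) / self.n_replicates))


def _selection_probs(
    freqs: np.ndarray,
    x: float,
    lineages: Sequence[Lineage],
    params: Mapping[str, ReactionNormParams],
) -> np.ndarray:
    """Post-selection lineage frequencies (deterministic update, log-space)."""
    alive = freqs > 0
    if not alive.any():
        raise ValueError("all lineage frequencies are zero")
    logw = np.full(freqs.shape, -np.inf)
    logw[alive] = np.log(freqs[alive]) + _xi_vector(x, lineages, params)[alive]
    p = np.exp(logw - logsumexp(logw))
    return p / p.sum()


def wf_step(
    freqs: np.ndarray,
    x: float,
    N: int,
    lineages: Sequence[Lineage],
    params: Mapping[str, ReactionNormParams],
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation: viability selection, then multinomial sampling of N."""
    if N < 2:
        raise ValueError("N must be >= 2")
    p = _selection_probs(np.asarray(freqs, dtype=float), x, lineages, params)
    return rng.multinomial(N, p) / N


def bottleneck(freqs: np.ndarray, n_founders: int, rng: np.random.Generator) -> np.ndarray:
    """Founder-effect bottleneck: multinomial draw of n_founders individuals."""
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    f = np.asarray(freqs, dtype=float)
    return rng.multinomial(n_founders, f / f.sum()) / n_founders


def simulate_wf(
    ancestral: AncestralState,
    params: Mapping[str, ReactionNormParams],
    config: WfConfig,
) -> np.ndarray:
    """Replicated forward simulation.

    Returns an array of shape (n_replicates, n_generations + 1, n_lineages)
    of lineage frequencies, reproducible from ``config.seed`` (replicate
    streams derive from ``SeedSequence((seed, replicate))``).
    """
    return _simulate(ancestral, params, config)


def sweep_probability(
    trajectories: np.ndarray,
    lineages: Sequence[Lineage],
    target_lineage_id: str,
    threshold: float = 0.5,
    by_generation: int | None = None,
) -> SweepCall:
    """Fraction of replicates where the target lineage sweeps, and where it is lost.

    A sweep is frequency >= ``threshold`` at ``by_generation`` (default: the
    final simulated generation); a loss is frequency 0 at any time point.
    """
    ids = [k.lineage_id for k in lineages]
    try:
        col = ids.index(target_lineage_id)
    except ValueError:
        raise ValueError(f"target lineage {target_lineage_id!r} not in lineage set") from None
    n_reps, n_gens_plus1, _ = trajectories.shape
    if by_generation is None:
        by_generation = n_gens_plus1 - 1
    target = trajectories[:, :, col]
    n_sweep = int((target[:, by_generation] >= threshold).sum())
    n_lost = int((target == 0).any(axis=1).sum())
    return SweepCall(
        target_lineage_id=target_lineage_id,
        threshold=threshold,
        by_generation=by_generation,
        n_replicates=n_reps,
        n_sweep=n_sweep,
        n_lost=n_lost,
    )


def founder_experiment(
    state: AncestralState,
    params: Mapping[str, ReactionNormParams],
    target_lineage_id: str,
    n_generations: int = 30,
    sizes: Mapping[str, int] = None,
    n_replicates: int = 500,
    bottleneck_size: int | None = None,
    threshold: float = 0.5,
    high_mM: float = 305.0,
    seed: int = 0,
) -> dict[str, SweepCall]:
    """Continued evolution in constant high salt at two population sizes.

    ``state`` is a (gradual) population at the restart generation; per census
    size the run is replicated and the target lineage's sweep/loss fractions
    summarized. With a rare target, loss is more frequent at the small size.
    """
    if sizes is None:
        sizes = {"large": 10_000, "small": 2_000}
    schedule = EnvironmentSchedule("constant_high", [1], [high_mM])
    out: dict[str, SweepCall] = {}
    for i, (label, N) in enumerate(sorted(sizes.items())):
        cfg = WfConfig(
            census_N=int(N),
            n_generations=n_generations,
            schedule=schedule,
            n_replicates=n_replicates,
            bottleneck_size=bottleneck_size,
            seed=int(np.random.SeedSequence((int(seed), i)).generate_state(1)[0] % (2**31)),
        )
        trajs = _simulate(state, params, cfg)
        out[label] = sweep_probability(
            trajs, state.lineages, target_lineage_id, threshold=threshold
        )
    return out


def _simulate(
    ancestral: AncestralState,
    params: Mapping[str, ReactionNormParams],
    config: WfConfig,
) -> np.ndarray:
    """Replicate-vectorized forward run (one multinomial call per generation)."""
    G = len(ancestral.lineages)
    R = config.n_replicates
    out = np.zeros((R, config.n_generations + 1, G))
    # per-generation selection coefficients depend only on x(t): precompute
    xs = config.schedule.values(0, config.n_generations)
    xi_by_gen = {
        float(x): _xi_vector(float(x), ancestral.lineages, params) for x in set(xs)
    }
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed),)))
    f = np.tile(ancestral.frequencies, (R, 1))
    if config.bottleneck_size is not None:
        f = rng.multinomial(config.bottleneck_size, f) / config.bottleneck_size
    out[:, 0] = f
    for t in range(1, config.n_generations + 1):
        xi = xi_by_gen[float(xs[t - 1])]
        with np.errstate(divide="ignore"):
            logw = np.log(f) + xi
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        p = w / w.sum(axis=1, keepdims=True)
        f = rng.multinomial(config.census_N, p) / config.census_N
        out[:, t] = f
        if ((f > 0).sum(axis=1) == 1).all():
            # every replicate fixed for some lineage; absorbing, so fill and stop
            out[:, t + 1 :] = f[:, None, :]
            break
    return out
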