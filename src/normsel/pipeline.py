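"""High-level glue: raw tables -> likelihood-ready data -> fitted ensemble."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .haplotypes import group_minor, pool_to_regime
from .inference import ANCESTRAL_REGIME, EnsembleFit, RegimeData
from .model import EnvironmentSchedule

__all__ = ["build_regime_data", "ensemble_to_json", "crossing_summary"]


def build_regime_data(
    counts: pd.DataFrame,
    fitness: pd.DataFrame,
    schedules: dict[str, EnvironmentSchedule] | pd.DataFrame | None = None,
    top_k: int = 3,
) -> RegimeData:
    """Assemble a :class:`RegimeData` bundle from replicate-level tables.

    Groups minor RWHs into background classes per replicate, pools counts to
    the regime level, and attaches environment schedules (built-ins for any
    evolution regime not covered by ``schedules``).
    """
    grouped = group_minor(counts, top_k=top_k)
    obs = pool_to_regime(grouped)
    if isinstance(schedules, pd.DataFrame):
        schedules = EnvironmentSchedule.from_frame(schedules)
    schedules = dict(schedules or {})
    for regime in obs.regimes():
        if regime != ANCESTRAL_REGIME and regime not in schedules:
            schedules[regime] = EnvironmentSchedule.builtin(regime)
    n_replicates = (
        counts[counts["regime"] != ANCESTRAL_REGIME]
        .groupby("regime")["replicate"]
        .nunique()
        .to_dict()
    )
    return RegimeData(
        genotypes=obs, fitness=fitness, schedules=schedules, n_replicates=n_replicates
    )


def ensemble_to_json(
    ensemble: EnsembleFit, path: str | Path, config: dict | None = None
) -> None:
    """Serialize an ensemble fit (per-draw parameters, logliks, quantiles)."""
    from . import __version__

    payload = {
        "package_version": __version__,
        "config": config or {},
        "n_failed": ensemble.n_failed,
        "draws": [
            {
                "lineages": {k.lineage_id: list(k.rwh_ids) for k in state.lineages},
                "g0": [float(v) for v in state.frequencies],
                "loglik": fit.loglik,
                "converged": fit.converged,
                "seed": list(fit.seed) if isinstance(fit.seed, (tuple, list)) else fit.seed,
                "params": {
                    l: {"form": p.form, "coefficients": list(p.coefficients)}
                    for l, p in fit.params.items()
                },
            }
            for state, fit in ensemble.draws
        ],
        "quantiles": ensemble.quantiles.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def crossing_summary(
    ensemble: EnsembleFit,
    lineage_a: tuple[str, ...],
    lineage_b: tuple[str, ...],
    x_range: tuple[float, float] = (25.0, 305.0),
) -> list[float]:
    """Per-draw crossing points of two lineages (matched by RWH composition)."""
    from .model import Lineage, crossing_points

    out: list[float] = []
    for state, fit in ensemble.draws:
        roots = crossing_points(
            Lineage("a", tuple(lineage_a)), Lineage("b", tuple(lineage_b)), fit.params, x_range
        )
        if roots:
            out.append(roots[0])
    return out
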