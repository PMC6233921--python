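import itertools

import numpy as np
import pandas as pd
import pytest

import normsel as ns
from normsel.haplotypes import GenotypeObservations
from normsel.inference import RegimeData
from normsel.model import AncestralState, EnvironmentSchedule, Lineage
from normsel.pipeline import build_regime_data
from normsel.synthetic import NormTruth


@pytest.fixture(scope="session")
def small_spec():
    return ns.DesignSpec(regimes={"sudden": 2, "gradual": 2}, snps_per_chromosome=10)


@pytest.fixture(scope="session")
def norms(small_spec):
    return ns.make_reaction_norms(
        small_spec, ns.CrossingControl(225.0, 0.003), np.random.default_rng(42)
    )


@pytest.fixture(scope="session")
def experiment(small_spec, norms):
    return ns.simulate_experiment(small_spec, norms, mode="deterministic", seed=42)


@pytest.fixture(scope="session")
def regime_data(experiment):
    return build_regime_data(experiment.rwh_counts, experiment.fitness)


def empty_fitness():
    return pd.DataFrame(
        columns=["regime", "generation", "env_mM", "replicate", "growth_rate"]
    )


def make_observations(rows, rwh_region):
    """Build regime-level observations directly from (regime, gen, region, rwh, count)."""
    df = pd.DataFrame(rows, columns=["regime", "generation", "region", "rwh_id", "count"])
    df["designation"] = "primary"
    return GenotypeObservations(table=df, rwh_region=dict(rwh_region), primary={})


def make_data(rows, rwh_region, schedules, fitness=None):
    return RegimeData(
        genotypes=make_observations(rows, rwh_region),
        fitness=fitness if fitness is not None else empty_fitness(),
        schedules=dict(schedules),
    )


def constant_schedule(name, x):
    return EnvironmentSchedule(name, [1], [x])


def random_likelihood_instance(rng, n_regions=2, max_rwh=4, max_lineages=5):
    """Random small instance for brute-force likelihood cross-checks."""
    region_ids = {
        r: [f"R{r}H{j}" for j in range(1, int(rng.integers(2, max_rwh + 1)) + 1)]
        for r in range(1, n_regions + 1)
    }
    all_combos = list(itertools.product(*region_ids.values()))
    n_lin = int(rng.integers(2, min(max_lineages, len(all_combos)) + 1))
    picks = rng.choice(len(all_combos), size=n_lin, replace=False)
    lineages = [Lineage("|".join(all_combos[i]), all_combos[i]) for i in picks]
    g0 = rng.dirichlet(np.ones(n_lin) * 2.0)
    # selection strengths mild enough that no marginal underflows the
    # likelihood floor over the simulated epochs
    params = {
        l: ns.ReactionNormParams("linear", (float(rng.uniform(-8e-4, 8e-4)),
                                            float(rng.uniform(-0.15, 0.15))))
        for ids in region_ids.values()
        for l in ids
    }
    schedules = {
        "regA": constant_schedule("regA", float(rng.uniform(25, 305))),
        "regB": constant_schedule("regB", float(rng.uniform(25, 305))),
    }
    rwh_region = {l: r for r, ids in region_ids.items() for l in ids}
    rows = []
    for regime in schedules:
        for gen in (5, 12):
            for r in range(1, n_regions + 1):
                # counts only over RWHs carried by some lineage
                carried = sorted({lin.rwh_ids[r - 1] for lin in lineages})
                counts = rng.multinomial(30, np.ones(len(carried)) / len(carried))
                for l, c in zip(carried, counts):
                    if c:
                        rows.append((regime, gen, r, l, int(c)))
    ancestral = AncestralState(lineages=lineages, frequencies=g0)
    data = make_data(rows, rwh_region, schedules)
    return params, ancestral, data
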