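"""Synthetic experiments with known ground truth.

Emulates the study design end to end: a selfing ancestral population of
homozygous lineages composed of one region-wide haplotype (RWH) per genomic
region; linear log-fitness reaction norms in which the lineage best at high
salt ("extreme best") crosses the lineage best at intermediate/ancestral salt
("intermediate best") at a controlled NaCl concentration; regime schedules
(sudden 305 mM, gradual 33->305 mM at +8 mM/generation, control 25 mM);
per-individual single-region SNP genotyping at generations {0, 10, 35, 50}
(64 ancestral / 16 evolved individuals per region); and log-normally noisy
population-mean fitness assays.

Two output granularities:

* :func:`simulate_experiment` emits full genotype/fitness/schedule tables that
  parse through the haplotype pipeline unchanged, plus a :class:`TruthRecord`;
* :func:`simulate_counts` skips SNP emission and draws RWH count tables
  directly from the same multinomial laws — statistically identical at the
  count level and much faster, used for repeated recovery studies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import haplotypes as hap
from .model import (
    AncestralState,
    EnvironmentSchedule,
    FrequencyState,
    Lineage,
    ReactionNormParams,
    mean_fitness,
    predict_trajectories,
)
from .stochastic import WfConfig, simulate_wf

__all__ = [
    "DesignSpec",
    "CrossingControl",
    "NormTruth",
    "TruthRecord",
    "SyntheticExperiment",
    "make_reaction_norms",
    "simulate_counts",
    "simulate_experiment",
    "write_fixture_suite",
]


@dataclass
class DesignSpec:
    """Study design: replicate structure, sampling depths, assay conditions.

    Defaults mirror the experimental design: 3 two-chromosome regions;
    sudden x4 / gradual x7 / control x3 replicate populations; genotyped
    generations {0, 10, 35, 50}; 64 ancestral and 16 evolved individuals per
    region per sample; census size 1e4; fitness assayed at 25/225/305 mM.
    """

    n_regions: int = 3
    rwh_per_region: int = 3
    n_lineages: int = 6
    regimes: dict[str, int] = field(
        default_factory=lambda: {"sudden": 4, "gradual": 7, "control": 3}
    )
    epochs: tuple[int, ...] = (0, 10, 35, 50)
    n_ancestral: int = 64
    n_evolved: int = 16
    census_N: int = 10_000
    assay_envs: tuple[float, ...] = (25.0, 225.0, 305.0)
    fitness_noise_sd: float = 0.1
    n_fitness_replicates: int = 4
    snps_per_chromosome: int = 60
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if list(self.epochs) != sorted(set(self.epochs)):
            raise ValueError("epochs must be strictly increasing")
        for name in ("n_regions", "rwh_per_region", "n_lineages", "n_ancestral", "n_evolved"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def schedules(self) -> dict[str, EnvironmentSchedule]:
        return {name: EnvironmentSchedule.builtin(name) for name in self.regimes}


@dataclass
class CrossingControl:
    """Target geometry of the two focal lineages' log-fitness norms.

    ``crossing_x``: NaCl concentration (mM) where the extreme-best and
    intermediate-best lineage norms cross. ``slope_contrast``: difference in
    lineage-level slope (per mM) between them; must be nonzero.
    """

    crossing_x: float = 225.0
    slope_contrast: float = 0.003


@dataclass
class NormTruth:
    """Planted reaction norms, lineage set and ancestral frequencies."""

    params: dict[str, ReactionNormParams]
    lineages: list[Lineage]
    ancestral_freqs: np.ndarray
    extreme_best_id: str
    intermediate_best_id: str

    def ancestral_state(self) -> AncestralState:
        return AncestralState(lineages=list(self.lineages), frequencies=self.ancestral_freqs.copy())


def make_reaction_norms(
    spec: DesignSpec,
    crossing_control: CrossingControl | None = None,
    rng: np.random.Generator | None = None,
) -> NormTruth:
    """Construct planted linear norms with a controlled crossing.

    Lineage-level log fitness of the intermediate-best lineage declines
    slightly with salt from log(4) offspring per capita at 25 mM; the
    extreme-best lineage's slope exceeds it by ``slope_contrast`` and its
    intercept is set in closed form so the two norms cross exactly at
    ``crossing_x``. Each focal lineage carries its own dedicated RWH per
    region with a third of the lineage-level coefficients. Remaining pure
    lineages are drawn with log fitness below the focal maximum at both 25 and
    305 mM; further lineages are random mixtures of non-extreme RWHs.
    """
    cc = crossing_control or CrossingControl()
    rng = np.random.default_rng(0) if rng is None else rng
    if not (25.0 <= cc.crossing_x <= 305.0):
        raise ValueError("crossing_x must lie inside [25, 305] mM")
    if cc.slope_contrast == 0:
        raise ValueError("slope_contrast must be nonzero")
    K, R = spec.rwh_per_region, spec.n_regions
    if spec.n_lineages < K or K < 2:
        raise ValueError("need n_lineages >= rwh_per_region >= 2")

    a_int = -0.001
    b_int = np.log(4.0) - a_int * 25.0
    a_ext = a_int + cc.slope_contrast
    b_ext = b_int - cc.slope_contrast * cc.crossing_x
    xi_int = lambda x: a_int * x + b_int
    xi_ext = lambda x: a_ext * x + b_ext
    focal_max = {x: max(xi_int(x), xi_ext(x)) for x in (25.0, 305.0)}

    # lineage-level (a, b) per pure lineage index j (0 = extreme, 1 = intermediate)
    lineage_level = [(a_ext, b_ext), (a_int, b_int)]
    for _ in range(2, K):
        lo = focal_max[25.0] - rng.uniform(0.1, 0.5)
        hi = focal_max[305.0] - rng.uniform(0.2, 0.8)
        a = (hi - lo) / 280.0
        lineage_level.append((a, lo - 25.0 * a))

    params: dict[str, ReactionNormParams] = {}
    for r in range(1, R + 1):
        for j, (a, b) in enumerate(lineage_level, start=1):
            params[f"R{r}H{j}"] = ReactionNormParams("linear", (a / R, b / R))

    pure = [tuple(f"R{r}H{j}" for r in range(1, R + 1)) for j in range(1, K + 1)]
    combos = list(pure)
    seen = set(combos)
    while len(combos) < spec.n_lineages:
        tup = tuple(f"R{r}H{int(rng.integers(2, K + 1))}" for r in range(1, R + 1))
        if tup not in seen:
            seen.add(tup)
            combos.append(tup)

    lineages = [Lineage("|".join(t), t) for t in combos]
    freqs = np.empty(len(combos))
    freqs[0] = 0.05  # extreme-best rare in the ancestor
    freqs[1] = 0.15
    if len(combos) > 2:
        freqs[2:] = 0.80 / (len(combos) - 2)
    freqs = freqs / freqs.sum()
    return NormTruth(
        params=params,
        lineages=lineages,
        ancestral_freqs=freqs,
        extreme_best_id=lineages[0].lineage_id,
        intermediate_best_id=lineages[1].lineage_id,
    )


@dataclass
class TruthRecord:
    """Everything needed to recompute downstream expectations exactly."""

    master_seed: int
    norms: NormTruth
    mode: str
    epoch_freqs: dict[str, dict[str, dict[int, list[float]]]]  # regime -> replicate -> gen
    genotype_draws: dict  # (population, generation, region) -> {truth rwh id: count}
    fitness_rows: list[dict]
    rwh_pipeline_ids: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "master_seed": self.master_seed,
            "mode": self.mode,
            "params": {
                l: {"form": p.form, "coefficients": list(p.coefficients)}
                for l, p in self.norms.params.items()
            },
            "lineages": {k.lineage_id: list(k.rwh_ids) for k in self.norms.lineages},
            "ancestral_freqs": list(map(float, self.norms.ancestral_freqs)),
            "extreme_best": self.norms.extreme_best_id,
            "intermediate_best": self.norms.intermediate_best_id,
            "epoch_freqs": self.epoch_freqs,
            "genotype_draws": {
                "|".join(map(str, k)): v for k, v in self.genotype_draws.items()
            },
            "fitness_rows": self.fitness_rows,
            "rwh_pipeline_ids": self.rwh_pipeline_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticExperiment:
    genotypes: pd.DataFrame | None
    rwh_counts: pd.DataFrame
    fitness: pd.DataFrame
    schedules: pd.DataFrame
    truth: TruthRecord


def _replicate_epoch_freqs(
    spec: DesignSpec,
    norms: NormTruth,
    mode: str,
    seed: int,
) -> dict[str, dict[str, dict[int, np.ndarray]]]:
    """Realized lineage frequencies at the genotyped generations."""
    schedules = spec.schedules()
    ancestral = norms.ancestral_state()
    horizon = max(spec.epochs)
    out: dict[str, dict[str, dict[int, np.ndarray]]] = {}
    regime_index = {name: i for i, name in enumerate(sorted(spec.regimes))}
    for regime, n_reps in spec.regimes.items():
        out[regime] = {}
        if mode == "deterministic":
            states = predict_trajectories(ancestral, schedules[regime], horizon, norms.params)
            freqs = {gen: states[gen].frequencies for gen in spec.epochs}
            for rep in range(1, n_reps + 1):
                out[regime][str(rep)] = {g: f.copy() for g, f in freqs.items()}
        elif mode == "wright-fisher":
            cfg = WfConfig(
                census_N=spec.census_N,
                n_generations=horizon,
                schedule=schedules[regime],
                n_replicates=n_reps,
                seed=int(
                    np.random.SeedSequence((seed, 3, regime_index[regime])).generate_state(1)[0]
                    % (2**31)
                ),
            )
            trajs = simulate_wf(ancestral, norms.params, cfg)
            for rep in range(1, n_reps + 1):
                out[regime][str(rep)] = {g: trajs[rep - 1, g] for g in spec.epochs}
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def _lineage_rwh_matrix(norms: NormTruth, region: int) -> dict[str, list[int]]:
    """RWH id -> lineage indices carrying it in the given region."""
    out: dict[str, list[int]] = {}
    for k, lin in enumerate(norms.lineages):
        out.setdefault(lin.rwh_ids[region - 1], []).append(k)
    return out


def _draw_region_counts(
    freqs: np.ndarray, norms: NormTruth, region: int, n: int, rng: np.random.Generator
) -> dict[str, int]:
    lineage_counts = rng.multinomial(n, freqs / freqs.sum())
    counts: dict[str, int] = {}
    for k, c in enumerate(lineage_counts):
        if c:
            rid = norms.lineages[k].rwh_ids[region - 1]
            counts[rid] = counts.get(rid, 0) + int(c)
    return counts


def _fitness_table(
    spec: DesignSpec, norms: NormTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[dict]]:
    """Ancestral-population fitness assays with log-normal noise."""
    state = norms.ancestral_state().as_state()
    rows, noise_rows = [], []
    for env in spec.assay_envs:
        true_mean = mean_fitness(state, env, norms.lineages, norms.params)
        for j in range(1, spec.n_fitness_replicates + 1):
            eps = rng.normal(0.0, spec.fitness_noise_sd)
            rows.append(
                {
                    "regime": "ancestral",
                    "generation": 0,
                    "env_mM": env,
                    "replicate": f"t{j}",
                    "growth_rate": float(np.exp(np.log(true_mean) + eps)),
                }
            )
            noise_rows.append({"env_mM": env, "replicate": j, "noise": float(eps),
                               "true_mean": float(true_mean)})
    return pd.DataFrame(rows), noise_rows


def simulate_counts(
    spec: DesignSpec,
    norms: NormTruth,
    mode: str = "deterministic",
    seed: int = 0,
) -> SyntheticExperiment:
    """Draw RWH count tables directly (no SNP emission). Fast path."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    epoch_freqs = _replicate_epoch_freqs(spec, norms, mode, seed)
    records = []
    draws: dict = {}

    anc = norms.ancestral_freqs
    for region in range(1, spec.n_regions + 1):
        counts = _draw_region_counts(anc, norms, region, spec.n_ancestral, rng)
        draws[("ancestral_0", 0, region)] = counts
        for rid, c in counts.items():
            records.append(("ancestral", "0", 0, region, rid, c))

    for regime, n_reps in spec.regimes.items():
        for rep in range(1, n_reps + 1):
            for gen in spec.epochs[1:]:
                f = epoch_freqs[regime][str(rep)][gen]
                for region in range(1, spec.n_regions + 1):
                    counts = _draw_region_counts(f, norms, region, spec.n_evolved, rng)
                    draws[(f"{regime}_{rep}", gen, region)] = counts
                    for rid, c in counts.items():
                        records.append((regime, str(rep), gen, region, rid, c))

    counts_df = pd.DataFrame(
        records, columns=["regime", "replicate", "generation", "region", "rwh_id", "count"]
    )
    fitness_df, noise = _fitness_table(spec, norms, rng)
    schedules = spec.schedules()
    sched_df = pd.concat(
        [s.to_frame(max(spec.epochs)) for s in schedules.values()], ignore_index=True
    )
    truth = TruthRecord(
        master_seed=seed,
        norms=norms,
        mode=mode,
        epoch_freqs={
            reg: {rep: {int(g): list(map(float, f)) for g, f in by_gen.items()}
                  for rep, by_gen in by_rep.items()}
            for reg, by_rep in epoch_freqs.items()
        },
        genotype_draws=draws,
        fitness_rows=noise,
    )
    return SyntheticExperiment(
        genotypes=None, rwh_counts=counts_df, fitness=fitness_df, schedules=sched_df, truth=truth
    )


def _allele_strings(
    spec: DesignSpec, rng: np.random.Generator, min_hamming: int = 4
) -> dict[str, tuple[str, str]]:
    """Distinct random binary CWH pairs per truth RWH id, Hamming >= 4 apart."""
    n = spec.snps_per_chromosome
    out: dict[str, tuple[str, str]] = {}
    for region in range(1, spec.n_regions + 1):
        chosen: list[np.ndarray] = []
        for j in range(1, spec.rwh_per_region + 1):
            while True:
                s = rng.integers(0, 2, 2 * n)
                if all((s != t).sum() >= min_hamming for t in chosen):
                    break
            chosen.append(s)
            bits = "".join(map(str, s))
            out[f"R{region}H{j}"] = (bits[:n], bits[n:])
    return out


def simulate_experiment(
    spec: DesignSpec,
    norms: NormTruth,
    mode: str = "deterministic",
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SyntheticExperiment:
    """Full synthetic experiment: genotype calls, fitness assays, schedules.

    Individuals are drawn multinomially from the lineage frequencies of their
    population and epoch and emitted as homozygous REF/ALT calls realizing
    their lineage's RWH allele strings (one region per individual, both
    chromosomes). Output files parse through the haplotype pipeline without
    modification; with ``missing_rate=0`` the tallied counts reproduce the
    recorded draws exactly.
    """
    exp = simulate_counts(spec, norms, mode=mode, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    alleles = _allele_strings(spec, rng)

    snp_meta: dict[str, list[tuple[str, int]]] = {}
    for region in range(1, spec.n_regions + 1):
        for chrom in hap.REGION_CHROMOSOMES[region]:
            snp_meta[chrom] = [
                (f"{chrom}_s{i:03d}", 1000 * (i + 1)) for i in range(spec.snps_per_chromosome)
            ]

    pipeline_ids = {}
    for rid, (s1, s2) in alleles.items():
        region = int(rid[1])
        pipeline_ids[rid] = f"R{region}:{s1}{s2}"
    exp.truth.rwh_pipeline_ids = pipeline_ids

    rows = []
    for (pop, gen, region), counts in exp.truth.genotype_draws.items():
        chroms = hap.REGION_CHROMOSOMES[region]
        i = 0
        for rid, c in sorted(counts.items()):
            s1, s2 = alleles[rid]
            for _ in range(c):
                i += 1
                ind = f"{pop}_g{gen}_r{region}_i{i:03d}"
                for chrom, s in zip(chroms, (s1, s2)):
                    for (snp_id, pos), bit in zip(snp_meta[chrom], s):
                        call = "ALT" if bit == "1" else "REF"
                        if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                            call = "MISSING"
                        rows.append((pop, gen, ind, region, chrom, snp_id, pos, call))
    genotypes = pd.DataFrame(rows, columns=hap.GENOTYPE_COLUMNS)
    exp = dataclasses.replace(exp, genotypes=genotypes)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)
        exp.rwh_counts.to_csv(out / "rwh_counts.tsv", sep="\t", index=False)
        exp.fitness.to_csv(out / "fitness.tsv", sep="\t", index=False)
        exp.schedules.to_csv(out / "schedules.tsv", sep="\t", index=False)
        exp.truth.to_json(out / "truth.json")
    return exp


def write_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the small worked-example fixtures.

    Manifest:

    * ``toy_two_lineage/`` — one region, two RWHs/lineages, deterministic
      counts and ancestral fitness with a ``truth.json`` holding the planted
      parameters.
    * ``recovery_small/`` — a down-scaled three-region experiment (2 regimes x
      2 replicates, 8 SNPs/chromosome) with full genotype files and truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    spec = DesignSpec(
        n_regions=1,
        rwh_per_region=2,
        n_lineages=2,
        regimes={"sudden": 1},
        snps_per_chromosome=8,
        fitness_noise_sd=0.0,
        n_fitness_replicates=1,
    )
    norms = make_reaction_norms(spec, CrossingControl(225.0, 0.003), np.random.default_rng(7))
    toy = simulate_experiment(spec, norms, mode="deterministic", seed=7, out_dir=out / "toy_two_lineage")
    paths["toy_two_lineage"] = out / "toy_two_lineage"

    spec2 = DesignSpec(
        regimes={"sudden": 2, "gradual": 2},
        snps_per_chromosome=8,
    )
    norms2 = make_reaction_norms(spec2, CrossingControl(225.0, 0.003), np.random.default_rng(11))
    simulate_experiment(spec2, norms2, mode="deterministic", seed=11, out_dir=out / "recovery_small")
    paths["recovery_small"] = out / "recovery_small"
    return paths
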