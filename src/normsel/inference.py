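"""Maximum-likelihood inference of RWH fitness reaction norms.

The observed data are (i) regime-level RWH counts at the genotyped epochs and
(ii) population-mean absolute fitness assays of the ancestral population. Both
are tied to the reaction-norm parameters Theta through the deterministic
lineage dynamics: given an ancestral lineage set A with frequencies g^[0],
each regime's environmental schedule determines the lineage frequencies
g^[h] at every epoch, hence the predicted marginal RWH frequencies and the
predicted population mean fitness.

Log-likelihood components (natural logs throughout):

* genotype term, a multinomial log-likelihood per regime and epoch::

      L_D = sum_h sum_l n_l^[h] * log( sum_k I(l in S_k) g_k^[h] )

* fitness term, a log-normal noise kernel around the predicted mean fitness::

      L_W = - sum_{h,m} [ log( sum_k lambda_k(x_m) g_k^[h] / phi_{m}^[h] ) ]^2

The total is their sum over regimes, optionally weighting the fitness term.
Fitting maximizes the total by quasi-Newton (L-BFGS-B) with an analytic
gradient, from multiple random starts. Because the ancestral pair (A, g^[0])
is itself uncertain, it is resampled from the ancestral genotype counts and
the fit repeated per draw; trajectory quantiles over draws give credible
envelopes.

The estimator classes follow scikit-learn conventions (``fit``,
``get_params``/``set_params``, fitted attributes with trailing underscores);
the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .haplotypes import BACKGROUND_IDS, GenotypeObservations
from .model import (
    AncestralState,
    EnvironmentSchedule,
    FrequencyState,
    Lineage,
    ReactionNormParams,
)

__all__ = [
    "RegimeData",
    "ModelFit",
    "EnsembleFit",
    "LikelihoodEngine",
    "ReactionNormMLE",
    "ReactionNormEnsemble",
    "estimate_ancestral_rwh_freqs",
    "sample_ancestral",
    "loglik_fitness",
    "loglik_genotypes",
    "total_loglik",
    "total_loglik_gradient",
    "fit_mle",
    "fit_ensemble",
    "select_fitness_for_fit",
]

ANCESTRAL_REGIME = "ancestral"
_P_FLOOR_DEFAULT = 1e-12


@dataclass
class RegimeData:
    """Bundle of regime-level observations used by the likelihood.

    ``fitness`` columns: regime, generation, env_mM, replicate, growth_rate.
    ``n_replicates`` (replicate populations per regime) sets the default
    number of secondary ancestral lineages (2 per replicate).
    """

    genotypes: GenotypeObservations
    fitness: pd.DataFrame
    schedules: dict[str, EnvironmentSchedule]
    n_replicates: dict[str, int] = field(default_factory=dict)

    def evolution_regimes(self) -> list[str]:
        return [r for r in self.genotypes.regimes() if r != ANCESTRAL_REGIME]

    def ancestral_region_counts(self) -> dict[int, dict[str, int]]:
        counts = self.genotypes.region_counts_at(ANCESTRAL_REGIME, 0)
        if not counts:
            raise ValueError("no ancestral (generation 0) genotype counts present")
        return counts


def select_fitness_for_fit(
    fitness: pd.DataFrame, envs: Sequence[float] = (25.0, 305.0)
) -> pd.DataFrame:
    """Ancestral-epoch fitness assays at the stated environments only.

    Reaction norms are anchored by the ancestral population's mean fitness at
    the two experienced extremes; intermediate assay environments are held out
    for validation.
    """
    mask = (fitness["generation"] == 0) & fitness["env_mM"].isin(list(envs))
    return fitness[mask]


# -- ancestral state -----------------------------------------------------------


def estimate_ancestral_rwh_freqs(
    region_counts: Mapping[int, Mapping[str, int]], add_one: bool = False
) -> dict[int, dict[str, float]]:
    """Plug-in multinomial RWH proportions per region from ancestral counts."""
    freqs: dict[int, dict[str, float]] = {}
    for region, counts in region_counts.items():
        n = sum(counts.values())
        if n == 0:
            raise ValueError(f"no ancestral individuals genotyped in region {region}")
        k = len(counts)
        if add_one:
            freqs[region] = {l: (c + 1) / (n + k) for l, c in counts.items()}
        else:
            freqs[region] = {l: c / n for l, c in counts.items()}
    return freqs


def sample_ancestral(
    region_counts: Mapping[int, Mapping[str, int]],
    primary: Mapping[int, Sequence[str]],
    n_secondary: int,
    rng: np.random.Generator,
    dirichlet_alpha: float | None = 1.0,
) -> AncestralState:
    """Draw one ancestral state (A, g^[0]) from the ancestral genotype counts.

    Per region, RWH frequencies are drawn from Dirichlet(counts + alpha) — the
    posterior under a uniform prior, so draw-to-draw variation reflects the
    ancestral sample sizes; ``dirichlet_alpha=None`` uses the plug-in
    proportions instead. The lineage set A is every combination of primary
    RWHs across regions, plus ``n_secondary`` lineages drawn by sampling one
    RWH per region proportionally to the region frequencies (duplicates
    merged); background pseudo-RWHs participate as ordinary RWHs. g^[0] is
    the product of constituent-RWH frequencies (linkage equilibrium),
    renormalized over A.
    """
    regions = sorted(region_counts)
    freq: dict[int, dict[str, float]] = {}
    for region in regions:
        ids = sorted(region_counts[region])
        counts = np.array([region_counts[region][l] for l in ids], dtype=float)
        if counts.sum() == 0:
            raise ValueError(f"no ancestral individuals genotyped in region {region}")
        if dirichlet_alpha is None:
            p = counts / counts.sum()
        else:
            p = rng.dirichlet(counts + dirichlet_alpha)
        freq[region] = dict(zip(ids, p))

    for region in regions:
        if not primary.get(region):
            raise ValueError(f"empty primary RWH set in region {region}")

    combos = set(itertools.product(*(tuple(primary[r]) for r in regions)))
    for _ in range(n_secondary):
        pick = []
        for region in regions:
            ids = sorted(freq[region])
            p = np.array([freq[region][l] for l in ids])
            pick.append(ids[rng.choice(len(ids), p=p / p.sum())])
        combos.add(tuple(pick))

    lineage_tuples = sorted(combos)
    g0 = np.array(
        [np.prod([freq[r][l] for r, l in zip(regions, tup)]) for tup in lineage_tuples]
    )
    total = g0.sum()
    if total <= 0:
        raise ValueError("all sampled lineages have zero ancestral frequency")
    lineages = [Lineage("|".join(tup), tup) for tup in lineage_tuples]
    return AncestralState(lineages=lineages, frequencies=g0 / total)


# -- likelihood engine ---------------------------------------------------------


class LikelihoodEngine:
    """Precomputed likelihood (and analytic gradient) for a fixed ancestral state.

    Parameters are a (n_rwh, P) coefficient matrix, P=2 for linear (a, b) or
    P=3 for quadratic (a, b, c) norms. The epoch dynamics only enter through
    per-epoch cumulative environment features (sum x^2, sum x, #generations),
    so epoch frequencies and their gradients are closed-form softmax algebra.
    """

    def __init__(
        self,
        ancestral: AncestralState,
        data: RegimeData,
        form: str = "linear",
        weight_fitness: float = 1.0,
        fitness_envs: Sequence[float] | None = (25.0, 305.0),
        p_floor: float = _P_FLOOR_DEFAULT,
    ):
        if form not in ("linear", "quadratic"):
            raise ValueError(f"unknown form {form!r}")
        self.form = form
        self.n_coef = 2 if form == "linear" else 3
        self.weight_fitness = float(weight_fitness)
        self.p_floor = float(p_floor)
        self.ancestral = ancestral
        self.lineages = ancestral.lineages
        self.log_g0 = np.log(np.maximum(ancestral.frequencies, 1e-300))

        self.rwh_ids = sorted({l for k in self.lineages for l in k.rwh_ids})
        self.rwh_index = {l: i for i, l in enumerate(self.rwh_ids)}
        G, R = len(self.lineages), len(self.rwh_ids)
        self.M = np.zeros((G, R))
        for k, lin in enumerate(self.lineages):
            for l in lin.rwh_ids:
                self.M[k, self.rwh_index[l]] = 1.0

        rwh_region = data.genotypes.rwh_region

        # genotype blocks, one per (regime, evolved epoch); the multinomial
        # term runs over evolved epochs only. Observed RWHs outside the
        # sampled lineage set fold into their region's background pseudo-RWH.
        blocks: list[tuple[np.ndarray, list[int], list[float], float]] = []
        self.n_floored = 0
        for regime in data.evolution_regimes():
            schedule = data.schedules[regime]
            for gen in data.genotypes.epochs(regime):
                if gen == 0:
                    continue
                phi = self._cum_features(schedule, gen)
                cols, counts = [], []
                unmapped = 0.0
                for rwh, n in data.genotypes.counts_at(regime, gen).items():
                    if rwh not in self.rwh_index:
                        region = rwh_region.get(rwh)
                        rwh = BACKGROUND_IDS.get(region, rwh)
                    if rwh in self.rwh_index:
                        cols.append(self.rwh_index[rwh])
                        counts.append(float(n))
                    else:
                        unmapped += float(n)
                blocks.append((phi, cols, counts, unmapped))
        # pad blocks to a rectangle so every likelihood call is one batched
        # softmax + einsum rather than a python loop
        B = len(blocks)
        Lmax = max((len(c) for _, c, _, _ in blocks), default=0)
        self._geno_phi = np.zeros((B, self.n_coef))
        self._geno_cols = np.zeros((B, max(Lmax, 1)), dtype=int)
        self._geno_counts = np.zeros((B, max(Lmax, 1)))
        self._geno_unmapped = 0.0
        for b, (phi, cols, counts, unmapped) in enumerate(blocks):
            self._geno_phi[b] = phi
            self._geno_cols[b, : len(cols)] = cols
            self._geno_counts[b, : len(counts)] = counts
            self._geno_unmapped += unmapped

        # fitness rows; epoch-0 rows get zero cumulative features (g = g0)
        fit = data.fitness
        if fitness_envs is not None:
            fit = select_fitness_for_fit(fit, fitness_envs)
        if np.any(fit["growth_rate"] <= 0):
            raise ValueError("observed growth rates must be > 0")
        phis, xs_list, logphi_list = [], [], []
        for row in fit.itertuples():
            gen = int(row.generation)
            if gen == 0 or row.regime == ANCESTRAL_REGIME:
                phis.append(np.zeros(self.n_coef))
            else:
                phis.append(self._cum_features(data.schedules[row.regime], gen))
            xs_list.append(float(row.env_mM))
            logphi_list.append(np.log(float(row.growth_rate)))
        self._fit_phi = np.array(phis).reshape(-1, self.n_coef)
        self._fit_psi = np.array([self._point_features(x) for x in xs_list]).reshape(
            -1, self.n_coef
        )
        self._fit_logphi = np.array(logphi_list)

    # feature vectors: order (a, b) -> (x, 1) for linear; (a, b, c) -> (x^2, x, 1)
    def _cum_features(self, schedule: EnvironmentSchedule, to_gen: int) -> np.ndarray:
        xs = schedule.values(0, to_gen)
        if self.form == "linear":
            return np.array([xs.sum(), float(len(xs))])
        return np.array([(xs**2).sum(), xs.sum(), float(len(xs))])

    def _point_features(self, x: float) -> np.ndarray:
        if self.form == "linear":
            return np.array([x, 1.0])
        return np.array([x * x, x, 1.0])

    def theta_from_params(self, params: Mapping[str, ReactionNormParams]) -> np.ndarray:
        theta = np.zeros((len(self.rwh_ids), self.n_coef))
        for l, i in self.rwh_index.items():
            try:
                p = params[l]
            except KeyError:
                raise KeyError(f"no reaction-norm parameters for RWH {l!r}") from None
            if p.form != self.form:
                raise ValueError(f"parameter form {p.form!r} != engine form {self.form!r}")
            theta[i] = p.coefficients
        return theta

    def params_from_theta(self, theta: np.ndarray) -> dict[str, ReactionNormParams]:
        return {
            l: ReactionNormParams(self.form, tuple(float(v) for v in theta[i]))
            for l, i in self.rwh_index.items()
        }

    def _epoch_logfreqs(self, theta: np.ndarray, phi_mat: np.ndarray) -> np.ndarray:
        """Log lineage frequencies per block, shape (G, n_blocks)."""
        u = self.log_g0[:, None] + self.M @ (theta @ phi_mat.T)
        return u - logsumexp(u, axis=0, keepdims=True)

    def genotype_loglik(self, theta: np.ndarray, grad: np.ndarray | None = None) -> float:
        self.n_floored = 0
        if self._geno_phi.shape[0] == 0:
            return 0.0
        G_mat = np.exp(self._epoch_logfreqs(theta, self._geno_phi))  # (G, B)
        M_cols = self.M[:, self._geno_cols]  # (G, B, Lmax)
        p = np.einsum("gb,gbl->bl", G_mat, M_cols)
        floored = (p < self.p_floor) & (self._geno_counts > 0)
        self.n_floored = int(floored.sum())
        p_safe = np.maximum(p, self.p_floor)
        total = float((self._geno_counts * np.log(p_safe)).sum())
        if self._geno_unmapped:
            self.n_floored += 1
            total += self._geno_unmapped * np.log(self.p_floor)
        if grad is not None:
            ratio = np.where(floored, 0.0, self._geno_counts / p_safe)
            w = np.einsum("gbl,bl->gb", M_cols, ratio)
            v = G_mat * (w - (G_mat * w).sum(axis=0, keepdims=True))
            grad += (self.M.T @ v) @ self._geno_phi
        return total

    def fitness_loglik(self, theta: np.ndarray, grad: np.ndarray | None = None) -> float:
        # log pred = logsumexp(log g + xi(x)) keeps wild starts from overflowing
        if self._fit_phi.shape[0] == 0:
            return 0.0
        logg = self._epoch_logfreqs(theta, self._fit_phi)  # (G, F)
        s = logg + self.M @ (theta @ self._fit_psi.T)
        logpred = logsumexp(s, axis=0)
        r = logpred - self._fit_logphi
        if grad is not None:
            q = np.exp(s - logpred)  # fitness-weighted lineage shares
            grad += (self.M.T @ (q * (-2.0 * r))) @ self._fit_psi
            grad += (self.M.T @ ((q - np.exp(logg)) * (-2.0 * r))) @ self._fit_phi
        return float(-(r * r).sum())

    def value(self, theta: np.ndarray) -> float:
        return self.weight_fitness * self.fitness_loglik(theta) + self.genotype_loglik(theta)

    def value_and_grad(self, theta_flat: np.ndarray) -> tuple[float, np.ndarray]:
        theta = theta_flat.reshape(len(self.rwh_ids), self.n_coef)
        grad_w = np.zeros_like(theta)
        grad_d = np.zeros_like(theta)
        lw = self.fitness_loglik(theta, grad_w)
        ld = self.genotype_loglik(theta, grad_d)
        value = self.weight_fitness * lw + ld
        grad = self.weight_fitness * grad_w + grad_d
        return value, grad.ravel()


# -- module-level likelihood wrappers (spec surface) ---------------------------


def _engine(params, ancestral, data, form=None, **kw) -> tuple[LikelihoodEngine, np.ndarray]:
    if form is None:
        form = next(iter(params.values())).form
    eng = LikelihoodEngine(ancestral, data, form=form, **kw)
    return eng, eng.theta_from_params(params)


def loglik_fitness(
    params: Mapping[str, ReactionNormParams],
    ancestral: AncestralState,
    data: RegimeData,
    fitness_envs: Sequence[float] | None = None,
) -> float:
    """Fitness-data log-likelihood term (up to its additive constant)."""
    eng, theta = _engine(params, ancestral, data, fitness_envs=fitness_envs)
    return eng.fitness_loglik(theta)


def loglik_genotypes(
    params: Mapping[str, ReactionNormParams],
    ancestral: AncestralState,
    data: RegimeData,
    p_floor: float = _P_FLOOR_DEFAULT,
) -> float:
    """Genotype-count multinomial log-likelihood term (up to its constant)."""
    eng, theta = _engine(params, ancestral, data, p_floor=p_floor)
    value = eng.genotype_loglik(theta)
    if eng.n_floored:
        warnings.warn(
            f"{eng.n_floored} observed RWH term(s) had predicted frequency below "
            f"the {p_floor:g} floor",
            stacklevel=2,
        )
    return value


def total_loglik(
    params: Mapping[str, ReactionNormParams],
    ancestral: AncestralState,
    data: RegimeData,
    weight_fitness: float = 1.0,
    fitness_envs: Sequence[float] | None = (25.0, 305.0),
) -> float:
    """Combined log-likelihood: weighted fitness term plus genotype term."""
    eng, theta = _engine(
        params, ancestral, data, weight_fitness=weight_fitness, fitness_envs=fitness_envs
    )
    return eng.value(theta)


def total_loglik_gradient(
    params: Mapping[str, ReactionNormParams],
    ancestral: AncestralState,
    data: RegimeData,
    weight_fitness: float = 1.0,
    fitness_envs: Sequence[float] | None = (25.0, 305.0),
) -> tuple[float, dict[str, np.ndarray]]:
    """Analytic gradient of the combined log-likelihood, keyed by RWH id."""
    eng, theta = _engine(
        params, ancestral, data, weight_fitness=weight_fitness, fitness_envs=fitness_envs
    )
    value, grad = eng.value_and_grad(theta.ravel())
    grad = grad.reshape(theta.shape)
    return value, {l: grad[i].copy() for l, i in eng.rwh_index.items()}


# -- fitted-model containers ---------------------------------------------------


@dataclass
class ModelFit:
    """Best-of-starts maximum-likelihood fit of the reaction-norm parameters."""

    params: dict[str, ReactionNormParams]
    loglik: float
    n_starts: int
    converged: bool
    seed: object
    start_logliks: list[float]
    n_floored: int = 0


@dataclass
class EnsembleFit:
    """Per-ancestral-draw fits and trajectory quantiles across draws.

    ``quantiles`` columns: regime, generation, lineage_id, q2.5, q50, q97.5;
    lineages are matched across draws by their RWH composition.
    """

    draws: list[tuple[AncestralState, ModelFit]]
    quantiles: pd.DataFrame
    n_failed: int = 0


# -- estimators ----------------------------------------------------------------


class ReactionNormMLE(BaseEstimator):
    """Multi-start maximum-likelihood estimator of RWH reaction norms.

    Parameters
    ----------
    form:
        ``"linear"`` or ``"quadratic"`` per-RWH log-fitness norms.
    n_starts:
        Number of random L-BFGS-B starts; the best final log-likelihood wins
        (ties broken by smaller parameter norm).
    weight_fitness:
        Relative weight of the fitness-assay term against the genotype term.
    fitness_envs:
        Assay environments (mM) of the ancestral fitness data used in the fit;
        ``None`` uses every fitness row in the data.
    random_state:
        Master seed; per-start seeds derive from ``SeedSequence((seed, start))``.

    Attributes
    ----------
    params_ : dict mapping RWH id to fitted :class:`ReactionNormParams`.
    loglik_ : best final log-likelihood.
    converged_ : whether the winning start reported convergence.
    start_logliks_ : final log-likelihood of every start.
    """

    def __init__(
        self,
        form: str = "linear",
        n_starts: int = 10,
        weight_fitness: float = 1.0,
        fitness_envs: Sequence[float] | None = (25.0, 305.0),
        tol: float = 1e-8,
        max_evals: int = 5000,
        p_floor: float = _P_FLOOR_DEFAULT,
        random_state: int = 0,
    ):
        self.form = form
        self.n_starts = n_starts
        self.weight_fitness = weight_fitness
        self.fitness_envs = fitness_envs
        self.tol = tol
        self.max_evals = max_evals
        self.p_floor = p_floor
        self.random_state = random_state

    def _random_start(self, rng: np.random.Generator, n_rwh: int) -> np.ndarray:
        if self.form == "linear":
            a = rng.uniform(-0.02, 0.02, n_rwh)
            b = rng.uniform(-1.0, 2.0, n_rwh)
            return np.column_stack([a, b]).ravel()
        a = rng.uniform(-1e-4, 1e-4, n_rwh)
        b = rng.uniform(-0.02, 0.02, n_rwh)
        c = rng.uniform(-1.0, 2.0, n_rwh)
        return np.column_stack([a, b, c]).ravel()

    def fit(self, X: RegimeData, y=None, *, ancestral: AncestralState):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        engine = LikelihoodEngine(
            ancestral,
            X,
            form=self.form,
            weight_fitness=self.weight_fitness,
            fitness_envs=self.fitness_envs,
            p_floor=self.p_floor,
        )

        def negative(flat: np.ndarray) -> tuple[float, np.ndarray]:
            v, g = engine.value_and_grad(flat)
            return -v, -g

        best = None
        start_logliks: list[float] = []
        diagnostics = []
        for start in range(self.n_starts):
            seed = np.random.SeedSequence(
                self._seed_entropy() + (start,)
            )
            rng = np.random.default_rng(seed)
            x0 = self._random_start(rng, len(engine.rwh_ids))
            res = minimize(
                negative,
                x0,
                jac=True,
                method="L-BFGS-B",
                options={"maxfun": self.max_evals, "ftol": self.tol, "gtol": 1e-9},
            )
            start_logliks.append(-float(res.fun))
            diagnostics.append(res.message)
            key = (-float(res.fun), -float(np.linalg.norm(res.x)))
            if best is None or key > best[0]:
                best = (key, res)
        assert best is not None
        res = best[1]
        if not np.isfinite(res.fun):
            raise RuntimeError(f"all optimization starts failed: {diagnostics}")

        theta = res.x.reshape(len(engine.rwh_ids), engine.n_coef)
        self.engine_ = engine
        self.ancestral_ = ancestral
        self.params_ = engine.params_from_theta(theta)
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success)
        self.start_logliks_ = start_logliks
        self.n_floored_ = engine.n_floored
        return self

    def _seed_entropy(self) -> tuple[int, ...]:
        rs = self.random_state
        if isinstance(rs, (tuple, list)):
            return tuple(int(v) for v in rs)
        return (int(rs),)

    def to_model_fit(self) -> ModelFit:
        return ModelFit(
            params=self.params_,
            loglik=self.loglik_,
            n_starts=self.n_starts,
            converged=self.converged_,
            seed=self.random_state,
            start_logliks=self.start_logliks_,
            n_floored=self.n_floored_,
        )

    def predict(self, schedule: EnvironmentSchedule, horizon: int) -> np.ndarray:
        """Predicted lineage frequencies, shape (horizon+1, n_lineages)."""
        from .model import predict_trajectories

        states = predict_trajectories(self.ancestral_, schedule, horizon, self.params_)
        return np.vstack([s.frequencies for s in states])


class ReactionNormEnsemble(BaseEstimator):
    """Ensemble of reaction-norm fits over resampled ancestral states.

    Each draw samples (A, g^[0]) from the ancestral genotype counts, fits the
    reaction norms by :class:`ReactionNormMLE`, and predicts per-regime
    lineage trajectories over ``horizon`` generations; 2.5/50/97.5% quantiles
    over draws give the credible envelopes, with lineages matched across
    draws by RWH composition.
    """

    def __init__(
        self,
        n_anc_samples: int = 20,
        n_secondary_per_replicate: int = 2,
        form: str = "linear",
        n_starts: int = 10,
        weight_fitness: float = 1.0,
        fitness_envs: Sequence[float] | None = (25.0, 305.0),
        horizon: int = 100,
        dirichlet_alpha: float | None = 1.0,
        random_state: int = 0,
    ):
        self.n_anc_samples = n_anc_samples
        self.n_secondary_per_replicate = n_secondary_per_replicate
        self.form = form
        self.n_starts = n_starts
        self.weight_fitness = weight_fitness
        self.fitness_envs = fitness_envs
        self.horizon = horizon
        self.dirichlet_alpha = dirichlet_alpha
        self.random_state = random_state

    def fit(self, X: RegimeData, y=None):
        if self.n_anc_samples < 1:
            raise ValueError("n_anc_samples must be >= 1")
        region_counts = {r: dict(c) for r, c in X.ancestral_region_counts().items()}
        # primary RWHs are designated per replicate population across all its
        # genotyped generations; the candidate lineage set combines the union
        # over regimes, so a haplotype that only rose to prominence during
        # evolution (rare or unseen in the ancestral sample) still enters A
        primary: dict[int, set[str]] = {}
        for (_regime, region), ids in X.genotypes.primary.items():
            primary.setdefault(region, set()).update(ids)
        if not primary:
            raise ValueError("no primary RWH designations in the data")
        primary = {r: tuple(sorted(v)) for r, v in primary.items()}
        for region, ids in primary.items():
            for rwh in ids:
                region_counts.setdefault(region, {}).setdefault(rwh, 0)
        n_secondary = self.n_secondary_per_replicate * max(
            1, sum(X.n_replicates.get(r, 1) for r in X.evolution_regimes())
        )

        draws: list[tuple[AncestralState, ModelFit]] = []
        n_failed = 0
        for draw in range(self.n_anc_samples):
            rng = np.random.default_rng(np.random.SeedSequence((int(self.random_state), draw)))
            try:
                state = sample_ancestral(
                    region_counts,
                    primary,
                    n_secondary,
                    rng,
                    dirichlet_alpha=self.dirichlet_alpha,
                )
                mle = ReactionNormMLE(
                    form=self.form,
                    n_starts=self.n_starts,
                    weight_fitness=self.weight_fitness,
                    fitness_envs=self.fitness_envs,
                    random_state=(int(self.random_state), draw, 1),
                ).fit(X, ancestral=state)
            except (ValueError, RuntimeError) as err:
                n_failed += 1
                warnings.warn(f"ancestral draw {draw} failed: {err}", stacklevel=2)
                continue
            draws.append((state, mle.to_model_fit()))
        if n_failed > self.n_anc_samples / 2:
            raise RuntimeError(
                f"{n_failed}/{self.n_anc_samples} ancestral draws failed to fit"
            )

        self.draws_ = draws
        self.n_failed_ = n_failed
        self.quantiles_ = self._trajectory_quantiles(X, draws)
        return self

    def _trajectory_quantiles(
        self, X: RegimeData, draws: list[tuple[AncestralState, ModelFit]]
    ) -> pd.DataFrame:
        from .model import predict_trajectories

        records = []
        horizon = self.horizon
        for regime in X.evolution_regimes():
            schedule = X.schedules[regime]
            # lineage key: RWH composition, shared across draws
            all_keys: dict[tuple[str, ...], int] = {}
            per_draw = []
            for state, fitres in draws:
                states = predict_trajectories(state, schedule, horizon, fitres.params)
                freqs = np.vstack([s.frequencies for s in states])
                keymap = {}
                for j, lin in enumerate(state.lineages):
                    all_keys.setdefault(lin.rwh_ids, len(all_keys))
                    keymap[lin.rwh_ids] = j
                per_draw.append((keymap, freqs))
            arr = np.zeros((len(per_draw), horizon + 1, len(all_keys)))
            for d, (keymap, freqs) in enumerate(per_draw):
                for key, j in keymap.items():
                    arr[d, :, all_keys[key]] = freqs[:, j]
            qs = np.quantile(arr, [0.025, 0.5, 0.975], axis=0)
            for key, col in all_keys.items():
                for t in range(horizon + 1):
                    records.append(
                        (regime, t, "|".join(key), qs[0, t, col], qs[1, t, col], qs[2, t, col])
                    )
        return pd.DataFrame(
            records, columns=["regime", "generation", "lineage_id", "q2.5", "q50", "q97.5"]
        )

    def to_ensemble_fit(self) -> EnsembleFit:
        return EnsembleFit(draws=self.draws_, quantiles=self.quantiles_, n_failed=self.n_failed_)


# -- functional wrappers -------------------------------------------------------


def fit_mle(
    ancestral: AncestralState,
    data: RegimeData,
    form: str = "linear",
    n_starts: int = 10,
    seed: int = 0,
    weight_fitness: float = 1.0,
    fitness_envs: Sequence[float] | None = (25.0, 305.0),
) -> ModelFit:
    """Best-of-``n_starts`` maximum-likelihood fit for a fixed ancestral state."""
    est = ReactionNormMLE(
        form=form,
        n_starts=n_starts,
        weight_fitness=weight_fitness,
        fitness_envs=fitness_envs,
        random_state=seed,
    ).fit(data, ancestral=ancestral)
    return est.to_model_fit()


def fit_ensemble(
    data: RegimeData,
    n_anc_samples: int = 20,
    form: str = "linear",
    n_starts: int = 10,
    seed: int = 0,
    horizon: int = 100,
    **kwargs,
) -> EnsembleFit:
    """Ensemble fit over resampled ancestral states with credible envelopes."""
    est = ReactionNormEnsemble(
        n_anc_samples=n_anc_samples,
        form=form,
        n_starts=n_starts,
        horizon=horizon,
        random_state=seed,
        **kwargs,
    ).fit(data)
    return est.to_ensemble_fit()
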