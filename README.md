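# normsel

Inference of lineage **fitness reaction norms** — a genotype's expected
per-capita growth rate as a function of an environmental value — from
haplotype-frequency time series collected during experimental evolution, and
forward prediction of lineage dynamics under deterministic
(infinite-population) and Wright–Fisher (finite-population) models.

The package targets evolve-and-resequence designs in selfing organisms
(e.g. *C. elegans* populations evolving under sudden, gradual, or control
NaCl regimes): individuals are essentially homozygous, so each genome is a
*lineage* behaving as an asexual clone, described by one region-wide
haplotype (RWH) per genotyped genomic region. For users who have (i)
individual SNP genotypes at several time points, and (ii) population-mean
growth-rate assays, `normsel` reconstructs RWH count tables, fits per-RWH
log-fitness norms by maximum likelihood, and asks when reaction norms cross
— the signature of genotype-by-environment fitness variance that makes the
*rate* of environmental change decisive for adaptation.

## Model

Lineage `k` has log fitness `ξ_k(x) = Σ_{l∈S_k} f(x|θ_l)` with per-RWH
norms `f(x|θ_l) = a_l x + b_l` (or quadratic), and frequencies evolve by

    g_k(t+1) ∝ exp(ξ_k(x(t+1))) · g_k(t).

Fitting maximizes, over the norm parameters Θ and per regime `c`,

    Σ_c [ −Σ_{h,m} log²( Σ_k λ_k(x_m) g_k^[h] / φ_{c,m}^[h] )       (fitness assays)
          + Σ_{h,l} n_{c,l}^[h] log( Σ_k 1(l∈S_k) g_k^[h] ) ]        (RWH counts)

by multi-start L-BFGS with an analytic gradient, repeated over resamples of
the uncertain ancestral state (A, g⁰) to produce credible envelopes. A
multinomial Wright–Fisher layer (drift + founder bottlenecks) turns the
fitted model into sweep/loss probabilities at finite census sizes. See
`docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Simulate a synthetic experiment with known crossing norms, fit the ensemble,
and compare the planted and fitted crossing points:

```python
import numpy as np
import normsel as ns

# 1. simulate a synthetic evolution experiment with known reaction norms
spec = ns.DesignSpec(regimes={"sudden": 4, "gradual": 4})
norms = ns.make_reaction_norms(
    spec, ns.CrossingControl(crossing_x=225.0, slope_contrast=0.003),
    np.random.default_rng(0))
exp = ns.simulate_counts(spec, norms, mode="deterministic", seed=0)

# 2. pool replicate counts to regime level and fit the ensemble
data = ns.build_regime_data(exp.rwh_counts, exp.fitness)
ens = ns.fit_ensemble(data, n_anc_samples=5, n_starts=6, seed=0, horizon=50)

# 3. fitted crossing point of the two focal lineages, per ensemble draw
from normsel.pipeline import crossing_summary
crossings = crossing_summary(ens, ("R1H1", "R2H1", "R3H1"), ("R1H2", "R2H2", "R3H2"))
print(f"fitted crossing (median of {len(crossings)} draws): {np.median(crossings):.1f} mM")

# 4. forward Wright-Fisher prediction under finite population size
from normsel.validation import headline_contrast_study
out = headline_contrast_study(census_N=1000, n_replicates=500, seed=0)
print(f"P(best lineage lost by arrival at 305 mM), gradual: {out['loss_by_arrival_gradual']:.2f}")
print(f"P(best lineage lost by arrival at 305 mM), sudden:  {out['loss_by_arrival_sudden']:.2f}")
```

Output:

```
fitted crossing (median of 5 draws): 208.7 mM
P(best lineage lost by arrival at 305 mM), gradual: 0.98
P(best lineage lost by arrival at 305 mM), sudden:  0.00
```

The fitted norms recover the planted crossing (225 mM) to within the
ensemble's spread, and the drift layer shows the headline asymmetry: the
lineage best at high salt starts rare, is disfavored until the gradual
schedule nears the crossing concentration, and at census size 10³ is almost
always lost by drift before it would be favored — whereas under a sudden
shift it is favored from generation one and essentially never lost. Slower
environmental change hinders adaptation from standing genetic variation.

## Command line

Thin wrappers over the library, each a pure function of inputs + seed:

```
normsel simulate   --mode det --seed 0 --out runs/sim
normsel qc         --genotypes runs/sim/genotypes.tsv --out runs/qc
normsel haplotypes --genotypes runs/sim/genotypes.tsv --out runs/hap
normsel infer      --rwh-counts runs/hap/rwh_counts.tsv --fitness runs/sim/fitness.tsv \
                   --n-anc-samples 20 --n-starts 10 --seed 1 --out runs/fit
normsel predict    --fit runs/fit/fit.json --regime gradual --horizon 100 --out runs/traj.tsv
normsel wf-sim     --fit runs/fit/fit.json --n 2000 --generations 30 --replicates 1000 \
                   --seed 2 --out runs/wf.json
normsel report     --fit runs/fit/fit.json --out runs/report.txt
```

File dialects (all TSV with headers) are documented in the module docstrings
of `normsel.haplotypes` and `normsel.model`.

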