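# Methods

## Model

`normsel` models an effectively asexual population of a fully selfing,
homozygous organism evolving under viability selection in a changing
environment (NaCl concentration `x`, in mM). The genome is partitioned into
`L` two-chromosome regions; the haplotype of a region is a region-wide
haplotype (RWH), and a *lineage* is a tuple of one RWH per region. Each RWH
`l` carries a log-fitness reaction norm

    f(x | θ_l) = a_l x + b_l                     (linear)
    f(x | θ_l) = a_l x² + b_l x + c_l            (quadratic)

and a lineage's log fitness is additive over its RWHs:
`ξ_k(x) = Σ_{l∈S_k} f(x|θ_l)`, `λ_k(x) = exp ξ_k(x)`. With infinite
population size, discrete non-overlapping generations and no mutation,
recombination, or density/frequency dependence, lineage frequencies follow

    g_k(t+1) = λ_k(x(t+1)) g_k(t) / Σ_j λ_j(x(t+1)) g_j(t).

Frequencies are stored as log frequencies and every update renormalizes with
a log-sum-exp, so strongly disfavored lineages decay smoothly without ever
being clipped to zero (no lineage is lost in the deterministic model), and
epoch-level propagation (summing the per-generation log increments and
renormalizing once) agrees with generation-by-generation composition to
better than 1e-10.

Assumption worth stating plainly: additivity of `f` across regions means no
epistasis between regions on the log scale, and homozygosity means no
dominance. Crossing points of two lineages' norms are roots of a polynomial
of degree ≤ 2 and are computed in closed form.

### Environment schedules

Built-in regimes: *sudden* (305 mM from generation 1), *gradual* (33 mM at
generation 1, +8 mM per generation, reaching 305 mM exactly at generation 35
and constant thereafter), *control* (25 mM). Schedules are breakpoint tables
with piecewise-constant forward fill, so sparse schedule files are allowed.
Generations are 1-based; genotyped generations are {0, 10, 35, 50}.

## Data pipeline

Individuals are genotyped for the SNPs of a single region (both
chromosomes). QC drops SNPs with more than 30% missing calls or more than
30% heterozygous calls, then individuals with more than 25% missing calls
among retained SNPs, iterating the two filters to a fixed point so the
thresholds hold jointly (this also makes QC idempotent). The heterozygosity
threshold is not pinned by the study design and defaults to 0.30 by symmetry
with the failure threshold; it is configurable.

Because the organism selfs, haplotype construction assumes homozygosity: any
individual with a residual HET call is excluded; at most one MISSING call
per chromosome is imputed to the sample's major allele, otherwise the
individual is excluded. Chromosome-wide haplotypes are the ordered allele
strings; the RWH identifier is the concatenation of the region's two CWH
strings, so identity is determined by the genotype itself.

Within each replicate population and region, RWHs are ranked by the maximum
frequency they reach across that replicate's genotyped generations (ties:
total count, then lexicographic id); the top `k` (default 3) are *primary*
and the rest are pooled into one *background* pseudo-RWH per region
(H0A/H0B/H0C). Replicates within a regime are modeled as draws from the same
regime-level frequencies, so pooling sums counts; the regime-level primary
set is the union over replicates (re-grouped from the raw counts, so an RWH
that is background in one replicate but primary in another keeps its full
count).

## Likelihood and fitting

Two data types enter the likelihood (natural logs):

* genotype counts `n_{c,l}^[h]` per regime `c`, epoch `h`, RWH `l`, with a
  multinomial term `Σ n log p_l^[h]`, where `p_l^[h] = Σ_k 1(l∈S_k) g_k^[h]`
  is the marginal predicted RWH frequency. Observed RWHs outside the sampled
  lineage set are folded into their region's background pseudo-RWH; a
  predicted marginal below 1e-12 is floored with a warning counter rather
  than returning −∞.
* population-mean fitness assays `φ` with a log-normal noise kernel,
  `−Σ [log(Σ_k λ_k(x_m) g_k^[h] / φ)]²`. Only the ancestral-epoch assays at
  25 and 305 mM are used in fitting by default; intermediate environments
  are held out for validation. The relative weight of the fitness term is
  configurable (default 1).

The fitness term is what identifies the absolute scale of the intercepts: a
uniform intercept shift within one region changes every lineage's absolute
fitness but no frequency. The complementary direction — adding a constant in
one region and subtracting it in another — cancels inside every lineage and
is exactly null; only region-summed norms are meaningful, which is why
reported quantities are lineage-level norms and crossing points.

Epoch frequencies depend on parameters only through per-epoch cumulative
environment features (Σx², Σx, generation count), so the likelihood and its
analytic gradient are batched softmax algebra; the gradient matches central
finite differences to ~1e-7 relative. Optimization is L-BFGS-B from
`n_starts` random starts (slopes U(−0.02, 0.02) per mM, intercepts U(−1, 2),
quadratic terms U(−1e-4, 1e-4) per mM²; these bracket per-generation growth
rates between roughly e⁻¹ and e² across the assayed salt range), tolerance
1e-8, at most 5000 evaluations; best final log-likelihood wins, ties broken
by smaller parameter norm. All seeding derives from one master seed through
`numpy.random.SeedSequence((master, draw, …))` counters.

### Ancestral resampling

The ancestral pair (A, g⁰) is not observed: each individual is genotyped in
one region only, so cross-region linkage is invisible. Per ensemble draw,
region-level RWH frequencies are sampled from Dirichlet(counts + 1) — the
posterior under a uniform prior, so draw-to-draw spread reflects the
ancestral sample size; the plug-in proportions are available via
`dirichlet_alpha=None`. The lineage set is every combination of primary RWHs
across regions (primaries taken as the union over regimes, so a haplotype
that only became prominent during evolution still enters), plus `2 ×
replicates` secondary lineages drawn one-RWH-per-region proportionally to
the region frequencies; g⁰ is the product of constituent frequencies
(linkage equilibrium), renormalized. Background pseudo-RWHs participate as
ordinary RWHs. Fitting is repeated per draw (default 20 draws) and
trajectory quantiles (2.5/50/97.5%) across draws, matched by RWH
composition, give the credible envelopes.

## Stochastic layer

Selfing without recombination makes lineages asexual clones, so drift is
exact multinomial resampling of `N` lineage labels per generation, applied
after the deterministic selection update (viability selection before
reproduction). Frequencies live on {0, 1/N, …, 1}; 0 and 1 are absorbing.
Founder-effect bottlenecks (freeze/revive) are a single multinomial draw of
the founder count. A *sweep* is the target lineage reaching a frequency
threshold (default 0.5) by a stated generation — not fixation; a *loss* is
frequency 0 at any time. The default sweep probability estimator is the
fraction of forward-simulated replicates that sweep, with binomial standard
errors; census `N` is used directly (emulate a smaller effective size by
passing a smaller `N`).

## Synthetic data generator

The generator emulates the study design: three regions; replicate structure
sudden×4 / gradual×7 / control×3; epochs {0, 10, 35, 50}; 64 ancestral and
16 evolved individuals per region per sample; census 1e4; fitness assays at
{25, 225, 305} mM with log-normal noise (sd 0.1 on the log scale — small
relative to the ~1-log-unit fitness contrasts between lineages). Planted
norms are linear; the intermediate-best lineage declines mildly from log 4
offspring/capita at 25 mM (slope −0.001/mM) and the extreme-best lineage's
slope exceeds it by the slope contrast (default 0.003/mM) with the intercept
set in closed form so the two cross exactly at the requested concentration
(default 225 mM, the validated crossing region). Other lineages are drawn
below the focal maximum at both 25 and 305 mM. The default ancestor holds 6
coherent (fully linked) lineages with the extreme-best rare (5%) —
emulating a selfing population's strong linkage. Each RWH gets a random
binary allele string (60 SNPs/chromosome) with pairwise Hamming distance
≥ 4. SNP emission is homozygous REF/ALT; uniform missingness is the only
platform error model.

What the generator does **not** emulate: residual heterozygosity,
outcrossing, mutation, recombination, genotyping batch effects, and linkage
*dis*equilibrium decay — so passing tests demonstrate correctness of the
estimator under its own assumptions, not robustness to those features of
real data.

Two granularities exist: full SNP-level tables (which must round-trip the
haplotype pipeline exactly) and direct RWH count tables drawn from the same
multinomial laws, used for repeated recovery studies where SNP emission adds
nothing.

## Validation studies and problem sizes

`normsel.validation` packages the operating-characteristic studies:

* **Recovery** (50 seeds): counts at the design scale with 2 regimes × 4
  replicates; one ancestral draw and a 6-start fit per seed; measures the
  rate at which the fitted lineage fitness at 305 mM ranks the extreme-best
  lineage on top, and the rate at which the fitted focal crossing falls
  within ±25 mM of the planted 225 mM.
* **Envelope coverage** (3 seeds × 20 ancestral draws, horizon 50):
  coverage of the 95% envelope for the focal *marginal RWH* trajectories.
  Lineage-level frequencies are not comparable between the linked truth and
  the linkage-equilibrium lineage sets the method samples, so coverage is
  evaluated on the observable marginals. Known limitation: the envelope
  propagates ancestral-sampling uncertainty only (resampling (A, g⁰)), not
  the multinomial noise of the evolved counts, and is therefore
  anti-conservative: the fitted trajectories track the observed counts, and
  where a realized count deviates from its expectation the planted truth can
  sit outside the envelope for stretches of generations. Coverage around
  0.6–0.9 per seed is typical at this design scale.
* **Drift calibration** (2000 replicates): neutral fixation probability vs
  initial frequency (N=30, 400 generations); founder loss of a 1/1000
  lineage through a 100-founder bottleneck vs the closed form 0.999¹⁰⁰;
  large-N convergence of the mean trajectory to the deterministic one.
* **Headline contrast** (N=1000, 1000 replicates): the extreme-best lineage
  (ancestral frequency 5%) is lost by the time the environment reaches
  305 mM far more often under the gradual schedule than the sudden one, and
  its deterministic generation-50 frequency is lower under gradual — slower
  environmental change hinders adaptation from standing variation.

## Numerical choices

* Simplex checks at 1e-9 on input, conservation asserted at 1e-12.
* Log-space dynamics throughout; no clipping of deterministic frequencies.
* Likelihood floor 1e-12 on predicted marginals, with a warning counter.
* Optimizer: L-BFGS-B, `ftol` 1e-8, `gtol` 1e-9, `maxfun` 5000.
* Ranking tie-breaks (max frequency, then total count, then id) make the
  grouping deterministic; ensemble lineages are matched across draws by RWH
  composition, with frequency 0 where a composition is absent from a draw.

## Known limitations

* Per-RWH parameters are only identified up to cross-region intercept
  transfers; interpret lineage-level (region-summed) norms.
* No standard errors from the Hessian; uncertainty is the ensemble envelope,
  with the anti-conservatism noted above.
* The sweep-probability estimator is a forward-simulation analogue and is
  not numerically comparable to discrepancy-based estimators computed from
  pooled genotyping data.
* VCF ingestion and haplotype imputation/phasing are out of scope (genotype
  tables are assumed homozygous after QC).
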