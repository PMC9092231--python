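# Methods

## Setting and assumptions

A closed population of unknown size *N* is sampled in *k* ≥ 2 encounter
events. Individual *i* has capture indicator x_ij ∈ {0,1} at event *j*;
observed individuals are those with at least one capture, so the data are
counts x_h over the 2ᵏ − 1 observable histories and the quantity of
interest is the empty cell x₀ = N − n, with n = Σ x_h the number of
distinct individuals seen. Throughout we assume the population is closed
over the study (short field windows), identifiers are neither lost nor
misread, and each event is a Bernoulli sample of the population. The
estimators differ in what they assume about *independence between events*
and *homogeneity across individuals*.

## Data dialects and the event-count inversion

Three input dialects are supported: capture-history tables (one count per
observable history), individual records (one 0/1 row per observed
individual, one column per event), and aggregate **event-count** data, in
which event *j* records only 2^(j−1) tallies — its count cross-tabulated
by receipt of the previous events' identifiers. Event-count data carry
exactly the same 2ᵏ − 1 numbers as a history table, aggregated by the
*first part* of each history: ec_j(S) = Σ_{F ⊆ {j+1..k}} x_{S∪{j}∪F}.
The converter inverts this by backward recursion over j = k..1,
subtracting already-resolved later-capture histories; a negative
intermediate value means the tallies are mutually inconsistent (recording
error or identifier loss) and is reported as such, naming the offending
cell. The inversion is exact; the round trip with the forward aggregation
is the identity, property-tested over random tables for k = 2..5.

Validation fills missing observable cells with explicit zeros (and says
so): downstream models need all 2ᵏ − 1 cells, and an absent row is almost
always an observed zero, not missing data. Counts must be integers;
duplicate patterns and the all-zero pattern are hard errors. One
published description of the individual-level dialect reads as one row per
*encounter*, but its accompanying example is one row per *individual* with
one column per event; we implement the latter, which is the only version
from which histories are recoverable without record linkage.

## Log-linear estimators

Expected cell counts are modelled as log μ_h = x_hᵀβ and fit by Poisson
IRLS (statsmodels GLM; relative tolerance 1e−10, max 100 iterations) over
the observable cells only. Every design column vanishes at the all-zero
history, so the empty cell extrapolates to exp(β₀) and
N̂ = n + exp(β₀). Columns by model class: M₀ uses the capture count c_h;
M_t one indicator per event; M_h adds a heterogeneity column g(c_h); M_th
uses event indicators plus g(c_h). The heterogeneity shapes are
g(c) = 2ᶜ − 1 (Poisson2), c²/2 (Darroch), −log(c + 3.5) + log 3.5
(Gamma3.5); all satisfy g(0) = 0, keeping the intercept the empty-cell
extrapolation. The base 2 and shape 3.5 are configurable module constants.
Darroch and especially Gamma3.5 produce larger corrections (and estimates)
than Poisson2 on heterogeneous data; the suite tests this as a statistical
tendency. With k = 2 the heterogeneity column is collinear with the
design, so M_h/M_th are excluded from comparison rather than fit-and-warned.

Uncertainty: Var(N̂) = exp(β₀) + exp(2β₀)·Var(β̂₀) (delta method with the
Poisson term for the empty cell), with the Wald interval built on the
log(N̂ − n) scale so the lower bound cannot cross n. A profile-likelihood
interval is available as an option (`--profile-ci`): the empty cell is
included with pseudo-count N − n and the profile deviance compared to the
χ²₁ cutoff. AIC = −2ℓ + 2p and BIC = −2ℓ + p·log n from the Poisson
likelihood of the observable cells; comparison rows sort by AIC, ties by
BIC then parameter count, and per-model failures become flagged rows
rather than aborting the table.

**Two facts about the estimator worth knowing.** First, M_t with k = 2 is
algebraically the Lincoln–Petersen estimator n₁n₂/m (the three-cell fit is
saturated); this is tested exactly. Second, N̂ = n + exp(β₀) is the
*conditional* MLE: it maximises the observable-cell likelihood and
extrapolates. The unconditional multinomial MLE over (N, p) sits O(1)
below it (about 0.7–2 individuals on small tables). The suite therefore
cross-checks the fit against a plain grid search of the estimator's own
likelihood surface (agreement to the grid) and against the exact
multinomial grid argmax (agreement within a couple of individuals).

**Chao bound.** N̂ = n + f₁²/(2f₂) from singletons and doubletons, with
the bias-corrected n + f₁(f₁−1)/(2(f₂+1)) when f₂ = 0 and Chao's 1987
variance. The log-linear "chao" variant saturates the c ≥ 3 cells
(indicator columns) over an intercept + c base; a plain design of that
shape extrapolates to (k−1)/k · f₁²/(2f₂), so we add a fixed offset
log(k/(k−1)) to the doubleton cells, which makes the M_h-chao GLM
extrapolation equal the moment bound exactly (tested to 0.5). The fit is
flagged `is_lower_bound`; its value bounds N rather than estimating it.

**Normal (logit-normal) mixing.** The M_th-normal model gives individual
*i* capture probability expit(μ_j + ε_i) with ε ~ Normal(0, σ²). History
probabilities are integrated by 20-node Gauss–Hermite quadrature and the
*conditional* multinomial likelihood of the observed cells is maximised by
L-BFGS-B over (μ₁..μ_k, log σ), multi-started from three σ scales so the
homogeneous boundary is covered; then N̂ = n/(1 − P₀). The standard error
comes from the numerical observed information of the Poissonised
likelihood in (log N, μ, log σ).

**Pairwise diagnostics.** Each of the C(k,2) event pairs is collapsed to a
two-list table and estimated with Chapman's (n_a+1)(n_b+1)/(m+1) − 1 and
Seber's variance, interval truncated below at n_a + n_b − m. Discordant
pairs point at list dependence; zero-overlap pairs are flagged as
lower-bound-only.

## Bayesian model averaging over decomposable models

List dependence is modelled as a graph on the k events; attention is
restricted to decomposable (chordal) graphs, for which the hyper-Dirichlet
prior on the full 2ᵏ table gives a closed-form marginal likelihood
factorising over cliques C and separators S of a junction forest:

  P(x | m, N) = multinomial coeff × Π_C h(C) / Π_S h(S),
  h(A) = Γ(α_A)/Γ(α_A + N) · Π_cells Γ(α_cell + n_cell)/Γ(α_cell),

with per-marginal-cell prior weight α_cell = δ·2^(k−|A|) and
α_A = δ·2ᵏ. The empty cell contributes N − n to every all-zero marginal
cell, so for a grid over N only a handful of gammaln terms change and the
whole grid vectorises. The cell weight δ (default 2^(−k)) is the
complexity control: smaller δ penalises rich interaction structures. The
model prior is uniform over the enumerated graphs — δ already does the
complexity work — with a pluggable `model_log_prior` hook for anything
stronger.

Chordality testing, cliques, and separators come from an in-package
maximum cardinality search (the MCS order is a perfect elimination order
iff the graph is chordal; running intersections of the clique sequence
give the separators, empty ones joining components). Enumeration covers
all labelled graphs for k = 3..5 (8, 61, 822 decomposable models); beyond
5 lists the space explodes and the bound is enforced. The saturated-model
marginal is verified against scipy's Dirichlet-multinomial pmf, the
independence model against a per-list factorisation written in plain
gammaln arithmetic, and the enumeration against networkx chordality over
all graphs.

The prior over N is either the scale-invariant improper 1/N on
{n..N_max}, or a log-normal elicited from a believed median and 90th
percentile: μ = ln median, σ = ln(q90/median)/z₀.₉₀ (z₀.₉₀ ≈ 1.2816),
truncated at N_max. N_max defaults to 20·n when unspecified — some
truncation is required and twenty-fold the observed count is past any
plausible posterior mass in a study worth fielding. The default grid
steps by max(1, (N_max − n)/50000); accumulation is in log space with
max-shift. The posterior reports the mean (point estimate), median,
equal-tailed credible interval, per-model posterior probabilities, and
the full grid for plotting.

## Latent-class sampler

The nonparametric alternative posits latent classes c = 1..K* with
per-event capture probabilities λ_jc and stick-breaking weights
π_c = ν_c·Π_{l<c}(1 − ν_l), ν_c ~ Beta(1, α), α ~ Gamma(shape 0.25,
scale 0.25) — *shape/scale*, mean a·b = 0.0625, a deliberately diffuse
prior on how strongly few classes are preferred. λ has a Beta(1,1) prior;
the prior on N is the same 1/N convention as above, which makes the
unobserved count a negative-binomial draw. Each Gibbs sweep:

1. split each observed history's count over classes
   ∝ π_c Π_j λ^x (1−λ)^(1−x) (multinomial, cell-wise — the likelihood
   depends only on the history, so no per-individual loop);
2. draw n₀ ~ NegBin(n, 1 − p₀) with p₀ = Σ_c π_c Π_j (1 − λ_jc), and
   split it over classes ∝ π_c Π_j (1 − λ_jc);
3. λ_jc ~ Beta(1 + captures, 1 + misses) over class members including the
   imputed unobserved;
4. ν, α from their full conditionals, recording N = n + n₀ after burn-in
   at the thinning interval.

Defaults: K* = 10, 10,000 kept samples, 10,000 burn-in, thinning 10;
`FSW_FIELD_PRESET` bundles the heavier settings used for a large field
study (100,000 / 100,000 / 100). Draws are deterministic given the seed.
If the occupied-class count hits K* in more than 5% of kept sweeps the
result warns to raise K* (the threshold is ours; the truncation only needs
to be "large enough"). k = 2 and single-history tables run but warn of
weak identifiability.

One numerical point matters: sticks are drawn through the two-Gamma
construction *in log space*, using the Gamma shape-boost identity
G_s = G_{s+1}·U^{1/s} for the small-shape component. Drawing ν directly
and clipping 1 − ν truncates the heavy lower tail of log(1 − ν) when α is
small, which visibly biases α's Gibbs chain (stationary mean drifted to
0.09–0.20 against the exact 0.0625 in a no-data chain); the log-space
draw reproduces the prior exactly, and the no-data invariance is unit
tested against an independent exact-arithmetic chain.

Diagnostics: ESS = M/(1 + 2Σρ_t) with Geyer's initial positive sequence
truncation (FFT autocorrelations); a linear-trend z statistic on the
trace, flagged at |z| > 3 as a burn-in warning — a numerical stand-in for
the visual trend check, not a calibrated test. Aim for ESS above ~1000
before quoting intervals. A constant chain reports ESS = M with a
degenerate-chain warning.

## Study-design simulation (and the synthetic-data generator)

Design precision is estimated by simulating whole studies. Heterogeneity
is a shared individual logit effect: capture of individual *i* at event
*j* with probability expit(μ_j + ε_i), ε ~ Normal(0, σ_h²). The amount is
elicited as an odds ratio r at quantile q ("q of the population has
capture odds below r× the average"), σ_h = ln(r)/Φ⁻¹(q) — the odds
multiplier exp(ε) relative to the ε = 0 individual, the natural reading
in this logit-normal model. Intercepts μ_j are calibrated by quadrature +
Brent root-finding so the *expected* per-event totals equal the planned
sample sizes (capture is Bernoulli, so planned sizes are expectations, not
quotas — the estimators assume exactly that sampling). Homogeneous
designs are estimated per replicate with M_t, heterogeneous ones with
M_th-normal, i.e. the estimator family matched to the generator. The
output table reports, over replicates, the fraction of estimates within
2.5/5/7.5/10/15/20% of truth and the 50/80/90/95th percentiles of
absolute relative error; failed fits are counted separately and more than
20% of them aborts with advice to enlarge the samples.

This generator is also the repository's synthetic-data source for the
estimation modules' tests. It emulates Bernoulli capture with shared
logit-normal heterogeneity and independent events; it does *not* emulate
list dependence, behavioural response to capture, population turnover, or
identifier loss — so passing tests demonstrate correct estimation under
the models' own sampling assumptions, not robustness to their violation
(the BMA tests generate dependence implicitly through model comparison on
independent data only).

Problem sizes in the shipped tests and acceptance script are chosen to
keep the whole suite at desk scale: 1000 replicates for the headline
design scenario (N = 20,000; samples 4410/2675/2519; r = 1.2 at q = 0.9),
which reproduces an 80th-percentile relative error near 7.7%;
120–500 replicates for bias/monotonicity tendencies; MCMC chains of a few
thousand sweeps for recovery checks, versus the 10⁴–10⁵ defaults meant
for real analyses.

## Known limitations

- Log-linear variance uses the delta method on the conditional fit;
  intervals can be optimistic on very sparse tables (use `--profile-ci`).
- The heterogeneous-model variants are often weakly identified; AIC/BIC
  can select badly among them, which is exactly why the comparison table,
  the pairwise diagnostics, and the averaged/latent-class estimators are
  shipped together rather than a single "best" model.
- BMA is limited to k ≤ 5 lists and decomposable dependence structures.
- The latent-class posterior can be multimodal (few-class vs many-class
  explanations); with weakly separated classes chains mix slowly between
  modes — watch the occupied-class trace and ESS.
- No record linkage: the data model assumes identifiers are already
  resolved; behavioural (M_b) and covariate models are out of scope.
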