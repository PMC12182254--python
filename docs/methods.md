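# Methods

## Model

Each subject *j* carries a latent node-position vector γ_j ∈ R^V and a
latent behavior score κ_j ∈ R. Connectivity edges follow a rank-1
eigenmodel with a per-subject intercept,

    c_{x,y,j} = d_j + γ_{x,j} γ_{y,j} + ε_{x,y,j},   ε ~ iid N(0, τ²),

summed over unordered node pairs x < y only; matrix diagonals carry no
information and are stored as 0. Behavioral indicators are exchangeable
measurements of the score,

    b_{j,p} = e_p + κ_j + ν_{j,p},   ν ~ iid N(0, σ²),

and the latents are coupled through a joint Gaussian,

    (γ_j, κ_j) ~ iid MVN((μ, 0), Σ),   Σ ∈ R^{(V+1)×(V+1)} SPD.

The cross block Σ[v, V+1] is the node–behavior covariance — the quantity
reported as biomarker strength. μ is the shared population connectivity
pattern; κ's mean is fixed at 0 because its location is absorbed by the
indicator intercepts e_p.

### Why a nonzero latent mean

With μ = 0 and a diagonal node block, the model is exactly symmetric under
joint negation of one subject's (γ_j, κ_j): the edge likelihood is even in
γ_j and a zero-mean Gaussian prior is symmetric. For a subject whose
behavior is masked (a test subject), nothing then pins the sign, the
posterior predictive mean of κ_j is exactly 0, and transductive prediction
is impossible *in principle*. Real connectomes do not look like that:
subjects share a strong common connectivity pattern, and it is precisely
this shared pattern that anchors the orientation of an individual's latent
vector. The package therefore models μ explicitly (conjugate Gaussian
update, prior N(0, 100·I)) and the synthetic generator plants
`gamma_mean = 1.0` by default. The analytic accuracy ceiling (below) is
unchanged by μ, but becomes attainable.

One global reflection remains: (Γ, μ, Σ-cross) → −(Γ, μ, Σ-cross) is an
exact symmetry of model and priors. Predictions are invariant under it;
reported node covariances are oriented by convention — each retained draw
is sign-aligned to a running reference (so the two modes cannot cancel in
the average), and the final summary is flipped, if necessary, so the net
node–behavior covariance is non-negative.

## Priors

Weakly informative conjugate choices enabling a pure Gibbs sampler:
d_j ~ N(0, 100), e_p ~ N(0, 100), μ_v ~ N(0, 100),
τ², σ² ~ InvGamma(2, 1), Σ ~ InvWishart(V+3, I) (the smallest proper
degrees of freedom keeping the prior diffuse). All are configurable via
`PriorSpec`.

## Sampler

A blocked Gibbs sweep updates, in order: each node column of Γ
(conditionally Gaussian — the rank-1 term is bilinear, so holding the
other columns fixed linearizes the likelihood), a per-subject sign-flip
Metropolis move (Γ_j → −Γ_j leaves the edge likelihood invariant; the
acceptance ratio is the latent-prior ratio), κ, d, e (conjugate normal),
τ², σ² (conjugate inverse-gamma), μ (conjugate normal), and Σ (conjugate
inverse-Wishart on the centered latent rows). Subjects with fully missing
behavior receive κ from the Γ-conditional alone — the mechanism of
transductive prediction.

Validation is two-fold: a Geweke-style joint-distribution test compares
the marginal-conditional sampler (draw parameters from the prior) against
the successive-conditional sampler (alternate data-given-parameters with
one Gibbs sweep); matching moments for every monitored statistic is a
sharp necessary condition for the correctness of all full conditionals.
Under the stated priors the raw moments of τ², σ² and the Σ cross entries
have infinite prior variance (InvGamma(2,1); InverseWishart at minimal
degrees of freedom), so the monitored statistics are monotone transforms
with finite variance: log τ², log σ², and the latent node–behavior
correlation Σ[0,V+1]/√(Σ[0,0]Σ[V+1,V+1]). The μ block mixes very slowly in
this prior-predictive test (its conditional is far tighter than its
prior), so it is verified separately against its closed-form conditional.
Convergence in applied runs is monitored with split-chain Gelman–Rubin R̂
(cross-checked against arviz in the tests).

### Initialization

Chains start from a per-subject rank-1 fit of the connectome: alternating
leading-eigenpair extraction (with diagonal imputation) and intercept
refinement — the intercept must be co-estimated because subtracting a
misestimated constant from every edge destroys the rank-1 structure.
Per-subject eigenvector signs are then synchronized to the common
population direction via the leading eigenvector of the subject Gram
matrix (a spectral Z2-synchronization step); a disordered sign assignment
is a deep local mode of the posterior that plain Gibbs cannot escape at
realistic N. Seeded Gaussian jitter (sd 0.1) keeps multiple random
initializations distinct; the multi-start protocol (default 10
initializations, selection by held-out predictive correlation, ties to the
lower index) remains available through `fit_predict`.

## Prediction protocol

`make_split` draws a random 90/10 subject split (train size =
round-half-up). `fit_predict` masks test-subject behavior, fits on all
connectomes, and predicts with the posterior mean of e_p + κ_j.
`crossval` repeats this on independent splits (seed = base + repeat
index) — the repeated-random-split reading of the protocol — and records
one accuracy (Pearson correlation; NaN-flagged when a vector is constant,
excluded from averages) per indicator × repeat. A validation-split
selection mode is deliberately not the default: selection by test-sample
fit is reproduced as specified.

## Condition and network regressions

Accuracy records are regressed on condition dummy indicators by OLS
(statsmodels). With dummies only, the intercept is the reference
condition's mean accuracy and each coefficient a condition-vs-reference
mean contrast — asserted against direct group-mean oracles in the tests.
R² is reported descriptively and defined as 0 when the total sum of
squares vanishes. The same machinery regresses |node covariance| on
functional-system dummies (reference = alphabetically first system).

## Biomarker detection

Node covariances are averaged entrywise across cross-validation folds;
the top 10 strictly positive and top 10 strictly negative entries form
the biomarker selection (ties to the lower node index; zeros belong to
neither list; fewer available signed entries simply truncate the list).
Selections are profiled per functional system with zero counts retained
(fixed spider-plot axes) and reduced to within-group edge lists for
circle-plot rendering; the elements highlighted are node groups, with the
edges among each signed group taken from the group-mean connectome.

## CPM baseline

Features are the row-wise upper triangle including the diagonal, length
(V²+V)/2. Edges are screened by the p-value (t transform of the Pearson
correlation with the training outcome) at threshold 0.001, split by
correlation sign, and summed into per-subject positive/negative network
strengths; the final fit regresses the outcome on both strengths (single
summary when one set is empty; training mean with an `empty` flag when
none survives). Constant features — e.g., diagonal self-edges under a
zero-diagonal convention — are dropped with a warning. An L2-penalized
baseline (scikit-learn Ridge/RidgeCV, penalty chosen by internal CV on
the training set) is provided alongside.

## Synthetic-data generator

`SimulationDesign` runs the generative equations forward. Defaults are the
planted-recovery study conditions: V=30 nodes, N=150 subjects, P=4
indicators, 10 biomarker nodes with cross-covariance 0.3, τ² = σ² = 0.5,
unit latent variances, intercept spreads 0.5, population pattern
`gamma_mean = 1.0`. Σ's node block is diagonal by default (a dense-SPD
option exists for robustness checks); the SPD feasibility bound
|cross| < √(γ-var · κ-var / #biomarkers) is enforced with an informative
error. `simulate_conditions` draws κ and the behaviors once and each
condition's Γ from its κ-conditional, emulating one cohort scanned under
several conditions with condition-specific signal. The analytic accuracy
ceiling

    √(Σ_κγ Σ_γγ⁻¹ Σ_γκ) / √(Σ_κκ + σ²)

is the maximum correlation any connectome-based predictor can reach for a
single indicator in the noiseless-connectome limit; it is the oracle the
small-noise experiment is checked against.

What the generator does **not** emulate: spatial autocorrelation of real
parcellations, non-Gaussian/heavy-tailed edge noise, site or motion
artifacts, rank-&gt;1 connectivity structure, and realistic BOLD
autocorrelation (the white-noise time-series helper exists only to
exercise the Fisher-z constructor). Passing tests therefore demonstrate
internal consistency of model + protocol, not robustness to real-data
violations.

## Experiment sizes and numerical choices

The packaged experiments use desk-scale problem sizes chosen once:
recovery at the default design with 1000 burn-in + 2000 retained sweeps
across 3 generator seeds; Geweke at V=4, N=8 with 20k draws; the
condition-differential, averaging and baseline comparisons at V=16,
N=100, P=3 with 400 burn-in + 800 retained sweeps and 5 repeats; the
ceiling check at V=10, N=120 with near-maximal cross-covariance and
τ²=0.01, σ²=1e-4. SPD checks tolerate eigenvalues down to −1e-8 times the
largest; 1e-8 jitter is added before Cholesky/inversion; correlations are
clipped to 1−1e-7 before atanh. All randomness flows through
numpy Generators seeded from user-visible integers; every stage is
bit-reproducible under a fixed seed.

## Known limitations

- One-dimensional latent positions by design; no multi-dimensional
  eigenmodel.
- The node-covariance sign is identified only relative to the global
  orientation convention; magnitudes and relative signs are what carry
  information.
- Selection of the best initialization by test-sample correlation leaks
  test information into model choice; it is reproduced as part of the
  protocol under study, not endorsed.
- No fMRI preprocessing: inputs are assumed to be clean Fisher-z
  connectivity matrices.
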