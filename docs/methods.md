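# Methods

This note records the models the package implements, the assumptions and
defaults behind them, what the synthetic generator does and does not
emulate, and the numerical choices that were genuinely open.

## Connection weights and laminar fractions

An injection record carries per-source labeled-cell counts split at the
centre of layer 4 (supragranular above, infragranular below). FLN is the
source's count over the total extrinsic count of that injection, so each
injection's extrinsic FLN values sum to one by construction; the
intrinsic (target-area) row is stored but excluded from numerator and
denominator, and its matrix entry is fixed at exactly 0.

Across repeat injections in the same target, FLN is averaged
arithmetically with absent connections contributing 0 — this is the only
convention under which the averaged row still sums to one. SLN is
aggregated as a weighted mean with weights equal to each injection's
total labeled-neuron count in the source, which makes the aggregate
identical to the pooled supra/(supra+infra) fraction; pooling is the
natural choice because the underlying datum is a cell count, not a
ratio. SLN is undefined (NaN/None, never a number) for agranular
sources — by default APir, Pir, Ent and A29a-c, overridable — because no
layer-4 boundary exists there.

Area codes are opaque, case-sensitive strings validated against a
user-supplied parcellation; no atlas is hard-coded.

## Hierarchy model

Each observed SLN of a projection X ← Y is modeled as
Beta-distributed with mean logistic(h_X − h_Y) and a single global
precision φ (mean–precision parametrization: shape parameters μφ and
(1−μ)φ). The log-likelihood is maximized jointly over {h} and log φ with
L-BFGS-B and an analytic gradient. Identifiability: one anchor area is
fixed at h = 0; reported indices are then affinely rescaled to [0, 1]
(raw logit-scale values are kept for prediction). Numerical choices:

* Only boundary observations (exact 0 or 1) are nudged off the boundary
  with (y(n−1)+0.5)/n; interior values are untouched — a blanket
  compression distorts small samples badly.
* The complement 1−μ is computed as logistic(−η) to avoid cancellation;
  h is bounded to ±10 on the logit scale and log φ to [−5, 12], which
  keeps the likelihood finite while exceeding any observable contrast
  (logistic(10) ≈ 0.99995); φ at the upper bound is a perfect-fit
  plateau.
* Initialization from the linear (logit-OLS) solution.

Observation weights default to 1. Optional labeled-neuron-count weights
(`count_weights=True`) markedly improve truth recovery on synthetic data
and recover the generating precision, because single-neuron sources
produce SLN values of exactly 0 or 1 whose unweighted influence
dominates the dispersion estimate; the same artifact exists in real
data, where the extremes of the SLN distribution come from connections
with very few labeled neurons.

A disconnected observation graph makes hierarchies incomparable across
components; the model warns and records the components. All SLN
identical sets a degenerate flag. The linear alternative clips SLN to
[1e−3, 1−1e−3] before the logit and solves the same signed-incidence
design by least squares; on model-generated data it agrees with the
beta fit in rank order.

A symmetry worth knowing: swapping target/source *and* complementing SLN
encodes the same projection seen from the other end, so the fit is
invariant under it; complementing SLN alone reverses the fitted ordering
exactly. The test suite checks both.

## Circular embedding

Radius R_i = √(1 − h_i) (top of the hierarchy central); angles minimize
the squared mismatch between −log₁₀ FLN and r·circdist(θ_i, θ_j) over
all connected ordered pairs, with the scale r ≥ 0 profiled out in closed
form and the anchor area (V1 in cortical data) fixed at θ = 0. Pairs
with FLN = 0 contribute nothing. The objective is invariant under global
reflection; the convention adopted is that the resultant of the
non-anchor angles lies in the upper half-plane. Optimization is
multi-restart L-BFGS (default 50 seed-controlled restarts); on small
instances the best objective matches a 1° exhaustive grid.

## Graph topology

The edge-complete subnetwork is the square over injected targets with
presence = FLN > 0 and an empty diagonal. Dyad and triad censuses use
the standard 16-class directed triad taxonomy (via networkx). The null
model preserves both degree sequences exactly by checkerboard edge
swaps — two random edges (a,b), (c,d) become (a,d), (c,b) unless a
self-loop or duplicate would result — with 10·M successful swaps per
realization (a standard mixing heuristic, exposed as a parameter); a
graph admitting no valid swap is returned unmodified with a warning.

A clique requires all ordered edges (100% directed density), i.e. it is
a clique of the mutual-edge graph; proportions divide counts by C(n, k).
The core is the union of the member sets of all maximum-size cliques —
the rule implied by a core of several overlapping maximum cliques — and
densities are reported within core, within periphery, and between (both
directions pooled; undefined blocks are NaN). Exhaustive clique counting
is exponential in the worst case and is guarded by a count cap.

Functional similarity of a pair is 1 − cosine similarity of their binary
in- or out-profiles with the entries involving the pair removed
(undefined for all-zero profiles). Connection probability versus
similarity distance s is a Bernoulli ML logistic fit on unbinned ordered
pairs, p(s) = 1/(1 + exp(a + b·s)); the reciprocal and unidirectional
pair curves p² and 2p(1−p) assume directional independence given s.
Degenerate or separated outcomes are flagged and handled by a saturated
or IRLS fallback. The logistic form and the cosine profile distance are
package choices validated against the qualitative shape of the empirical
binned curves; the source literature does not pin them down.

## Exponential distance rule

Lengths are histogrammed in 2 mm bins, heights normalized by the total
count (so heights sum to one, matching how projection-length histograms
are conventionally drawn), and a line is fitted to log₁₀ height versus
bin centre over nonempty bins. Conversions: λ = −slope·ln 10 (λ = 0 for
a non-negative slope), c = 10^intercept. The published coefficient pair
(−0.1295, −0.0262) converts to λ = 0.298 ≈ 0.3 mm⁻¹ and c = 0.94; the
printed formula's inner "log10(projection length)" is treated as a
typographical slip, since only a fit linear in d yields exactly these
constants.

The fit is weighted by √count by default: the variance of log of a
Poisson count is ≈ 1/count, and equal weighting lets the sparse far bins
(whose log heights are biased low) drag the slope steep — measured on
the package's own recovery setup (10⁵ exponential(0.3) lengths), equal
weighting errs by up to ~8% on unlucky seeds while √count weighting
stays within 1%. `weighting="equal"` reproduces the plain fit.

The sliding-window profile of log₁₀ FLN versus interareal distance uses
a 173-point window advanced by 20 points (both exposed; the overlap
scheme in the source figure caption is ambiguous, and this reading
reproduces its point density). Distance-distribution comparisons use the
two-sided two-sample KS test plus ML Gaussian fits of both samples.

The allometric model is OLS of log₁₀ λ on log₁₀ gray-matter volume
across species; species values are user-supplied inputs, never
hard-coded. On points generated exactly from a power law the fit is
exact to machine precision.

## Synthetic generator

The generator emulates, with a single master seed feeding a splittable
`SeedSequence`:

* geometry: areas uniform in a 3-D box (default 20 mm), giving unimodal,
  approximately normal pairwise distances with a ~13 mm mean and ~35 mm
  maximum — the scale of marmoset wiring distances;
* weights: expected extrinsic count ∝ exp(−λd)·10^ε, ε ~ N(0, σ_log10),
  defaults λ = 0.3 mm⁻¹ and σ = 1.0;
* counts: multinomial allocation of a per-injection budget, so FLN
  normalization is exact (the definitional property of a fraction);
  the realized budget is log-normal around an expected 10⁴ neurons with
  0.5 orders of spread, reflecting the strong variation of tracer uptake
  across real injections — without it a fixed budget imposes a hard
  detection floor at FLN = 1/budget that truncates the weight
  distribution near 4 orders of span;
* laminae: supragranular counts beta-binomial with mean
  logistic(h_target − h_source) and concentration κ = 20, giving SLN the
  overdispersion real laminar counts show;
* lengths: exponential(λ) truncated at the maximum pairwise distance;
* replicates: independent injections sharing ground truth, with optional
  extra log-normal jitter of expected weights (the between-injection
  noise law is not characterized empirically; log-normal is a modeling
  choice, exposed as a parameter).

Under the defaults a 55-of-116 synthetic study shows ~62% edge-complete
density, ~3 900 of 6 380 present connections and log₁₀ FLN spanning ~4.8
orders — the regime of the real atlas. What the generator does **not**
emulate: cortical geometry (folding, laminar thickness, white-matter
routing — distances are Euclidean), tracer chemistry and uptake-zone
effects, areal-border uncertainty, hemispheric asymmetries, and any
spatial correlation of the hierarchy. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated generative
assumptions, not robustness to these real-data complications. At large
sample sizes the single-neuron detection floor visibly censors the
lower tail of log FLN, so strict normality tests reject on pooled
high-noise samples even though the latent weights are log-normal.

## Statistical tests and effect sizes

Feedforward (SLN > 0.5) versus feedback (SLN < 0.5) weights are compared
on log₁₀ FLN with the two-sided two-sample KS test, the equal-variance t
test (equal variances chosen because the accompanying F test of the
variance ratio is reported alongside), the two-sided F test, and Hedges
g — pooled-SD standardized mean difference with the small-sample
correction 1 − 3/(4·df − 1). Projections with SLN exactly 0.5 are
unclassified and excluded. Normalized density histograms divide counts
by bin size and total n, with bins anchored at integer multiples of the
bin size so histograms are reproducible.

Microstructure: hierarchy indices are normalized by their maximum, then
averaged within area groups sharing a published spine count (the
alternative — duplicating the spine count per member area — is a mode
flag). Power laws are fitted by log–log OLS, which is scale-free and
exact on noiseless power-law data.

## Pipeline

`run_all` executes matrices → weights → topology → hierarchy/embedding →
spatial → (optional) microstructure → (optional) ground-truth recovery,
writing one JSON per stage plus provenance (SHA-256 of inputs, seed,
versions). All randomness flows from the configured seed; re-running
with the same inputs and seed reproduces the stage reports byte for
byte. Any stage failure aborts with a stage-tagged error. Default
problem sizes in the test suite and acceptance script (30–55 areas, 10⁵
lengths, 100 null realizations, 20–50 embedding restarts) keep a full
run at desk scale on one CPU.

## Known limitations

* The hierarchy precision φ is a single global parameter; per-target
  dispersion is not modeled.
* The embedding objective is non-convex; multi-restart local search can
  in principle miss the global optimum on large instances (on small ones
  it matches exhaustive search).
* Clique counting is exact and therefore exponential in pathological
  dense graphs; the cap surfaces this rather than silently truncating.
* Statistics that depend on the real atlas (its density, dyad mix,
  clique structure, core membership, and the biological orderings of
  specific areas) can only be checked when that matrix is supplied by
  the user; the package verifies the machinery on synthetic and toy
  graphs.
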