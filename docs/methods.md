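# Methods

## The model behind the estimator

A gene's molecular function is represented as a K-dimensional vector of
molecular phenotypes under Gaussian stabilizing selection around a single
optimum; mutations perturb all K components with (multivariate) normal
effects, and the optimum itself drifts slowly (microadaptation), which keeps
substitution possible even under strong selection. In this regime the mean
conservation of the protein, once adjusted for among-site rate variation,
depends on K through

    g = (dN/dS) / (1 - H) = 2^(-K/2) (1 + phi(K)),
    phi(K) = 0.0208 K (K + 2) / (1 + 0.289 K),

where 2^(-K/2) is the strong-selection limit of the per-site relative
substitution rate (each selected component multiplies the rate by a factor
that falls from 1 to sqrt(1/2) as its selection intensity grows) and
(1 + phi) is a finite-K correction. The estimate Ke obtained by inverting
this curve is *conservative*: components under weak selection attenuate the
rate less than their strong-selection share, so they are partially invisible
to the estimator and Ke <= K, with the bias shrinking as the baseline
selection intensity B0 grows. Se = -Ke * Be and Be = 2(g^(-2/Ke) - 1) map
the same fit onto selection-intensity scale; the Be closed form is this
package's reconstruction of the underlying stabilizing-selection result and
reproduces the published TPI1 worked values within 1%.

The estimator is therefore only defined for genes under purifying selection
with dN/dS in (0, 1), and g = (dN/dS)/(1 - H) must also be below 1; both are
enforced as hard errors.

## Per-site change counts and the multiple-hit correction

Counts of amino-acid changes per alignment column are minimum-change
(Fitch) parsimony scores on the tree, computed by the Hartigan
generalization so multifurcating (e.g. arbitrarily rooted unrooted) trees
are scored exactly; the score is invariant to root placement, which is why
an arbitrary rooting of the NJ output is legitimate. Missing residues (gap
`-` and ambiguity codes `X`, `B`, `Z`) carry the full alphabet and never
force a change; columns missing in every taxon are excluded and reported.

Parsimony undercounts when multiple substitutions hit one site, which
deflates the apparent rate variation and inflates Ke. The correction
implemented here rescales all counts by a single global factor

    c = max(1, T / mean(raw counts)),

where T is the total tree length in expected substitutions per site
(Poisson-corrected distances). This matches the mean count to the
distance-based expectation while preserving the relative among-site
dispersion that H measures; the clamp at 1 encodes that parsimony never
overcounts. The exact correction used by the original implementation of
this method is not published; the tree-length rescaling is this package's
declared reconstruction, `mode="none"` is retained for comparison, and the
report provenance records the mode used. Uncorrected counts give larger Ke
on divergent data (tested), consistent with the 5-10% sensitivity expected
between count treatments.

## Trees and distances

When no tree is supplied, neighbor joining (Saitou-Nei) is run on
Poisson-corrected p-distances d = -ln(1 - p), with p computed over columns
where both taxa have non-missing residues. The Poisson correction was
chosen (over Gamma or matrix-based distances) so branch lengths are in the
same expected-substitutions-per-site units the multiple-hit correction
needs. The NJ implementation is in-package and fully deterministic
(row-major first-minimum tie-break), so identical inputs give byte-identical
trees and reports; negative estimated branch lengths are clamped to zero
with a logged message. NJ exactly recovers additive distance matrices
(property-tested against independently computed path distances).

## Sampling variances

Var(H) is estimated by bootstrapping alignment columns: the cached corrected
counts are resampled with replacement (default n_boot = 100, seeded), H is
recomputed per replicate, and Var(H) is the replicate variance. The point
estimate of Ke always comes from the original data, not the bootstrap mean.
Var(Ke) uses the delta-method form

    Var(Ke) = (1/1.037) [ Var(dN)/dN^2 + Var(dS)/dS^2 + Var(H)/(1-H)^2 ],

implemented exactly as printed (the 1/1.037 constant is adopted from the
published numerical analysis without re-derivation). Var(dN) and Var(dS)
default to zero — users should supply them (e.g. from codeml's standard
errors), since omitting them can severely understate Var(Ke). Bootstrap
variances are calibrated within a factor of two of a regeneration oracle in
the tests.

## The simulator

The simulator defines the evaluation conditions for the estimator. A cell
is (model, K, B0) with K in 1..20 and B0 in {0.5, 1.0, 2.0} by default;
component strengths w_1..w_K are

* model a (independent-equal): w_k = B0;
* model b (independent-unequal): i.i.d. Exponential, rescaled to mean B0;
* model c (random-matrix): the eigenvalue spectrum of W W'/K with W a K x K
  standard-normal matrix, rescaled to mean B0 — the Marchenko-Pastur-like
  spectrum concentrates mass near zero, emulating correlated components of
  very unequal effect.

All models satisfy sum(w) = K * B0, so the mean total site intensity equals
K * B0, consistent with S = -K * B0. Per site, each component contributes a
squared standard-normal effect z^2, the total intensity is S_i = sum_k w_k
z_ik^2, and the relative substitution rate is the per-component attenuation
product

    lambda_i = prod_k sqrt( (1 + w_k z_ik^2) / (1 + 2 w_k z_ik^2) ),

which is 1 with no selection and tends to 2^(-K/2) as selection strengthens
— the same limit the estimating equation is built on. (A naive
"deleterious-mutation" map lambda = 2S/(e^(2S) - 1) is exposed as
`fixation_ratio` for single-mutation calculations, but it is not the site
rate law: it decays to zero at large K * B0, extinguishing substitutions
entirely, which contradicts the microadaptation regime and makes the
estimator degenerate. The attenuation product is the package's model
choice.) Counts are Poisson(lambda_i * T); grid mode feeds mean(count)/T to
the estimator as the simulation's observable analog of dN/dS, while
full-pipeline mode evolves an explicit alignment on the tree (uniform root
residue; Poisson(lambda_i * b) replacement events per branch, each to a
uniformly chosen different residue) and exercises NJ, parsimony and the
correction end to end.

Defaults: 2000 sites, 50 replicates per cell, and a symmetric 8-leaf tree
of total length T = 4.0 — enough substitutions to be informative without
saturating parsimony; these sizes keep a full 45-cell grid to a few seconds.
Randomness follows one root seed with per-cell and per-replicate spawned
streams, so grids are reproducible and cells are independent.

What the simulator does *not* emulate: codon structure (dN/dS is replaced
by the count-rate observable in grid mode), among-site correlation,
alignment error, indels beyond missing-data handling, and explicit
microadaptation dynamics (optimum shifts are subsumed in the drawn
intensities). Passing grid tests therefore demonstrates the estimator's
behaviour under the stated stabilizing-selection model, not robustness to
real-data artifacts. The published evaluation table is treated as a source
of qualitative patterns only — conservativeness (mean estimated Ke <= K in
every cell), bias decreasing in B0, and model ordering a >= b >= c at K >= 8
— because the original simulator's equations are not published;
bit-reproduction of its numbers is out of scope.

## Numerical choices and degenerate inputs

* Ke solver: bracketed bisection on [0, 100], xtol 1e-12; the curve is
  verified strictly decreasing on a 0.01 grid, so the root is unique.
  g >= 1 - 1e-12 returns Ke = 0 (neutral boundary); a root beyond 100 is an
  error ("out of supported range").
* H is clamped into [0, 1 - 1e-12] with logged warnings; underdispersed
  counts (V < M, common for near-constant alignments) carry no evidence of
  rate variation and clamp to 0.
* Constant alignments (no substitutions) are a hard estimation error — H is
  undefined.
* At least 4 sequences are required (hard error); exactly 4 logs a warning.
  Mean pairwise identity > 90% and dS >= 1 warn but never abort.
* Saturated pairwise distances (p = 1) are a hard error advising more
  closely related sequences.
* Report serialization uses full-precision `repr` for floats, so TSV and
  JSON reports round-trip losslessly and fixed-seed runs are byte-identical.

## Known limitations

* Ke is a rank estimate: it is bounded by the effective dimensionality of
  mutational effects visible in the alignment (at most 19 per site in the
  amino-acid alphabet) and reads as a minimum pleiotropy, not a count of all
  components.
* The multiple-hit correction and the Be/Se closed form are reconstructions
  validated against the single published worked example; both are tagged in
  report provenance (`correction_mode`, `be_formula`) so downstream users
  can condition on them.
* dN/dS is consumed, never computed: codon-level estimation (and its
  variance) must come from an external tool.
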