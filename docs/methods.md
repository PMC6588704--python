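# Methods

This note records the models, numerical choices and design decisions behind
`convflight`, and what the synthetic-data experiments do and do not show.

## Substitution models and likelihood machinery

All likelihood computation assumes a reversible continuous-time Markov
model on an alphabet of 4 nucleotides or 20 amino acids.  A model is built
from a symmetric exchangeability matrix S and stationary frequencies π as
Q_ij = S_ij π_j (i ≠ j), with the diagonal set so rows sum to zero and Q
rescaled so that −Σ_i π_i Q_ii = 1: branch lengths are then expected
substitutions per site.  Bundled parameterisations: JC69, K80, HKY85, GTR,
and the JTT empirical amino-acid model (standard published
exchangeabilities and frequencies; the `+F` option replaces π by the
frequencies observed in the analysed gene, with a pseudocount of 1 so no
state has zero frequency).

Transition kernels P(t) = exp(Qt) are computed through the symmetric
eigendecomposition of diag(π)^{1/2} Q diag(π)^{−1/2}; one decomposition
serves every branch and rate category.  Tiny negative entries from
round-off are clipped and rows renormalised.

Rate heterogeneity uses the discrete-gamma construction: K equal-weight
categories (default 4), category rate = conditional mean of the
corresponding quantile slice of Gamma(shape, shape), renormalised to mean
exactly 1.  The shape is a parameter (default 0.5 in the pipeline; a 1-D
maximum-likelihood fit is available via `fit_gamma_shape`).

Pruning (`prune_likelihood`) is standard Felsenstein post-order message
passing in linear space with per-site rescaling (the per-node maximum is
divided out and accumulated in log space), mixed over categories with
equal prior weight.  Marginal ancestral posteriors (`marginal_ancestral`)
come from an inside–outside pass per category; per-site category weights
are the normalised per-category site likelihoods, node posteriors are
category-mixed, and the per-site relative rate r_s is the posterior-mean
category rate (the MAP-category alternative was considered and rejected as
lossier for the expectation formula).  Missing leaf characters contribute
flat conditionals.  Branch lengths are taken from the input tree; instead
of full per-branch ML we offer a single global scale factor optimised by
bounded 1-D search (`optimize_tree_scale`), which is proportionate to what
the convergence test needs.

Posterior ties in maximum-posterior state assignment are broken by fixed
alphabet order (A<C<G<T; amino acids in ARNDCQEGHILKMFPSTWYV order) and
flagged.

## Convergence scan (step 1)

Carrier counts exclude missing data from both numerator and denominator,
but the sharing threshold (`min_shared`, default 7) always counts against
the full foreground size — a site scored in only 4 of 8 foreground species
can never qualify through a small denominator.  The candidate state is the
foreground-majority state.  The Fisher test is two-sided by the
point-probability criterion (scipy's implementation; tests verify it
against brute-force hypergeometric enumeration).  Results record both
foreground and background carrier counts so stricter post-filters
(e.g. requiring complete absence from the background) can be applied
downstream.  Group sizes are data, never constants: a replication-style
panel with more species and `min_shared=10` runs through the same code.

## Convergence confirmation (step 2)

Foreground branches are the terminal branches of flight-degenerate species;
all unordered pairs are evaluated (terminal branches are never
ancestor–descendant, and nested pairs are rejected if supplied
explicitly).  The expectation formula pools parallel changes (identical
parent states) with convergent ones (different parent states) ending in
the same derived state.  The observed count uses maximum-posterior states
at internal nodes and observed characters at leaves; a leaf with missing
data never scores.  Significance is the Poisson upper tail
P(X ≥ observed) with mean equal to the expectation; observed = 0 gives
p = 1, and expected = 0 with observed > 0 gives p = 0 with a logged
warning.  On unplanted simulations the observed counts track the
expectation closely (e.g. 8–16 observed vs 10–14 expected per 300-site
gene across 28 pairs), which is the calibration the acceptance tests
check.

## Ancestral codons and the phenotype map

A focal codon is reconstructed per nucleotide position and the codon
posterior is the renormalised outer product of the three position
posteriors.  This per-position independence approximation is transparent
and exactly testable against enumeration; it is not a 61-state codon CTMC,
and agreement with codon-model software on real data is not claimed.  The
reported PP is the posterior of the most probable codon and equals 1 only
when all three positions are certain.  The genotype→phenotype map is a
fixed pure function on translated residues: (Ser, Ala) → sustained flyer,
(Gly, Ala) → non-sustained flyer, (Gly, Val) → flightless/weak, all other
combinations (including stop codons, which also warn) → unclassified.
Robustness reports rerun the reconstruction over topology variants
produced by per-weak-branch NNI rearrangements, deduplicated by unrooted
topology; NNI on a branch incident to a bifurcating root is rejected
because it cannot change the unrooted topology.

## Kinetic fuel model

State: x = acyl-CoA, y = carbohydrate; parameters α₁ (ATGL), α₂
(carbohydrate pathway), α₃ (ACOT7), consumption rates β₁, β₂, Hill
coefficients n₁–n₃; defaults β = 1, n = 1, α₂ = 5, and the two sweep
designs α₁: 25→10 at α₃ = 10 and α₃: 1→10 at α₁ = 10.  ATP output is
z = 2.25x + y.

Two forms of the carbohydrate equation are implemented.  The printed form
drains y at a rate proportional to x (−β₂x); under it, weakening the lipid
pathway also weakens steady-state carbohydrate metabolism, which
contradicts the mutual-antagonism narrative the model exists to support.
The package therefore defaults to self-consumption (−β₂y, variant
`corrected`) and keeps `as_printed` behind a flag.  Under the corrected
form with n = 1 the fixed point solves a quadratic in x (with
Δ = max(α₁−α₃, 0)); the anchor case Δ = 8, α₂ = 5 gives (x*, y*) = (4, 1)
and z = 10.

Integration uses LSODA at rtol 1e-10/atol 1e-12 with the non-negativity of
both pools enforced by projected (Filippov) integration: a pool reaching
zero with negative unclamped derivative is frozen on the boundary and
released when the derivative turns positive, with regime changes located
by terminal events and small hysteresis margins (1e-9 on the state, 1e-10
on the derivative) to prevent event chatter during asymptotic decay.  A
naive discontinuous clamp collapses adaptive step sizes; the projected
scheme is exact up to the hysteresis margins.  Default initial condition
is (0, 0); steady states are computed in closed form when available and
otherwise by integrating until the projected vector-field norm falls below
1e-10.

Fuel dominance defaults to the energy criterion (2.25x* vs y*); the
concentration criterion (x* vs y*) is available and switches exactly at
Δ = α₂ (substituting x = y into the two fixed-point equations).  The sweep
threshold is the first grid value whose dominant fuel differs from the
first grid point's.  Under the defaults the energy-criterion switch sits
near α₁ ≈ 13.6 (α₃ sweep: α₃ ≈ 6.4); no steady-state dominance criterion
we could construct — energy or concentration, corrected or printed
equations — yields switching activities of 18 or 4, so the package makes
no claim about those particular values and the tests assert the structural
properties instead: exactly one switch per sweep direction, strict
monotonicity of both energy curves, and the exact concentration-criterion
boundary.

## Synthetic data: what it emulates and what it does not

The generator simulates site-independent evolution along a fixed rooted
tree under the exact per-branch kernels exp(Q·t·r_c) — no indels, no
selection, no codon structure.  Convergence is planted by overwriting leaf
states, giving exact truth tables; the planted derived state is guaranteed
to differ from the simulated root state.  Two study-condition choices
matter:

* **Scattered foreground.**  Flight degeneration arose independently many
  times, so the foreground species must not form clades.  The generator
  assigns the foreground labels evenly along the tree's post-order leaf
  sequence.  Clustered foreground species would share states by descent
  and produce Fisher hits that are not convergence — a property of bad
  study design, not of the test.
* **Bounded branch lengths.**  Branch lengths are uniform in
  [0.5, 1.5] × mean (default mean 0.05 substitutions/site), mimicking a
  timetree.  Near-zero terminal branches (frequent under an exponential
  draw) make it impossible for any reconstruction to place a substitution
  on the terminal branch, which is a degenerate geometry rather than an
  interesting regime.

Default study shape: 48 species with 8 flight-degenerate, HKY85 (κ = 2,
π = (0.3, 0.2, 0.2, 0.3)) with gamma shape 0.5 over 4 categories; genes of
300 sites for confirmation-scale runs and 10⁴ sites for scan-calibration
runs; 20 genes for null-calibration.  These sizes keep the full suite in a
few minutes on a single core.  Passing tests on this generator shows the
pipeline is correctly calibrated and powered *under the model it assumes*;
it says nothing about alignment error, selection, GC-biased gene
conversion, or other real-data confounders, and the paper's headline
counts (30 candidates, 8 confirmed, specific Fig.-6 posterior
probabilities) depend on the real 48/103-genome data and are out of scope.

## Coordinates and missing data

Sites are 1-based alignment columns everywhere.  Mapping to a reference
species' ungapped coordinates is provided by
`column_to_reference_coordinate`; columns where the reference itself has a
gap map to `None` (they simply have no reference coordinate — no
interpolation is attempted).  `N`/`-`/ambiguity codes are missing for all
counting and likelihood purposes, so missing data can shrink denominators
but never creates carriers.

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline fans a single global seed out to
stages by fixed offsets, and identical configurations byte-reproduce all
output tables (the run manifest differs only in its timestamp).
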