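# convflight

Tools for detecting convergent molecular evolution in flight-degenerate
birds and for modelling the metabolic consequence — a switch of the
dominant pectoral-muscle fuel from lipids to carbohydrates.

Flight has degenerated many times independently across modern birds
(ratites, galliforms, and many weak flyers).  If those independent losses
share a molecular basis, the genomes of flight-degenerate species should
carry *convergent substitutions*: alignment sites at which unrelated
flight-degenerate lineages independently acquired the same derived state
that flying species do not carry.  `convflight` implements the full
computational chain for testing this hypothesis on aligned orthologous
genes, plus the kinetic model that links two of the implicated enzymes
(ATGL, a triglyceride lipase, and ACOT7, an acyl-CoA thioesterase) to the
fuel economy of flight muscle.

## What the package computes

**1. Per-site two-group scan** (`site_scan`).  For every alignment column,
the state dominating the flight-degenerate (foreground) group is tabulated
against the flying (background) group and tested with a two-sided Fisher's
exact test on the 2×2 carrier table.  A site is a candidate when the
dominant state is shared by ≥ `min_shared` foreground species (default 7 of
8) and p < α (default 10⁻³).  Missing characters (`N`, gaps) are excluded
from the tables but the sharing threshold always counts against the full
group size.

**2. Neutral-expectation convergence test** (`convergence`,
`likelihood`).  Chance convergence is common in large alignments, so each
candidate gene is re-tested against the number of convergent substitutions
expected under neutral evolution.  Felsenstein pruning under a reversible
substitution model with discrete-gamma rate heterogeneity (4 equal-weight
categories) yields marginal ancestral posteriors at every internal node and
a posterior-mean relative rate r_s per site.  For each pair of foreground
terminal branches (b₁, b₂) the neutral expectation is

    E = Σ_sites Σ_pairs Σ_d [Σ_{i≠d} P(parent₁=i)·P(i→d | t₁ r_s)]
                          · [Σ_{j≠d} P(parent₂=j)·P(j→d | t₂ r_s)]

pooling parallel and convergent changes to the same derived state d.  The
observed count assigns each node its maximum-posterior state and counts
sites where both branches of a pair substitute to the same state.
Significance is the Poisson upper tail P(X ≥ observed) at mean E
(retained when p < 0.01).

**3. Ancestral codon reconstruction** (`ancestral_codons`).  Focal codons
(e.g. ATGL residue 321, ACOT7 residue 197) are reconstructed marginally per
nucleotide position; the codon posterior is the renormalised product of the
three position posteriors.  Reconstructed genotypes map to flight-phenotype
classes: (Ser, Ala) → sustained flyer, (Gly, Ala) → non-sustained flyer,
(Gly, Val) → flightless/weak.  Robustness is assessed over
nearest-neighbour-interchange variants of weakly supported branches.

**4. Kinetic fuel model** (`energy`).  Acyl-CoA (x) and carbohydrate (y)
pools inhibit one another:

    dx/dt = −β₁x + α₁/(1+y^n₁) − α₃/(1+y^n₃)
    dy/dt = −β₂y + α₂/(1+x^n₂)

with α₁ the ATGL activity feeding the lipid pool, α₃ the ACOT7 activity
draining it, and ATP output z = 2.25·x + y (lipids yield ~2.25× the energy
of carbohydrates per unit).  The package integrates the system, solves the
n = 1 steady state in closed form, and sweeps α₁ (or α₃) to locate the
activity at which the dominant fuel switches from lipid to carbohydrate.

**5. Synthetic data** (`simulate`).  Alignments are simulated along a
rooted tree under the exact transition kernels exp(Q·t·r), with convergence
planted into scattered foreground species and reported in an exact truth
table — so every stage is testable without genome downloads.

## Worked example

```python
import numpy as np
import convflight as cf

# a 48-species study (8 scattered flight-degenerate), 3 genes of 300 sites,
# with two convergent sites planted into gene001
bundle = cf.synthetic_study(n_species=48, n_foreground=8, n_genes=3,
                            n_sites=300, n_planted_genes=1,
                            planted_sites_per_gene=2, seed=11)

hits = []
for aln in bundle["alignments"].values():
    hits.extend(cf.scan_alignment(aln, min_shared=7, alpha=1e-3))
for h in hits:
    print(f"candidate {h.gene_id} site {h.site} state {h.state} "
          f"fg {h.fg_carriers}/{h.fg_total} bg {h.bg_carriers}/{h.bg_total} "
          f"p={h.p_fisher:.3e}")

model = cf.hky85(2.0, np.array([0.3, 0.2, 0.2, 0.3]),
                 gamma_shape=0.5, n_categories=4)
for r in cf.confirm_candidates(hits, bundle["alignments"], bundle["tree"],
                               model, alpha=0.01):
    print(f"{r.gene_id}: observed={r.observed} expected={r.expected:.2f} "
          f"p_poisson={r.p_poisson:.3e} retained={r.retained}")

sweep = cf.sweep(cf.KineticParams(alpha3=10.0), "alpha1",
                 np.linspace(25, 10, 31))
print("dominance switch at alpha1 =", sweep.threshold)
```

prints

```
candidate gene001 site 39 state G fg 8/8 bg 0/40 p=2.650e-09
candidate gene001 site 41 state C fg 8/8 bg 0/40 p=2.650e-09
gene001: observed=55 expected=11.31 p_poisson=1.046e-20 retained=True
dominance switch at alpha1 = 13.5
```

The scan recovers exactly the two planted sites (both shared by all 8
flight-degenerate species and absent from the 40 flying species; p is the
minimum attainable for these group sizes, 1/C(48,8)).  The confirmation
step counts 55 observed convergent pair-events against a neutral
expectation of 11.3, so the gene survives the Poisson filter.  In the
kinetic sweep, lowering ATGL activity α₁ from 25 toward 10 (at α₃ = 10,
α₂ = 5) flips the dominant energy source from lipid to carbohydrate.

A `convflight` command-line interface wraps the same functions
(`convflight pipeline --config run.yaml` runs simulate → scan → confirm →
energy end to end and writes TSV tables plus a JSON manifest).

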