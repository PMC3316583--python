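# consegment

Bayesian multiple change-point segmentation of cross-species conservation
codes, with posterior conservation profiles, a profile-threshold coding
classifier, splicing-regulatory motif scanning, and protein tail-domain
analysis.

**Who it is for.**  Comparative genomicists studying a single locus at base
resolution: given a reference-anchored multi-species alignment (MAF), the
package finds latent *classes of conservation* along the sequence —
protein-coding-like, regulatory, weakly constrained — without annotating
them in advance, and locates short regulatory motifs (G triplets, CA
repeats, YCAY, the PTB-bound CUCUCU/UCUUC elements, the AAUAAA polyA
signal) that are conserved across all aligned species.  The protein module
handles the companion analysis of alternative 3′ isoforms: tail-domain
decomposition and Kyte–Doolittle hydropathy profiles, plus PROSITE-style
kinase acceptor motifs ([ST]XX[DE], [ST]X[RK], [RK]XX[ST]).

**The model.**  Each alignment column is encoded as a conservation code
c ∈ {0, 1, 2} = (number of distinct symbols, gap counted as a symbol) − 1.
Codes are segmented by a change-point mixture model: boundaries are
changepoints independently with probability ρ; segments carry latent class
labels g ~ Categorical(π); a segment labelled g emits its codes i.i.d. from
θ ~ Dirichlet(α_g), with θ integrated out analytically (a
Dirichlet-multinomial segment marginal).  MCMC (collapsed Gibbs over
boundaries, conjugate π/ρ updates, Metropolis α updates) yields
per-position posterior class-membership *profiles*; the class count k is
chosen by AIC computed from the exactly marginalised likelihood
log P(codes | π, α, ρ).  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from consegment import ChangepointModel, profiles, simulate

# a 20 kb synthetic three-species region with four conservation classes
truth = simulate.simulate_scenario("well_separated", seed=1)
res = ChangepointModel(truth.codes, k=4).fit(n_iter=1000, burn_in=500, seed=1)
print(res.summary())

g = res.most_conserved_class()
cc = profiles.classifier_confusion(res.profiles.class_profile(g),
                                   truth.coding_intervals, threshold=0.5)
sens, spec = profiles.sensitivity_specificity(cc)
print(f"coding classifier: sensitivity={sens:.3f} specificity={spec:.3f}")
```

Output (seed 1):

```
Change-point mixture model (MCMC)
============================================
positions            20000
classes (k)          4
iterations           1000 (burn-in 500)
seed                 1
mean changepoints    82.6
mean rho             0.00422
alpha MH acceptance  0.43

class   pi      code proportions (alpha / sum alpha)
  1    0.306   0.949 0.039 0.012
  2    0.396   0.730 0.206 0.064
  3    0.177   0.571 0.294 0.135
  4    0.120   0.268 0.545 0.186

log-likelihood drift z = 1.82 (ok)
coding classifier: sensitivity=0.982 specificity=0.973
```

Classes come out ordered by conservation (class 1 ≈ 95% invariant columns —
the protein-coding-like class; class 4 ≈ 27% — weakly constrained), the
posterior changepoint count (82.6) tracks the simulated truth (90), and
thresholding the class-1 profile at 0.5 recovers the coding annotation with
sensitivity 0.98 and specificity 0.97.

The same pipeline runs from the shell:

```
consegment simulate --scenario gfap_like --seed 5 --out-dir bundle/
consegment encode bundle/alignment.maf --out codes.tsv
consegment segment codes.tsv -k 4 --seed 5 --out-dir fit/
consegment evaluate fit/profile_class1.wig bundle/coding.bed --out eval.tsv
```

`segment` writes one fixedStep WIG track per class for genome-browser
viewing, the MCMC traces as TSV, and a manifest recording the full
configuration; identical config + seed reproduces every output byte for
byte.

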