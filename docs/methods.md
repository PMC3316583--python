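# Methods

## The model

`consegment` segments a sequence of per-position *conservation codes* into
latent conservation classes.  The codes come from a reference-anchored
multi-species alignment: each alignment column is reduced to the number of
distinct symbols it contains minus one (a gap counts as a symbol of its own,
so for three species the codes are 0, 1 or 2).  Columns in which the
reference carries a gap are dropped, so codes sit on reference coordinates.

The generative model for a code sequence of length N:

- each of the N−1 boundaries between adjacent positions is a changepoint
  independently with probability ρ;
- the resulting segments receive i.i.d. class labels g ∈ {1..k} with mixture
  weights π;
- a segment labelled g draws code proportions θ ~ Dirichlet(α_g) and emits
  its codes i.i.d. Categorical(θ).

θ is integrated out analytically, giving the Dirichlet-multinomial segment
marginal

    log P(segment | g) = log Γ(A) − log Γ(A+n) + Σ_c [log Γ(α_gc + n_c) − log Γ(α_gc)],

with A = Σ_c α_gc and n_c the code counts.  Hyperpriors: ρ ~ Beta(1, 1),
π ~ Dirichlet(1, …, 1), each α component log-uniform on (10⁻³, 10⁶).  The
upper bound matters: on real data the most conserved class is nearly
deterministic and its fitted α components reach the 10⁴–10⁵ range.

The model assumes codes are exchangeable within segments.  Gap runs are
scored column by column, not compressed, which introduces short-range
dependence the model ignores; this is a deliberate trade of model fidelity
for retention of per-base conservation information.

## Posterior sampling

One MCMC iteration consists of:

1. **Collapsed Gibbs sweep over boundaries.**  For each boundary b the class
   labels of the segment(s) touching b are marginalised analytically, the
   changepoint indicator is drawn from its exact conditional
   (split vs. merge), and the affected labels are redrawn from their
   conditional.  Segment count lookups are O(1) via prefix sums; the
   log-gamma terms come from per-iteration lookup tables built by the
   recurrence lgamma(a+n+1) = lgamma(a+n) + log(a+n), re-anchored with an
   exact lgamma every 1024 entries.
2. **Label Gibbs pass** over all segments (refreshes every label once more).
3. **Conjugate updates**: ρ from Beta(1 + #changepoints, 1 + #non-boundaries),
   π from Dirichlet(1 + class counts).
4. **α updates**, two kinds per class: (a) a log-space random-walk
   Metropolis step per component (step size 0.3, adapted toward 44%
   acceptance during burn-in only); (b) an *anchored independence proposal*:
   with probability 0.8 a new α_g is proposed as s·m with m ~
   Dirichlet(counts of a uniformly chosen segment + 1) and log s uniform on
   (0, log 10⁵), otherwise from the diffuse per-component log-uniform; the
   Hastings ratio uses the exact mixture proposal density.  The anchored
   move is what lets a starved class jump back onto an occupied region of
   composition space instead of random-walking through the prior.

Moves (1)–(2) subsume separate birth/death, shift and label moves: every
boundary is resampled from its exact conditional each sweep, so a
changepoint "shift" is just a death and a birth, both of which are proposed
every iteration.

**Initialisation** is by moment matching: code proportions in fixed
100-position windows are clustered by k-means (k-means++ seeding, seeded
deterministically), each class α starts at its cluster centre scaled to
concentration 30, π at the cluster shares, ρ at 0.01.  This puts every
chain near the relevant mode from iteration 0 and makes short chains
(hundreds of iterations) usable for model scans.

**Label switching.**  The posterior is invariant under class relabelling,
which would smear the per-position profiles if a chain migrated between
labellings.  Every retained sample is therefore relabelled canonically:
classes ordered by decreasing code-0 mean proportion α₀/Σα (ties broken by
total concentration), so class 1 is always the most conserved.  In
fixed-parameter mode (used for exact validation) no relabelling is applied,
since the labels are anchored by the fixed α values.

Defaults: 1000 iterations with a burn-in of 500; profiles are the fraction
of post-burn-in samples assigning each position to each class.  No thinning
is applied.  All randomness flows through a single integer seed; chains are
bit-reproducible.

## Class-count selection

For each candidate k the *integrated* likelihood log P(codes | π, α, ρ) —
segmentations and labels marginalised — is computed exactly by a forward
dynamic programme over segment start positions, with the
Dirichlet-multinomial term grown incrementally (Polya-urn update, O(1) per
character per class; O(N²k) total, or O(N·L·k) when segments are capped at
L).  The likelihood is evaluated at two candidate estimates per chain (the
posterior mean and the retained sample with the best complete-data
likelihood) and the larger value is used.  Then

    AIC = −2 log P + 2p,   BIC = −2 log P + p ln N,   p = Ck + (k−1) + 1,

and DIC = mean(deviance) + var(deviance)/2 over thinned posterior draws of
(π, α, ρ), with deviance −2 log P.  Using the integrated likelihood rather
than the complete-data likelihood is essential: the complete-data maximum
keeps improving with k because extra latent labels are free, whereas the
integrated likelihood pays for unused classes only through the 2p penalty.
Selection uses the AIC minimum (lowest k on ties); BIC and DIC are reported
but not used — on this model BIC's heavier penalty favours degenerately few
classes and DIC is too variable across replicates to rank neighbouring k.

## Profiles as a coding classifier

A position is unambiguously assigned to a class when that class's profile
value strictly exceeds a threshold ≥ 0.5 (so at most one class can qualify).
Treating the most conserved class's profile as a protein-coding classifier
against an annotation: coding positions above threshold are TP, coding
below are FN, non-coding above are FP, non-coding below are TN;
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).  UTRs count as
non-coding.  (One published description of this scheme labels the
non-coding strata inconsistently with these formulas; this package uses the
standard definitions, which are the only ones compatible with
specificity = TN/(TN+FP).)

Conserved-feature intervals are maximal runs of above-threshold positions;
runs separated by at most `merge_gap` (default 5) positions are merged and
merged runs shorter than `min_length` (default 10) are dropped — defaults
chosen so that features of a few tens of bases survive.  The reported mean
is over the contributing (above-threshold) positions, so mean ≥ threshold
holds across merged gaps.

## Synthetic data

The generator mirrors the inference model exactly — same boundary, label,
and Dirichlet-multinomial structure — so ground truth is available for
every pipeline stage.  Two named scenarios:

- **gfap_like** (default): N = 20,000, k = 4, π = (0.1, 0.3, 0.4, 0.2),
  ρ = 0.005 (mean segment 200), class mean code proportions
  (0.35, 0.45, 0.20), (0.95, 0.045, 0.005), (0.60, 0.32, 0.08),
  (0.45, 0.40, 0.15), concentration 60.  Class 2 is the near-deterministic
  "coding-like" class and defines the coding annotation.  The code-0 levels
  echo the qualitative spread seen in real three-species conservation data;
  the 0.35/0.45 classes deliberately overlap, as weakly constrained
  sequence classes do in practice.  Full four-class recovery is *not*
  expected here: with these means the hierarchical posterior can merge the
  two weak classes (the Bayes classifier with the true parameters reaches
  only ≈ 0.86–0.91 positionwise accuracy).  The scenario exercises the
  pipeline and the conserved-class classifier, not class-count recovery.
- **well_separated**: identical except the class mean code-0 proportions are
  (0.25, 0.95, 0.75, 0.50) with the remaining mass split 3:1 between codes
  1 and 2.  Evenly spaced conservation levels make all four classes
  identifiable; this scenario is used for the parameter-recovery,
  classifier and class-count-selection checks.

Alignment columns are emitted per-column from pattern mixtures consistent
with each code (code 0 → AAA; code 1 → AAB/ABA/ABB/AA-/A-A/A--;
code 2 → ABC/AB-/A-B), so re-encoding reproduces the simulated codes
exactly.  Indel patterns are i.i.d. across columns by default — real gap
runs are autocorrelated, so passing tests under the default say nothing
about gap-run dependence; an optional ``gap_run_length`` extends drawn gap
patterns over geometric-length runs (code-consistent at every column) for
robustness probing only.
The generator makes no attempt at realistic molecular evolution (no
phylogeny, no substitution model): it mirrors the inference model by
design, so recovery results validate the sampler, not the model's fit to
real alignments.

## Problem sizes used in the checks

Recovery, classifier and profile checks run the well-separated scenario at
full scale (N = 20,000, k = 4, 1000 iterations, burn-in 500, three seeds).
The class-count scan runs 20 replicates of k = 1..6 at N = 20,000 with
400-iteration chains (burn-in 200) and a segment cap L = 800 in the
marginal-likelihood DP — at ρ = 0.005 the prior probability of a segment
exceeding L is e⁻⁴ ≈ 1.8%, the cap is identical across k, and the
likelihood there is evaluated at the posterior-mean hyperparameters only.  Shorter chains suffice for the scan because the moment-matched
initialisation starts each chain near its mode; the exact small-N validation
(enumeration over all 2¹¹ boundary configurations at N = 12) uses long
fixed-parameter chains instead.

## Motif and protein conventions

DNA motifs are scanned on the sense strand with IUPAC degeneracy (RNA
motifs given with U are scanned as T); all overlapping matches are
reported, except G runs and CA repeats, which use maximal-run semantics.
Because no published threshold defines a motif "cluster", clustering is
reported as a sliding 50-nt hit-start density rather than a binary call.  A
reference-coordinate hit counts as conserved only if every other species'
gapless subsequence over the hit's columns is itself fully matched by the
same scanner; any gap breaks conservation.  The kinase acceptor patterns
are [ST]XX[DE] (CKII), [ST]X[RK] (PKC) and [RK]XX[ST] (cAMP/cGMP-dependent
kinase), matched exactly (no mismatches); flank annotation classifies the
residue immediately N-terminal of a match as acidic {D,E} / basic {K,R,H} /
other and reports the residue five positions C-terminal of the acceptor.

Hydropathy profiles are sliding-window means of Kyte–Doolittle residue
values, window 9, full windows only, value at the window centre (1-based
centre coordinates, tail-relative when applied to tail domains).
Alternative scales are supplied as residue→value mappings.

## Numerical choices and degenerate inputs

- All probability arithmetic is in log space; no per-segment products.
- The lgamma lookup tables introduce < 10⁻¹² relative error between exact
  anchors; the exact-enumeration tests at small N bound any effect.
- Argmax class assignment breaks ties toward the lowest class index.
- A sequence of length 1 has no boundaries: the sampler degenerates to
  label/parameter updates only.  k = 1 yields constant profiles of 1.
- Empty sequences, k = 0, burn-in ≥ chain length, non-simplex π,
  non-positive α and ρ outside (0, 1) raise `ValueError`.
- Unknown residues and non-IUPAC motif characters raise; 'N' bases are
  treated as a fifth symbol and counted with a logged warning.

## Known limitations

- The changepoint prior (independent Bernoulli boundaries) and the sampler
  are this package's own design; numerical agreement with other
  change-point software outputs is not claimed, only agreement with the
  model's exact posterior (validated by enumeration at small N).
- Within-segment exchangeability ignores gap-run autocorrelation (above).
- The integrated-likelihood DP is O(N²k); for megabase-scale inputs use the
  segment cap.
- Class identity across independent runs is only meaningful through the
  canonical conservation ordering; classes with near-identical code-0
  proportions may still swap.
- k is fixed per run and scanned externally; there is no transdimensional
  sampling.
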