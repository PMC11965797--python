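# Methods

## The ohnolog-loss chain

Each pillar (one ancestral, pre-WGD locus) is a realization of a four-state
continuous-time Markov chain over `{U, S1, S2, F}` running down a rooted
phylogeny whose root *is* the WGD event.  `U` is the undifferentiated
duplicated state every pillar starts in; `S1`/`S2` are the single-copy
states after loss of the subgenome-2 / subgenome-1 copy; `F` is a fixed
pair that can never lose a copy.  The only transient state is `U`, with
off-diagonal rates `(U->S1, U->S2, U->F) = (1, ε, γ)`; the other three
states are absorbing.  Because the chain has a single transient state, the
transition matrix has the closed form

    P(U->U; t) = exp(-(1+ε+γ) t),
    P(U->x; t) = q_x / (1+ε+γ) * (1 - exp(-(1+ε+γ) t)),

which the implementation uses directly; a truncated-series matrix
exponential exists only as an independent oracle in the test suite.

Identifiability choices: the base loss rate is fixed at α ≡ 1, so branch
lengths are in expected-loss units; ε is restricted to [0, 1], which
resolves the subgenome-labeling symmetry by convention (subgenome 1 is the
favored one); γ is bounded above by 100 as an optimizer stand-in for an
unbounded rate.  The root state is `U` with probability 1 — a pillar is by
construction duplicated immediately after the WGD — and the "root branch"
from the WGD to the first speciation is encoded as the Newick root edge
length.

## Subgenome assignment as a hidden chain

Which observed track (a/b) of a genome descends from which subgenome is
never observed.  A hidden assignment vector with one bit per genome is
tracked along the pillar order as a Markov chain: uniform initial
distribution over the 2^N vectors and independent per-genome flips with
probability θ between adjacent pillars.  This stands in for synteny-block
orthology tracking in pillar-based WGD browsers, whose exact along-genome
model is not public; θ is shared across genomes, estimated by ML
(default 0.01, bounds [1e-6, 0.5]).  Pillar likelihoods given an assignment
come from Felsenstein pruning with leaf compatibility {U, F} for a
both-copies observation and the single matching S-state otherwise; the
dataset likelihood is a forward pass over pillars, and per-pillar
assignment posteriors (the confidence *c*) come from forward–backward.
Emissions depend only on the observation-code pattern of a pillar, so they
are computed once per distinct pattern (at most 3^N) and broadcast; the
sequential forward/backward recursions are JIT-compiled.

A consequence worth knowing: with a nonzero root branch, even unbiased
(ε = 1) single-copy observations in different genomes carry assignment
information, because a single shared loss on the root branch explains
equal-bit assignments more cheaply than parallel losses.  Only when the
root branch has zero length are such posteriors exactly uniform.

## Fitting

Bounded L-BFGS-B over log branch lengths, ε (linear), log γ and θ (linear),
with a heuristic start (leaf lengths from observed retention fractions) and
seeded random restarts (default 5; the θ chain can make the surface mildly
multimodal).  Convergence tolerance is tight (relative ftol 1e-11) because
nested-model comparisons consume lnL differences.  `fit_model_family` fits
the four flavors warm-started along the nesting partial order and never
reports a richer model below a nested optimum (which is a feasible point of
the richer model), making the nesting inequalities exact rather than
approximate.  Topology search enumerates all (2n-3)!! rooted bifurcating
topologies by recursive leaf insertion and fits each; ties are broken by
canonical Newick string.  For five taxa this count is 105; one software
lineage in this field reports 115 for the same setting, a discrepancy we
surface rather than reproduce, since (2n-3)!! is the standard count.

Nested comparisons use the 1-df chi-square LRT throughout, following field
practice.  Note that the null values of ε (= 1) and γ (= 0) lie on their
parameter boundaries, so the asymptotic null of the LRT statistic is a
50:50 mixture of 0 and chi-square(1) and the plain chi-square test is
conservative (empirically ~2.5% rejections at nominal 5%); we keep the
plain test because the comparisons of interest reject at overwhelming
margins.

## Shared vs. independent polyploidy

Independent polyploidies imply no genuinely shared losses, i.e. a
zero-length root branch.  The test (i) fits the zero-root model to the
observed table, (ii) simulates `n_sims` tables of the same size under the
fitted parameters, (iii) refits the free-root model to each, and (iv)
reports add-one p-values `(count >= observed + 1)/(n + 1)` for two
statistics: the fitted root-branch length and the free-minus-zero lnL gap.
Simulation refits are warm-started at the generating parameters with two
optimizer starts — the null surface is unimodal near the truth, and this
keeps 100-simulation runs fast; all free parameters (including θ) are
re-estimated per simulated dataset, and the observed free-root fit uses
exactly the same optimizer protocol as the simulated ones so the decision
statistic is exchangeable with its null (an asymmetric protocol measurably
biases the bootstrap p-value in either direction).

Both statistics have a boundary atom under a zero-root truth: roughly half
of the fitted root lengths sit at the lower bound (and the corresponding
lnL gaps at zero), so a plain `>=` count would park half the p-values at 1.
Exact and near-exact ties between the observed and null values are
therefore broken uniformly at random; the p-value keeps its `1/(n+1)` floor
and reduces to the plain convention whenever the observed statistic is away
from the boundary — which it always is when a genuinely shared event is
being detected.  For two-genome tables the default
flavor is `WGD_n`: with only two genomes the bias parameter can absorb
loss-rate asymmetry into apparent shared losses and inflate the root
branch.

## Fixation scan

`p_fix^i` is the posterior probability of state `F` at leaf *i*, computed
by an inside–outside pass per assignment vector and mixed over vectors with
their forward–backward weights.  Because `F` is absorbing, the tip-state
posterior equals the probability that fixation occurred along any branch on
the root-to-tip path, so no per-branch marginalization is needed.
`p_nonfix = Π_i (1 − p_fix^i)` is computed as that exact product.  Windowed
averages use a centered window of `max(1, round(frac * N))` pillars
(default 2%), truncated at the edges, stepped one pillar at a time, over
the single concatenated pillar order (pillar files carry no chromosome
field); positions are scaled to [0, 1].

## Codon model and the conversion test

The triplet test fits a GY94-type codon model on the unrooted 3-taxon star
tree: 61 sense codons, single-nucleotide steps, shared
transition/transversion ratio κ (ML-estimated), F3×4 codon frequencies
estimated from the triplet itself, and per-branch *separate* synonymous and
nonsynonymous flow parameters `(bs_b, bn_b)`, normalized so a branch
accumulates `bs_b` expected synonymous and `bn_b` nonsynonymous
substitutions per codon.  `Ka_b = bn_b / (3 ρ_N)` and `Ks_b = bs_b / (3
ρ_S)` with site proportions from neutral flux.  Keeping synonymous rates
free in the constrained fit means the LRT targets Ka only; the constraint
is `Ka_O = Ka_G2` exactly as the trigger condition (`Ka_O > Ka_G1, Ka_G2`)
suggests, and the synonymous-rate treatment is recorded in the fit output.
Gapped codon columns are dropped listwise, alignments below 50 ungapped
codons are refused, and transition probabilities use the symmetric
eigendecomposition available for reversible chains, floored at 1e-18 so
log-likelihoods stay finite and differentiable near boundaries.

No multiple-testing correction is applied across triplets (raw p ≤ 0.05
flags an event, matching field practice for this test); users can apply
their own FDR control over the returned p-values.  The clustering statistic
is the mean pillar-index distance to the nearest other significant event,
compared against uniform draws of the same number of distinct positions
(add-one p over 1,000 randomizations by default).

### Calibration geometry

The type-I calibration of the conversion test simulates under the LRT's own
null — equal nonsynonymous divergence on the O and G2 star branches — not
under the biologically realistic no-conversion geometry.  In the realistic
geometry (O diverging at a recent speciation) `Ka_O` essentially never
exceeds `Ka_G2` and the procedure almost never fires, so its false-positive
rate is far below nominal; the calibration harness instead checks the
p-value's accuracy where the null hypothesis is actually true.  Because the
candidate trigger conditions on the direction of the discrepancy, the
procedure is conservative (observed type-I ≈ 2.5–5% at nominal 5%).

## Synthetic data

The generators realize exactly the processes above: the pillar simulator
samples the assignment chain, evolves states down the tree (optionally with
a per-pillar γ profile to plant fixation hot spots), and emits gene ids
through the assignment bits; the triplet simulator evolves codons along the
WGD-then-speciation tree and implements conversion by overwriting a
contiguous codon tract of G2 with G1's sequence at a chosen time before
present, then letting both evolve on.  Under the four-state chain every
genome always retains at least one copy, so the at-least-one-copy filter of
real pillar sets never rejects a simulated pillar; the rejection count is
reported (always zero) for interface compatibility.  Packaged scenarios
(`shared_wgd`, `independent_wgd`, `fixation_hotspot`,
`clustered_conversions`) write self-describing bundles; random streams are
keyed by stable labels so adding one output does not reshuffle the others.

Defaults mirror the study conditions the analyses are designed for:
two-genome shared-event tables use 2,000 pillars, leaf branches 0.4 and a
root branch of 0.3 (vs. 0 for independent events) under `WGD_n`;
parameter-recovery datasets use four genomes, ε = 0.5, γ = 0.3, θ = 0.02;
triplets use 300 codons, ω = 0.2, κ = 2, uniform codon frequencies, paralog
background Ks ≈ 0.3 and speciation Ks ≈ 0.1.  What the simulations do not
emulate: gene gain, tandem duplication, translocation, chromosome-scale
rearrangement, more than two tracks per genome (octoploids), alignment
error, or conversion-aware sequence evolution beyond the single overwrite
event — so passing tests demonstrate correctness of the inference machinery
under its own model, not robustness to real-data violations of it.

## Problem sizes and numerical choices

The test suite runs the expensive checks at the scales the methods are
stated for: oracle equivalence on ≤3 leaves × ≤3 pillars (tolerance 1e-10
relative), nesting on 1,000 pillars, parameter recovery with exhaustive
search on 5,000 pillars, shared-event power at 2,000 pillars × 100
simulations and calibration at 800 pillars × 20 simulations × 50
repetitions, conversion calibration on 200 null triplets of 300 codons,
and clustering on 10,000 pillars × 1,000 randomizations.  The acceptance
script uses slightly smaller sizes (3,000-pillar recovery, 50-simulation
shared-event test, 12 triplets) chosen to finish comfortably on one CPU.

Degenerate inputs: a dataset impossible under the parameters returns
−inf log-likelihood with a warning rather than raising; `t = 0` branches
yield identity transitions; a table with no losses drives all branch-length
estimates to the 1e-6 lower bound; clustering with fewer than two events
and scans under flavors without fixation raise informative errors.

## Known limitations

* The θ-flip assignment chain is a deliberate simplification of
  block-structured orthology tracking; c values are well calibrated under
  the model but will understate uncertainty if real assignment errors are
  block-correlated.
* The conversion test inherits the conservativeness of its trigger
  condition and tests full-gene signal; partial tracts shorter than ~20% of
  the alignment lose power quickly.
* Branch lengths are expected losses, not time; comparing them across
  events requires equal loss rates, which delayed rediploidization itself
  violates.
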