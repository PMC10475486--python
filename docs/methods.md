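# Methods

## Model

`chainstab` simulates a meta-community of at most N species on two habitat
patches joined in a one-way chain — an abstraction of an upstream and a
downstream gut segment.  Within-patch dynamics follow a generalized
Lotka-Volterra (gLV) model with a shared interaction matrix A
(`A[i, k]` = effect of species k on species i, self-interaction fixed at
−1) and patch-specific intrinsic growth rates r1, r2:

    dx_i1/dt = x_i1 ( r_i1 + Σ_k a_ik x_k1 )
    dx_i2/dt = x_i2 ( r_i2 + Σ_k a_ik (x_k1 + x_k2) )

Upstream abundances enter the downstream equations because metabolites
produced or consumed upstream flow downstream; the coupling is strictly
one-way.  Collecting the upstream terms defines the *realized* downstream
growth rate r̂_i2 = r_i2 + Σ_k a_ik x_k1: the downstream patch is a
single-patch gLV whose growth-rate vector is controlled by the upstream
community.  Self-limitation at −1 puts every mono-culture equilibrium at
x\* = r.

Time is split into short within-cycle dynamics (t, one cycle = 300 t units)
and long cycles (T) at whose boundaries exactly one species invades, chosen
from the migration model below with inoculum 0.01.

## Stability statistic

Stability of the downstream community at a cycle boundary is the
probability q0 that its presence/absence pattern is unchanged one cycle
after a single random invasion.  Because the dynamics are deterministic,
q0 needs only 2N trial integrations — each pool species dropped once into
each patch:

* **Resistance to invasion** Ri(i) = 1 iff species i invading *downstream*
  leaves the downstream pattern unchanged.
* **Structural persistence** Sp(i) = 1 iff species i invading *upstream*
  drives no downstream resident extinct (upstream compositional change is
  ignored; only its effect on realized downstream growth rates matters).

With migration probabilities p1, p2, q0 = Σ_i p_i1 Sp(i) + Σ_i p_i2 Ri(i).
The trial outcomes do not depend on (ρ, μ); the migration parameters enter
only as weights.  The implementation exploits this: one set of 2N trials is
re-weighted across whole (ρ, μ) grids, and trials with exactly zero weight
are skipped.  Invading a species already present adds the inoculum to its
abundance (its own presence cannot change; residents may be perturbed).

## Migration model

One invader per cycle.  Routes: pool→upstream (weight ρ), pool→downstream
(1−ρ), upstream→downstream (μ per species present upstream; presence is
the indicator x > 0 evaluated after extinction thresholding).  With
S = upstream richness and D = N + μS:  p_i1 = ρ/D,
p_i2 = ((1−ρ) + μ·δ(x_i1))/D.  The 2N probabilities always sum to 1.

## Ensembles

Random pools: off-diagonal a_ik i.i.d. N(0, 0.25²), diagonal −1.  Growth
rates in both patches are i.i.d. Uniform(0.1, 1) — positive (every species
persists alone, x\* = r) and bounded away from 0 so that mono-culture
equilibria are not degenerate.  This distribution is a package choice; the
statistics reported by the acceptance script are tolerance-banded partly
because feature medians (realized interaction totals) are sensitive to it.

Design targets and upstream communities are random subsets (richness
uniform on 1..10 unless stated) accepted when (i) the linear equilibrium
A_sub x\* = −r_sub is strictly positive, (ii) the community Jacobian
diag(x\*) A_sub is Hurwitz-stable, and (iii) one 300-t cycle from x\* keeps
every member above the extinction threshold within 1e-3 of x\*.  Both the
analytic and the numeric check are enforced.

## Scenarios

**Assembly** starts from two sterile patches and runs 250 invasion cycles;
stability, features and a changed/unchanged flag are recorded every cycle.
**Design** places a target community (downstream, at its isolated
equilibrium) under a random *unscreened* upstream community — a uniformly
random subset whose members start at their mono-culture equilibria — then
relaxes the joint system for one cycle, discards replicates that lose any
species in either patch, and evaluates survivors across the (ρ, μ) grid by
trial re-weighting.  Not screening the upstream subsets for coexistence is
deliberate: the joint-relaxation extinction filter is then the step that
makes rich random meta-communities rare (species are lost upstream as well
as downstream), which matches how the scenario is described and how hard
locally stable meta-communities are to generate.  A screened generator
(`generate_upstream_community`, same rejection contract as targets) is
also provided for experiments that need a self-coexistent upstream
community.

The "invasion did not change abundances" filter marks cycles whose end
state is *identical* to the pre-invasion state (strict equality by
default, tolerance configurable).  With the tight integrator tolerances
used here, a failed invasion reproduces the previous equilibrium to
~1e-10 while genuine transients sit orders of magnitude higher, so a
positive tolerance would conflate the two and skew the stability sample
toward unstable early states; strict identity keeps the sample's cycle
weighting intact.

## Interventions

**Block meta-communities.** Two disjoint 8-species communities (accepted
when the full community coexists under both its growth vectors) occupy the
patches of a 16-species pool.  Up→down interactions are half-normal
(σ·|N(0,1)|, all positive); down→up interactions are negated independent
half-normal draws, keeping the off-diagonal mean at zero.  A σ sweep scales
*one* pair of unit half-normal blocks drawn per meta-community, so the
per-community stability curve isolates the effect of the cross-interaction
scale; per-σ independent redraws would bury that effect in draw-to-draw
noise.  Down→up entries only matter when upstream species invade the
downstream patch (the chain coupling is one-way), which is exactly the
negative-reception bias the zero-feedback variant removes.

**Pseudo-spatial model.** A single patch of 25 species where species 0
affects three designated residents via sign(m)·Beta(10|m|, 10(1−|m|))
interactions (mean strength m) but is itself dynamically autonomous (its
row of A is zeroed in the dynamics; the literal alternative reading is
available behind `autonomous_species0=False`).  Systems are regenerated
until {species 0} + residents coexist; a system is discarded only if the
residents fail to coexist after species 0 is removed.  Stability without
species 0 uses the remaining 24 invaders at weight 1/25 and is rescaled by
25/24, so both measurements share a common per-species invasion weight.

## Statistical layer

Stability values are probabilities, so regressions use a fractional logit:
a binomial GLM with logit link on the fractional response with robust
(HC1) standard errors, features standardized to mean 0 / population-SD 1
(constant columns dropped with a warning).  Covariate choice follows the
backdoor criterion on the shipped causal diagram
(`chainstab/data/causal_diagram.txt`): richness drives interaction totals
and degrees; within-patch totals drive within-patch invasion resistance;
trans totals, ρ and μ drive both stability metrics; degrees and mean
strengths have no edges into the metrics; upstream invasion resistance and
the two stability metrics are unavailable for adjustment.  Adjustment-set
search enumerates observed non-descendant subsets in increasing size
(lexicographic tie-break) and checks d-separation in the backdoor graph —
feasible because the diagram is small, and verified in tests against full
enumeration.  Effect sizes are Cliff's delta (independent samples) and the
rank-biserial correlation (paired signed-rank convention).

## Numerical choices

* Integrator: LSODA (stiff/non-stiff switching) with rtol 1e-8,
  atol 1e-10 and the analytic gLV Jacobian, applied to the present-species
  subsystem only (exact: absent species have identically zero derivatives).
* Extinction threshold 1e-6, applied at cycle ends (inoculum is 0.01, so
  invaders sit 4 orders of magnitude above it).
* Cycle length 300 t; all durations configurable.
* Rare diverging trajectories (net positive feedback) are flagged as
  integrator failures; assembly annuls the offending invasion and
  continues, design discards the replicate, and summary drivers drop
  flagged records.
* Within an assembly run, states equal after quantization at 1e-8 are
  treated as the same Markov state and reuse cached trial outcomes
  (stability is deterministic and depends only on the current state).

## Reproduction scales

The full-scale study (60 replicates × 250 cycles; 60 targets × 200
upstream communities × 25 (ρ, μ) sets) amounts to hundreds of thousands
of stability evaluations.  `scripts/acceptance.py` and the acceptance
tests instead use reduced sampling sizes with the same study conditions: unstructured design 60 communities;
unstructured assembly 8 replicates × 250 cycles; structured assembly
2 replicates × 250 cycles on a 15-cell grid (full ρ marginal
{0, .25, .5, .75, 1} × μ {0, .5, 1}); structured design 30 targets × 50
upstream communities re-weighted over the full 5×5 grid; pseudo-spatial
30 systems per m ∈ {0.1, 0.3, 0.6, 0.9}.  Assembly keeps the full 250
cycles because the pooled median is dominated by the mature phase of the
time series; replicate counts are cut instead.

## What the generator does and does not emulate

The synthetic ensembles reproduce the study's random-matrix world:
phenomenological pairwise interactions that are identical in both patches,
no explicit resources or toxins, environment-independent interaction
signs, and exactly two patches with one-way flow.  Passing tests therefore
demonstrate properties of that model world, not of real gut communities —
in particular, real microbial interactions are metabolite-mediated and can
change sign with context, which a gLV cannot express.

## Known limitations

* The interaction-strength feature medians run above the original
  report (~40%) while all stability medians and correlations reproduce;
  they scale directly with realized richness, which is sensitive to the
  growth-rate distribution (only constrained, not pinned, by the main
  text) and to pre-screening upstream communities for isolated
  coexistence.
* Trial outcomes near the extinction threshold can flip under tolerance
  changes; the threshold sits 4 orders below the inoculum to keep this
  rare.
* The causal diagram is an input assumption; adjustment sets are only as
  valid as its edges.
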