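# Methods

This note documents the models, algorithms, parameter choices and
numerical conventions behind `disparitree`, and what the synthetic-data
tests do and do not establish about real data.

## Shape variables

Raw 2-D landmark configurations are superimposed by generalized
Procrustes analysis: each configuration is centred, scaled to unit
centroid size, and rotated to the current consensus; the consensus is
the normalised mean of the aligned shapes and is re-estimated until it
moves by less than `tol` (default 1e-10, `max_iter` 100 with a warning
on non-convergence). The initial consensus is the plain average of the
centred/scaled shapes, which makes re-alignment of an already-aligned
sample a no-op; if random orientations nearly cancel that average
(norm < 1e-6) the first shape is used as the starting reference
instead. Reflections are never fitted: the rotation comes from the 2×2
cross-product SVD with its determinant sign corrected, and a
configuration that would fit better mirrored is flagged with a
warning. Full Procrustes (unit-size) scaling is used throughout, the
standard choice in morphometrics.

PCA operates on the flattened (x₁, y₁, …, x_k, y_k) coordinates via
SVD of the centred data matrix; eigenvalues are sample variances (n−1
denominator). Alignment removes two translations, one rotation and one
scale, so at most 2k−4 eigenvalues are non-zero — exactly so only to
first order, because the unit-size and rotation constraints are curved;
the residual curvature eigenvalues scale with the square of the shape
scatter and are negligible for small-variation data.

Axis retention uses the broken-stick rule: keep the leading contiguous
run of axes whose observed eigenvalue proportion strictly exceeds
bⱼ = (1/p)·Σᵢ₌ⱼᵖ 1/i, with a floor of one axis. A tie counts as not
exceeding, which makes the rule deterministic. Analyses that fix the
axis count a priori can override the rule (`n_retained`).

## Dating ensembles

Tip ages are Ma before present (larger = older); durations Myr. Each
fossil tip carries a stratigraphic range [younger, older]; extant tips
are 0/0. Two age modes exist: `older_bound` pins each fossil at its
oldest bound; `uniform` draws uniformly within the range. Polytomies
are resolved by recursive random pairing: two children of a polytomous
node are chosen uniformly and joined under a new node until the node is
binary; every input clade survives, and a trichotomy yields each of its
three resolutions with probability 1/3.

The *equal* dating procedure runs in three stages:

1. every internal node gets the age of its oldest descendant tip,
   raised to any applicable constraint minimum (constraints are
   expressed as MRCA tip-sets; maxima propagate rootward because each
   parent takes the max over its children);
2. the root age is increased by `vartime` (default 1 Myr),
   guaranteeing slack to share;
3. zero-duration branches receive time: repeatedly take the deepest
   zero-duration branch, walk up to the nearest ancestral branch with
   positive duration, and respace the node ages along that path
   evenly. Chains that branch share their upper portion with the first
   chain processed and are finished in later passes. Root and tip ages
   never move, so all root-to-tip spans are conserved, and node ages
   only increase, so constraint minima stay satisfied.

The contract is this three-stage procedure plus its invariants
(strictly positive durations, exact tip-age fidelity, constraint
satisfaction); byte-level replication of any particular existing
implementation is not attempted.

Replicates draw from RNG substreams seeded by (root seed, replicate
index), so replicate *i* is identical no matter how many replicates are
requested, and a rerun of the whole pipeline is byte-identical. The
three standard ensemble recipes are exposed as tree sets #1 (resolve +
older_bound), #2 (unresolved + uniform) and #3 (resolve + uniform).

## Ancestral states

For Brownian motion with a constant diffusion rate, the ML point
estimates of internal-node values minimise Σ (x_child − x_parent)²/v —
squared-change parsimony weighted by branch duration. The rate cancels
in the point estimates, so it is not estimated, and dimensions
decouple, so p axes are solved jointly as arrays. The solver is the
two-pass pruning algorithm (tip-to-root contraction into conditional
values with effective extra durations, root-to-tip combination with the
parent's finalised value), O(n·p). Branch durations below 1e-8 Myr —
impossible after *equal* dating but possible in hand-built input — are
floored at 1e-8 with a warning rather than rejected. No uncertainty is
attached to the estimates; the pipeline uses point values only.

## Disparity

A time bin [older, younger] is sampled at its midpoint. Every branch
whose age interval contains the midpoint contributes the linear
interpolation between its parent and child values (the *gradual*
model); membership uses the half-open rule child ≤ t < parent plus the
root's own value at t = root age, so a node sitting exactly on a
midpoint is counted once, via its parent branch. The alternative
*punctuated* interpolation model is deliberately out of scope.

Disparity per bin is the sum over retained axes of the sample variance
(n−1) of the interpolated values. Only interpolated branch samples
enter; observed terminal and estimated node values are not appended
separately. Bins crossed by fewer than two lineages yield a missing
value, not zero — zero disparity would be a biological claim that a
single lineage cannot support. The Recent can be represented as a
degenerate point bin [0, 0], sampled exactly at 0 Ma, where extant tips
contribute their observed values.

Ensembles are summarised per bin by median, 2.5 %/97.5 % quantiles
(linear-interpolation quantiles) and min/max over the replicates whose
value is defined in that bin. Clade subsets carry node ages and values
over unchanged — no re-estimation — so a whole-tree slice restricted to
a clade equals the clade-subset slice exactly. The fossil-exclusion
variant drops all non-extant tips before dating and suppresses the
resulting degree-2 nodes with edge lengths summed.

## Covariate tests

Point series (age, value) are binned by the half-open rule
younger < age ≤ older, so a point on a shared boundary belongs to
exactly one bin (the one whose older bound it equals); empty bins are
missing, and all tests drop incomplete pairs pairwise. Spearman uses
average ranks for ties, an exact two-sided permutation p-value for
n ≤ 9 (full enumeration) and the t approximation above; a variable
whose ranks are all tied gives r_S = 0 with a warning. OLS reports the
slope t-test p and R² = 1 − SSE/SST. The GLS fit assumes AR(1)
residual correlation across the ordered bins — the error structure was
an open choice; AR(1) is the minimal serial-correlation model for a
bin sequence — with φ and the coefficients found by profiled maximum
likelihood (bounded scalar optimisation of the profile log-likelihood
over φ ∈ (−1, 1)); with φ = 0 the estimates and p-value reduce exactly
to OLS. Optimisation failure is flagged on the result object rather
than raised. The first-difference test applies the Spearman test to
changes across successive bins, dropping differences that touch a
missing value. All p-values are two-sided and uncorrected; the result
table reports them raw.

Note that the ML estimate of φ is biased downward by O(1/n); the
calibration tests therefore run at n = 200 bins, where the bias is
inside the Monte Carlo noise. Empirical series of 10–30 bins will show
visibly low φ estimates; this is a property of ML AR(1) estimation,
not of the implementation.

## Synthetic data

The generator emulates the study design end to end, with ground truth
retained at every stage:

- **Trees.** A crown-conditioned constant-rate birth–death process
  (two initial lineages), simulated event by event; extinct tips keep
  their extinction ages. Stop rules: fixed depth, or a target count of
  simultaneously extant lineages (the run then stops between the
  target-reaching event and the next one, so terminal branches have
  positive duration). Total extinction triggers rejection and redraw.
- **Traits.** Forward Brownian motion, child = parent + N(0, σ²v) per
  dimension; true values at every node are returned for recovery
  scoring.
- **Landmarks.** BM deviations added to a reference configuration and
  hidden behind nuisance similarity transforms — rotation ~ U(0, 2π),
  scale ~ exp N(0, 0.1), translation ~ N(0, 10 × reference scale) —
  which alignment must remove.
- **Stratigraphy.** Contiguous units of fixed width; each fossil tip
  is assigned the unit containing its true age, so any age redrawn
  from the range can bracket the truth. Extant tips get 0/0.
- **Polytomies.** A chosen fraction of internal edges is collapsed,
  and ages discarded, emulating an undated supertree.
- **Clock constraints.** Molecular clocks date extant divergences, so
  each emulated posterior sample constrains the MRCAs of extant tip
  groups: nodes that are exact MRCAs of their extant descendants are
  included with probability 0.8, with the enforced minimum drawn as
  true age × U(0.9, 1.1) — posterior estimates scatter around the
  truth, over- as well as undershooting it.

Default study conditions (`make_dataset`): birth 0.1/Myr, death
0.05/Myr, stopped at 40 extant tips (clade depth on the order of
40–100 Myr), 7 trait dimensions at rate 1 per Myr, 12 landmarks, 30 %
of internal edges collapsed, 10-Myr stratigraphic units, 50 constraint
sets.

### What the synthetic tests do and do not show

The generator produces isotropic Brownian variation, clock-like
stratigraphic units and unbiased clock constraints. Real data have
correlated trait axes, non-uniform preservation, taxonomically biased
sampling and clock estimates with structured error; passing the
synthetic suite shows the pipeline computes its quantities correctly
under its own model, not that the model describes any particular
clade.

Two systematic effects observed on the synthetic fixtures are worth
recording. First, squared-change-parsimony ancestors shrink toward the
mean, so a disparity curve built from reconstructed values
underestimates the disparity of the true (latent) node values in bins
dominated by internal branches; the ensemble band quantifies dating
and topology uncertainty, not this shrinkage, which is shared by every
curve in the ensemble. The end-to-end recovery test therefore compares
the ensemble band against the pipeline's own curve on the true
chronogram. Second, even on that like-for-like comparison the
100-replicate min–max band covers the true-tree curve in all bins on
the default fixture but misses one or two sparse, near-root bins in
roughly half of alternative fixture draws (coverage 0.7–1.0, mean
≈ 0.93 over ten draws): *equal* dating compresses the ages of nodes
that subtend only extinct lineages (which no clock constraint dates),
so the oldest bins of the dated trees can be emptier than the true
tree's. This mirrors the method's known behaviour on real fossil data
and is the main caveat on the oldest portion of any curve it produces.

## Numerical conventions

- Ages in Ma, larger = older; durations in Myr; zero-duration
  detection threshold 1e-12 in the dating stage.
- Sample variances and covariances use the n−1 denominator throughout.
- Quantiles are linear-interpolation quantiles of the defined values.
- CSV output is comma-separated UTF-8 with a header row and '.'
  decimals; trees travel as Newick/NEXUS with durations as branch
  lengths and node ages available as annotations.
- All randomness flows from named SeedSequence substreams; rerunning
  any configuration with the same seed is byte-identical.

## Known limitations

- Only the *equal* dating method is implemented (no cal3, minimum
  branch length or tip-dating).
- Ancestral states are BM point estimates; no OU/early-burst models,
  rate estimation or reconstruction uncertainty.
- Disparity is sum of variances only (no sum of ranges, pairwise
  distances or rarefaction).
- The GLS error structure is AR(1) over bins; irregular bin spacing is
  treated as a regular sequence.
- Landmark support is 2-D fixed landmarks; no semilandmark sliding or
  3-D configurations.
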