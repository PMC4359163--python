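# Methods

## Scales and normalization

All effect analysis happens on the log2-ratio scale
`x = log2(percent / 100)`, where percent is the measured value expressed
as a percentage of the untreated control. Untreated is 0, doubling +1,
halving -1. The alternative reading `log2(percent)` differs only by the
constant log2(100) and cannot change any sign- or quantile-based
decision; the chosen interpretation is recorded in the summary frame's
metadata. Exact zeros on the log2 scale support neither an increase nor
a decrease and are excluded from sign counts (but kept in the replicate
denominator). Missing replicate cells are dropped, never imputed: the
retention criteria are counts over available replicates.

## Deconvolution

The 3x3 replicate-triple systems are solved exactly
(`numpy.linalg.solve`); a triple whose composition matrix has condition
number above `condition_limit` (default 1e8) is flagged singular and
skipped rather than regularized — the median over the many remaining
triples already provides robustness, and any regularization would bias
the noiseless-recovery guarantee. The median of an even number of
solutions is the usual midpoint convention. The 1% floor
(`clamp_floor`, percent units) is applied *after* median aggregation,
matching the reading that the inferred (aggregated) amount is what gets
floored; the affected population labels are reported. Solution spread
(per-population IQR across triples) is exported as raw dispersion, not
modelled.

With n replicates the estimator solves C(n,3) systems (4 at n = 4, 84 at
n = 9). Noiseless forward-simulated mixtures are recovered to 1e-6 for
every n in 3..9; this is a property of exact solving plus the median and
is enforced by tests.

## Link retention

* `reproducibility_fraction` = 0.75: the majority effect direction must
  cover at least 3/4 of replicates. A tie or an all-zero profile has no
  majority sign and fails.
* `amplitude_quantiles` = (0.25, 0.75): a cell's mean log2 effect must
  reach the upper or lower quartile of the pooled mean effects. The
  reference pool is all (treatment, readout) cells *of the same readout
  kind* — pooling receptors with cytokines would mix measurement scales.
  Quantiles use linear interpolation on sorted values; ties at a cutoff
  are inclusive.
* coherence: evaluated on the sign products of *informative* cells —
  those passing reproducibility and amplitude (the amplitude requirement
  is config-switchable via `coherence_requires_amplitude`). At least
  `coherence_min_treatments` = 2 informative treatments are required;
  consistency over fewer observations is vacuous.
* a retained link requires both its receptor and cytokine cells to pass
  both per-cell criteria (`require_both_amplitude`; the either-passes
  variant is exposed but off).

Tightening any threshold can only shrink the retained set (monotonicity
is tested). Amplitude alone admits 50% of cells (25% per tail), hence
25% of receptor-cytokine cell pairs; the three criteria jointly retain
about 4% of candidates under an all-noise model.

## Boolean networks

Update functions use `& | !` over declared nodes with constants 0/1, in
the BoolNet-style `targets, factors` text dialect (chosen for
interoperability). Undeclared symbols become input nodes with
self-identity functions, so each ligand's presence is a free boundary
condition. Phenotypes are fixed points only: they are identical under
synchronous and asynchronous update, which removes any update-scheme
ambiguity; cyclic attractors are out of scope. Fixed points are found by
an exhaustive, chunked, vectorized scan (refused above 30 nodes; the
intended regime is <= ~20). Clamps override update functions and model
ligand addition (1) or kinase inhibition (0).

Networks assembled from links use one AND node per combined treatment
and the template `OR(activating treatments) & !OR(inhibiting
treatments)` per readout. The template makes inhibition dominant by
construction: under a combined-ligand boundary condition, a single-ligand
treatment contained in it is also active, and an inhibiting combination
overrides an activating component. Planted signs are therefore
guaranteed to be reproduced at single-ligand boundary conditions; a
curated equation file can always replace the template.

## Minimal intervention sets

Validity of a clamp set is "force" semantics: the clamped network has at
least one fixed point *and* every fixed point satisfies the phenotype
constraint. A therapy that merely permits the desired state would not
force it; the weaker exists-only semantics is available via
`MISQuery(semantics="permit")`. Minimality is subset-minimality,
enforced by size-ordered enumeration with subset pruning; the empty set
is reported as the unique MIS when the unperturbed network already meets
the constraint.

The brute-force solver is the oracle. The unrolling solver builds one
tree per constraint (root) node by following regulators backwards,
cutting a path when a node repeats on it; required polarities are pushed
root-to-leaf through every regulator assignment realising them, and
candidate clamp vectors are merged leaf-to-root, discarding vectors that
clamp one node both ways at path merges. Polarity propagation is a
local, logic-level argument: it is not complete for non-monotone update
functions, nor can it propose the stabilizing clamps needed when a node
*outside* the constraint's regulator cone oscillates (e.g. `B, !B`
removes every fixed point until B is clamped, yet no backward path from
the roots reaches B). The propagated vectors therefore seed and order an
exactness-preserving completion pass over the same candidate space, all
validity checks running against a per-network truth-table cache (one
vectorized evaluation of every node over all states, after which any
clamp set is pure boolean-array algebra). The result is set-equal to the
oracle by construction, and the equivalence is still exercised over
hundreds of random networks to catch implementation defects. Propagation
is capped (512 vectors per node/polarity, regulator expansion skipped
above in-degree 6); the caps affect only seeding order, never results.

For TEM-style phenotype queries the candidate interventions are the
therapeutically accessible ones: ligands may only be added
(over-expressed) and receptors only inhibited — receptor over-expression
is not a treatment one can administer. Constraint nodes themselves are
eligible (inhibiting both root receptors directly is a legitimate, and
reported, dampening set). Results are sorted by size then
lexicographically for reproducible diffs.

## Synthetic generators

*Response tables.* Planted cells receive per-replicate log2 effects
`sign * effect_size + N(0, noise_sd)` (defaults 1.0 and 0.1 log2 units,
4 replicates), noise-only cells `N(0, noise_sd)`; values are emitted on
the percent scale as `100 * 2^x`, hence strictly positive. Noise is
Gaussian on the log2 scale because biological variation in fold-changes
is multiplicative. The default planted design fills exactly the upper
and lower quartile of cells per readout kind (21 + 21 of 84 receptor
cells, 33 + 33 of 132 cytokine cells; one cytokine responds with
inverted polarity so anti-correlated links exist), emulating a strong,
broadly remodelling treatment panel: half the cells respond, half are
noise. Under this design the pooled quartile cutoffs fall in the gap
between the noise cluster and the responding clusters, which is what
makes exact planted-link recovery a well-posed expectation. With a
sparse planted set the cutoffs would necessarily sit inside the noise
distribution and chance-coherent noise triples would contaminate any
finite battery — the sign of N(0, sd) is ±1/2 regardless of sd.

*Mixtures.* True contributions default to (20, 60, 160) percent — the
DP population (the differentiated TEM) dominates secretion, DN is
weakest. Compositions are Dirichlet(1, 1, 1), i.e. uniform on the
simplex, reflecting strong donor-to-donor variability of the three
population fractions; measurement noise is Gaussian on the percent scale
(sd 5), where the bulk arithmetic lives. Bulk values are floored at 0.

*Random networks.* 1..`max_indegree` distinct regulators per non-input
node with uniformly random truth tables (serialized as sum-of-products),
a configurable input fraction, deterministic under seed. Used as the
MIS solver battery.

*What the generators do not emulate:* heteroscedastic flow-cytometry
noise, replicate correlation and batch structure, measurement error on
the population fractions (the forward model treats compositions as
exact), detection floors/saturation, and treatments whose true effects
are intermediate rather than a fixed ±effect size. Passing recovery
tests therefore demonstrates correctness of the inference chain under
its own assumptions, not performance on real cytometry data.

*Fixture network.* `paperlike_network()` is a curated, qualitative
reconstruction (flagged as such in its metadata): 6 ligand inputs, 3 AND
nodes, 7 receptors, wired only from qualitatively reported behaviors
(TGF-β raises TIE-2, lowers VEGFR-1 and CD11b; TNF-α with PlGF or ANG-2
raises TIE-2; only the full TNF-α/PlGF/ANG-2 combination, synergising
with TIE-2 signalling, induces VEGFR-1). Its headline behavior: clamping
the TNF-α/PlGF/ANG-2 triple on forces TIE-2 = VEGFR-1 = 1 in all fixed
points and is the unique promoting MIS; TIE-2 knock-down with TGF-β and
VEGF forces VEGFR-1 = 0. Being a coarse reconstruction it collapses
finer structure of the deposited model — in particular its dampening
sets reduce to two (TIE-2 inhibition plus either TGF-β or VEGFR-1
inhibition) rather than the fuller grouped table of the original
equations, which is why the study-reproduction check uses the deposited
equation file, not this fixture.

## Problem sizes

Default verification sizes, chosen to keep the full suite fast while
leaving no criterion under-sampled: 50 seeded planted datasets for
link-recovery precision/recall; 10 (tests) to 200 (acceptance script)
seeded mixtures for deconvolution error; 100 random networks of 6-10
nodes, in-degree <= 3, k_max = 3 for solver equivalence; exhaustive
state scans up to 2^16 states for the fixture.

## Known limitations

* Fixed points only; sustained oscillations are invisible to the model.
* Exhaustive engines stop at ~20-30 nodes; no symbolic/BDD backend.
* The 12-treatment roster identity is configuration, not code: the
  original design lists it only implicitly, so the default roster is a
  six-ligand emulation.
* The pipeline's ancestor-closure reduction before fixed-point/MIS
  stages is exact only when the removed part is purely downstream (true
  for link-built networks, where readouts never feed back).
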