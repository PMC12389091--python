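# Methods

## Problem and model

Lead optimization is cast as Pareto maximization of n desirability-scored
molecular properties over chemical space. Each objective is a raw scoring
function — an RDKit descriptor (TPSA, Crippen logP, average molecular weight
in Daltons, rotatable-bond/aromatic-ring/fluorine counts, QED), a Tanimoto
similarity to a fixed reference drug on a typed fingerprint (ECFP4/6, FCFP4/6,
or atom-pair), or a registered plugin — composed with a modifier mapping the
raw value to [0, 1]:

* `Gaussian(μ, σ)`: exp(−(x−μ)²/2σ²);
* `MaxGaussian` / `MinGaussian`: a plateau of 1 at/beyond μ with a Gaussian
  tail on the unfavourable side;
* `ThresholdedLinear(μ)`: min(x, μ)/μ.

These follow the GuacaMol goal-directed conventions, which the benchmark
tasks are drawn from; the tasks themselves only name the modifiers.
Similarity uses the standard Tanimoto (Jaccard) coefficient |A∩B|/|A∪B| on
folded on-bit sets (2048 bits by default), so that similarity and the
crowding distance are exact complements: sim + dist = 1.

## Success windows

Success-rate reporting needs a window on the *raw* value of every objective.
Windows are derived from the modifiers: μ ± σ (endpoints inclusive) for the
Gaussian family — reproducing, e.g., TPSA ∈ [80, 100] from MaxGaussian(90, 10)
and logP ∈ [2, 6] from MinGaussian(4, 2) on the fexofenadine task — and
`raw < μ` for ThresholdedLinear similarity objectives, read as a novelty
constraint (a success must stay *below* the similarity threshold). The
saturation reading (`raw ≥ μ`) is selectable per task (`threshold_rule`)
because the thresholded modifier rewards what the novelty window forbids;
the default follows the stated evaluation convention. Two documented
consequences: the osimertinib MinGaussian(0.85, 2) similarity window
[−1.15, 2.85] covers all of [0, 1] and is vacuous; and on plateau-modified
objectives the optimizer is free to push raw values out of the μ ± σ window
(e.g. TPSA past 100 under MaxGaussian(90, 10)) without any score penalty,
which depresses desk-scale success rates on the fexofenadine task.

The cobimetinib task's CNS objective is a pluggable scorer. The default is a
four-component CNS-MPO-style desirability average (piecewise-linear terms in
logP, molecular weight, TPSA, and H-bond donors; the pKa terms are omitted
for lack of a pKa predictor), output in [0, 1], success at ≥ 0.5. The plugin
registry (`register_scorer`) is also the extension point for bioactivity
models, which are out of scope.

## Evolutionary core

Fitness is the geometric mean of the modified score vector; parent selection
is roulette-wheel on fitness with a floor of 1e−6 to keep the wheel defined
when scores underflow. Each generation produces N offspring (an even
crossover/mutation split by default) and selects N survivors from the 2N
merged pool.

Non-dominated sorting is the standard O(n²m) front-peeling procedure.
Crowding is computed per front: the Tanimoto variant is the mean Jaccard
distance on ECFP4 fingerprints to all frontmates (singleton fronts get 1,
i.e. maximal isolation; an empty-set average is undefined); the classical
variant is Deb's normalized-gap sum with infinite boundary values. Ties in
crowding order break by higher fitness, then stable input order, so a seeded
run is bit-reproducible.

The update carries whole fronts while they fit. The first overflowing front
is sorted by crowding descending and filled by one Bernoulli(p_a) pass in
that order; if rejections leave slots open, they are topped up
deterministically from the rejected candidates in the same order, which
guarantees exact capacity and termination (the source text does not say how
unfilled slots are handled). The acceptance probability
p_a(g) = exp(−(1/g)^β) uses a 1-based generation counter (g = 0 would divide
by zero), giving p_a(1) = e⁻¹ for every β; β defaults to 0.45. Mode `mogat`
forces p_a = 1 and `nsga2` swaps in objective-space crowding; both then
reduce to classical rank-and-crowding truncation.

## Variation operators

The core is a Bemis–Murcko-style ring-and-linker scaffold obtained by
iteratively pruning acyclic leaves, then pulling atoms attached through
double/triple bonds (ring carbonyls and the like) back into the core so that
every side chain hangs off a single breakable single bond. Side chains carry
isotope-numbered dummy atoms and reassembly is RDKit `molzip`, which makes
decompose → reassemble an exact canonical-SMILES round trip (tested on the
full fixture corpus). Ring-free molecules are treated as all-core; mutation
still applies to them via fragment addition on any atom with a free
hydrogen.

Crossover picks one parent's core uniformly and dresses each attachment
point with a chain sampled from both parents' pooled chains (left bare with
probability 0.2). Mutation chooses uniformly among add / replace / delete
(falling back to add when no chain exists), drawing fragments from the
current population's harvested side chains plus a built-in set of sixteen
small substituents. Both operators sanitize every product, retry up to 10
times, and fall back to a parent copy, so offspring are always valid —
invalid chemistry is handled as data, never as an exception crossing the GA
loop.

## Metrics

Hypervolume is the Lebesgue measure of the union of boxes [0, p] over the
rank-0 front, computed exactly by dimension-sweep slicing with Pareto
pruning (a 2-D staircase base case); since all objectives are modified into
[0, 1] and the reference point is the origin, HV ∈ [0, 1]. Beyond five
objectives a Monte Carlo estimator takes over. Internal similarity defaults
to the mean pairwise Tanimoto similarity over unordered pairs; an n-ary
"extended" coincidence index (strict-majority agreement over fingerprint
columns) is selectable, as the n-ary formulation in the source is not fully
specified. Per-run values are final-generation summaries; multi-trial
reporting is the arithmetic mean across trials.

## Synthetic seed library

The fixture generator enumerates a deterministic grid of ten ring scaffolds
(benzene, pyridine, cyclohexane, piperidine, morpholine, thiazolidinedione,
biphenyl, naphthalene, furan, thiophene, plus di/tri-substituted benzene and
piperazine templates) × twenty substituents × three linker lengths,
validates and deduplicates everything with RDKit (≈ 1.7 k distinct
molecules), shuffles by seed, and truncates. It emulates the *coverage* of a
drug-like screening set — TPSA ≈ 0–130 Å², logP ≈ −2–6, MW ≈ 78–405 Da, 0–11
rotatable bonds, including molecules inside the benchmark success windows —
but not the scale, scaffold richness, or property correlations of a real
compound database. Results on it therefore exercise the algorithmic
machinery and directional behaviour, not the absolute benchmark values
attainable from a large screening library.

## Problem sizes and known limitations

The packaged evaluation runs use population 50, 50 generations, and 5 trials
per mode (the protocol defaults remain population 100, 150 generations, 20
trials, which need a user-supplied library to be meaningful). At this scale
the deterministic Tanimoto-crowding update (`mogat`) reproducibly lowers
internal similarity versus the classical baseline — the structural-diversity
mechanism behaves as designed — but the acceptance-probability churn
interacts badly with a small seed library: with p_a between 0.37 and 0.84
over 50 generations, distinctive low-fitness structures are frequently
discarded at random while fitness-proportional parenting amplifies a few
high-fitness clones, so populations can fixate early (unique-structure
counts collapse) and success rate/hypervolume fall below the `nsga2`
baseline. Longer horizons anneal p_a toward 1 and large diverse libraries
keep reseeding the population, so this pathology is specific to small-scale
settings; it is surfaced, not hidden, by the desk-scale trend checks in the
test suite. Other limitations: no stereochemistry or 3-D information is
used; the fragmentation scheme cannot exchange ring systems; and the best
geometric mean is not strictly monotone under the stochastic update, since
the incumbent can sit in the overflowing front and be rejected by the
Bernoulli pass.
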