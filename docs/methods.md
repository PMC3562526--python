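# Methods

## The problem

Expression profiling of a species without its own array (papaya) on a
heterologous chip (the *Arabidopsis* ATH1 design) is corrupted by sequence
divergence: a probe whose 25-mer target has drifted binds weakly, and its
measured intensity is dominated by nonspecific background rather than
transcript abundance.  The XSpecies remedy is empirical: hybridize the
target species' genomic DNA — present at uniform copy number for every gene
— and treat the gDNA intensity of each probe as a direct readout of its
binding capacity.  Probes with weak gDNA signal are masked out *before* any
expression analysis.

## Probe masking

Given one or more gDNA arrays, the per-probe criterion is the arithmetic
mean of the PM intensities across gDNA arrays, compared **strictly** to the
threshold (ties at the threshold are dropped).  A probe-set survives if it
retains at least two probe-pairs — "more than one" read as ≥ 2.  Only PM
probes are thresholded; MM probes are carried in the data model but unused
(the summarization is PM-only, and no MM rule is defined).  The default
sweep is 0, 25, …, 500 fluorescence units.

Two properties follow from the rule and are enforced by tests: masks *nest*
(everything retained at a higher threshold is retained at a lower one), and
the relative probe-set retention dominates the relative probe-pair
retention — a set only dies when it is down to one pair.  The second
property provably flips deep in the tail: if a fraction *q* of pairs
survives, sets survive at ≈ P(Bin(11, q) ≥ 2) ≈ 55q², which falls below *q*
once q ≲ 2%.  Tests therefore assert the ordering wherever pair retention
is ≥ 2%.

The working threshold is chosen by brute force: at each threshold the full
mask → RMA → DE pipeline runs and the threshold maximizing the DE count
wins, ties resolving to the smallest threshold (most probes retained).

## Mask-aware RMA

Summarization follows the canonical Robust Multichip Average:

1. **Background correction** (optional, default on).  Observed intensity is
   modelled as exponential signal plus normal background,
   x = s + b, s ~ Exp(α), b ~ N(μ, σ²); x is replaced by the posterior mean
   E[s|x] = a + σ·φ(a/σ)/Φ(a/σ) with a = x − μ − σ²α, which is always
   positive and strictly increasing in x.  The model is estimated per array
   on **every** probe of the array, not only the retained ones — the
   masked-out, background-dominated probes are precisely what anchors μ.
   The estimator first tries the closed-form method-of-moments fit
   (α = (2/m₃)^{1/3}, σ² = var − 1/α², μ = mean − 1/α from the first three
   central moments), which recovers the true parameters when the
   convolution model holds; when that system is infeasible (non-positive
   skewness, σ² or μ — the usual case on strongly lognormal chip signal)
   it falls back to the kernel-density route: μ = mode of the points below
   the overall density mode, σ from the half-normal spread left of μ,
   α = 1/mean-excess above μ.  Both routes are deterministic.  With fewer
   than 100 retained probes the correction is skipped with a warning
   (the model is not estimable).
2. **log2** with corrected intensities floored at 2⁻²⁰.
3. **Quantile normalization** over the retained PM probes: each column is
   replaced rank-by-rank with the across-array mean of per-rank values.
   Ties break by stable sort order of probe index (no mid-rank averaging),
   which makes the operation reproducible and idempotent.
4. **Median polish** per probe-set on the probes × arrays table: row sweep
   first from zero effects, iterated until the largest residual change is
   < 10⁻⁶ or 10 iterations; expression per array = overall + column effect.
   Probe-sets with equal retained-pair counts are polished as one batched
   3-D operation (identical sweep schedule; extra sweeps on
   already-converged sets are numerically inert), which is what keeps a
   full 21-point threshold sweep at desk scale.

A caveat documented because it surprised us during design: quantile
normalization interacts with differential expression even at zero noise —
a DE probe changes rank between conditions and inherits neighboring rank
means, so noiseless fold changes are recovered to ~10⁻² (scaling with the
DE fraction), not exactly.  Exactness holds per stage (median polish is
location-equivariant; an additive matrix is its fixed point).

## Differential expression

log2 fold change is the difference of condition means of RMA expression;
the p-value comes from a one-way ANOVA F-test, identical to a two-sided
pooled-variance t-test for two groups (each group needs ≥ 2 replicate
arrays).  Zero within-group variance is floored at 10⁻¹² and flagged so
noiseless fixtures do not crash.  BH adjustment is the step-up rule
q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j capped at 1.  Selection requires both
|log2fc| > log2(1.25) ≈ 0.3219 and p ≤ 0.05; the p cut applies to the
BH-adjusted values by default and can be switched to raw p (both
conventions are in circulation for this kind of analysis, and the package
exposes the choice rather than guessing).

## Clustering, enrichment, cross-platform comparison

Selected probe-sets are clustered on their log2 expression profiles with
complete-linkage agglomeration under the chord distance
(d = √(2 − 2cosθ); scale-invariant, range [0, 2]), implemented on
scipy's hierarchy machinery; the dendrogram is cut to *k* clusters
(default 8).  Determinism is guaranteed for a fixed input order by scipy's
nearest-neighbor-chain agglomeration; how the original analysis cut its
tree is not recoverable, so *k* is a parameter, not a claim.

Bin enrichment is a two-sided Mann–Whitney rank-sum of a bin's member log2
fold changes against all non-members: exact enumeration when the smaller
group has ≤ 8 values and no ties, otherwise the tie-corrected normal
approximation with continuity correction; BH across bins; the direction
(up/down) is reported from the member-vs-rest median, separately from the
two-sided p.

Cross-platform comparison takes per-species gene → log2fc tables, forms
up-sets at log2fc ≥ 0.3, and reports every Venn cell.  Genes are matched by
shared identifier; matching across heterogeneous platforms is genuinely
ambiguous, so the matching key is the caller's explicit choice, and an
empty shared namespace warns rather than errors.

## qPCR

Technical replicates are averaged at the Ct level.  Per gene, an OLS fit of
Ct on log10 quantity over ≥ 3 distinct dilution points gives slope,
intercept, R², and efficiency E = 10^(−1/slope) − 1 (slope −3.3219 ⇔ 100%,
perfect doubling).  Quantities are 10^((Ct − intercept)/slope).  The target
is normalized by the geometric mean of the reference quantities (the
combination rule for dual references is a package choice; geometric mean is
the standard for multi-reference normalization) and scaled so the
calibrator sample is exactly 1.  Significance across time points: one-way
ANOVA plus Tukey HSD (Tukey–Kramer for unbalanced groups) at α = 0.05,
with a per-sample "differs from calibrator" flag.

## Phylogenetics

Distances are uncorrected p-distances with pairwise gap deletion (the
fraction of differing positions among gap-free pairs); a pair with no
comparable positions is an error.  The original trees were drawn from
ClustalW-derived distances whose exact model is not recoverable, so the
simplest documented choice is used and tree topologies are never asserted
against the published figures.  Neighbor joining is the Saitou–Nei
algorithm (join the pair minimizing Q(i,j) = (n−2)d(i,j) − Σd(i,·) −
Σd(j,·)); ties break by lexicographically smallest taxon-label pair, so
output is deterministic; trees are unrooted (degree-3 root) and exactly
reproduce additive input matrices.  Negative branch lengths are kept as
computed and reported via a warning — clamping would break additivity.
Newick is written at 6 decimals; parsing uses scikit-bio.

## The simulator

`synth.simulate` emulates the study design: 1 gDNA array, 3 replicate cRNA
arrays per condition (unripe/ripe), 11 probe-pairs per set.  On the log2
scale every probe has an affinity a ~ N(0, 0.5) shared across arrays (a
sequence property, absorbed by median polish); each set has abundance
μ ~ N(0, 1) around a baseline of 8 (≈ 256 units) and a planted shift ±1 on
a configurable fraction of sets (half up, half down); arrays add
N(0, 0.2) noise per probe.  A probe is diverged with probability 0.5 and
its specific signal multiplied by 0.05 on gDNA and RNA alike (the shared
mismatch is the premise of gDNA masking).  The gDNA level is 7 (≈ 128
units) so the informative thresholds fall inside the conventional 0–500
sweep.  On the raw scale every probe additionally receives nonspecific
background 32·2^N(0, 0.5) per array — without it, a purely multiplicative
attenuation would be a constant log-offset absorbed by median polish,
diverged probes would stay fully informative, and masking could never
help; with it, attenuated probes (≈ 13 units of signal under ≈ 34 of
background) are noise, which is the phenomenon the method exists for.
Setting `nonspecific_scale=0` recovers the purely multiplicative model.

What the simulator does **not** model: spatial chip artifacts, MM
cross-hybridization, probe-sequence-dependent affinity (GC content),
partial divergence gradients, or biological replicate heterogeneity beyond
i.i.d. noise.  Passing tests therefore demonstrate the pipeline's
correctness and calibration under a clean generative model, not performance
on real CEL data.

## Problem sizes and numerical choices

Tests and the acceptance script run at 200–2,000 synthetic probe-sets
(against 22,810 on the real chip) with a full 0–500/25 sweep; at these
sizes the complete pipeline sweep takes seconds and the 200-replicate null
calibration about a minute.  Under the default conditions the optimizer
lands at threshold 75 with a DE count ~20% above the unmasked count, the
null raw-p rate is ~4–5%, BH's mean false-discovery proportion over null
replicates stays ≤ 0.07, and ≥ 95% of planted effects are recovered.  Under
the background floor, fold changes of low-abundance sets are compressed
(≈ 80% within ±0.2 of truth at noise 0.15 — the familiar low-intensity
compression of RMA); under the background-free model recovery within ±0.2
is ≈ 99%.

Degenerate inputs are handled explicitly: constant intensity vectors and
< 100 probes are errors for background estimation; a mask retaining nothing
refuses to produce an empty layout (the threshold just scores 0 in the
optimization); single-array quantile normalization warns and no-ops;
zero-variance DE rows are floored and flagged; zero vectors are rejected by
the chord distance; empty reference quantities and non-negative standard
curve slopes are qPCR errors.
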