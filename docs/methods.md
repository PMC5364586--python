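# Methods

## The problem

Plasma cell-free DNA (cfDNA) in a cancer patient is a mixture: most
fragments come from normal hematopoietic turnover, a fraction θ (the
circulating-tumor-DNA burden) from the tumor. Tumors carry tissue- and
type-specific DNA methylation patterns, so a genome-wide methylation
profile of plasma cfDNA carries information about both *whether* tumor DNA
is present and *where* it came from. `ctorigin` jointly infers θ and the
tumor tissue of origin t from low-coverage whole-genome bisulfite
sequencing (WGBS) of plasma, using reference methylation profiles of solid
tumors and healthy plasma.

## Features: CpG clusters

Single CpG sites are too noisy at low sequencing depth, so probed CpG
sites are merged into **CpG clusters**: each site gets a ±`flank_bp`
(default 100 bp) flanking region; adjacent sites whose flanking regions
overlap are merged transitively; clusters with fewer than `min_probes`
(default 3) probed sites are discarded. Flanking regions are treated as
closed base intervals, so a gap of exactly `2·flank_bp` still merges —
only the strict-overlap examples are constrained either way, and the
closed convention keeps the rule symmetric. Coordinates are 0-based
half-open; cluster ids are `chrom:start-end`.

Cluster-level methylation is the mean of non-NA site levels for
array-style data (NA iff strictly more than half the sites are NA — an
even split keeps the value), and m/n for sequencing counts, NA when the
total n falls below 30 cytosines. These NA rules govern *reporting* of
methylation levels; the likelihood below uses every cluster with n ≥ 1,
because the count model is well defined for any n ≥ 1 and discarding
low-coverage clusters would waste most of a ~4× genome.

## Reference model

For each cluster k and class t (t = 0 normal plasma, t = 1..T tumor
types) the methylation level across individuals is Beta(α_kt, β_kt),
fitted by the method of moments: with sample mean μ and unbiased variance
s², c = μ(1−μ)/s² − 1, α = μc, β = (1−μ)c. Degenerate inputs are tamed by
clamping levels to [1e-6, 1−1e-6], flooring s² at 1e-6, and pulling s²
back to 0.999·μ(1−μ) when it exceeds the Beta-feasible bound; fits need at
least 5 usable samples per class. Features are selected by the
**methylation range** MR = max − min of the per-class mean levels
(computed in the same training pass as the fits); the cutoff MR ≥ 0.25 is
inclusive.

## Likelihood

The plasma level at cluster k is x_k = (1−θ) v_k + θ u_k with
v_k ~ Beta(α_k0, β_k0) and u_k ~ Beta(α_kt, β_kt). The density of x_k,
ψ(x|θ,t), is the scaled convolution of the two Beta densities (the
change-of-variable Jacobian 1/(1−θ) is included so ψ integrates to 1).
Sequencing observes m_k ~ Binomial(n_k, x_k), giving the per-cluster
marginal

    f(m_k | θ, t, n_k) = E_{v,u}[ Binomial(m_k | n_k, (1−θ)v + θu) ],

and, with clusters treated as independent, the sample log-likelihood
log L(θ,t) = Σ_k log f(m_k | θ, t, n_k). The MLE is a grid search over
θ ∈ {0, 1/J, …, (J−1)/J} (J = 100 by default: 1% burden resolution) and
t ∈ 1..T. The cancer call uses the per-feature-normalized score

    λ = (1/K_used) [ max_{θ,t} log L − log L(θ=0) ] ≥ 0,

with `is_cancer = λ > 0.023` by default. The threshold is exposed in the
API and CLI; it was originally chosen against a specific plasma cohort, so
it should be recalibrated for data that differ substantially from the
regime simulated here. Ties in the argmax break toward the smallest θ,
then the smallest t — conservative toward non-cancer. K_used counts the
selected features with n_k ≥ 1 (configurable); clusters with n_k = 0
carry no information and are excluded. A sample with zero usable features
raises an error rather than silently predicting.

## Numerics

Three independent evaluation routes exist for f(m|θ,t,n); agreement among
them (and with Monte-Carlo sampling) is asserted in the test suite.

1. **Exact (production path).** Expanding x^m (1−x)^{n−m} with
   x = (1−θ)v + θu and 1−x = (1−θ)(1−v) + θ(1−u) binomially gives

       f = C(n,m) Σ_s G_s (1−θ)^s θ^{n−s},
       G_s = Σ_{i+j=s} C(m,i) C(n−m,j) E[v^i (1−v)^j] E[u^{m−i} (1−u)^{n−m−j}],

   a degree-n polynomial in θ with *nonnegative* coefficients built from
   joint Beta moments E[v^a (1−v)^b] = B(α+a, β+b)/B(α, β). The moments
   obey a two-term recurrence with factors in (0,1), so the whole
   computation has no cancellation and no quadrature error. Coefficients
   are built once per cluster; the θ grid is then a single inner product.
   A numba-compiled kernel does this per sample (~0.1 s for 1500 features
   × 5 classes × 100 grid points at ~80 cytosines/cluster); a pure-numpy
   implementation of the same algorithm is the fallback and cross-check.
   G_s is evaluated in max-normalized form with log-scaled prefactors, so
   counts up to n = 1000 are supported without overflow.
2. **Quadrature (cross-check path).** Substituting each Beta variable by
   its CDF turns f into an integral of a bounded function over the unit
   square, evaluated by composite Simpson with nodes graded toward the
   endpoints by a quintic map (plain uniform nodes under-resolve the
   boundary layers that quantile functions create for concentrated or
   endpoint-singular Betas; grading brings 201 nodes to ~1e-6 relative
   error). Probabilities then sum to 1 over m by construction.
3. **ψ directly.** `psi_density` evaluates the convolution integral per x
   node, by adaptive quadrature by default (robust to α < 1 or β < 1
   endpoint singularities) or by eps-clipped Simpson. It exists for
   inspection and testing; the inference path never tabulates ψ.

Log arguments are floored at 1e-320; λ is clipped at 0 (θ = 0 is on the
grid, so the max can only exceed it by rounding).

## Simulator

A simulated cancer plasma sample mixes one normal-plasma and one tumor
profile drawn from held-out pools:

1. θ ~ Uniform(θ_L, θ_U);
2. per cluster a copy number c_k ~ Cat(p_0..p_5) with defaults
   (0.005, 0.16, 0.7, 0.105, 0.025, 0.005) — mean copy number exactly 2,
   aberration probability 30%; presets for other rates scale the
   non-diploid mass proportionally, preserving both moments;
3. locus burden θ'_k = θc_k / (θc_k + 2(1−θ)) and
   x_k = (1−θ'_k) v_k + θ'_k u_k;
4. coverage n_k ~ Poisson(Z·B_k), with B_k ∝ b_k (1−θ+θc_k/2)
   renormalized — amplified loci attract reads;
5. m_k ~ Binomial(n_k, x_k).

Normal plasma samples are simulated by mixing two distinct normal-pool
profiles at a Uniform(0,1) ratio with all copy numbers fixed at 2. The
alignment bias b_k is synthetic: proportional to the cluster's probed-site
count (optionally Dirichlet-perturbed), standing in for a bias profile
estimated from real read alignments. Clusters where a drawn profile is NA
are dropped from that sample and recorded; the bias is not renormalized
over the survivors, so expected total coverage is Z times the usable bias
mass. Every sample is driven by one seeded generator, so scenarios are
bit-reproducible.

**Coverage model.** Z is the total cytosine budget. In the study
configurations Z = depth × CpG content, with depth 4× (the regime of
public plasma WGBS) and content modeled as 3 CpG dinucleotides per probed
site: bisulfite reads report *every* CpG in a cluster's interval, and
arrays probe only a minority of the CpGs in the island/shore regions the
clusters occupy. With a mean of 6.5 probed sites per synthetic cluster
this yields ~78 cytosines per cluster. A budget of a few cytosines per
cluster would starve the likelihood of the information that a real 4×
genome provides and is not a faithful rendering of "4× coverage".

## Synthetic reference generator

The generator emulates TCGA-style training pools: T tumor classes plus
normal plasma over K clusters on a synthetic genome (3–10 probed sites
per cluster, built through the real clustering code). A fraction
`frac_informative` of clusters is informative: one uniformly chosen class
(possibly normal) has its mean offset from the shared baseline by an
offset drawn U(separation, 0.9) — the one-class-differs structure of
hyper-/hypomethylation markers, which guarantees true MR ≥ separation.
Uninformative clusters share a single mean. Beta precision α+β is drawn
U(20, 200) per (cluster, class), spanning tight tissue-specific and noisy
clusters. Pools are i.i.d. Beta draws per sample.

What this does *not* emulate: batch effects, probe artifacts, real
inter-cluster correlation, tumor purity variation, or subclonal
heterogeneity. Passing results therefore demonstrate correctness of the
method under its own model assumptions — the same role the mixing-based
simulation plays in the original study design — not clinical performance.

## Evaluation protocol

Per run: reference pools are split per class 75% / 25%; the panel
(selection + fits) is learned on the training side; test samples are
simulated from the held-out side across ten burden bins (θ, θ+10%],
θ = 0..90% (left-open/right-closed), each bin pairing cancer samples of
every tumor class with a non-cancer arm of normal-mixing samples.
Predictions from all runs are pooled into a single (T+1)×(T+1) confusion
matrix; the error rate is the fraction of incorrect six-class predictions.
Burden PCC/RMSE are computed over cancer samples (normals, whose true θ
is 0, are summarized separately as the fraction with θ̂ ≤ 0.02 and the
maximum θ̂). A uniform-guess stub predictor reproduces the balanced
six-class random floor of 5/6.

## Study conditions for the shipped reproduction

`scripts/acceptance.py` fixes: T = 5 tumor classes, K_total = 2000
clusters, 75% informative at separation 0.3, pools of 120 samples per
class (90 train / 30 test after the split), ~1500 selected features at
MR ≥ 0.25, 4× depth with the CpG-content model above, 30% CNA preset,
J = 100, λ threshold 0.023. Problem sizes: 500 cancer profiles for burden
recovery, 200 normals, 50 samples/class for each of the two lowest burden
bins, 20 samples/class/bin for the ten-bin pooled error. All randomness
derives from the single `--seed` argument.

## Known limitations

- The independence assumption across clusters is inherited from the
  model; correlated features would narrow the likelihood artificially.
- At most one tumor type per sample; no multi-tumor co-occurrence.
- Point estimates only; no posterior uncertainty on θ.
- The λ threshold is a fixed operating point, not a calibrated error rate.
- The engine rejects clusters with more than 1000 cytosines (float-range
  guard); aggregate or thin deeper data upstream.
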