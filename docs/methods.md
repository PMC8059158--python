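# Methods

This note documents the models, conventions and numerical choices
behind `convmorph`, in the order the pipeline applies them, together
with what the synthetic-data generator does and does not emulate.

## Procrustes superimposition

Configurations are centred, scaled to unit centroid size (CS = the
square root of summed squared landmark distances to the centroid), and
rotated to the iteratively re-estimated consensus by the least-squares
orthogonal rotation.  Reflections are excluded (the determinant of the
rotation is forced positive): biological shapes must not mirror.
Convergence is declared when the consensus changes by less than 1e-8
RMS per coordinate; the iteration cap is 100.  The summed squared
distance of specimens to the consensus is recorded per iteration and is
non-increasing (a regression test asserts this).

Semilandmark sliding is available behind a flag and **off by default**:
whether the original digitizing pipeline slid semilandmarks is not
stated in the protocols this package emulates, and sliding changes the
data, so the default is the conservative no-op.  When enabled, curve
semilandmarks slide along their index-neighbour chord and patch
semilandmarks in a locally estimated tangent plane, minimizing
thin-plate-spline bending energy (3D kernel U(r) = r) against the
consensus before each rotation round.  Curves are assumed
index-contiguous; data whose curve points are scattered through the
index space should not enable sliding.

Patch subsets (facial, neurocranial) are **re-superimposed
independently** by default: each patch is analysed as its own shape
space with its own ordination, matching how separate functional modules
are interrogated.  Subset centroid sizes are the sizes of the subset
landmarks in the original mm-scale configurations.  Species mean shapes
are coordinate-wise means of aligned specimens, without
re-superimposition of the means.

## Ordination

PCA is the ordinary eigendecomposition of the covariance of vectorized
Procrustes coordinates — unweighted, with the phylogeny only projected
in afterwards (internal nodes at maximum-likelihood ancestral scores).
Axis signs follow a deterministic convention (the largest-magnitude
loading of each axis is positive) so results reproduce across
platforms.  PC selection keeps axes explaining *strictly more* than the
threshold percentage (defaults: 1 % for multivariate analyses, 5 % for
the univariate screens).

## Brownian-motion machinery

The phylogenetic covariance matrix C holds shared root-to-MRCA path
lengths.  Ancestral states are the Brownian-motion maximum-likelihood
(equivalently GLS, equivalently branch-length-weighted squared-change)
reconstruction, computed by solving the weighted tree-Laplacian system;
because the solution is linear in the tip values, the solve is
precomputed once per tree as an operator matrix, which is what makes
thousand-replicate simulation nulls cheap.  Polytomies are handled
natively; zero-length branches are replaced by 1e-8 × tree depth with a
warning.

The evolutionary rate matrix is the GLS estimator
R = (X − 1â)ᵀC⁻¹(X − 1â)/(n − 1) with â the GLS root state.  On binary
trees this equals the average outer product of phylogenetically
independent contrasts (asserted against a hand-computed contrast); it
extends to polytomies without arbitrary resolution.  BM simulation
draws independent per-branch increments with covariance
(branch length) × R; per-simulation random streams are spawned
deterministically from the seed so any prefix of a simulation batch is
reproducible.

## Phylogenetic signal and PGLS

K_mult is the multivariate generalization of Blomberg's K: the ratio of
(summed squared distance of tips to the phylogenetically weighted mean)
to (the same after whitening by C^{-1/2}), scaled by its analytic
Brownian expectation (tr C − n/ΣC⁻¹)/(n − 1); it reduces exactly to the
univariate K (asserted against a literal transcription of the formula)
and is ≈ 1 under BM.  Significance permutes tip rows; all permutation
p-values in the package use the +1 correction, p = (count + 1)/(n + 1),
so p is never 0.

PGLS whitens both sides by C^{-1/2} and measures R², the pseudo-F, a
permutation p from residual randomization (RRPP: reduced-model
residuals permuted in the whitened space, n_perm = 1000 by default) and
the effect size Z = (F − mean F_null)/sd F_null.  With an identity
covariance the fit equals OLS to 1e-9.  Degrees of freedom follow the
usual (rank − 1, n − rank) bookkeeping; a focal unknown species can be
excluded from ecological fits via the `exclude` argument (the
covariance submatrix of the remaining tips is exact).

**Known limitation.**  Distance-based PGLS on raw Procrustes
coordinates is anti-conservative when the response contains
non-phylogenetic within-species error: whitening by C^{-1/2} amplifies
iid error on short branches, and the permutation null does not restore
exchangeability.  Under the generator's realistic specimen noise
(~1.4 % of between-species shape variance) the empirical type-I rate of
the prey-ratio model on full species-mean coordinates is far above
nominal, while responses that are exactly Brownian calibrate correctly.
Interpret small PGLS p-values on noisy patch datasets with this in
mind; the calibration tests therefore validate the estimator on exact
BM responses, and the ordination-filtered analyses (which discard the
noise-dominated minor axes) are the better-behaved route.

## Prey-size ecology and discrimination

The prey/predator mass ratio is mean prey mass divided by pack size
(social hunters) over predator body mass, log-transformed for analysis;
the small/large class boundary is ratio > 0.45, held in the single
constant `PREY_RATIO_CUT`.  Diet categories come from
percentage-biomass fractions: fine labels take the main (> 50 %) source,
hyphenated with a secondary source in [20 %, 50 %); coarse labels are
carnivorous (≥ 50 % vertebrates), insectivorous (≥ 50 % invertebrates),
otherwise generalist.

CVA is the two-group canonical variates analysis on selected PC scores
at the **specimen level**: the canonical axis is W⁻¹(m₁ − m₀) (the sole
discriminant direction for two groups), assignment is by Mahalanobis
distance to the group means with **equal priors** (group sizes are
study-design artifacts, not prevalences), and posteriors are normalized
Gaussian likelihoods under the pooled within-group covariance.
Validation is leave-one-out: the model is refit without each known
specimen in turn.  Unknown (focal) specimens are scored against the
full known fit.  The rank-sum screens use exact enumeration for
tie-free samples of ≤ 20 per group and the tie-corrected normal
approximation otherwise; both rank-sum and Spearman tests ignore
phylogeny by design and should be read as descriptive.

## Convergence tests

**Candidate selection.**  Average-linkage (UPGMA) clustering of
species-mean scores on the > 1 %-variance axes yields the candidate
set: the phenogram cluster containing the focal species at the cut with
the largest jump in log merge height along the focal cluster's merge
path (the classic dendrogram-gap heuristic, scale-free because merge
heights span orders of magnitude), with the constraint that a candidate
set is a *group* — at least two companions.  The alternative
penultimate-merge rule (the focal's side of the phenogram's final
split) and explicit height cuts are selectable.  The gap default was
adopted after the penultimate rule proved degenerate on simulated
morphospaces, returning ~90 % of all species whenever a lone outlier
merged last; a candidate set that large defeats the purpose of
phenotypic pre-selection and dilutes the FDR families downstream.

**Distance metrics.**  For a pair of tips, D_tip is the Euclidean
distance between their phenotypes and D_max the maximum distance over
all node pairs (u, v) with u on the MRCA→tip₁ path and v on the
MRCA→tip₂ path — tips and MRCA included.  C1 = 1 − D_tip/D_max ∈ [0,1];
C2 = D_max − D_tip; C3 and C4 scale C2 by the summed magnitudes of
phenotypic change along the two lineages and over the whole clade
descending from the MRCA.  Ancestral states default to the BM-ML
reconstruction, with an injection hook (`node_states`) so tests and
worked examples can supply exact states.  Significance simulates BM
datasets at the estimated rate matrix, re-reconstructs each, and counts
simulated metrics ≥ observed.  All pairs in an analysis share one
simulation batch — statistically identical to independent nulls and an
order of magnitude faster.

**Angle test.**  Each species' phenotypic vector runs from the
reconstructed MRCA phenotype to its tip; θ is the angle between the two
vectors (mean over pairs for larger state groups), and θ/time divides
by the patristic path between the species through the MRCA.  The null
reassigns the state labels uniformly over the tips and compares
**time-adjusted** angles, one-sided (small θ for the elapsed time =
convergence): under Brownian motion close relatives have small raw
angles by inheritance alone, so an unadjusted comparison would reward
phylogenetic proximity rather than convergence — the time adjustment is
the point of the method.  Both θ (degrees) and θ/time are reported.

A structural property worth knowing: the state-shuffle null can itself
draw pairs of genuinely convergent tips, so when k tips share a
convergent regime on an n-tip tree the attainable p is bounded below by
roughly C(k,2)/C(n,2) regardless of shuffle count.  With few species
and several convergent tips this floor can collide with step-up FDR
thresholds.

**Decision rule.**  Raw p-values are BH-adjusted within one family per
dataset × test (total/facial/neurocranial × C1/θ; alternative family
groupings are selectable), α = 0.10.  A candidate is *maximally
convergent* when significant under both tests in the total dataset and
under both tests in at least one patch dataset.  The rule is monotone:
lowering any p-value can only grow the maximal set.

## Synthetic studies

The generator emulates the sampling design of a mid-sized mammalian
cranial study: 57 species on a unit-depth pure-birth tree, 4 specimens
(two per sex) per species, 36 landmarks partitioned into facial /
neurocranial / other thirds of a stretched-ellipsoid template (a
synthetic stand-in — no anatomical realism is claimed).  Species means
evolve as 4 latent Brownian axes with geometrically decaying rates
(0.004 × 2⁻ᵏ, giving the leading-axis dominance seen in real cranial
ordinations; ~0.0075 total Procrustes variance).  A convergent regime
blends focal species' latents toward a shared drawn target,
x ← (1 − w)x + w·target; blending (rather than an OU pull) gives direct
control of realized tip distances, which is what both tests measure.
When no focal set is given, focal species are chosen to span distant
lineages (greedy max–min patristic distance): convergence between close
relatives is confounded by inheritance, and the emulated study design
compares across clades.

The latent-to-landmark map is a random orthonormal basis, so shape
analyses see exactly the simulated covariance; specimens add iid
coordinate noise (sd 0.002 shape units ≈ 1.4 % of between-species
variance, within the 1–5 % measurement-error range typical of 3D GM
datasets), a lognormal size factor exp(b·z₁) (b = 0.15) around a
100-mm base centroid size, and a random rotation + translation that GPA
must undo.  The log prey/predator ratio is a·z₁ standardized
(a = 1.0) plus N(0, 0.4) noise, centred at ln 0.45 so both prey-size
classes are populated; body masses are lognormal around 10 kg, two
random species get pack sizes 4–10 to exercise the per-capita division,
and coarse diet classes are drawn with guaranteed minority
(insectivorous/generalist) representation so factor models are
estimable.  Clade labels come from the three lineages present after the
tree's second split.

What passing tests on this generator do **not** show: robustness to
anatomically structured (non-isotropic) digitizing error, missing
landmarks, asymmetry, non-Brownian evolution (e.g. OU attraction or
rate shifts), or misspecified trees.  The generator's linearity is a
feature for calibration and a limit for realism.

## Problem sizes and determinism

Default inference counts follow the emulated study (1000 permutations /
simulations / shuffles).  The package's own Monte-Carlo test batteries
use 100–200 replicates with 100–300 simulations and 199–999 shuffles
per replicate — sizes chosen so the full suite runs in a few minutes
while keeping binomial noise on measured rates at the percent level.
Every stage draws its randomness from a seed spawned deterministically
from the single run seed (recorded in the run log), so a pipeline run
is a pure function of (inputs, config, seed) and re-runs are
bit-identical; any prefix of a simulation batch is reproducible because
per-simulation streams are spawned per index.
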