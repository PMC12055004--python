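# Methods

## The statistic

`coevotree` quantifies protein coevolution with the mirrortree approach:
two gene families whose evolutionary rates covary along a shared species
history produce similar interspecies distance matrices, and the Pearson
correlation of those matrices measures the association. Concretely, both
matrices are restricted to their common organisms, rows and columns are
sorted alphabetically so entries pair up organism-for-organism, and the
strict upper triangles are vectorized as paired observations (R_i, S_i),
i = 1..N(N−1)/2. Only the strict upper triangle enters the correlation:
the zero diagonal is uninformative and would mechanically inflate r, and
including the lower triangle would merely duplicate every pair without
changing r. N is the number of common organisms, not the number of pairs;
all downstream sampling theory uses N.

Correlations are compared through Fisher's transformation
r′ = ½ ln|(1+r)/(1−r)| (equal to atanh r on (−1, 1)), treated as normal
with variance 1/(N−3), giving z = (r′₁ − r′₂)/√(1/(N₁−3) + 1/(N₂−3)).
Both sign conventions in circulation are supported: the default returns z
exactly as written above; the `negated` convention flips it so that a
larger first correlation scores negative. P-values are standard-normal
tails, two-sided by default with a one-sided option; no multiple-testing
correction is applied across a control panel unless the Benjamini–Hochberg
flag is set, since the panel is used descriptively. Comparisons require
N ≥ 4 in both correlations; below that the Fisher variance is undefined
and the row is flagged rather than computed.

The mirrortree r of two families evolving on the same species tree is
substantially positive even with completely independent rate variation
(≈ 0.76 on average under this package's default synthetic conditions).
This baseline inflation is intrinsic — the species history is a common
cause of both distance matrices — and is the reason practice judges target
pairs against control-gene panels and an empirical cutoff of 0.8 rather
than against r = 0. The package ships the conventional control-panel
labels (housekeeping genes and lipid-metabolism enzymes) as constants and
reports, per control, r, r′, N, z versus the target, and p.

## Genetic distances

The distance between two aligned protein sequences is the maximum-
likelihood number of substitutions per site under the JTT empirical model
with uniform site rates: d maximizing Σ_sites log(π_a [exp(Qd)]_{ab}).
The generator Q is built from the published JTT exchangeabilities and
equilibrium frequencies and normalized to one expected substitution per
site per unit branch length, so all distances and branch lengths share
that unit. Implementation choices:

- **Gap handling** — pairwise deletion: a site is dropped for a pair if
  either member has a gap there. Ambiguous residues (B, Z, X, U, O, J and
  `*`/`.`) are treated as gaps. A pair with no comparable sites raises an
  error naming the pair.
- **Optimization** — bounded scalar maximization on [0, cap] with
  tolerance 1e-8. Transition matrices come from one eigendecomposition of
  the π-symmetrized generator (reversibility guarantees a real spectrum),
  so each likelihood evaluation costs a few 20×20 products. Pair counts
  are symmetrized before the likelihood; by detailed balance this leaves
  the maximizer unchanged while making d(a,b) = d(b,a) bit-exact.
- **Saturation** — distances are clamped at 10 substitutions/site
  (configurable) and flagged; beyond a few substitutions per site the
  likelihood is essentially flat and the point estimate uninformative.
  Identical sequences short-circuit to d = 0.
- **Bootstrap** — alignment columns are resampled with replacement, the
  same column draw for every pair, and each pairwise distance re-estimated;
  the standard error is the replicate standard deviation (ddof = 1, defined
  as 0 for a single replicate). The default 1000 replicates matches common
  practice. Bootstrap errors are reported alongside the distances but do
  not enter the mirrortree point estimate. Replicates that leave a pair
  with no comparable sites are skipped for that pair and counted.

## Trees

Patristic distance is the sum of branch lengths on the unique path between
two leaves; it is independent of rooting, so rooted and unrooted inputs are
handled identically. Newick support values on internal nodes are parsed
and ignored for distance computation; missing branch lengths raise an
error naming the branch. No cross-method normalization is applied to
patristic matrices by default (Pearson r is scale-invariant, so it would
not change the statistic); an optional min–max rescaling is provided for
plotting on a common scale.

Neighbor joining follows the classic Saitou–Nei agglomeration with the
standard Q-criterion. Ties in the criterion are broken by the first
(row-major) minimum, making the output deterministic. Negative inferred
branch lengths are clamped to zero and counted on the returned tree; on an
additive matrix no clamping occurs and the reconstruction reproduces the
input matrix to floating-point precision. Trees produced by likelihood,
Bayesian, or minimum-evolution software are consumed as Newick inputs —
tree search is out of scope, and minimum evolution is approximated in
practice by NJ on the same distances.

## The synthetic generator

Real mirrortree studies start from curated ortholog sets; this package
instead generates data with the exact statistical structure the method
assumes, with the coevolution strength as an explicit dial:

1. **Species tree** — a pure-birth (Yule) process: starting from the root
   split, each of k extant lineages splits after an Exp(k·λ) waiting time.
   After the final split an additional Exp(n·λ) interval elapses so every
   pendant branch has positive length (stopping exactly at the n-th birth
   would leave two zero-length tips and degenerate, duplicated sequences).
   Branch lengths are in expected substitutions per site; the default
   birth rate λ = 1 gives tree depths of order 1–4 substitutions/site for
   the 40–50-taxon trees used throughout, i.e. divergences typical of a
   eukaryote-wide ortholog set without being saturated.
2. **Gene-tree pair** — each branch b of the species tree (length L_b)
   receives, for gene g, length L_b · exp(ε_gb − σ²/2), where
   (ε_1b, ε_2b) are bivariate normal with standard deviation σ
   (`rate_sd`) and correlation ρ. The −σ²/2 term makes the multiplier
   mean-one, so expected branch lengths are preserved at any σ. ρ = 1
   with a shared draw makes the trees identical; ρ = 0 makes the rate
   noise independent. The default σ = 0.5 produces per-branch rate
   variation of roughly ±60 % (one lognormal sd), comparable to the
   across-lineage rate variation seen in protein families, and leaves a
   clear gap between the ρ = 0 baseline (mean r ≈ 0.76) and strong
   coupling (ρ = 0.9, mean r ≈ 0.97) without making either regime trivial.
   The drawn ε values are retained on the result for inspection.
3. **Sequences** — root states are drawn from the JTT equilibrium; each
   branch applies exp(QL) site-independently. No indels, no site-rate
   heterogeneity, no compositional drift: alignments are ungapped and
   exchangeable across sites by construction.

What passing synthetic tests therefore shows: the estimators recover the
quantities they target under the model's own assumptions, the ρ dial is
monotonically recovered by the mirrortree statistic, and the control-panel
logic separates coupled from uncoupled pairs at realistic noise levels.
What they do not show: robustness to alignment error, indels, paralogy,
lineage-specific composition, or rate heterogeneity — real data violate
all of these to some degree, and the 0.8 cutoff's calibration on real
ortholog sets is outside what synthetic data can establish.

## Determinism and problem sizes

Every stochastic stage takes an integer seed; a top-level seed fans out to
stage-specific child seeds via numpy's `SeedSequence`, and fixed seeds give
byte-identical FASTA/Newick/JSON outputs. The self-validation suite and
the acceptance script use: 50-taxon trees with 50 replicates per ρ for the
sweep; 100 runs of the one-target/eight-control panel experiment;
50,000-site pairwise alignments for the ML-consistency check (where the
estimator lands within 10 % of truth in ≥ 95 % of replicates); and 100
random 4–12-leaf trees for the NJ round trip. These sizes give
Monte-Carlo error comfortably below the effects being measured while
keeping a full run in the tens of seconds on one core.

## Known limitations

- The lognormal correlated-rate construction is one explicit stand-in for
  "shared evolutionary pressure"; its parameters are chosen for realism,
  not calibrated to any particular empirical dataset.
- Mirrortree variants that subtract the species-tree background
  (e.g. projection- or context-based corrections) are not implemented;
  the baseline inflation documented above is reported, not removed.
- The ML distance assumes the JTT model that also generated the synthetic
  data; model misspecification (e.g. WAG/LG-like data scored under JTT) is
  not assessed.
- Presence/absence profiling is a descriptive co-occurrence score
  (Jaccard plus a hypergeometric tail); it does not model phylogenetic
  non-independence of taxa.
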