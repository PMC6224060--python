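# Methods

## Model

Each subject enters as a symmetric 94×94 correlation matrix **F** over the
Harvard-Oxford cortical nodes (1–47 left, 48–94 right).  Negative entries
are set to zero before any processing: the pipeline deliberately analyses
non-negative connectivity only, and weighting of anticorrelations is out
of scope.

**First threshold.**  The distribution of a subject's non-negative
correlations is viewed on a 10-bin histogram over [0, 1]; resting-state
correlations pile up in the first two bins, so the neighbourhood of
interest is everything *strictly above* the upper edge of bin 2, i.e. a
fixed cut at 0.2.  Ties at exactly 0.2 are dropped.  The cut is exposed
(`first_cut`) for sensitivity analysis, but the quantile machinery behind
the histogram description collapses to this single number and is not a
free parameter.

**FD weights.**  With degrees computed on the thresholded matrix
**F**ˢ and the normalized centroid distance matrix **D** (entries in
[0, 1], η = 1 absorbed by normalization),

    w_ij = deg(i) · deg(j) · exp(−(D_ij − Fˢ_ij)),   W = w / max(w).

All off-diagonal pairs are weighted — the formula imposes no support
mask — so two high-degree nodes obtain a nonzero weight even where their
own correlation fell below the cut (`mask_zero_correlation=True`
restricts to the Fˢ support).  Normalization is per subject; a subject
whose thresholded matrix is empty (all degrees zero) contributes an
all-zero matrix downstream.  W is invariant to any constant factor on the
raw weights, strictly increasing in Fˢ_ij and strictly decreasing in
D_ij at fixed degrees.

**Grouping and second threshold.**  Subjects split by sex into fourteen
age bands (6–10, …, 76–79); each band's W matrices are averaged
elementwise.  The group matrix is then cut at λ = m/2, where m is the
centre of the bin formed by the top 10% of its nonzero entries.  The
phrase "bin formed by the highest 10% of entries" admits two readings,
both implemented:

- `top_decile_midpoint` (default): m = (q90 + max)/2 with nearest-rank
  q90 over the nonzero off-diagonal entries — the top decile treated as
  one bin whose centre is the midpoint of its range;
- `top_bin_of_10`: m = centre of the 10th bin of a 10-bin histogram over
  [min, max] of the nonzero entries.

The printed worked value (m = 0.3848 ⇒ λ = 0.1924) cannot arbitrate
between the readings without the raw data; both are logged per group.

**Emerging links and the representative graph.**  Links nonzero in at
least one of the 14 per-sex group matrices form the link table, with
per-group intensities and a frequency in 1..14.  The Centrality Index of
node v is its degree summed over the 14 thresholded group matrices,
normalized by the largest such sum (defined only for nodes with at least
one incident link).  The principal-vertex cutoff is the midpoint of bin 5
of a 10-bin histogram spanning the *observed* CI range — on the published
centrality tables (min 0.02, max 1.00) this yields 0.461, i.e. the
printed 0.46, where a unit-interval histogram would give 0.45; the cutoff
is rounded to two decimals before the comparison, matching the published
precision (on the published tables both rounded and unrounded cutoffs
select the same vertices).  V′ collects nodes with CI ≥ cutoff; E′ the
links inside V′; V″ the outside nodes attached to V′ by a link of
frequency ≥ 7 (half the 14 groups); E″ those attaching links plus any
link fully inside V″ at any nonzero frequency.  The representative graph
is G(V′ ∪ V″, E′ ∪ E″); components and planarity (networkx's linear-time
test) are reported.  On the packaged published tables this reproduces the
published vertex sets exactly, with the same 12-node union for both sexes
and two planar components per sex.

**Sex-difference testing.**  The statistical comparison runs on the union
L of the male and female link sets (Q = |L|), with the 14 bands merged
pairwise into 7 to raise sample sizes.  Per band, each subject
contributes the vector of its link values on L; the per-link statistic is
the classical two-group one-way ANOVA F, and the global statistic is its
sum over the Q links — a combination that remains usable when Q exceeds
the sample size, where parametric MANOVA does not exist.  p-values come
from permutation of the sex labels: all C(n, n_M) distinct reassignments
when that count is at most 20 000 (p = proportion of permuted statistics
≥ observed, identity included, hence never 0), else Monte-Carlo with
p = (1 + #{T ≥ T_obs}) / (1 + n_perm).  Permuted statistics are ranked
against the observed one with a 1e−9 relative tolerance so that
mathematically tied relabelings (e.g. the mirror partition) count as
ties despite floating-point rounding.  A link with zero pooled
within-group variance gets F = 0 when the group means agree and a +inf
sentinel when they differ; the sentinel ranks above every finite value.
The 7 global p-values, and within a flagged band the Q local p-values,
are adjusted by the step-down Holm procedure (implemented directly;
cross-checked against statsmodels in the tests).  Defaults: 9 999
permutations, α = 5%, a 10% "weak evidence" level for local links,
mandatory seed.

**Model comparison.**  W and the clipped correlation matrices are each
averaged over all 133 subjects (sexes pooled); links where the difference
M = W_rep − F_rep exceeds a threshold are reported with their atlas
names.  The default threshold is data-derived: the lower edge of the
first bin above the widest run of empty bins in a 10-bin histogram of the
positive entries of M (ties between equally wide runs take the lowest;
with no empty bin there is no clear separation and the top bin's lower
edge is used, with a warning).  The published fixed value 0.1116 is
available via `threshold_mode="fixed"`.  Negative entries are never
selected but are counted in the report.

## Subject link values: weights versus correlations

By default the test statistics consume the per-subject FD weights at the
links of L (`link_values="fd_weight"`), mirroring the reference analysis.
A documented alternative uses the first-threshold correlations
(`link_values="correlation"`).  The distinction matters at the very top
of the weight distribution: because each subject's W is normalized by its
own maximum, the strongest link of a homogeneous community sits at or
near W = 1 for every subject, so subject-level differences there are
censored at the ceiling, and a genuine increase on that link instead
surfaces as a *decrease* on all other links through the shared
normalizer.  The parameter-recovery experiment below therefore evaluates
selection on the correlation values; the ceiling behaviour of the weight
route is a known limitation of max-normalized weights, not of the test.

## Synthetic cohorts

Subjects are simulated as latent-factor Gaussian time series of length
160 samples (matching the acquisition length of the emulated study):
every node loads √ρ_out on a cohort-wide factor, nodes of a community
additionally load on a community factor so that within-community
correlation is ρ_in, and the empirical correlation matrix of the finite
series is returned — hence symmetric, unit-diagonal and positive
semidefinite by construction, with realistic sampling noise
(sd ≈ (1−ρ²)/√160).  Defaults: the single community is the 12-node
medial/posterior block {1, 22, 28, 29, 30, 31, 48, 69, 75, 76, 77, 78}
(the union V′ ∪ V″ of the published representative graph, so
graph-recovery tests have known ground truth), ρ_in = 0.6, ρ_out = 0.05,
and the published cohort composition (51 M / 82 F across the 14 bands,
ages uniform within band).  ρ_out = 0.05 keeps the background correlation
mass in the first two histogram bins and the thresholded support outside
the community sparse, as described for the real data; at ρ_out = 0.1
roughly a tenth of background sample correlations cross the 0.2 cut and
the emerging-link set balloons to ≈1 100 links, an order of magnitude
beyond the published scale.

Injected sex effects replace a fraction of each endpoint node's
idiosyncratic noise with a component shared by the two endpoints, raising
that link's expected correlation by exactly δ while leaving node
variances and *all other* correlations untouched (an additive latent with
renormalization would attenuate the endpoints' other within-community
correlations).  δ must stay below the endpoints' residual noise budget
(δ < 1 − ρ_in within the community, i.e. < 0.4 at the defaults).

Centroids are synthetic: left-hemisphere coordinates drawn once in
plausible MNI-like millimetre ranges, right nodes the x-mirror of their
homologues.  What the generator does *not* model: haemodynamics, motion
and physiological noise, age trends in connectivity, inter-subject
variability beyond sampling noise, and heterogeneous within-community
strength.  Passing tests therefore show the pipeline's selection and
error-control properties under clean block structure, not performance on
real scans.

## Operating characteristics (computed by the tests / acceptance script)

- *Familywise error*: 500 simulated null cohorts, full pipeline, 7-band
  global analysis with 200 permutations and Holm at 5%.  The flag rate is
  checked against 5% with a 2-point Monte-Carlo margin.  The rate sits
  near the nominal level rather than well below it because the link set L
  is selected from the same data that is subsequently tested — the same
  reuse present in the emulated procedure.
- *Recovery*: δ ∈ {0, 0.1, 0.2, 0.3} on link 31–78 for females of the
  oldest band (7 M vs 12 F), 100 cohorts per δ, local analysis with 4 999
  permutations on correlation values (4 999 ≈ the granularity needed for
  Holm over ≈100 links at 5%): power must rise monotonically, exceed 0.8
  at δ = 0.3, and stay at or below 5% at δ = 0.

Problem sizes (500/100 cohorts, 200/4 999 permutations) are the package's
chosen simulation scales; the permutation machinery is vectorized over
permutations and links, so a full cohort pipeline plus testing runs in
~0.2 s.

## Known limitations

- The ceiling effect of per-subject weight normalization (above).
- The second-threshold bin rule and the comparison histogram-gap rule are
  reconstructions of verbal descriptions; both alternatives are exposed
  as modes and every run logs the realized m, λ and thresholds.
- Emerging-link selection and subsequent testing share the data; the
  global test's familywise error is controlled only approximately under
  that reuse (empirically ≈5% at the defaults).
- The published per-group intensity and p-value tables cannot be
  recomputed without the original scans; they are packaged as fixtures
  for validating the selection rules and the expected report layout.
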