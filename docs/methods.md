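# Methods

`costim` analyses double time-course phosphoproteomic experiments in which
budding yeast is co-stimulated with NaCl (hyper-osmotic shock, HOG MAPK
pathway) and alpha-factor pheromone (mating MAPK pathway). The experimental
unit is a 6x6 stimulation matrix: each axis holds stimulation periods of
0, 1, 5, 10, 20 and 45 minutes (0 = stimulus never applied; harvest at
addition), every combination is measured in three biological replicates,
and each (condition, replicate) is one label-free MS run. The six time
points are configurable; the default emphasises early times because both
MAPK cascades transit their activation within the first 10-20 minutes.

## Preprocessing

Intensities are normalized by each run's total ion current (TIC):
`I' = I / TIC(run) x mean(TIC)`, which corrects sample-amount and LC-MS
drift without touching within-run ratios. MS1 features of the same peptide
species — identical backbone sequence and phosphate count, different
charge, retention time or site call — are merged by summation; divergent
site calls are flagged ambiguous. Peptides must be detected (any replicate)
at >= 4 of the 6 NaCl time points **and** >= 4 of the 6 pheromone time
points; a time point counts as covered if any condition sharing that
coordinate has a detection. The literal filter sentence is ambiguous
between a conjunctive and a per-experiment reading; the conjunctive
matrix-coordinate reading is implemented because it matches the design's
row/column structure. Replicates are then averaged (s.d. with ddof 1;
recorded as 0 for singletons so coefficients of variation stay computable),
and remaining gaps are filled by natural cubic splines along the NaCl axis
at fixed pheromone duration, falling back to the pheromone axis when fewer
than three points are observed; cells imputable on neither axis stay
missing and are flagged. Imputation runs after averaging (the alternative
order is configurable). Negative spline output is clipped to 0; observed
cells are never altered.

Mock-handling control: two surfaces are "negligibly different" for a
peptide iff every compared cell's larger/smaller ratio is strictly below
1.5 (pseudocount: 1% of the global median intensity).

## Shape and Intensity Effects

For each peptide the imputed surface is read as six NaCl-axis curves (one
per pheromone duration) and six pheromone-axis curves. To judge how
stimulus S2 modulates the response to S1, all S1-axis curves of the panel
are clustered jointly by Euclidean K-means — K = 6 for NaCl-axis curves,
K = 8 for pheromone-axis curves, best of 50 seeded restarts. Curves are
divided by their own mean first so clustering sees shape, not level, and
the whole classification is invariant to global rescaling (the source
analysis does not state whether curves were rescaled; raw mode is
available). If a peptide's six curves occupy >= 3 distinct clusters
(numerically identical curves counted once), the call is a **Shape
Effect**. Otherwise the six per-curve mean levels v_j (one per S2 duration)
are scored as (max v - min v) / mean v; a score >= 0.7 is an **Intensity
Effect**, else **No Effect**. The per-curve reading of the score follows
the definition of the Intensity Effect as level modulation by S2; the
alternative literal reading (pointwise average across curves, range along
the S1 axis) is implemented as `score_mode="axis_range"`. Full 36-value
profiles are grouped by complete-linkage hierarchical clustering under the
Minkowski distance (defaults p = 2, seven clusters).

## Specificity ratios

The specificity of a peptide for S1 under modulation by S2 is
`S(i,j) = (I(t1_i, 0) + eps) / (I(t1_i, t2_j) + eps)` with eps defaulting
to 1% of the global median: < 1 means S2 amplifies the S1 response, > 1
means it inhibits it, and column j = 0 is identically 1. Basal
normalization would cancel in the ratio and is omitted. Column means give
a 6-entry specificity vector per (peptide, stimulus). The screen for
peptides tracking a query (e.g. doubly phosphorylated Hog1) correlates
log specificity vectors over the first window of S2 durations (default 4,
i.e. 0-10 min) — the log makes amplification and inhibition symmetric —
and keeps candidates with r >= r_min (similar) or r <= -r_min (opposite),
ranked by |r|. The screen ranks candidates; it makes no causal claim.

## Peptide selection and network construction

For modeling only the 16 single-time-origin conditions are used: first
row (NaCl only), first column (pheromone only) and diagonal (simultaneous
co-stimulation) of the matrix. Peptides are kept when (a) the median over
multi-replicate conditions of the replicate CV is strictly below 0.25 and
(b) strictly fewer than 25% of the training-condition data points are
missing. Redundant same-protein trajectories are merged by affinity
propagation on max-normalized trajectory vectors (similarity = negative
squared Euclidean distance); near-identical trajectories are pre-merged
before message passing because two-sample affinity propagation is
degenerate. Defaults are damping 0.5 and preference = 0.02 x median
similarity: the conventional median preference empirically merges clearly
distinct temporal shapes, which would defeat the purpose of the merge
step (the median rule remains selectable). A cluster is represented by its
member with previously known function when one exists (ties broken
lexicographically), else by the exemplar.

The shipped protein-level prior network and the 33-peptide modeling list
are **synthetic stand-ins**, transcribed from the canonical HOG/pheromone
pathway literature (the original network and peptide tables exist only as
figures/supplements that are not machine-readable). They are jointly
constrained so that substituting the peptides into the prior reproduces
the published model sizes: every protein with surviving peptides is
replaced by its peptide nodes and every prior edge A->B expands to all
(a_i, b_j) pairs with the prior sign, giving 45 nodes (33 measured
peptides + 12 undetected proteins) and 93 interactions. Mechanistic
variants: restricting crosstalk mediation to Ste20_T511 removes the other
six Ste20 peptide nodes with their incident edges; the double-negative
Gpd1-Hog1 feedback adds mutual inhibitory edges between ppGpd1 and both
Hog1 phospho-forms (four edges, consistent with the combinatorial
expansion rule); together: 39 nodes, 73 interactions. Unmeasured nodes
left unreachable from any stimulus are pruned. The default ensemble —
4 mechanism combinations, 4 No-Effect interaction-group removals, 15
documented single-edge removals — deduplicates to 23 models; the identity
of the 15 single-removal edges is a documented configuration choice, since
the source leaves it ambiguous (it also reports testing four interaction
removals "in all possible combinations" as four models, which is
internally inconsistent; the scheme reproduces the stated counts).

## Logic ODEs, fitting, and model comparison

Data for modeling are normalized to [0,1] by a Hill transform
`x -> x^n/(x^n + k^n)` with n = 4 and k the per-peptide median (the
midpoint of the empirical CDF), which tames very large intensities. Each
non-stimulus node follows `dx/dt = tau_x (Phi_x(inputs) - x)` where an
activating edge contributes the normalized Hill transfer
`f(u) = u^n (1+k^n)/(u^n + k^n)` (so f(0)=0, f(1)=1 — the unit range is
required for clamped stimuli at 1 to fully activate targets), inhibition
contributes 1 - f(u), AND gates multiply transfers, and multiple inputs
combine as OR = 1 - prod(1 - term). Stimuli are step clamps at t = 0 —
valid exactly for the 16 training conditions, which is why they are the
training set; the simulator also supports staggered onsets for off-diagonal
conditions. Initial states are measured basal values where available, else
0. Integration uses LSODA with rtol 1e-6 / atol 1e-8; outputs are reported
clipped to [0,1]. Parameters: tau in [0.01, 2] 1/min (activation
time-scales from sub-minute to near-static on a 45-min horizon), Hill n in
[1, 10], k in (0, 1).

Fitting minimizes the MSE over observed training points of a node subset
common to all compared models. Each restart runs seeded differential
evolution followed by bounded least-squares refinement on the residual
vector; the derivative-based local step replaces a derivative-free one
because with tens to hundreds of parameters it converges within a few
hundred evaluations where simplex methods cannot. The budget is counted in
objective evaluations per restart, restart starts come from a single
seed-derived stream (so adding restarts never worsens the best fit), and
every `FitResult` records seed, evaluations used, per-restart bests, and
the AIC formula applied. The AIC is `n ln(MSE) + 2k` by default (the
source's exact equation is not machine-readable; the formula is
configurable and recorded). Models are ranked by ascending AIC on the
common node subset.

## Synthetic data: what it emulates, and what it does not

The generator plants closed-form archetypes: a transient spike
`A (t/p) e^{1-t/p}` (default peak p = 5 min, the fast Hog1-like response),
a logistic rise with half-time ~10 min and slow linear decay after 20 min
(the slower Fus3-like response), a sustained rise, and flat
non-responders; a basal floor of 10% of amplitude keeps intensities
strictly positive. Crosstalk modifiers driven by the other stimulus'
duration: a transient dip at one duration (factor 0.3 — strong transient
down-regulation of the kind seen for activated Hog1 under 1-min pheromone
stimulation; planted as an Intensity Effect), a monotone scaling up to
2.5x (Intensity), and a phase shift growing to ~15 min (Shape, on both
axes, since timing changes propagate to both curve families). Measurement
noise is multiplicative log-normal with CV 5% by default, per-run scale
factors are log-normal (sigma 0.05), missingness is MCAR (an
intensity-dependent logistic dropout is available for robustness checks),
and the recorded TIC includes a constant bulk-proteome background (100x
the mean panel signal) scaled by the run factor — without it a small
panel's TIC would co-vary with the planted signal and TIC normalization
would distort flat peptides into apparent responders, an artifact no
full-proteome run exhibits. The `modeling_panel` generator mirrors the
modeling-set membership: the 33 retained peptides carry mutually distinct
per-protein trajectory recipes, plus four high-variability peptides, four
peptides missing 6 of 16 training conditions, and two redundant
trajectories duplicating known-function peptides, so the filter cascade
must reproduce the 33-peptide set.

Passing tests on these panels show the *rules* are implemented correctly
and are recoverable under the stated noise; they do not show that real
spectra produce such clean archetypes, that real missingness is MCAR, or
that the transcribed prior network equals the original one. Real-data fit
quality metrics are therefore out of scope.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale problems: a 60-peptide
panel x 10 noise seeds for classifier recovery; a 43-peptide panel for the
filter cascade; exhaustive 32-vector Boolean-limit checks on a 5-input
acyclic toy (steep transfers n = 10, k = 0.5, steady state by integration
to t = 150 with tau = 2); and parameter recovery on a 6-node network
(2 stimuli + 4 measured nodes, 5 edges, 14 free parameters) fit with 10
restarts of 3000 evaluations each, chosen as the smallest configuration
on which identifiability of every tau is unambiguous. K-means ties are
broken by collapsing numerically identical curves; zero-variance
specificity vectors are skipped in the screen with a warning; a zero MSE
yields AIC = -infinity with a warning.

## Known limitations

* The prior network, modeling-peptide list, and the 15-edge removal list
  are literature-guided reconstructions, not the original supplementary
  tables; counts match the published model sizes by construction, edge
  identities may differ.
* Off-diagonal (staggered) co-stimulation conditions are simulated but not
  fitted, mirroring the original training choice.
* The classifier's cluster-count rule depends on panel composition (labels
  are assigned relative to the co-clustered panel), so single-peptide
  classification is not meaningful.
* No FDR estimation, spectra processing, or SBML-qual export.
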