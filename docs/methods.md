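# Methods

This note documents the statistical and algorithmic choices behind
peakmine: what each component computes, which conventions were fixed
where several are in common use, and what the synthetic fixtures do and
do not emulate.

## Input model

The unit of analysis is a *peak table*: a dense molecules x samples
matrix of non-negative concentrations in arbitrary abundance units,
assumed aligned and normalized upstream.  Exactly `0` encodes "not
detected"; this single sentinel drives both the detection-frequency
filter and the fold-change edge cases.  Missing or empty cells in a
concentration column are rejected rather than imputed — silent imputation
would corrupt detection-frequency semantics.

Sample metadata lives in a two-section CSV: `key,value` experiment
descriptors (id, description, platform, MS mode, `time_unit`), then a
sample block introduced by a header whose first cell is `sample_id`, one
row per sample with its feature values.  `time` is numeric in the
declared unit.  Analysis groups are the observed combinations of any
chosen feature subset (label = underscore-joined values), which always
partition the sample set.

Column auto-selection in a peak table takes every column whose cells all
parse as finite numbers — with one domain-driven exception: headers that
conventionally carry per-molecule MS metadata (`m/z`, `mz`, `mass`,
`rt`, `retention time`, case-insensitive) are always treated as
annotations, because m/z values are fully numeric yet are not expression
data.  Passing `value_columns` explicitly overrides the heuristic.
Delimiter sniffing counts tabs vs commas in the header line (ties go to
comma); matching of metadata to columns is by exact, case-sensitive
header string.  Written tables serialize floats via `repr` (17
significant digits), so write→read is the identity on float64 data.

## Detection-frequency filter

Detection frequency of a molecule in a sample set = (#samples with value
> 0) / (#samples).  The filter has two levels applied in a fixed order:

1. *cross-board*: keep a molecule iff max over groups of its frequency
   is ≥ the threshold (so a dropped molecule is never partially zeroed);
2. *group-based*: in each retained molecule, zero all values of every
   group whose frequency is < the threshold.

Comparisons are `>=` at both levels; threshold 0 makes the filter the
identity.  The operation is idempotent and monotone in the threshold
(raising it never enlarges the retained set), and it always returns a
new table.  Group-based zeroing happens strictly upstream of all other
analyses: zeros it introduces *are* visible to correlation, fold change
and clustering.

## Correlation and significance

Three methods, all authored against their defining formulas:

* Pearson: sample covariance / (sd·sd);
* Spearman: Pearson applied to mid-ranks (average ranks over ties);
* Kendall tau-b: (C − D)/√((n₀ − T_x)(n₀ − T_y)), n₀ = n(n−1)/2,
  T = Σ t(t−1)/2 over tied groups.

Two-tailed p-values: t = r·√((n−2)/(1−r²)) on n−2 df for Pearson and
Spearman (|r| = 1 maps to p = 0); for Kendall the normal approximation of
S = C − D with the tie-corrected variance (Kendall 1947), used at every
n — small-sample exactness is delegated to the brute-force enumeration
oracle in the test suite, never to the implementation.  The one-tailed
probability is defined as exactly half the two-tailed one.  No
multiple-testing correction is applied by default; a Benjamini–Hochberg
helper exists for callers who want adjusted p-values.

A pair involving a constant vector (e.g. a molecule fully zeroed by the
filter) is *undefined*: flagged explicitly, excluded from visibility and
histograms, never coerced to 0 or NaN arithmetic.  Zeros from
non-detection are included in the computation — there is no pairwise
deletion — so the filter's zeroing decisions deliberately propagate into
the network.

The network object stores all C(m,2) results permanently; the
correlation-range filter (closed `[low, high]` inside mode, or the
complement of the open interval in outside mode, e.g. |r| ≥ c) only
controls which pairs count as edges.  Degree statistics and average
neighbors (2|E|/|V|) are over visible edges; the correlation histogram
(0.1-wide bins over [−1, 1]) covers all defined pairs regardless of
visibility; neighborhood connectivity maps degree k to the mean over
degree-k nodes of their neighbors' mean degree.

## Layouts

All layouts are pure functions of (graph, parameters, seed).

* *Single circle*: node k of n at angle 2πk/n, input order preserved.
* *Multiple circle*: up/down/neutral regulation sets (FC = arithmetic
  mean(test)/mean(control); up iff FC ≥ T, down iff FC ≤ 1/T, default
  T = 2; control mean 0 with test signal → FC = +∞, counted up; both
  means 0 → neutral) on three horizontally adjacent circles with radius
  ∝ √(set size).  Thresholding happens on the raw ratio; a log2 display
  is a presentation choice left to callers.  Adjacent rather than
  concentric circles is a convention.  Border colors: up = green,
  down = red, neutral = none.
* *Kamada–Kawai*: spring energy E = Σ k_ij(‖p_i − p_j‖ − l_ij)²/2 with
  ideal length l_ij equal to the graph distance and k_ij = 1/d_ij².  One
  node per iteration (the one with the largest gradient) takes a 2×2
  Newton step, halved until the energy does not increase, so the
  recorded per-component energy trace is monotone non-increasing by
  construction.  Start is a deterministic circle with a small seeded
  jitter to break symmetry.  Connected components are solved separately
  and packed on a grid.
* *Fruchterman–Reingold*: classic forces (attractive d²/k on edges,
  repulsive k²/d between all pairs, k = √(area/n)) with displacement
  capped by a linearly cooling temperature; seeded uniform start.
* *Random*: uniform in the unit square per seed.
* *Heatmap*: the m×m matrix of correlations in input order (no
  seriation); filtered-out pairs, undefined pairs and the diagonal carry
  NaN as the neutral background value.

Edge color semantics everywhere: signed r on a symmetric diverging scale,
+1 → red, −1 → blue, 0 → neutral midpoint.

## Distribution analysis

Boxplot statistics use linear interpolation of order statistics for the
quartiles — conventions differ and this one affects which points are
called outliers, so it is fixed and stated.  Fences sit at Q1 − c·IQR and
Q3 + c·IQR with Tukey's c = 1.5 by default (configurable); outliers lie
strictly outside the fences, whiskers at the most extreme in-fence
values.

Two trend-fit options, both straight lines in time (the curve family is
configurable in principle but degree 1 is the default and the only one
exercised):

* *Robust linear*: iteratively reweighted least squares with Huber
  weights, cutoff c = 1.345 × robust scale, scale = MAD/0.6745
  re-estimated each iteration; converged when the coefficients move less
  than the tolerance.  When no residual exceeds the cutoff all weights
  are 1 and the result is exactly ordinary least squares.  A Tukey
  bisquare weight function is available behind a flag.
* *Chi-square*: closed-form weighted normal equations minimizing
  Σ((y − a − bt)/σ)².  When σ is not supplied, each point inherits the
  standard deviation of the replicates at its time point; singleton and
  zero-spread time points fall back to σ = 1 (a zero σ would otherwise
  be a hard error the user never caused).

The distribution panel produces per-group {time → boxplot stats}, the
chosen fit, and the per-sample scatter, over a shared time axis when a
group pair is compared side by side; sample/time-point deselection simply
restricts the inputs.

## Trajectory clustering

Profiles are rows of the peak table, z-scored by default so shape rather
than magnitude drives similarity (constant rows map to zeros and are
flagged); distances are Euclidean.  Cluster indices are contiguous from
1 and every algorithm emits a total partition.

* *k-means*: Lloyd with k-means++ seeding; empty clusters are repaired
  by reseeding from the worst-fitting point; 10 independent starts are
  run and the lowest within-cluster sum of squares kept, because single
  Lloyd runs converge to local optima.  The winning run's per-iteration
  inertia trace is exposed and is non-increasing.
* *k-medoids*: PAM — greedy BUILD from the 1-medoid optimum, then
  best-improvement SWAP passes; medoids are always data rows; ties break
  to the lowest index, making the result deterministic outright.
* *Farthest-first*: Hochbaum–Shmoys traversal; the seed (or an explicit
  `first_center`) picks the first center, each next center is the point
  farthest from the chosen set; assignment to nearest center.
* *SOM*: rectangular grid of prototypes initialized by sampling data
  rows; online training for 100·m presentations with a Gaussian
  neighborhood.  The radius decays geometrically from max(grid)/2 to
  0.5 and the learning rate from 0.5 to 0.01.  Ending the radius below
  one unit makes late training effectively BMU-only (the classic
  ordering-then-convergence schedule); ending at a full unit was
  observed to keep adjacent units coupled strongly enough to merge
  well-separated clusters onto one unit.  Clusters are the *occupied*
  units after training, so the effective cluster count is data-driven
  and bounded by the grid size; no secondary unit-merging is applied.

Cluster trajectories aggregate raw (not standardized) concentrations per
sample — average by default; mode (most frequent value, ties to the
smallest), maximum and minimum are selectable — with samples ordered by
time point first, then alphabetically by id.

## Synthetic fixtures

The generator emulates a two-cohort murine time-course design: control
group `D` (samples `C…`) with 5, 5, 3 animals and test group `DE`
(samples `T…`) with 5, 7, 5 animals at weeks 0, 2, 4 — 30 samples.
Concentrations are log-normal around per-molecule base abundances drawn
log-uniformly over three decades (positive, right-skewed, like
high-resolution MS peak intensities), with multiplicative noise of
σ = 0.25 in log space by default.

Planted structure, allocated to disjoint molecule ranges and recorded in
a ground-truth sidecar:

* *Correlation blocks* share a latent per-sample factor with loading
  √r in log space.  Block members carry their entire log-variance
  through this structure (they skip the independent noise term), so the
  latent correlation equals the target exactly and the small log
  amplitude (max(0.25, σ)) keeps the exponential map from distorting it;
  realized raw-scale correlations land within about ±0.1 of the target
  at n = 30.
* *Regulated sets* scale the test cohort's pre-noise values by the exact
  fold change; with σ = 0 the realized FC is exact.
* *Trajectory archetypes* are families sharing a per-sample log-profile;
  the within-family spread is set so that (minimum center separation) /
  (within-family spread) equals the requested ratio *after* noise —
  archetype members also fold their noise budget into this term — with
  6 as the default separation.
* *Dropout* zeroes cells of a group with the given probability, after
  noise, matching the 0 sentinel.

Everything is deterministic per seed down to the bytes of the written
files (`Normalization.csv`, `project_info.csv`, `ground_truth.tsv`; the
sidecar is never an analysis input).

What the fixtures do **not** emulate: correlated noise across molecules
outside planted blocks, missingness that depends on abundance (real
non-detection is intensity-censored, not uniformly random), isotope
structure or realistic m/z spacing, batch effects, and drift within a
time point.  Passing tests therefore demonstrate algorithmic
correctness on data whose generative assumptions are known, not
robustness to every artifact of real acquisitions.

## Numerical conventions

* Floats serialize via `repr` everywhere reproducibility is promised;
  figures suppress embedded timestamps.
* Correlations are clipped to [−1, 1] after computation to absorb
  floating-point overshoot.
* Undefined states (constant vectors, 0/0 fold change) are explicit
  flags or sentinels (`undefined`, NaN, +∞), never silent numerics.
* Seeds feed `numpy.random.default_rng`; every stochastic routine takes
  one and repeated runs are bit-identical.
* Test and acceptance problem sizes (200 molecules / 30 samples for
  clustering recovery, 200 vector pairs for the correlation oracles,
  200 simulations for fit recovery) were chosen to keep the full suite
  in the tens of seconds while leaving the measured properties far from
  their pass boundaries.
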