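# Methods

## Canonicalization by inscribed circles

A worm imaged under a coverslip lies essentially flat, so straightening is
modeled as a 2D map acting on x/y with z passed through — the body hull is a
single binary raster (the largest-area z-slice), and the vertical dimension
is left unchanged until the final rescale.

The hull boundary is traced at sub-pixel precision (marching squares at the
0.5 level), smoothed with a periodic cubic spline whose smoothing budget is
proportional to pixel size (≈ a third of a pixel of residual per vertex —
enough to remove stair-step artifacts without rounding genuine shape), and
split at the two body tips into edge curves r₋(s), r₊(s′), each an
interpolating cubic spline parameterized by normalized arc length.  Tips are
found as the boundary pair at maximal Euclidean separation (computed on the
convex hull), each snapped to the nearest local curvature maximum; shapes
whose diameter is below 1.3× that of the equal-area disk are rejected as
having no stable tips.  The edge labeled r₋ is the arc for which the normal
(−ẏ, ẋ) points into the body.

For each s, the inscribed radius t(s) solves min_{s′} d(s, s′, t) = 0 with
d(s, s′, t) = |r₋(s) + n̂₋(s)t − r₊(s′)| − t.  Because every individual
term is non-increasing in t, so is the minimum, and the root is found by
bisection (expanding the bracket by doubling from the locally-parallel guess
t = d(s, 0)/2; tolerance 10⁻³ μm).  The inner minimum over s′ uses 1024
cached samples of r₊ followed by bounded local refinement.  Values of s
where no circle fits (the tapered tips) are skipped.

Solver noise in the circle centres would otherwise inflate the midline: a
polyline through noisy centres is strictly longer than the true midline.
The centre polyline is therefore regularized with a lightly smoothing spline
(≈0.15 μm residual per centre) before the chain is resampled to `n_circles`
circles equally spaced in cumulative midline arc length (default 1000; the
tests use 150–300, which changes results by well under the positional noise
of real data).

Each circle k defines a rigid map: rotate the local midline tangent (central
difference of centres) onto +x and translate the centre to (Lₖ, 0), Lₖ its
cumulative arc length — so distances between adjacent circle centres are
preserved exactly.  A neuron is mapped by every circle whose disc contains
its xy-projection and the images are averaged; neurons inside no disc
(beyond the terminal circles or just outside the hull) use the nearest
centre.  Finally all coordinates are isotropically rescaled so the neuron
x-range spans [0, 800] μm.  Orientation is fixed deterministically (chain
starts at the tip with the smaller x, then y); `flip_ap` reverses it.

A basic skeleton-based straightener (x = arc length along the morphological
skeleton, y = signed perpendicular offset) is included only as a comparison
baseline; it is known to distort the dense head and tail.

## Atlas construction

Per neuron name, the atlas position is the componentwise **median** over
contributing worms and the spread the per-axis median absolute deviation.
The median is used for robustness to outliers and because it does not shrink
the cloud the way a mean of misaligned points does.  MAD was chosen as the
variability statistic (any robust spread would serve; it pairs naturally
with the median).  Neurons present in only some worms are kept, with the
contributing count recorded; a minimum-count filter is exposed (default 1).
The CAN pair is excluded at the data level — panneuronal imaging strains do
not label it — so the shipped name list has 300 of 302 entries; exclusion is
the data generator's job, not the algorithm's.

Sub-atlas merging fits a closed-form least-squares rigid transform (SVD
Kabsch with reflection guard; no scale, since both atlases are already in
the canonical frame) on the neurons shared within the requested region,
replaces region entries by transformed sub-atlas positions, and leaves all
other entries bitwise untouched.  Degenerate (collinear) shared sets are
rejected.

## Generalized-mean alignment

The loss for moving positions x_j against labeled positions r_i with colors
c is

    ℓ = Σ_j ( Σ_i δ(c_i, c_j) |r_i − x_j|^γ / Σ_i δ(c_i, c_j) )^(1/γ),

γ < 0 (default −6).  Colorless clouds are treated as one color class.
Summing over the moving cloud only is what makes the loss robust to set-size
imbalance: moving neurons seek partners, surplus reference neurons exert no
penalty.  Distances are floored at ε (default 10⁻³ μm) because |r|^γ
diverges at contact; floored pairs contribute no gradient.  Note the
normalized power mean of n distances approaches the minimum only as
γ → −∞, overshooting it by up to n^(−1/γ) at finite γ (≈34% for n = 300 at
γ = −6) — the floor-dominated loss value at a perfect fit is therefore
n₂·ε·n₁^(1/γ⁻¹)-ish, not n₂·ε exactly.

Evaluation factors out each row's minimum distance so that (d/μ)^γ stays in
[0, 1]; this keeps γ as extreme as −400 finite in float64.  The analytic
gradient in the moving positions is
Σ_i w_ij (x_j − r_i)/d_ij with w_ij = g_j^(1−γ) d_ij^(γ−1)/m_j, computed in
the same normalized form and verified against central differences in the
tests.

Two descent parameterizations:

* **GM** — every moving position is free (3n₂ parameters).
* **GM Realistic** — positions are x_j = r_j + f(r_j) with the
  Gaussian-mixture field f(r) = Σₙ dₙ exp(−|r − (rₙ + s)|²/2σ²): 6N+1
  field parameters (displacements dₙ, centres rₙ, shared width σ) plus the
  redundant global centre shift s retained for conditioning.  σ and the
  centres are optimized along with the displacements; σ descends in
  log-space so it stays positive.  An optional quadratic penalty on ‖dₙ‖²
  (`ridge`, default 0) is available but off, since the smoothness of the
  field already regularizes the fit.

Initialization: zero displacements, centres on a uniform grid over the
moving cloud's bounding box (grid shape proportioned to the box, nodes
farthest from data dropped to hit N, default N = 64), σ = ¼ of the box
diagonal, zero centre shift.  A centroid-matching start was deliberately
rejected: when the moving cloud is a cropped subset of the reference their
centroids should *not* coincide, and forcing them together measurably hurt
the cropping benchmark.

The optimizer is full-batch gradient descent along the normalized gradient
with a backtracking line search (step halved until the loss strictly
decreases, then doubled for the next iteration, capped at 64× the base
step of 1 μm), which makes the loss trace monotone by construction.
Convergence is declared when the relative loss decrease stays below
`convergence_tol` (10⁻⁶) for 10 consecutive iterations, or after
`max_iters` (2000).  With γ = 2 the per-neuron term is the RMS distance to
the reference — the quantity minimized by a Gaussian-mixture likelihood —
which is checked analytically in the tests.

Identity assignment is greedy: build the moving×reference distance matrix,
mask color-mismatched pairs, repeatedly take the global minimum (ties broken
by lowest row then column, which is `argmin`'s row-major order) and delete
its row and column.  Moving neurons left without an admissible partner are
reported unmatched.  On well-separated mutually-nearest instances this
agrees with the Hungarian optimum (property-tested); it is not optimal in
general but is cheap and is the procedure the benchmark accuracy figures
are defined against.

## Simulated perturbations and the worm fixture

The perturbation generators reproduce the benchmark conditions: a single
shared rigid jitter drawn uniformly from [−5, +5] μm per axis; axis
cropping; uniform random dropout; "biological noise" from a random
Gaussian-mixture field with N = 100 centres uniform over the cloud's
bounding box and displacement vectors of fixed magnitude 6.1 μm in
isotropic random directions, with the influence radius σ swept.  (An
alternative reading draws dₙ from N(0, σ²I); that is available behind
`gaussian_magnitude=True`, but the fixed-amplitude reading is the default
because σ is separately defined as the field's spatial influence radius.)
Color assignments are drawn per neuron *name*, identically in both clouds,
uniformly over k colors; a `unique` mode gives every name its own color.
All generators are pure functions of (input, seed).

`synth_worm` builds a tube of length 800 μm (default) and half-width 40 μm
bent along a circular arc, with elliptical tapering to pointed tips over the
outer 12% of the body at each end.  300 neurons (default; the full name
complement minus CAN) are placed with 55% in the anterior 20% of arc length
and 20% in the posterior 15% — emulating the dense head/tail ganglia and
sparse midbody cord — at perpendicular offsets within 70% of the local
half-width and |z| ≤ 15 μm.  Ground-truth canonical positions are (arc
length, perpendicular offset, z), rescaled with the same convention the
straightener uses, so the full pipeline can be scored without real data.

What the fixture does **not** emulate: left/right ganglion bilaterality and
stereotyped per-neuron positions (placement is random per seed), optical
anisotropy, segmentation errors in the hull, partial volume effects, or
real inter-individual positional variability structure.  Benchmark results
on fixtures therefore validate the *algorithms* (robustness to the modeled
perturbations), not absolute accuracy figures on real microscopy data.

## Benchmark harness

Each scenario repetition perturbs a substrate cloud, aligns with each
requested method, assigns IDs greedily and scores the fraction of correct
identities (unmatched = wrong); repetitions use seeds base+rep and results
report mean and standard error over repetitions.  Scenario geometry:
cropping rescales the substrate to x ∈ [−600, 200] μm, takes x > 0 as the
unlabeled head set and crops reference copies at the swept thresholds;
dropout removes the swept number of neurons; bionoise applies the field at
the swept σ; the color sweep assigns the swept number of colors to both
clouds.  In every scenario the *reference* copy receives the shared ±5 μm
rigid jitter.  GM methods consume colors natively through the loss's δ
term; color-unaware plug-in baselines are run once per color class on the
restricted point sets and the assignments combined.  External registration
baselines can be registered by name (`register_aligner`); none ship with
the package.

Hyperparameter search (`tune_hyperparameters`) is a seeded uniform random
search over a box followed by coordinate-wise local search whose step
halves when neither direction improves, stopping below 10⁻³ of each
parameter's range.

## Problem sizes and numerical choices

Defaults follow the studies (1000 circles, 40 repetitions, N = 100 noise
centres, γ = −6); the shipped tests and the acceptance script run
desk-scale versions chosen as the package's own test sizes — 150–300
circles, 10–40 repetitions, fixtures of 80–302 neurons — at which every
reported property already holds with margin.  Tolerances that matter:
boundary smoothing ≈0.3 px, circle-radius bisection 10⁻³ μm, midline
regularization 0.15 μm, distance floor ε = 10⁻³ μm, descent tolerance
10⁻⁶ relative.  Known limitations: the straightener assumes a simple,
non-self-overlapping posture (an Ω-shaped worm whose body touches itself
has no valid hull split); greedy assignment is not globally optimal;
gradient descent on the GM loss is non-convex and the field fit can leave
~1 μm residuals at isolated neurons when the field resolution (N) is low.
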