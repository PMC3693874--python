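# Methods

This note records the models implemented in `rodcell`, the numerical choices
behind them, the synthetic data used for validation, and the limits of what
the validation shows.

## Rod geometry and the active contour

A rod-shaped cell is modeled as a stadium: a rectangle of half-length ℓ and
half-width ρ capped by two semicircles of radius ρ (area 4ℓρ + πρ²). The
contour state is three points P, Q, R. Their centroid M is taken as the
ellipse center; the unique ellipse through the three points with that center
(the Steiner circumellipse) follows from the conjugate semi-diameters
u = P − M and v = (Q − R)/√3: the matrix S = uuᵀ + vvᵀ has the squared
semi-axes as eigenvalues and the axis directions as eigenvectors. The outer
rod takes the semi-minor axis b as cap radius and cap centers at ±(a − b)
along the major axis, so all four ellipse axis-endpoints lie on the rod
border. The inner rod is the outer rod scaled by 1/√2 about M: same
orientation and barycenter, exactly half the area, and the inner ellipse's
endpoints lie on its border. When the three points form an equilateral
triangle the ellipse is a circle and the rod degenerates to a disk (ℓ = 0);
states whose axis ratio b/a falls below 0.02 are rejected as degenerate.

The contrast energy E_R = (1/|Σ|)(∫_{Σ∖Σ′} f − ∫_{Σ′} f) is discretized as a
weighted pixel sum. Each pixel's coverage weight is a linear ramp of the
stadium signed distance, clip(0.5 − d, 0, 1), and the weights of each rod
are renormalized to the rod's analytic area. The renormalization makes E_R
*identically* zero on constant images (both region integrals reduce to the
same constant times equal areas), and the linear ramp keeps the energy
piecewise linear in the state, which finite-difference gradients handle
well. An earlier design with boundary-band supersampling was dropped for
both reasons. Pixels outside the frame take mirrored boundary values, which
avoids energy cliffs at the image edge.

For a bright stadium cell of area A on dark background, E(Σ′) is uniquely
minimized when the inner rod coincides with the cell (E = −h/2 for contrast
h; any growth or shrinkage strictly increases E), so the reported cell
outline, length (tip-to-tip), width (2ρ) and extremities are read from the
inner rod. The outer rod is the generous region used as the "inside the
cell" predicate for tracking.

The gradient is central finite differences with step 0.1 px — small against
the 1-px coverage ramp, large enough to average its kinks. (The analytic
gradient of the continuous energy exists but adds nothing at this
discretization; the implementation validates FD steps 0.1 vs 0.05 against
each other.) The optimizer is Polak–Ribière(+) nonlinear conjugate gradient
with Armijo backtracking, first trial step capped at 2 px of control-point
motion, gradient tolerance 1e−4, at most 500 iterations; accepted iterates
are strictly decreasing in energy, and line-search failure after a
steepest-descent restart terminates ("step size below tolerance", the usual
exit on the kinked discretized energy). Degenerate trial states evaluate to
+∞ and are rejected by the line search. A segmentation is flagged
non-informative when |E_R| < 3σ̂/√|Σ| — the standard deviation of the energy
of a pure-noise region pair of those areas, with σ̂ the image noise std
estimated from the median absolute deviation of horizontal pixel
differences.

Stacks are reduced by average z-projection, then contrast-stretched linearly
between the 0.3 % and 99.7 % intensity percentiles.

## Spot detection and intensity estimation

Detection uses a single-parameter Laplacian-of-Gaussian kernel, truncated at
4σ and corrected to zero sum (so constant regions give exactly zero
response), sign-flipped and scaled by σ² so bright spots of size ≈ σ give
positive, scale-comparable peaks. Candidates are local maxima (flat
plateaus excluded) visited in descending response with euclidean
non-maximum suppression at a minimum separation; an optional mask restricts
them to a segmented cell.

Intensity is the amplitude A of a least-squares fit of the rotated
2D-Gaussian-plus-offset model over an odd window (default 9×9 px). The
quadratic form uses the standard sin 2θ cross-term and reduces exactly to
the axis-aligned Gaussian at θ = 0; θ is reported in (−π/2, π/2] and set to
0 for isotropic fits, where it is unidentifiable. Initialization follows
the microscope: σ₀ = diffraction limit / pixel size, A₀ = max − min,
B₀ = min, θ₀ = 0, center at the candidate. The optimizer is scipy's
bounded trust-region least squares (a Levenberg–Marquardt-type method that
accepts bounds; plain LM cannot). Default σ bounds are [0.3, window/2];
callers that know the optics should pass `sigma_bounds = (σ₀, window/2)`,
because no spot can be narrower than the PSF — without that bound, fits to
undersampled spots (σ ≈ 0.65 px) chase single noisy pixels (σ pinned low, A
inflated by tens of gray levels), while with it the amplitude error is
noise-limited. Landing on this physical lower bound is a valid in-focus
fit; only the upper bound flags a failure. 3D stacks are handled by
maximum-intensity projection for detection, with the fit on the argmax
slice.

## Tracking

The reference tracker is exact dynamic programming on the candidate graph:
edges connect candidates in consecutive frames within the declared motion
bound (no gap closing), and the cost of an edge is
λ_int(1 − Â_j) + λ_var|Â_j − Â_i| + λ_dist d/d_max + λ_dir(1 − cos φ)/2 +
λ_out[outside cell], with Â the intensity normalized to the 99.5th
percentile of the sequence's candidate intensities. All terms are bounded
in [0, 1] except the deliberate outside-cell penalty; defaults λ = (1, 0.5,
0.5, 0.25, 10). The directional term depends on the predecessor, so the DP
state is the (vertex, predecessor) pair — an exact polynomial
reformulation. Ties are broken by the lexicographically smallest
candidate-index sequence, implemented identically in the DP and in the
exhaustive-enumeration oracle so the two agree exactly, path and cost, on
every graph small enough to enumerate.

At very low peak SNR (PSNR = 20·log₁₀(A/σ_noise) near 0 dB) sparse
candidate graphs fail for a structural reason: detection misses the spot in
a sizable fraction of frames, and with edges only between consecutive
frames a single miss truncates the track. The dense tracker
(`track_spot_dense`) therefore uses *every* in-cell pixel as a vertex, with
the LoG response as its intensity. Static structure (the cytoplasm and the
membrane's LoG ridge, which is as bright as a 0 dB spot) is removed by
subtracting the temporal median of the response per pixel — static
features cancel, moving or fading ones survive. Because the validation
motion model is an undirected random walk, the directional term carries no
information and is disabled; that also collapses the DP state to single
vertices, so each frame transition is one vectorized matrix step. The
distance weight is raised to 1.0 (on a dense grid the 0.5 default
under-penalizes hopping to bright noise pixels) and edges reach the motion
bound plus a 1-px margin for pixel quantization of the true displacement.
Recovered positions are refined by the PSF fit where it converges within
2.5 px. Matched-filter arithmetic sets the feasible regime: the LoG
response to a matched Gaussian spot is 0.5·A against a noise response std
of ≈ 0.4·σ_noise/σ, so per-frame discriminability at 0 dB is ≈ 1.25·σ_spot;
the tracking-robustness experiment uses σ_spot = 2.5 px — the
diffraction-limited width under the default microscope parameters
(0.25 µm limit, 0.1 µm pixels) — giving d′ ≈ 3, which a path-optimal
tracker can exploit while a per-frame detector cannot.

The loss-of-fluorescence frame F_t0 fits a two-level step to the
fitted-amplitude series (least squares over all change points, the
maximal-correlation criterion) and reports the last frame at or above the
threshold background + k·σ_noise with k = 3. In two-channel data the
signal-channel amplitude is measured at the *reference* track's positions:
once a spot has faded its own track necessarily latches onto residual
structure, but the non-fading reference protein still marks where the
structure is. Single-channel fading tracks are handled by treating a
truncated track's untracked tail as zero amplitude.

## Kymographs

The cell-frame kymograph renders each spot at the rounded column of its
orthogonal projection onto the axis through the barycenter (sign fixed by
the cap ordering at frame 1), one row per frame, value = fitted amplitude;
off-axis displacement is discarded. The relative kymograph places the two
spots at ±d/2 of their euclidean separation, so positions are symmetric
about the midline by construction and brightness asymmetry is the visible
signal; past a track's loss frame its side renders at amplitude 0. Raw
matrices are kept for numeric use; a 1-px Gaussian smear is applied only
for display/saving.

## Synthetic phantoms and what the validation shows

The generator renders stadium cells of uniform cytoplasmic intensity
(optionally with darker circular "nucleus holes", since the tagged protein
is excluded from the nucleus), an optional petri-dish disk, isotropic
Gaussian spots sampled at pixel centers, and additive Gaussian white noise,
clipped to the bit range last. Overlapping cells are rejected (stadium
distance = axis-segment distance minus radii). Defaults are 8-bit with
background 10 and interior 214, chosen so the cell-contrast signal
(~204 gray levels) reproduces the published noise series: std {10, 30, 60,
90, 120} ↔ SNR ≈ {26, 16, 10, 7, 4} dB. The built-in 5×5 reference PSF
kernel (A = 95.9719, σ = 0.65 px, optional offset 80) is exactly a
point-sampled Gaussian and drives the intensity-estimation experiments
(38 spots, noise std 15). Time lapses move spots by bounded random walks
confined to their cell (default ≤ 4 px/frame) with per-spot amplitude
profiles for fading; per-frame noise streams are spawned from one seed.

The phantoms deliberately omit shot (Poisson) noise, camera gain, focus
drift, bent or touching cells, and textured cytoplasm. Passing the
validation therefore demonstrates correctness of the geometry, energy,
estimators and optimality of the tracking under the stated noise model — it
does not by itself guarantee field performance on real micrographs, where
initialization quality and deviations from the stadium shape dominate.

Validation problem sizes (one CPU, seconds to a few tens of seconds each):
segmentation robustness uses a 64×96 px scene, 10 noise seeds per level;
the intensity comparison 19 cells / 38 spots × 10 seeds; tracking 20
replicates of 50-frame 64×64 sequences; loss detection 20 constructed
fades; the DP oracle 100 random graphs of ≤ 6 frames × ≤ 4 candidates.

## Interfaces

Images are 8/16-bit grayscale TIFF (color rejected); results are
tab-delimited text with a header row, decimal points, 6 significant digits,
positions in px and µm. The pipeline configuration is a flat key=value text
file; channel 0 is the reference channel by convention. The full pipeline
is deterministic given its configuration — repeated runs are byte-identical,
which is the automated counterpart of zero inter-operator variability in
manual measurement.

## Known limitations

- One stadium per cell; bent, dividing or overlapping cells are out of
  scope, as is interactive re-initialization.
- The candidate tracker does not close gaps across missed frames; the dense
  tracker assumes an undirected motion model (no persistence term).
- The 2D PSF model is applied slice-wise to 3D data; there is no volumetric
  Gaussian fit and no multi-emitter deconvolution.
- Segmentation accuracy on real yeast populations (the regime of manual
  initialization quality and cell-shape deviations) is not measurable on
  phantoms and is not claimed.
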