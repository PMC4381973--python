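# Methods

This note records the models behind each module, the parameters that matter,
the numerical choices made where the procedure was genuinely open, and what
the synthetic generators do and do not emulate.

## Coordinate and unit conventions

All localization coordinates are nanometres; diffusion coefficients are
µm²/s; times are seconds; genomic coordinates are 0-based half-open (BED).
Voxel/pixel centres sit at `(index + 0.5) × size` with the origin at the
array corner.  Every generator is a pure function of its seed: identical
seed and parameters give bit-identical output.

## Localization

The emitter model is a 3D Gaussian with shared lateral width σ_xy, axial
width σ_z, amplitude A₀ and a constant local background B, evaluated at voxel
centres.  Fits use trust-region least squares with width bounds
σ_xy ∈ [50, 500] nm and σ_z ∈ [100, 1500] nm, which stabilise low-photon
fits; background is fitted per spot since nuclear background varies locally.
The integrated photon count N is the background-subtracted sum over voxels
within 3 S.D. of the fitted centre, and τ = B/A₀ is the background-to-peak
ratio.

Per-axis precision follows the photon-statistics estimator
Δ² = (σ² + a²/12)/N · (16/9 + 4τ) with a the voxel size along the axis.  The
estimator is itself an approximation (it ignores pixelation cross-terms and
fit correlations); in the test suite the empirical scatter of repeated
Poisson-noise fits is required to agree with it within a factor of two, not
exactly.

Drift correction subtracts the displacement of the per-block centroid of all
localizations (blocks of 50 frames by default) relative to the first block;
empty blocks carry the previous displacement forward.  The procedure is
idempotent.  When the frame interval is supplied, datasets drifting faster
than 800 nm/min are rejected outright — centroid tracking at that rate
confuses drift with content changes.

## Tracking and stable sites

Linking is greedy nearest-neighbour between consecutive frames under a radial
gate, either given directly or derived from a maximum diffusion coefficient
as r_max = √(2·d·D_max·dt) (default D_max = 0.05 µm²/s for bound-molecule
tracking).  Ties resolve by smallest distance, then earliest index; gaps of
one frame may be bridged (conservative against false merges).  Every
detection belongs to exactly one track.

A stable site is a track whose every step *and* end-to-end displacement stay
below 50 nm and whose duration (frames × frame interval) reaches the cutoff —
3 s for 3D catalogs, 2 s for 2D maps.  Each qualifying track contributes one
site at the mean of its localizations, so repeat appearances of one molecule
never inflate the clustering statistics.  Under slow (500 ms) acquisition,
where moving molecules blur away, single-frame detections may be counted as
bound with a 0.5 s duration (`single_frame="bound"`); under fast acquisition
they are discarded.  Duration is n_frames × dt rather than (n−1) × dt, which
is what makes the single-frame convention representable.

## 3D pair correlation

The estimator compares non-redundant pair counts in the data catalog, DD(r),
against those of a uniform random catalog of 10× the size drawn in the same
volume, RR(r):

    g(r) = [N_R (N_R − 1)] / [N (N − 1)] · DD(r) / RR(r).

The prefactor is the ratio of the number of point pairs in each catalog; it
is what makes g = 1 for complete spatial randomness at any random_factor.
Bins are 50 nm wide with edges at multiples of the width and (lo, hi]
closure, so the bin sum equals N(N−1)/2 exactly and tree-based counts match a
brute-force distance histogram bit for bit.  Bins where RR = 0 are returned
undefined (NaN), never divided through.

The random catalog's volume is, by default, the 3D convex hull of the data.
For a catalog drawn in a known geometry the hull is biased small — at 7000
uniform points in a 5 µm sphere the hull covers ~95% of the ball and
depresses mean g to ≈0.96 — so a known volume can and should be declared
explicitly (`volume=NuclearVolume(...)`); the reference computations on
spherical synthetic catalogs do so.  Re-drawing the random catalog
(`n_random_draws`) provides an uncertainty band on g.

Hard-core catalogs (minimum pairwise separation s) have empty bins below s by
construction; analyses report from the first informative (DD > 0) bin, and
trend checks across bins start above s, where bins are fully sampled.

## Fluctuation model

Clustering with no preferred shape produces an exponential pair correlation
g_true(r) = A·e^{−r/ε} + 1, with amplitude A proportional to the in-cluster
density enrichment over the global mean and range ε proportional to cluster
size.  Finite localization precision blurs each site by an effective Gaussian
of S.D. σ̄, σ̄² = s̄² + ā²/12 (mean PSF S.D. plus voxel quantisation), whose
pair-correlation kernel is the normalised 3D Gaussian of per-axis variance
2σ̄².  The observed curve is the 3D convolution of the two.

For isotropic functions the 3D convolution reduces to a 1D integral,

    (f ⊗ K)(r) = [r √(2πv)]⁻¹ ∫₀^∞ s f(s) [e^{−(r−s)²/2v} − e^{−(r+s)²/2v}] ds,

v = 2σ̄², evaluated by trapezoidal quadrature on a grid finer than both σ̄/4
and ε/10.  Because the kernel integrates to one, the flat baseline passes
through unchanged and only the exponential term is convolved.  Fitting uses
trust-region least squares with A ≥ 0 and ε ≥ 1 nm; a flat curve pins A at 0.
The repeat-appearance ("stochastic") self-correlation term is taken as zero
because stable sites are counted once at their average position.  Simulated
catalogs with no localization blur are fitted with the exponential directly
(`psf_convolution=False`).  Parameter recovery is exact to within 5% over
A ∈ [0.5, 50], ε ∈ [50, 1000] nm at the 1% noise level.

## Intensity maps and masked correlation

Density maps are binned kernel density estimates: a 2D histogram on a
100 × 100 grid smoothed by a Gaussian of 2 grid units, normalised to total
mass 1, with the physical pixel size recorded (160 nm at the default
16 µm field).  Masks threshold the max-normalised map at 0.2.  Channel
normalisation subtracts a low-percentile background estimate and divides by
the maximum.

The masked cross-correlation is FFT-based:

    c(r⃗) = Re{FFT⁻¹(FFT(I₁)·conj FFT(I₂))} / (ρ₁ ρ₂ N(r⃗)),
    N(r⃗) = FFT⁻¹(|FFT(mask)|²),

with images zeroed outside the mask, ρ the mean in-mask intensities, and
N(r⃗) the number of overlapping mask pixels at each lag.  Arrays are
zero-padded to twice their linear size so circular wrap-around never mixes
opposite edges — without this the N(r⃗) normalisation is wrong at large lags.
Lags with less than one overlapping pixel are undefined.  Angular averaging
uses 1-pixel radial bins weighted by N(r⃗); values are meaningful beyond one
pixel (the kernel scale).  The implementation agrees with a brute-force
shift-and-sum to 10⁻¹⁰ and is invariant to zero-padding of the inputs.

One systematic deserves note: the KDE kernel spreads mass beyond the point
support, so pixels within a kernel scale of the nucleus rim under-represent
the local density, which biases the large-r autocorrelation upward by ~3%.
The intensity-pair generator therefore returns the nucleus mask eroded by
1.5× the kernel bandwidth, inside which the rendered maps are stationary.

The pixel-wise Pearson coefficient is computed over in-mask pixels after
excluding pixels where both max-normalised channels fall below the same 0.2
gate used for masks; quadrant fractions at that gate are reported alongside.
RFI = (I_region − I_background)/(I_surround − I_background) on mean gray
intensities.  Outline registration thresholds both images into masks and
locates the integer shift by phase correlation.

## Regional diffusion

Tracks are classified pixel-by-pixel against a mask and cut at boundary
crossings; tracking is never redone, fragments keep their source id, and
detection counts are conserved.  Diffusion coefficients come from a linear
fit (free intercept, absorbing static localization error) of the
time-averaged MSD at lags 1..max(4, n/4) for tracks of at least 8 consecutive
frames; fits with R² < 0.8 are excluded from histograms.  D = slope/(2d) with
d the dimensionality of the coordinates.  D̂ is not corrected for the
localization-noise floor, which dominates the bound population (a 20 nm
noise floor reads as D ~ 0.01–0.02 µm²/s at 10 ms frames) — a known,
documented bias shared with the MSD literature.

Population structure is fitted as a Gaussian mixture on log₁₀D.  The bound
and free populations sit two decades apart, so linear-scale Gaussians cannot
represent both; log-domain fitting is the package's choice, and component
means are reported back-transformed.  BIC is exposed for order selection —
note that a mixture *forced* to more components than the data support splits
a population into overlapping components with arbitrary weight division, so
"one population" is diagnosed by order preference, not by a dominant weight.

## Target-search simulation

The search is a random-walk trapping problem: a point TF takes per-axis
Gaussian steps of S.D. √(2Dδt) inside a reflecting sphere (radius 5 µm,
desk preset 2 µm) containing non-overlapping absorbing spheres (radius 40 nm,
centre separation ≥ 80 nm; 7000 targets, desk 700).  A trial ends when an
end-of-step position lies inside any target (binding probability 1 by
default); there is no continuous-path bridge test, so the step S.D. is
required to stay below the target radius (configs violating this are
rejected).  The default δt = 10 µs gives 14 nm steps for D = 10 µm²/s; the
desk preset uses 20 µs (20 nm steps), still well under the 40 nm targets.
The boundary reflection is a radial fold (r → 2R − r), valid because steps
are tiny relative to the nucleus.  Trials exceeding the step cap are censored
and reported, never dropped.

Injection is uniform in the nucleus excluding target interiors, or uniform on
a shell of given radius around the target centre of mass (release
experiments).  Target lookup uses a k-d tree; a brute-force mode exists and
produces identical hit times and indices — the tree is an accelerator, not an
approximation.  Uniform reference arrangements are re-drawn per experiment,
as are cluster centres.

Fold of Delay = mean τ₃D (clustered) / mean τ₃D (uniform), with a percentile
bootstrap CI.  τ₃D distributions are decomposed by maximum likelihood into
one or two exponential components (EM for the mixture; coincident lifetimes
collapse to one component), compared by likelihood ratio.  The Smoluchowski
closed form τ₃D = 1/(4πRDρ) anchors the dilute uniform limit; at the default
(non-dilute) density the simulated mean sits ~30% above it, within the
factor-of-two agreement expected of the dilute-limit formula.

Desk-scale problem sizes used by the reference computations: 2 µm nucleus,
700 targets, 7 clusters, 300–1000 trials per condition.  These preserve every
qualitative trend of the full geometry (delay growing as σ falls from 800 to
200 nm, shrinking with cluster count, τ₃D rising with release radius) at a
small fraction of the cost.

## ChIP-exo

Exonuclease digestion leaves the 5′ read end at the protein–DNA cross-link,
so reads reduce to single points: start for forward reads, end−1 for reverse.
Peak calling on the per-strand point counts is deliberately plain plumbing —
Gaussian smoothing (S.D. 5 bp), local maxima above a height threshold, extent
as the contiguous region above half maximum, score as the raw count sum in
the extent.  Pairing takes a forward ("left") and reverse ("right") peak
whose midpoints — (start+end)//2, floor on odd widths — lie within 20 bp,
greedily by increasing midpoint distance (ties by leftmost coordinate), each
peak used at most once; by default the forward midpoint may not lie
downstream of the reverse one (the orientation a cross-link footprint
implies), relaxable by flag.  The bound region spans the two midpoints.
Chromosome-bin densities count the score-ranked top-N region midpoints in 500
equal-width bins per chromosome; TSS analysis reports the empirical CDF of
absolute distances from region midpoints to the nearest annotated TSS, with a
uniform-random-position reference on the same chromosome sizes.  Read
trimming, alignment, and depth normalisation are upstream of this package
and out of scope.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analyses assume:
uniform or Gaussian-clustered point catalogs with hard-core separation in
spherical/hull volumes; Brownian and bound/free mixture tracks with exact
per-population label fractions and a Gaussian localization-noise floor;
Poisson photon statistics over a constant background for spot stacks; paired
intensity maps sharing a controlled fraction of cluster centres inside a
circular nucleus; stranded reads/peaks flanking hidden sites at a set
offset and jitter, with a 200 bp minimum site separation so the ground truth
stays unambiguous.

They deliberately do not emulate: photophysics beyond a constant detection
probability (no blinking or bleaching kinetics), camera noise beyond Poisson,
anisotropic or shaped clusters, chromatin context or sequence composition,
mappability, or duplicate-read artefacts.  Passing tests therefore validate
the estimators under their stated assumptions; they do not certify
performance on real data where those assumptions bend (e.g. residence times
truncated by bleaching, masks from noisy widefield channels).

## Degenerate inputs and tie-breaking

Empty or single-point catalogs raise; all-zero maps cannot be thresholded;
RR = 0 bins and sub-pixel correlation lags are NaN, not errors; linking ties
break by distance then index; pairing ties by distance then coordinate;
EM lifetime fits collapse to one component within 1% lifetime coincidence;
packing that cannot satisfy a hard-core constraint fails explicitly after a
bounded retry budget (100× oversampling) rather than silently relaxing it.
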