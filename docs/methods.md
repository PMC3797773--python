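# Methods

This note documents the models, parameter choices and numerical decisions
behind `palmcell`, and what the synthetic validation does and does not
establish about real data.

## Coordinate and data conventions

Positions are continuous nanometre coordinates with the origin at the
top-left corner of the field; the camera pixel of a position is
`floor(pos / pixel_size_nm)` (pixel size default 110 nm).  Frames are
0-based and an event's time is `frame × frame_time_ms` (default 50 ms).
The localization CSV dialect is comma-separated, dot-decimal UTF-8 with
header `frame,x_nm,y_nm,intensity,channel,id`; a column map ingests
foreign exports (e.g. ThunderSTORM's `x [nm]`).  The default localization
precision σ_loc is 25 nm.

## Drift correction

Bead localizations are linked frame-to-frame with a globally optimal
(Hungarian) nearest-neighbour assignment; links longer than `max_jump_nm`
(default 500 nm) are broken.  Interior gaps in a track are filled by
linear interpolation, never extrapolated.  Each selected track is
re-zeroed to its first valid frame (the procedure is silent on the zero
point; the first frame is the natural choice since the reference must
start at (0, 0)), and the reference trajectory is the unweighted per-frame
mean.  Equal weighting is an assumption; weighting by localization
precision would be a refinement.  QC subtracts the reference from every
track; the model is accepted iff the largest per-bead residual σ over both
axes is < 10 nm (`threshold_nm`).  With n beads of iid noise σ the
residual is σ√(1 − 1/n) — ~4.6 nm for 7 beads at σ = 5 nm — so homogeneous
fields pass comfortably while agarose-like per-bead anomalies of a few
tens of nm fail.  No temporal smoothing is applied to the reference by
default (a smoothing window is configurable); smoothing trades noise for
lag under fast drift.

Two bead-selection workflows exist: all accepted beads (flow-chamber
fields, where one trajectory fits the whole field of view) and the 7
nearest tracks to a cell centroid, ties broken by bead id (agarose-style
fields with local motion).

## Channel registration

Per axis a 6-term second-order polynomial (basis 1, x, y, x², xy, y²) is
fitted by least squares on matched bead pairs, with coordinates centered
and scaled by their standard deviation for conditioning.  Six beads
determine the fit algebraically; the default minimum of 7 adds redundancy.
Residuals are reported in nm and in pixels (the conventional acceptance
bound is 0.1 pixel).  Any noiseless distortion within the order-2 model is
recovered to machine precision; with iid noise σ, held-out residual RMS ≈
σ.

When more beads are available than the fit uses,
`select_beads_g_optimal` picks the fitting subset by G-optimal design:
the subset minimizing the maximum polynomial prediction variance over the
evaluation positions.  The selection uses bead *positions* only, so it
cannot bias the fit; it exists because with exactly 7 fitting beads the
order-2 model has one degree of freedom per axis and a poorly spread
subset extrapolates noisily.  Even so, the maximum residual over a
10-bead field at 3 nm noise is intrinsically close to the 0.1-pixel
bound: the evaluation-channel noise alone contributes ~0.06 px to a
max-of-20 statistic, and held-out model error adds comparably.  Typical
values land at 0.05–0.11 px depending on the draw.

## Clusterization

Steps: (1) isolate localizations in the ROI; (2) rasterize onto a virtual
pixel grid (`virtual_pixel_nm`, default 10 nm, valid 5–10 — finer than
σ_loc); (3) label 8-connected components; (4) keep components with
≥ `min_events` localizations (default 20, sensible range 5–50 depending on
fluorophore photophysics) *and* area ≥ 2 virtual pixels; (5) collect
member events; (6) grow each cluster's search radius in `merge_step_nm`
steps (default 30 nm, range 10–50) and absorb the events in the enlarged
area — including whole neighbouring clusters — whenever the count rises by
more than `growth_frac` (strict >, default 5%).

Decisions the procedure leaves open, fixed here for determinism:

* processing order in step 6 is descending event count, ties broken by the
  smallest member id; the cluster envelope R is the largest member
  distance from the centroid;
* growth probes count **all** rasterized events, including members of
  sub-threshold components discarded in step 4
  (`include_unclustered_in_growth=True`) — large sparse clusters are
  exactly the ones whose fragments fail the filter;
* FWHM is the Gaussian-equivalent `2√(2 ln 2) × sample std` per axis
  (mean of axes as the scalar size) rather than a histogram half-maximum,
  which is noisy at low counts;
* classification: PALM-limited iff FWHM ≤ 1.3 × 2√(2 ln 2) σ_loc (the 1.3
  accommodates the 45–65 nm sizes observed at σ_loc ≈ 25 nm) *and* the
  center-of-mass displacement between the first and last temporal thirds
  of events is ≤ 2 σ_loc;
* duty cycle uses the full acquisition length as denominator;
* MSD uses disjoint windows of `window_events` (default 10) events; for a
  static cluster of spread σ the floor is 4σ²/window.

The pipeline is deterministic and invariant to input row order (the table
is canonically sorted by frame then id).

## Cell detection and staging

Nucleoid segmentation is deliberately simple: Otsu threshold,
morphological opening (disk radius 1), border clearing, connected
components.  It exploits the fact that chromosome signals from touching
cells stay separated even when membranes fuse.  Contour refinement moves
each of 140 resampled vertices along its outward normal to the
distance-penalized intensity maximum within `search_range_nm` (default
1200 nm), smooths with a circular moving average (window 5), and iterates
to a 5 nm mean-displacement tolerance.  Two safeguards matter in practice:
the search is asymmetric (inward travel capped at search/8) because
nucleoid seeds always underfill the cell and a bright interior septum ring
would otherwise capture vertices; and ties between near-equal ridges (the
opposite membrane wall is within reach on an 800 nm-wide cell) are broken
toward the nearer ridge by a distance penalty of up to 25% of the local
dynamic range.  A low-confidence flag is set when ≥ 30% of normals find no
signal above background (median + 3 robust σ).

The medial axis is the skeleton of the rasterized contour, ordered along
the principal axis and extended to the poles along the global principal
direction (robust to skeleton end spurs).  The membrane profile samples
bilinearly at half-pixel spacing along the axis, averaged across the local
width.  Septum detection takes the highest interior peak with relative
position in [0.15, 0.85] whose prominence exceeds 1.5 × the median of the
baseline-subtracted profile (10th percentile as baseline) *and* 0.4 × the
profile's full contrast; the second gate rejects noise bumps on flat
vegetative profiles while the baseline subtraction keeps the criterion
meaningful when diffuse membrane signal raises the interior plateau.  Peak
positions are refined by parabolic interpolation.  Staging: no septum →
vegetative/pre-divisional; septum in the closed middle third [1/3, 2/3] →
dividing (boundary septa take the more conservative class); otherwise →
sporulating.

Cluster-to-cell assignment requires the cluster centroid inside a cell
contour dilated by one σ_loc (membrane-bound clusters sit at the contour);
a centroid inside two *undilated* contours is an error, and between two
dilated contours the nearer cell wins.  Every cell record carries a
`needs_review` flag as the hook for the manual verification step any
automatic classifier needs on real data.

## Tilt and movement QC

Axial line profiles (a narrow 3-row band through the poles — averaging
across the full width would wash out the pole peaks) are fitted with a
baseline + 2- or 3-Gaussian model, the order chosen by BIC; bounds keep
components inside the sampled range and fits with components closer than
3 samples are rejected as degenerate.  With d_R/d_L the central-to-pole
peak distances, the verdict is *inclined* iff the slopes of d_R(z) and
d_L(z) across ≥ 3 planes have opposite signs and each exceeds its standard
error; symmetric shrinking (defocus) stays *flat*.  The minimal detectable
tilt is defined by this package's convention as arctan(precision / z_step)
— the angle at which the per-plane lateral peak shift equals the peak
localization precision (8 nm precision, 125 nm z-step ⇒ 3.66°).

Residual cell movement is scored by the pairwise center statistic
Ψ(t) = |(X_j,t − X_k,t)/2 − (X_j,0 − X_k,0)/2| with X the midpoint of the
two fitted cell edges; Ψ is zero at t = 0 by construction and cancels any
common translation of the field, so it isolates genuine cell-on-surface
motion (a single cell moving 20 nm against a fixed neighbour yields
Ψ = 10 nm).

## Synthetic scenes: what they emulate, and what they do not

The generator's defaults encode the study conditions: 110 nm camera
pixels, 50 ms frames, σ_loc = 25 nm, ~200 nm of common drift over a
10-minute (12 000-frame) acquisition, 5–15 beads per field, and cell
classes of 2.5 ± 0.5 µm (vegetative), 4 ± 0.6 µm (dividing, midcell
septum) and 3.1 ± 0.2 µm (sporulating, polar septum).

* **Bead tracks** — common drift is a linear ramp (60%) plus a seeded
  Gaussian random walk (40%), rescaled so the net displacement equals
  `total_drift_nm`; agarose mode adds independent per-bead walks of net
  scale `anomaly_nm`.
* **Blinking** — each emitter occupies one contiguous on-window of 1–3
  frames (uniform), windows non-overlapping within a cluster, so no two
  emitters of a cluster are on in the same frame.  No fluorophore
  photophysics is published for these conditions, so on/off kinetics are
  an artifact choice; absolute molecule counting is out of scope for
  exactly this reason.
* **Cells** — spherocylinders rendered as 3D membrane shells through a
  Gaussian PSF (σ 120 nm default), integrated over a configurable depth of
  field (500 nm default; use ~150 nm for optically sectioned SIM-like
  stacks).  The depth integration is what makes a septum — a transverse
  membrane disc seen through the cell depth — bright against the interior,
  as in wide-field images.  The septum is an annulus whose inner radius is
  `septum_openness × R` and whose amplitude scales with (1 − openness).
  Nucleoids are axially elongated Gaussian blobs (two flanking blobs when
  a septum exists, one central otherwise) sized to overlap into a single
  DNA object per cell.  Noise is Poisson shot noise plus Gaussian read
  noise.

Known, deliberate idealizations: no bleaching or triplet kinetics, no
sCMOS fixed-pattern noise, no cell curvature or contact between membranes,
no axial drift (handled in hardware by autofocus systems).  Passing tests
on these scenes demonstrates the *procedures* are implemented correctly at
realistic geometry and noise, not that real-data error rates (e.g. the ~5%
manual misclassification rate seen in practice) are reproduced.

A systematic effect worth knowing: depth-integrated rendering foreshortens
the hemispherical poles by ~40 nm per pole, so image-derived cell lengths
run ~2–4% below the geometric truth and relative septum positions inherit
up to ~1% of that.  The measured septum position error on clean scenes is
≤ 1% of cell length; stage classification is exact on all tested scenes.

## Problem sizes and budgets

The test suite (≈ 200 tests) runs in well under a minute on one CPU: bead
simulations use 2 000 frames except the drift-QC gate, which uses the full
12 000-frame acquisition; statistical oracles (FWHM convergence, residual
noise propagation) use 10⁴ samples; the labeling oracle checks 1 000
random grids; end-to-end pipeline tests use 3 cells and 3 000 frames.
`scripts/acceptance.py` completes in seconds.
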