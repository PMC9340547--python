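# Methods

## The measurement problem

During gastrulation the mouse segmentation clock switches on: after a
quasi-synchronous, tissue-wide rise of the Notch-reporter signal (the
"pulse"), periodic waves of reporter activity appear that travel from a
proximal wave origin toward the distal end of the nascent mesoderm.  The
package quantifies this onset from 3D+t light-sheet recordings along a
curved *line of interest* (LOI) on the mesoderm surface:

* **Wave number** `q(t) = |φ(distal) − φ(origin)| / 2π` — the total
  oscillation-phase difference across the tissue; `q = 1` means one full
  wave spans the domain.
* **Phase-gradient slope** `q(t) / L(t)` with `L` the tissue length along
  the LOI — the phase difference per micrometre.
* **Period gradient** — instantaneous oscillation periods measured near
  the origin (proximal) and near the moving domain boundary (distal),
  sampled 2–6 h after wave onset and summarised as median and IQR.
* **Tissue flow** — mean cell velocities near the LOI, from separate
  cell-tracking data, averaged into a vector field.

A spatial period gradient is the mechanism of interest: if distal
oscillators run slower than proximal ones, phase differences accumulate
linearly in time (`q(t) = t·(1/P_prox − 1/P_dist)` for fixed-period
oscillators), producing travelling phase waves without any signal
propagation.

## Processing chain

1. **Preprocessing** (`preprocess`).  Temporal background reduction: the
   per-frame mean of a fixed 30×30×150-voxel box outside the specimen is
   subtracted and a constant offset of 1000 counts added back (values
   floored at 0), pinning the box mean at the offset.  Registration is
   recursive: each frame is aligned against the already-registered
   neighbour, propagating away from a reference frame in both directions;
   the default pairwise estimator is an integer-voxel translation from the
   Fourier cross-correlation peak (scikit-image) and is pluggable.  The
   time-summed mask of voxels above 1030 counts defines the embryo COM,
   which is translated (whole voxels) to the image centre and rotated by
   operator-supplied angles; the same transform is applied to landmark
   annotations.  Z is linearly resampled by 3.59 to an isotropic 2.088
   μm grid.
2. **LOI geometry** (`loi`).  Keyframe anchors (origin, left/right distal
   ends) are linearly interpolated per frame, clamped outside the keyframe
   span.  The intermediate anchor is the intensity maximum along the ray
   from the COM through the origin–distal midpoint (first maximum on ties),
   smoothed over time with a cubic smoothing spline.  The LOI through the
   three anchors is the unique circular arc (polyline when collinear);
   see *Design choices*.  Arc length is tabulated by 100,000 equal-parameter
   chords and sampled at integer micrometres.  Surface kymographs average
   intensity in a 12-px-diameter sphere at each arc point after 3D Gaussian
   smoothing (σ = 6 px), with the origin's series on the midline, the left
   arc extending above it and the right arc below.
3. **Phase extraction** (`spectral`).  Frames before the wave-onset frame
   are cropped; out-of-domain cells carry the fill value 1067 and a
   validity mask; rows are smoothed across space with a masked Gaussian
   (σ = 5 px) so boundary cells are not contaminated by the fill.  Each
   row is sinc-detrended (cut-off period 220 min) and convolved with 600
   complex Morlet wavelets spanning 100–220 min.  The per-time power
   maximum (the ridge) yields instantaneous period; the complex
   coefficient there yields phase (cosine convention, 0 at an oscillation
   maximum, wrapped to (−π, π]) and power.
4. **Wave statistics** (`wavestats`).  One body side only (left/top by
   default).  Per column, phases are unwrapped from the midline outward
   over the contiguous valid run, 20 px are cropped at the distal end, and
   q is the end-to-end phase difference over 2π; `L` is the cropped column
   length × spatial pixel; slope = q/L.  The proximal period series is an
   8-px corridor mean around the midline; the distal series follows the
   domain-boundary contour shifted 20 px toward the midline (tracking the
   expanding tissue) with the same corridor; both run through the same
   detrend → wavelet → ridge chain, and period values with time-after-onset
   in (2 h, 6 h] are the samples (24 at a 10-min frame interval).
5. **Flow** (`flow`).  Track clocks are shifted so t = 0 falls 260 min
   after the pulse peak.  A track is kept iff it stays within 30 μm of the
   LOI for ≥300 consecutive minutes ("over 300" read inclusively; the
   boundary case is tested).  Samples are projected onto a common
   reference LOI — orthogonal projection onto the chord table, giving a
   continuous arc coordinate and a signed lateral offset along the LOI
   plane normal — and finite-difference velocities (central interior,
   one-sided ends) are averaged on a grid that covers the data, so the
   total bin count equals the number of samples.

## The phantom

The synthetic embryo is an "egg cylinder": a cylindrical shell capped by a
hemisphere (distal pole down), mid-surface radius 100 μm, thickness 30 μm,
cylinder height 120 μm, rendered at 2.088 μm isotropic voxels.  Shell
intensity follows

    I(s, t) = B + A_p·exp(−(t − t_p)²/2w²) + A·(1 + cos φ(s, t))/2 + ε,

with arc distance `s` measured along the meridian from the rim (the wave
origin), background B = 200 counts, pulse amplitude A_p = 300 (Gaussian
width 75 min), oscillation amplitude A = 300 and ε Gaussian noise
(σ = 20 counts, clipped at zero).  Oscillations start synchronously
(φ = 0 everywhere) 260 min after the pulse peak; the period varies
linearly from 133 min at the origin to 153 min at the initial arc end
(the proximal/distal period medians reported for this stage), constant
beyond it.  The
domain grows at 0.1 μm/min by rim extension.  Tracks are seeded near the
origin and advected distally at per-track speeds uniform in 0.1–0.3
μm/min (the reported mesoderm motility range) with 0.5 μm positional
jitter; positions are lab-frame, so zero advection means strictly
stationary cells.  One seeded random stream per artifact (volume,
kymograph, tracks) makes every artifact independently reproducible.

Ground truth carries the analytic phase field, `q(t) = t·(1/P_p − 1/P_d)`,
landmark positions and per-track speeds.  What the phantom does *not*
emulate: point-spread function and scattering, bleaching, nuclear texture,
irregular anatomy, phase diffusion between oscillators, and cell-level
intensity variation.  Passing recovery tests therefore demonstrates the
correctness of the measurement chain under the model's assumptions, not
robustness to every property of real recordings.

## Design choices

* **LOI interpolant.**  Three points admit many interpolants.  A parabola
  systematically under-measures arc length on curved anatomy (0.53 % short
  on a quarter circle — outside our 0.5 % geometry budget), so the LOI is
  the unique circular arc through the anchors, which is exact wherever the
  surface is locally circular (the distal dome) and degenerates gracefully
  to a polyline for collinear anchors.
* **Detrend filter.**  Blackman-windowed sinc FIR, half-width 3× the
  cut-off period, mirror-extended boundaries.  The stated cut-off period
  (220 min) is the *passband edge*: the design frequency is shifted down
  by half the transition width so every period in the 100–220 min analysis
  band passes with unit gain.  Centring the 6-dB point at the cut-off
  instead would attenuate a 210-min oscillation ~50 % and, worse, tilt the
  wavelet response enough to bias its ridge period by several minutes.
* **Wavelet.**  Morlet with ω₀ = 2π, so scale equals Fourier period; per
  scale the amplitude is normalised so a unit sinusoid at a grid period
  has ridge power 1 away from the edges.  The CWT uses zero-extended
  boundaries: mirroring reflects the oscillation back into the analysis
  band and measurably biases edge-adjacent ridge periods.  The cone of
  influence (one e-folding time, √2 × scale, from either end) is computed
  and reported but not masked.
* **Ridge.**  Per-column argmax with ties toward the smaller period; no
  continuity penalty.  The power threshold defaults to 0 (everything
  valid).
* **Wave number conventions.**  Unwrap direction is fixed
  midline → distal; q is reported as a magnitude.  Both choices are gauge
  conventions — q is invariant under a constant phase offset per column,
  which is tested.
* **Distal crop.**  The 20-px crop protects real, growing-domain columns
  from the moving boundary (which spatial smoothing corrupts).  On a
  static noiseless phantom there is no such boundary, and the crop would
  shorten the measured span by c/L (an ~8 % geometric deficit in q for a
  330 μm domain); the wave-number recovery checks therefore run with crop
  0, while the pipeline default stays 20.
* **Degenerate inputs.**  Empty masks, coincident anchors, rays from a
  degenerate COM, all-constant profiles, sub-Nyquist period grids, and
  too-short post-onset recordings raise informative errors; partial
  sampling spheres at the volume border average over in-bounds voxels
  (distal anchors may touch the border).

## Problem sizes

Recovery tests run on kymograph-level phantoms (431 rows × 121 frames,
10-min interval, ≈4 s per phantom through the full wavelet chain).  The
end-to-end volume run uses 168×128×128 voxels × 75 frames (~42 s on one
CPU): the lateral extent holds the 230-μm-wide shell at 2.088 μm voxels,
and the recording is long enough that the 2–6 h period-sampling window
stays clear of the wavelet cone of influence at the slowest analysis
periods — with materially shorter recordings the distal median becomes an
edge-effect lottery.  Real recordings in this regime are many hours long,
so the window is deep interior there as well.

## Known limitations

* The pairwise registration estimator is translation-only; rotational
  drift must be handled by the operator-supplied alignment angles (as in
  the protocol, where reorientation angles are manual).
* Ridge tracing has no continuity constraint; for signals with two
  near-equal spectral components the ridge may hop between them.
* The phase convention ties phase 0 to an intensity maximum; reporter
  maturation delays between transcription and fluorescence are not
  modelled.
* `q` from unwrapped phases assumes adjacent-pixel phase steps below π;
  gradients steeper than half a cycle per pixel would alias.
* Period estimates within ~√2 scales of the recording ends are edge
  -affected; the cone of influence quantifies this but nothing is masked
  by default.
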