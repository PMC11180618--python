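# Methods

This note records the models, numerical choices and limitations behind
each stage of the pipeline, in the order data flows through it.

## Input model

A recording is a stack of grayscale frames, intensities in [0, 255],
row 0 at the top, column 0 at the left, all intervals half-open.
Calibration defaults describe the reference acquisition: 5 frames/s,
110.85 px/mm, with the oviductal end of the horn on the image's left
(`orientation` flips the map's spatial axis otherwise, so a positive
band slope always reads "toward the cervix"). Incoming videos are
assumed contrast-adjusted with the organ bright on a dark background;
the package does not re-threshold. Colour input is collapsed to
luminance with a warning, because the contraction signal lives in a
single fluorescence channel and channel mixing corrupts it.

## Boundary detection

*Smoothing.* The stack is Gaussian-smoothed along time (window 3) and
along the horn axis (window 5) before edge detection only; raw
intensities feed the later intensity analysis. Rows are deliberately
not smoothed: blurring the vertical edge profile biases the boundary
estimate outward by ~2 px. A window length `k` implies
`sigma = 0.3·((k−1)/2 − 1) + 0.8`, the common automatic-sigma rule, so
results are reproducible from the stated sizes alone.

*Edge evidence.* Separable Sobel responses at aperture 5 (binomial
smoothing × central-difference derivative, the standard construction)
give `S_h` (horizontal edges) and `S_v` (vertical edges); the edge
index is `S_h + 2·S_v`. For the boundary *search* the evidence is
combined as `|S_h| + 2·|S_v|`: the signed sum cancels at whichever
boundary has `S_h` opposing `2·S_v` (the sign of `S_h` flips between
the upper and lower edge), which destroys the weaker edge wherever the
organ also has strong axial gradients; component magnitudes keep the
search exactly equivariant under vertical flips.

*Crossing rule.* Per column, evidence below the frame's noise ceiling
(median + 3×1.4826×MAD of the whole evidence field — sensor noise is
spatially homogeneous, and the ceiling is ~0 on a clean background) is
zeroed; the remainder is normalised by the column mean, so the
threshold θ = 2 reads "two average rows' worth of edge evidence" and
the rule is invariant to global intensity rescaling. The upper
boundary is the first top-down crossing, the lower the symmetric
bottom-up crossing; each is then refined to the parabolic-interpolated
local peak of the evidence, because the raw crossing sits on the
leading shoulder of the spread edge response (a systematic ~2 px
outward bias) while the response peaks at the edge itself. Columns
with no crossing, or whose peak evidence is below `min_edge_snr = 2`
times the noise ceiling, are flagged invalid — in practice the thin,
dim ends of the organ, where the sensor genuinely carries no boundary
information.

*Spline smoothing.* Per frame, only the longest contiguous valid run
(bridging interior gaps up to the knot spacing) is analysed. Before
fitting, the raw boundary is split at column-to-column jumps > 5 px —
an organ boundary drifts smoothly, so sharp steps mark hijacks by
bright stains — and short deviant segments (≤ 2 knot spacings,
median > 5 px from the dominant segment) are discarded. Knots every 10
valid columns carry the median boundary over a ±2-column window and
sit at the window's median column (so affine boundaries are reproduced
exactly); a natural cubic spline is evaluated over the run, followed
by one residual-rejection pass (drop points > max(3 robust sigmas,
2 px) from the fit and refit). Crossing boundaries after splining are
clamped to their midpoint ± 0.5 px. Frames with fewer than four knots
are flagged unusable.

On simulated ground truth (1200×160 px, 300 frames) this yields a mean
absolute boundary error of ~0.7 px noise-free and ~1.1 px at noise
sd 5 with three stain blobs; the documented accuracy targets are ≤ 2
and ≤ 4 px. Known limitation: a stain wider than about two knot
spacings that overlaps the organ's silhouette cannot be rejected — the
boundary under it is simply not observable.

## Spatiotemporal maps

`area[c, t] = lower − upper` (pixels; unit pixel width makes it a
cross-section proxy) and `intensity[c, t]` = mean raw intensity over
rows `ceil(upper)..floor(lower)`. Invalid cells are NaN and stay NaN
through every later step — no value is fabricated. Enhancement is
(1) Sobel gradient magnitude at aperture 5 on the space×time matrix
(magnitude, not a directional derivative, so bands are detected
regardless of travel direction; direction is read later from the
annotated slope), (2) subtraction of a centred 51-column moving
average along space (removes the horn's static thickness/intensity
profile), (3) a centred 5-frame moving average along time. The two
moving averages are the simplest zero-phase filters with the stated
windows; masked cells are filled by nearest-valid interpolation for
the convolutions and re-masked afterwards. The printed order (detect
change, then detrend, then low-pass) is followed as stated.

## Waveform metrics

Velocity is the absolute ridge slope converted to μm/s; speeds below
0.1 μm/s are reported as stationary (manual marking cannot resolve
slower drift). Amplitude is the spatial extent of the wave band in μm
— the only reading that gives μm on both area and intensity maps.
Period is the time between successive crests at a fixed position
(from the annotated next-crest frame), making frequency = 1/period
independent of velocity; wavelength = velocity/frequency then holds as
a definitional identity to machine precision. A wave without an
annotated successor (the last in a window) gets velocity, amplitude
and direction only, and summaries count each metric separately.

Segments: a wave belongs to the third of the spatial axis holding its
ridge midpoint; boundaries at `floor(n/3)` and `floor(2n/3)`,
half-open. Sampling is uniform without replacement per segment,
seeded; 3 per segment reproduces the nine-wave-per-horn protocol.

## Statistics

Mann–Whitney is two-tailed. With no ties and `n_a·n_b ≤ 400` the p
comes from exact enumeration of the U distribution (dynamic program
over rank arrangements). Otherwise the normal approximation is used
with tie and continuity corrections; for untied samples it also
carries an Edgeworth kurtosis term with the exact excess kurtosis of U
(`−(6/5)(m²+n²+mn+m+n)/(mn(N+1))`), which brings the worst exact-vs-
approximate discrepancy for 8 ≤ n ≤ 20 from ~0.011 down to ~0.0004.
Identical pooled values give p = 1 with a degeneracy flag.

ROUT is reduced to the univariate case: the robustly fitted "model" of
a single sample is its median; the robust scale is the RSDR (68.27th
percentile of absolute residuals, corrected by n/(n−1)); residual
t-scores (n−1 df) enter a Benjamini–Hochberg step at rate Q (default
0.01); flagged points are removed and the fit iterated until stable.
Samples below n = 5 and degenerate samples are never trimmed. ROUT is
applied per group, not per pooled metric. On clean Gaussian n = 20
samples it removes nothing in ≥ 97% of runs.

## Embryo positions

All distances use the orthogonal XY projection (the z axis of the 3D
renderings is depth) and are normalised by the supplied horn length,
which is taken as given — whether it was measured along the 3D path or
the projection is upstream of this package. Adjacency for
embryo–embryo distances follows ascending oviduct-distance order, the
only order recoverable from the distances themselves. Thirds are
half-open; negative positions (embryos at the junction) clamp to the
oviductal third and positions slightly above 1 (projection shorter
than the measured path) fall in the cervical third. Horns with fewer
than three embryos raise an exclusion error.

## Simulator

The tube is centred vertically with relaxed half-diameter `r0`; a
raised-cosine bump train (unit peak, compact support = band width,
period = wave spacing) travels at the configured speed. Circular mode:
`r = r0·(1 − a·w)` with interior intensity `I0·(r0/r)^γ`, so γ = 1
conserves the per-column fluorophore proxy (intensity × diameter)
exactly. Longitudinal mode: fixed diameter, intensity `I0·(1 + a·w)^γ`
— the case area maps cannot see. Horn ends taper smoothly to 25% of
radius and brightness over `taper_fraction` of the width, reproducing
the thin low-gradient ends real recordings have; pixels at the tube
wall use a ±1.5 px linear coverage ramp; static bright Gaussian blobs
outside the tube emulate petri-dish stains; Gaussian noise is added
per pixel per frame and frames are quantised to 8 bits. All randomness
derives from one seed; identical parameters give bit-identical stacks.

Defaults are the reference acquisition (1200×160 px, 300 s at 5 fps,
110.85 px/mm) with waves at the scale reported for the most
contractile stage: 12.8 μm/s speed, 800 μm spacing, 190 μm band width,
30% constriction. Truth annotations lie exactly on crest trajectories;
an optional jitter parameter adds Gaussian scatter to the marked
columns to emulate manual placement.

What the simulator does *not* emulate: real myometrial mechanics
(waves here are kinematic, constant-speed, equally spaced), wave
birth/death and collisions, horn curvature and pinning artefacts,
photobleaching, or intensity heterogeneity across the tube
cross-section. Passing the validation suite therefore shows the
*computational* chain is correct and noise-robust at realistic scales,
not that the biological assumptions hold for any particular recording.

## Problem sizes and runtime choices

The validation suite runs its full-scale checks at 1200×160 px ×
300 frames (boundary accuracy) and 600×140 × 200–300 frames (map
discrimination, end-to-end recovery); statistical oracles use 1000
replicates. These sizes make the whole suite and the acceptance script
each complete in well under a minute on one CPU while keeping every
per-frame computation identical to a full 1500-frame analysis, which
scales linearly in frame count.
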