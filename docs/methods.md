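# Methods

## Signal model and processing chain

An acquisition is a stack of complex-valued B-scans in two polarization
channels, ordered slow-major: at each of `n_slow_positions` locations,
`n_repeats` B-scans are recorded back to back. The frame interval is
`n_fast / (ascan_rate × duty_cycle)`; with the full protocol (512 A-scans at
80 kHz, no fly-back) that is 6.4 ms. Axial motion of scattering tissue
between two frames advances the interferometric phase by

    ΔΦ = 4 π n Δd / λ₀

with λ₀ the center wavelength (840 nm) and n the tissue refractive index
(1.35), so one phase cycle corresponds to λ₀/(2n) ≈ 311 nm of optical path
and the largest unambiguous per-pair displacement is λ₀/(4n) ≈ 156 nm.

The chain is:

1. **Surface segmentation.** The ILM is the shallowest qualifying rising edge
   in the co-polarized intensity; the upper RPE edge is found the same way in
   the cross-polarized channel, where the depolarizing RPE is the only strong
   band. The IS/OS junction is the intensity argmax in a 15-pixel slab
   directly above the RPE (`[rpe−15, rpe−1]`, shallowest tie wins).
2. **Phasor differencing.** Hermitian products C₂·conj(C₁) of consecutive
   repeats, box-smoothed over 10 px axially × 20 px laterally. The argument
   of the smoothed product is the amplitude-weighted circular mean of the raw
   phase differences — smoothing wrapped phase values directly would corrupt
   estimates near ±π.
3. **Bulk referencing.** The amplitude-weighted mean phasor over rows
   `[rpe, rpe+4)` of the *unsmoothed* products is divided out per A-scan and
   pair. Placing the window at and below the upper RPE edge matters: the
   smoothed products at the edge itself blend in pulsating tissue from up to
   half a kernel above the RPE, and that leak biases every compensated phase
   in the A-scan (observed as a ~12% MAV deficit at the ILM and ~30% at the
   IS/OS before the window was moved into the band).
4. **Displacement and heart rate.** Phase converts to nm by the relation
   above. The per-pair mean phase at the ILM (±2 px, phasor-weighted) forms a
   time series on the uniform frame grid (pairs never straddle slow
   positions; the missing slot at each block boundary contributes zero after
   linear detrending). Its zero-padded magnitude spectrum is searched in
   4–12 Hz (240–720 bpm, covering the murine range under all three
   anesthetics) and the peak is refined by local quadratic interpolation. A
   peak below 3× the median in-band magnitude is flagged low-confidence.
5. **MAV.** Mean |Δd| over the pairs spanning one heart cycle, divided by the
   frame interval (nm/ms). A repeat block holds only `n_repeats − 1` pairs
   (25.6 ms at protocol timing), far less than a ~125 ms heart cycle, so
   pairs are pooled from adjacent slow positions until a cycle is covered;
   pulsation is treated as laterally smooth at that scale. Maps are sampled
   en face at a surface as the mean over a ±2 px depth window, after an
   intensity mask keeping only pixels in `[ILM−10, RPE]` with intensity
   ≥ 0.95× the B-scan mean.
6. **Thickness.** RT = (RPE − ILM) × axial pitch per A-scan, summarized over
   an annulus (inner 0.2 mm, outer 0.4 mm, both inclusive, membership tested
   at pixel centers with explicit per-axis mm/px scales — the 1 mm field is
   sampled anisotropically, 400 × 512). The ONH center is a required input,
   matching manual annotation practice; `suggest_onh_center` proposes the
   centroid of the lowest-thickness depression but never overrides the input.
   Variants: full annulus, excluding vessel pixels, restricted to vessel
   pixels. The two variant means recombine count-weighted to the full mean
   exactly; ΔRT = RT − RT₋SVP.
7. **Angiography.** Per pair, |C₂ − C₁·e^{iφ_b}| with the bulk phase φ_b from
   the RPE band; static tissue cancels, decorrelated (flowing) pixels do not.
   The en-face map averages a slab from the ILM to 30 µm below it (the
   superficial plexus; the slab depth is configurable since no canonical
   value exists). The noise floor is the median tomogram value in the
   vitreous (above ILM−10 px), a pure-noise, vessel-independent statistic;
   the vessel mask is en-face signal ≥ 20× that floor. Thresholding the
   projection (not per-voxel) was chosen for robustness of the floor
   estimate; the 20× rule is scale-invariant. Density is the vessel-pixel
   percentage of valid annulus pixels.
8. **Statistics.** OLS with R² = 1 − SS_res/SS_tot; Bland–Altman with
   1.96 × sample-SD limits (not t-quantiles); per-subject OLS slopes over
   minutes averaged unweighted within sex × anesthetic; pooled group
   mean ± sample SD per cell (single-record cells report SD 0; empty cells
   are absent, not zero). Mixed-effects inference is deliberately excluded:
   the tidy long-format table (`subject, sex, anesthetic, minutes, parameter,
   value`) is shaped for off-the-shelf mixed-model software. Grouping labels
   never enter image computation; they join the table in batch mode only.

## The phantom

The generator emulates the acquisition rather than the instrument: no
spectral raw data, k-linearization or dispersion — volumes start life as
complex tomograms.

* **Structure.** Three surfaces over a uniform tissue band. Co-channel
  amplitude: band ×1, half-Gaussian boosts (σ = 1.2 px) at the ILM and IS/OS
  (peak 2.5×), and a 4-px boxcar RPE band (2×) with a sharp upper edge.
  Cross-channel = 5% of co everywhere except 80% in the RPE band — the
  simplest depolarization contrast that makes dual-channel segmentation
  meaningful. Sharp upper edges make noiseless segmentation pixel-exact,
  which the exactness tests rely on.
* **Motion.** d(z, t) = A·p(z)·sin(2πf t): amplitude decays piecewise
  linearly from 1 at the ILM to a configurable fraction (default 0.5) at the
  IS/OS and 0 at the RPE. Defaults: A = 50 nm at the ILM, f from 480 bpm.
  At protocol timing the largest per-pair displacement is then ~16 nm
  (ΔΦ ≈ 0.32 rad), safely below the wrapping limit; the truth record carries
  the full displacement series per surface and its brute-force MAV.
* **Bulk motion** is one global phase per frame, N(0, σ) with σ configurable
  (default 0 in the constructor; recovery studies use 0.3 rad) — sufficient
  to exercise the RPE-referencing contract.
* **Vessels** are en-face disks: voxels from the ILM to 30 µm below get 2×
  amplitude (blood backscatter) and a per-frame uniform random phase scaled
  by a decorrelation level (default 1), plus a local ILM elevation
  (thickness bump, default 3 µm) producing the thicker retina over vessels.
* **Noise** is circular complex Gaussian with E|noise|² = 1; tissue amplitude
  is 10^(SNR_dB/20) (default 25 dB). Measured band-over-vitreous intensity
  SNR calibrates within 0.1 dB.
* **Determinism.** One `numpy` Generator seeded from the config; identical
  config ⇒ bit-identical volume and truth.

What the phantom does **not** emulate: speckle spatial correlation (each
voxel's phase is independent), vessel shadowing below the lumen, projection
artifacts in OCTA, eye drift/saccades beyond global phase, A-scan-to-A-scan
bulk variation, and respiratory motion. Passing recovery tests therefore
demonstrates correctness of the processing contracts, not performance on
animal data.

## Parameters that matter

| Parameter | Default | Units | Why |
| --- | --- | --- | --- |
| λ₀ | 840 | nm | light-source center wavelength |
| n | 1.35 | – | retinal refractive index |
| phasor kernel | 10 × 20 | px | axial × lateral smoothing of Hermitian products |
| RPE baseline window | `[rpe, rpe+4)` | px | static depolarizing band; see above |
| IS/OS slab | 15 | px | search depth above the RPE |
| axial pitch | 1.55 | µm/px | puts a ~200 µm retina at ~129 px, keeping the 15-px slab anatomically sensible; the true pitch is instrument-specific and configurable |
| HR band | 4–12 | Hz | 240–720 bpm |
| intensity mask | [ILM−10, RPE], ≥0.95× mean | – | excludes noisy low-signal MAV pixels |
| annulus | 0.2 / 0.4 | mm | peripapillary evaluation region |
| OCTA slab | 30 | µm | superficial-plexus projection depth |
| SVP threshold | 20× noise floor | – | vessel/background separation |
| surface sampling window | ±2 | px | en-face sampling at a named surface |

## Numerical choices

* Hermitian products are formed from separately rounded real multiplies in
  float64: numpy's fused complex multiply leaves ~1 ulp imaginary residue
  even for bit-identical frames, which would break the exact-zero contract of
  static inputs. After box smoothing, products below 1e−12 of the per-scan
  maximum are zeroed — the filter's cancellation residues otherwise acquire
  meaningless arguments (including exactly π).
* Displacement arrays are float64 throughout; the conversion is a single
  multiplication, matching a scalar evaluation to ≲1e−15 relative.
* Edge detection thresholds adaptively (mean + 2 SD of the vitreous-region
  log-gradient) and gates candidates on leading into structure brighter than
  both 25% of the B-scan's 98th percentile and 5× the vitreous median, so an
  all-noise B-scan yields no surfaces instead of spurious ones. Surfaces are
  localized by the largest raw-intensity step inside the candidate window
  (pixel-exact on clean data), then median-filtered (width 9) laterally.
  A-scans with total signal under 20% of the B-scan median (vessel shadows)
  are interpolated from lateral neighbors and flagged, not segmented.
* Per-pair displacement beyond λ₀/(4n) aliases; the converter flags the
  result `saturated` (and warns) when >1% of signal-bearing pixels sit within
  10% of ±π rather than returning silently wrong MAV.
* Ties in the IS/OS slab resolve to the shallowest maximum; annulus radii are
  both inclusive; depth index 0 is the shallowest pixel and "above the RPE"
  means smaller indices; positive Δd is motion toward the instrument.

## Problem sizes

Evaluation and test phantoms keep the temporal protocol exact — 5 repeats per
location and the 6.4 ms frame interval of 512 A-scans at 80 kHz, encoded via
the duty cycle — while reducing raster density to 160 axial × 32–64 lateral
voxels and 8–400 slow positions depending on what a study measures.
Heart-rate recovery uses the full 400 slow positions (12.8 s records, the
quantity is set by record length); segmentation and vessel studies use
shorter stacks (their metrics are per-B-scan). A full-scale volume
(400 × 5 × 1024 × 512, two complex64 channels) is ~16 GB and is neither
generated nor loaded whole here; chunked/streaming I/O would be the natural
extension.

## Known limitations

* The complex-OCTA statistic (bulk-corrected inter-repeat difference
  magnitude) is a declared stand-in with the canonical 20×-noise-floor
  threshold semantics; published variants differ in normalization and would
  change absolute densities (not the threshold rule's behavior).
* MAV near the IS/OS is biased low by a few percent: the 10-px axial kernel
  averages across the steep amplitude ramp between IS/OS and RPE. The effect
  is inherent to fixed-kernel phasor smoothing near the reference layer.
* Whether heart-rate spectroscopy should use compensated or raw phase at the
  ILM is an open choice; compensated is used (bulk jitter otherwise floods
  the spectrum at low SNR).
* The per-cell "mean ± SD" pools all time points and subjects; averaging
  per-subject means first is a defensible alternative and would shrink SDs.
* Respiratory-rate extraction is out of scope: volumetric scans revisit a
  location too slowly to sample breathing reliably.
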