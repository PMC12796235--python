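# Methods

## Scan model and indexing

An MS-OPUS scan holds two strictly timestamped streams: ultrasound images
`I_US^(j)` (j = 1..N_US) and single-wavelength optoacoustic images
`I_OA^(k)` (k = 1..N_OA) whose wavelengths cycle through a preset Λ with
period N_Λ. MS frames are *sliding*: one starts at every OA image, so there
are N_MS = N_OA − N_Λ + 1 frames and consecutive frames overlap in N_Λ − 1
OA images; within a frame the OA images are reordered by ascending
wavelength before spectral analysis. Frame k is associated with the US
indices s whose timestamps fall in the closed interval
[t_OA(k), t_OA(k + N_Λ − 1)]; membership is evaluated in double precision
with no tolerance. All public file formats (annotation JSON) use the 1-based
inclusive conventions common in the imaging literature; everything internal
is 0-based half-open, with the closed-interval US membership kept as
defined. Timestamps are float64 seconds.

Frames spanning fewer than two US images cannot be scored; they carry a
missing (NaN) value, are excluded from selection and evaluation, and are
never silently zeroed. The intended remedy for wavelength presets so short
that this happens routinely is combining several MS frames for scoring; the
package does not do this implicitly.

## Dissimilarity measures

Four measures ship in the registry; all are symmetric with d(a, a) at the
range minimum:

* `l2` — Euclidean norm of the pixel difference; unbounded, scale-sensitive.
* `xcorr` — negated mean elementwise product −(Σ a·b)/p. Deliberately
  unnormalized; it ranks poorly as a motion proxy and serves as a baseline.
* `znxc` — 1 minus the Pearson correlation of the flattened pixels (zero
  displacement), in [0, 2]. Degenerate cases carry no correlation
  information: both images constant → 0, exactly one constant → 1 (a
  neutral value).
* `ssim` — 1 minus mean structural similarity, in [0, 2]. Gaussian window
  of size 11 with σ = 1.5, stabilizers C1 = (0.01 L)², C2 = (0.03 L)²,
  sample-free covariance normalization. The dynamic range L defaults to the
  per-pair max − min; it can be pinned for cross-pair comparability.
  Windowed SSIM is only approximately invariant to adding one constant to
  both images, because its luminance terms use local means.

Correlation is evaluated at zero displacement only (whole-frame
comparison): the dissimilarity matrix consumes global frame similarity, not
a template search. Learned optical-flow dissimilarities are supported only
as user-registered `Measure` plug-ins; no network is bundled.

## Motion score

For each measure the banded matrix `D_ij = d(I_US^(j), I_US^(j+i))` is
computed for lags i ≤ K, K = max_k |s^(k)| (an MS frame never needs longer
lags). Rows are normalized scan-wide, not per frame:

* **rank**: 0-based fractional rank within the row with average ties,
  divided by N_US − i − 1, so a full row spans exactly [0, 1] and any
  strictly monotone transform of the measure leaves the result unchanged.
  Single-entry rows map to 0. Constant rows map to 0.5 (every element is
  the average tie), which is why a perfectly stationary scan scores
  0.5·(|s| − 1)/|s| rather than 0 — ranks encode relative, not absolute,
  motion.
* **minmax**: (x − min)/(max − min) per row; constant rows map to 0. Kept
  as the *normalized* variant; more outlier-sensitive than ranking.

The per-frame score averages all within-frame US pairs across the measure
set Δ with the 2/(|Δ| |s|²) prefactor, giving range [0, (|s|−1)/|s|]. The
default configuration is the validated one: ranked variant with
Δ = {znxc, ssim}. The naive baseline is implemented exactly as defined —
divisor |s| over |s| − 1 consecutive-pair terms, even though 1/(|s|−1)
would be the unbiased mean; the printed form is kept deliberately.

## Frame selection

Local minima of the motion vector are found per NaN-free segment with the
standard peak finder (negated input, no prominence/height conditions, so
gaps never fabricate candidates and endpoint frames are never candidates;
plateaus are represented by their midpoints). Minima closer than d_min are
thinned by visiting candidates in ascending score order — equivalent to the
peak finder's own priority-based distance enforcement — with ties broken
toward the earlier frame for determinism. Survivors are sorted ascending
and the first N_peaks returned. Defaults d_min = ⌊N_MS/20⌋ (clamped to
≥ 1) and N_peaks = 5 suit the 28-wavelength preset; both depend on the
scanning protocol and should be adapted with it.

## Evaluation protocol

Human annotators mark stationary US-index intervals; per-US coverage counts
(0..A) are averaged over each frame's US images and thresholded at A/2
(1.5 for three annotators). Maximal runs of stationary frames are target
events. A prediction inside any event is a TP, outside all events an FP; an
event containing no prediction is an FN; TP1 credits at most one prediction
per event. Precision = TP/(TP+FP), recall = TP1/(TP1+FN). Average precision
integrates the precision–recall curve stepwise (Σ ΔR·P, no interpolation)
over prefix sizes of the full distance-respecting minima pool — the
selector can only ever emit such minima, so sweeping them is the exact
attainable operating range. mAP averages per-scan APs; scans with no events
have undefined AP and are excluded with a warning.

## Spectral quality

A frame's pixel-spectra matrix I (p × |Λ|, columns in ascending wavelength)
is unmixed non-negatively, I ≈ C·W. With known spectra the Frobenius
objective separates per pixel and each row of C is an independent NNLS
problem (deterministic active-set solution); wavelength-grid mismatches are
an error, never silently interpolated (an explicit `interpolated_to` step
exists for that). Blind unmixing uses seeded NMF (multiplicative updates,
NNDSVD-based init, tolerance 1e−6, cap 1000 iterations) with k chosen to
match the expected number of absorbers (k = 4 for the clinical chromophore
set). Negative intensities — reconstruction artifacts — are clipped to zero
for NMF only; NNLS consumes them as-is. The quality metric is the relative
L2,1 residual E = Σ_pixels‖residual spectrum‖₂ / Σ_pixels‖measured
spectrum‖₂: 0 for a perfect fit, 1 for C = 0, scale-invariant, undefined
(NaN) for an identically zero frame.

The bundled `chromophores.csv` (Hb, HbO₂, water, lipid at 700–970 nm) is an
approximate compilation from standard literature sources, linearly
interpolated onto a scan's wavelength grid on request; it supports
qualitative decomposition, not metrological quantification.

## Synthetic data generator

The simulator emulates exactly the structure the algorithm relies on and
nothing more:

* **Geometry/timing** — OA at f_OA = 25 Hz cycling a 28-wavelength
  700–970 nm preset; US at f_US = 6.25 Hz with a 0.02 s phase offset;
  both streams sample one rigid 2-D pose trajectory (dx, dy, θ) at their
  own timestamps, like a single physical probe.
* **US images** — a fixed seeded scatterer field smoothed by a small
  point-spread kernel and envelope-detected to non-negative speckle,
  rigidly resampled per pose (bilinear), plus Gaussian noise (σ = 0.02).
* **OA images** — generated exactly under the linear mixing model:
  pose-transformed absorber concentration maps times spectrum value at the
  current wavelength, optional wavelength-independent exponential depth
  decay, plus Gaussian noise (σ = 0.005, may go negative like
  reconstruction artifacts). Stationary noise-free frames therefore unmix
  with E = 0 by construction, and E grows with within-frame displacement.
* **Motion taxonomy** — piecewise segments: stationary (constant pose),
  drift (constant velocity), rotation (constant angular velocity), jitter
  (zero-mean per-timestamp Gaussian displacement), jerk (step displacement,
  the only discontinuity). On top, a correlated hand-tremor
  Ornstein–Uhlenbeck process (σ = 0.2 px, τ = 0.4 s) runs through the whole
  scan: a handheld probe is never pixel-perfect still, and without tremor
  all stationary holds are statistically identical noise floors, which
  makes "pick one frame per hold" a meaningless tie-break rather than the
  measurement it is on real data.
* **Ground truth** — stationary segments define stationary time and
  US-index intervals; frame-level truth applies the identical aggregation
  rule used for human annotations (the simulator acting as one perfect
  annotator on the US stream, threshold A/2): US video is what both the
  annotators and the score can observe at 6.25 Hz.
* **Determinism** — one root seed fans out into independent substreams
  (trajectory, speckle, per-stream noise); equal seeds give bit-identical
  scans.

The default validation corpus is 10 scans of 36 s (within the 35–120 s
range typical of validation acquisitions), each with 2–3 stationary holds
of 2.0–2.6 s separated by drift (velocity 1.5–5 px/s), rotation
(1.5–4 deg/s), jitter (σ 0.6–1.2 px) and brief jerks (0.6 s, 3–8 px).
Motion is parameterized by velocity so that segments labeled "motion" are
actually faster than the tremor floor. Images are 64×64 px to keep a full
corpus run under a minute.

**What passing corpus tests does and does not show.** The simulator uses
rigid in-plane motion, wavelength-independent fluence, stationary Gaussian
noise, and spectra that exactly obey the linear mixing model. Real tissue
adds elastic deformation, out-of-plane motion, spectral coloring and
reconstruction artifacts, so corpus-level precision/recall are statements
about the algorithmic contract (pairwise-lag scoring separates drift from
jitter and recovers deliberate holds), not a clinical performance claim.

## Numerical choices and edge cases

* Timestamp comparisons are exact float64; simulated grids avoid ties by a
  phase offset between streams.
* Rank ties use average fractional ranks so constant rows land mid-range.
* Selection is fully deterministic; score ties order by frame index.
* NNLS per pixel is deterministic; NMF is deterministic given its seed.
* E with a zero-norm frame, precision with no predictions, AP with no
  events: all NaN (undefined), never 0 by fiat.
* Scoring a frame with |s| < 2 warns and yields NaN.

## Known limitations

* Global (whole-image) similarity cannot localize motion; rotation about
  the image center is under-penalized relative to its edge displacement.
* The score is relative within a scan (ranks), so values are not comparable
  across scans and cannot serve as an absolute quality threshold.
* The full banded matrix requires the complete scan; the method is
  post-processing by construction and unsuitable for live operator
  feedback.
* No learned optical-flow measure is bundled; the registry hook exists.
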