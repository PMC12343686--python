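# Methods

## Recovery model

Fluorescence recovery into a bleached spot on an FtsZ ring or filament is
modelled as exchange from two bound states:

    f(t) = (1 − r)(1 − C_eq1 e^(−koff1 t) − C_eq2 e^(−koff2 t)),   t ≥ 0

`C_eq1`, `C_eq2` ∈ [0, 1] with `C_eq1 + C_eq2 ≤ 1` are the equilibrium
fractions of molecules in the fast- and slow-exchanging bound states,
`koff1 ≥ koff2 > 0` (s⁻¹) their dissociation rate constants, and
`0 ≤ r < 1` the incomplete-recovery parameter (`1 − r` is the mobile
fraction). The model assumes binding-dominated kinetics: diffusion of
unbound subunits is fast relative to the 10 s frame interval, so any
unbound fraction `1 − C_eq1 − C_eq2` refills the spot within the first
frame interval and appears as the instantaneous step `f(0+) =
(1 − r)(1 − C_eq1 − C_eq2)`. `f` is non-decreasing and approaches `1 − r`.

Because recovery of these structures is far from complete at the end of
the 260 s observation window, no half-time is defined; the turnover summary
is **R₁₃₀**, the percent of fluorescence recovered at 130 s post-bleach.

## Trace correction and normalization

Each cell contributes three per-frame mean-intensity ROI traces: the
bleached spot, an unbleached reference region on the same kind of
structure, and a signal-free background region. The corrected trace is the
standard double normalization

    F_norm(t) = [(F_bl − F_bg) / (F_ref − F_bg)]
                × [(mean_pre F_ref − mean_pre F_bg) / (mean_pre F_bl − mean_pre F_bg)]

with pre-bleach means over the pre-bleach frames. The reference ratio
cancels acquisition photobleaching exactly when both ROIs lose the same
per-frame fraction; the background subtraction removes additive offset.
Full-scale rescaling then anchors recovery at the bleach floor:

    g(t) = (F_norm(t) − f0) / (1 − f0),   f0 = F_norm at the bleach frame

so `g(0) = 0` and `g` is on the same scale as `f(t)` ("percent of
fluorescence recovered"). Inputs with `F_ref − F_bg ≤ 0` at any frame, or
with `f0 ≥ 1` (no detectable bleach), are rejected rather than silently
producing non-physical traces.

Time is re-indexed so the first post-bleach frame is `t = 0`; the 20 ms
bleach is treated as instantaneous. The default schedule is 3 pre-bleach
frames at −30, −20, −10 s and 27 post-bleach frames at 0, 10, …, 260 s.

**The bleach-frame anchor.** The `t = 0` sample records the raw bleach
floor: the fast free-pool step `f(0+)` completes on the sub-second
diffusion timescale, after the bleach snapshot but before the next frame.
Consequently `g(t) = f(t)` for every frame `t > 0`, while `g(0) = 0` is
fixed by construction and carries no kinetic information. The fit therefore
excludes `t = 0` points by default (`include_anchor=True` restores them).
This also keeps all five parameters identifiable: if the anchor frame were
assumed to lie on the model curve, the normalized data would be exactly
reproduced by a relabelled parameter set with `C_eq1 + C_eq2 = 1`, and the
bound fractions could not be separated from `r`.

## Fitting

The model is fit to the cross-cell averaged `g` (per the figure-caption
convention "curve fitting using averaged recovery data"); per-cell fits
use the same entry point on a single trace. Estimation is unweighted
bounded least squares (`scipy.optimize.least_squares`, trust-region
reflective) in the parametrization

    x = (a, s, log10 koff1, log10 koff2, r),  C_eq1 = a·s, C_eq2 = a·(1 − s)

with box bounds `a, s ∈ [0, 1]` (this makes `C_eq1 + C_eq2 ≤ 1` a box
constraint), `koff ∈ [10⁻⁴, 1] s⁻¹` and `r ∈ [0, 0.99]`. A fixed
multi-start grid — all ordered pairs of koff decades 10⁻⁴…1, amplitude
levels {0.6, 0.95}, splits {0.25, 0.5, 0.75}, r ∈ {0, 0.2, 0.5} — is run at
moderate tolerance and the best solution polished at `xtol = ftol = 1e-15`,
making the fit deterministic given the trace. Labels are swapped after
fitting so `koff1 ≥ koff2`, which prevents label-switching across starts.
Parameter standard errors are the asymptotic values
`√diag(s² (JᵀJ)⁺)` with `s² = SSE/(n − 5)`.

A solution pinned at the bounds whose fitted curve spans less than 10⁻³
is flagged `degenerate` (e.g. a no-recovery trace, where `r` and the
amplitudes are not identifiable). Fewer than 6 usable points is an error.

**Identifiability caveat.** When `koff2 · 260 s ≪ 1` the slow state is
nearly indistinguishable from immobile material within the observation
window, and `koff2`, `C_eq2` and `r` trade off; the reported SEs grow
accordingly. R₁₃₀ and the fitted curve remain well determined. This is a
property of the protocol length, not of the optimizer.

## R₁₃₀

Two estimates are reported side by side:

* **empirical** (default headline): each cell's `g` at the frame nearest
  130 s (exactly `t = 130 s` on the default grid), averaged across cells,
  ×100, with the standard error across cells — matching the
  "mean ± SE, n cells" convention;
* **model**: `100 · f(130)` from the averaged-data fit.

If no frame lies within one frame interval of 130 s the request is
rejected rather than extrapolated.

## Condition comparison

Per-cell R₁₃₀ values are compared pairwise with a two-sided Welch
unequal-variance t test (the natural contrast for mean ± SE summaries with
per-condition n). For small n, a permutation test of the absolute mean
difference is available: exact enumeration of all C(n_a+n_b, n_a) splits
when that count is ≤ 10⁵, otherwise seeded Monte-Carlo with the add-one
correction (so p ≥ 1/(n_perm+1)). Benjamini–Hochberg adjustment is applied
across the full contrast table. Both-samples-zero-variance contrasts return
p = 1 with a flag.

## GTPase assay

In the coupled regeneration assay each hydrolyzed GTP is regenerated at
the expense of one NAD(P)H, so A₃₄₀ declines at
`slope = −rate · [FtsZ] · ε · l`. The module fits an OLS slope over a
user window, or auto-selects the contiguous window of ≥ 10 points
maximizing r² (ties: earliest start, then longer window; r² is compared at
1e-9 resolution so float noise cannot break ties; a zero-variance window
counts as a perfect zero-slope fit). The turnover rate is
`max(0, −slope)/(ε·l)/[FtsZ]` in GTP FtsZ⁻¹ min⁻¹; a positive slope is
non-physical for this assay and is clamped to 0 with a warning. Defaults:
ε = 6220 M⁻¹cm⁻¹ at 340 nm, path 1 cm — microplate geometries need a
user-supplied effective path. The chromophore is treated generically as
NAD(P)H at 340 nm (assay buffers typically supply NADH; some protocol
descriptions say NADPH — the optics and stoichiometry are the same).
Auto-windowing is a convention of this package; published protocols rarely
state their windows.

## Synthetic data generator

The generator emulates the acquisition protocol — 3 pre-bleach frames at
10 s, instantaneous bleach of a 20 px spot, 260 s of monitoring at 10 s —
with condition-level kinetics and per-cell variation. Construction, with
`P` the pre-bleach plateau, `d ∈ (0,1]` the bleach depth, `q ≥ 0` the
per-frame acquisition-bleach fraction, `k` the acquired-frame index:

* bleach ROI: `P·[1 − d(1 − f(t))]·(1−q)^k + B` (pre-bleach frames at
  `P·(1−q)^k + B`; the bleach frame at the raw floor `P(1−d)·(1−q)^k + B`,
  see the anchor discussion above);
* reference ROI: `P·(1−q)^k + B` — shares acquisition bleaching but not
  the spot bleach, which is what makes the reference correction meaningful;
* background ROI: `B`;
* independent additive Gaussian noise per frame and ROI (detector-dominated
  regime; shot noise, triplet photophysics, diffusion during the bleach and
  3-D optics are deliberately out of scope).

With these distortions and zero noise, `correct_and_normalize` restores
`f(t)` to float precision — the correction is the exact inverse of the
construction, which is what the round-trip tests verify.

**Per-cell variation.** Rate constants get mean-preserving log-normal
jitter (`σ² = ln(1+cv²)` with `−σ²/2` drift). Bounded fractions get
logit-normal jitter applied to the total bound fraction and to the split
between states, so `C_eq1 + C_eq2 ≤ 1` holds for every cell by
construction; the logit-scale spread is `cv/max(p, 1−p)`, i.e. the
relative spread applies to the distance from the nearer boundary
(sd ≈ cv·min(p, 1−p)), which keeps draws physical at both bounds with
O(cv²) mean bias. Values exactly at a boundary (e.g. a total bound
fraction of 1) carry no jitter. Labels are re-swapped if the koff draws
cross.

**Defaults as study conditions.** The default condition
(`C_eq1 = 0.15, C_eq2 = 0.85, koff1 = 0.01 s⁻¹, koff2 = 2×10⁻⁴ s⁻¹,
r = 0.1`) gives R₁₃₀ ≈ 12%, typical of a slow membrane-tethered ring and
inside the 8.7–46% range such reconstitution experiments report;
`n_cells = 12` matches typical per-condition cell counts,
`bleach_depth = 0.85` a deep but incomplete spot bleach,
`acq_bleach_per_frame = 0.002` mild acquisition bleaching,
`cell_cv = 0.15` a moderate between-cell spread, and, on a pre-bleach
plateau of 1 AU, `noise_sd = 0.02` (2% of signal) and
`background_level = 0.1`. Published FRAP studies of this kind do not state
their achieved bleach depth or noise level, so these are realistic
placeholders, not estimates of any specific dataset.

**Rendering.** `render_frap_stack` draws each experiment as a 16-bit
time-lapse: a bright annulus (ring) or ±80° arc (filament) of width 26 px
at radius 0.3 × image size, carrying the bleach trace inside the 20 px
bleach ROI and the reference trace elsewhere, Gaussian-blurred (PSF σ = 1
px), scaled by a gain (default 8000 counts/AU) and quantized. The emitted
ROI records (bleach on the structure, reference across the ring or at 50°
along the arc, background in a corner) are consistent with the content.
Because the PSF mixing is time-invariant and linear, double normalization
cancels it exactly; the noiseless render→extract→normalize round trip is
limited only by uint16 quantization (≲0.1 percentage point on R₁₃₀ at the
default gain).

The GTPase generator produces `A₃₄₀(t) = A₀ − rate·[FtsZ]·ε·l·t_min`,
linear until the NADH pool (default 0.4 mM) is exhausted and flat after,
plus optional Gaussian reading noise.

**What passing tests do and do not show.** The generator shares the
estimator's model family, so round-trip accuracy demonstrates correctness
of the arithmetic and the estimators' statistical behavior under the
stated noise model — not robustness to focus drift, structure movement,
reference-region heterogeneity, shot noise, or model misspecification,
none of which are simulated.

## Numerical conventions and problem sizes

* ROI membership: a pixel belongs to a circular ROI iff its center lies
  within diameter/2 (0-based pixel-center coordinates, pixel (i,j) has
  center (x=j, y=i)); no partial-pixel weighting. Mean (not summed)
  intensity, so ROI size differences do not rescale traces.
* Cross-cell averaging requires a shared post-bleach time grid (tolerance
  1e-9 s); resampling is out of scope.
* Validation work in the test suite uses sizes chosen to estimate each
  property well: 200 replicates for stochastic R₁₃₀ recovery, 1000 null
  replicates for the Welch type-I rate, 150 replicates per effect size for
  power monotonicity, ~10⁶-point grids for the fit-vs-exhaustive-search
  comparison, 100 random ROIs against whole-image enumeration.
* Statistical comparisons across pipeline variants are seeded everywhere;
  identical inputs (including seeds) give bitwise-identical outputs, and
  the CLI manifest (config echo + versions + derived seeds) suffices to
  reproduce any table.

## Known limitations

* `koff2`/`r` confounding for very slow states within a 260 s window (see
  above); extending `post_duration_s` in simulations resolves it.
* The double-normalization formula assumes the reference ROI bleaches at
  the acquisition rate only; a reference placed on a structure that itself
  exchanges with a bleached pool would bias the correction.
* The per-cell R₁₃₀ Welch test treats cells as independent units; no
  hierarchical (cell-within-experiment) structure is modelled.
* Rendering is 2-D with a Gaussian PSF and uniform gain; it is a test
  harness for the extraction path, not a microscope model.
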