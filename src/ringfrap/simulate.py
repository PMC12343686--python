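"""Synthetic FRAP acquisitions and GTPase absorbance traces with ground truth.

Emulates a confocal spot-bleach protocol on fluorescently tagged FtsZ
rings/filaments reconstituted in yeast: three pre-bleach frames at 10 s
intervals, an instantaneous bleach of a 20-pixel-diameter circular spot,
then post-bleach monitoring at 10 s intervals out to 260 s.  Recovery in
the bleached spot follows the two-binding-state exchange model; a
reference ROI shares the per-frame acquisition photobleaching but not the
spot bleach, and a background ROI carries only the additive offset.
Detector noise is additive Gaussian (shot noise is out of scope).

Every generator is fully determined by the config seed, so downstream
stages can be tested against known ground truth without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .frap import two_state_model
from .imaging import FrapExperiment, RoiSpec

_PARAM_STREAM = 101
_NOISE_STREAM = 202


@dataclass
class SimulationConfig:
    """Condition-level parameters of a synthetic FRAP experiment.

    Kinetic parameters are the condition means; per-cell values are
    jittered around them with relative spread ``cell_cv`` (log-normal on
    the rate constants, logit-normal on the bounded fractions).
    ``prebleach_level`` sets the pre-bleach ROI intensity plateau in
    arbitrary detector units; ``noise_sd`` and ``background_level`` are on
    the same scale.
    """

    n_cells: int = 12
    c_eq1: float = 0.15
    c_eq2: float = 0.85
    koff1: float = 0.01
    koff2: float = 2e-4
    r: float = 0.1
    bleach_depth: float = 0.85
    frame_interval_s: float = 10.0
    n_prebleach: int = 3
    post_duration_s: float = 260.0
    acq_bleach_per_frame: float = 0.002
    background_level: float = 0.1
    noise_sd: float = 0.02
    cell_cv: float = 0.15
    prebleach_level: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _finite(name, v):
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

        for name in ("c_eq1", "c_eq2", "r"):
            v = getattr(self, name)
            _finite(name, v)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.c_eq1 + self.c_eq2 > 1 + 1e-12:
            raise ValueError(
                f"c_eq1 + c_eq2 must be <= 1, got {self.c_eq1 + self.c_eq2}"
            )
        for name in ("koff1", "koff2"):
            v = getattr(self, name)
            _finite(name, v)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.koff1 < self.koff2:
            raise ValueError(
                f"koff1 must be >= koff2, got {self.koff1} < {self.koff2}"
            )
        _finite("bleach_depth", self.bleach_depth)
        if not 0 < self.bleach_depth <= 1:
            raise ValueError(
                f"bleach_depth must lie in (0, 1], got {self.bleach_depth}"
            )
        for name in ("n_cells", "n_prebleach"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")
        for name in ("frame_interval_s", "post_duration_s", "prebleach_level"):
            v = getattr(self, name)
            _finite(name, v)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("acq_bleach_per_frame", "background_level", "noise_sd",
                     "cell_cv"):
            v = getattr(self, name)
            _finite(name, v)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.acq_bleach_per_frame >= 1:
            raise ValueError(
                "acq_bleach_per_frame must be < 1, got "
                f"{self.acq_bleach_per_frame}"
            )


@dataclass
class GroundTruth:
    """Realized per-cell kinetic parameters plus the condition means."""

    cell_id: str
    c_eq1: float
    c_eq2: float
    koff1: float
    koff2: float
    r: float
    cond_c_eq1: float
    cond_c_eq2: float
    cond_koff1: float
    cond_koff2: float
    cond_r: float
    seed: int


def frame_schedule(config: SimulationConfig) -> np.ndarray:
    """Frame times: n_prebleach at -(nΔ)..-Δ s, then 0, Δ, ..., post_duration."""
    dt = config.frame_interval_s
    pre = -dt * np.arange(config.n_prebleach, 0, -1)
    n_post = int(np.floor(config.post_duration_s / dt + 1e-9)) + 1
    post = dt * np.arange(n_post)
    return np.concatenate([pre, post])


def _logit_normal(rng, p: float, cv: float) -> float:
    """Jitter a fraction in (0,1) on the logit scale.

    The spread is relative to the distance from the nearer boundary,
    sd ~= cv * min(p, 1-p) (delta method: sd(sigmoid) ~= sigma * p * (1-p)),
    so the draw respects both bounds and the mean bias stays O(cv^2).
    """
    if p <= 0 or p >= 1:
        return p  # boundary values carry no jitter
    sigma = cv / max(p, 1.0 - p)
    z = rng.standard_normal()
    logit = np.log(p / (1.0 - p)) + sigma * z
    return float(1.0 / (1.0 + np.exp(-logit)))


def _log_normal(rng, k: float, cv: float) -> float:
    """Mean-preserving multiplicative log-normal jitter on a rate constant."""
    sigma = np.sqrt(np.log1p(cv**2))
    return float(k * np.exp(sigma * rng.standard_normal() - sigma**2 / 2.0))


def realize_cell_params(config: SimulationConfig, cell_index: int) -> GroundTruth:
    """Draw one cell's kinetic parameters; deterministic in (seed, cell).

    Rate constants get mean-preserving log-normal jitter; the bounded
    fractions get logit-normal jitter applied to the *total* bound fraction
    c_eq1 + c_eq2 and the *split* c_eq1/(c_eq1 + c_eq2), so the invariant
    c_eq1 + c_eq2 <= 1 holds for every cell by construction (jittering the
    two fractions independently would force a repair step that biases the
    realized means whenever the total sits near 1).
    """
    rng = np.random.default_rng(
        [config.seed % (2**31), int(cell_index), _PARAM_STREAM]
    )
    cv = config.cell_cv
    if cv == 0:
        c1, c2, k1, k2, r = (
            config.c_eq1, config.c_eq2, config.koff1, config.koff2, config.r
        )
    else:
        total0 = config.c_eq1 + config.c_eq2
        split0 = config.c_eq1 / total0 if total0 > 0 else 0.0
        total = _logit_normal(rng, total0, cv)
        split = _logit_normal(rng, split0, cv)
        c1, c2 = total * split, total * (1.0 - split)
        k1 = _log_normal(rng, config.koff1, cv)
        k2 = _log_normal(rng, config.koff2, cv)
        r = _logit_normal(rng, config.r, cv)
        if k1 < k2:
            k1, k2 = k2, k1
    return GroundTruth(
        cell_id=f"cell{cell_index:03d}",
        c_eq1=c1, c_eq2=c2, koff1=k1, koff2=k2, r=r,
        cond_c_eq1=config.c_eq1, cond_c_eq2=config.c_eq2,
        cond_koff1=config.koff1, cond_koff2=config.koff2, cond_r=config.r,
        seed=config.seed,
    )


def simulate_frap_trace(
    config: SimulationConfig, cell_index: int
) -> Tuple[FrapExperiment, GroundTruth]:
    """Simulate one cell's raw bleach/reference/background ROI traces.

    Construction (before noise), with P the pre-bleach level, d the bleach
    depth, q the per-frame acquisition-bleach fraction and k the 0-based
    acquired-frame index:

      bleach ROI:    P * [1 - d * (1 - f(t))] * (1-q)^k + background
                     (pre-bleach frames use the constant P instead)
      reference ROI: P * (1-q)^k + background
      background ROI: background

    The bleach-frame sample (t = 0) records the raw floor P * (1 - d): the
    model's instantaneous component f(0+) = (1-r)(1-c_eq1-c_eq2) — refilling
    by the unbound pool — equilibrates in well under a frame interval but
    after the 20 ms bleach snapshot, so the first acquired frame precedes
    it.  For c_eq1 + c_eq2 = 1 this coincides with the formula above at
    every frame.  Gaussian noise (sd ``noise_sd``) is added independently
    per frame and ROI.  Identical (config, cell_index) always yields
    identical traces.
    """
    config.validate()
    truth = realize_cell_params(config, cell_index)
    times = frame_schedule(config)
    n_frames = len(times)
    i0 = config.n_prebleach

    t_post = times[i0:]
    f = two_state_model(
        t_post, truth.c_eq1, truth.c_eq2, truth.koff1, truth.koff2, truth.r
    )
    P = config.prebleach_level
    d = config.bleach_depth
    bleach = np.empty(n_frames)
    bleach[:i0] = P
    bleach[i0:] = P * (1.0 - d * (1.0 - f))
    bleach[i0] = P * (1.0 - d)  # bleach frame: raw floor, pre fast recovery
    reference = np.full(n_frames, P)

    acq = (1.0 - config.acq_bleach_per_frame) ** np.arange(n_frames)
    bleach = bleach * acq
    reference = reference * acq
    background = np.zeros(n_frames)

    traces = {
        "bleach": bleach + config.background_level,
        "reference": reference + config.background_level,
        "background": background + config.background_level,
    }
    if config.noise_sd > 0:
        rng = np.random.default_rng(
            [config.seed % (2**31), int(cell_index), _NOISE_STREAM]
        )
        for role in ("bleach", "reference", "background"):
            traces[role] = traces[role] + config.noise_sd * rng.standard_normal(
                n_frames
            )
    exp = FrapExperiment(
        cell_id=truth.cell_id,
        times_s=times,
        intensities=traces,
        bleach_frame_index=i0,
        n_prebleach=i0,
    )
    return exp, truth


def simulate_condition(
    config: SimulationConfig,
) -> Tuple[List[FrapExperiment], pd.DataFrame]:
    """Simulate all cells of a condition; returns experiments + truth table."""
    exps, truths = [], []
    for i in range(config.n_cells):
        exp, truth = simulate_frap_trace(config, i)
        exps.append(exp)
        truths.append(asdict(truth))
    return exps, pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# image-stack rendering


def render_frap_stack(
    experiment: FrapExperiment,
    geometry: str = "ring",
    image_size_px: int = 192,
    psf_sigma_px: float = 1.0,
    seed: int = 0,
    gain: float = 8000.0,
    ring_width_px: float = 26.0,
    bleach_roi_diameter_px: float = 20.0,
    noise_sd_counts: float = 0.0,
) -> Tuple[np.ndarray, List[RoiSpec]]:
    """Render an experiment as a 16-bit time-lapse stack plus its ROIs.

    A bright annulus (``ring``) or arc (``filament``) carries the reference
    trace everywhere except inside the bleach ROI, where it carries the
    bleach trace; off-structure pixels carry the background trace.  The
    frame is Gaussian-blurred (PSF), scaled by ``gain`` counts per
    intensity unit, optionally given extra counting noise, and quantized
    to uint16.  The returned RoiSpec records are consistent with the
    rendered content (bleach ROI on the structure, reference ROI on the
    structure away from the bleach spot, background ROI off-structure).
    """
    if geometry not in ("ring", "filament"):
        raise ValueError(f"geometry must be 'ring' or 'filament', got {geometry!r}")
    size = int(image_size_px)
    radius = 0.30 * size
    half_w = ring_width_px / 2.0
    roi_r = bleach_roi_diameter_px / 2.0
    if radius + half_w + roi_r >= size / 2.0:
        raise ValueError(
            f"image of {size} px cannot contain the ring (radius {radius:.0f} "
            f"+ width/2 {half_w:.0f}) plus ROIs"
        )
    cx = cy = (size - 1) / 2.0

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rad = np.hypot(xx - cx, yy - cy)
    on_structure = np.abs(rad - radius) <= half_w
    ang = np.degrees(np.arctan2(yy - cy, xx - cx))
    if geometry == "filament":
        on_structure &= np.abs(ang) <= 80.0  # arc spanning +/- 80 degrees
        ref_angle = 50.0
    else:
        ref_angle = 180.0

    def _roi_center(angle_deg):
        a = np.radians(angle_deg)
        return cx + radius * np.cos(a), cy + radius * np.sin(a)

    bx, by = _roi_center(0.0)
    rx, ry = _roi_center(ref_angle)
    bg_xy = (bleach_roi_diameter_px, bleach_roi_diameter_px)
    rois = [
        RoiSpec("roi_bleach", "bleach", bx, by, bleach_roi_diameter_px),
        RoiSpec("roi_reference", "reference", rx, ry, bleach_roi_diameter_px),
        RoiSpec("roi_background", "background", bg_xy[0], bg_xy[1],
                bleach_roi_diameter_px),
    ]
    for roi in rois:
        half = roi.diameter_px / 2.0
        if (roi.center_x_px - half < 0 or roi.center_y_px - half < 0
                or roi.center_x_px + half > size - 1
                or roi.center_y_px + half > size - 1):
            raise ValueError(f"ROI {roi.roi_id!r} falls outside the image")

    in_bleach_spot = np.hypot(xx - bx, yy - by) <= roi_r
    bleach_zone = on_structure & in_bleach_spot
    ref_zone = on_structure & ~in_bleach_spot

    bl = experiment.intensities["bleach"]
    ref = experiment.intensities["reference"]
    bg = experiment.intensities["background"]
    rng = np.random.default_rng(seed % (2**31))
    frames = []
    for k in range(len(experiment.times_s)):
        img = np.full((size, size), bg[k], dtype=float)
        img[ref_zone] = ref[k]
        img[bleach_zone] = bl[k]
        if psf_sigma_px > 0:
            img = ndimage.gaussian_filter(img, psf_sigma_px, mode="nearest")
        img = img * gain
        if noise_sd_counts > 0:
            img = img + noise_sd_counts * rng.standard_normal(img.shape)
        frames.append(np.clip(np.rint(img), 0, 65535).astype(np.uint16))
    return np.stack(frames), rois


# ---------------------------------------------------------------------------
# GTPase absorbance traces

NADH_EXTINCTION_M_CM = 6220.0  # epsilon(NAD(P)H, 340 nm)


def simulate_gtpase_trace(
    turnover_per_min: float,
    ftsz_conc_molar: float = 5e-6,
    epsilon_M_cm: float = NADH_EXTINCTION_M_CM,
    path_cm: float = 1.0,
    duration_min: float = 30.0,
    interval_s: float = 10.0,
    noise_sd_AU: float = 0.0,
    seed: int = 0,
    nadh_conc_molar: float = 4e-4,
    a0_AU: float | None = None,
) -> pd.DataFrame:
    """Simulate an NADH-coupled regeneration-assay absorbance trace.

    Each GTP hydrolyzed regenerates one GTP from GDP at the expense of one
    NAD(P)H, so A340 falls linearly at

        slope = -turnover_per_min * ftsz_conc_molar * epsilon_M_cm * path_cm

    (AU/min) until the NADH pool (``nadh_conc_molar``) is exhausted, after
    which the trace is flat.  ``a0_AU`` defaults to the pool's own
    absorbance, epsilon * path * nadh_conc.  Gaussian noise with sd
    ``noise_sd_AU`` is added per reading.  Returns a DataFrame with
    columns ``t_min`` and ``a340``.
    """
    for name, v in (
        ("turnover_per_min", turnover_per_min),
        ("ftsz_conc_molar", ftsz_conc_molar),
        ("epsilon_M_cm", epsilon_M_cm),
        ("path_cm", path_cm),
        ("duration_min", duration_min),
        ("interval_s", interval_s),
        ("nadh_conc_molar", nadh_conc_molar),
    ):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    if turnover_per_min < 0:
        raise ValueError(f"turnover_per_min must be >= 0, got {turnover_per_min}")
    for name, v in (
        ("ftsz_conc_molar", ftsz_conc_molar),
        ("epsilon_M_cm", epsilon_M_cm),
        ("path_cm", path_cm),
        ("duration_min", duration_min),
        ("interval_s", interval_s),
        ("nadh_conc_molar", nadh_conc_molar),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")

    pool_abs = nadh_conc_molar * epsilon_M_cm * path_cm
    a0 = pool_abs if a0_AU is None else float(a0_AU)
    t_min = np.arange(0.0, duration_min + 1e-9, interval_s / 60.0)
    slope = turnover_per_min * ftsz_conc_molar * epsilon_M_cm * path_cm
    a340 = np.maximum(a0 - slope * t_min, a0 - pool_abs)
    if noise_sd_AU > 0:
        rng = np.random.default_rng(seed % (2**31))
        a340 = a340 + noise_sd_AU * rng.standard_normal(len(t_min))
    return pd.DataFrame({"t_min": t_min, "a340": a340})
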