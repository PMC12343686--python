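"""GTP turnover rates from NADH-coupled regeneration-assay traces.

In the coupled assay each hydrolyzed GTP is regenerated from GDP at the
expense of one NAD(P)H molecule, so the decline of absorbance at 340 nm
reports GTP hydrolysis directly (1:1 stoichiometry):

    rate (GTP FtsZ^-1 min^-1) = -slope / (epsilon * path) / [FtsZ]

with slope in AU/min, epsilon the NAD(P)H extinction coefficient at
340 nm (6220 M^-1 cm^-1), path the optical path in cm and [FtsZ] the
protein concentration in mol/L.  Note: microplate readers need a
user-supplied effective path length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

NADH_EXTINCTION_M_CM = 6220.0
MIN_WINDOW_POINTS = 10
_POSITIVE_SLOPE_TOL = 1e-9


@dataclass
class GtpaseResult:
    slope_AU_per_min: float
    window_min: tuple
    r_squared: float
    rate_turnover: float  # GTP FtsZ^-1 min^-1
    epsilon_M_cm: float
    path_cm: float
    ftsz_conc_molar: float


def _as_trace(trace) -> pd.DataFrame:
    df = pd.DataFrame(trace)
    if not {"t_min", "a340"}.issubset(df.columns):
        raise ValueError("trace needs columns t_min and a340")
    t = df["t_min"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("trace needs >= 3 points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("t_min must be strictly increasing")
    return df


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and r^2; a zero-variance (flat) segment fits perfectly."""
    if np.ptp(y) == 0:
        return 0.0, 1.0
    res = sps.linregress(t, y)
    return float(res.slope), float(min(max(res.rvalue**2, 0.0), 1.0))


def fit_linear_rate(
    trace, window: tuple[float, float] | None = None
) -> tuple[float, float, tuple[float, float]]:
    """OLS slope (AU/min) of a340 vs t_min over a window.

    With ``window=(start, end)`` minutes, fits the >= 3 points inside it.
    With no window, the contiguous sub-window of >= 10 points maximizing
    r^2 is selected automatically (ties: earliest start, then longer
    window) — this skips lag phases and the post-exhaustion plateau.
    Returns (slope, r_squared, (start_min, end_min)).
    """
    df = _as_trace(trace)
    t = df["t_min"].to_numpy(dtype=float)
    y = df["a340"].to_numpy(dtype=float)

    if window is not None:
        lo, hi = float(window[0]), float(window[1])
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 3:
            raise ValueError(
                f"window [{lo}, {hi}] min contains {int(mask.sum())} points; "
                "need >= 3"
            )
        slope, r2 = _ols(t[mask], y[mask])
        return slope, r2, (float(t[mask][0]), float(t[mask][-1]))

    n = len(t)
    if n < MIN_WINDOW_POINTS or np.ptp(y) == 0:
        slope, r2 = _ols(t, y)
        return slope, r2, (float(t[0]), float(t[-1]))

    # prefix sums make each candidate window O(1)
    st, sy = np.concatenate([[0], np.cumsum(t)]), np.concatenate([[0], np.cumsum(y)])
    stt = np.concatenate([[0], np.cumsum(t * t)])
    syy = np.concatenate([[0], np.cumsum(y * y)])
    sty = np.concatenate([[0], np.cumsum(t * y)])

    best = None  # (r2, start_idx, -length, slope)
    for i in range(0, n - MIN_WINDOW_POINTS + 1):
        for j in range(i + MIN_WINDOW_POINTS - 1, n):
            m = j - i + 1
            vt = stt[j + 1] - stt[i] - (st[j + 1] - st[i]) ** 2 / m
            vy = syy[j + 1] - syy[i] - (sy[j + 1] - sy[i]) ** 2 / m
            cty = sty[j + 1] - sty[i] - (st[j + 1] - st[i]) * (sy[j + 1] - sy[i]) / m
            if vy <= 0:
                r2, slope = 1.0, 0.0  # flat segment: perfect zero-slope fit
            else:
                slope = cty / vt
                r2 = min(max(cty * cty / (vt * vy), 0.0), 1.0)
            # r^2 compared at 1e-9 so float noise cannot break the tie rule
            key = (round(r2, 9), -i, m)
            if best is None or key > best[0]:
                best = (key, i, j, slope, r2)
    _, i, j, slope, r2 = best
    return float(slope), float(r2), (float(t[i]), float(t[j]))


def to_turnover_rate(
    slope_AU_per_min: float,
    epsilon_M_cm: float = NADH_EXTINCTION_M_CM,
    path_cm: float = 1.0,
    ftsz_conc_molar: float = 5e-6,
) -> float:
    """Convert an A340 slope to GTP FtsZ^-1 min^-1 (1:1 NADH:GTP).

    A positive slope is non-physical for this assay; it triggers a warning
    and the rate is clamped at 0.
    """
    for name, v in (
        ("epsilon_M_cm", epsilon_M_cm),
        ("path_cm", path_cm),
        ("ftsz_conc_molar", ftsz_conc_molar),
    ):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    if slope_AU_per_min > _POSITIVE_SLOPE_TOL:
        warnings.warn(
            f"positive A340 slope ({slope_AU_per_min:.3g} AU/min) is "
            "non-physical for an NADH-coupled assay; rate clamped at 0",
            stacklevel=2,
        )
    return max(0.0, -slope_AU_per_min) / (epsilon_M_cm * path_cm) / ftsz_conc_molar


def analyze_gtpase(
    trace,
    ftsz_conc_molar: float = 5e-6,
    epsilon_M_cm: float = NADH_EXTINCTION_M_CM,
    path_cm: float = 1.0,
    window: tuple[float, float] | None = None,
) -> GtpaseResult:
    """Full assay analysis: window selection, OLS slope, unit conversion."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        slope, r2, win = fit_linear_rate(trace, window=window)
        rate = to_turnover_rate(slope, epsilon_M_cm, path_cm, ftsz_conc_molar)
    return GtpaseResult(
        slope_AU_per_min=slope,
        window_min=win,
        r_squared=r2,
        rate_turnover=rate,
        epsilon_M_cm=epsilon_M_cm,
        path_cm=path_cm,
        ftsz_conc_molar=ftsz_conc_molar,
    )
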