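"""Time-lapse stack reading, circular ROI resolution, and trace extraction.

A FRAP acquisition is represented as a frames x height x width grayscale
stack plus three circular regions of interest: the photobleached spot
(``bleach``), an unbleached signal region used to correct for acquisition
photobleaching (``reference``), and a signal-free region estimating the
detector/medium background (``background``).  Extraction reduces each ROI to
its per-frame mean pixel intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Sequence

import numpy as np
import tifffile

ROI_ROLES = ("bleach", "reference", "background")


@dataclass(frozen=True)
class RoiSpec:
    """A circular ROI on an image, in 0-based pixel-center coordinates.

    Pixel (row i, column j) has center (x=j, y=i).  Membership is by
    center distance: a pixel belongs to the ROI iff its center lies within
    ``diameter_px / 2`` of (``center_x_px``, ``center_y_px``).
    """

    roi_id: str
    role: str
    center_x_px: float
    center_y_px: float
    diameter_px: float

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise ValueError(
                f"role must be one of {ROI_ROLES}, got {self.role!r}"
            )
        if not np.isfinite(self.diameter_px) or self.diameter_px <= 0:
            raise ValueError(f"diameter_px must be > 0, got {self.diameter_px}")


@dataclass
class FrapExperiment:
    """Raw per-frame mean ROI intensities for one photobleached cell.

    ``times_s`` is the acquisition clock (pre-bleach frames at negative
    times, first post-bleach frame at 0 by the generator's convention).
    ``bleach_frame_index`` is the index of the first post-bleach frame and
    equals ``n_prebleach``.
    """

    cell_id: str
    times_s: np.ndarray
    intensities: Dict[str, np.ndarray]
    bleach_frame_index: int
    n_prebleach: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1 or len(self.times_s) < 2:
            raise ValueError("times_s must be a 1-D array of >= 2 frame times")
        if not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        missing = [r for r in ROI_ROLES if r not in self.intensities]
        if missing:
            raise ValueError(f"missing ROI roles: {missing}")
        n = len(self.times_s)
        for role, trace in self.intensities.items():
            trace = np.asarray(trace, dtype=float)
            self.intensities[role] = trace
            if trace.shape != (n,):
                raise ValueError(
                    f"trace for role {role!r} has length {trace.shape}, "
                    f"expected ({n},)"
                )
        if self.bleach_frame_index != self.n_prebleach:
            raise ValueError(
                "bleach_frame_index must equal n_prebleach "
                f"({self.bleach_frame_index} != {self.n_prebleach})"
            )
        if not 1 <= self.n_prebleach < n:
            raise ValueError("need >= 1 pre-bleach and >= 1 post-bleach frame")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page single-channel grayscale TIFF as (T, H, W).

    Multi-channel (e.g. RGB) input is rejected: split channels upstream and
    pass a single fluorescence channel.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(
                f"{path}: {page.samplesperpixel} samples per pixel; expected a "
                "single-channel grayscale stack (split RGB/multi-channel data "
                "into one channel per file)"
            )
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a (frames, height, width) stack, got shape "
            f"{arr.shape}"
        )
    return arr


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (T, H, W) stack as a multi-page grayscale TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"expected (T, H, W), got shape {stack.shape}")
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def roi_pixels(roi: RoiSpec, image_shape: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a circular ROI to the (rows, cols) of member pixels.

    A pixel is a member iff its center is within ``diameter/2`` (Euclidean)
    of the ROI center.  Deterministic; no partial-pixel weighting.
    """
    h, w = int(image_shape[-2]), int(image_shape[-1])
    radius = roi.diameter_px / 2.0
    # bounding box to avoid scanning the whole image
    r0 = max(0, int(np.floor(roi.center_y_px - radius)))
    r1 = min(h - 1, int(np.ceil(roi.center_y_px + radius)))
    c0 = max(0, int(np.floor(roi.center_x_px - radius)))
    c1 = min(w - 1, int(np.ceil(roi.center_x_px + radius)))
    if r1 < r0 or c1 < c0:
        raise ValueError(f"ROI {roi.roi_id!r} does not intersect the image")
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    dist2 = (cc - roi.center_x_px) ** 2 + (rr - roi.center_y_px) ** 2
    inside = dist2 <= radius**2
    if not inside.any():
        raise ValueError(f"ROI {roi.roi_id!r} contains no pixel centers")
    return rr[inside], cc[inside]


def extract_traces(
    stack: np.ndarray,
    rois: Sequence[RoiSpec],
    times_s: Sequence[float],
    n_prebleach: int,
    cell_id: str = "cell",
) -> FrapExperiment:
    """Extract per-frame mean-intensity traces for each ROI role.

    Exactly one ROI per role is expected; the per-frame statistic is the
    arithmetic mean over member pixels, so ROI size does not rescale traces.
    """
    stack = np.asarray(stack)
    times_s = np.asarray(times_s, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"expected (T, H, W) stack, got shape {stack.shape}")
    if len(times_s) != stack.shape[0]:
        raise ValueError(
            f"times length {len(times_s)} != frame count {stack.shape[0]}"
        )
    by_role: Dict[str, RoiSpec] = {}
    for roi in rois:
        if roi.role in by_role:
            raise ValueError(f"duplicate ROI for role {roi.role!r}")
        by_role[roi.role] = roi
    traces: Dict[str, np.ndarray] = {}
    for role, roi in by_role.items():
        rows, cols = roi_pixels(roi, stack.shape)
        traces[role] = stack[:, rows, cols].mean(axis=1).astype(float)
    return FrapExperiment(
        cell_id=cell_id,
        times_s=times_s,
        intensities=traces,
        bleach_frame_index=n_prebleach,
        n_prebleach=n_prebleach,
    )
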