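"""Keypoint ingestion and preprocessing.

Pipeline: mask low-confidence cells, impute them with the per-keypoint
median, flatten planar coordinates to per-keypoint Euclidean magnitudes
(10-dimensional position matrix over time), z-score per keypoint, then gate
out configurations whose stimulation-ON limb speed never exceeds a
velocity threshold derived from the OFF (rest) epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import KeypointSeries

__all__ = [
    "PositionMatrix",
    "ImputationError",
    "GatingError",
    "filter_low_likelihood",
    "impute_median",
    "flatten_euclidean",
    "standardize",
    "inverse_standardize",
    "frame_speed",
    "movement_gate",
    "evaluate_tracking_error",
    "epoch_tags",
    "preprocess_series",
]


class ImputationError(ValueError):
    """A keypoint has no unmasked samples to impute from."""


class GatingError(ValueError):
    """Movement gating impossible (no OFF frames for the rest baseline)."""


@dataclass
class PositionMatrix:
    """T x K per-keypoint position magnitudes with per-frame epoch tags.

    ``values`` holds the working representation (z-scored after
    ``standardize``); ``raw`` always keeps the unstandardized magnitudes so
    that frame speeds retain their pixel scale.
    """

    values: np.ndarray  # (T, K)
    keypoints: tuple[str, ...]
    fps: float
    raw: np.ndarray | None = None
    epoch_tag: np.ndarray | None = None  # per-frame configuration label or "OFF"
    subject_id: str = "subject01"
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.raw is None:
            self.raw = self.values.copy()
        if np.isnan(self.values).any():
            raise ValueError("position matrix must be complete (no NaN)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "PositionMatrix":
        return replace(
            self,
            values=self.values.copy(),
            raw=self.raw.copy(),
            epoch_tag=None if self.epoch_tag is None else self.epoch_tag.copy(),
        )


# ---------------------------------------------------------------------------
# Likelihood filtering and imputation
# ---------------------------------------------------------------------------

def filter_low_likelihood(
    series: KeypointSeries, threshold: float = 0.5
) -> KeypointSeries:
    """Mask cells whose tracking likelihood is strictly below ``threshold``.

    Masked cells have x and y set to NaN.  The number of masked cells is
    recorded on the returned series as ``n_masked``.  Keypoints left with no
    unmasked frame trigger a warning naming the keypoint.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    out = series.copy()
    mask = out.likelihood < threshold
    out.x[mask] = np.nan
    out.y[mask] = np.nan
    for k, bp in enumerate(out.bodyparts):
        if mask[:, k].all():
            warnings.warn(f"keypoint {bp!r} fully masked at threshold {threshold}")
    out.n_masked = int(mask.sum())  # type: ignore[attr-defined]
    return out


def impute_median(series: KeypointSeries, window: int | None = None) -> KeypointSeries:
    """Replace masked cells with the per-keypoint median of unmasked samples.

    With ``window=None`` (default) the median is taken over the whole trial
    for each keypoint's x and y vectors.  With an integer window, a centered
    rolling median of unmasked values is used instead (falling back to the
    whole-trial median where the window is empty).
    """
    out = series.copy()
    mask = out.mask()
    for k, bp in enumerate(out.bodyparts):
        mk = mask[:, k]
        if not mk.any():
            continue
        if mk.all():
            raise ImputationError(f"keypoint {bp!r} has no unmasked samples")
        for arr in (out.x, out.y):
            col = arr[:, k]
            global_med = np.nanmedian(col)
            if window is None:
                col[mk] = global_med
            else:
                filled = (
                    pd.Series(col)
                    .rolling(window, center=True, min_periods=1)
                    .median()
                    .to_numpy()
                )
                col[mk] = np.where(np.isnan(filled[mk]), global_med, filled[mk])
    return out


# ---------------------------------------------------------------------------
# Flattening and standardization
# ---------------------------------------------------------------------------

def flatten_euclidean(
    series: KeypointSeries,
    origin: str = "image_origin",
    epochs: pd.DataFrame | None = None,
) -> PositionMatrix:
    """Collapse (x, y) per keypoint to a Euclidean magnitude.

    ``image_origin`` takes sqrt(x^2 + y^2) relative to the image origin;
    ``hip_anchored`` measures distances from the hip keypoint at each frame
    (the hip column is then identically zero).  Output is the T x 10
    position matrix, unstandardized.
    """
    if series.mask().any():
        raise ValueError("series has masked cells; impute before flattening")
    if origin == "image_origin":
        ox = np.zeros((series.n_frames, 1))
        oy = np.zeros((series.n_frames, 1))
    elif origin == "hip_anchored":
        try:
            hip = series.bodyparts.index("hip")
        except ValueError as exc:
            raise ValueError("hip_anchored flattening needs a 'hip' keypoint") from exc
        ox = series.x[:, hip : hip + 1]
        oy = series.y[:, hip : hip + 1]
    else:
        raise ValueError(f"unknown origin {origin!r}")
    values = np.hypot(series.x - ox, series.y - oy)
    tag = None if epochs is None else epoch_tags(epochs, series.n_frames)
    return PositionMatrix(
        values=values,
        keypoints=series.bodyparts,
        fps=series.fps,
        epoch_tag=tag,
        subject_id=series.subject_id,
    )


def epoch_tags(epochs: pd.DataFrame, n_frames: int) -> np.ndarray:
    """Per-frame configuration label, 'OFF' outside stimulation-ON spans."""
    tag = np.array(["OFF"] * n_frames, dtype=object)
    for row in epochs.itertuples(index=False):
        tag[int(row.on_start) : int(row.on_stop)] = str(row.label)
    return tag


def standardize(matrix: PositionMatrix) -> PositionMatrix:
    """Z-score each keypoint column (population SD convention)."""
    means = matrix.values.mean(axis=0)
    sds = matrix.values.std(axis=0, ddof=0)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [matrix.keypoints[int(i)] for i in zero]
        raise ValueError(f"zero-variance keypoint column(s): {names}")
    out = matrix.copy()
    out.values = (matrix.values - means) / sds
    out.means, out.sds, out.standardized = means, sds, True
    return out


def inverse_standardize(matrix: PositionMatrix) -> np.ndarray:
    """Undo the z-scoring using the stored means/SDs."""
    if not matrix.standardized or matrix.means is None:
        raise ValueError("matrix is not standardized")
    return matrix.values * matrix.sds + matrix.means


# ---------------------------------------------------------------------------
# Movement gating
# ---------------------------------------------------------------------------

def frame_speed(matrix: PositionMatrix) -> np.ndarray:
    """Per-frame limb speed: Euclidean frame-to-frame displacement of the
    unstandardized position magnitudes times fps (px/s).  First frame is 0."""
    disp = np.zeros(matrix.n_frames)
    if matrix.n_frames > 1:
        disp[1:] = np.linalg.norm(np.diff(matrix.raw, axis=0), axis=1)
    return disp * matrix.fps


def movement_gate(
    matrix: PositionMatrix,
    epochs: pd.DataFrame,
    k_sd: float = 3.0,
    smooth_s: float = 0.25,
    rest_fraction: float = 0.5,
) -> pd.DataFrame:
    """Flag configurations that failed to induce movement.

    Frame speeds are smoothed with a centered ``smooth_s``-second rolling
    mean.  The rest baseline is the smoothed-speed distribution over the
    settled tail of each OFF epoch (the last ``rest_fraction`` of it, so the
    post-stimulation relaxation transient does not inflate the baseline).  A
    configuration is retained iff the peak smoothed speed of (at least one
    of) its ON epochs exceeds baseline_mean + k_sd * baseline_SD.
    """
    speed = frame_speed(matrix)
    window = max(1, int(round(smooth_s * matrix.fps)))
    smoothed = (
        pd.Series(speed).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    rest_idx: list[np.ndarray] = []
    for row in epochs.itertuples(index=False):
        a, b = int(row.off_start), int(row.off_stop)
        rest_idx.append(np.arange(b - int(round((b - a) * rest_fraction)), b))
    rest = np.concatenate(rest_idx) if rest_idx else np.array([], dtype=int)
    rest = rest[(rest >= 1) & (rest < matrix.n_frames)]  # frame 0 has no speed
    if rest.size == 0:
        raise GatingError("no OFF frames available for the rest baseline")
    base_mean = float(smoothed[rest].mean())
    base_sd = float(smoothed[rest].std(ddof=0))
    threshold = base_mean + k_sd * base_sd

    out = epochs.copy()
    retained = []
    peak_speed = []
    for row in epochs.itertuples(index=False):
        span = smoothed[int(row.on_start) + 1 : int(row.on_stop)]
        peak = float(span.max()) if span.size else 0.0
        peak_speed.append(peak)
        retained.append(peak > threshold)
    out["on_peak_speed"] = peak_speed
    out["retained"] = retained
    out.attrs["gate_threshold"] = threshold
    out.attrs["baseline_mean"] = base_mean
    out.attrs["baseline_sd"] = base_sd
    return out


# ---------------------------------------------------------------------------
# Tracking-error evaluation
# ---------------------------------------------------------------------------

def evaluate_tracking_error(
    predicted: KeypointSeries, labeled: KeypointSeries, mm_per_px: float
) -> dict:
    """Median per-keypoint and pooled tracking error in mm over labeled frames."""
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    if predicted.bodyparts != labeled.bodyparts:
        raise ValueError(
            "keypoint schema mismatch: "
            f"{predicted.bodyparts} vs {labeled.bodyparts}"
        )
    if predicted.n_frames != labeled.n_frames:
        raise ValueError("frame count mismatch between predicted and labeled")
    err_mm = (
        np.hypot(predicted.x - labeled.x, predicted.y - labeled.y) * mm_per_px
    )
    per_kp = {
        bp: float(np.nanmedian(err_mm[:, k]))
        for k, bp in enumerate(predicted.bodyparts)
    }
    return {"per_keypoint_mm": per_kp, "overall_mm": float(np.nanmedian(err_mm))}


# ---------------------------------------------------------------------------
# Convenience: the full preprocessing chain
# ---------------------------------------------------------------------------

def preprocess_series(
    series: KeypointSeries,
    epochs: pd.DataFrame,
    likelihood_threshold: float = 0.5,
    impute_window: int | None = None,
    origin: str = "image_origin",
) -> PositionMatrix:
    """filter -> impute -> flatten -> standardize, with epoch tags attached."""
    filtered = filter_low_likelihood(series, likelihood_threshold)
    complete = impute_median(filtered, window=impute_window)
    flat = flatten_euclidean(complete, origin=origin, epochs=epochs)
    return standardize(flat)
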