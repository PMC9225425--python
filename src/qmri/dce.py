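"""DCE-MRI enhancement curves and area-under-curve (AUC) quantification.

The enhancement metric is deliberately model-free: per voxel (or per ROI),
signal is converted to relative enhancement over a pre-injection baseline,
integrated over the post-injection window by a trapezoid rule on frame
midpoints, and normalized to the same session's muscle-reference AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .phantom import DceSeries, RoiMaskSet

__all__ = [
    "EnhancementCurve",
    "AucResult",
    "baseline_signal",
    "enhancement_curve",
    "roi_enhancement_curve",
    "trapezoid_weights",
    "auc",
    "auc_map",
    "normalize_to_muscle",
    "roi_auc_table",
]

MUSCLE_EPS = 1e-9


@dataclass
class EnhancementCurve:
    """Relative-enhancement time course (S(t) - S_base) / S_base."""

    frame_times_min: np.ndarray
    rel_enh: np.ndarray
    s_base: float

    def __post_init__(self) -> None:
        self.frame_times_min = np.asarray(self.frame_times_min, dtype=float)
        self.rel_enh = np.asarray(self.rel_enh, dtype=float)
        if self.frame_times_min.shape != self.rel_enh.shape:
            raise ValueError("frame_times_min and rel_enh lengths differ")


@dataclass
class AucResult:
    """Raw and muscle-normalized AUC over a time window (minutes)."""

    auc_raw: float
    auc_norm: Optional[float]
    window: Tuple[float, float]
    excluded: bool = False


def _validate_baseline(series: DceSeries, n: int) -> None:
    if not 1 <= n < series.data.shape[-1]:
        raise ValueError("n_baseline_frames must satisfy 1 <= n < n_frames")
    window_end = n * series.frame_duration_min
    if window_end > series.injection_start_min + 1e-9:
        raise ValueError(
            f"baseline window (first {n} frames, ending {window_end:g} min) "
            f"overlaps the injection at {series.injection_start_min:g} min"
        )


def baseline_signal(series: DceSeries, n_baseline_frames: int = 2) -> np.ndarray:
    """Per-voxel baseline: mean of the first ``n_baseline_frames`` frames.

    The baseline window must end before contrast injection begins; with the
    default 1-min frames and injection at 2 min that allows at most 2 frames.
    """
    n = int(n_baseline_frames)
    _validate_baseline(series, n)
    return series.data[..., :n].mean(axis=-1)


def enhancement_curve(signal: np.ndarray, frame_times_min: np.ndarray,
                      s_base: float) -> EnhancementCurve:
    """Convert one signal time course to relative enhancement.

    A non-positive baseline makes relative enhancement undefined; callers
    should exclude such voxels (see :func:`roi_enhancement_curve`).
    """
    if s_base <= 0:
        raise ValueError("s_base must be > 0; exclude the voxel instead")
    signal = np.asarray(signal, dtype=float)
    return EnhancementCurve(frame_times_min=frame_times_min,
                            rel_enh=(signal - s_base) / s_base,
                            s_base=float(s_base))


def roi_enhancement_curve(series: DceSeries, mask: np.ndarray,
                          n_baseline_frames: int = 2) -> EnhancementCurve:
    """ROI-mean enhancement curve: average signal over the mask per frame,
    then relative enhancement against the ROI-mean baseline."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    _validate_baseline(series, int(n_baseline_frames))
    ts = series.data[mask].mean(axis=0)
    s_base = float(ts[:n_baseline_frames].mean())
    return enhancement_curve(ts, series.frame_times_min, s_base)


def trapezoid_weights(frame_times_min: np.ndarray,
                      window: Tuple[float, float]) -> np.ndarray:
    """Quadrature weights for the windowed midpoint-trapezoid AUC.

    Frames whose midpoints fall inside ``window`` get composite-trapezoid
    weights; the first and last in-window samples are additionally extended
    as rectangles to the window edges so the integral spans the full window
    (exact for constant and linear curves).  Returns a weight per frame
    (zero outside the window) such that ``auc = weights @ rel_enh``.
    """
    t = np.asarray(frame_times_min, dtype=float)
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError("window must have positive length")
    if t0 < t[0] - 0.5 * (t[1] - t[0]) - 1e-9 or t1 > t[-1] + 0.5 * (t[-1] - t[-2]) + 1e-9:
        raise ValueError("window endpoints must lie within the frame-time range")
    inside = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        raise ValueError("no frame midpoints inside the window")
    w = np.zeros_like(t)
    ti = t[idx]
    if idx.size > 1:
        dt = np.diff(ti)
        w[idx[:-1]] += dt / 2.0
        w[idx[1:]] += dt / 2.0
    w[idx[0]] += max(ti[0] - t0, 0.0)
    w[idx[-1]] += max(t1 - ti[-1], 0.0)
    return w


def auc(curve: EnhancementCurve,
        window: Optional[Tuple[float, float]] = None) -> float:
    """Windowed trapezoidal AUC of relative enhancement, in minutes."""
    if window is None:
        window = (float(curve.frame_times_min[0]), float(curve.frame_times_min[-1]))
    w = trapezoid_weights(curve.frame_times_min, window)
    return float(w @ curve.rel_enh)


def auc_map(series: DceSeries, n_baseline_frames: int = 2,
            window: Optional[Tuple[float, float]] = None) -> np.ndarray:
    """Voxelwise AUC map; voxels with non-positive baseline are NaN."""
    s_base = baseline_signal(series, n_baseline_frames)
    if window is None:
        window = (series.injection_start_min, float(series.frame_times_min[-1]
                  + 0.5 * series.frame_duration_min))
    w = trapezoid_weights(series.frame_times_min, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (series.data - s_base[..., None]) / s_base[..., None]
    out = rel @ w
    out[s_base <= 0] = np.nan
    return out


def normalize_to_muscle(roi_auc: Mapping[str, float] | pd.Series,
                        muscle_auc: float,
                        eps: float = MUSCLE_EPS) -> Tuple[pd.Series, bool]:
    """Divide each ROI's raw AUC by the session's muscle AUC.

    Returns ``(auc_norm, excluded)``; when the muscle AUC is at or below
    ``eps`` (poor contrast uptake) the values are NaN and the session is
    flagged for exclusion rather than silently divided.
    """
    s = pd.Series(roi_auc, dtype=float)
    if muscle_auc <= eps:
        return pd.Series(np.nan, index=s.index), True
    return s / muscle_auc, False


def roi_auc_table(series: DceSeries, rois: RoiMaskSet,
                  n_baseline_frames: int = 2,
                  window: Optional[Tuple[float, float]] = None) -> pd.DataFrame:
    """Per-ROI raw and muscle-normalized AUC for one session.

    Enhancement is computed on the ROI-mean signal (mean curve, then AUC);
    the bilateral muscle region is pooled into the single reference value.
    """
    if window is None:
        window = (series.injection_start_min, float(series.frame_times_min[-1]
                  + 0.5 * series.frame_duration_min))
    raw = {}
    nvox = {}
    for name in rois.names:
        m = rois.mask(name)
        nvox[name] = int(m.sum())
        curve = roi_enhancement_curve(series, m, n_baseline_frames)
        raw[name] = auc(curve, window)
    muscle = raw.get("muscle")
    if muscle is None:
        raise ValueError("ROI set lacks the muscle reference region")
    norm, excluded = normalize_to_muscle(raw, muscle)
    return pd.DataFrame({
        "roi": list(raw),
        "auc_raw": [raw[k] for k in raw],
        "auc_norm": [norm[k] for k in raw],
        "n_voxels": [nvox[k] for k in raw],
        "session_excluded": excluded,
    })


def roi_auc_stats(series: DceSeries, rois: RoiMaskSet,
                  n_baseline_frames: int = 2,
                  window: Optional[Tuple[float, float]] = None,
                  mad_k: Optional[float] = 4.0) -> pd.DataFrame:
    """Voxelwise per-ROI AUC summary with robust outlier rejection.

    Computes the voxelwise AUC map, then per ROI drops non-evaluable voxels
    (non-positive baseline) and, when ``mad_k`` is given, voxels outside
    median +/- mad_k * MAD; the ROI value is the mean of survivors.  The
    muscle reference pools its bilateral voxels into one raw AUC used for
    normalization; ``auc_norm`` is NaN and ``session_excluded`` True when
    the muscle AUC is non-positive.
    """
    from .roistats import mad_filter

    amap = auc_map(series, n_baseline_frames, window)
    rows = []
    for name in rois.names:
        m = rois.mask(name)
        vals = amap[m]
        vals = vals[np.isfinite(vals)]
        n_roi = int(m.sum())
        n_excl = n_roi - vals.size
        if mad_k is not None and vals.size:
            vals, dropped = mad_filter(vals, mad_k)
            n_excl += dropped
        rows.append(dict(roi=name,
                         auc_raw=float(vals.mean()) if vals.size else np.nan,
                         n_voxels=int(vals.size), n_excluded=n_excl))
    df = pd.DataFrame(rows)
    if "muscle" not in set(df.roi):
        raise ValueError("ROI set lacks the muscle reference region")
    muscle_auc = float(df.loc[df.roi == "muscle", "auc_raw"].iloc[0])
    if not np.isfinite(muscle_auc):
        muscle_auc = 0.0
    norm, excluded = normalize_to_muscle(
        dict(zip(df.roi, df.auc_raw)), muscle_auc)
    df["auc_norm"] = norm.to_numpy()
    df["muscle_auc_raw"] = muscle_auc
    df["session_excluded"] = excluded
    return df
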