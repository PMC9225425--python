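"""Voxelwise T2 relaxometry from multi-echo spin-echo stacks.

The signal model is mono-exponential transverse decay,

    S(TE) = S0 * exp(-TE / T2),

fitted per voxel either by weighted log-linear least squares (weights S^2 to
de-bias the log transform) or by nonlinear least squares initialized from the
log-linear solution.  Fitting is fully vectorized over voxels: the nonlinear
path runs a batched Levenberg-Marquardt on the 2-parameter problem, so whole
volumes fit in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .phantom import MultiEchoStack, RoiMaskSet

__all__ = ["T2Map", "T2Decay", "T2DecayResults", "fit_t2_voxel", "fit_t2_map", "roi_t2"]

#: Voxels fitting above this T2 (ms) are marked unfittable — guards against
#: CSF/artifact voxels with effectively flat decay.
T2_MAX_MS = 2000.0


@dataclass
class T2Map:
    """Per-voxel fit results. ``t2_ms`` and ``s0`` are NaN where ``fit_ok`` is False."""

    t2_ms: np.ndarray
    s0: np.ndarray
    rss: np.ndarray
    fit_ok: np.ndarray


def _as_batch(signal: np.ndarray) -> Tuple[np.ndarray, Tuple[int, ...]]:
    sig = np.asarray(signal, dtype=float)
    shape = sig.shape[:-1]
    return sig.reshape(-1, sig.shape[-1]), shape


def _loglinear(sig: np.ndarray, tes: np.ndarray, t2_max: float):
    """Weighted LLS of ln S on TE, weights S^2; batched over rows."""
    pos = np.all(sig > 0, axis=1)
    s0 = np.full(sig.shape[0], np.nan)
    t2 = np.full(sig.shape[0], np.nan)
    if pos.any():
        s = sig[pos]
        w = s ** 2
        y = np.log(s)
        sw = w.sum(axis=1)
        swx = w @ tes
        swy = (w * y).sum(axis=1)
        swxx = w @ tes ** 2
        swxy = (w * y) @ tes
        denom = sw * swxx - swx ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (sw * swxy - swx * swy) / denom
            intercept = (swy - slope * swx) / sw
        with np.errstate(divide="ignore"):
            t2p = np.where(slope < 0, -1.0 / slope, np.inf)
        s0p = np.exp(intercept)
        t2[pos] = t2p
        s0[pos] = s0p
    ok = pos & np.isfinite(t2) & (t2 > 0) & (t2 <= t2_max) & np.isfinite(s0)
    return s0, t2, ok


def _model(tes: np.ndarray, s0: np.ndarray, t2: np.ndarray) -> np.ndarray:
    return s0[:, None] * np.exp(-tes / t2[:, None])


def _rss(sig, tes, s0, t2):
    with np.errstate(over="ignore", invalid="ignore"):
        r = sig - _model(tes, s0, t2)
    return np.einsum("ij,ij->i", r, r)


def _nlls(sig: np.ndarray, tes: np.ndarray, s0: np.ndarray, t2: np.ndarray,
          t2_max: float, max_iter: int = 60, tol: float = 1e-12):
    """Batched Levenberg-Marquardt for the 2-parameter decay, one lambda per voxel."""
    n = sig.shape[0]
    ok_init = np.isfinite(s0) & np.isfinite(t2) & (t2 > 0)
    s0 = np.where(ok_init, s0, np.nanmax(np.abs(sig), axis=1) + 1e-12)
    t2 = np.where(ok_init, t2, np.median(tes))
    lam = np.full(n, 1e-3)
    rss = _rss(sig, tes, s0, t2)
    active = np.isfinite(rss)
    rss = np.where(active, rss, np.inf)
    for _ in range(max_iter):
        if not active.any():
            break
        e = np.exp(-tes / t2[active, None])
        f = s0[active, None] * e
        r = sig[active] - f
        j1 = e
        j2 = f * tes / t2[active, None] ** 2
        a11 = np.einsum("ij,ij->i", j1, j1)
        a12 = np.einsum("ij,ij->i", j1, j2)
        a22 = np.einsum("ij,ij->i", j2, j2)
        b1 = np.einsum("ij,ij->i", j1, r)
        b2 = np.einsum("ij,ij->i", j2, r)
        l = lam[active]
        d11 = a11 * (1 + l)
        d22 = a22 * (1 + l)
        det = d11 * d22 - a12 ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            ds0 = (d22 * b1 - a12 * b2) / det
            dt2 = (d11 * b2 - a12 * b1) / det
        s0_new = s0[active] + np.where(np.isfinite(ds0), ds0, 0.0)
        t2_new = np.clip(t2[active] + np.where(np.isfinite(dt2), dt2, 0.0),
                         1e-6, 10.0 * t2_max)
        rss_new = _rss(sig[active], tes, s0_new, t2_new)
        better = np.isfinite(rss_new) & (rss_new <= rss[active])
        idx = np.flatnonzero(active)
        gi, bi = idx[better], idx[~better]
        step = np.abs(np.where(np.isfinite(ds0), ds0, 0.0)) + np.abs(
            np.where(np.isfinite(dt2), dt2, 0.0))
        s0[gi] = s0_new[better]
        t2[gi] = t2_new[better]
        improv = rss[gi] - rss_new[better]
        rss[gi] = rss_new[better]
        lam[gi] = np.maximum(lam[gi] * 0.3, 1e-12)
        lam[bi] = np.minimum(lam[bi] * 10.0, 1e8)
        done = np.zeros(len(idx), dtype=bool)
        done[better] = (improv <= tol * (rss_new[better] + tol)) & (
            step[better] <= 1e-8 * (np.abs(t2[gi]) + np.abs(s0[gi]) + 1.0))
        done[~better] = lam[bi] >= 1e8
        active[idx[done]] = False
    ok = np.isfinite(t2) & (t2 > 0) & (t2 <= t2_max) & np.isfinite(s0) & np.isfinite(rss)
    return s0, t2, ok


def _fit_batch(sig: np.ndarray, tes: np.ndarray, method: str, t2_max: float):
    if sig.shape[-1] != tes.size:
        raise ValueError("signal and echo_times_ms lengths differ")
    if sig.shape[-1] < 3:
        raise ValueError("need at least 3 echoes")
    if np.unique(tes).size != tes.size:
        raise ValueError("echo times must be distinct")
    s0, t2, ok = _loglinear(sig, tes, t2_max)
    if method == "nlls":
        s0, t2, ok2 = _nlls(sig, tes, s0.copy(), t2.copy(), t2_max)
        ok = ok2 & np.all(np.isfinite(sig), axis=1)
    elif method != "loglinear":
        raise ValueError(f"unknown method {method!r}")
    ok &= np.nanmax(np.abs(sig), axis=1) > 0  # no signal, no fit
    rss = _rss(sig, tes, s0, t2)
    s0 = np.where(ok, s0, np.nan)
    t2 = np.where(ok, t2, np.nan)
    rss = np.where(ok, rss, np.nan)
    return s0, t2, rss, ok


class T2Decay:
    """Mono-exponential T2 decay model for one or many voxels.

    Parameters
    ----------
    signal : array, shape (..., n_echoes)
        Magnitude signal; trailing axis runs over echoes.
    echo_times_ms : array, shape (n_echoes,)
        Echo times (ms); any order, must be distinct.

    Examples
    --------
    >>> tes = np.array([10., 30., 50., 70., 90., 110.])
    >>> res = T2Decay(100 * np.exp(-tes / 50.0), tes).fit()
    >>> round(res.t2_ms, 3)
    50.0
    """

    def __init__(self, signal: np.ndarray, echo_times_ms: np.ndarray):
        self.signal = np.asarray(signal, dtype=float)
        self.echo_times_ms = np.asarray(echo_times_ms, dtype=float)
        if self.signal.shape[-1] != self.echo_times_ms.size:
            raise ValueError("signal and echo_times_ms lengths differ")

    def fit(self, method: str = "nlls", t2_max: float = T2_MAX_MS) -> "T2DecayResults":
        batch, shape = _as_batch(self.signal)
        s0, t2, rss, ok = _fit_batch(batch, self.echo_times_ms, method, t2_max)
        return T2DecayResults(self, method,
                              s0.reshape(shape), t2.reshape(shape),
                              rss.reshape(shape), ok.reshape(shape))


class T2DecayResults:
    """Results of a :class:`T2Decay` fit; scalar attributes for single-voxel fits."""

    def __init__(self, model, method, s0, t2_ms, rss, fit_ok):
        self.model = model
        self.method = method
        self._scalar = np.ndim(t2_ms) == 0
        self.s0 = float(s0) if self._scalar else s0
        self.t2_ms = float(t2_ms) if self._scalar else t2_ms
        self.rss = float(rss) if self._scalar else rss
        self.fit_ok = bool(fit_ok) if self._scalar else fit_ok

    def fittedvalues(self) -> np.ndarray:
        tes = self.model.echo_times_ms
        return np.asarray(self.s0)[..., None] * np.exp(-tes / np.asarray(self.t2_ms)[..., None])

    def summary(self) -> str:
        if self._scalar:
            lines = [
                "T2 decay fit (" + self.method + ")",
                f"  S0     : {self.s0:.4f}",
                f"  T2 (ms): {self.t2_ms:.4f}",
                f"  RSS    : {self.rss:.4g}",
                f"  fit_ok : {self.fit_ok}",
            ]
            return "\n".join(lines)
        ok = np.asarray(self.fit_ok)
        t2 = np.asarray(self.t2_ms)[ok]
        return (f"T2 decay fit ({self.method}): {ok.sum()}/{ok.size} voxels ok, "
                f"median T2 = {np.median(t2):.2f} ms" if ok.any()
                else f"T2 decay fit ({self.method}): no voxel fit")


def fit_t2_voxel(signal: np.ndarray, echo_times_ms: np.ndarray,
                 method: str = "nlls",
                 t2_max: float = T2_MAX_MS) -> Tuple[float, float, float, bool]:
    """Fit one voxel; returns ``(s0, t2_ms, rss, fit_ok)``."""
    res = T2Decay(np.asarray(signal, dtype=float), echo_times_ms).fit(
        method=method, t2_max=t2_max)
    return res.s0, res.t2_ms, res.rss, res.fit_ok


def estimate_background_sigma(stack: MultiEchoStack, background: np.ndarray) -> float:
    """Rician noise scale from background voxels: a pure-noise magnitude voxel
    is Rayleigh with mean sigma*sqrt(pi/2)."""
    vals = stack.data[np.asarray(background, dtype=bool)]
    if vals.size == 0:
        return 0.0
    return float(vals.mean() / np.sqrt(np.pi / 2.0))


def fit_t2_map(stack: MultiEchoStack, mask: Optional[Union[RoiMaskSet, np.ndarray]] = None,
               method: str = "nlls", t2_max: float = T2_MAX_MS,
               signal_floor: Optional[float] = None) -> T2Map:
    """Fit the decay at every voxel (inside ``mask`` if given).

    Voxels whose first-echo signal falls below ``signal_floor`` are skipped
    (``fit_ok`` False).  When a :class:`~qmri.phantom.RoiMaskSet` is supplied
    and no floor is given, the floor defaults to 3x the background noise
    scale estimated from unlabelled voxels.
    """
    if isinstance(mask, RoiMaskSet):
        fit_where = mask.labels > 0
        if signal_floor is None:
            sigma = estimate_background_sigma(stack, mask.labels == 0)
            signal_floor = 3.0 * sigma
    elif mask is not None:
        fit_where = np.asarray(mask, dtype=bool)
    else:
        fit_where = np.ones(stack.data.shape[:-1], dtype=bool)
    if signal_floor is None:
        signal_floor = 0.0

    first_echo = stack.data[..., int(np.argmin(stack.echo_times_ms))]
    fit_where = fit_where & (first_echo >= signal_floor)

    shape = stack.data.shape[:-1]
    t2 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    ok = np.zeros(shape, dtype=bool)
    if fit_where.any():
        sig = stack.data[fit_where]
        s0_v, t2_v, rss_v, ok_v = _fit_batch(sig, stack.echo_times_ms, method, t2_max)
        t2[fit_where] = t2_v
        s0[fit_where] = s0_v
        rss[fit_where] = rss_v
        ok[fit_where] = ok_v
    return T2Map(t2_ms=t2, s0=s0, rss=rss, fit_ok=ok)


def roi_t2(t2map: T2Map, rois: RoiMaskSet, mad_k: Optional[float] = None) -> pd.DataFrame:
    """Per-ROI T2 summary over successfully fitted voxels.

    ``n_excluded`` counts voxels dropped for failed fits plus, when ``mad_k``
    is given, robust outliers outside median +/- mad_k * MAD.  ROIs left with
    no usable voxels are flagged ``missing`` (never reported as zero).
    """
    from .roistats import mad_filter

    rows = []
    for name in rois.names:
        m = rois.mask(name)
        vals = t2map.t2_ms[m & t2map.fit_ok]
        n_roi = int(m.sum())
        n_excl = n_roi - vals.size
        if mad_k is not None and vals.size:
            vals, dropped = mad_filter(vals, mad_k)
            n_excl += dropped
        missing = vals.size == 0
        rows.append(dict(
            roi=name,
            mean=float(vals.mean()) if not missing else np.nan,
            median=float(np.median(vals)) if not missing else np.nan,
            n_voxels=int(vals.size),
            n_excluded=n_excl,
            missing=missing,
        ))
    return pd.DataFrame(rows)
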