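"""Temperature extraction from thermal sequences.

Two extraction routes are implemented:

* the *semi-automatic* route — an operator-style rectangular ROI,
  repositioned frame by frame, from which the maximum and minimum
  temperatures are read (one thermogram every 30 s, 20 frames over a
  10-min exercise);
* the *automatic* route — temperatures sampled at tracked keypoint
  coordinates (one frame per second, ~600 frames), with entries below a
  likelihood cut discarded.

Profiles can be smoothed with a robust lowess filter (2% span by
default) to suppress outlier spikes while preserving the overall trend.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np

from .datatypes import (KeypointTrack, RectROI, ThermalSequence, ZoneProfile,
                        ZoneProfileSet)


def sample_indices(timestamps: np.ndarray, interval_s: float) -> np.ndarray:
    """Indices of the frames nearest to interval_s, 2*interval_s, ...

    Target times run up to the nominal duration (one frame period past
    the last timestamp); the t=0 frame is never a target, so a 600 s run
    yields exactly 20 frames at a 30 s interval and 600 at 1 s. Ties
    between two equally near frames resolve to the earlier frame.
    """
    ts = np.asarray(timestamps, dtype=float)
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    if len(ts) == 0:
        return np.empty(0, dtype=int)
    if len(ts) > 1:
        spacing = (ts[-1] - ts[0]) / (len(ts) - 1)
        if interval_s < spacing - 1e-9:
            raise ValueError(
                f"interval {interval_s} s is shorter than the frame "
                f"spacing {spacing:.6g} s")
        duration = ts[-1] + spacing
    else:
        duration = ts[-1]
    n_targets = int(math.floor(duration / interval_s + 1e-9))
    if n_targets < 1:
        warnings.warn("sampling interval exceeds the sequence duration; "
                      "no frames selected")
        return np.empty(0, dtype=int)
    targets = interval_s * np.arange(1, n_targets + 1)

    pos = np.searchsorted(ts, targets)
    pos = np.clip(pos, 0, len(ts) - 1)
    prev = np.clip(pos - 1, 0, len(ts) - 1)
    take_prev = np.abs(ts[prev] - targets) <= np.abs(ts[pos] - targets)
    return np.where(take_prev, prev, pos).astype(int)


def sample_frames(seq: ThermalSequence, interval_s: float) -> ThermalSequence:
    """Subsample a sequence to one frame per ``interval_s`` seconds."""
    idx = sample_indices(seq.timestamps, interval_s)
    return ThermalSequence(frames=seq.frames[idx], timestamps=seq.timestamps[idx])


def roi_extrema(frame: np.ndarray, roi: RectROI):
    """Max and min temperature inside a rectangular ROI.

    The ROI is clipped to the frame; an empty intersection raises.
    Returns ``(t_max, t_min, argmax_xy, argmin_xy)`` with argument
    positions as (x, y) in full-frame coordinates; ties break to the
    row-major first occurrence.
    """
    frame = np.asarray(frame, dtype=float)
    x0, x1, y0, y1 = roi.clipped(frame.shape)
    sub = frame[y0:y1, x0:x1]
    imax = int(np.argmax(sub))
    imin = int(np.argmin(sub))
    my, mx = divmod(imax, sub.shape[1])
    ny, nx = divmod(imin, sub.shape[1])
    return (float(sub.flat[imax]), float(sub.flat[imin]),
            (x0 + mx, y0 + my), (x0 + nx, y0 + ny))


def track_roi(prev_roi: RectROI, displacement_px: tuple[int, int],
              frame_shape: tuple[int, int] | None = None) -> RectROI:
    """Translate an ROI by (dx, dy), emulating per-frame repositioning.

    Size is preserved. If ``frame_shape`` (height, width) is given and
    the displaced ROI no longer intersects the frame, raises.
    """
    dx, dy = displacement_px
    moved = RectROI(prev_roi.x0 + int(dx), prev_roi.y0 + int(dy),
                    prev_roi.w, prev_roi.h)
    if frame_shape is not None and not moved.intersects(frame_shape):
        raise ValueError("displaced ROI leaves the frame entirely")
    return moved


def sample_at_keypoints(seq: ThermalSequence, track: KeypointTrack,
                        p_cut: float = 0.5,
                        radius_px: int = 1) -> ZoneProfileSet:
    """Extract per-zone temperature profiles at tracked keypoints.

    For each frame and zone with likelihood >= ``p_cut``, the
    temperature is the mean over the (2r+1) x (2r+1) pixel window
    centred at the keypoint rounded half-up to a pixel, with the window
    clipped to the frame. Entries below the cut, or whose rounded
    centre falls outside the frame, are omitted (counted in ``.qc``).
    """
    if not 0.0 <= p_cut <= 1.0:
        raise ValueError("p_cut must lie in [0, 1]")
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if len(track) != len(seq) or not np.allclose(track.times, seq.timestamps,
                                                 atol=1e-6, rtol=0):
        track = track.at_times(seq.timestamps)

    h, w = seq.frames.shape[1:]
    r = int(radius_px)
    out = ZoneProfileSet()
    keep = track.likelihood >= p_cut
    out.qc["dropped_low_likelihood"] = int((~keep).sum())

    px = np.floor(track.x + 0.5).astype(int)
    py = np.floor(track.y + 0.5).astype(int)
    inside = (px >= 0) & (px < w) & (py >= 0) & (py < h)
    n_oob = int((keep & ~inside).sum())
    if n_oob:
        warnings.warn(f"{n_oob} keypoint(s) fell outside the frame and "
                      "were omitted")
    out.qc["dropped_out_of_frame"] = n_oob

    for zi, zone in enumerate(track.zones):
        sel = np.flatnonzero(keep[:, zi] & inside[:, zi])
        temps = np.empty(len(sel))
        for k, fi in enumerate(sel):
            cx, cy = px[fi, zi], py[fi, zi]
            win = seq.frames[fi,
                             max(cy - r, 0):min(cy + r + 1, h),
                             max(cx - r, 0):min(cx + r + 1, w)]
            temps[k] = win.mean()
        if len(sel) == 0:
            warnings.warn(f"zone {zone.value}: no keypoints above p_cut; "
                          "profile is empty")
            out.qc["empty_zones"].append(zone.value)
        out[zone] = ZoneProfile(zone=zone, times=seq.timestamps[sel],
                                temps_c=temps, method="automatic")
    return out


def _rlowess(t: np.ndarray, y: np.ndarray, window: int,
             robust_iters: int = 5) -> np.ndarray:
    """Robust locally weighted linear regression (lowess).

    Each point is fit by weighted linear regression over its ``window``
    nearest neighbours in time with tricube distance weights; bisquare
    robustness weights, computed from the residuals with the 6*MAD rule,
    are re-estimated for ``robust_iters`` iterations to reject outlier
    spikes. A pure line (zero residuals) is reproduced exactly.
    """
    n = len(y)
    window = min(max(2, int(window)), n)
    fit = y.astype(float).copy()
    rw = np.ones(n)
    for itr in range(robust_iters + 1):
        for j in range(n):
            lo, hi = j, j + 1
            while hi - lo < window:
                if lo == 0:
                    hi += 1
                elif hi == n:
                    lo -= 1
                elif t[j] - t[lo - 1] <= t[hi] - t[j]:
                    lo -= 1
                else:
                    hi += 1
            tt = t[lo:hi]
            yy = y[lo:hi]
            d = np.abs(tt - t[j])
            dmax = d.max()
            wts = (1.0 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
            wts = wts * rw[lo:hi]
            sw = wts.sum()
            if sw <= 0:
                fit[j] = y[j]
                continue
            tm = (wts * tt).sum() / sw
            ym = (wts * yy).sum() / sw
            var = (wts * (tt - tm) ** 2).sum()
            if var > 0:
                b = (wts * (tt - tm) * (yy - ym)).sum() / var
                fit[j] = ym + b * (t[j] - tm)
            else:
                fit[j] = ym
        if itr == robust_iters:
            break
        resid = y - fit
        # Residuals at float rounding level count as an exact fit: the
        # robust scale is the MAD of the residuals above that floor
        # (otherwise an exactly-fit series with isolated spikes drives
        # the MAD to rounding noise and every weight to zero). Weights
        # only ever decrease, so a rejected spike stays rejected instead
        # of oscillating back in once the fit elsewhere is exact.
        floor = 1e-9 * max(1.0, float(np.max(np.abs(y))))
        big = np.abs(resid) > floor
        if not np.any(big):
            break  # perfect fit; nothing to robustify
        scale = 6.0 * float(np.median(np.abs(resid[big])))
        u = np.clip(resid / scale, -1.0, 1.0)
        rw = np.minimum(rw, (1.0 - u * u) ** 2)
    return fit


def smooth_profile(p: ZoneProfile, span_fraction: float = 0.02) -> ZoneProfile:
    """Robust lowess smoothing of a zone profile.

    The local window holds ``max(2, ceil(span_fraction * n))`` nearest
    points. Profiles with fewer than 3 points are returned unsmoothed
    with a warning.
    """
    if not 0.0 < span_fraction <= 1.0:
        raise ValueError("span_fraction must lie in (0, 1]")
    n = len(p)
    if n < 3:
        warnings.warn("fewer than 3 points; profile returned unsmoothed")
        return replace(p)
    window = max(2, math.ceil(span_fraction * n))
    smoothed = _rlowess(p.times, p.temps_c, window)
    return ZoneProfile(zone=p.zone, times=p.times.copy(), temps_c=smoothed,
                       method=p.method, smoothed=True)
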