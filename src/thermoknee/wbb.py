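"""Balance-board (four corner load cells) processing.

Converts a corner-load record into total weight, sit/stand phase
labels, per-leg and fore/rearfoot load shares, centre-of-pressure
trajectories and a participant-level weight-asymmetry flag. No
filtering is applied to the board data.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .datatypes import CoPSeries, LoadCellSeries, PhaseSegmentation, WeightSummary

#: Published sensor spacing of the board, mm (x: medio-lateral,
#: y: antero-posterior). Share computations are span-independent.
DEFAULT_SPAN_X_MM = 433.0
DEFAULT_SPAN_Y_MM = 238.0

#: Standing samples with a board total below this are unreliable.
MIN_VALID_TOTAL_KG = 1.0


def total_weight(s: LoadCellSeries) -> np.ndarray:
    """Element-wise sum of the four corner loads, kg."""
    return s.tl + s.tr + s.bl + s.br


def segment_phases(s: LoadCellSeries, stand_frac: float = 0.8,
                   sit_frac: float = 0.25) -> PhaseSegmentation:
    """Label each sample sitting / standing / transition.

    The static (standing) weight is the median of the totals above
    their 75th percentile. Samples at or above ``stand_frac`` of the
    static weight are standing, at or below ``sit_frac`` sitting, the
    rest transition. The cycle count is the number of sitting ->
    standing passages.
    """
    if not 0.0 < sit_frac < stand_frac < 1.0:
        raise ValueError("need 0 < sit_frac < stand_frac < 1")
    total = total_weight(s)
    if len(total) == 0:
        raise ValueError("empty series")
    q75 = np.quantile(total, 0.75)
    static = float(np.median(total[total >= q75]))
    if static < MIN_VALID_TOTAL_KG:
        raise ValueError("no standing phase detected")

    labels = np.full(len(total), "transition", dtype=object)
    labels[total >= stand_frac * static] = "standing"
    labels[total <= sit_frac * static] = "sitting"
    labels = labels.astype(str)
    if not np.any(labels == "standing"):
        raise ValueError("no standing phase detected")

    plateau = labels[labels != "transition"]
    cycles = int(np.sum((plateau[:-1] == "sitting")
                        & (plateau[1:] == "standing"))) if len(plateau) else 0
    return PhaseSegmentation(labels=labels, static_weight_kg=static,
                             cycle_count=cycles)


def leg_shares(s: LoadCellSeries, phases: PhaseSegmentation):
    """Left/right load fractions over standing samples.

    Returns ``(left, right, valid)`` full-length arrays; entries are
    NaN outside standing samples or where the total is below 1 kg
    (marked invalid). Negative corner readings are clipped to zero
    before the shares are formed.
    """
    c = np.clip(s.corners(), 0.0, None)
    total = c.sum(axis=1)
    standing = phases.standing
    valid = standing & (total >= MIN_VALID_TOTAL_KG)
    left = np.full(len(s), np.nan)
    left[valid] = (c[valid, 0] + c[valid, 2]) / total[valid]
    right = np.where(np.isnan(left), np.nan, 1.0 - left)
    return left, right, valid


def foot_region_shares(s: LoadCellSeries, phases: PhaseSegmentation):
    """Rearfoot load fraction per leg over standing samples.

    Returns ``(rear_left, rear_right, valid_left, valid_right)``;
    samples where a leg carries less than 0.5 kg are invalid (NaN).
    """
    c = np.clip(s.corners(), 0.0, None)
    standing = phases.standing
    left_total = c[:, 0] + c[:, 2]
    right_total = c[:, 1] + c[:, 3]
    valid_l = standing & (left_total >= 0.5)
    valid_r = standing & (right_total >= 0.5)
    rear_l = np.full(len(s), np.nan)
    rear_r = np.full(len(s), np.nan)
    rear_l[valid_l] = c[valid_l, 2] / left_total[valid_l]
    rear_r[valid_r] = c[valid_r, 3] / right_total[valid_r]
    return rear_l, rear_r, valid_l, valid_r


def cop(s: LoadCellSeries, span_x_mm: float = DEFAULT_SPAN_X_MM,
        span_y_mm: float = DEFAULT_SPAN_Y_MM,
        phases: Optional[PhaseSegmentation] = None) -> CoPSeries:
    """Centre-of-pressure trajectory from the corner-moment balance.

    x = (span_x/2) * ((TR+BR) - (TL+BL)) / total  (medio-lateral,
    positive toward the participant's right);
    y = (span_y/2) * ((TL+TR) - (BL+BR)) / total  (antero-posterior,
    positive forward). Samples with total < 1 kg are flagged invalid.
    ``corner_pct`` is each corner's time-integrated load fraction over
    standing samples (all valid samples if no segmentation is given).
    """
    if span_x_mm <= 0 or span_y_mm <= 0:
        raise ValueError("sensor spans must be positive")
    total = total_weight(s)
    valid = total >= MIN_VALID_TOTAL_KG
    x = np.full(len(s), np.nan)
    y = np.full(len(s), np.nan)
    x[valid] = 0.5 * span_x_mm * ((s.tr + s.br) - (s.tl + s.bl))[valid] / total[valid]
    y[valid] = 0.5 * span_y_mm * ((s.tl + s.tr) - (s.bl + s.br))[valid] / total[valid]

    sel = valid if phases is None else (phases.standing & valid)
    corner_pct: dict[str, float] = {}
    if np.any(sel):
        sums = np.clip(s.corners()[sel], 0.0, None).sum(axis=0)
        corner_pct = dict(zip(("TL", "TR", "BL", "BR"),
                              (sums / sums.sum()).tolist()))
    return CoPSeries(x_mm=x, y_mm=y, valid=valid, corner_pct=corner_pct)


def asymmetry_flag(left_share_mean: float, threshold: float = 0.52):
    """Weight-asymmetry flag from the mean standing left-leg share.

    True iff either leg carries strictly more than ``threshold`` of the
    load on average; returns ``(flag, heavier_leg)`` with the heavier
    leg as "left", "right" or None.
    """
    right = 1.0 - left_share_mean
    if left_share_mean > threshold:
        return True, "left"
    if right > threshold:
        return True, "right"
    heavier = ("left" if left_share_mean > 0.5
               else "right" if right > 0.5 else None)
    return False, heavier


def summarize_weight(s: LoadCellSeries, phases: Optional[PhaseSegmentation] = None,
                     stand_frac: float = 0.8, sit_frac: float = 0.25,
                     asym_threshold: float = 0.52) -> WeightSummary:
    """Participant-level weight-distribution summary."""
    if phases is None:
        phases = segment_phases(s, stand_frac=stand_frac, sit_frac=sit_frac)
    left, right, _ = leg_shares(s, phases)
    rear_l, rear_r, _, _ = foot_region_shares(s, phases)
    left_mean = float(np.nanmean(left))
    trajectory = cop(s, phases=phases)
    flag, heavier = asymmetry_flag(left_mean, asym_threshold)
    rears = np.concatenate([rear_l[~np.isnan(rear_l)], rear_r[~np.isnan(rear_r)]])
    return WeightSummary(
        static_weight_kg=phases.static_weight_kg,
        left_share_mean=left_mean,
        left_share_max=float(np.nanmax(left)),
        right_share_max=float(np.nanmax(right)),
        rear_share=float(rears.mean()) if len(rears) else float("nan"),
        corner_pct=trajectory.corner_pct,
        asymmetric=flag,
        heavier_leg=heavier,
        cycle_count=phases.cycle_count,
    )
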