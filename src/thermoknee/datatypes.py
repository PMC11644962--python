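"""Core in-memory containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .zones import KneeZone, ZONES


@dataclass
class ThermalSequence:
    """Timestamped stack of 2-D temperature grids (degC).

    ``frames`` has shape (n, height, width); ``timestamps`` are seconds
    from the start of the recording, strictly increasing.
    """

    frames: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps must match frame count")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("temperatures must be finite")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def height_px(self) -> int:
        return self.frames.shape[1]

    @property
    def width_px(self) -> int:
        return self.frames.shape[2]

    @property
    def nominal_duration_s(self) -> float:
        """End of the recording assuming one more frame period after the
        last timestamp (a 600 s run at 20 Hz ends at 600 s, not 599.95)."""
        ts = self.timestamps
        if len(ts) < 2:
            return float(ts[-1]) if len(ts) else 0.0
        return float(ts[-1] + (ts[-1] - ts[0]) / (len(ts) - 1))


@dataclass
class RectROI:
    """Axis-aligned rectangular region of interest.

    ``x0, y0`` is the top-left pixel (0-based, inclusive); ``w, h`` are
    the width and height in pixels.
    """

    x0: int
    y0: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError("ROI must be at least 1x1 pixel")

    def clipped(self, frame_shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Return (x0, x1, y0, y1) of the ROI intersected with a
        (height, width) frame; raises if the intersection is empty."""
        fh, fw = frame_shape
        x0 = max(self.x0, 0)
        y0 = max(self.y0, 0)
        x1 = min(self.x0 + self.w, fw)
        y1 = min(self.y0 + self.h, fh)
        if x0 >= x1 or y0 >= y1:
            raise ValueError("ROI does not intersect the frame")
        return x0, x1, y0, y1

    def intersects(self, frame_shape: tuple[int, int]) -> bool:
        try:
            self.clipped(frame_shape)
        except ValueError:
            return False
        return True


@dataclass
class KeypointTrack:
    """Per-frame, per-zone tracked image coordinates with likelihood.

    Coordinates are 0-based with the origin at the top-left corner and y
    increasing downward. Arrays ``x``, ``y`` and ``likelihood`` have
    shape (n_frames, 12) in the canonical zone order.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    zones: tuple[KneeZone, ...] = ZONES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n = len(self.times)
        nz = len(self.zones)
        for name, arr in (("x", self.x), ("y", self.y),
                          ("likelihood", self.likelihood)):
            if arr.shape != (n, nz):
                raise ValueError(f"{name} must have shape (n_frames, n_zones)")
        if np.any((self.likelihood < 0) | (self.likelihood > 1)):
            raise ValueError("likelihood must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)

    def subset(self, indices: np.ndarray) -> "KeypointTrack":
        return KeypointTrack(self.times[indices], self.x[indices],
                             self.y[indices], self.likelihood[indices],
                             self.zones)

    def at_times(self, times: np.ndarray, tol: float = 1e-6) -> "KeypointTrack":
        """Subset to the rows whose timestamps match ``times``."""
        idx = np.searchsorted(self.times, times)
        idx = np.clip(idx, 0, len(self.times) - 1)
        left = np.clip(idx - 1, 0, len(self.times) - 1)
        use_left = np.abs(self.times[left] - times) < np.abs(self.times[idx] - times)
        idx = np.where(use_left, left, idx)
        if np.any(np.abs(self.times[idx] - times) > tol):
            raise ValueError("track does not cover the requested timestamps")
        return self.subset(idx)


@dataclass
class LoadCellSeries:
    """Four-corner balance-board record in kg at a fixed rate.

    Corners are named from the participant's perspective: T = top
    (forefoot), B = bottom (rearfoot), L/R = left/right leg.
    """

    times: np.ndarray
    tl: np.ndarray
    tr: np.ndarray
    bl: np.ndarray
    br: np.ndarray
    rate_hz: float = 20.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("tl", "tr", "bl", "br"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.times.shape:
                raise ValueError("all load-cell channels must match times")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        low = min(a.min() for a in (self.tl, self.tr, self.bl, self.br)) \
            if len(self.times) else 0.0
        if low < -0.5:
            raise ValueError("load below -0.5 kg: not sensor noise")

    def __len__(self) -> int:
        return len(self.times)

    def corners(self) -> np.ndarray:
        """(n, 4) array in TL, TR, BL, BR order."""
        return np.stack([self.tl, self.tr, self.bl, self.br], axis=1)


@dataclass
class ZoneProfile:
    """Temperature-vs-time series for one zone from one method."""

    zone: Optional[KneeZone]
    times: np.ndarray
    temps_c: np.ndarray
    method: str = "automatic"
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temps_c = np.asarray(self.temps_c, dtype=float)
        if self.times.shape != self.temps_c.shape:
            raise ValueError("times and temps_c must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


class ZoneProfileSet(dict):
    """Mapping zone -> ZoneProfile, with extraction QC counters."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.qc: dict = {"dropped_low_likelihood": 0,
                         "dropped_out_of_frame": 0,
                         "empty_zones": []}


@dataclass
class CoPSeries:
    """Centre-of-pressure trajectory on the board plane.

    x is medio-lateral (positive toward the participant's right), y is
    antero-posterior (positive forward); (0, 0) is the board centre.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    valid: np.ndarray
    corner_pct: dict[str, float] = field(default_factory=dict)


@dataclass
class PhaseSegmentation:
    """Per-sample sit/stand/transition labels with cycle count."""

    labels: np.ndarray  # values in {"sitting", "standing", "transition"}
    static_weight_kg: float
    cycle_count: int

    @property
    def standing(self) -> np.ndarray:
        return self.labels == "standing"

    @property
    def sitting(self) -> np.ndarray:
        return self.labels == "sitting"


@dataclass
class WeightSummary:
    """Participant-level weight-distribution summary over standing samples."""

    static_weight_kg: float
    left_share_mean: float
    left_share_max: float
    right_share_max: float
    rear_share: float
    corner_pct: dict[str, float]
    asymmetric: bool
    heavier_leg: Optional[str]
    cycle_count: int

    def to_dict(self) -> dict:
        return {
            "static_weight_kg": self.static_weight_kg,
            "left_share_mean": self.left_share_mean,
            "left_share_max": self.left_share_max,
            "right_share_max": self.right_share_max,
            "rear_share": self.rear_share,
            "corner_pct": self.corner_pct,
            "asymmetric": self.asymmetric,
            "heavier_leg": self.heavier_leg,
            "cycle_count": self.cycle_count,
        }
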