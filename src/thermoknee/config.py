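"""Configuration objects for the synthetic cohort generator."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .zones import DEFAULT_ZONE_TRENDS_C_PER_MIN, DEFAULT_BASELINES_C, REGIONS


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic participant recording.

    Defaults reproduce the acquisition conditions the pipeline is built
    for: a 10-min sit-to-stand exercise recorded by a 382x288 px thermal
    camera at 20 Hz with 0.04 degC sensitivity, cycles paced at one
    every 3-4 s, a markerless tracker with 9.3 px RMS error and mean
    likelihood 0.99, and a four-cell balance board sampled at 20 Hz.

    Parameters
    ----------
    duration_s : float
        Recording length in seconds (default 600).
    frame_rate_hz : float
        Thermal and load-cell sampling rate (default 20).
    width_px, height_px : int
        Thermal frame size (defaults 382 x 288).
    thermal_noise_c : float
        Per-pixel i.i.d. Gaussian noise std in degC (default 0.04,
        the camera's thermal sensitivity).
    cycle_period_s : (float, float)
        Range from which each sit-to-stand cycle period is drawn
        uniformly, seconds (default (3, 4)).
    zone_trends_c_per_min : dict
        Region -> temperature slope in degC/min, applied to both legs.
        Default: SM warming +0.08, P and PT cooling -0.05, others flat.
    zone_baselines_c : dict
        Region -> baseline temperature at t=0 in degC.
    background_c : float
        Uniform skin-background temperature of the rendered field, degC.
    blob_sigma_px : float
        Gaussian footprint (std) of each zone's thermal deviation, px.
    tracker_rms_px : float
        RMS radial keypoint error of the simulated tracker (default 9.3).
    likelihood_mean : float
        Mean tracker likelihood for retained detections (default 0.99).
    dropout_prob : float
        Fraction of (frame, zone) entries whose likelihood falls below
        the 0.5 cut (default 0.01).
    left_share : float
        Fraction of the standing load carried by the left leg
        (0.50 symmetric; the asymmetric regime of interest is
        0.52-0.545).
    rear_share : float
        Fraction of each leg's standing load on the rearfoot (0.65).
    body_mass_kg : float
        Participant mass (default 69.1 kg, the cohort mean).
    coupling_gain : float
        Extra warming slope (degC/min per unit excess load share) added
        to the heavier leg's SM zone.
    cooling_gain : float
        Extra cooling slope (degC/min per unit excess share) added to
        the heavier leg's P zone (default 0; enables constructing
        cooling-mode agreement scenarios).
    excursion_amplitude_px : float
        Vertical knee-centre excursion between sitting and standing, px.
    layout_scale : float
        Scale factor applied to the zone layout offsets (use < 1 with
        small frames).
    knee_x_frac : (float, float)
        Horizontal knee-centre positions as fractions of the width
        (right knee first: the participant faces the camera).
    sit_knee_y_frac : float
        Vertical knee-centre position while sitting, fraction of height.
    sitting_load_frac : float
        Residual fraction of body mass on the board while seated.
    loadcell_noise_kg : float
        Gaussian noise std per load cell, kg (default 0.1).
    seed : int
        Master seed; identical configs produce bit-identical outputs.
    """

    duration_s: float = 600.0
    frame_rate_hz: float = 20.0
    width_px: int = 382
    height_px: int = 288
    thermal_noise_c: float = 0.04
    cycle_period_s: tuple[float, float] = (3.0, 4.0)
    zone_trends_c_per_min: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_TRENDS_C_PER_MIN))
    zone_baselines_c: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES_C))
    background_c: float = 31.0
    blob_sigma_px: float = 30.0
    tracker_rms_px: float = 9.3
    likelihood_mean: float = 0.99
    dropout_prob: float = 0.01
    left_share: float = 0.50
    rear_share: float = 0.65
    body_mass_kg: float = 69.1
    coupling_gain: float = 1.0
    cooling_gain: float = 0.0
    excursion_amplitude_px: float = 40.0
    layout_scale: float = 1.0
    knee_x_frac: tuple[float, float] = (0.28, 0.72)
    sit_knee_y_frac: float = 0.55
    sitting_load_frac: float = 0.05
    loadcell_noise_kg: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.left_share < 1.0:
            raise ConfigurationError("left_share must lie in (0, 1)")
        if not 0.0 < self.rear_share < 1.0:
            raise ConfigurationError("rear_share must lie in (0, 1)")
        if self.frame_rate_hz <= 0:
            raise ConfigurationError("frame_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.thermal_noise_c < 0:
            raise ConfigurationError("thermal_noise_c must be >= 0")
        if self.tracker_rms_px < 0:
            raise ConfigurationError("tracker_rms_px must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError("dropout_prob must lie in [0, 1]")
        if not 0.0 <= self.likelihood_mean <= 1.0:
            raise ConfigurationError("likelihood_mean must lie in [0, 1]")
        lo, hi = self.cycle_period_s
        if not 0 < lo <= hi:
            raise ConfigurationError("cycle_period_s must satisfy 0 < lo <= hi")
        if self.excursion_amplitude_px < 0:
            raise ConfigurationError("excursion_amplitude_px must be >= 0")
        missing = [r for r in REGIONS if r not in self.zone_baselines_c]
        if missing:
            raise ConfigurationError(f"zone_baselines_c missing regions {missing}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cycle_period_s"] = list(self.cycle_period_s)
        d["knee_x_frac"] = list(self.knee_x_frac)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "cycle_period_s" in d:
            d["cycle_period_s"] = tuple(d["cycle_period_s"])
        if "knee_x_frac" in d:
            d["knee_x_frac"] = tuple(d["knee_x_frac"])
        return cls(**d)
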