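"""Synthetic participant generator.

Emulates the three data streams of a sit-to-stand thermography session
with known ground truth: a thermal image sequence, a markerless-tracker
keypoint file, and a four-cell balance-board record. The thermal field
is a uniform skin background plus per-zone Gaussian deviations combined
by largest magnitude, so each zone's centre pixel carries exactly its
configured true temperature; zone centres ride a raised-cosine vertical
excursion between the sitting and standing poses.

Determinism: every random stream is derived from ``cfg.seed`` through
fixed sub-stream keys, so identical configs give bit-identical outputs
(including when only a subset of frames is rendered).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import ConfigurationError, SyntheticConfig
from .datatypes import KeypointTrack, LoadCellSeries, ThermalSequence
from .zones import ZONES, ZONE_OFFSETS_PX, Leg

_STREAM_KINEMATICS = 0
_STREAM_TRACKER = 1
_STREAM_THERMAL = 2
_STREAM_LOADCELLS = 3


@dataclass
class GroundTruth:
    """True state of a synthetic recording, per frame.

    ``zone_centers_px`` (n, 12, 2) holds integer-valued (x, y) centres;
    ``zone_temps_c`` (n, 12) the true centre temperatures;
    ``zone_amp_c`` their deviation from the background (the renderer
    uses the stored amplitude so background + amp reproduces the
    temperature bit-exactly); ``phase`` per-sample labels in
    {sitting, standing, transition}; ``excursion_px`` the continuous
    knee-lift signal the labels derive from.
    """

    times: np.ndarray
    zone_centers_px: np.ndarray
    zone_temps_c: np.ndarray
    zone_amp_c: np.ndarray
    phase: np.ndarray
    excursion_px: np.ndarray
    cycle_count: int
    static_weight_kg: float
    knee_centers_px: np.ndarray  # (n, 2, 2): [right, left] knee (x, y)

    def __len__(self) -> int:
        return len(self.times)


def _heavier_leg(cfg: SyntheticConfig) -> Optional[Leg]:
    if cfg.left_share > 0.5:
        return Leg.LEFT
    if cfg.left_share < 0.5:
        return Leg.RIGHT
    return None


def zone_slopes_c_per_min(cfg: SyntheticConfig) -> np.ndarray:
    """True temperature slope of each of the 12 zones, degC/min.

    The regional trend applies to both legs; the load-coupling terms add
    ``coupling_gain * excess`` warming to the heavier leg's SM zone and
    ``cooling_gain * excess`` extra cooling to its P zone, where excess
    is the share above 0.5.
    """
    slopes = np.array([cfg.zone_trends_c_per_min.get(z.region, 0.0)
                       for z in ZONES])
    heavy = _heavier_leg(cfg)
    if heavy is not None:
        excess = abs(cfg.left_share - 0.5)
        for i, z in enumerate(ZONES):
            if z.leg is heavy and z.region == "SM":
                slopes[i] += cfg.coupling_gain * excess
            if z.leg is heavy and z.region == "P":
                slopes[i] -= cfg.cooling_gain * excess
    return slopes


def generate_kinematics(cfg: SyntheticConfig) -> GroundTruth:
    """Simulate the sit-to-stand motion and true zone temperatures.

    Cycle periods are drawn uniformly from ``cfg.cycle_period_s``; the
    knee centres rise by a raised-cosine excursion within each cycle and
    only complete cycles are generated (any remainder is spent sitting).
    Phase labels: sitting below 25% of the excursion amplitude, standing
    above 75%, transition in between (a zero-amplitude configuration is
    a static standing pose).
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_KINEMATICS])
    n = cfg.n_samples
    times = np.arange(n) / cfg.frame_rate_hz
    amp = cfg.excursion_amplitude_px

    # Draw complete cycles until the duration is filled.
    starts, periods = [], []
    t = 0.0
    while True:
        period = rng.uniform(*cfg.cycle_period_s)
        if t + period > cfg.duration_s + 1e-12:
            break
        starts.append(t)
        periods.append(period)
        t += period
    cycle_count = len(periods)

    excursion = np.zeros(n)
    for s, p in zip(starts, periods):
        mask = (times >= s) & (times < s + p)
        excursion[mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (times[mask] - s) / p))
    excursion *= amp

    if amp == 0:
        phase = np.full(n, "standing", dtype=object)
    else:
        phase = np.full(n, "transition", dtype=object)
        phase[excursion < 0.25 * amp] = "sitting"
        phase[excursion > 0.75 * amp] = "standing"
    phase = phase.astype(str)

    # Knee centres: fixed x, vertical raised-cosine lift (image y is down).
    kx = np.array([cfg.knee_x_frac[0] * cfg.width_px,
                   cfg.knee_x_frac[1] * cfg.width_px])
    sit_y = cfg.sit_knee_y_frac * cfg.height_px
    knee = np.empty((n, 2, 2))
    knee[:, :, 0] = kx[None, :]
    knee[:, :, 1] = (sit_y - excursion)[:, None]

    # Zone centres: knee centre + mirrored anatomical offsets, rounded
    # to pixel centres.
    centers = np.empty((n, len(ZONES), 2))
    for i, z in enumerate(ZONES):
        dx, dy = ZONE_OFFSETS_PX[z.region]
        dx *= cfg.layout_scale
        dy *= cfg.layout_scale
        if z.leg is Leg.RIGHT:
            k, medial = 0, 1.0   # right knee on image left; medial is +x
        else:
            k, medial = 1, -1.0
        centers[:, i, 0] = knee[:, k, 0] + medial * dx
        centers[:, i, 1] = knee[:, k, 1] + dy
    centers = np.floor(centers + 0.5)  # integer pixel centres

    if (centers[:, :, 0].min() < 0 or centers[:, :, 1].min() < 0
            or centers[:, :, 0].max() >= cfg.width_px
            or centers[:, :, 1].max() >= cfg.height_px):
        raise ConfigurationError(
            "image too small to contain the 12-zone layout; reduce "
            "layout_scale/excursion or enlarge the frame")

    baselines = np.array([cfg.zone_baselines_c[z.region] for z in ZONES])
    slopes = zone_slopes_c_per_min(cfg)
    t_min = times / 60.0
    amp_c = (baselines - cfg.background_c)[None, :] + t_min[:, None] * slopes[None, :]
    temps = cfg.background_c + amp_c

    return GroundTruth(times=times, zone_centers_px=centers,
                       zone_temps_c=temps, zone_amp_c=amp_c, phase=phase,
                       excursion_px=excursion, cycle_count=cycle_count,
                       static_weight_kg=cfg.body_mass_kg,
                       knee_centers_px=knee)


def _render_frame(cfg: SyntheticConfig, gt: GroundTruth, i: int) -> np.ndarray:
    """Noise-free thermal field of frame ``i``.

    Background + per-zone Gaussian deviations; where blobs overlap the
    deviation of largest magnitude wins, so each zone centre reads
    exactly its true temperature.
    """
    h, w = cfg.height_px, cfg.width_px
    sigma = cfg.blob_sigma_px * cfg.layout_scale  # blob scales with the layout
    half = int(np.ceil(4.0 * sigma))
    dev = np.zeros((h, w))
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for zi in range(len(ZONES)):
        a = gt.zone_amp_c[i, zi]
        cx, cy = gt.zone_centers_px[i, zi]
        x0 = max(int(cx) - half, 0)
        x1 = min(int(cx) + half + 1, w)
        y0 = max(int(cy) - half, 0)
        y1 = min(int(cy) + half + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        g = a * np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) * inv2s2)
        sub = dev[y0:y1, x0:x1]
        np.copyto(sub, g, where=np.abs(g) > np.abs(sub))
    return cfg.background_c + dev


def render_thermal(cfg: SyntheticConfig, gt: GroundTruth,
                   indices: Optional[Sequence[int]] = None) -> ThermalSequence:
    """Render (a subset of) the thermal sequence.

    ``indices`` selects which ground-truth frames to render (all by
    default); per-frame noise streams are keyed by the absolute frame
    index, so a rendered frame is identical whether or not its
    neighbours were rendered.
    """
    idx = np.arange(len(gt)) if indices is None else np.asarray(indices, dtype=int)
    frames = np.empty((len(idx), cfg.height_px, cfg.width_px))
    for k, i in enumerate(idx):
        f = _render_frame(cfg, gt, int(i))
        if cfg.thermal_noise_c > 0:
            rng = np.random.default_rng([cfg.seed, _STREAM_THERMAL, int(i)])
            f = f + rng.normal(0.0, cfg.thermal_noise_c, f.shape)
        frames[k] = f
    return ThermalSequence(frames=frames, timestamps=gt.times[idx])


def simulate_tracker(cfg: SyntheticConfig, gt: GroundTruth) -> KeypointTrack:
    """Simulate markerless-tracker output for every frame.

    Observed keypoints are the true centres plus isotropic Gaussian
    error with radial RMS ``tracker_rms_px`` (per-axis std rms/sqrt(2)).
    Likelihoods are Beta-distributed around ``likelihood_mean``; a
    ``dropout_prob`` fraction of entries instead draw a likelihood
    uniformly below the 0.5 cut.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_TRACKER])
    n, nz = len(gt), len(ZONES)
    sd = cfg.tracker_rms_px / np.sqrt(2.0)
    err = rng.normal(0.0, sd, (n, nz, 2)) if sd > 0 else np.zeros((n, nz, 2))
    obs = gt.zone_centers_px + err

    if cfg.likelihood_mean >= 1.0:
        base = np.ones((n, nz))
    elif cfg.likelihood_mean <= 0.0:
        base = np.zeros((n, nz))
    else:
        conc = 200.0
        base = rng.beta(cfg.likelihood_mean * conc,
                        (1.0 - cfg.likelihood_mean) * conc, (n, nz))
    low = rng.uniform(0.0, 0.5, (n, nz))
    drop = rng.random((n, nz)) < cfg.dropout_prob
    lik = np.where(drop, low, base)

    return KeypointTrack(times=gt.times, x=obs[:, :, 0], y=obs[:, :, 1],
                         likelihood=lik, zones=ZONES)


def simulate_loadcells(cfg: SyntheticConfig, gt: GroundTruth) -> LoadCellSeries:
    """Simulate the four-corner balance-board record.

    The instantaneous board total follows the excursion: full body mass
    while standing, a small chair-residual fraction while sitting, with
    smooth raised-cosine transitions in between. The total splits
    left/right by ``left_share`` and fore/rear by ``rear_share``; the
    corner sum equals the instantaneous total exactly before noise.
    """
    amp = cfg.excursion_amplitude_px
    lift = gt.excursion_px / amp if amp > 0 else np.ones(len(gt))
    resid = cfg.sitting_load_frac
    total = cfg.body_mass_kg * (resid + (1.0 - resid) * np.clip(lift, 0.0, 1.0))

    left = total * cfg.left_share
    right = total - left
    bl = left * cfg.rear_share
    tl = left - bl
    br = right * cfg.rear_share
    tr = right - br

    if cfg.loadcell_noise_kg > 0:
        rng = np.random.default_rng([cfg.seed, _STREAM_LOADCELLS])
        noise = rng.normal(0.0, cfg.loadcell_noise_kg, (4, len(gt)))
        tl, tr = tl + noise[0], tr + noise[1]
        bl, br = bl + noise[2], br + noise[3]
        clip = -0.49
        tl, tr = np.maximum(tl, clip), np.maximum(tr, clip)
        bl, br = np.maximum(bl, clip), np.maximum(br, clip)

    return LoadCellSeries(times=gt.times, tl=tl, tr=tr, bl=bl, br=br,
                          rate_hz=cfg.frame_rate_hz)


def generate_participant(cfg: SyntheticConfig):
    """Convenience: (GroundTruth, KeypointTrack, LoadCellSeries).

    Thermal frames are rendered separately with :func:`render_thermal`
    (typically only at the analysis sampling times, since a full 20 Hz
    render of a 10-min session is rarely needed).
    """
    gt = generate_kinematics(cfg)
    track = simulate_tracker(cfg, gt)
    cells = simulate_loadcells(cfg, gt)
    return gt, track, cells
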