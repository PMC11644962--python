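"""End-to-end orchestration: generate -> extract -> board -> compare.

A run processes a cohort of participants (synthesized, or loaded from
files), extracts temperature profiles with both methods, processes the
balance-board record, computes the per-participant agreement
statistics, stratifies the cohort, and writes a machine-readable
report. Given the same :class:`RunConfig` (including the seed) the
report bytes are identical run to run.
"""
from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import __version__
from .compare import (align, bland_altman, classify_agreement, fit_linear,
                      leg_thermal_match, rmse_vs_trend, stratify)
from .config import SyntheticConfig
from .datatypes import RectROI, ZoneProfile
from .synth import (GroundTruth, generate_kinematics, render_thermal,
                    simulate_loadcells, simulate_tracker)
from .thermal import (roi_extrema, sample_at_keypoints, sample_indices,
                      smooth_profile, track_roi)
from .wbb import segment_phases, cop, summarize_weight
from .zones import ZONE_OFFSETS_PX, KneeZone

log = logging.getLogger("thermoknee")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and participant."""


@dataclass
class ParticipantSpec:
    """One participant: metadata plus synthesis overrides or input paths."""

    participant_id: str
    gender: str = "M"
    height_cm: float = 170.0
    mass_kg: float = 69.1
    bmi: Optional[float] = None
    left_share: float = 0.50
    coupling_gain: float = 1.0
    cooling_gain: float = 0.0
    seed: Optional[int] = None
    thermal_path: Optional[str] = None
    keypoints_path: Optional[str] = None
    loadcells_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.bmi is None:
            h_m = self.height_cm / 100.0
            self.bmi = self.mass_kg / (h_m * h_m)

    @property
    def from_files(self) -> bool:
        return self.thermal_path is not None


@dataclass
class RunConfig:
    """Source of truth for one reproducible pipeline run."""

    out_dir: str = "thermoknee_run"
    participants: list[ParticipantSpec] = field(default_factory=list)
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    interval_s: float = 30.0          # semi-automatic sampling
    auto_interval_s: float = 1.0      # automatic sampling
    p_cut: float = 0.5
    radius_px: int = 1
    span_fraction: float = 0.02
    smooth_for_slopes: bool = True
    stand_frac: float = 0.8
    sit_frac: float = 0.25
    asym_threshold: float = 0.52
    strength_threshold: float = 0.5
    bmi_cutoff: float = 25.0
    span_x_mm: float = 433.0
    span_y_mm: float = 238.0
    seed: int = 0
    save_intermediate: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"] = self.synth.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["participants"] = [ParticipantSpec(**p)
                             for p in d.get("participants", [])]
        if "synth" in d and not isinstance(d["synth"], SyntheticConfig):
            d["synth"] = SyntheticConfig.from_dict(d["synth"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def participant_seed(self, index: int) -> int:
        return int((self.seed * 100_003 + 7919 * index + 1) % (2 ** 31))


@dataclass
class ParticipantData:
    """Per-participant artefacts kept in memory for figures."""

    spec: ParticipantSpec
    auto_profiles: dict
    semi_profiles: dict
    cells: object
    phases: object
    cop: object
    summary: object
    pairs: dict
    stats: dict


@dataclass
class PipelineResult:
    report: dict
    participants: list[ParticipantData]
    out_dir: Path


# Comparison layout: (name, automatic zone per leg, semi profile kind).
_COMPARISONS = (
    ("right_ligament", KneeZone.RSM, "max", "right"),
    ("left_ligament", KneeZone.LSM, "max", "left"),
    ("right_patella", KneeZone.RP, "min", "right"),
    ("left_patella", KneeZone.LP, "min", "left"),
)


def _participant_synth_config(cfg: RunConfig, spec: ParticipantSpec,
                              index: int) -> SyntheticConfig:
    base = cfg.synth.to_dict()
    base.update(left_share=spec.left_share, body_mass_kg=spec.mass_kg,
                coupling_gain=spec.coupling_gain,
                cooling_gain=spec.cooling_gain,
                seed=spec.seed if spec.seed is not None
                else cfg.participant_seed(index))
    return SyntheticConfig.from_dict(base)


def _knee_roi(scfg: SyntheticConfig, knee_xy: tuple[float, float],
              margin_px: float = 6.0) -> RectROI:
    """Operator-style ROI centred on a knee, sized to cover the zone layout."""
    s = scfg.layout_scale
    dxs = [abs(dx) for dx, _ in ZONE_OFFSETS_PX.values()]
    dys = [dy for _, dy in ZONE_OFFSETS_PX.values()]
    half_x = max(dxs) * s + margin_px
    y_lo = min(dys) * s - margin_px
    y_hi = max(dys) * s + margin_px
    cx, cy = knee_xy
    return RectROI(x0=int(round(cx - half_x)), y0=int(round(cy + y_lo)),
                   w=int(round(2 * half_x)) + 1,
                   h=int(round(y_hi - y_lo)) + 1)


def _semi_extract(cfg: RunConfig, scfg: SyntheticConfig, seq, knee_centers):
    """ROI max/min per frame for each knee, with per-frame repositioning.

    ``knee_centers`` is an (n_frames, 2, 2) array of [right, left] knee
    (x, y) centres aligned with ``seq``.
    """
    shape = seq.frames.shape[1:]
    profiles = {}
    for k, leg in ((0, "right"), (1, "left")):
        centers = np.floor(knee_centers[:, k, :] + 0.5).astype(int)
        roi = _knee_roi(scfg, tuple(centers[0]))
        tmax = np.empty(len(seq))
        tmin = np.empty(len(seq))
        for i in range(len(seq)):
            if i > 0:
                d = centers[i] - centers[i - 1]
                roi = track_roi(roi, (int(d[0]), int(d[1])), shape)
            hi, lo, _, _ = roi_extrema(seq.frames[i], roi)
            tmax[i] = hi
            tmin[i] = lo
        profiles[("max", leg)] = ZoneProfile(
            zone=None, times=seq.timestamps, temps_c=tmax,
            method="semi_automatic_max")
        profiles[("min", leg)] = ZoneProfile(
            zone=None, times=seq.timestamps, temps_c=tmin,
            method="semi_automatic_min")
    return profiles


def _keypoint_knee_centers(track, p_cut: float) -> np.ndarray:
    """Fallback knee centres from the tracked zones (files mode)."""
    n = len(track)
    centers = np.empty((n, 2, 2))
    for k, leg_char in ((0, "R"), (1, "L")):
        cols = [i for i, z in enumerate(track.zones)
                if z.value.startswith(leg_char)]
        x = track.x[:, cols].mean(axis=1)
        y = track.y[:, cols].mean(axis=1)
        centers[:, k, 0] = x
        centers[:, k, 1] = y
    return centers


def _match_or_none(left: Optional[ZoneProfile], right: Optional[ZoneProfile],
                   heavier: Optional[str], mode: str) -> Optional[bool]:
    if heavier is None or left is None or right is None \
            or len(left) < 2 or len(right) < 2:
        return None
    return leg_thermal_match(left, right, heavier, mode)


def _process_participant(cfg: RunConfig, spec: ParticipantSpec,
                         index: int) -> ParticipantData:
    pid = spec.participant_id
    stage = "synthesize"
    try:
        if spec.from_files:
            stage = "load"
            for attr in ("thermal_path", "keypoints_path", "loadcells_path"):
                p = getattr(spec, attr)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"missing {attr.replace('_path', '')} file: {p}")
            seq_full = tio.read_thermal_tiff(spec.thermal_path)
            track_full = tio.read_keypoints_csv(spec.keypoints_path)
            cells = tio.read_loadcells_csv(spec.loadcells_path)
            scfg = cfg.synth
            gt = None
            auto_idx = sample_indices(seq_full.timestamps, cfg.auto_interval_s)
            seq_auto = type(seq_full)(frames=seq_full.frames[auto_idx],
                                      timestamps=seq_full.timestamps[auto_idx])
        else:
            scfg = _participant_synth_config(cfg, spec, index)
            gt = generate_kinematics(scfg)
            track_full = simulate_tracker(scfg, gt)
            cells = simulate_loadcells(scfg, gt)
            auto_idx = sample_indices(gt.times, cfg.auto_interval_s)
            seq_auto = render_thermal(scfg, gt, indices=auto_idx)

        stage = "extract_automatic"
        track_auto = track_full.at_times(seq_auto.timestamps)
        auto = sample_at_keypoints(seq_auto, track_auto, p_cut=cfg.p_cut,
                                   radius_px=cfg.radius_px)

        stage = "extract_semi_automatic"
        semi_sel = sample_indices(seq_auto.timestamps, cfg.interval_s)
        seq_semi = type(seq_auto)(frames=seq_auto.frames[semi_sel],
                                  timestamps=seq_auto.timestamps[semi_sel])
        if gt is not None:
            knees = gt.knee_centers_px[auto_idx][semi_sel]
        else:
            knees = _keypoint_knee_centers(track_auto, cfg.p_cut)[semi_sel]
        semi = _semi_extract(cfg, scfg, seq_semi, knees)

        stage = "wbb"
        phases = segment_phases(cells, stand_frac=cfg.stand_frac,
                                sit_frac=cfg.sit_frac)
        summary = summarize_weight(cells, phases,
                                   asym_threshold=cfg.asym_threshold)
        trajectory = cop(cells, cfg.span_x_mm, cfg.span_y_mm, phases=phases)

        stage = "compare"
        pairs, regs, bas, rmses = {}, {}, {}, {}
        for name, zone, kind, leg in _COMPARISONS:
            auto_p = auto.get(zone)
            semi_p = semi[(kind, leg)]
            pair = align(auto_p, semi_p, zone_pair=name, leg=leg)
            pairs[name] = pair
            regs[name] = fit_linear(pair, cfg.strength_threshold)
            bas[name] = bland_altman(pair)
            rmses[name] = {"automatic": rmse_vs_trend(auto_p),
                           "semi_automatic": rmse_vs_trend(semi_p)}

        stage = "agreement"
        maybe_smooth = ((lambda p: smooth_profile(p, cfg.span_fraction))
                        if cfg.smooth_for_slopes else (lambda p: p))
        heavier = summary.heavier_leg
        sm_l, sm_r = auto.get(KneeZone.LSM), auto.get(KneeZone.RSM)
        p_l, p_r = auto.get(KneeZone.LP), auto.get(KneeZone.RP)
        auto_heat = _match_or_none(maybe_smooth(sm_l), maybe_smooth(sm_r),
                                   heavier, "heating_SM")
        auto_cool = _match_or_none(maybe_smooth(p_l), maybe_smooth(p_r),
                                   heavier, "cooling_P")
        semi_heat = _match_or_none(maybe_smooth(semi[("max", "left")]),
                                   maybe_smooth(semi[("max", "right")]),
                                   heavier, "heating_SM")
        semi_cool = _match_or_none(maybe_smooth(semi[("min", "left")]),
                                   maybe_smooth(semi[("min", "right")]),
                                   heavier, "cooling_P")
        labels = {}
        for mode, s_m, a_m in (("heating", semi_heat, auto_heat),
                               ("cooling", semi_cool, auto_cool)):
            labels[mode] = (classify_agreement(s_m, a_m).value
                            if s_m is not None and a_m is not None else None)
            labels[f"{mode}_semi_match"] = s_m
            labels[f"{mode}_auto_match"] = a_m

        stats = {
            "regression": {k: v.to_dict() for k, v in regs.items()},
            "bland_altman": {k: v.to_dict() for k, v in bas.items()},
            "rmse_vs_trend": rmses,
            "labels": labels,
            "weight": summary.to_dict(),
            "qc": {
                "dropped_low_likelihood": auto.qc["dropped_low_likelihood"],
                "dropped_out_of_frame": auto.qc["dropped_out_of_frame"],
                "empty_zones": auto.qc["empty_zones"],
                "invalid_wbb_samples": int(np.sum(
                    phases.standing
                    & (np.clip(cells.corners(), 0, None).sum(axis=1) < 1.0))),
                "interp_points_dropped": int(sum(p.n_dropped
                                                 for p in pairs.values())),
            },
        }
        return ParticipantData(spec=spec, auto_profiles=auto,
                               semi_profiles=semi, cells=cells, phases=phases,
                               cop=trajectory, summary=summary, pairs=pairs,
                               stats=stats)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise PipelineError(
            f"stage '{stage}' failed for participant '{pid}': {exc}") from exc


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full cohort and write report.json plus CSV tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    seen = set()
    for spec in cfg.participants:
        if spec.participant_id in seen:
            raise PipelineError(
                f"duplicate participant id '{spec.participant_id}'")
        seen.add(spec.participant_id)

    try:
        log.info("run start: %d participant(s), seed %d",
                 len(cfg.participants), cfg.seed)
        data: list[ParticipantData] = []
        for i, spec in enumerate(cfg.participants):
            t0 = time.perf_counter()
            pd_i = _process_participant(cfg, spec, i)
            log.info("participant %s done in %.1f s", spec.participant_id,
                     time.perf_counter() - t0)
            data.append(pd_i)

        rows = []
        for d in data:
            for name in d.stats["regression"]:
                rows.append({
                    "participant": d.spec.participant_id,
                    "gender": d.spec.gender,
                    "bmi": d.spec.bmi,
                    "asymmetric": d.stats["weight"]["asymmetric"],
                    "comparison": name,
                    "r2": d.stats["regression"][name]["r2"],
                    "strong": d.stats["regression"][name]["strong"],
                    "label_heating": d.stats["labels"]["heating"],
                    "label_cooling": d.stats["labels"]["cooling"],
                })
        records = pd.DataFrame(rows)
        strata = stratify(records, bmi_cutoff=cfg.bmi_cutoff)

        report = {
            "config": cfg.to_dict(),
            "versions": {"thermoknee": __version__,
                         "numpy": np.__version__, "pandas": pd.__version__},
            "participants": {d.spec.participant_id: d.stats for d in data},
            "cohort": {
                "n_participants": len(data),
                "n_asymmetric": int(sum(d.stats["weight"]["asymmetric"]
                                        for d in data)),
                "n_strong": int(records["strong"].sum()),
                "n_comparisons": int(len(records)),
                "strong_fraction": (float(records["strong"].mean())
                                    if len(records) else float("nan")),
                "r2_by_group": strata["r2_by_group"].reset_index()
                               .to_dict(orient="records"),
                "label_counts": strata["label_counts"]
                                .to_dict(orient="records"),
            },
        }
        tio.write_json(report, out / "report.json")
        records.to_csv(out / "comparisons.csv", index=False,
                       float_format="%.8g")
        strata["r2_by_group"].to_csv(out / "r2_by_group.csv",
                                     float_format="%.8g")
        strata["label_counts"].to_csv(out / "label_counts.csv", index=False)
        if cfg.save_intermediate:
            for d in data:
                pid = d.spec.participant_id
                tio.write_profiles_csv(d.auto_profiles,
                                       out / f"{pid}_auto_profiles.csv")
                tio.write_profiles_csv(d.semi_profiles,
                                       out / f"{pid}_semi_profiles.csv")
                tio.write_loadcells_csv(d.cells, out / f"{pid}_loadcells.csv")
        log.info("run complete")
        return PipelineResult(report=report, participants=data, out_dir=out)
    finally:
        log.removeHandler(handler)
        handler.close()


def make_figures(result: PipelineResult, out_dir: Optional[Path] = None) -> list[Path]:
    """Write the standard figure set (8 files) for a completed run.

    Detail plots show the first participant; the agreement bar chart
    covers the cohort. Empty report sections are skipped with a log
    entry.
    """
    from matplotlib.figure import Figure

    out = Path(out_dir) if out_dir is not None else result.out_dir / "figures"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not result.participants:
        log.info("figures skipped: no participants")
        return written
    d = result.participants[0]

    def save(fig: Figure, name: str) -> None:
        path = out / name
        fig.savefig(path, dpi=110)
        written.append(path)

    fig = Figure(figsize=(8, 4))
    ax = fig.subplots()
    for (kind, leg), p in d.semi_profiles.items():
        color = "tab:red" if leg == "right" else "tab:blue"
        ls = "-" if kind == "max" else "--"
        ax.plot(p.times, p.temps_c, ls, color=color,
                label=f"{leg} {kind}", marker="o", ms=3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("temperature (degC)")
    ax.set_title("Semi-automatic ROI max/min profiles")
    ax.legend(fontsize=7)
    save(fig, "semi_profiles.png")

    fig = Figure(figsize=(8, 5))
    ax = fig.subplots()
    for zone, p in d.auto_profiles.items():
        if len(p):
            ax.plot(p.times, p.temps_c, lw=0.8, label=zone.value)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("temperature (degC)")
    ax.set_title("Automatic keypoint profiles (12 zones)")
    ax.legend(fontsize=6, ncol=4)
    save(fig, "auto_profiles.png")

    cells = d.cells
    fig = Figure(figsize=(8, 7))
    axes = fig.subplots(3, 1, sharex=True)
    total = cells.tl + cells.tr + cells.bl + cells.br
    axes[0].plot(cells.times, total, lw=0.7)
    axes[0].set_ylabel("total (kg)")
    axes[1].plot(cells.times, cells.tl + cells.bl, lw=0.7, color="tab:red",
                 label="left")
    axes[1].plot(cells.times, cells.tr + cells.br, lw=0.7, color="tab:blue",
                 label="right")
    axes[1].set_ylabel("per-leg (kg)")
    axes[1].legend(fontsize=7)
    axes[2].plot(cells.times, cells.bl, lw=0.7, color="tab:red", label="L rear")
    axes[2].plot(cells.times, cells.br, lw=0.7, color="tab:blue", label="R rear")
    axes[2].plot(cells.times, cells.tl, lw=0.7, color="tab:olive", label="L fore")
    axes[2].plot(cells.times, cells.tr, lw=0.7, color="tab:cyan", label="R fore")
    axes[2].set_ylabel("per-cell (kg)")
    axes[2].set_xlabel("time (s)")
    axes[2].legend(fontsize=7, ncol=2)
    save(fig, "wbb_forces.png")

    fig = Figure(figsize=(5, 5))
    ax = fig.subplots()
    v = d.cop.valid
    ax.plot(d.cop.x_mm[v], d.cop.y_mm[v], ".", ms=2, alpha=0.4)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    for (corner, frac), (ha, va, x, y) in zip(
            d.cop.corner_pct.items(),
            (("left", "top", 0.02, 0.98), ("right", "top", 0.98, 0.98),
             ("left", "bottom", 0.02, 0.02), ("right", "bottom", 0.98, 0.02))):
        ax.text(x, y, f"{corner}: {100 * frac:.1f}%", ha=ha, va=va,
                transform=ax.transAxes, fontsize=8)
    ax.set_xlabel("medio-lateral x (mm)")
    ax.set_ylabel("antero-posterior y (mm)")
    ax.set_title("Centre of pressure")
    save(fig, "cop.png")

    counts = result.report["cohort"]["label_counts"]
    fig = Figure(figsize=(7, 4))
    axes = fig.subplots(1, 2, sharey=True)
    for ax, mode in zip(axes, ("cooling", "heating")):
        sub = [r for r in counts if r["mode"] == mode]
        if not sub:
            log.info("figure section empty: %s labels", mode)
            continue
        labels = ("AG", "NAG", "PAG")
        genders = sorted({r["gender"] for r in sub})
        width = 0.8 / max(len(genders), 1)
        for gi, g in enumerate(genders):
            vals = [next((r["count"] for r in sub
                          if r["gender"] == g and r["label"] == lab), 0)
                    for lab in labels]
            ax.bar(np.arange(3) + gi * width, vals, width,
                   label={"M": "men", "F": "women"}.get(g, g),
                   color={"M": "tab:blue", "F": "tab:green"}.get(g))
        ax.set_xticks(np.arange(3) + 0.4 - width / 2)
        ax.set_xticklabels(labels)
        ax.set_title(f"greatest {mode}")
        ax.legend(fontsize=7)
    axes[0].set_ylabel("participants")
    save(fig, "agreement_bars.png")

    fig = Figure(figsize=(8, 7))
    axes = fig.subplots(2, 2)
    for ax, (name, pair) in zip(axes.ravel(), d.pairs.items()):
        reg = d.stats["regression"][name]
        ax.plot(pair.a, pair.b, "o", ms=3)
        xs = np.array([pair.a.min(), pair.a.max()])
        ax.plot(xs, reg["intercept"] + reg["slope"] * xs, "-", color="tab:red")
        ax.set_title(f"{name}  R2={reg['r2']:.3f}", fontsize=9)
        ax.set_xlabel("semi-automatic (degC)", fontsize=8)
        ax.set_ylabel("automatic (degC)", fontsize=8)
    fig.tight_layout()
    save(fig, "regression.png")

    fig = Figure(figsize=(8, 7))
    axes = fig.subplots(2, 2)
    for ax, (name, pair) in zip(axes.ravel(), d.pairs.items()):
        ba = d.stats["bland_altman"][name]
        ax.plot(0.5 * (pair.a + pair.b), pair.b - pair.a, "d",
                ms=4, color="tab:green")
        ax.axhline(ba["bias"], color="tab:blue")
        ax.axhline(ba["loa_low"], color="tab:red", ls="--")
        ax.axhline(ba["loa_high"], color="tab:red", ls="--")
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("mean of methods (degC)", fontsize=8)
        ax.set_ylabel("difference (degC)", fontsize=8)
    fig.tight_layout()
    save(fig, "bland_altman.png")

    fig = Figure(figsize=(6, 4))
    ax = fig.subplots()
    names = list(d.stats["rmse_vs_trend"])
    autos = [d.stats["rmse_vs_trend"][n]["automatic"] for n in names]
    semis = [d.stats["rmse_vs_trend"][n]["semi_automatic"] for n in names]
    xs = np.arange(len(names))
    ax.bar(xs - 0.2, autos, 0.4, label="automatic")
    ax.bar(xs + 0.2, semis, 0.4, label="semi-automatic")
    ax.set_xticks(xs)
    ax.set_xticklabels(names, rotation=20, fontsize=7)
    ax.set_ylabel("RMSE about linear trend (degC)")
    ax.legend(fontsize=8)
    save(fig, "rmse_vs_trend.png")

    return written
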