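"""Readers and writers for the on-disk interchange formats.

* Thermal sequences: multi-page float TIFF in degC plus a sidecar CSV
  of frame timestamps, or a directory of one CSV matrix per frame.
* Keypoint tracks: CSV with the three-row header layout of common
  markerless-tracker exports (scorer / bodyparts / coords), one row per
  frame.
* Load cells: CSV with columns t_s, TL_kg, TR_kg, BL_kg, BR_kg.
* Zone profiles: CSV with columns t_s, temp_c, zone, method, smoothed.
* Ground truth: long-format CSV plus a JSON run manifest.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import SyntheticConfig
from .datatypes import KeypointTrack, LoadCellSeries, ThermalSequence, ZoneProfile
from .synth import GroundTruth
from .zones import ZONES, KneeZone

_FLOAT_FMT = "%.6f"


def timestamps_path(tiff_path: Path) -> Path:
    tiff_path = Path(tiff_path)
    return tiff_path.with_name(tiff_path.stem + "_timestamps.csv")


def write_thermal_tiff(seq: ThermalSequence, path: Path) -> Path:
    """Multi-page float32 TIFF (degC) + sidecar timestamps CSV."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames.astype(np.float32))
    pd.DataFrame({"t_s": seq.timestamps}).to_csv(
        timestamps_path(path), index=False, float_format=_FLOAT_FMT)
    return path


def read_thermal_tiff(path: Path) -> ThermalSequence:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    ts = pd.read_csv(timestamps_path(path))["t_s"].to_numpy()
    return ThermalSequence(frames=frames, timestamps=ts)


def write_thermal_csvdir(seq: ThermalSequence, directory: Path) -> Path:
    """One CSV matrix per frame, plus a timestamps index CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(seq.frames):
        name = f"frame_{i:06d}.csv"
        np.savetxt(directory / name, frame, delimiter=",", fmt=_FLOAT_FMT)
        names.append(name)
    pd.DataFrame({"file": names, "t_s": seq.timestamps}).to_csv(
        directory / "timestamps.csv", index=False, float_format=_FLOAT_FMT)
    return directory


def read_thermal_csvdir(directory: Path) -> ThermalSequence:
    directory = Path(directory)
    index = pd.read_csv(directory / "timestamps.csv")
    frames = np.stack([np.loadtxt(directory / name, delimiter=",", ndmin=2)
                       for name in index["file"]])
    return ThermalSequence(frames=frames, timestamps=index["t_s"].to_numpy())


def write_keypoints_csv(track: KeypointTrack, path: Path,
                        scorer: str = "thermoknee") -> Path:
    """Three-header-row keypoint CSV (scorer / bodyparts / coords)."""
    cols = pd.MultiIndex.from_tuples(
        [(scorer, z.value, coord) for z in track.zones
         for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"])
    data = np.empty((len(track), 3 * len(track.zones)))
    data[:, 0::3] = track.x
    data[:, 1::3] = track.y
    data[:, 2::3] = track.likelihood
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, ("time", "t", "s"), track.times)
    df.to_csv(path, index=False, float_format="%.8g")
    return Path(path)


def read_keypoints_csv(path: Path) -> KeypointTrack:
    df = pd.read_csv(path, header=[0, 1, 2])
    times = df.iloc[:, 0].to_numpy(dtype=float)
    body = df.columns.get_level_values(1)[1:]
    zones = tuple(KneeZone(b) for b in body[0::3])
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    return KeypointTrack(times=times, x=vals[:, 0::3], y=vals[:, 1::3],
                         likelihood=np.clip(vals[:, 2::3], 0.0, 1.0),
                         zones=zones)


def write_loadcells_csv(s: LoadCellSeries, path: Path) -> Path:
    pd.DataFrame({"t_s": s.times, "TL_kg": s.tl, "TR_kg": s.tr,
                  "BL_kg": s.bl, "BR_kg": s.br}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_loadcells_csv(path: Path, rate_hz: float | None = None) -> LoadCellSeries:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    if rate_hz is None:
        rate_hz = float((len(t) - 1) / (t[-1] - t[0])) if len(t) > 1 else 20.0
    return LoadCellSeries(times=t, tl=df["TL_kg"].to_numpy(),
                          tr=df["TR_kg"].to_numpy(), bl=df["BL_kg"].to_numpy(),
                          br=df["BR_kg"].to_numpy(), rate_hz=rate_hz)


def write_profiles_csv(profiles, path: Path) -> Path:
    """Write zone profiles (iterable or mapping) to a tidy CSV."""
    if hasattr(profiles, "values"):
        profiles = list(profiles.values())
    rows = []
    for p in profiles:
        zone = p.zone.value if p.zone is not None else ""
        for t, v in zip(p.times, p.temps_c):
            rows.append({"t_s": t, "temp_c": v, "zone": zone,
                         "method": p.method, "smoothed": p.smoothed})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")
    return Path(path)


def read_profiles_csv(path: Path) -> list[ZoneProfile]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for (zone, method, smoothed), g in df.groupby(
            ["zone", "method", "smoothed"], sort=False):
        z = KneeZone(zone) if zone else None
        out.append(ZoneProfile(zone=z, times=g["t_s"].to_numpy(),
                               temps_c=g["temp_c"].to_numpy(),
                               method=str(method), smoothed=bool(smoothed)))
    return out


def write_ground_truth(gt: GroundTruth, cfg: SyntheticConfig,
                       csv_path: Path, manifest_path: Path) -> None:
    """Long-format ground-truth CSV + JSON manifest of the full config."""
    n = len(gt)
    nz = len(ZONES)
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(n), nz),
        "t_s": np.repeat(gt.times, nz),
        "zone": np.tile([z.value for z in ZONES], n),
        "cx_px": gt.zone_centers_px[:, :, 0].ravel(),
        "cy_px": gt.zone_centers_px[:, :, 1].ravel(),
        "temp_c": gt.zone_temps_c.ravel(),
        "phase": np.repeat(gt.phase, nz),
    })
    df.to_csv(csv_path, index=False, float_format="%.8g")
    manifest = {"config": cfg.to_dict(), "cycle_count": gt.cycle_count,
                "static_weight_kg": gt.static_weight_kg}
    Path(manifest_path).write_text(json.dumps(manifest, indent=2,
                                              sort_keys=True) + "\n")


def write_json(obj: dict, path: Path) -> Path:
    """Deterministic JSON dump (sorted keys, fixed layout)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")
    return Path(path)
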