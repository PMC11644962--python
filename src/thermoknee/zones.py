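"""Knee zone nomenclature and default anatomy layout.

Twelve zones are tracked, six per knee: superior lateral (SL), superior
medial (SM), patella (P), lateral and medial joint line areas (LJLA,
MJLA) and patellar tendon (PT), each prefixed R or L for the leg.
"""
from __future__ import annotations

from enum import Enum

#: Per-knee region codes, superior to inferior.
REGIONS: tuple[str, ...] = ("SL", "SM", "P", "LJLA", "MJLA", "PT")


class Leg(str, Enum):
    RIGHT = "right"
    LEFT = "left"


class KneeZone(str, Enum):
    """The 12 knee zones ({R, L} x {SL, SM, P, LJLA, MJLA, PT})."""

    RSL = "RSL"
    RSM = "RSM"
    RP = "RP"
    RLJLA = "RLJLA"
    RMJLA = "RMJLA"
    RPT = "RPT"
    LSL = "LSL"
    LSM = "LSM"
    LP = "LP"
    LLJLA = "LLJLA"
    LMJLA = "LMJLA"
    LPT = "LPT"

    @property
    def leg(self) -> Leg:
        return Leg.RIGHT if self.value[0] == "R" else Leg.LEFT

    @property
    def region(self) -> str:
        return self.value[1:]


#: Canonical zone ordering used for all array axes of length 12.
ZONES: tuple[KneeZone, ...] = tuple(KneeZone)

ZONE_INDEX: dict[KneeZone, int] = {z: i for i, z in enumerate(ZONES)}


def zone(leg: Leg, region: str) -> KneeZone:
    prefix = "R" if leg is Leg.RIGHT else "L"
    return KneeZone(prefix + region)


# Zone centre offsets from the knee centre (patella), in pixels at
# layout_scale=1. The first component is along the medial direction of
# that knee (mirrored between legs), the second is image-down.
ZONE_OFFSETS_PX: dict[str, tuple[float, float]] = {
    "SL": (-35.0, -60.0),
    "SM": (35.0, -60.0),
    "P": (0.0, 0.0),
    "LJLA": (-45.0, 30.0),
    "MJLA": (45.0, 30.0),
    "PT": (0.0, 65.0),
}

# Baseline skin temperature per region (degC) at t=0. The superior
# medial region (medial collateral ligament vicinity) is the warmest
# and the patella the coolest, so ROI max/min land on SM and P.
DEFAULT_BASELINES_C: dict[str, float] = {
    "SL": 31.5,
    "SM": 32.3,
    "P": 30.3,
    "LJLA": 31.3,
    "MJLA": 31.7,
    "PT": 30.7,
}

# Default warming/cooling trends (degC per minute): the medial
# collateral ligament region warms during the exercise while patella
# and patellar tendon cool; the remaining zones are flat.
DEFAULT_ZONE_TRENDS_C_PER_MIN: dict[str, float] = {
    "SL": 0.0,
    "SM": 0.08,
    "P": -0.05,
    "LJLA": 0.0,
    "MJLA": 0.0,
    "PT": -0.05,
}
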