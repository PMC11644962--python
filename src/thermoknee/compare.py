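"""Method-agreement statistics.

Compares the semi-automatic (ROI max/min) and automatic (keypoint)
temperature profiles: interpolation onto the sparse semi-automatic
grid, ordinary-least-squares regression with R-squared, RMSE about the
profile's own linear trend, Bland-Altman agreement, heavier-leg /
most-responsive-leg matching with AG / NAG / PAG labels, and cohort
stratification by gender, BMI and weight asymmetry.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ZoneProfile


class AgreementLabel(str, Enum):
    AG = "AG"    # both methods match the heavier leg
    NAG = "NAG"  # neither method matches (figure alias: DAG)
    PAG = "PAG"  # exactly one method matches


#: The figure nomenclature uses DAG for the disagreement class.
DAG = AgreementLabel.NAG


@dataclass
class PairedSeries:
    """Semi-automatic values ``a`` paired with automatic values ``b``
    interpolated onto the semi-automatic time grid."""

    times: np.ndarray
    a: np.ndarray
    b: np.ndarray
    zone_pair: str = ""
    leg: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.times) == len(self.a) == len(self.b)):
            raise ValueError("times, a, b must have equal length")
        if len(self.times) < 3:
            raise ValueError("paired series needs at least 3 points")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    strong: bool

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r2": self.r2, "strong": self.strong}


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_outside: int
    means: np.ndarray
    diffs: np.ndarray

    def to_dict(self) -> dict:
        return {"bias": self.bias, "sd_diff": self.sd_diff,
                "loa_low": self.loa_low, "loa_high": self.loa_high,
                "n_outside": self.n_outside}


@dataclass
class ParticipantStrata:
    gender: str            # "M" or "F"
    bmi_kg_m2: float
    asymmetric: bool

    def __post_init__(self) -> None:
        if self.bmi_kg_m2 <= 0:
            raise ValueError("BMI must be positive")


def align(auto: ZoneProfile, semi: ZoneProfile, zone_pair: str = "",
          leg: str = "") -> PairedSeries:
    """Interpolate the automatic profile onto the semi-automatic grid.

    Linear interpolation; semi-automatic points outside the automatic
    coverage are dropped (edge extrapolation is forbidden) and counted
    in ``n_dropped``. Fewer than 3 overlapping points raises.
    """
    if len(auto) < 2:
        raise ValueError("automatic profile too short to interpolate")
    lo, hi = auto.times[0], auto.times[-1]
    inside = (semi.times >= lo - 1e-9) & (semi.times <= hi + 1e-9)
    n_dropped = int((~inside).sum())
    t = semi.times[inside]
    if len(t) < 3:
        raise ValueError("fewer than 3 points of overlap between methods")
    b = np.interp(t, auto.times, auto.temps_c)
    return PairedSeries(times=t, a=semi.temps_c[inside], b=b,
                        zone_pair=zone_pair, leg=leg, n_dropped=n_dropped)


def fit_linear(p: PairedSeries,
               strength_threshold: float = 0.5) -> RegressionResult:
    """OLS regression of the automatic on the semi-automatic values.

    R-squared is 1 - SSres/SStot of the fit b ~ a; the pair is
    "strongly correlated" when R-squared reaches the threshold.
    """
    if np.var(p.a) == 0:
        raise ValueError("zero variance in the semi-automatic values; "
                         "R-squared undefined")
    res = stats.linregress(p.a, p.b)
    r2 = float(res.rvalue ** 2)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept), r2=r2,
                            strong=r2 >= strength_threshold)


def rmse_vs_trend(p: ZoneProfile) -> float:
    """RMS residual of a profile about its own OLS line in time.

    Low values indicate a clean (near-linear) temperature trend; the
    sparse operator-driven extraction typically shows larger values
    than the keypoint-driven one.
    """
    if len(p) < 3:
        raise ValueError("profile needs at least 3 points")
    if np.var(p.times) == 0:
        raise ValueError("degenerate time axis")
    res = stats.linregress(p.times, p.temps_c)
    resid = p.temps_c - (res.intercept + res.slope * p.times)
    return float(np.sqrt(np.mean(resid ** 2)))


def bland_altman(p: PairedSeries) -> BlandAltmanResult:
    """Bland-Altman agreement between the two methods.

    Differences are b - a; the bias is their mean and the limits of
    agreement bias +/- 1.96 * sd (sample sd, n-1 denominator).
    Per-point (mean, difference) coordinates are returned for plotting.
    """
    diffs = p.b - p.a
    means = 0.5 * (p.a + p.b)
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    n_outside = int(np.sum((diffs < lo) | (diffs > hi)))
    return BlandAltmanResult(bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi,
                             n_outside=n_outside, means=means, diffs=diffs)


def classify_agreement(method1_match: bool,
                       method2_match: bool) -> AgreementLabel:
    """AG if both methods match the heavier leg, NAG if neither does,
    PAG if exactly one does."""
    if method1_match and method2_match:
        return AgreementLabel.AG
    if not method1_match and not method2_match:
        return AgreementLabel.NAG
    return AgreementLabel.PAG


def profile_slope_c_per_min(p: ZoneProfile) -> float:
    """OLS slope of a profile, degC per minute."""
    if len(p) < 2 or np.var(p.times) == 0:
        raise ValueError("profile too short for a slope")
    res = stats.linregress(p.times / 60.0, p.temps_c)
    return float(res.slope)


def leg_thermal_match(profile_left: ZoneProfile, profile_right: ZoneProfile,
                      heavier_leg: str, mode: str = "heating_SM",
                      tie_tol_c_per_min: float = 1e-6) -> Optional[bool]:
    """Does the most thermally responsive leg match the heavier leg?

    Heating mode compares the SM (medial-ligament) profiles and takes
    the leg with the larger warming slope; cooling mode compares the
    patella profiles and takes the leg with the more negative slope.
    Slopes within ``tie_tol_c_per_min`` are indeterminate: the case is
    excluded (returns None) with a warning.
    """
    if mode not in ("heating_SM", "cooling_P"):
        raise ValueError("mode must be 'heating_SM' or 'cooling_P'")
    if heavier_leg not in ("left", "right"):
        raise ValueError("heavier_leg must be 'left' or 'right'")
    sl = profile_slope_c_per_min(profile_left)
    sr = profile_slope_c_per_min(profile_right)
    if abs(sl - sr) < tie_tol_c_per_min:
        warnings.warn("slope tie between legs; agreement indeterminate")
        return None
    if mode == "heating_SM":
        responsive = "left" if sl > sr else "right"
    else:
        responsive = "left" if sl < sr else "right"
    return responsive == heavier_leg


def stratify(records: pd.DataFrame, bmi_cutoff: float = 25.0) -> dict:
    """Cohort stratification of the per-comparison regressions.

    ``records`` needs one row per comparison with columns
    ``participant, gender, bmi, asymmetric, r2, strong`` and optionally
    ``label_heating`` / ``label_cooling`` (per-participant labels,
    repeated across that participant's rows).

    Returns ``{"r2_by_group": DataFrame, "label_counts": DataFrame}``:
    mean and sd of R-squared among strongly correlated comparisons per
    group (overall, by gender, BMI above/below the cutoff, balanced /
    unbalanced; groups with no members are absent, single-member groups
    report sd as NaN), and AG/NAG/PAG counts per gender and mode.
    """
    req = {"participant", "gender", "bmi", "asymmetric", "r2", "strong"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    strong = records[records["strong"]]

    groups: dict[str, pd.DataFrame] = {"all": strong}
    for g in ("F", "M"):
        groups[g] = strong[strong["gender"] == g]
    groups[f"bmi>={bmi_cutoff:g}"] = strong[strong["bmi"] >= bmi_cutoff]
    groups[f"bmi<{bmi_cutoff:g}"] = strong[strong["bmi"] < bmi_cutoff]
    groups["balanced"] = strong[~strong["asymmetric"].astype(bool)]
    groups["unbalanced"] = strong[strong["asymmetric"].astype(bool)]

    rows = []
    for name, df in groups.items():
        if len(df) == 0:
            continue
        rows.append({"group": name, "n": len(df),
                     "mean_r2": float(df["r2"].mean()),
                     "sd_r2": float(df["r2"].std(ddof=1))
                     if len(df) > 1 else float("nan")})
    r2_by_group = pd.DataFrame(
        rows, columns=["group", "n", "mean_r2", "sd_r2"]).set_index("group")

    label_rows = []
    per_part = records.drop_duplicates("participant")
    for mode_col, mode in (("label_heating", "heating"),
                           ("label_cooling", "cooling")):
        if mode_col not in records.columns:
            continue
        for gender, df in per_part.groupby("gender"):
            counts = df[mode_col].value_counts()
            for label in ("AG", "NAG", "PAG"):
                label_rows.append({"mode": mode, "gender": gender,
                                   "label": label,
                                   "count": int(counts.get(label, 0))})
    label_counts = pd.DataFrame(label_rows)
    return {"r2_by_group": r2_by_group, "label_counts": label_counts}
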