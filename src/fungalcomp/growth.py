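"""Plate records and exponential-phase growth-rate estimation.

The growth rate of a colony is the slope of an ordinary least-squares fit
of ln(colony area) against experimental day, restricted to the exponential
window (the first few days of growth; default day 0 to day 4).  The maximum
colony area over the whole series is kept alongside as an alternate,
interference-competition-oriented response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateRecord",
    "GrowthFit",
    "PlateFormatError",
    "InsufficientDataError",
    "DEFAULT_WINDOW",
    "read_plates",
    "fit_growth",
    "fit_plates",
    "select_svs_plug",
    "write_fits",
]

DEFAULT_WINDOW = (0.0, 4.0)

PLATES_COLUMNS = [
    "plate_id",
    "treatment",
    "focal",
    "opponent",
    "ph",
    "replicate",
    "plug",
    "day",
    "area_mm2",
    "excluded",
    "exclusion_reason",
]

TREATMENTS = ("single", "SvS", "competition")


class PlateFormatError(ValueError):
    """Malformed plate table (missing columns, bad grouping)."""


class InsufficientDataError(ValueError):
    """Too few in-window points to fit a growth rate."""


@dataclass
class PlateRecord:
    """One plug's measurement series plus its plate metadata.

    Single plates carry one plug, SvS (self-versus-self) and competition
    plates two; ``plug_index`` says which plug this record describes.
    """

    plate_id: str
    treatment: str
    focal: str
    opponent: str | None
    ph: float
    replicate: int
    plug_index: int
    days: np.ndarray
    areas: np.ndarray
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise PlateFormatError(
                f"{self.plate_id}: unknown treatment {self.treatment!r}"
            )
        self.days = np.asarray(self.days, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.days.shape != self.areas.shape:
            raise PlateFormatError(f"{self.plate_id}: days/areas length mismatch")
        if np.any(np.diff(self.days) <= 0):
            raise PlateFormatError(
                f"{self.plate_id} plug {self.plug_index}: days not strictly increasing"
            )
        if np.any(self.areas <= 0):
            raise PlateFormatError(
                f"{self.plate_id} plug {self.plug_index}: non-positive area"
            )


@dataclass(frozen=True)
class GrowthFit:
    """OLS fit of ln(area) ~ day on one plug, restricted to a day window."""

    plate_id: str
    plug_index: int
    rate: float            # slope, day^-1
    intercept: float       # ln(area) at day 0
    window: tuple[float, float]
    n_points: int
    r_squared: float
    max_area: float        # max observed area over the FULL series, mm^2


def read_plates(path, on_error: str = "warn") -> list[PlateRecord]:
    """Read a long-format plates CSV into plug-level records.

    Rows failing validation (non-positive area, negative day) are rejected
    individually and reported with their 1-based file line numbers;
    ``on_error`` is ``"warn"`` (default) or ``"raise"``.  A missing required
    column raises :class:`PlateFormatError`.
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in PLATES_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"plates CSV missing columns: {missing}")
    df["ph"] = pd.to_numeric(df["ph"], errors="coerce")
    df["day"] = pd.to_numeric(df["day"], errors="coerce")
    df["area_mm2"] = pd.to_numeric(df["area_mm2"], errors="coerce")
    bad = (
        df["area_mm2"].isna()
        | (df["area_mm2"] <= 0)
        | df["day"].isna()
        | (df["day"] < 0)
        | df["ph"].isna()
    )
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # header is line 1
        msg = f"rejected {int(bad.sum())} malformed rows at lines {lines}"
        if on_error == "raise":
            raise PlateFormatError(msg)
        warnings.warn(msg)
        df = df[~bad]
    records = []
    excl = df["excluded"].astype(str).str.lower().isin(["true", "1", "yes"])
    df = df.assign(_excluded=excl)
    for (plate_id, plug), grp in df.groupby(["plate_id", "plug"], sort=False):
        grp = grp.sort_values("day")
        first = grp.iloc[0]
        opponent = first["opponent"] if str(first["opponent"]) != "" else None
        records.append(
            PlateRecord(
                plate_id=str(plate_id),
                treatment=str(first["treatment"]),
                focal=str(first["focal"]),
                opponent=None if opponent is None else str(opponent),
                ph=float(first["ph"]),
                replicate=int(first["replicate"]),
                plug_index=int(plug),
                days=grp["day"].to_numpy(),
                areas=grp["area_mm2"].to_numpy(),
                excluded=bool(first["_excluded"]),
                exclusion_reason=str(first["exclusion_reason"]),
            )
        )
    return records


def fit_growth(record: PlateRecord, window: tuple[float, float] = DEFAULT_WINDOW) -> GrowthFit:
    """Fit ln(area) ~ day by OLS within ``window`` (inclusive bounds).

    The slope is the exponential-phase growth rate in day^-1; points after
    the window (e.g. a saturating colony) never influence it.  ``max_area``
    is taken over the full observed series.
    """
    lo, hi = float(window[0]), float(window[1])
    mask = (record.days >= lo) & (record.days <= hi)
    x = record.days[mask]
    y = np.log(record.areas[mask])
    if x.size < 3:
        raise InsufficientDataError(
            f"{record.plate_id} plug {record.plug_index}: "
            f"{x.size} points in window [{lo}, {hi}], need >= 3"
        )
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return GrowthFit(
        plate_id=record.plate_id,
        plug_index=record.plug_index,
        rate=float(slope),
        intercept=float(intercept),
        window=(lo, hi),
        n_points=int(x.size),
        r_squared=r2,
        max_area=float(record.areas.max()),
    )


def fit_plates(
    records: list[PlateRecord],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Fit every non-excluded plug and return a tidy fits table.

    Columns: plate metadata plus rate, intercept, window bounds, n_points,
    r_squared, max_area.  Excluded plates are dropped (they propagate as
    absent observations); plugs with too few in-window points are reported
    via a warning and skipped.
    """
    rows = []
    failures = []
    for rec in records:
        if rec.excluded:
            continue
        try:
            fit = fit_growth(rec, window)
        except InsufficientDataError as err:
            failures.append(str(err))
            continue
        rows.append(
            {
                "plate_id": rec.plate_id,
                "treatment": rec.treatment,
                "focal": rec.focal,
                "opponent": rec.opponent,
                "ph": rec.ph,
                "replicate": rec.replicate,
                "plug": rec.plug_index,
                "rate": fit.rate,
                "intercept": fit.intercept,
                "window_lo": fit.window[0],
                "window_hi": fit.window[1],
                "n_points": fit.n_points,
                "r_squared": fit.r_squared,
                "max_area": fit.max_area,
            }
        )
    if failures:
        warnings.warn("growth fits skipped: " + "; ".join(failures))
    return pd.DataFrame(rows)


def select_svs_plug(svs_fits: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Randomly keep one plug per SvS plate (reproducible under ``seed``).

    Because the two plugs of a self-versus-self plate are interchangeable,
    one is chosen at random as the plate's baseline measurement.  Plates
    with a number of plugs other than two are a structural error.
    """
    df = svs_fits[svs_fits["treatment"] == "SvS"]
    counts = df.groupby("plate_id")["plug"].nunique()
    bad = counts[counts != 2]
    if len(bad):
        raise PlateFormatError(
            f"SvS plates without exactly 2 plugs: {sorted(bad.index.tolist())}"
        )
    rng = np.random.default_rng(seed)
    keep = []
    for plate_id in sorted(df["plate_id"].unique()):
        plugs = sorted(df.loc[df["plate_id"] == plate_id, "plug"].unique())
        keep.append((plate_id, plugs[rng.integers(2)]))
    keep_df = pd.DataFrame(keep, columns=["plate_id", "plug"])
    return df.merge(keep_df, on=["plate_id", "plug"]).reset_index(drop=True)


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, index=False, float_format="%.10g")
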