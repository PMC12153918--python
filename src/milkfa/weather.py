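"""Temperature-humidity index and weather-station linkage.

THI combines dry-bulb temperature and relative humidity into the standard
dairy heat-stress indicator:

    THI = 0.8 * tsa + (hra / 100) * (tsa - 14.4) + 46.4

with tsa in degrees C and hra in percent.  Herd locations are linked to
their nearest station (the Voronoi rule for points) and daily station
weather is merged onto milk records by station and date.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_thi", "assign_nearest_station", "join_weather", "simulate_weather"]


def compute_thi(tsa, hra):
    """THI from dry temperature (degrees C) and relative humidity (%).

    Accepts scalars or arrays; humidity outside [0, 100] is rejected.
    """
    tsa = np.asarray(tsa, dtype=float)
    hra = np.asarray(hra, dtype=float)
    valid = np.isnan(hra) | ((hra >= 0) & (hra <= 100))
    if not valid.all():
        raise ValueError("relative humidity must be within [0, 100]")
    thi = 0.8 * tsa + hra / 100.0 * (tsa - 14.4) + 46.4
    return float(thi) if thi.ndim == 0 else thi


def assign_nearest_station(
    locations: pd.DataFrame, stations: pd.DataFrame
) -> pd.DataFrame:
    """Map each location to its Euclidean-nearest station.

    ``locations`` needs columns ``x, y`` (plus any id columns, preserved);
    ``stations`` needs ``station_id, x, y`` with unique ids.  Distance ties
    go to the lowest station_id, which makes the assignment independent of
    station row order.
    """
    if stations.empty:
        raise ValueError("station set is empty")
    if stations["station_id"].duplicated().any():
        raise ValueError("station_ids must be unique")
    st = stations.sort_values("station_id", kind="stable").reset_index(drop=True)
    sxy = st[["x", "y"]].to_numpy(dtype=float)
    lxy = locations[["x", "y"]].to_numpy(dtype=float)
    if not (np.isfinite(sxy).all() and np.isfinite(lxy).all()):
        raise ValueError("coordinates must be finite")
    d2 = ((lxy[:, None, :] - sxy[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first (lowest-id) minimiser thanks to the sort
    nearest = d2.argmin(axis=1)
    out = locations.copy()
    out["station_id"] = st["station_id"].to_numpy()[nearest]
    return out


def join_weather(
    records: pd.DataFrame,
    assignments: pd.DataFrame,
    weather: pd.DataFrame,
) -> pd.DataFrame:
    """Attach each record's station THI on its date.

    ``assignments`` maps ``herd_id -> station_id``; ``weather`` has
    ``station_id, date, tsa, hra`` (one row per station-date).  Records
    without coverage keep the row with ``thi`` missing and
    ``thi_missing=True`` rather than being dropped.
    """
    wx = weather.copy()
    wx["date"] = pd.to_datetime(wx["date"])
    if "thi" not in wx.columns:
        wx["thi"] = compute_thi(wx["tsa"].to_numpy(), wx["hra"].to_numpy())
    out = records.merge(
        assignments[["herd_id", "station_id"]], on="herd_id", how="left"
    )
    out["date"] = pd.to_datetime(out["date"])
    out = out.merge(
        wx[["station_id", "date", "thi"]], on=["station_id", "date"], how="left"
    )
    out["thi_missing"] = out["thi"].isna()
    out.index = records.index
    return out


def simulate_weather(
    stations: pd.DataFrame,
    dates: pd.DatetimeIndex,
    seed: int = 0,
    base_temp: float = 10.0,
    seasonal_amplitude: float = 8.0,
    heat_wave: tuple[str, str, float] | None = None,
) -> pd.DataFrame:
    """Synthetic daily station weather with an annual cycle.

    ``heat_wave`` is an optional ``(start, end, extra_degC)`` window added
    on top of the seasonal cycle, used to create a THI contrast in tests.
    """
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(dates).unique().sort_values()
    doy = dates.dayofyear.to_numpy()
    season = base_temp + seasonal_amplitude * np.sin(2 * np.pi * (doy - 105) / 365.25)
    rows = []
    for sid in stations["station_id"]:
        tsa = season + rng.normal(0, 2.0, size=len(dates))
        if heat_wave is not None:
            start, end, extra = heat_wave
            mask = (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
            tsa = tsa + np.where(mask, extra, 0.0)
        hra = np.clip(rng.normal(75, 10, size=len(dates)), 0, 100)
        rows.append(
            pd.DataFrame(
                {"station_id": sid, "date": dates, "tsa": tsa, "hra": hra}
            )
        )
    wx = pd.concat(rows, ignore_index=True)
    wx["thi"] = compute_thi(wx["tsa"].to_numpy(), wx["hra"].to_numpy())
    return wx
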