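"""Dead-reckoned pseudotracks, GPS forcing, and bathymetry lookup.

The tags carry no GPS, so the horizontal track is reconstructed by
integrating heading, pitch and an assumed swim speed from an origin fix
(dead reckoning) and then forcing the result through the GPS fixes taken
at surfacings: between consecutive fixes the accumulated drift is removed
linearly in time, so the corrected track passes exactly through every fix.

Positions use a local equirectangular tangent plane about the origin --
deployment extents of a few kilometers do not warrant great-circle
machinery.  Bathymetry is read from an ESRI ASCII grid and sampled at the
nearest cell to each dive-start position; the grid cells (15 arc-seconds
in the source data) are coarser than the residual track error, so no
interpolation is attempted.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .dives import DiveRecord
from .records import GPSFix, SensorSeries

__all__ = [
    "Track",
    "BathymetryGrid",
    "dead_reckon",
    "speed_from_depth_rate",
    "force_through_fixes",
    "bathymetry_at_dives",
    "read_esri_ascii",
    "write_esri_ascii",
]

METERS_PER_DEGREE = 111_194.93  # pi * mean Earth radius / 180


@dataclass
class Track:
    time: np.ndarray  # seconds, decimated grid
    latitude: np.ndarray
    longitude: np.ndarray
    corrected: bool = False

    def position_at(self, t: float) -> tuple[float, float]:
        return (
            float(np.interp(t, self.time, self.latitude)),
            float(np.interp(t, self.time, self.longitude)),
        )


def speed_from_depth_rate(
    series: SensorSeries, default: float = 1.5, min_pitch: float = 30.0
) -> np.ndarray:
    """Per-sample swim speed from |depth rate| / |sin(pitch)|.

    The vertical-speed heuristic: where the body is steeply pitched the
    depth rate divided by sin(pitch) estimates speed along the longitudinal
    axis; elsewhere the constant ``default`` (m/s) is used.
    """
    fs = series.sampling_rate
    dzdt = np.gradient(series.depth) * fs
    pitch = np.deg2rad(series.pitch)
    speed = np.full(len(series), float(default))
    steep = np.abs(series.pitch) > min_pitch
    speed[steep] = np.abs(dzdt[steep]) / np.abs(np.sin(pitch[steep]))
    return speed


def dead_reckon(
    series: SensorSeries,
    speed: Union[float, np.ndarray],
    origin: GPSFix,
    decimate_hz: float = 1.0,
) -> Track:
    """Integrate heading/pitch/speed into an uncorrected pseudotrack.

    Each sample advances the position by ``speed * cos(pitch) * dt`` along
    the heading.  The track starts at the origin fix's position and is
    decimated to ``decimate_hz`` -- position needs no 50-250 Hz resolution.
    """
    speed_arr = np.broadcast_to(np.asarray(speed, dtype=float), (len(series),))
    if np.any(speed_arr <= 0):
        raise ValueError("swim speed must be positive")
    fs = series.sampling_rate
    dt = 1.0 / fs
    horiz = speed_arr * np.cos(np.deg2rad(series.pitch)) * dt
    east = np.concatenate([[0.0], np.cumsum(horiz * np.sin(np.deg2rad(series.heading)))[:-1]])
    north = np.concatenate([[0.0], np.cumsum(horiz * np.cos(np.deg2rad(series.heading)))[:-1]])
    lat = origin.latitude + north / METERS_PER_DEGREE
    lon = origin.longitude + east / (
        METERS_PER_DEGREE * np.cos(np.deg2rad(origin.latitude))
    )
    step = max(int(round(fs / decimate_hz)), 1)
    idx = np.arange(0, len(series), step)
    return Track(time=series.time[idx], latitude=lat[idx], longitude=lon[idx])


def force_through_fixes(track: Track, fixes: Sequence[GPSFix]) -> Track:
    """Distribute dead-reckoning drift linearly between GPS fixes.

    The corrected track equals every fix at its time; before the first and
    after the last fix a constant offset is applied.  Fix times must lie
    within the track's time span.
    """
    if not fixes:
        raise ValueError("at least one GPS fix is required")
    ft = np.array([f.time for f in fixes])
    if ft.min() < track.time[0] - 1e-9 or ft.max() > track.time[-1] + 1e-9:
        raise ValueError("GPS fixes outside the track time span")
    res_lat = np.array(
        [f.latitude - np.interp(f.time, track.time, track.latitude) for f in fixes]
    )
    res_lon = np.array(
        [f.longitude - np.interp(f.time, track.time, track.longitude) for f in fixes]
    )
    # the correction is piecewise linear with kinks at the fix times, so the
    # output grid carries the fix times explicitly: the corrected track is
    # then exact at every fix even under later linear interpolation
    time = np.union1d(track.time, ft)
    lat = np.interp(time, track.time, track.latitude)
    lon = np.interp(time, track.time, track.longitude)
    corr_lat = np.interp(time, ft, res_lat)  # constant beyond the end fixes
    corr_lon = np.interp(time, ft, res_lon)
    return Track(
        time=time,
        latitude=lat + corr_lat,
        longitude=lon + corr_lon,
        corrected=True,
    )


@dataclass
class BathymetryGrid:
    """Regular lat/lon grid of water depth, meters positive-down.

    ``depth[0, 0]`` is the north-west corner, as in the ESRI ASCII layout.
    """

    xllcorner: float  # longitude of the west edge
    yllcorner: float  # latitude of the south edge
    cellsize: float  # degrees
    depth: np.ndarray  # (nrows, ncols), row 0 northmost
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.depth = np.atleast_2d(np.asarray(self.depth, dtype=float))
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    def _cell_index(self, value: float, origin: float) -> int:
        v = (value - origin) / self.cellsize
        idx = int(np.floor(v))
        # exact boundary between cells belongs to the lower-index cell
        if v == idx and idx > 0:
            idx -= 1
        return idx

    def value_at(self, latitude: float, longitude: float) -> Optional[float]:
        """Nearest-cell depth, or None outside the grid / at NODATA."""
        nrows, ncols = self.depth.shape
        col = self._cell_index(longitude, self.xllcorner)
        row_from_south = self._cell_index(latitude, self.yllcorner)
        row = nrows - 1 - row_from_south
        if not (0 <= col < ncols and 0 <= row < nrows):
            return None
        v = self.depth[row, col]
        return None if v == self.nodata else float(v)


def read_esri_ascii(path) -> BathymetryGrid:
    header: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline().split()
            if len(line) != 2 or not line[0].isalpha():
                break
            header[line[0].lower()] = float(line[1])
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII grid missing header field {key}")
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid dimensions do not match header")
    return BathymetryGrid(
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        depth=data,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_esri_ascii(grid: BathymetryGrid, path) -> None:
    nrows, ncols = grid.depth.shape
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {grid.xllcorner!r}\nyllcorner {grid.yllcorner!r}\n"
            f"cellsize {grid.cellsize!r}\nNODATA_value {grid.nodata!r}\n"
        )
        np.savetxt(fh, grid.depth, fmt="%.6g")


def bathymetry_at_dives(
    track: Track, dives: Sequence[DiveRecord], grid: BathymetryGrid
) -> list[DiveRecord]:
    """Attach dive-start position and nearest-cell bathymetry to each dive."""
    if not track.corrected:
        warnings.warn("bathymetry lookup on an uncorrected track")
    out = []
    for d in dives:
        lat, lon = track.position_at(d.start_time)
        depth = grid.value_at(lat, lon)
        if depth is None:
            warnings.warn(f"dive {d.dive_id} start position outside bathymetry grid")
        out.append(
            dataclasses.replace(
                d, start_latitude=lat, start_longitude=lon, bathymetry=depth
            )
        )
    return out
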