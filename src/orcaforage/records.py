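"""Domain types and file I/O for DTAG deployment data.

The central objects are :class:`DeploymentRecord` (one tag deployment with
its demographic metadata), :class:`SensorSeries` (the regular-rate depth /
orientation / acceleration stream recorded by the tag), :class:`GPSFix`
(surfacing positions taken from the tracking vessel) and :class:`SoundEvent`
(echolocation click or prey-handling event times extracted from the tag
audio).  A summary table of the 52 analyzed NRKW/SRKW deployments from the
2009-2014 field seasons ships with the package and anchors the cohort-level
analyses; :func:`load_deployment_fixture` returns it.

All within-deployment timestamps are seconds from deployment start; absolute
datetimes appear only in deployment metadata, which sidesteps timezone
ambiguity entirely.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DeploymentRecord",
    "SensorSeries",
    "GPSFix",
    "SoundEvent",
    "ValidationReport",
    "read_deployment_table",
    "write_deployment_table",
    "load_deployment_fixture",
    "read_sensor_series",
    "write_sensor_series",
    "read_gps_fixes",
    "write_gps_fixes",
    "read_sound_events",
    "write_sound_events",
    "validate_cohort",
]

ADULT_AGE = 12  # years; adulthood cutoff for both sexes
CALF_MAX_AGE = 3  # years; a dependent calf is <= 3 years old


@dataclass(frozen=True)
class DeploymentRecord:
    """One tag deployment on an individual whale.

    ``calf_age``/``has_calf`` are meaningful only for adult females and
    ``mother_age``/``mother_alive`` only for adult males; for everyone else
    they are ``None`` (not applicable).  ``searching_h`` is ``None`` when the
    audio record could not be analyzed -- an explicit missing value, distinct
    from a measured zero.
    """

    deployment_id: str
    start_datetime: pd.Timestamp
    population: str  # "NRKW" | "SRKW"
    sex: str  # "F" | "M" | "U"
    age: int  # years at tagging
    duration_h: float
    n_dives: Optional[int] = None
    n_capture_dives: Optional[int] = None
    has_calf: Optional[bool] = None
    calf_age: Optional[float] = None
    mother_alive: Optional[bool] = None
    mother_age: Optional[float] = None
    searching_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.population not in ("NRKW", "SRKW"):
            raise ValueError(f"unknown population {self.population!r}")
        if self.sex not in ("F", "M", "U"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.duration_h <= 0:
            raise ValueError("deployment duration must be positive")
        if self.age < 2:
            raise ValueError("tagged whales are at least 2 years old")

    @property
    def adult(self) -> bool:
        return self.age >= ADULT_AGE

    @property
    def week_year(self) -> str:
        """ISO week-of-year label, e.g. ``'2009-W35'``.

        A pure function of the deployment start date: the categorical level
        used as a random intercept absorbing week-scale environmental
        variation (salmon availability in particular).
        """
        iso = self.start_datetime.isocalendar()
        return f"{iso.year}-W{iso.week:02d}"


@dataclass
class SensorSeries:
    """Uniform-rate tag sensor stream, already in the animal frame.

    depth is meters positive-down; accel is an (n, 3) array in m/s^2;
    pitch/roll in degrees with roll in [-180, 180]; heading in [0, 360).
    """

    sampling_rate: float
    depth: np.ndarray
    accel: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    heading: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        n = self.depth.size
        if self.accel.shape != (n, 3):
            raise ValueError("accel must have shape (n, 3)")
        for name in ("pitch", "roll", "heading"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match depth")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if n and self.depth.min() < -0.5:
            raise ValueError("depth below -0.5 m: sign convention is positive-down")
        if n and (self.roll.min() < -180 or self.roll.max() > 180):
            raise ValueError("roll outside [-180, 180] degrees")
        if n and (self.heading.min() < 0 or self.heading.max() >= 360):
            raise ValueError("heading outside [0, 360) degrees")

    def __len__(self) -> int:
        return self.depth.size

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds from deployment start."""
        return np.arange(len(self)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.sampling_rate if len(self) else 0.0


@dataclass(frozen=True)
class GPSFix:
    time: float  # seconds from deployment start
    latitude: float
    longitude: float
    horizontal_error: Optional[float] = None  # meters


@dataclass(frozen=True)
class SoundEvent:
    time: float  # seconds from deployment start
    kind: str  # "click" | "handling"
    click_class: Optional[str] = None  # "slow" | "fast" | "buzz" for classified clicks

    def __post_init__(self) -> None:
        if self.kind not in ("click", "handling"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.click_class not in (None, "slow", "fast", "buzz"):
            raise ValueError(f"unknown click class {self.click_class!r}")


# ---------------------------------------------------------------------------
# Deployment table I/O

_MISSING = ""  # empty cell in CSV == not applicable / not available


def _parse_calf(cell: str) -> tuple[Optional[bool], Optional[float]]:
    if cell in (_MISSING, "nan"):
        return None, None
    if cell == "N":
        return False, None
    return True, float(cell)


def _parse_mother(cell: str) -> tuple[Optional[bool], Optional[float]]:
    if cell in (_MISSING, "nan"):
        return None, None
    if cell == "N":
        return False, None
    return True, float(cell)


def read_deployment_table(path) -> list[DeploymentRecord]:
    """Read a deployment metadata CSV into records.

    Empty cells map to missing/not-applicable.  Rows that cannot be parsed
    and duplicated deployment ids are rejected with the offending row index.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"deployment_id", "start_datetime", "population", "sex", "age", "duration_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"deployment table missing columns: {sorted(missing)}")
    records: list[DeploymentRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        try:
            dep_id = row["deployment_id"]
            if dep_id in seen:
                raise ValueError(f"duplicate deployment_id {dep_id!r}")
            seen.add(dep_id)
            has_calf, calf_age = _parse_calf(row.get("calf_age", _MISSING))
            mother_alive, mother_age = _parse_mother(row.get("mother_age", _MISSING))
            searching = row.get("searching_h", _MISSING)
            n_dives = row.get("n_dives", _MISSING)
            n_cap = row.get("n_capture_dives", _MISSING)
            records.append(
                DeploymentRecord(
                    deployment_id=dep_id,
                    start_datetime=pd.Timestamp(row["start_datetime"]),
                    population=row["population"],
                    sex=row["sex"],
                    age=int(row["age"]),
                    duration_h=float(row["duration_h"]),
                    n_dives=int(n_dives) if n_dives != _MISSING else None,
                    n_capture_dives=int(n_cap) if n_cap != _MISSING else None,
                    has_calf=has_calf,
                    calf_age=calf_age,
                    mother_alive=mother_alive,
                    mother_age=mother_age,
                    searching_h=float(searching) if searching != _MISSING else None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed deployment row {i}: {exc}") from exc
    return records


def _calf_cell(r: DeploymentRecord) -> str:
    if r.has_calf is None:
        return _MISSING
    if not r.has_calf:
        return "N"
    v = r.calf_age
    return str(int(v)) if v == int(v) else str(v)


def _mother_cell(r: DeploymentRecord) -> str:
    if r.mother_alive is None:
        return _MISSING
    if not r.mother_alive:
        return "N"
    v = r.mother_age
    return str(int(v)) if v == int(v) else str(v)


def write_deployment_table(records: Sequence[DeploymentRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "deployment_id": r.deployment_id,
                "start_datetime": r.start_datetime.strftime("%Y-%m-%d %H:%M:%S"),
                "population": r.population,
                "sex": r.sex,
                "age": r.age,
                "duration_h": f"{r.duration_h:.2f}",
                "n_dives": "" if r.n_dives is None else r.n_dives,
                "n_capture_dives": "" if r.n_capture_dives is None else r.n_capture_dives,
                "calf_age": _calf_cell(r),
                "mother_age": _mother_cell(r),
                "searching_h": "" if r.searching_h is None else f"{r.searching_h:.2f}",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def records_to_frame(records: Sequence[DeploymentRecord]) -> pd.DataFrame:
    """Deployment records as a modeling table (one row per deployment).

    ``calf`` / ``mother_alive`` are 0/1 floats with NaN where not
    applicable; ``week_year`` is the ISO label used as a random intercept.
    """
    return pd.DataFrame(
        {
            "deployment_id": [r.deployment_id for r in records],
            "population": [r.population for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
            "adult": [r.adult for r in records],
            "duration_h": [r.duration_h for r in records],
            "n_capture_dives": [
                np.nan if r.n_capture_dives is None else float(r.n_capture_dives)
                for r in records
            ],
            "calf": [np.nan if r.has_calf is None else float(r.has_calf) for r in records],
            "mother_alive": [
                np.nan if r.mother_alive is None else float(r.mother_alive) for r in records
            ],
            "searching_h": [
                np.nan if r.searching_h is None else r.searching_h for r in records
            ],
            "week_year": [r.week_year for r in records],
        }
    )


def load_deployment_fixture() -> list[DeploymentRecord]:
    """The packaged summary table of the 52 analyzed NRKW/SRKW deployments."""
    ref = importlib.resources.files("orcaforage") / "data" / "dtag_deployments.csv"
    with importlib.resources.as_file(ref) as p:
        return read_deployment_table(p)


# ---------------------------------------------------------------------------
# Sensor series I/O

_SENSOR_COLS = ["depth", "ax", "ay", "az", "pitch", "roll", "heading"]


def _check_uniform(time: np.ndarray, fs: float) -> None:
    if time.size >= 2:
        dt = np.diff(time)
        if not np.allclose(dt, 1.0 / fs, atol=1e-6 / fs, rtol=1e-6):
            if np.any(dt <= 0):
                raise ValueError("time column is not strictly increasing")
            raise ValueError("time grid is not uniform at the declared sampling rate")


def write_sensor_series(series: SensorSeries, path) -> None:
    """Write a sensor stream as CSV (``.csv``) or NetCDF (anything else)."""
    path = Path(path)
    if path.suffix == ".csv":
        with open(path, "w") as fh:
            fh.write(f"# sampling_rate_hz: {series.sampling_rate!r}\n")
            df = pd.DataFrame(
                {
                    "time_s": series.time,
                    "depth": series.depth,
                    "ax": series.accel[:, 0],
                    "ay": series.accel[:, 1],
                    "az": series.accel[:, 2],
                    "pitch": series.pitch,
                    "roll": series.roll,
                    "heading": series.heading,
                }
            )
            df.to_csv(fh, index=False)
    else:
        import xarray as xr

        ds = xr.Dataset(
            {
                "depth": ("time", series.depth),
                "ax": ("time", series.accel[:, 0]),
                "ay": ("time", series.accel[:, 1]),
                "az": ("time", series.accel[:, 2]),
                "pitch": ("time", series.pitch),
                "roll": ("time", series.roll),
                "heading": ("time", series.heading),
            },
            coords={"time": series.time},
            attrs={"sampling_rate_hz": series.sampling_rate},
        )
        ds.to_netcdf(path, engine="scipy")


def read_sensor_series(path) -> SensorSeries:
    """Read a sensor stream from CSV or NetCDF, enforcing grid uniformity."""
    path = Path(path)
    if path.suffix == ".csv":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# sampling_rate_hz:"):
                raise ValueError("sensor CSV must declare '# sampling_rate_hz:' on line 1")
            fs = float(header.split(":", 1)[1])
            df = pd.read_csv(fh)
        missing = set(["time_s"] + _SENSOR_COLS) - set(df.columns)
        if missing:
            raise ValueError(f"sensor CSV missing channels: {sorted(missing)}")
        time = df["time_s"].to_numpy(float)
        data = {c: df[c].to_numpy(float) for c in _SENSOR_COLS}
    else:
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            fs = float(ds.attrs["sampling_rate_hz"])
            missing = set(_SENSOR_COLS) - set(ds.data_vars)
            if missing:
                raise ValueError(f"sensor file missing channels: {sorted(missing)}")
            time = ds["time"].to_numpy().astype(float)
            data = {c: ds[c].to_numpy().astype(float) for c in _SENSOR_COLS}
    if np.any(~np.isfinite(time)) or any(np.any(~np.isfinite(v)) for v in data.values()):
        raise ValueError("sensor stream contains gaps (non-finite samples)")
    _check_uniform(time, fs)
    return SensorSeries(
        sampling_rate=fs,
        depth=data["depth"],
        accel=np.column_stack([data["ax"], data["ay"], data["az"]]),
        pitch=data["pitch"],
        roll=data["roll"],
        heading=data["heading"],
    )


# ---------------------------------------------------------------------------
# GPS and sound-event I/O


def write_gps_fixes(fixes: Sequence[GPSFix], path) -> None:
    pd.DataFrame(
        {
            "time_s": [f.time for f in fixes],
            "lat": [f.latitude for f in fixes],
            "lon": [f.longitude for f in fixes],
            "err_m": [f.horizontal_error for f in fixes],
        }
    ).to_csv(path, index=False)


def read_gps_fixes(path) -> list[GPSFix]:
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("GPS fix times must be strictly increasing")
    errs = df["err_m"] if "err_m" in df.columns else [None] * len(df)
    return [
        GPSFix(float(t), float(la), float(lo), None if pd.isna(e) else float(e))
        for t, la, lo, e in zip(times, df["lat"], df["lon"], errs)
    ]


def write_sound_events(events: Sequence[SoundEvent], path) -> None:
    pd.DataFrame(
        {
            "time_s": [e.time for e in events],
            "kind": [e.kind for e in events],
            "class": [e.click_class or "" for e in events],
        }
    ).to_csv(path, index=False)


def read_sound_events(path) -> list[SoundEvent]:
    df = pd.read_csv(path, dtype={"kind": str, "class": str}, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        cls = row.get("class", "")
        out.append(SoundEvent(float(row["time_s"]), row["kind"], cls if cls else None))
    return out


# ---------------------------------------------------------------------------
# Cohort validation


@dataclass
class ValidationReport:
    """Report-only summary of cohort composition (never raises)."""

    n_records: int
    n_known_sex: int
    group_counts: dict  # (population, sex) -> count, known sex only
    n_adult_females: int
    n_adult_males: int
    n_adult_females_with_calf_info: int
    n_adult_males_with_mother_info: int
    total_hours: float
    hours_by_population: dict


def validate_cohort(records: Sequence[DeploymentRecord]) -> ValidationReport:
    known = [r for r in records if r.sex != "U"]
    groups: dict = {}
    for r in known:
        key = (r.population, r.sex)
        groups[key] = groups.get(key, 0) + 1
    af = [r for r in known if r.sex == "F" and r.adult]
    am = [r for r in known if r.sex == "M" and r.adult]
    hours_by_pop: dict = {}
    for r in records:
        hours_by_pop[r.population] = hours_by_pop.get(r.population, 0.0) + r.duration_h
    return ValidationReport(
        n_records=len(records),
        n_known_sex=len(known),
        group_counts=groups,
        n_adult_females=len(af),
        n_adult_males=len(am),
        n_adult_females_with_calf_info=sum(r.has_calf is not None for r in af),
        n_adult_males_with_mother_info=sum(r.mother_alive is not None for r in am),
        total_hours=sum(r.duration_h for r in records),
        hours_by_population=hours_by_pop,
    )
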