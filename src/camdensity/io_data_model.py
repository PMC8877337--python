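"""Tabular input/output and per-estimator observation structures.

This module owns the study's data model: camera deployments (with active
windows and viewshed geometry), timestamped detection events, and the
builders that turn them into the observation structures each estimator
consumes —

* snapshot (space-to-event) occasions: at every sampling tick, the
  cumulative viewshed area scanned, in randomized station order, until a
  station containing an animal is reached; ticks with no detection are
  censored at the total active area and are stored as aggregate counts
  per active-station configuration, never materialized one by one;
* time-to-event occasions: fixed-length occasions anchored on a regular
  grid, subdivided into movement-rate–derived periods, recording the
  first period with a detection (or censoring at the last period);
* site-by-occasion count matrices for the site-based abundance model;
* individual × trap × occasion capture histories for SECR.

Timestamps are timezone-naive local time at 1-second resolution; all
instruments are assumed to share one clock.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .viewshed import LARGEST, ViewshedScenario, station_area, trapezoid_area

__all__ = [
    "CameraViewshed",
    "Deployment",
    "DetectionEvent",
    "SteOccasions",
    "TTEOccasion",
    "CountMatrix",
    "SECRData",
    "StudyConfig",
    "DataFormatError",
    "EmptySurveyError",
    "read_deployments",
    "read_detections",
    "write_deployments",
    "write_detections",
    "station_areas",
    "split_by_window",
    "build_ste_occasions",
    "build_tte_occasions",
    "build_count_matrix",
    "build_secr_histories",
]


class DataFormatError(ValueError):
    """A structural problem with an input table (missing columns, bad rows)."""

    def __init__(self, message: str, row_errors: Sequence[str] = ()):
        self.row_errors = list(row_errors)
        if self.row_errors:
            message = message + "\n  " + "\n  ".join(self.row_errors)
        super().__init__(message)


class EmptySurveyError(ValueError):
    """Raised when a builder is asked to operate on a survey with no effort."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraViewshed:
    """Trapezoid dimensions of one camera's viewshed, in meters."""

    near_width_m: float
    far_width_m: float
    depth_m: float

    @property
    def area_m2(self) -> float:
        return trapezoid_area(self.near_width_m, self.far_width_m, self.depth_m)


@dataclass
class Deployment:
    """One camera station: location, active windows, and camera viewsheds.

    ``active_windows`` are half-open ``[start, end)`` intervals during which
    the station was operational; they must be non-overlapping with
    ``start < end``.  A stolen or failed camera simply has no window covering
    the lost span — absence of effort, never zeros.
    """

    station_id: str
    x: float
    y: float
    active_windows: list[tuple[datetime, datetime]]
    cameras: dict[str, CameraViewshed] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wins = sorted(self.active_windows)
        for start, end in wins:
            if not start < end:
                raise ValueError(
                    f"station {self.station_id}: window start {start} not before end {end}"
                )
        for (s0, e0), (s1, e1) in zip(wins, wins[1:]):
            if s1 < e0:
                raise ValueError(
                    f"station {self.station_id}: overlapping windows {e0} / {s1}"
                )
        self.active_windows = wins

    def is_active(self, t: datetime) -> bool:
        return any(s <= t < e for s, e in self.active_windows)

    def area_m2(self, scenario: ViewshedScenario = LARGEST) -> float:
        """Station viewshed area under a scenario (largest camera × multiplier)."""
        return station_area([c.area_m2 for c in self.cameras.values()], scenario)

    def mean_depth_m(self) -> float:
        depths = [c.depth_m for c in self.cameras.values()]
        return float(np.mean(depths))


@dataclass(frozen=True)
class DetectionEvent:
    """One timestamped photo-encounter of a species at a station."""

    station_id: str
    species: str
    timestamp: datetime
    group_count: int = 1
    individual_id: str | None = None

    def __post_init__(self) -> None:
        if self.group_count < 1:
            raise ValueError("group_count must be >= 1")


@dataclass
class SteOccasions:
    """Space-to-event observations for one species.

    Event occasions (ticks with at least one detection) are materialized with
    their area-to-event ``s`` and total active area; occasions with no
    detection are censored at the total active area and stored only as
    ``(count, A_total)`` aggregates per distinct active-station configuration.
    """

    s_events: np.ndarray          # area-to-event, m², one per event occasion
    event_a_total: np.ndarray     # total active area at each event occasion
    censored: list[tuple[int, float]]   # (n occasions, A_total) per configuration
    seed: int
    n_flagged: int = 0            # detections excluded (inactive station/unknown)
    meta: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return int(len(self.s_events))

    @property
    def n_censored(self) -> int:
        return int(sum(c for c, _ in self.censored))

    @property
    def n_occasions(self) -> int:
        return self.n_events + self.n_censored


@dataclass(frozen=True)
class TTEOccasion:
    """One time-to-event occasion at one station.

    The occasion is divided into ``J`` movement-rate–derived periods of
    ``period_length_hr`` hours each; ``T`` is the 1-based index of the first
    period containing a detection, or ``None`` when censored at ``J``.
    """

    station_id: str
    occasion_start: datetime
    period_length_hr: float
    J: int
    T: int | None

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.T is not None and not 0 < self.T <= self.J:
            raise ValueError("T must lie in (0, J] when not censored")

    @property
    def censored(self) -> bool:
        return self.T is None


@dataclass
class CountMatrix:
    """Site × occasion counts for the site-based abundance model.

    ``C`` is float-valued with NaN marking site-occasions where the camera
    was inactive — distinct from observed zeros.
    """

    C: np.ndarray
    site_ids: list[str]
    occasion_dates: list[datetime]

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2:
            raise ValueError("C must be 2-D (sites × occasions)")
        if self.C.shape != (len(self.site_ids), len(self.occasion_dates)):
            raise ValueError("C shape does not match site/occasion labels")
        obs = self.C[~np.isnan(self.C)]
        if (obs < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def M(self) -> int:
        return self.C.shape[0]

    @property
    def J(self) -> int:
        return self.C.shape[1]


@dataclass
class SECRData:
    """Spatial capture histories: individual × trap × occasion counts.

    ``usage`` is a trap × occasion 0/1 matrix of camera effort; counts must
    be zero wherever usage is zero.
    """

    trap_ids: list[str]
    trap_xy: np.ndarray            # (n_traps, 2) in meters
    individual_ids: list[str]
    y: np.ndarray                  # (n_individuals, n_traps, K) integer counts
    usage: np.ndarray              # (n_traps, K) in {0, 1}
    occasion_dates: list[datetime] = field(default_factory=list)
    n_excluded: int = 0            # detections dropped (no individual id, or off-usage)

    def __post_init__(self) -> None:
        self.trap_xy = np.asarray(self.trap_xy, dtype=float)
        self.y = np.asarray(self.y)
        self.usage = np.asarray(self.usage)
        n, ntr, K = self.y.shape
        if ntr != len(self.trap_ids) or n != len(self.individual_ids):
            raise ValueError("history tensor shape does not match labels")
        if self.usage.shape != (ntr, K):
            raise ValueError("usage shape does not match traps × occasions")
        if (self.y < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.y.sum(axis=(1, 2)) < 1).any():
            raise ValueError("every individual must have at least one detection")
        if (self.y[:, self.usage == 0] > 0).any():
            raise ValueError("detections recorded at inactive trap-occasions")

    @property
    def K(self) -> int:
        return self.y.shape[2]

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]


@dataclass(frozen=True)
class StudyConfig:
    """Study-level settings: the area used to convert density to abundance."""

    study_area_km2: float
    density_unit: str = "per 100 km2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study_area_km2 <= 0:
            raise ValueError("study_area_km2 must be positive")

    @property
    def study_area_m2(self) -> float:
        return self.study_area_km2 * 1e6


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_DEPLOY_COLS = [
    "station_id", "camera_id", "x", "y", "start", "end",
    "near_width_m", "far_width_m", "depth_m",
]
_DETECT_COLS = ["station_id", "species", "timestamp", "group_count", "individual_id"]


def _parse_ts(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, errors="coerce")


def read_deployments(path: str | Path) -> list[Deployment]:
    """Read a deployment table (one row per camera per active window).

    Raises :class:`DataFormatError` listing offending rows (1-based, counting
    the header as row 1) for unparseable timestamps, negative dimensions, or
    windows with ``end <= start``.
    """
    df = pd.read_csv(path, dtype={"station_id": str, "camera_id": str})
    missing = [c for c in _DEPLOY_COLS if c not in df.columns]
    if missing:
        raise DataFormatError(f"deployment file {path} missing columns: {missing}")

    start = _parse_ts(df["start"])
    end = _parse_ts(df["end"])
    row_errors: list[str] = []
    for idx in df.index:
        row_no = idx + 2  # header is row 1
        if pd.isna(start[idx]):
            row_errors.append(f"row {row_no}: unparseable start {df['start'][idx]!r}")
        if pd.isna(end[idx]):
            row_errors.append(f"row {row_no}: unparseable end {df['end'][idx]!r}")
        if not (pd.isna(start[idx]) or pd.isna(end[idx])) and end[idx] <= start[idx]:
            row_errors.append(f"row {row_no}: window end {end[idx]} <= start {start[idx]}")
        for c in ("near_width_m", "far_width_m", "depth_m"):
            if df[c][idx] < 0:
                row_errors.append(f"row {row_no}: negative {c} ({df[c][idx]})")
    if row_errors:
        raise DataFormatError(f"deployment file {path} has malformed rows", row_errors)

    deployments: list[Deployment] = []
    for sid, grp in df.groupby("station_id", sort=True):
        cams = {
            str(cid): CameraViewshed(
                float(g["near_width_m"].iloc[0]),
                float(g["far_width_m"].iloc[0]),
                float(g["depth_m"].iloc[0]),
            )
            for cid, g in grp.groupby("camera_id")
        }
        windows = sorted(
            {
                (start[i].to_pydatetime(), end[i].to_pydatetime())
                for i in grp.index
            }
        )
        deployments.append(
            Deployment(
                station_id=str(sid),
                x=float(grp["x"].iloc[0]),
                y=float(grp["y"].iloc[0]),
                active_windows=windows,
                cameras=cams,
            )
        )
    return deployments


def read_detections(path: str | Path) -> list[DetectionEvent]:
    """Read a detection table; ``individual_id`` may be blank."""
    df = pd.read_csv(path, dtype={"station_id": str, "individual_id": str})
    required = [c for c in _DETECT_COLS if c != "individual_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"detection file {path} missing columns: {missing}")
    if "individual_id" not in df.columns:
        df["individual_id"] = pd.NA

    ts = _parse_ts(df["timestamp"])
    row_errors = [
        f"row {i + 2}: unparseable timestamp {df['timestamp'][i]!r}"
        for i in df.index
        if pd.isna(ts[i])
    ]
    if row_errors:
        raise DataFormatError(f"detection file {path} has malformed rows", row_errors)

    events = []
    for i in df.index:
        iid = df["individual_id"][i]
        events.append(
            DetectionEvent(
                station_id=str(df["station_id"][i]),
                species=str(df["species"][i]),
                timestamp=ts[i].to_pydatetime(),
                group_count=int(df["group_count"][i]),
                individual_id=None if pd.isna(iid) else str(iid),
            )
        )
    return events


def write_deployments(deps: Iterable[Deployment], path: str | Path) -> None:
    rows = []
    for d in deps:
        for cid, cam in sorted(d.cameras.items()):
            for s, e in d.active_windows:
                rows.append(
                    {
                        "station_id": d.station_id, "camera_id": cid,
                        "x": d.x, "y": d.y,
                        "start": s.isoformat(sep=" "), "end": e.isoformat(sep=" "),
                        "near_width_m": cam.near_width_m,
                        "far_width_m": cam.far_width_m,
                        "depth_m": cam.depth_m,
                    }
                )
    pd.DataFrame(rows, columns=_DEPLOY_COLS).to_csv(path, index=False)


def write_detections(dets: Iterable[DetectionEvent], path: str | Path) -> None:
    rows = [
        {
            "station_id": e.station_id, "species": e.species,
            "timestamp": e.timestamp.isoformat(sep=" "),
            "group_count": e.group_count,
            "individual_id": "" if e.individual_id is None else e.individual_id,
        }
        for e in dets
    ]
    pd.DataFrame(rows, columns=_DETECT_COLS).to_csv(path, index=False)


def write_result_json(payload: dict, path: str | Path, *, seed: int | None = None,
                      settings: dict | None = None) -> None:
    """Write a result with a provenance metadata block."""
    from . import __version__

    out = {
        "metadata": {
            "package": "camdensity",
            "version": __version__,
            "seed": seed,
            "settings": settings or {},
        },
        **payload,
    }
    Path(path).write_text(json.dumps(out, indent=2, default=str))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def station_areas(deps: Iterable[Deployment],
                  scenario: ViewshedScenario = LARGEST) -> dict[str, float]:
    """Station-id → viewshed area (m²) under a scenario."""
    return {d.station_id: d.area_m2(scenario) for d in deps}


def split_by_window(deps: Sequence[Deployment], dets: Iterable[DetectionEvent],
                    species: str | None = None
                    ) -> tuple[list[DetectionEvent], list[DetectionEvent]]:
    """Partition detections into (usable, flagged).

    Flagged detections fall outside every active window of their station, or
    reference an unknown station.  Every detection lands in exactly one bin.
    """
    by_id = {d.station_id: d for d in deps}
    used, flagged = [], []
    for e in dets:
        if species is not None and e.species != species:
            continue
        dep = by_id.get(e.station_id)
        (used if dep is not None and dep.is_active(e.timestamp) else flagged).append(e)
    return used, flagged


def _epoch_s(t: datetime, origin: datetime) -> int:
    return int((t - origin).total_seconds())


# ---------------------------------------------------------------------------
# observation builders
# ---------------------------------------------------------------------------


def build_ste_occasions(
    deps: Sequence[Deployment],
    dets: Iterable[DetectionEvent],
    *,
    species: str | None = None,
    scenario: ViewshedScenario = LARGEST,
    freq_s: int = 1,
    length_s: int = 1,
    seed: int = 0,
) -> SteOccasions:
    """Build space-to-event occasions on a regular tick grid.

    A tick at instant ``t`` covers ``[t, t + length_s)``; ticks are laid every
    ``freq_s`` seconds from the earliest window start.  At each tick with at
    least one detection, stations active at that tick are scanned in a fresh
    seeded random order and the area-to-event ``s`` is the cumulative station
    area up to and including the first detecting station.  Ticks with no
    detection are censored at the total active area and only counted, grouped
    by the set of stations active at the tick.
    """
    if freq_s < length_s:
        raise ValueError("sampling frequency must be >= sampling length")
    areas = station_areas(deps, scenario)
    all_windows = [(w, d.station_id) for d in deps for w in d.active_windows]
    if not all_windows:
        raise EmptySurveyError("no active camera windows in the survey")
    origin = min(w[0][0] for w in all_windows)

    # integer-second windows per station
    win_s: dict[str, list[tuple[int, int]]] = {}
    for d in deps:
        win_s[d.station_id] = [
            (_epoch_s(s, origin), _epoch_s(e, origin)) for s, e in d.active_windows
        ]

    def ticks_in(a: int, b: int) -> range:
        """Tick indices k with a <= k*freq_s < b (tick start inside [a, b))."""
        k0 = -((-a) // freq_s)
        k1 = -((-b) // freq_s)
        return range(k0, k1)

    # boundary sweep: constant active-station set between consecutive boundaries
    bounds = sorted({t for wins in win_s.values() for w in wins for t in w})
    seg_config: list[tuple[int, int, frozenset[str]]] = []
    for a, b in zip(bounds, bounds[1:]):
        active = frozenset(
            sid for sid, wins in win_s.items() if any(s <= a and b <= e for s, e in wins)
        )
        if active:
            seg_config.append((a, b, active))

    # ticks per configuration (exact count, no materialization)
    config_ticks: dict[frozenset[str], int] = {}
    for a, b, cfg in seg_config:
        config_ticks[cfg] = config_ticks.get(cfg, 0) + len(ticks_in(a, b))

    usable, flagged = split_by_window(deps, dets, species)

    # map detections to ticks
    tick_hits: dict[int, set[str]] = {}
    for e in usable:
        t = _epoch_s(e.timestamp, origin)
        k, rem = divmod(t, freq_s)
        if rem < length_s and t >= 0:
            tick_hits.setdefault(k, set()).add(e.station_id)

    def active_at(t: int) -> list[str]:
        return sorted(
            sid for sid, wins in win_s.items() if any(s <= t < e for s, e in wins)
        )

    rng = np.random.default_rng(seed)
    s_events, a_totals = [], []
    config_events: dict[frozenset[str], int] = {}
    for k in sorted(tick_hits):
        t = k * freq_s
        active = active_at(t)
        if not active:
            continue
        detecting = tick_hits[k] & set(active)
        if not detecting:
            continue
        order = rng.permutation(len(active))
        s = 0.0
        for idx in order:
            sid = active[idx]
            s += areas[sid]
            if sid in detecting:
                break
        a_tot = sum(areas[sid] for sid in active)
        s_events.append(s)
        a_totals.append(a_tot)
        cfg = frozenset(active)
        config_events[cfg] = config_events.get(cfg, 0) + 1

    censored = []
    for cfg, n in sorted(config_ticks.items(), key=lambda kv: sorted(kv[0])):
        n_c = n - config_events.get(cfg, 0)
        if n_c > 0:
            censored.append((n_c, sum(areas[sid] for sid in cfg)))

    return SteOccasions(
        s_events=np.asarray(s_events, dtype=float),
        event_a_total=np.asarray(a_totals, dtype=float),
        censored=censored,
        seed=seed,
        n_flagged=len(flagged),
        meta={
            "scenario": scenario.name,
            "freq_s": freq_s,
            "length_s": length_s,
            "origin": origin.isoformat(sep=" "),
            "n_ticks": sum(config_ticks.values()),
        },
    )


def build_tte_occasions(
    deps: Sequence[Deployment],
    dets: Iterable[DetectionEvent],
    movement_rate_m_per_hr: float,
    *,
    species: str | None = None,
    occasion_spacing_hr: float = 2.0,
    occasion_length_hr: float = 1.0,
    crossing_distance_m: Mapping[str, float] | float | None = None,
) -> list[TTEOccasion]:
    """Build time-to-event occasions anchored every ``occasion_spacing_hr``.

    The period length is the time an animal moving at the supplied rate takes
    to cross the viewshed: crossing distance / rate.  The crossing distance
    defaults to the station's mean camera viewshed depth; pass a scalar or a
    per-station mapping to override.  ``J = floor(occasion_length / period)``
    (at least 1); ``T`` is the first period containing a detection, else the
    occasion is censored at ``J``.  Occasions that would extend past the end
    of an active window are not formed.
    """
    if movement_rate_m_per_hr <= 0:
        raise ValueError("movement rate must be positive")
    usable, _flagged = split_by_window(deps, dets, species)
    det_by_station: dict[str, list[float]] = {}
    origin = min(w[0] for d in deps for w in d.active_windows)
    for e in usable:
        det_by_station.setdefault(e.station_id, []).append(
            (e.timestamp - origin).total_seconds() / 3600.0
        )
    for v in det_by_station.values():
        v.sort()

    occasions: list[TTEOccasion] = []
    for d in deps:
        if crossing_distance_m is None:
            dist = d.mean_depth_m()
        elif isinstance(crossing_distance_m, Mapping):
            dist = crossing_distance_m[d.station_id]
        else:
            dist = float(crossing_distance_m)
        period_hr = dist / movement_rate_m_per_hr
        if period_hr > occasion_length_hr:
            warnings.warn(
                f"station {d.station_id}: period ({period_hr:.3g} hr) exceeds "
                f"occasion length; J clamped to 1",
                stacklevel=2,
            )
            J = 1
            period_hr = occasion_length_hr
        else:
            J = max(1, int(np.floor(occasion_length_hr / period_hr)))
        times = np.asarray(det_by_station.get(d.station_id, []))
        for w_start, w_end in d.active_windows:
            ws = (w_start - origin).total_seconds() / 3600.0
            we = (w_end - origin).total_seconds() / 3600.0
            n_occ = int(np.floor((we - ws - occasion_length_hr) / occasion_spacing_hr)) + 1
            if we - ws < occasion_length_hr:
                n_occ = 0
            for i in range(n_occ):
                a = ws + i * occasion_spacing_hr
                horizon = a + J * period_hr
                in_occ = times[(times >= a) & (times < horizon)]
                if in_occ.size:
                    T = int((in_occ[0] - a) // period_hr) + 1
                    T = min(T, J)
                else:
                    T = None
                occasions.append(
                    TTEOccasion(
                        station_id=d.station_id,
                        occasion_start=origin + timedelta(hours=a),
                        period_length_hr=period_hr,
                        J=J,
                        T=T,
                    )
                )
    return occasions


def build_count_matrix(
    deps: Sequence[Deployment],
    dets: Iterable[DetectionEvent],
    *,
    species: str | None = None,
    occasion_length_days: int = 1,
    count_rule: str = "max_group",
) -> CountMatrix:
    """Site × occasion count matrix with NaN marking inactive site-occasions.

    ``count_rule='max_group'`` (default) takes the largest group count among
    the occasion's events — repeated photos of the same group do not inflate
    the count; ``'n_events'`` counts detection events instead.
    """
    if count_rule not in ("max_group", "n_events"):
        raise ValueError("count_rule must be 'max_group' or 'n_events'")
    if not deps:
        raise EmptySurveyError("no deployments")
    usable, _ = split_by_window(deps, dets, species)

    day0 = min(w[0] for d in deps for w in d.active_windows).date()
    # last instant of effort decides the final day (midnight end adds no day)
    day_end = (max(w[1] for d in deps for w in d.active_windows)
               - timedelta(seconds=1)).date()
    n_days = (day_end - day0).days + 1
    n_occ = -(-n_days // occasion_length_days)
    if n_occ == 0:
        raise EmptySurveyError("survey spans zero occasions")

    site_ids = sorted(d.station_id for d in deps)
    site_idx = {s: i for i, s in enumerate(site_ids)}
    occ_dates = [
        datetime.combine(day0, datetime.min.time())
        + timedelta(days=j * occasion_length_days)
        for j in range(n_occ)
    ]

    C = np.full((len(site_ids), n_occ), np.nan)
    for d in deps:
        for j, start in enumerate(occ_dates):
            end = start + timedelta(days=occasion_length_days)
            active = any(s < end and start < e for s, e in d.active_windows)
            if active:
                C[site_idx[d.station_id], j] = 0.0

    for e in usable:
        j = (e.timestamp.date() - day0).days // occasion_length_days
        i = site_idx[e.station_id]
        if np.isnan(C[i, j]):
            # detection inside a window but occasion marked inactive cannot happen
            C[i, j] = 0.0
        if count_rule == "max_group":
            C[i, j] = max(C[i, j], e.group_count)
        else:
            C[i, j] += 1
    return CountMatrix(C=C, site_ids=site_ids, occasion_dates=occ_dates)


def build_secr_histories(
    deps: Sequence[Deployment],
    dets: Iterable[DetectionEvent],
    *,
    species: str | None = None,
    occasion_length_days: int = 1,
) -> SECRData:
    """Individual × trap × occasion capture histories with a usage matrix.

    Detections lacking an individual id are excluded (their number reported
    in ``n_excluded``), as are detections at trap-occasions without effort.
    """
    if not deps:
        raise EmptySurveyError("no deployments")
    usable, flagged = split_by_window(deps, dets, species)
    with_id = [e for e in usable if e.individual_id is not None]
    n_no_id = len(usable) - len(with_id)
    if n_no_id:
        warnings.warn(f"{n_no_id} detections lack individual_id and were excluded",
                      stacklevel=2)

    day0 = min(w[0] for d in deps for w in d.active_windows).date()
    day_end = (max(w[1] for d in deps for w in d.active_windows)
               - timedelta(seconds=1)).date()
    K = ((day_end - day0).days + 1 + occasion_length_days - 1) // occasion_length_days

    trap_ids = sorted(d.station_id for d in deps)
    trap_idx = {s: i for i, s in enumerate(trap_ids)}
    trap_xy = np.array([[d.x, d.y] for d in sorted(deps, key=lambda d: d.station_id)])

    occ_dates = [
        datetime.combine(day0, datetime.min.time())
        + timedelta(days=t * occasion_length_days)
        for t in range(K)
    ]
    usage = np.zeros((len(trap_ids), K), dtype=int)
    for d in deps:
        for t, start in enumerate(occ_dates):
            end = start + timedelta(days=occasion_length_days)
            if any(s < end and start < e for s, e in d.active_windows):
                usage[trap_idx[d.station_id], t] = 1

    ind_ids = sorted({e.individual_id for e in with_id})
    ind_idx = {s: i for i, s in enumerate(ind_ids)}
    y = np.zeros((len(ind_ids), len(trap_ids), K), dtype=int)
    n_off_usage = 0
    for e in with_id:
        t = (e.timestamp.date() - day0).days // occasion_length_days
        k = trap_idx[e.station_id]
        if usage[k, t] == 0:
            n_off_usage += 1
            continue
        y[ind_idx[e.individual_id], k, t] += 1
    if n_off_usage:
        warnings.warn(f"{n_off_usage} identified detections fell on inactive "
                      "trap-occasions and were excluded", stacklevel=2)

    keep = y.sum(axis=(1, 2)) > 0
    return SECRData(
        trap_ids=trap_ids,
        trap_xy=trap_xy,
        individual_ids=[i for i, k in zip(ind_ids, keep) if k],
        y=y[keep],
        usage=usage,
        occasion_dates=occ_dates,
        n_excluded=n_no_id + n_off_usage + len(flagged),
    )
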