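"""Synthetic camera-trap data generators.

Each generator produces data under exactly the statistical assumptions of
one estimator (so parameter recovery is a clean test of the fitting code),
plus ``make_study_like_dataset``, which emulates the field design the
package targets: 27 paired-camera stations on a jittered 2-km lattice run
in three 16–18-day blocks, photographing one group-living species (packs of
6–12, detections correlated within packs) and one solitary, individually
identifiable species.

Every generator is deterministic given its seed and returns a
:class:`SimTruth` recording the generating parameters alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .io_data_model import (
    CameraViewshed,
    CountMatrix,
    Deployment,
    DetectionEvent,
    SECRData,
)
from .secr import halfnormal_rate
from .tte import MovementRate
from .viewshed import LARGEST, ViewshedScenario

__all__ = [
    "SimTruth",
    "sim_sba_counts",
    "sim_snapshot_stream",
    "sim_tte_stream",
    "sim_secr",
    "make_study_like_dataset",
]


@dataclass
class SimTruth:
    """Generating parameters stored beside every synthetic dataset."""

    seed: int
    density_per_100km2: float | None = None
    site_abundance: np.ndarray | None = None
    alpha: float | None = None
    beta: float | None = None
    lam: float | None = None
    lam0: float | None = None
    sigma_m: float | None = None
    movement: MovementRate | None = None
    extra: dict = field(default_factory=dict)


def sim_sba_counts(
    M: int, J: int, lam: float, alpha: float, beta: float, seed: int
) -> tuple[CountMatrix, SimTruth]:
    """Exact generative draw from the beta-binomial/Poisson mixture."""
    if lam < 0 or alpha <= 0 or beta <= 0:
        raise ValueError("lam must be >= 0 and alpha, beta positive")
    rng = np.random.default_rng(seed)
    N = rng.poisson(lam, size=M)
    p = rng.beta(alpha, beta, size=(M, J))
    C = rng.binomial(N[:, None], p).astype(float)
    t0 = datetime(2019, 4, 1)
    cm = CountMatrix(
        C=C,
        site_ids=[f"S{i + 1:02d}" for i in range(M)],
        occasion_dates=[t0 + timedelta(days=j) for j in range(J)],
    )
    return cm, SimTruth(seed=seed, site_abundance=N, alpha=alpha, beta=beta, lam=lam)


def _station_ticks(dep: Deployment, origin: datetime, freq_s: int = 1) -> np.ndarray:
    """Tick offsets (seconds from origin) at which the station is active."""
    chunks = []
    for s, e in dep.active_windows:
        a = int((s - origin).total_seconds())
        b = int((e - origin).total_seconds())
        k0, k1 = -((-a) // freq_s), -((-b) // freq_s)
        chunks.append(np.arange(k0, k1) * freq_s)
    return np.concatenate(chunks) if chunks else np.array([], dtype=int)


def sim_snapshot_stream(
    true_density_per_m2: float,
    deps: list[Deployment],
    seed: int,
    *,
    species: str = "sim",
    scenario: ViewshedScenario = LARGEST,
    freq_s: int = 1,
) -> list[DetectionEvent]:
    """Simulate the instantaneous-snapshot process the STE model assumes.

    At every tick, each active station independently contains an animal
    with probability ``1 − exp(−density · a)``.  Only ticks with a presence
    are materialized, mirroring the lazy censored counting of the occasion
    builder.
    """
    if true_density_per_m2 < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    origin = min(w[0] for d in deps for w in d.active_windows)
    events: list[DetectionEvent] = []
    for d in sorted(deps, key=lambda d: d.station_id):
        a = d.area_m2(scenario)
        p = 1.0 - np.exp(-true_density_per_m2 * a)
        ticks = _station_ticks(d, origin, freq_s)
        if not len(ticks) or p == 0:
            continue
        n_hits = rng.binomial(len(ticks), p)
        if n_hits == 0:
            continue
        hit_ticks = rng.choice(ticks, size=n_hits, replace=False)
        for t in sorted(hit_ticks.tolist()):
            events.append(
                DetectionEvent(d.station_id, species, origin + timedelta(seconds=t))
            )
    return events


def sim_tte_stream(
    true_density_per_m2: float,
    deps: list[Deployment],
    movement: MovementRate,
    seed: int,
    *,
    species: str = "sim",
    scenario: ViewshedScenario = LARGEST,
    occasion_spacing_hr: float = 2.0,
    occasion_length_hr: float = 1.0,
) -> list[DetectionEvent]:
    """Simulate first-detection periods under the TTE model's assumptions.

    For every occasion the period-to-first-detection is geometric with
    per-period hazard ``1 − exp(−density · a)``; an event inside the horizon
    J places one detection at that period's start.
    """
    if true_density_per_m2 < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    origin = min(w[0] for d in deps for w in d.active_windows)
    events: list[DetectionEvent] = []
    for d in sorted(deps, key=lambda d: d.station_id):
        a = d.area_m2(scenario)
        period_hr = d.mean_depth_m() / movement.rate_m_per_hr
        period_hr = min(period_hr, occasion_length_hr)
        J = max(1, int(np.floor(occasion_length_hr / period_hr)))
        p = 1.0 - np.exp(-true_density_per_m2 * a)
        for ws, we in d.active_windows:
            span_hr = (we - ws).total_seconds() / 3600.0
            n_occ = (
                int(np.floor((span_hr - occasion_length_hr) / occasion_spacing_hr)) + 1
                if span_hr >= occasion_length_hr else 0
            )
            if n_occ == 0 or p == 0:
                continue
            G = rng.geometric(p, size=n_occ)
            for i in np.nonzero(G <= J)[0]:
                # mid-period placement keeps the 1-s timestamp inside period G
                t = ws + timedelta(hours=i * occasion_spacing_hr
                                   + (int(G[i]) - 0.5) * period_hr)
                events.append(DetectionEvent(d.station_id, species, t.replace(microsecond=0)))
    return events


def sim_secr(
    true_D_per_100km2: float,
    lam0: float,
    sigma_m: float,
    trap_xy: np.ndarray,
    K: int,
    region: tuple[float, float, float, float],
    seed: int,
) -> tuple[SECRData, SimTruth]:
    """Simulate SECR count data: uniform activity centers, half-normal rates.

    ``region`` is (xmin, xmax, ymin, ymax) in meters; individuals never
    detected are dropped, as in real data.
    """
    if true_D_per_100km2 < 0 or lam0 <= 0 or sigma_m <= 0:
        raise ValueError("parameters must be positive (density may be zero)")
    rng = np.random.default_rng(seed)
    trap_xy = np.asarray(trap_xy, dtype=float)
    xmin, xmax, ymin, ymax = region
    area_m2 = (xmax - xmin) * (ymax - ymin)
    D = true_D_per_100km2 / 1e8
    n_animals = rng.poisson(D * area_m2)
    centers = np.column_stack([
        rng.uniform(xmin, xmax, n_animals), rng.uniform(ymin, ymax, n_animals)
    ])
    usage = np.ones((len(trap_xy), K), dtype=int)
    if n_animals:
        d = np.sqrt(((centers[:, None, :] - trap_xy[None, :, :]) ** 2).sum(axis=2))
        mu = halfnormal_rate(d, lam0, sigma_m)
        y = rng.poisson(mu[:, :, None] * usage[None, :, :])
    else:
        y = np.zeros((0, len(trap_xy), K), dtype=int)
    detected = y.sum(axis=(1, 2)) > 0
    y = y[detected]
    data = SECRData(
        trap_ids=[f"T{k + 1:02d}" for k in range(len(trap_xy))],
        trap_xy=trap_xy,
        individual_ids=[f"A{i + 1:03d}" for i in range(y.shape[0])],
        y=y,
        usage=usage,
    )
    truth = SimTruth(
        seed=seed, density_per_100km2=true_D_per_100km2, lam0=lam0, sigma_m=sigma_m,
        extra={"n_simulated": int(n_animals), "n_detected": int(y.shape[0]),
               "region": region, "centers_detected": centers[detected] if n_animals else centers},
    )
    return data, truth


# ---------------------------------------------------------------------------
# study-mimicking dataset
# ---------------------------------------------------------------------------


def make_study_like_dataset(
    seed: int,
    *,
    solitary_density_per_100km2: float = 4.0,
    n_packs: int = 3,
) -> tuple[list[Deployment], list[DetectionEvent], SimTruth]:
    """A dataset mimicking the target field design.

    27 paired-camera stations on a jittered 2-km lattice, three survey
    blocks of 16, 17 and 18 days (April–May), trapezoid viewsheds sized for
    1.5–2 m camera spacing on a forest trail.  Two species are generated:

    * ``"dhole"`` — group-living: packs of 6–12 with home-range centers;
      pack visits to a station are a Poisson process whose rate decays with
      distance from the pack center, and each visit yields a short burst of
      photos with the pack id and group count, producing the within-pack
      correlation (overdispersion) the beta-binomial layer targets;
    * ``"leopard"`` — solitary and individually identified: per-individual
      detections follow a half-normal encounter rate around an activity
      center, suitable for SECR.
    """
    rng = np.random.default_rng(seed)
    t0 = datetime(2019, 4, 1)

    # 27 stations: 9 per block, jittered 2-km lattice over ~ 18 × 12 km
    stations: list[Deployment] = []
    block_days = [16, 17, 18]
    block_starts = [t0, t0 + timedelta(days=18), t0 + timedelta(days=36)]
    idx = 0
    for bi in range(3):
        for r in range(3):
            for c in range(3):
                x = (bi * 3 + c) * 2000.0 + rng.uniform(-400, 400)
                y = r * 2000.0 + rng.uniform(-400, 400) + (bi % 2) * 1000.0
                cams = {}
                for side in ("A", "B"):
                    near = rng.uniform(1.5, 2.0)       # trail width at the lens
                    far = near + rng.uniform(1.0, 2.5)
                    depth = rng.uniform(5.0, 8.0)
                    cams[side] = CameraViewshed(near, far, depth)
                ws = block_starts[bi]
                we = ws + timedelta(days=block_days[bi])
                idx += 1
                stations.append(
                    Deployment(
                        station_id=f"ST{idx:02d}", x=x, y=y,
                        active_windows=[(ws, we)], cameras=cams,
                    )
                )

    xy = np.array([[d.x, d.y] for d in stations])
    extent = xy.max(axis=0) - xy.min(axis=0)

    events: list[DetectionEvent] = []

    # grouped species: pack-level presence process
    pack_sizes = rng.integers(6, 13, size=n_packs)
    pack_centers = np.column_stack([
        rng.uniform(xy[:, 0].min(), xy[:, 0].max(), n_packs),
        rng.uniform(xy[:, 1].min(), xy[:, 1].max(), n_packs),
    ])
    home_sigma = 4000.0          # m; pack use concentrated within a few km
    base_visits_per_day = 0.12   # at a station at the pack's center: sparse
                                 # encounters, as typical for wide-ranging packs
    for p in range(n_packs):
        for d in stations:
            dist = float(np.hypot(d.x - pack_centers[p, 0], d.y - pack_centers[p, 1]))
            rate = base_visits_per_day * np.exp(-dist**2 / (2 * home_sigma**2))
            for ws, we in d.active_windows:
                days = (we - ws).total_seconds() / 86400.0
                n_visits = rng.poisson(rate * days)
                for _ in range(n_visits):
                    visit_t = ws + timedelta(seconds=float(rng.uniform(0, days * 86400)))
                    n_photos = 1 + rng.poisson(1.2)
                    seen = int(rng.integers(max(1, pack_sizes[p] - 3), pack_sizes[p] + 1))
                    for ph in range(n_photos):
                        ts = visit_t + timedelta(seconds=float(rng.uniform(0, 180)))
                        if ts >= we:
                            continue
                        events.append(
                            DetectionEvent(
                                d.station_id, "dhole", ts.replace(microsecond=0),
                                group_count=seen, individual_id=f"pack{p + 1}",
                            )
                        )

    # solitary species: half-normal encounters around activity centers
    study_area_km2 = (extent[0] / 1000 + 4) * (extent[1] / 1000 + 4)
    n_solitary = max(1, int(round(solitary_density_per_100km2 * study_area_km2 / 100)))
    sol_sigma = 2500.0
    sol_lam0 = 0.15              # encounters per day at the center: sparse but
                                 # enough recaptures for spatial estimation
    centers = np.column_stack([
        rng.uniform(xy[:, 0].min() - 2000, xy[:, 0].max() + 2000, n_solitary),
        rng.uniform(xy[:, 1].min() - 2000, xy[:, 1].max() + 2000, n_solitary),
    ])
    for i in range(n_solitary):
        for d in stations:
            dist = float(np.hypot(d.x - centers[i, 0], d.y - centers[i, 1]))
            rate = halfnormal_rate(dist, sol_lam0, sol_sigma)
            for ws, we in d.active_windows:
                days = (we - ws).total_seconds() / 86400.0
                n_det = rng.poisson(rate * days)
                for _ in range(n_det):
                    ts = ws + timedelta(seconds=float(rng.uniform(0, days * 86400)))
                    events.append(
                        DetectionEvent(
                            d.station_id, "leopard", ts.replace(microsecond=0),
                            group_count=1, individual_id=f"L{i + 1:02d}",
                        )
                    )

    events.sort(key=lambda e: (e.timestamp, e.station_id))
    truth = SimTruth(
        seed=seed,
        density_per_100km2=float(pack_sizes.sum() / study_area_km2 * 100),
        extra={
            "pack_sizes": pack_sizes.tolist(),
            "grouped_total": int(pack_sizes.sum()),
            "n_solitary": n_solitary,
            "study_area_km2": float(study_area_km2),
            "solitary_density_per_100km2": solitary_density_per_100km2,
        },
    )
    return stations, events, truth
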