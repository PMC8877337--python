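"""Shared fixtures: small deployments and study-scale survey layouts."""

from datetime import datetime, timedelta

import pytest

from camdensity import CameraViewshed, Deployment, StudyConfig

T0 = datetime(2019, 4, 1)


def grid_deployments(n=27, window_s=100_000, near=1.8, far=3.0, depth=6.5,
                     spacing_m=2000.0, t0=T0):
    """n identical paired-camera stations on a line, one active window each."""
    cams = {s: CameraViewshed(near, far, depth) for s in "AB"}
    return [
        Deployment(
            station_id=f"S{i:02d}", x=i * spacing_m, y=0.0,
            active_windows=[(t0, t0 + timedelta(seconds=window_s))],
            cameras=dict(cams),
        )
        for i in range(n)
    ]


@pytest.fixture
def three_station_deps():
    """Three stations with distinct camera areas 10, 12 and 8 m²."""
    mk = lambda a: {"A": CameraViewshed(2.0, 2.0, a / 2.0)}  # rectangle of area a
    return [
        Deployment("S1", 0.0, 0.0, [(T0, T0 + timedelta(hours=1))], mk(10)),
        Deployment("S2", 1000.0, 0.0, [(T0, T0 + timedelta(hours=1))], mk(12)),
        Deployment("S3", 2000.0, 0.0, [(T0, T0 + timedelta(hours=1))], mk(8)),
    ]


@pytest.fixture
def study_config():
    return StudyConfig(study_area_km2=351.0, seed=0)
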