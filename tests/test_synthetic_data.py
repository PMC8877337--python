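"""Generators: determinism, moment checks, and study-design emulation."""

import numpy as np
import pytest

from camdensity import MovementRate, StudyConfig, build_ste_occasions, fit_ste
from camdensity.synthetic_data import (
    make_study_like_dataset,
    sim_sba_counts,
    sim_secr,
    sim_snapshot_stream,
    sim_tte_stream,
)

from conftest import grid_deployments


# ---------------------------------------------------------------------------
# SBA counts
# ---------------------------------------------------------------------------


def test_sba_counts_zero_rate_all_zero():
    cm, truth = sim_sba_counts(M=5, J=4, lam=0.0, alpha=2.0, beta=3.0, seed=0)
    assert not cm.C.any()
    assert truth.site_abundance.sum() == 0


def test_sba_counts_moment_check():
    """E[C] = λ · α/(α+β), checked over 10⁵ cells within 3 Monte-Carlo SE."""
    lam, a, b = 5.0, 2.0, 3.0
    cm, _ = sim_sba_counts(M=500, J=200, lam=lam, alpha=a, beta=b, seed=1)
    mean_c = cm.C.mean()
    expect = lam * a / (a + b)
    # var(C) = E[N p(1-p)] + var(N p); bound it loosely by simulation scatter
    se = cm.C.std() / np.sqrt(cm.C.size)
    assert abs(mean_c - expect) < 3 * se


def test_sba_counts_deterministic():
    a = sim_sba_counts(M=10, J=5, lam=3.0, alpha=1.0, beta=1.0, seed=7)[0]
    b = sim_sba_counts(M=10, J=5, lam=3.0, alpha=1.0, beta=1.0, seed=7)[0]
    assert np.array_equal(a.C, b.C)


# ---------------------------------------------------------------------------
# snapshot stream
# ---------------------------------------------------------------------------


def test_snapshot_zero_density_no_events():
    deps = grid_deployments(n=3, window_s=1000)
    assert sim_snapshot_stream(0.0, deps, seed=0) == []


def test_snapshot_event_count_matches_binomial_expectation():
    """One 10 m² station, density 10⁻³, 10⁵ ticks → n ≈ 10⁵(1−e^{−0.01})."""
    deps = grid_deployments(n=1, window_s=100_000, near=2.0, far=2.0, depth=5.0)
    events = sim_snapshot_stream(1e-3, deps, seed=3)
    p = 1 - np.exp(-0.01)
    expect = 100_000 * p
    se = np.sqrt(100_000 * p * (1 - p))
    assert abs(len(events) - expect) < 3 * se


def test_snapshot_fit_recovers_density(study_config):
    """End-to-end: stream → occasions → STE fit covers the truth."""
    deps = grid_deployments(n=27, window_s=100_000)
    true_d = 1e-6
    events = sim_snapshot_stream(true_d, deps, seed=11)
    occ = build_ste_occasions(deps, events, seed=11)
    est = fit_ste(occ, study_config)
    lo, hi = est.density_CI95
    assert lo <= true_d * 1e8 <= hi


# ---------------------------------------------------------------------------
# TTE stream
# ---------------------------------------------------------------------------


def test_tte_zero_density_all_censored():
    deps = grid_deployments(n=3, window_s=86_400)
    assert sim_tte_stream(0.0, deps, MovementRate("sim", 266.0), seed=0) == []


def test_tte_mean_first_period_matches_geometric():
    """Mean T ≈ 1/hazard for small per-period hazard."""
    from camdensity import build_tte_occasions

    deps = grid_deployments(n=27, window_s=16 * 86_400)
    mv = MovementRate("sim", 266.0)
    true_d = 2e-4          # high density so most occasions are uncensored
    events = sim_tte_stream(true_d, deps, mv, seed=5)
    occs = build_tte_occasions(deps, events, 266.0)
    a = deps[0].area_m2()
    hazard = 1 - np.exp(-true_d * a)
    T = np.array([o.T for o in occs if not o.censored])
    J = occs[0].J
    # conditional mean of a geometric truncated at J
    k = np.arange(1, J + 1)
    pmf = (1 - hazard) ** (k - 1) * hazard
    expect = (k * pmf).sum() / pmf.sum()
    assert T.mean() == pytest.approx(expect, rel=0.05)


def test_tte_fit_recovers_density(study_config):
    from camdensity import build_tte_occasions, fit_tte
    from camdensity.io_data_model import station_areas

    deps = grid_deployments(n=27, window_s=16 * 86_400)
    mv = MovementRate("sim", 266.0)
    true_d = 5e-6
    events = sim_tte_stream(true_d, deps, mv, seed=11)
    occs = build_tte_occasions(deps, events, 266.0)
    est = fit_tte(occs, station_areas(deps), study_config, movement=mv)
    assert abs(est.lambda_hat - true_d) < 2 * est.lambda_hat / np.sqrt(est.n_events)


# ---------------------------------------------------------------------------
# SECR
# ---------------------------------------------------------------------------


def test_secr_zero_density_zero_individuals():
    traps = np.array([[0.0, 0.0], [1000.0, 0.0]])
    data, _ = sim_secr(0.0, 0.5, 1000.0, traps, K=5,
                       region=(-2000, 3000, -2000, 2000), seed=0)
    assert data.n_individuals == 0


def test_secr_expected_detections_matches_integral():
    """E[n detected] = D ∫ p·(s) ds, by numeric integration over the region."""
    traps = np.array([[0.0, 0.0]])
    K, lam0, sigma = 5, 0.8, 500.0
    region = (-3000.0, 3000.0, -3000.0, 3000.0)
    D100 = 300.0                      # dense, to keep Monte-Carlo error small
    D = D100 / 1e8
    xs = np.linspace(region[0], region[1], 241)
    ys = np.linspace(region[2], region[3], 241)
    gx, gy = np.meshgrid(xs, ys)
    d = np.hypot(gx, gy)
    pdot = 1 - np.exp(-K * lam0 * np.exp(-d**2 / (2 * sigma**2)))
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    expect = D * pdot.sum() * cell
    counts = [
        sim_secr(D100, lam0, sigma, traps, K, region, seed=100 + r)[0].n_individuals
        for r in range(40)
    ]
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - expect) < 3 * se


# ---------------------------------------------------------------------------
# study-like dataset
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def study_like():
    return make_study_like_dataset(seed=13)


def test_study_design_shape(study_like):
    deps, dets, truth = study_like
    assert len(deps) == 27
    assert all(len(d.cameras) == 2 for d in deps)
    blocks = {tuple(d.active_windows) for d in deps}
    assert len(blocks) == 3
    lengths = sorted((w[0][1] - w[0][0]).days for w in blocks)
    assert lengths == [16, 17, 18]


def test_study_pack_sizes_in_range(study_like):
    _, _, truth = study_like
    assert all(6 <= s <= 12 for s in truth.extra["pack_sizes"])
    assert len(truth.extra["pack_sizes"]) == 3


def test_study_two_species_present(study_like):
    _, dets, truth = study_like
    species = {e.species for e in dets}
    assert species == {"dhole", "leopard"}
    leo_ids = {e.individual_id for e in dets if e.species == "leopard"}
    assert len(leo_ids) <= truth.extra["n_solitary"]
    assert all(i is not None for i in leo_ids)


def test_study_seed_changes_detections_not_design():
    d1, e1, _ = make_study_like_dataset(seed=1)
    d2, e2, _ = make_study_like_dataset(seed=2)
    assert [d.station_id for d in d1] == [d.station_id for d in d2]
    assert [d.active_windows for d in d1] == [d.active_windows for d in d2]
    assert e1 != e2


def test_study_detections_fall_in_windows(study_like):
    deps, dets, _ = study_like
    by_id = {d.station_id: d for d in deps}
    assert all(by_id[e.station_id].is_active(e.timestamp) for e in dets)
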