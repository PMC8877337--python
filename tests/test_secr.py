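"""Likelihood SECR: detection function, dual-implementation oracle, fitting."""

import math

import numpy as np
import pytest

from camdensity.io_data_model import SECRData
from camdensity.secr import (
    HabitatMask,
    fit_secr,
    halfnormal_rate,
    make_mask,
    secr_loglik,
)
from camdensity.synthetic_data import sim_secr


def brute_force_loglik(theta, data, mask):
    """Independent Poisson-count SECR log-likelihood, all loops, no vectorization.

    ln L = Σ_i ln[ D Σ_s Pr(hist_i|s) Δ ] − D Σ_s p·(s) Δ with
    Pr(hist_i|s) = Π_{k,t} Poisson(y_ikt; u_kt λ0 e^{−d²/2σ²}).
    """
    D, lam0, sigma = (math.exp(v) for v in theta)
    delta = mask.spacing**2
    n, ntr, K = data.y.shape
    total = 0.0
    sum_pdot = 0.0
    for s in mask.points:
        haz = 0.0
        for k in range(ntr):
            d = math.dist(s, data.trap_xy[k])
            lam = lam0 * math.exp(-d * d / (2 * sigma * sigma))
            for t in range(K):
                haz += data.usage[k, t] * lam
        sum_pdot += 1.0 - math.exp(-haz)
    for i in range(n):
        a_i = 0.0
        for s in mask.points:
            logpr = 0.0
            for k in range(ntr):
                d = math.dist(s, data.trap_xy[k])
                lam = lam0 * math.exp(-d * d / (2 * sigma * sigma))
                for t in range(K):
                    if data.usage[k, t]:
                        y = data.y[i, k, t]
                        logpr += y * math.log(lam) - lam - math.lgamma(y + 1)
                    # usage 0 forces y = 0: contributes log 1
            a_i += math.exp(logpr) * delta
        total += math.log(D * a_i)
    return total - D * sum_pdot * delta


def tiny_dataset():
    traps = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
    y = np.zeros((2, 3, 2), dtype=int)
    y[0, 0, 0] = 2
    y[0, 1, 1] = 1
    y[1, 2, 0] = 1
    usage = np.array([[1, 1], [1, 1], [1, 0]])
    return SECRData(["A", "B", "C"], traps, ["i1", "i2"], y, usage)


# ---------------------------------------------------------------------------
# detection function
# ---------------------------------------------------------------------------


def test_halfnormal_values():
    assert halfnormal_rate(0.0, 0.7, 50.0) == pytest.approx(0.7)
    half_d = 50.0 * math.sqrt(2 * math.log(2))
    assert halfnormal_rate(half_d, 0.7, 50.0) == pytest.approx(0.35)
    assert halfnormal_rate(1e6, 0.7, 50.0) == pytest.approx(0.0, abs=1e-30)


def test_halfnormal_domain():
    with pytest.raises(ValueError):
        halfnormal_rate(10.0, 0.5, 0.0)
    with pytest.raises(ValueError):
        halfnormal_rate(-1.0, 0.5, 10.0)


# ---------------------------------------------------------------------------
# likelihood oracle
# ---------------------------------------------------------------------------


def test_single_point_mask_hand_computation():
    """1 trap, 1 occasion, 1 individual, mask = the trap location."""
    traps = np.array([[0.0, 0.0]])
    y = np.ones((1, 1, 1), dtype=int)
    data = SECRData(["A"], traps, ["i1"], y, np.ones((1, 1), dtype=int))
    mask = HabitatMask(np.array([[0.0, 0.0]]), spacing=10.0, buffer=10.0)
    theta = np.log([1e-3, 0.5, 20.0])
    # by hand: λ(0)=0.5; Pr(y=1|s)=0.5 e^{-0.5}; a = Pr·Δ; p· = 1−e^{-0.5}
    D, delta = 1e-3, 100.0
    expected = math.log(D * 0.5 * math.exp(-0.5) * delta) - D * (1 - math.exp(-0.5)) * delta
    assert secr_loglik(theta, data, mask) == pytest.approx(expected, abs=1e-10)


@pytest.mark.parametrize("theta", [
    np.log([1e-4, 0.3, 60.0]),
    np.log([5e-4, 1.2, 120.0]),
])
def test_loglik_matches_brute_force(theta):
    """Vectorized likelihood equals the loop-based oracle on a 4-point mask."""
    data = tiny_dataset()
    mask = HabitatMask(
        np.array([[20.0, 30.0], [80.0, 10.0], [40.0, 90.0], [-30.0, -30.0]]),
        spacing=50.0, buffer=50.0,
    )
    assert secr_loglik(theta, data, mask) == pytest.approx(
        brute_force_loglik(theta, data, mask), abs=1e-8
    )


def test_loglik_invariant_to_individual_relabeling():
    data = tiny_dataset()
    swapped = SECRData(data.trap_ids, data.trap_xy, ["i2", "i1"],
                       data.y[::-1].copy(), data.usage)
    mask = make_mask(data.trap_xy, buffer=150.0, spacing=60.0)
    theta = np.log([1e-4, 0.4, 70.0])
    assert secr_loglik(theta, data, mask) == pytest.approx(
        secr_loglik(theta, swapped, mask), abs=1e-12
    )


def test_loglik_translation_invariance():
    data = tiny_dataset()
    mask = make_mask(data.trap_xy, buffer=150.0, spacing=60.0)
    shift = np.array([12_345.0, -6_789.0])
    data2 = SECRData(data.trap_ids, data.trap_xy + shift, data.individual_ids,
                     data.y, data.usage)
    mask2 = HabitatMask(mask.points + shift, mask.spacing, mask.buffer)
    theta = np.log([1e-4, 0.4, 70.0])
    assert secr_loglik(theta, data, mask) == pytest.approx(
        secr_loglik(theta, data2, mask2), rel=1e-12
    )


def test_proximity_detector_binary_likelihood():
    """Proximity reduces counts to Bernoulli; checked against a direct loop."""
    data = tiny_dataset()
    mask = HabitatMask(np.array([[20.0, 30.0], [80.0, 10.0]]), 50.0, 50.0)
    theta = np.log([1e-4, 0.6, 80.0])
    D, lam0, sigma = np.exp(theta)
    delta = mask.spacing**2
    total, sum_pdot = 0.0, 0.0
    for s in mask.points:
        surv = 1.0
        for k in range(3):
            d = math.dist(s, data.trap_xy[k])
            p = 1 - math.exp(-lam0 * math.exp(-d * d / (2 * sigma**2)))
            surv *= (1 - p) ** data.usage[k].sum()
        sum_pdot += 1 - surv
    for i in range(2):
        a_i = 0.0
        for s in mask.points:
            pr = 1.0
            for k in range(3):
                d = math.dist(s, data.trap_xy[k])
                p = 1 - math.exp(-lam0 * math.exp(-d * d / (2 * sigma**2)))
                for t in range(2):
                    if data.usage[k, t]:
                        pr *= p if data.y[i, k, t] > 0 else 1 - p
            a_i += pr * delta
        total += math.log(D * a_i)
    expected = total - D * sum_pdot * delta
    assert secr_loglik(theta, data, mask, detector="proximity") == pytest.approx(
        expected, abs=1e-8
    )


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        HabitatMask(np.zeros((0, 2)), 10.0, 10.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def simulated_fit():
    gx, gy = np.meshgrid(np.arange(6) * 2000.0, np.arange(6) * 2000.0)
    traps = np.column_stack([gx.ravel(), gy.ravel()])
    region = (-8000.0, 18_000.0, -8000.0, 18_000.0)
    data, truth = sim_secr(5.0, 0.5, 2000.0, traps, K=10, region=region, seed=42)
    fit = fit_secr(data)
    return data, truth, fit


def test_fit_recovers_parameters_single_replicate(simulated_fit):
    """One well-sampled replicate lands near truth (loose single-run check)."""
    _, truth, fit = simulated_fit
    assert fit.converged
    assert fit.D_per_100km2 == pytest.approx(truth.density_per_100km2, rel=0.5)
    assert fit.sigma_m == pytest.approx(truth.sigma_m, rel=0.3)


def test_buffer_sufficiency(simulated_fit):
    """Doubling the mask buffer beyond 4σ moves D̂ by < 1%."""
    data, _, fit = simulated_fit
    wide = make_mask(data.trap_xy, buffer=8 * fit.sigma_m,
                     spacing=fit.mask.spacing)
    fit_wide = fit_secr(data, wide)
    assert fit_wide.D_per_100km2 == pytest.approx(fit.D_per_100km2, rel=0.01)


def test_single_detection_individuals_flagged():
    traps = np.array([[0.0, 0.0], [3000.0, 0.0]])
    y = np.zeros((2, 2, 3), dtype=int)
    y[0, 0, 0] = 1
    y[1, 1, 2] = 1
    data = SECRData(["A", "B"], traps, ["i1", "i2"], y, np.ones((2, 3), dtype=int))
    with pytest.warns(UserWarning, match="weakly identified"):
        fit = fit_secr(data)
    assert fit.warnings
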