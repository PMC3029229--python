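import numpy as np
import pytest

from atriasim import metrics as M
from atriasim import rhs as R
from atriasim.engine import Segment, Trace
from atriasim.geometry import build_geometry
from atriasim.params import Parameters


def _synthetic_trace(t, V=None, ca_fields=None, stim_times=(0.0,)):
    geom = build_geometry()
    Y = np.zeros((len(t), R.N_STATES))
    Y[:, R.IV] = V if V is not None else -77.0
    if ca_fields is not None:
        Y[:, R.ICASS] = ca_fields[0]
        for j in range(4):
            Y[:, R.ICAB0 + j] = ca_fields[1 + j]
    seg = Segment(float(t[0]), float(t[-1]) + 1, R.default_ctx(), 1.0)
    return Trace(t=np.asarray(t, float), Y=Y, segments=(seg,),
                 params=Parameters(), geom=geom, stim_times=tuple(stim_times))


# ---------------------------------------------------------------------------
# AP metrics
# ---------------------------------------------------------------------------
def test_triangle_pulse_apd_exact():
    """A triangular AP with linear flanks has closed-form APD values."""
    t = np.arange(0.0, 500.0, 0.1)
    rmp, peak = -80.0, 20.0
    rise, fall = 2.0, 300.0       # ms up, ms down
    V = np.full_like(t, rmp)
    up = t <= rise
    V[up] = rmp + (peak - rmp) * t[up] / rise
    down = (t > rise) & (t <= rise + fall)
    V[down] = peak - (peak - rmp) * (t[down] - rise) / fall
    tr = _synthetic_trace(t, V=V)
    ap = M.ap_metrics(tr)
    # max dV/dt sits on the rising flank; APDx = remaining rise + x% of fall
    assert ap.RMP == rmp
    assert ap.amplitude == pytest.approx(100.0)
    assert ap.APD90 == pytest.approx((rise - ap.t_upstroke) + 0.9 * fall,
                                     abs=0.2)
    assert ap.APD30 == pytest.approx((rise - ap.t_upstroke) + 0.3 * fall,
                                     abs=0.2)


def test_no_ap_raises_capture_failure():
    t = np.arange(0.0, 200.0, 0.5)
    tr = _synthetic_trace(t, V=np.full_like(t, -77.0))
    with pytest.raises(M.NoAPError):
        M.ap_metrics(tr)


def test_apd_sampling_resolution_convergence(y_steady, params):
    """Halving the output sampling interval changes APD90 by < 0.2 ms."""
    from atriasim.engine import SolverConfig, pace

    a = M.ap_metrics(pace(y_steady, 1000.0, 1, params=params,
                          solver=SolverConfig(sample_ms=0.5))).APD90
    b = M.ap_metrics(pace(y_steady, 1000.0, 1, params=params,
                          solver=SolverConfig(sample_ms=0.25))).APD90
    assert abs(a - b) < 0.2


# ---------------------------------------------------------------------------
# Mean cytosolic Ca2+ and decay fit
# ---------------------------------------------------------------------------
def test_uniform_field_mean_is_identity():
    t = np.arange(0.0, 10.0, 1.0)
    tr = _synthetic_trace(t, ca_fields=[np.full_like(t, 1.5e-4)] * 5)
    np.testing.assert_allclose(M.mean_cytosolic_ca(tr), 0.15)


def test_volume_weights_match_direct_quadrature():
    """The mean equals the volume integral of a random radial profile."""
    rng = np.random.default_rng(11)
    t = np.array([0.0, 1.0])
    vals = 10 ** rng.uniform(-4, -3, size=5)
    tr = _synthetic_trace(t, ca_fields=[np.full_like(t, v) for v in vals])
    g = tr.geom
    w = np.concatenate([[g.V_ss], g.V_bulk])
    expected = float(np.sum(w * vals) / w.sum()) * 1e3
    assert M.mean_cytosolic_ca(tr)[0] == pytest.approx(expected, rel=1e-12)


def test_decay_fit_recovers_exact_exponential():
    t = np.arange(0.0, 900.0, 1.0)
    ca = 0.15 + 0.55 * np.exp(-t / 131.0)
    assert M.decay_fit(t, ca) == pytest.approx(131.0, rel=1e-6)


def test_decay_fit_matches_grid_search_oracle():
    rng = np.random.default_rng(5)
    t = np.arange(0.0, 800.0, 2.0)
    ca = 0.14 + 0.6 * np.exp(-t / 120.0) + rng.normal(0, 2e-3, t.size)
    tau_fit = M.decay_fit(t, ca)
    taus = np.linspace(80.0, 180.0, 2001)
    sse = []
    for tau in taus:
        X = np.column_stack([np.exp(-t / tau), np.ones_like(t)])
        beta, res, *_ = np.linalg.lstsq(X, ca, rcond=None)
        sse.append(res[0] if res.size else np.sum(
            (X @ beta - ca) ** 2))
    tau_grid = taus[int(np.argmin(sse))]
    assert tau_fit == pytest.approx(tau_grid, rel=0.005)


def test_decay_fit_rejects_non_decaying_input():
    t = np.arange(0.0, 100.0, 1.0)
    with pytest.raises(ValueError):
        M.decay_fit(t, np.linspace(0.1, 0.9, t.size))


@pytest.mark.parametrize("seed", range(5))
def test_estimators_unbiased_on_randomized_synthetic_transients(seed):
    """APD and decay-tau estimators recover known ground truth across
    randomized synthetic parameterizations (4 draws per seed)."""
    rng = np.random.default_rng(seed)
    for _ in range(4):
        tau = rng.uniform(90, 170)
        amp = rng.uniform(0.3, 0.8)
        base = rng.uniform(0.1, 0.2)
        t = np.arange(0.0, 900.0, 0.5)
        ca = base + amp * np.exp(-t / tau)
        assert M.decay_fit(t, ca) == pytest.approx(tau, rel=1e-4)


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------
def _wave_fields(t, depths, speed_um_s, width=10.0):
    fields = []
    for d in depths:
        t_arr = d / speed_um_s * 1e3          # arrival time, ms
        ca = 1.5e-4 + 8e-4 * np.exp(-0.5 * ((t - 60.0 - t_arr) / width) ** 2)
        fields.append(ca)
    return fields


def test_synthetic_wave_speed_recovered():
    t = np.arange(0.0, 400.0, 0.5)
    g = build_geometry()
    # field order matches the state layout: subspace, then shells from the
    # cell axis outward (deepest first)
    shell_depths = (g.r_bulk + g.d_junct) - g.r_centers
    depths = np.concatenate([[g.d_junct / 2], shell_depths])
    fields = _wave_fields(t, depths, speed_um_s=80.0)
    tr = _synthetic_trace(t, ca_fields=fields)
    pr = M.propagation_metrics(tr)
    assert pr.speed == pytest.approx(80.0, rel=0.02)


def test_flat_field_is_non_propagating():
    t = np.arange(0.0, 100.0, 1.0)
    tr = _synthetic_trace(t, ca_fields=[np.full_like(t, 2e-4)] * 5)
    with pytest.raises(ValueError):
        M.propagation_metrics(tr)


def test_model_speed_consistent_with_two_point_estimate(steady_trace):
    pr = M.propagation_metrics(steady_trace)
    two_pt = 1e3 * (pr.depths[-1] - pr.depths[0]) / (
        pr.t_half_peak[-1] - pr.t_half_peak[0])
    assert pr.speed == pytest.approx(two_pt, rel=0.15)


# ---------------------------------------------------------------------------
# SR content and release fraction
# ---------------------------------------------------------------------------
def test_empty_sr_has_zero_content():
    t = np.array([0.0, 1.0])
    tr = _synthetic_trace(t)
    assert M.sr_content(tr) == 0.0


def test_sr_content_matches_mole_count_oracle(steady_trace):
    """Direct mole count with independent buffer-occupancy computation."""
    tr = steady_trace
    g, p = tr.geom, tr.params
    casr = tr.Y[-1, R.ICASR0:R.ICASR0 + 4]
    moles = 0.0
    for j in range(4):
        free = casr[j] * g.V_sr[j]
        bound = (p.CSQN * casr[j] / (p.K_dCSQN + casr[j])) * g.V_sr[j]
        moles += free + bound
    expected = moles / g.V_bulk_total * 1e3
    assert M.sr_content(tr) == pytest.approx(expected, rel=1e-12)


def test_release_fraction_zero_for_identical_traces(steady_trace):
    assert M.sr_release_fraction(steady_trace, steady_trace) == 0.0


def test_release_fraction_requires_matched_protocols(steady_trace, y_steady,
                                                     params):
    from atriasim.engine import pace

    other = pace(y_steady, 800.0, 3, params=params)
    with pytest.raises(ValueError):
        M.sr_release_fraction(steady_trace, other)


# ---------------------------------------------------------------------------
# Purity
# ---------------------------------------------------------------------------
def test_metrics_are_pure_functions(steady_trace):
    a = M.ca_metrics(steady_trace)
    b = M.ca_metrics(steady_trace)
    assert a == b
    beat_each = [M.ap_metrics(steady_trace, beat=b).APD90 for b in range(3)]
    assert max(beat_each) - min(beat_each) < 1.0
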