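import numpy as np
import pytest

import deskmri as dm
from deskmri.engine import (absorption_lineshape, add_noise, apply_crusher,
                            record_signal, step_bm, step_free, step_rf)
from deskmri.sequence import (AcquisitionWindow, Block, BlockGroup,
                              SoftwareCrusher)

GAMMA = dm.GAMMA_1H


# ------------------------------------------------------------- step oracles

def test_free_precession_phase_advance():
    m = step_free(np.array([[1.0, 0.0, 0.0]]), 5e-3, 100.0, np.inf, np.inf, 0.0)
    assert m[0] == pytest.approx([-1.0, 0.0, 0.0], abs=1e-12)


def test_inversion_recovery_closed_form_any_partitioning(rng):
    """Mz(t) = M0 (1 - 2 exp(-t/T1)) after ideal inversion, independent of
    how the interval is cut into steps."""
    t1, t2 = 0.9, 0.05
    for _ in range(5):
        cuts = np.sort(rng.uniform(0, 1.0, 30))
        edges = np.concatenate(([0.0], cuts, [1.0]))
        m = np.array([[0.0, 0.0, -1.0]])
        for dt in np.diff(edges):
            m = step_free(m, dt, 77.0, t1, t2, 1.0)
        assert m[0, 2] == pytest.approx(1 - 2 * np.exp(-1.0 / t1), rel=1e-9)


def test_free_step_composition_is_exact():
    dt = 1e-6
    m1 = np.array([[0.6, -0.3, 0.5]])
    m2 = m1.copy()
    for _ in range(1000):
        m1 = step_free(m1, dt, 130.0, 0.8, 0.06, 1.0)
    m2 = step_free(m2, 1000 * dt, 130.0, 0.8, 0.06, 1.0)
    assert np.allclose(m1, m2, atol=1e-12)


def test_hard_180_and_90_conventions():
    tau, b1_180 = 1e-3, 0.5 / (GAMMA * 1e-3)
    m = step_rf(np.array([[0.0, 0.0, 1.0]]), tau, b1_180, 0.0, 0.0,
                np.inf, np.inf, 1.0)
    assert m[0, 2] == pytest.approx(-1.0, abs=1e-9)
    m = step_rf(np.array([[0.0, 0.0, 1.0]]), tau, b1_180 / 2, 0.0, 0.0,
                np.inf, np.inf, 1.0)
    assert m[0] == pytest.approx([0.0, 1.0, 0.0], abs=1e-9)


def test_slice_profile_emerges_from_sinc_and_gradient():
    """Spins 10 mm off-center of a 10 mm slice see < 10% of the on-center
    transverse response of the three-lobe 15 deg pulse."""
    g = dm.GlobalParams(slice_thickness=0.01)
    p = dm.make_sinc_rf(15.0, 3e-3, raster=5e-6, gamma=g.gamma)
    g_ss = (4 / 3e-3) / (g.gamma * g.slice_thickness)
    z = np.array([0.0, 0.01, -0.01])
    m = np.zeros((3, 3))
    m[:, 2] = 1.0
    for b1 in p.amplitude_samples:
        m = step_rf(m, p.raster, np.abs(b1), np.angle(b1),
                    g.gamma * g_ss * z, np.inf, np.inf, 1.0)
    mxy = np.hypot(m[:, 0], m[:, 1])
    assert mxy[1] < 0.1 * mxy[0] and mxy[2] < 0.1 * mxy[0]


def test_bm_reduces_to_single_pool_when_bound_fraction_zero():
    m = np.array([[0.1, 0.2, 0.7]])
    b1 = 2e-6
    ref = step_rf(m, 1e-4, b1, 0.3, 40.0, 1.0, 0.08, 1.0)
    out, zs = step_bm(m, 0.0, 1e-4, b1, 0.3, 40.0, 1.0, 0.08, 1.0,
                      bound_fraction=0.0, k_exchange=0.0, t1_semisolid=1.0, g0=0.0)
    assert np.allclose(out, ref, atol=1e-12)


def test_bm_pools_relax_independently_without_exchange_or_rf():
    f = 0.1
    m = np.array([[0.0, 0.0, 0.2]])
    zs = 0.05
    t1f, t1s = 1.2, 0.5
    out, zs2 = step_bm(m, zs, 0.3, 0.0, 0.0, 0.0, t1f, 0.05, 1.0,
                       bound_fraction=f, k_exchange=0.0, t1_semisolid=t1s, g0=0.0)
    assert out[0, 2] == pytest.approx(1 + (0.2 - 1) * np.exp(-0.3 / t1f), rel=1e-9)
    m0s = 1.0 * f
    assert zs2 == pytest.approx(m0s + (zs - m0s) * np.exp(-0.3 / t1s), rel=1e-9)


def test_bm_rf_saturates_semisolid_pool():
    f, g0 = 0.1, 1.4e-5
    m = np.array([[0.0, 0.0, 1.0]])
    zs = 0.1
    out, zs2 = step_bm(m, zs, 5e-3, 10e-6, 0.0, 0.0, 1.0, 0.05, 1.0,
                       bound_fraction=f, k_exchange=30.0, t1_semisolid=1.0, g0=g0)
    assert zs2 < zs          # W > 0 drives the semisolid pool down


def test_crusher_nulls_transverse_and_is_idempotent():
    m = np.array([[0.3, -0.4, 0.6]])
    out = apply_crusher(m)
    assert np.allclose(out, [[0.0, 0.0, 0.6]])
    assert np.allclose(apply_crusher(out), out)
    assert record_signal(out) == 0


def test_record_signal_linearity_and_cancellation():
    m = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    assert record_signal(m) == pytest.approx(2.0)
    m[1, 0] = -1.0
    assert record_signal(m) == pytest.approx(0.0)
    sens = np.full((1, 2), 3.0 - 1.0j)
    m[1, 0] = 1.0
    assert record_signal(m, sens)[0] == pytest.approx(2 * (3 - 1j))


def test_superlorentzian_lineshape_properties():
    g_a = absorption_lineshape(0.0, 12e-6)
    g_b = absorption_lineshape(5000.0, 12e-6)
    assert g_a > 0 and g_b > 0 and g_b < g_a
    lor = absorption_lineshape(0.0, 12e-6, kind="lorentzian")
    assert lor == pytest.approx(12e-6 / np.pi, rel=1e-12)


# ------------------------------------------------------- kernel equivalence

def _random_scenario_table(rng, n_steps=2000, dt=2e-6):
    """Piecewise-constant B1 episodes separated by free precession."""
    z = np.zeros(n_steps)
    t = dm.TimeStepTable(dt, z.copy(), z.copy(), z.copy(), z.copy(), z.copy(),
                         np.full(n_steps, -1, np.int64), z.copy(),
                         np.zeros(n_steps, bool),
                         np.full(n_steps, -1, np.int64), z.copy())
    i, n_rec = 0, 0
    while i < n_steps - 10:
        burst = rng.integers(20, 120)
        if rng.random() < 0.4:
            t.b1_mag[i:i + burst] = rng.uniform(0.2, 1.2) * 5e-6
            t.b1_phase[i:i + burst] = rng.uniform(0, 2 * np.pi)
        t.recorder_index[i] = n_rec
        n_rec += 1
        i += burst
    t.adc_index[n_steps - 1] = 0
    return t


def _reference_trajectory(table, t1, t2, off, sub):
    """Pure-numpy trajectory with each step cut into ``sub`` substeps."""
    n = len(t1)
    m = np.zeros((n, 3))
    m[:, 2] = 1.0
    traj = np.zeros((table.n_recorders, n), dtype=complex)
    for s in range(table.n_steps):
        r = table.recorder_index[s]
        if r >= 0:
            traj[r] = m[:, 0] + 1j * m[:, 1]
        for _ in range(sub):
            if table.b1_mag[s] > 0:
                m = step_rf(m, table.dt / sub, table.b1_mag[s],
                            table.b1_phase[s], off, t1, t2, np.ones(n))
            else:
                m = step_free(m, table.dt / sub, off, t1, t2, np.ones(n))
    return traj


def test_kernel_matches_independent_reference(rng):
    """50 random single-spin scenarios (random T1, T2, off-resonance,
    piecewise-constant B1): the compiled kernel trajectory agrees with the
    independent pure-numpy step functions to <= 1e-9."""
    table = _random_scenario_table(rng)
    n = 50
    t1 = rng.uniform(0.1, 2.0, n)
    t2 = np.minimum(rng.uniform(0.02, 0.3, n), t1)
    off = rng.uniform(-500, 500, n)
    ph = dm.IsochromatSet(positions=np.zeros((n, 3)), t1=t1, t2=t2,
                          pd=np.ones(n), b0_offset_hz=off)
    traj_kernel = dm.simulate(table, ph, dm.SimConfig()).recorded
    traj_ref = _reference_trajectory(table, t1, t2, off, sub=1)
    scale = np.abs(traj_ref).max()
    assert np.abs(traj_kernel - traj_ref).max() / scale < 1e-9


def test_kernel_matches_fine_step_reference(rng):
    """dt/100 convergence: exact (<= 1e-6) where the per-step splitting is
    exact (free precession; relaxation-free RF), and within the documented
    O(dt) bound when RF and relaxation act in the same step."""
    table = _random_scenario_table(rng)
    n = 50
    off = rng.uniform(-500, 500, n)
    # relaxation-free spins: subdividing constant-field steps is exact
    huge = np.full(n, 1e9)
    ph = dm.IsochromatSet(positions=np.zeros((n, 3)), t1=huge, t2=huge,
                          pd=np.ones(n), b0_offset_hz=off)
    traj_kernel = dm.simulate(table, ph, dm.SimConfig()).recorded
    traj_ref = _reference_trajectory(table, huge, huge, off, sub=100)
    assert (np.abs(traj_kernel - traj_ref).max()
            / np.abs(traj_ref).max()) < 1e-6
    # with relaxation during RF the splitting is first order in dt
    t1 = rng.uniform(0.1, 2.0, n)
    t2 = np.minimum(rng.uniform(0.02, 0.3, n), t1)
    ph = dm.IsochromatSet(positions=np.zeros((n, 3)), t1=t1, t2=t2,
                          pd=np.ones(n), b0_offset_hz=off)
    traj_kernel = dm.simulate(table, ph, dm.SimConfig()).recorded
    traj_ref = _reference_trajectory(table, t1, t2, off, sub=100)
    assert (np.abs(traj_kernel - traj_ref).max()
            / np.abs(traj_ref).max()) < 1e-4


# ------------------------------------------------- steady states and noise

def _hard_pulse_train(flip_deg, tr, n_reps, te, alternate, crush, adc_phase,
                      tau=100e-6):
    """Sequence of hard-pulse TRs with one ADC sample at TE (from the RF
    pulse center)."""
    g = dm.GlobalParams(receiver_bw=1e5, base_dt=1e-6)
    seq = dm.Sequence(globals=g)
    bid = 0
    for r in range(n_reps):
        phase = np.pi * (r % 2) if alternate else 0.0
        rf = dm.make_hard_rf(flip_deg, tau, raster=1e-6, gamma=g.gamma,
                             phase_offset=phase)
        blk = Block(id=(bid := bid + 1), duration=tr, rf=rf,
                    adc=AcquisitionWindow(tau / 2 + te, 1, g.dwell,
                                          phase=phase if adc_phase else 0.0))
        if crush:
            blk.add(SoftwareCrusher(tr - 1e-6))
        seq.groups.append(BlockGroup(id=r + 1, blocks=[blk]))
    return seq


def test_spoiled_gre_reaches_ernst_steady_state():
    """Perfectly spoiled GRE signal matches the Ernst formula to <= 0.5%."""
    flip, tr, te = 15.0, 10e-3, 4e-3
    seq = _hard_pulse_train(flip, tr, 400, te, alternate=False, crush=True,
                            adc_phase=False)
    t1, t2 = 0.9, 0.05
    ph = dm.IsochromatSet(positions=np.zeros((1, 3)), t1=[t1], t2=[t2], pd=[1.0])
    ks = dm.simulate(dm.compress(dm.discretize(seq)), ph, dm.SimConfig(),
                     header={"n_images": 1, "n_pe": 400, "n_fe": 1})
    e1 = np.exp(-tr / t1)
    a = np.radians(flip)
    expected = (np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
                * np.exp(-te / t2))
    assert abs(ks.samples[0, -1]) == pytest.approx(expected, rel=5e-3)


def test_bssfp_steady_state_matches_analytic(rng):
    """Alternating-phase bSSFP on resonance: 10 random (T1, T2) match the
    analytic steady state at TE = TR/2 to <= 1%."""
    flip, tr = 35.0, 4e-3
    te = tr / 2
    seq = _hard_pulse_train(flip, tr, 1200, te, alternate=True,
                            crush=False, adc_phase=True, tau=10e-6)
    n = 10
    t1 = rng.uniform(0.3, 2.0, n)
    t2 = np.minimum(rng.uniform(0.03, 0.25, n), t1)
    ph = dm.IsochromatSet(positions=np.zeros((n, 3)), t1=t1, t2=t2, pd=np.ones(n))
    # per-spin signal via per-spin "coils"
    sens = np.eye(n, dtype=complex)
    ph = dm.IsochromatSet(positions=np.zeros((n, 3)), t1=t1, t2=t2,
                          pd=np.ones(n), sens=sens)
    ks = dm.simulate(dm.compress(dm.discretize(seq)), ph, dm.SimConfig(),
                     header={"n_images": 1, "n_pe": 1200, "n_fe": 1})
    a = np.radians(flip)
    e1, e2 = np.exp(-tr / t1), np.exp(-tr / t2)
    expected = (np.sin(a) * (1 - e1)
                / (1 - (e1 - e2) * np.cos(a) - e1 * e2) * np.exp(-te / t2))
    measured = np.abs(ks.samples[:, -1])
    assert np.allclose(measured, expected, rtol=1e-2)


def test_noise_statistics_and_reproducibility(rng):
    x = np.zeros((1, 1_000_000), dtype=complex)
    noisy = add_noise(x, 20.0, seed=7)
    assert np.std(noisy.real) == pytest.approx(20.0, rel=5e-3)
    assert np.std(noisy.imag) == pytest.approx(20.0, rel=5e-3)
    again = add_noise(x, 20.0, seed=7)
    assert np.array_equal(noisy, again)
    assert np.array_equal(add_noise(x, 0.0, seed=7), x)
    with pytest.raises(ValueError):
        add_noise(x, -1.0, seed=0)


def test_results_independent_of_chunk_size(small_gre, small_disk_phantom):
    tl = small_gre["compressed"]
    a = dm.simulate(tl, small_disk_phantom, dm.SimConfig(chunk_size=10**6))
    b = dm.simulate(tl, small_disk_phantom, dm.SimConfig(chunk_size=7))
    scale = np.abs(a.samples).max()
    assert np.abs(a.samples - b.samples).max() / scale < 1e-12


def test_noise_off_equals_sd_zero(small_gre, small_disk_phantom):
    tl = small_gre["compressed"]
    a = dm.simulate(tl, small_disk_phantom, dm.SimConfig(noise_sd=0.0, seed=3))
    b = dm.simulate(tl, small_disk_phantom, dm.SimConfig(noise_sd=0.0, seed=99))
    assert np.array_equal(a.samples, b.samples)


def test_readout_phase_ramp_for_off_center_spin():
    """A single spin at x = 10 mm accrues exactly 2 pi gamma G x dwell of
    phase between consecutive readout samples."""
    g = dm.GlobalParams(matrix_size=16, fov=0.2, receiver_bw=1e5)
    seq = dm.build_gre(g, tr=5e-3)
    ph = dm.IsochromatSet(positions=[[0.01, 0.0, 0.0]], t1=[0.9], t2=[0.05],
                          pd=[1.0])
    ks = dm.simulate(dm.compress(dm.discretize(seq)), ph, dm.SimConfig(),
                     header=seq.header)
    line = ks.images_matrix()[0, 0, 8]        # ky = 0 line
    g_read = g.receiver_bw / (g.gamma * g.fov_fe)
    expected = -2 * np.pi * g.gamma * g_read * 0.01 * g.dwell
    dphi = np.angle(line[1:] / line[:-1])
    assert np.allclose(dphi, np.angle(np.exp(1j * expected)), atol=1e-6)
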