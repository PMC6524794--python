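"""Bloch / Bloch-McConnell simulation engine.

Two implementations of the same physics live here:

* plain-numpy step functions (:func:`step_free`, :func:`step_rf`,
  :func:`step_bm`) — the readable reference path, used directly by tests and
  as the fine-step oracle;
* :func:`simulate` / :func:`simulate_dictionary`, which drive the compiled
  per-step/per-isochromat loop in :mod:`deskmri._kernel` over a discretized
  timeline.

Conventions
-----------
B1 at phase 0 lies along +x of the rotating frame; a positive flip rotates
+z toward +y.  A spin with positive off-resonance ``f`` precesses as
``Mxy(t) = Mxy(0) * exp(-2i*pi*f*t)``, so a readout gradient G produces the
standard Cartesian k-space signal ``sum(pd * exp(-2i*pi*k.r))``.  Relaxation
is applied after the rotation of each step (operator splitting, exact for
free precession).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence as Seq

import numpy as np
from scipy.integrate import quad

from ._kernel import run_timeline
from .sequence import GAMMA_1H
from .timeline import TimeStepTable

__all__ = [
    "SimConfig",
    "SpinState",
    "KSpaceData",
    "SignalDictionary",
    "step_free",
    "step_rf",
    "step_bm",
    "apply_crusher",
    "record_signal",
    "simulate",
    "simulate_reference",
    "simulate_dictionary",
    "make_dictionary_grid",
    "add_noise",
    "absorption_lineshape",
]


@dataclass
class SimConfig:
    """Run configuration for the simulation kernel."""

    gamma: float = GAMMA_1H
    noise_sd: float = 0.0
    seed: int = 0
    mt_enabled: bool = False
    motion_enabled: bool = False
    chunk_size: int = 200_000
    mt_lineshape: str = "super_lorentzian"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


@dataclass
class SpinState:
    """Magnetization state of N isochromats."""

    m: np.ndarray            # (N, 3)
    m0: np.ndarray           # (N,) equilibrium = proton density
    mz_semisolid: Optional[np.ndarray] = None
    m0_semisolid: Optional[np.ndarray] = None

    @classmethod
    def equilibrium(cls, pd: np.ndarray, bound_fraction: Optional[np.ndarray] = None):
        pd = np.asarray(pd, dtype=float)
        m = np.zeros((pd.size, 3))
        m[:, 2] = pd
        if bound_fraction is None:
            return cls(m=m, m0=pd.copy())
        m0s = pd * np.asarray(bound_fraction, dtype=float)
        return cls(m=m, m0=pd.copy(), mz_semisolid=m0s.copy(), m0_semisolid=m0s)


@dataclass
class KSpaceData:
    """Complex ADC samples per coil element, in acquisition order."""

    samples: np.ndarray       # (n_coils, n_adc)
    header: Dict[str, object] = field(default_factory=dict)

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]

    def images_matrix(self) -> np.ndarray:
        """Reshape to (n_coils, n_images, n_pe, n_fe) using the header."""
        n_img = int(self.header.get("n_images", 1))
        n_pe = int(self.header["n_pe"])
        n_fe = int(self.header["n_fe"])
        return self.samples.reshape(self.n_coils, n_img, n_pe, n_fe)


@dataclass
class SignalDictionary:
    """Grid of simulated signal evolutions for dictionary matching.

    One entry per (T1, T2[, B0]) combination; the slice-position spins are
    summed (complex) into the entry, so ``n_entries = len(t1) * len(t2)``
    for the default single B0 value.
    """

    t1_values: np.ndarray
    t2_values: np.ndarray
    b0_values: np.ndarray
    slice_positions: np.ndarray
    signals: np.ndarray       # (n_entries, n_points)
    entry_t1: np.ndarray      # (n_entries,)
    entry_t2: np.ndarray
    header: Dict[str, object] = field(default_factory=dict)

    @property
    def n_entries(self) -> int:
        return self.signals.shape[0]

    @property
    def n_points(self) -> int:
        return self.signals.shape[1]


# ----------------------------------------------------------------- reference

def step_free(m, dt, off_hz, t1, t2, m0):
    """Free precession + relaxation over ``dt`` (exact closed form)."""
    m = np.array(m, dtype=float, copy=True).reshape(-1, 3)
    off = np.broadcast_to(np.asarray(off_hz, float), m.shape[:1])
    phi = 2.0 * np.pi * off * dt
    c, s = np.cos(phi), np.sin(phi)
    x = m[:, 0] * c + m[:, 1] * s
    y = -m[:, 0] * s + m[:, 1] * c
    e1 = np.exp(-dt / np.broadcast_to(np.asarray(t1, float), m.shape[:1]))
    e2 = np.exp(-dt / np.broadcast_to(np.asarray(t2, float), m.shape[:1]))
    out = np.empty_like(m)
    out[:, 0] = x * e2
    out[:, 1] = y * e2
    out[:, 2] = m[:, 2] * e1 + np.broadcast_to(np.asarray(m0, float), m.shape[:1]) * (1.0 - e1)
    return out


def step_rf(m, dt, b1_mag, b1_phase, off_hz, t1, t2, m0, gamma=GAMMA_1H):
    """Rotation about the rotating-frame effective field, then relaxation."""
    m = np.array(m, dtype=float, copy=True).reshape(-1, 3)
    npts = m.shape[0]
    off = np.broadcast_to(np.asarray(off_hz, float), (npts,))
    fx = gamma * b1_mag * np.cos(b1_phase) * np.ones(npts)
    fy = gamma * b1_mag * np.sin(b1_phase) * np.ones(npts)
    fz = off
    f = np.sqrt(fx * fx + fy * fy + fz * fz)
    with np.errstate(invalid="ignore", divide="ignore"):
        nx = np.where(f > 0, fx / np.where(f > 0, f, 1.0), 0.0)
        ny = np.where(f > 0, fy / np.where(f > 0, f, 1.0), 0.0)
        nz = np.where(f > 0, fz / np.where(f > 0, f, 1.0), 1.0)
    ang = -2.0 * np.pi * f * dt
    ca, sa = np.cos(ang), np.sin(ang)
    om = 1.0 - ca
    x, y, z = m[:, 0], m[:, 1], m[:, 2]
    dot = nx * x + ny * y + nz * z
    x2 = x * ca + (ny * z - nz * y) * sa + nx * dot * om
    y2 = y * ca + (nz * x - nx * z) * sa + ny * dot * om
    z2 = z * ca + (nx * y - ny * x) * sa + nz * dot * om
    e1 = np.exp(-dt / np.broadcast_to(np.asarray(t1, float), (npts,)))
    e2 = np.exp(-dt / np.broadcast_to(np.asarray(t2, float), (npts,)))
    out = np.empty_like(m)
    out[:, 0] = x2 * e2
    out[:, 1] = y2 * e2
    out[:, 2] = z2 * e1 + np.broadcast_to(np.asarray(m0, float), (npts,)) * (1.0 - e1)
    return out


def _bm_longitudinal(zf, zs, dt, t1f, t1s, k, kr, w, m0f, m0s):
    """Exact 2x2 longitudinal exchange/saturation propagator (scalar inputs)."""
    a11 = -(1.0 / t1f + k)
    a12 = kr
    a21 = k
    a22 = -(1.0 / t1s + kr + w)
    c1, c2 = m0f / t1f, m0s / t1s
    det = a11 * a22 - a12 * a21
    p1 = -(a22 * c1 - a12 * c2) / det
    p2 = -(-a21 * c1 + a11 * c2) / det
    tr = a11 + a22
    disc = np.sqrt((a11 - a22) ** 2 + 4.0 * a12 * a21)
    l1, l2 = 0.5 * (tr + disc), 0.5 * (tr - disc)
    if disc > 1e-12:
        g1, g2 = np.exp(l1 * dt), np.exp(l2 * dt)
        e11 = (g1 * (a11 - l2) - g2 * (a11 - l1)) / disc
        e12 = (g1 - g2) * a12 / disc
        e21 = (g1 - g2) * a21 / disc
        e22 = (g1 * (a22 - l2) - g2 * (a22 - l1)) / disc
    else:
        g1 = np.exp(l1 * dt)
        e11 = g1 * (1.0 + (a11 - l1) * dt)
        e12 = g1 * a12 * dt
        e21 = g1 * a21 * dt
        e22 = g1 * (1.0 + (a22 - l1) * dt)
    zf2 = p1 + e11 * (zf - p1) + e12 * (zs - p2)
    zs2 = p2 + e21 * (zf - p1) + e22 * (zs - p2)
    return zf2, zs2


def step_bm(m, mzs, dt, b1_mag, b1_phase, off_hz, t1, t2, m0,
            bound_fraction, k_exchange, t1_semisolid, g0,
            gamma=GAMMA_1H):
    """Two-pool Bloch-McConnell step (scalar spin parameters).

    The free pool rotates and loses transverse magnetization exactly as in
    :func:`step_rf`; the longitudinal components of both pools are advanced
    with the exact 2x2 matrix exponential of exchange + RF saturation, where
    the semisolid saturation rate is ``W = pi * (gamma*B1)^2 * g0`` with
    ``g0`` the absorption lineshape value (s).  ``bound_fraction = 0``
    reduces exactly to the single-pool update.
    """
    if bound_fraction == 0:
        return step_rf(m, dt, b1_mag, b1_phase, off_hz, t1, t2, m0, gamma), mzs
    # rotation + T2 decay on the free pool, longitudinal handled below
    rot = step_rf(m, dt, b1_mag, b1_phase, off_hz, np.inf, t2, m0, gamma)
    w = np.pi * (gamma * b1_mag) ** 2 * g0 if b1_mag > 0 else 0.0
    kr = k_exchange / bound_fraction
    m0s = m0 * bound_fraction
    zf, zs = _bm_longitudinal(float(rot[0, 2]), float(mzs), dt, t1, t1_semisolid,
                              k_exchange, kr, w, m0, m0s)
    rot[0, 2] = zf
    return rot, zs


def apply_crusher(m):
    """Null all transverse components; Mz untouched.  Idempotent."""
    m = np.array(m, dtype=float, copy=True).reshape(-1, 3)
    m[:, 0] = 0.0
    m[:, 1] = 0.0
    return m


def record_signal(m, sens=None):
    """Complex signal per coil: ``S_e = sum_i sens_e(i) * (Mx_i + i My_i)``."""
    m = np.asarray(m, dtype=float).reshape(-1, 3)
    mxy = m[:, 0] + 1j * m[:, 1]
    if sens is None:
        return mxy.sum()
    sens = np.atleast_2d(np.asarray(sens, dtype=complex))
    return sens @ mxy


# ----------------------------------------------------------------- lineshape

def absorption_lineshape(delta_hz, t2s, kind="super_lorentzian", cutoff_hz=1000.0):
    """Semisolid-pool absorption lineshape g(delta) in seconds.

    The super-Lorentzian (standard for agar/tissue) diverges on resonance;
    following common practice its value inside ``|delta| < cutoff_hz`` is
    taken at the cutoff.
    """
    t2s = float(t2s)
    if kind == "lorentzian":
        return t2s / np.pi / (1.0 + (2.0 * np.pi * float(delta_hz) * t2s) ** 2)
    if kind != "super_lorentzian":
        raise ValueError(f"unknown lineshape {kind!r}")
    d = max(abs(float(delta_hz)), float(cutoff_hz))

    def integrand(theta):
        u = np.abs(3.0 * np.cos(theta) ** 2 - 1.0)
        if u < 1e-12:
            return 0.0
        return (np.sin(theta) * np.sqrt(2.0 / np.pi) * t2s / u
                * np.exp(-2.0 * (2.0 * np.pi * d * t2s / u) ** 2))

    val, _ = quad(integrand, 0.0, np.pi / 2.0, limit=200)
    return val


# ----------------------------------------------------------------- simulate

def _timeline_arrays(timeline: TimeStepTable):
    dts = np.ascontiguousarray(timeline.step_durations(), dtype=float)
    t0s = np.concatenate(([0.0], np.cumsum(dts)))[:-1]
    return dts, t0s


def _phantom_arrays(phantom):
    pos = np.ascontiguousarray(phantom.positions, dtype=float)
    t1 = np.ascontiguousarray(phantom.t1, dtype=float)
    t2 = np.ascontiguousarray(phantom.t2, dtype=float)
    pd = np.ascontiguousarray(phantom.pd, dtype=float)
    n = len(t1)
    db0 = np.zeros(n)
    if phantom.b0_offset_hz is not None:
        db0 = db0 + np.asarray(phantom.b0_offset_hz, dtype=float)
    if phantom.chem_shift_hz is not None:
        db0 = db0 + np.asarray(phantom.chem_shift_hz, dtype=float)
    return pos, t1, t2, pd, np.ascontiguousarray(db0)


def _mt_arrays(phantom, config, n):
    """Per-spin MT parameter arrays for the kernel (zeros when inactive)."""
    zeros = np.zeros(n)
    if not (config.mt_enabled and phantom.mt is not None):
        return False, np.zeros(n, np.int64), zeros, zeros, zeros, np.ones(n), zeros
    f = np.asarray(phantom.mt["bound_fraction"], dtype=float) * np.ones(n)
    k = np.asarray(phantom.mt["k_exchange"], dtype=float) * np.ones(n)
    t1s = np.asarray(phantom.mt["t1_semisolid"], dtype=float) * np.ones(n)
    t2s = np.asarray(phantom.mt["t2_semisolid"], dtype=float) * np.ones(n)
    flag = (f > 0).astype(np.int64)
    kr = np.where(f > 0, k / np.where(f > 0, f, 1.0), 0.0)
    g0 = np.zeros(n)
    for val in np.unique(t2s[flag == 1]):
        g0[(t2s == val) & (flag == 1)] = absorption_lineshape(
            0.0, val, kind=config.mt_lineshape)
    t1s = np.where(t1s > 0, t1s, 1.0)
    return True, flag, k, kr, g0, t1s, f


def _motion_params(phantom, config):
    if not (config.motion_enabled and phantom.motion is not None):
        return 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    mo = phantom.motion
    if mo.kind == "translation":
        ax = np.asarray(mo.axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        return 1, ax[0], ax[1], ax[2], mo.amplitude_d, 0.0, 0.0, 0.0, mo.frequency
    if mo.kind == "rotation":
        cx, cy = mo.center
        return 2, 0.0, 0.0, 0.0, 0.0, np.deg2rad(mo.theta_max_deg), cx, cy, mo.frequency
    raise ValueError(f"unknown motion kind {mo.kind!r}")


def simulate(timeline: TimeStepTable, phantom, config: SimConfig,
             header: Optional[Dict[str, object]] = None) -> KSpaceData:
    """Run the kernel over a timeline and return k-space data.

    Isochromats are processed in chunks of ``config.chunk_size`` whose
    per-coil signals are summed; the result is independent of the chunk
    size up to floating-point reassociation.
    """
    dts, t0s = _timeline_arrays(timeline)
    pos, t1, t2, pd, db0 = _phantom_arrays(phantom)
    n = len(t1)
    if n == 0:
        raise ValueError("phantom has no isochromats")
    n_adc = timeline.n_adc
    if n_adc == 0 and timeline.n_recorders == 0:
        raise ValueError("timeline has no ADC samples or recorders")

    if phantom.sens is not None:
        sens_all = np.ascontiguousarray(phantom.sens, dtype=complex)
        if sens_all.shape != (sens_all.shape[0], n):
            raise ValueError("sens must have shape (n_coils, n_isochromats)")
    else:
        sens_all = np.ones((1, n), dtype=complex)
    n_coil = sens_all.shape[0]

    mt_on, mt_flag, mt_k, mt_kr, mt_g0, mt_t1s, mt_f = _mt_arrays(phantom, config, n)
    mkind, ax, ay, az, amp, theta, cx, cy, freq = _motion_params(phantom, config)

    adc_idx = np.ascontiguousarray(timeline.adc_index, dtype=np.int64)
    rec_idx = np.ascontiguousarray(timeline.recorder_index, dtype=np.int64)
    crush = np.ascontiguousarray(timeline.crusher, dtype=np.bool_)
    n_rec = timeline.n_recorders

    adc_total = np.zeros((n_coil, n_adc), dtype=complex)
    rec_total = np.empty((n_rec, n), dtype=complex)
    for lo in range(0, n, config.chunk_size):
        hi = min(lo + config.chunk_size, n)
        mx = np.zeros(hi - lo)
        my = np.zeros(hi - lo)
        mz = pd[lo:hi].copy()
        mzs = (pd[lo:hi] * mt_f[lo:hi]).copy()
        adc_out = np.zeros((n_coil, n_adc), dtype=complex)
        rec_out = np.zeros((n_rec, hi - lo), dtype=complex)
        run_timeline(
            dts, t0s,
            np.ascontiguousarray(timeline.gx), np.ascontiguousarray(timeline.gy),
            np.ascontiguousarray(timeline.gz),
            np.ascontiguousarray(timeline.b1_mag), np.ascontiguousarray(timeline.b1_phase),
            adc_idx, crush, rec_idx,
            np.ascontiguousarray(pos[lo:hi, 0]), np.ascontiguousarray(pos[lo:hi, 1]),
            np.ascontiguousarray(pos[lo:hi, 2]),
            t1[lo:hi], t2[lo:hi], pd[lo:hi], db0[lo:hi],
            np.ascontiguousarray(sens_all[:, lo:hi]),
            mt_on, mt_flag[lo:hi], mt_k[lo:hi], mt_kr[lo:hi], mt_g0[lo:hi],
            mt_t1s[lo:hi], (pd[lo:hi] * mt_f[lo:hi]),
            mkind, ax, ay, az, amp, theta, cx, cy, freq,
            config.gamma, mx, my, mz, mzs, adc_out, rec_out,
        )
        adc_total += adc_out
        rec_total[:, lo:hi] = rec_out

    # receiver phase demodulation
    order = np.argsort(adc_idx[adc_idx >= 0])
    adc_phases = timeline.adc_phase[adc_idx >= 0][order]
    adc_total *= np.exp(-1j * adc_phases)[None, :]
    rec_order = np.argsort(rec_idx[rec_idx >= 0])
    rec_phases = timeline.recorder_phase[rec_idx >= 0][rec_order]
    if n_rec:
        rec_total *= np.exp(-1j * rec_phases)[:, None]

    hdr = dict(header or {})
    hdr.setdefault("n_images", 1)
    hdr["noise_sd"] = config.noise_sd
    hdr["seed"] = config.seed
    out = KSpaceData(samples=adc_total, header=hdr)
    out.recorded = rec_total  # per-spin recorder output, if any
    if config.noise_sd > 0:
        out = add_noise(out, config.noise_sd, config.seed)
    return out


def simulate_reference(timeline: TimeStepTable, phantom, gamma=GAMMA_1H):
    """Pure-numpy simulation (no kernel, no chunking): the slow oracle.

    Supports static phantoms without MT; intended for small test problems.
    """
    dts, _ = _timeline_arrays(timeline)
    pos, t1, t2, pd, db0 = _phantom_arrays(phantom)
    m = np.zeros((len(t1), 3))
    m[:, 2] = pd
    sens = phantom.sens if phantom.sens is not None else None
    n_adc = timeline.n_adc
    n_coil = 1 if sens is None else np.atleast_2d(sens).shape[0]
    adc_out = np.zeros((n_coil, n_adc), dtype=complex)
    for s in range(len(dts)):
        if timeline.crusher[s]:
            m = apply_crusher(m)
        a = timeline.adc_index[s]
        if a >= 0:
            sig = record_signal(m, sens)
            adc_out[:, a] = (sig * np.exp(-1j * timeline.adc_phase[s]))
        off = gamma * (timeline.gx[s] * pos[:, 0] + timeline.gy[s] * pos[:, 1]
                       + timeline.gz[s] * pos[:, 2]) + db0
        if timeline.b1_mag[s] > 0:
            m = step_rf(m, dts[s], timeline.b1_mag[s], timeline.b1_phase[s],
                        off, t1, t2, pd, gamma)
        else:
            m = step_free(m, dts[s], off, t1, t2, pd)
    return adc_out


def make_dictionary_grid(t1_axis, t2_axis, slice_positions, b0_axis=(0.0,)):
    """Spin grid for dictionary generation: one spin per combination.

    Returns dict of flat arrays in C order over (t1, t2, b0, slice); the
    total spin count is the product of the axis lengths.
    """
    t1_axis = np.asarray(t1_axis, dtype=float)
    t2_axis = np.asarray(t2_axis, dtype=float)
    b0_axis = np.asarray(b0_axis, dtype=float)
    zpos = np.asarray(slice_positions, dtype=float)
    if t1_axis.size == 0 or t2_axis.size == 0 or zpos.size == 0:
        raise ValueError("dictionary axes must be non-empty")
    tt1, tt2, bb0, zz = np.meshgrid(t1_axis, t2_axis, b0_axis, zpos, indexing="ij")
    return {
        "t1": tt1.ravel(), "t2": tt2.ravel(), "b0": bb0.ravel(), "z": zz.ravel(),
        "shape": (t1_axis.size, t2_axis.size, b0_axis.size, zpos.size),
        "t1_axis": t1_axis, "t2_axis": t2_axis, "b0_axis": b0_axis,
        "slice_positions": zpos,
    }


def simulate_dictionary(timeline: TimeStepTable, t1_axis, t2_axis,
                        slice_positions, config: SimConfig,
                        b0_axis=(0.0,),
                        header: Optional[Dict[str, object]] = None) -> SignalDictionary:
    """Simulate a signal dictionary over a (T1, T2[, B0]) x slice grid.

    One spin is simulated per grid combination; at every single-point
    recorder the complex transverse magnetization of each spin is stored and
    the slice-position spins are summed into one fixed-length entry per
    (T1, T2[, B0]) combination.
    """
    from .phantom import IsochromatSet

    if timeline.n_recorders == 0:
        raise ValueError("timeline has no single-point recorders")
    grid = make_dictionary_grid(t1_axis, t2_axis, slice_positions, b0_axis)
    n = grid["t1"].size
    pos = np.zeros((n, 3))
    pos[:, 2] = grid["z"]
    ph = IsochromatSet(
        positions=pos, t1=grid["t1"], t2=grid["t2"], pd=np.ones(n),
        b0_offset_hz=grid["b0"],
    )
    ks = simulate(timeline, ph, config, header=header)
    rec = ks.recorded                      # (n_rec, n)
    nt1, nt2, nb0, nz = grid["shape"]
    sig = rec.T.reshape(nt1, nt2, nb0, nz, -1).sum(axis=3)
    signals = sig.reshape(nt1 * nt2 * nb0, -1)
    et1, et2, _ = np.meshgrid(grid["t1_axis"], grid["t2_axis"], grid["b0_axis"],
                              indexing="ij")
    return SignalDictionary(
        t1_values=grid["t1_axis"], t2_values=grid["t2_axis"],
        b0_values=grid["b0_axis"], slice_positions=grid["slice_positions"],
        signals=signals, entry_t1=et1.ravel(), entry_t2=et2.ravel(),
        header=dict(header or {}),
    )


def add_noise(kspace, sd: float, seed: int):
    """Add i.i.d. Gaussian noise (zero mean, SD ``sd``) to the real and
    imaginary channel of every sample.  ``sd = 0`` is the identity."""
    if sd < 0:
        raise ValueError("noise SD must be >= 0")
    if isinstance(kspace, KSpaceData):
        out = KSpaceData(samples=add_noise(kspace.samples, sd, seed),
                         header=dict(kspace.header))
        if hasattr(kspace, "recorded"):
            out.recorded = kspace.recorded
        return out
    samples = np.asarray(kspace, dtype=complex)
    if sd == 0:
        return samples.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd, samples.shape) + 1j * rng.normal(0.0, sd, samples.shape)
    return samples + noise
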