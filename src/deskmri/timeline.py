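"""Uniform discretization of sequences and fast-algorithm compression.

:func:`discretize` renders a :class:`~deskmri.sequence.Sequence` onto a
uniform time grid (the kernel's temporal resolution, typically 1 us) as
piecewise-constant field arrays plus event flags.  :func:`compress`
implements the variable-time-step "fast algorithm": maximal runs of steps
with identical gradients, zero B1 and no ADC/crusher/recorder flag are merged
into a single long step.  Because the Bloch update over constant fields
composes exactly, a compressed timeline produces the same signal as the
uniform one (to floating-point accuracy); that equivalence is enforced by
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .sequence import RasterError, Sequence

__all__ = ["TimeStepTable", "CompressedTimeline", "discretize", "compress"]

_NS = 1e9


def _ns(t: float) -> int:
    return int(round(t * _NS))


@dataclass
class TimeStepTable:
    """Uniform-step rendering of a sequence.

    Fields hold the value applied during ``[k*dt, (k+1)*dt)``.  Flags apply
    at the *start* instant of their step.  ``adc_index``/``recorder_index``
    are global sample/recorder ordinals, -1 where absent.
    """

    dt: float
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    b1_mag: np.ndarray
    b1_phase: np.ndarray
    adc_index: np.ndarray
    adc_phase: np.ndarray
    crusher: np.ndarray
    recorder_index: np.ndarray
    recorder_phase: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.gx)

    @property
    def n_adc(self) -> int:
        return int((self.adc_index >= 0).sum())

    @property
    def n_recorders(self) -> int:
        return int((self.recorder_index >= 0).sum())

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def step_durations(self) -> np.ndarray:
        return np.full(self.n_steps, self.dt)


@dataclass
class CompressedTimeline(TimeStepTable):
    """Variable-step timeline produced by :func:`compress`.

    ``dts[k]`` is the duration of step ``k``; ``dt`` keeps the base raster.
    Every step carrying a flag or nonzero B1 retains the base duration.
    """

    dts: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def duration(self) -> float:
        # integer-nanosecond arithmetic: exact conservation
        return int(round(self.dts.sum() * _NS)) / _NS

    def step_durations(self) -> np.ndarray:
        return self.dts


def discretize(seq: Sequence, dt: Optional[float] = None) -> TimeStepTable:
    """Render ``seq`` on a uniform grid of step ``dt`` (default: base_dt).

    Every object boundary must fall on the raster within 1 ns, otherwise a
    :class:`RasterError` is raised.
    """
    if dt is None:
        dt = seq.globals.base_dt
    dt_ns = _ns(dt)
    if dt_ns <= 0:
        raise ValueError("dt must be positive")

    total_ns = _ns(seq.duration)
    if total_ns % dt_ns:
        raise RasterError("sequence duration is not a multiple of dt")
    n = total_ns // dt_ns

    gx = np.zeros(n)
    gy = np.zeros(n)
    gz = np.zeros(n)
    b1m = np.zeros(n)
    b1p = np.zeros(n)
    adc = np.full(n, -1, dtype=np.int64)
    adcp = np.zeros(n)
    crush = np.zeros(n, dtype=bool)
    rec = np.full(n, -1, dtype=np.int64)
    recp = np.zeros(n)

    def _steps(a_ns: int, b_ns: int):
        if a_ns % dt_ns or b_ns % dt_ns:
            raise RasterError(
                f"object boundary at {a_ns / _NS:.9f}s not on the {dt:.2e}s raster"
            )
        return a_ns // dt_ns, b_ns // dt_ns

    def _instant(t_ns: int) -> int:
        if t_ns % dt_ns:
            raise RasterError(
                f"event at {t_ns / _NS:.9f}s not on the {dt:.2e}s raster"
            )
        return t_ns // dt_ns

    n_adc = 0
    n_rec = 0
    for t0, blk in seq.iter_blocks():
        for grad, arr in ((blk.gx, gx), (blk.gy, gy), (blk.gz, gz)):
            if grad is not None:
                s0, s1 = _steps(t0 + _ns(grad.start), t0 + _ns(grad.start) + _ns(grad.duration))
                arr[s0:s1] = grad.amplitude
        if blk.rf is not None:
            rf = blk.rf
            r_ns = _ns(rf.raster)
            if r_ns % dt_ns:
                raise RasterError("RF raster is not a multiple of dt")
            per = r_ns // dt_ns
            s0, _ = _steps(t0 + _ns(rf.start), t0 + _ns(rf.start))
            mag = np.abs(rf.amplitude_samples)
            pha = np.angle(rf.amplitude_samples)
            if rf.freq_offset:
                # carrier offset folded into a phase ramp at the sample midpoints
                t_mid = (np.arange(len(mag)) + 0.5) * rf.raster
                pha = pha + 2.0 * np.pi * rf.freq_offset * t_mid
            b1m[s0:s0 + per * len(mag)] = np.repeat(mag, per)
            b1p[s0:s0 + per * len(mag)] = np.repeat(pha, per)
        if blk.adc is not None:
            w = blk.adc
            for k in range(w.n_samples):
                s = _instant(t0 + _ns(w.start) + k * _ns(w.dwell))
                adc[s] = n_adc
                adcp[s] = w.phase
                n_adc += 1
        for c in blk.crushers:
            crush[_instant(t0 + _ns(c.time_point))] = True
        for r in blk.recorders:
            s = _instant(t0 + _ns(r.time_point))
            rec[s] = n_rec
            recp[s] = r.phase
            n_rec += 1

    return TimeStepTable(dt, gx, gy, gz, b1m, b1p, adc, adcp, crush, rec, recp)


def compress(table: TimeStepTable) -> CompressedTimeline:
    """Merge maximal idle runs (constant gradients, zero B1, no flags).

    The merged step's duration is the run length; all flagged steps and all
    steps under nonzero B1 keep the base step.  The total duration is
    conserved exactly (integer-nanosecond arithmetic).
    """
    n = table.n_steps
    if n == 0:
        return CompressedTimeline(
            table.dt, *[np.empty(0) for _ in range(2)],
            np.empty(0), np.empty(0), np.empty(0),
            np.empty(0, dtype=np.int64), np.empty(0),
            np.empty(0, dtype=bool), np.empty(0, dtype=np.int64), np.empty(0),
            dts=np.empty(0),
        )
    active = (
        (table.b1_mag != 0)
        | (table.adc_index >= 0)
        | table.crusher
        | (table.recorder_index >= 0)
    )
    # a new run starts where any field changes or where activity starts/stops
    boundary = np.ones(n, dtype=bool)
    changed = (
        (np.diff(table.gx) != 0)
        | (np.diff(table.gy) != 0)
        | (np.diff(table.gz) != 0)
        | active[1:]
        | active[:-1]
    )
    boundary[1:] = changed
    starts = np.flatnonzero(boundary)
    lengths = np.diff(starts, append=n)

    dt_ns = _ns(table.dt)
    dts = lengths * dt_ns / _NS
    out = CompressedTimeline(
        table.dt,
        table.gx[starts], table.gy[starts], table.gz[starts],
        table.b1_mag[starts], table.b1_phase[starts],
        table.adc_index[starts], table.adc_phase[starts],
        table.crusher[starts], table.recorder_index[starts],
        table.recorder_phase[starts],
        dts=dts,
    )
    assert int(lengths.sum()) == n
    return out
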