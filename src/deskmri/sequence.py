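"""Pulse-sequence object model.

A :class:`Sequence` is an ordered tree of :class:`BlockGroup`s holding
:class:`Block`s.  Each block holds *up to one* object of each hardware
category (RF pulse, gradient pulse per axis, acquisition window) plus any
number of simulation-only events: software crushers (instant nullification of
all transverse magnetization) and single-point recorders (store the
transverse magnetization of every spin, used to build signal dictionaries).

All times are seconds, gradients T/m, B1 tesla.  Internally every event
boundary is snapped to an integer-nanosecond grid so that discretization and
timeline compression are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "GlobalParams",
    "RFPulse",
    "GradientPulse",
    "AcquisitionWindow",
    "SoftwareCrusher",
    "SinglePointRecorder",
    "Block",
    "BlockGroup",
    "Sequence",
    "RasterError",
    "GAMMA_1H",
]

#: proton gyromagnetic ratio in Hz/T
GAMMA_1H = 42.577478518e6

_NS = 1e9


def _to_ns(t: float) -> int:
    return int(round(t * _NS))


class RasterError(ValueError):
    """An event boundary does not fall on the simulation raster."""


@dataclass
class GlobalParams:
    """Global parameters shared by every object of a sequence.

    ``matrix_size`` and ``fov`` may be a single number (square) or a
    ``(frequency-encode, phase-encode)`` pair.
    """

    matrix_size: object = 128
    fov: object = 0.4
    slice_thickness: float = 0.01
    receiver_bw: float = 1.0e5
    gamma: float = GAMMA_1H
    b0: float = 1.5
    g_max: float = 0.04
    base_dt: float = 1.0e-6

    def __post_init__(self):
        for name in ("slice_thickness", "receiver_bw", "gamma", "b0", "g_max", "base_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_fe <= 0 or self.n_pe <= 0:
            raise ValueError("matrix_size must be positive")
        if self.fov_fe <= 0 or self.fov_pe <= 0:
            raise ValueError("fov must be positive")
        dwell_ns = _to_ns(self.dwell)
        dt_ns = _to_ns(self.base_dt)
        if dwell_ns % dt_ns != 0:
            raise RasterError(
                f"dwell time {self.dwell:.3e}s is not a multiple of base_dt {self.base_dt:.3e}s"
            )

    @property
    def n_fe(self) -> int:
        return int(self.matrix_size[0]) if np.iterable(self.matrix_size) else int(self.matrix_size)

    @property
    def n_pe(self) -> int:
        return int(self.matrix_size[1]) if np.iterable(self.matrix_size) else int(self.matrix_size)

    @property
    def fov_fe(self) -> float:
        return float(self.fov[0]) if np.iterable(self.fov) else float(self.fov)

    @property
    def fov_pe(self) -> float:
        return float(self.fov[1]) if np.iterable(self.fov) else float(self.fov)

    @property
    def dwell(self) -> float:
        """ADC dwell time, 1 / receiver bandwidth."""
        return 1.0 / self.receiver_bw

    def as_context(self) -> Dict[str, float]:
        """Symbol table for functional (expression-valued) attributes."""
        return {
            "N": self.n_fe,
            "N_pe": self.n_pe,
            "fov": self.fov_fe,
            "fov_pe": self.fov_pe,
            "slice_thickness": self.slice_thickness,
            "rbw": self.receiver_bw,
            "gamma": self.gamma,
            "b0": self.b0,
            "gmax": self.g_max,
            "dt": self.base_dt,
            "dwell": self.dwell,
        }


@dataclass
class RFPulse:
    """A sampled RF pulse: complex B1(t) on a uniform raster.

    ``amplitude_samples[k]`` is held constant over
    ``[start + k*raster, start + (k+1)*raster)``.  Carrier frequency offsets
    are represented as a phase ramp folded into the sample phases at
    discretization time.
    """

    start: float
    duration: float
    amplitude_samples: np.ndarray
    raster: float
    flip_angle: float = 0.0
    freq_offset: float = 0.0
    phase_offset: float = 0.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("RF duration must be positive")
        self.amplitude_samples = np.asarray(self.amplitude_samples, dtype=complex)
        n = _to_ns(self.duration) // _to_ns(self.raster)
        if len(self.amplitude_samples) != n or _to_ns(self.duration) % _to_ns(self.raster):
            raise RasterError("RF duration must equal n_samples * raster")

    @property
    def center(self) -> float:
        return self.start + self.duration / 2.0


@dataclass
class GradientPulse:
    """Rectangular (steep-ramp) gradient lobe on one axis."""

    axis: str
    start: float
    duration: float
    amplitude: float

    def __post_init__(self):
        if self.axis not in ("x", "y", "z"):
            raise ValueError("axis must be 'x', 'y' or 'z'")
        if self.duration <= 0:
            raise ValueError("gradient duration must be positive")

    @property
    def area(self) -> float:
        return self.amplitude * self.duration


@dataclass
class AcquisitionWindow:
    """ADC window: ``n_samples`` instants at ``dwell`` spacing.

    Sample ``k`` is taken at ``start + k*dwell``; the window occupies
    ``n_samples*dwell``.  ``phase`` is the receiver phase (rad), subtracted
    from the recorded signal (it tracks the transmitter phase in
    phase-alternated sequences).
    """

    start: float
    n_samples: int
    dwell: float
    phase: float = 0.0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def duration(self) -> float:
        return self.n_samples * self.dwell


@dataclass
class SoftwareCrusher:
    """Instant nullification of all transverse magnetization at one instant."""

    time_point: float


@dataclass
class SinglePointRecorder:
    """Record every spin's transverse magnetization at one instant."""

    time_point: float
    index: int
    phase: float = 0.0


@dataclass
class Block:
    """A time interval holding up to one object of each hardware category."""

    id: int
    duration: float
    rf: Optional[RFPulse] = None
    gx: Optional[GradientPulse] = None
    gy: Optional[GradientPulse] = None
    gz: Optional[GradientPulse] = None
    adc: Optional[AcquisitionWindow] = None
    crushers: List[SoftwareCrusher] = field(default_factory=list)
    recorders: List[SinglePointRecorder] = field(default_factory=list)

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("block duration must be >= 0")
        self._check_fit()

    def _check_fit(self):
        dur_ns = _to_ns(self.duration)
        for obj in (self.rf, self.gx, self.gy, self.gz, self.adc):
            if obj is None:
                continue
            a, b = _to_ns(obj.start), _to_ns(obj.start) + _to_ns(obj.duration)
            if a < 0 or b > dur_ns:
                raise ValueError(
                    f"{type(obj).__name__} [{obj.start}, {obj.start + obj.duration}] "
                    f"does not fit in block of duration {self.duration}"
                )
        for ev in list(self.crushers) + list(self.recorders):
            t = _to_ns(ev.time_point)
            if t < 0 or t > dur_ns:
                raise ValueError("event time point outside block")

    def add(self, obj) -> "Block":
        """Attach an object, enforcing 'up to one object of each category'."""
        slot = {
            RFPulse: "rf",
            AcquisitionWindow: "adc",
        }.get(type(obj))
        if isinstance(obj, GradientPulse):
            slot = "g" + obj.axis
        if slot is not None:
            if getattr(self, slot) is not None:
                raise ValueError(f"block {self.id} already holds a {slot} object")
            setattr(self, slot, obj)
        elif isinstance(obj, SoftwareCrusher):
            self.crushers.append(obj)
        elif isinstance(obj, SinglePointRecorder):
            self.recorders.append(obj)
        else:
            raise TypeError(f"cannot add {type(obj).__name__} to a block")
        self._check_fit()
        return self


@dataclass
class BlockGroup:
    """An ordered list of blocks with a unique, increasing id."""

    id: int
    blocks: List[Block] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return sum(b.duration for b in self.blocks)


@dataclass
class Sequence:
    """A complete pulse sequence: globals, ordered block groups, metadata."""

    globals: GlobalParams
    groups: List[BlockGroup] = field(default_factory=list)
    header: Dict[str, object] = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return _to_ns(sum(g.duration for g in self.groups)) / _NS

    def iter_blocks(self):
        """Yield ``(absolute_start_ns, block)`` in document order."""
        t = 0
        for grp in self.groups:
            for blk in grp.blocks:
                yield t, blk
                t += _to_ns(blk.duration)

    def validate(self) -> None:
        """Check id ordering and that the sequence can produce a signal."""
        gids = [g.id for g in self.groups]
        if gids != sorted(gids) or len(set(gids)) != len(gids):
            raise ValueError("group ids must be unique and increasing")
        has_output = any(
            blk.adc is not None or blk.recorders for _, blk in self.iter_blocks()
        )
        if not has_output:
            raise ValueError("sequence has no acquisition window or recorder")
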