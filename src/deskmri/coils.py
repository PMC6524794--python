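"""Receiver-coil geometry and Biot-Savart sensitivity maps.

Each coil element is a circular loop carrying a nominal 1 A, discretized as
a closed polygon; the magnetic field at each isochromat position is the sum
of the exact segment contributions, and the receive sensitivity follows the
reciprocity convention ``B1- = (Bx - i By) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["CoilLoop", "CoilArray", "biot_savart_sensitivity", "ring_array"]

MU0 = 4e-7 * np.pi


@dataclass
class CoilLoop:
    center: Tuple[float, float, float]
    normal: Tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("loop radius must be positive")
        n = np.asarray(self.normal, dtype=float)
        self.normal = tuple(n / np.linalg.norm(n))


@dataclass
class CoilArray:
    elements: List[CoilLoop] = field(default_factory=list)

    @property
    def n_coils(self) -> int:
        return len(self.elements)


def _loop_polygon(loop: CoilLoop, n_segments: int) -> np.ndarray:
    """Vertices of the loop polygon (closed: first vertex repeated last)."""
    n = np.asarray(loop.normal, dtype=float)
    # orthonormal in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    phi = np.linspace(0.0, 2.0 * np.pi, n_segments + 1)
    pts = (np.asarray(loop.center)[None, :]
           + loop.radius * (np.cos(phi)[:, None] * u[None, :]
                            + np.sin(phi)[:, None] * v[None, :]))
    return pts


def _segment_field(p0: np.ndarray, p1: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Exact B field (T per ampere) of a straight segment p0->p1 at points r."""
    # Standard finite-wire result: B = mu0 I/(4 pi d) (sin a2 - sin a1) e_phi
    dl = p1 - p0
    length = np.linalg.norm(dl)
    e = dl / length
    r0 = r - p0[None, :]
    r1 = r - p1[None, :]
    # perpendicular vector from the wire line to each point
    proj = r0 @ e
    perp = r0 - proj[:, None] * e[None, :]
    d = np.linalg.norm(perp, axis=1)
    sin1 = -proj / np.linalg.norm(r0, axis=1)
    sin2 = -(r1 @ e) / np.linalg.norm(r1, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mag = MU0 / (4.0 * np.pi * d) * (sin2 - sin1)
    direction = np.cross(np.broadcast_to(e, r.shape), perp)
    nrm = np.linalg.norm(direction, axis=1)
    ok = nrm > 0
    direction[ok] /= nrm[ok, None]
    return np.where(ok[:, None], mag[:, None] * direction, 0.0)


def biot_savart_sensitivity(coils: CoilArray, positions, n_segments: int = 360,
                            guard: float = 1e-4) -> np.ndarray:
    """Complex receive sensitivities, shape ``(n_coils, N)``.

    Raises on any position closer than ``guard`` (m) to a loop wire, naming
    the offending isochromat.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    out = np.empty((coils.n_coils, pos.shape[0]), dtype=complex)
    for ci, loop in enumerate(coils.elements):
        pts = _loop_polygon(loop, n_segments)
        # singularity guard: distance to the polygon vertices is a cheap
        # lower-bound proxy for distance to the wire at this segment count
        dmin = np.min(np.linalg.norm(pos[:, None, :] - pts[None, :-1, :], axis=2), axis=1)
        bad = np.flatnonzero(dmin < guard)
        if bad.size:
            raise ValueError(
                f"isochromat {bad[0]} lies within {guard} m of coil element {ci}")
        b = np.zeros_like(pos)
        for k in range(n_segments):
            b += _segment_field(pts[k], pts[k + 1], pos)
        out[ci] = 0.5 * (b[:, 0] - 1j * b[:, 1])
    return out


def ring_array(n_coils: int = 8, loop_radius: float = 0.06,
               ring_radius: float = 0.14, z: float = 0.0,
               look_at=(0.0, 0.0, 0.0)) -> CoilArray:
    """Evenly spaced circular elements on a ring in the slice plane, normals
    pointing at ``look_at``."""
    elements = []
    target = np.asarray(look_at, dtype=float)
    for k in range(n_coils):
        ang = 2.0 * np.pi * k / n_coils
        c = np.array([ring_radius * np.cos(ang), ring_radius * np.sin(ang), z])
        elements.append(CoilLoop(center=tuple(c), normal=tuple(target - c),
                                 radius=loop_radius))
    return CoilArray(elements=elements)
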