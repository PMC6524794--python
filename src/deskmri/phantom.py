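"""Virtual phantoms: isochromat sets with MR tissue properties.

Isochromat grids are cell-centered; a phantom's "diameter" means the support
of nonzero proton density.  Multiple isochromats may share a position (e.g.
when concatenating sub-phantoms), and every optional attribute (chemical
shift, B0 offset map, MT parameters, coil sensitivities, motion) defaults to
"absent", which leaves simulation results identical to a phantom without the
attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "IsochromatSet",
    "MTParams",
    "MotionSpec",
    "make_cylinder_phantom",
    "make_annulus_phantom",
    "make_brainlike_phantom",
    "make_linear_b0_map",
    "concat_phantoms",
    "displace",
    "AGAR_MT_DEFAULTS",
    "BRAIN_TISSUES_1P5T",
]


@dataclass
class MTParams:
    """Two-pool magnetization-transfer parameters of one tissue.

    ``bound_fraction`` is the semisolid/free pool-size ratio; 0 disables MT.
    ``k_exchange`` is the free-to-semisolid rate (1/s); the reverse rate is
    balanced at equilibrium (``k / bound_fraction``).
    """

    bound_fraction: float = 0.0
    k_exchange: float = 0.0
    t1_semisolid: float = 1.0
    t2_semisolid: float = 12e-6

    def __post_init__(self):
        if min(self.bound_fraction, self.k_exchange, self.t1_semisolid,
               self.t2_semisolid) < 0:
            raise ValueError("MT parameters must be >= 0")


#: Literature-informed two-pool parameters for agarose gels of increasing
#: macromolecular content (values of this kind are tabulated for agar in the
#: quantitative-MT literature; they are configuration inputs, not constants).
AGAR_MT_DEFAULTS: Dict[str, MTParams] = {
    "2%": MTParams(bound_fraction=0.0068, k_exchange=20.0, t1_semisolid=1.0,
                   t2_semisolid=12e-6),
    "4%": MTParams(bound_fraction=0.0136, k_exchange=40.0, t1_semisolid=1.0,
                   t2_semisolid=12e-6),
    "8%": MTParams(bound_fraction=0.0272, k_exchange=60.0, t1_semisolid=1.0,
                   t2_semisolid=12e-6),
}


@dataclass
class MotionSpec:
    """Rigid-body motion: sinusoidal translation along an axis, or sinusoidal
    rotation in the XY-plane about a center."""

    kind: str                         # "translation" | "rotation"
    axis: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    amplitude_d: float = 0.0          # m (translation)
    theta_max_deg: float = 0.0        # degrees (rotation)
    center: Tuple[float, float] = (0.0, 0.0)
    frequency: float = 0.0            # Hz

    def __post_init__(self):
        if self.kind not in ("translation", "rotation"):
            raise ValueError("kind must be 'translation' or 'rotation'")
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")


@dataclass
class IsochromatSet:
    """A virtual phantom: N isochromats with positions and MR properties."""

    positions: np.ndarray                      # (N, 3) m
    t1: np.ndarray                             # (N,) s
    t2: np.ndarray                             # (N,) s
    pd: np.ndarray                             # (N,) arbitrary units
    chem_shift_hz: Optional[np.ndarray] = None
    b0_offset_hz: Optional[np.ndarray] = None
    mt: Optional[Dict[str, np.ndarray]] = None  # bound_fraction, k_exchange, t1_semisolid, t2_semisolid
    sens: Optional[np.ndarray] = None          # (n_coils, N) complex
    motion: Optional[MotionSpec] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = self.positions.shape[0]
        for name in ("t1", "t2", "pd"):
            arr = np.asarray(getattr(self, name), dtype=float) * np.ones(n)
            setattr(self, name, arr)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must have shape (N, 3)")
        if np.any(self.t2 <= 0) or np.any(self.t1 <= 0):
            raise ValueError("T1 and T2 must be positive")
        # T1 >= T2 is a physics expectation, reported by validate_inputs
        # rather than enforced here so malformed inputs can be diagnosed
        if np.any(self.pd < 0):
            raise ValueError("proton density must be >= 0")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def with_mt(self, params: MTParams) -> "IsochromatSet":
        """Return a copy with uniform MT parameters on every isochromat."""
        ones = np.ones(self.n)
        return replace(self, mt={
            "bound_fraction": params.bound_fraction * ones,
            "k_exchange": params.k_exchange * ones,
            "t1_semisolid": params.t1_semisolid * ones,
            "t2_semisolid": params.t2_semisolid * ones,
        })


def _grid_1d(extent: float, spacing: float) -> np.ndarray:
    """Cell-centered coordinates covering [-extent, extent]."""
    n = max(int(np.floor(2 * extent / spacing)), 1)
    return (np.arange(n) - (n - 1) / 2.0) * spacing


def make_cylinder_phantom(radius, height, spacing, t1, t2, pd=1.0,
                          center=(0.0, 0.0, 0.0)) -> IsochromatSet:
    """Solid cylinder (axis along z) filled with a cell-centered grid."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xs = _grid_1d(radius, spacing)
    zs = _grid_1d(height / 2.0, spacing)
    xx, yy, zz = np.meshgrid(xs, xs, zs, indexing="ij")
    mask = xx ** 2 + yy ** 2 <= radius ** 2
    if not mask.any() or 2 * radius < spacing or height <= 0:
        raise ValueError("phantom is empty: spacing larger than the geometry")
    pos = np.stack([xx[mask], yy[mask], zz[mask]], axis=1) + np.asarray(center)
    n = pos.shape[0]
    return IsochromatSet(
        positions=pos, t1=np.full(n, t1), t2=np.full(n, t2), pd=np.full(n, pd),
        meta={"shape": "cylinder", "radius": radius, "height": height,
              "spacing": spacing, "center": tuple(center)},
    )


def make_annulus_phantom(outer_diameter, wall, height, spacing, t1, t2,
                         pd=1.0, center=(0.0, 0.0, 0.0)) -> IsochromatSet:
    """Hollow cylinder: outer radius ``outer_diameter/2``, inner radius
    ``outer/2 - wall`` (a wall of half the outer diameter gives a solid
    cylinder)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    r_out = outer_diameter / 2.0
    r_in = max(r_out - wall, 0.0)
    xs = _grid_1d(r_out, spacing)
    zs = _grid_1d(height / 2.0, spacing)
    xx, yy, zz = np.meshgrid(xs, xs, zs, indexing="ij")
    r2 = xx ** 2 + yy ** 2
    mask = (r2 <= r_out ** 2) & (r2 > r_in ** 2)
    if not mask.any():
        raise ValueError("phantom is empty: spacing larger than the geometry")
    pos = np.stack([xx[mask], yy[mask], zz[mask]], axis=1) + np.asarray(center)
    n = pos.shape[0]
    return IsochromatSet(
        positions=pos, t1=np.full(n, t1), t2=np.full(n, t2), pd=np.full(n, pd),
        meta={"shape": "annulus", "r_out": r_out, "r_in": r_in, "height": height,
              "spacing": spacing, "center": tuple(center)},
    )


#: (T1 s, T2 s, PD) per tissue class at 1.5 T, typical literature values.
BRAIN_TISSUES_1P5T: Dict[str, Tuple[float, float, float]] = {
    "skin_muscle": (0.90, 0.050, 0.9),
    "skull": (0.40, 0.010, 0.3),
    "fat": (0.26, 0.060, 1.0),
    "connective": (0.80, 0.070, 0.8),
    "glial": (1.10, 0.090, 0.9),
    "grey": (0.95, 0.100, 0.9),
    "white": (0.60, 0.080, 0.8),
}


def make_brainlike_phantom(shape=(0.18, 0.22), spacing=2e-3,
                           tissue_table: Optional[Dict[str, Tuple[float, float, float]]] = None,
                           height=2e-3, seed=0) -> IsochromatSet:
    """Deterministic brain-like slice phantom: seven nested-ellipse tissue
    shells (skin/muscle outermost to white matter innermost), one discrete
    tissue per position.

    This is a synthetic stand-in with the same *structure* as a labeled
    digital head phantom (7 tissue classes, discrete labels), not a
    reproduction of any acquired dataset.
    """
    table = dict(BRAIN_TISSUES_1P5T if tissue_table is None else tissue_table)
    labels = list(table.keys())
    if len(labels) != 7:
        raise ValueError("tissue_table must map exactly 7 labels")
    for lab in labels:
        if len(table[lab]) != 3:
            raise ValueError(f"missing (T1, T2, PD) for label {lab!r}")
    a, b = shape[0] / 2.0, shape[1] / 2.0
    xs = _grid_1d(a, spacing)
    ys = _grid_1d(b, spacing)
    zs = _grid_1d(height / 2.0, spacing)
    xx, yy, zz = np.meshgrid(xs, ys, zs, indexing="ij")
    # nested shells: fractional semi-axes of the 7 boundaries, outermost first
    fracs = [1.0, 0.94, 0.90, 0.86, 0.78, 0.62, 0.40]
    rho = (xx / a) ** 2 + (yy / b) ** 2
    label_idx = np.full(xx.shape, -1, dtype=int)
    for li, f in enumerate(fracs):
        label_idx[rho <= f ** 2] = li
    mask = label_idx >= 0
    pos = np.stack([xx[mask], yy[mask], zz[mask]], axis=1)
    li = label_idx[mask]
    props = np.array([table[lab] for lab in labels])
    return IsochromatSet(
        positions=pos, t1=props[li, 0], t2=props[li, 1], pd=props[li, 2],
        meta={"shape": "brainlike", "labels": labels, "label_index": li,
              "spacing": spacing, "extent": tuple(shape), "seed": seed},
    )


def concat_phantoms(phantoms: List[IsochromatSet]) -> IsochromatSet:
    """Concatenate isochromat sets (properties travel with each isochromat)."""

    def cat_opt(attr):
        vals = [getattr(p, attr) for p in phantoms]
        if all(v is None for v in vals):
            return None
        return np.concatenate([
            v if v is not None else np.zeros(p.n)
            for v, p in zip(vals, phantoms)
        ])

    mt = None
    if any(p.mt is not None for p in phantoms):
        mt = {}
        for key in ("bound_fraction", "k_exchange", "t1_semisolid", "t2_semisolid"):
            mt[key] = np.concatenate([
                p.mt[key] if p.mt is not None else
                (np.ones(p.n) if key.startswith("t") else np.zeros(p.n))
                for p in phantoms
            ])
    return IsochromatSet(
        positions=np.concatenate([p.positions for p in phantoms]),
        t1=np.concatenate([p.t1 for p in phantoms]),
        t2=np.concatenate([p.t2 for p in phantoms]),
        pd=np.concatenate([p.pd for p in phantoms]),
        chem_shift_hz=cat_opt("chem_shift_hz"),
        b0_offset_hz=cat_opt("b0_offset_hz"),
        mt=mt,
        meta={"shape": "composite",
              "parts": [p.meta for p in phantoms],
              "part_slices": np.cumsum([0] + [p.n for p in phantoms]).tolist()},
    )


def make_linear_b0_map(phantom: IsochromatSet, span_hz: float, axis=1) -> IsochromatSet:
    """Linear B0 inhomogeneity: offsets run from -span to +span across the
    phantom extent along ``axis`` (0=x, 1=y/PE, 2=z), zero at the center."""
    coords = phantom.positions[:, axis]
    support = phantom.pd > 0
    lo, hi = coords[support].min(), coords[support].max()
    if hi - lo <= 0:
        raise ValueError("phantom has no extent along the requested axis")
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    offsets = span_hz * (coords - mid) / half
    return replace(phantom, b0_offset_hz=offsets)


def displace(positions: np.ndarray, t: float, motion: MotionSpec) -> np.ndarray:
    """Rigid-body displaced positions at time ``t``.

    Translation: ``p + axis * D * sin(2 pi f t)``.  Rotation: rotate the XY
    coordinates about the center by ``theta(t) = theta_max * sin(2 pi f t)``
    (an isometry; z is unchanged).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    out = pos.copy()
    if motion.kind == "translation":
        ax = np.asarray(motion.axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        out += ax[None, :] * motion.amplitude_d * np.sin(2 * np.pi * motion.frequency * t)
        return out
    theta = np.deg2rad(motion.theta_max_deg) * np.sin(2 * np.pi * motion.frequency * t)
    c, s = np.cos(theta), np.sin(theta)
    cx, cy = motion.center
    dx = pos[:, 0] - cx
    dy = pos[:, 1] - cy
    out[:, 0] = c * dx - s * dy + cx
    out[:, 1] = s * dx + c * dy + cy
    return out
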