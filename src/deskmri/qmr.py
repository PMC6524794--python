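"""Quantitative analysis: MOLLI three-parameter fitting with Look-Locker
correction, T1 map assembly, six-segment ROI statistics and dictionary
matching (SQUAREMR/MRF-style).

The inversion-recovery model is ``S(TI) = A - B * exp(-TI / T1*)`` fitted to
magnitude data with exhaustive polarity restoration (the earliest m samples
by inversion time are sign-flipped, every m is tried, lowest residual wins,
ties broken toward fewer flips), followed by the Look-Locker correction
``T1 = T1* (B/A - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["MolliFit", "ROISpec", "molli_fit", "make_t1_map",
           "segment_annulus", "squaremr_match"]


@dataclass
class MolliFit:
    a: float
    b: float
    t1_star: float
    t1: float
    residual: float
    polarity_flip_index: int
    converged: bool = True


@dataclass
class ROISpec:
    masks: List[np.ndarray]
    labels: List[str] = field(default_factory=list)


def _linear_fit(signed: np.ndarray, basis_e: np.ndarray):
    """Closed-form least squares of S = A - B*e against one exp basis.

    ``basis_e`` may be (n_tau, n_ti): solved for every tau at once.
    Returns (a, b, sq_residual) arrays over the tau axis.
    """
    e = np.atleast_2d(basis_e)
    n = e.shape[1]
    se = e.sum(axis=1)
    see = (e * e).sum(axis=1)
    sy = signed.sum()
    sey = e @ signed
    det = n * see - se * se
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (see * sy - se * sey) / det
        nb = (n * sey - se * sy) / det          # coefficient of e (= -B)
    pred = a[:, None] + nb[:, None] * e
    res = ((pred - signed[None, :]) ** 2).sum(axis=1)
    bad = ~np.isfinite(res)
    res[bad] = np.inf
    return a, -nb, res


def molli_fit(signal, ti, t1_star_bounds=(0.02, 8.0), n_grid: int = 60) -> MolliFit:
    """Fit the 3-parameter inversion-recovery model to magnitude samples.

    The separable structure is exploited: for each candidate T1* the optimal
    (A, B) follow in closed form; T1* is located on a log grid and polished
    with bounded scalar minimization.  Requires at least 3 samples.
    """
    s = np.asarray(signal, dtype=float).ravel()
    t = np.asarray(ti, dtype=float).ravel()
    if s.size != t.size or s.size < 3:
        raise ValueError("need >= 3 (TI, S) pairs")
    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    s_sorted = s[order]
    taus = np.geomspace(t1_star_bounds[0], t1_star_bounds[1], n_grid)
    e_grid = np.exp(-t_sorted[None, :] / taus[:, None])

    best = None
    for m in range(s.size + 1):
        signed = s_sorted.copy()
        signed[:m] *= -1.0
        a_g, b_g, res_g = _linear_fit(signed, e_grid)
        k = int(np.argmin(res_g))

        def cost(log_tau, signed=signed):
            e = np.exp(-t_sorted / np.exp(log_tau))
            _, _, r = _linear_fit(signed, e[None, :])
            return r[0]

        lo = np.log(taus[max(k - 1, 0)])
        hi = np.log(taus[min(k + 1, n_grid - 1)])
        if lo == hi:
            tau_opt = taus[k]
        else:
            opt = minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-12, "maxiter": 200})
            tau_opt = float(np.exp(opt.x))
        a_o, b_o, res_o = (x[0] for x in _linear_fit(
            np.where(np.arange(s.size) < m, -s_sorted, s_sorted),
            np.exp(-t_sorted / tau_opt)[None, :]))
        # strictly-fewer-flips tie break
        if best is None or res_o < best[0] - 1e-15 * max(1.0, best[0]):
            best = (res_o, a_o, b_o, tau_opt, m)

    res, a, b, tau, m = best
    converged = np.isfinite(res) and a > 0 and b > 0
    t1 = tau * (b / a - 1.0) if converged else np.nan
    return MolliFit(a=a, b=b, t1_star=tau, t1=t1,
                    residual=float(np.sqrt(res / s.size)),
                    polarity_flip_index=m, converged=bool(converged))


def make_t1_map(images, ti, mask=None, rois: Optional[ROISpec] = None):
    """Pixelwise MOLLI T1 map over ``mask`` plus per-ROI statistics.

    ``images``: (n_ti, ny, nx) magnitude stack.  Pixels whose fit does not
    converge are NaN and excluded from the ROI means.  Returns
    ``(t1_map, stats)`` where stats maps ROI label -> (mean, sd, n).
    """
    imgs = np.asarray(images, dtype=float)
    if imgs.ndim != 3:
        raise ValueError("images must be (n_ti, ny, nx)")
    n_ti, ny, nx = imgs.shape
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
        if rois is not None:
            mask = np.any([m for m in rois.masks], axis=0)
    t1_map = np.full((ny, nx), np.nan)
    for j, i in zip(*np.nonzero(mask)):
        fit = molli_fit(imgs[:, j, i], ti)
        if fit.converged:
            t1_map[j, i] = fit.t1
    stats: Dict[str, Tuple[float, float, int]] = {}
    if rois is not None:
        labels = rois.labels or [str(k + 1) for k in range(len(rois.masks))]
        for lab, m in zip(labels, rois.masks):
            if not m.any():
                raise ValueError(f"ROI {lab!r} is empty")
            vals = t1_map[m]
            vals = vals[np.isfinite(vals)]
            stats[lab] = (float(vals.mean()) if vals.size else np.nan,
                          float(vals.std()) if vals.size else np.nan,
                          int(vals.size))
    return t1_map, stats


def segment_annulus(shape, pixel_spacing, center, r_in, r_out,
                    n_segments: int = 6, roi_fraction: float = 0.5) -> ROISpec:
    """Six equal angular sectors of an annular wall; each ROI is the central
    patch of its sector (central ``roi_fraction`` radially and angularly).

    Segment 1 is centered on the +y (phase-encode) axis and numbering
    proceeds clockwise, so segments 1 and 4 lie on the y axis.
    """
    ny, nx = shape
    dy, dx = pixel_spacing
    cy, cx = center
    yy = (np.arange(ny) - ny // 2) * dy - cy
    xx = (np.arange(nx) - nx // 2) * dx - cx
    x = xx[None, :] * np.ones((ny, 1))
    y = yy[:, None] * np.ones((1, nx))
    r = np.hypot(x, y)
    ang = np.arctan2(x, y)            # 0 at +y, increasing clockwise
    wall = r_out - r_in
    r_ok = (r >= r_in + (1 - roi_fraction) / 2 * wall) & \
           (r <= r_out - (1 - roi_fraction) / 2 * wall)
    sector = 2 * np.pi / n_segments
    masks, labels = [], []
    for k in range(n_segments):
        c = k * sector
        d = np.angle(np.exp(1j * (ang - c)))
        masks.append(r_ok & (np.abs(d) <= roi_fraction * sector / 2))
        labels.append(str(k + 1))
    return ROISpec(masks=masks, labels=labels)


def _signed_candidates(vec: np.ndarray, order: np.ndarray) -> np.ndarray:
    """All prefix-flip polarity restorations of a magnitude vector."""
    n = vec.size
    out = np.empty((n + 1, n))
    for m in range(n + 1):
        v = vec.copy()
        v[order[:m]] *= -1.0
        out[m] = v
    return out


def squaremr_match(measured, dictionary, ti=None):
    """Match measured signal vectors against a simulated dictionary.

    ``measured``: (n_pixels, L) magnitude vectors.  Each dictionary entry is
    reduced to a signed real evolution (phase-referenced to its last,
    most-recovered point); measured vectors are polarity-restored exactly as
    in :func:`molli_fit` and the entry maximizing the normalized absolute
    inner product (scale-invariant L2) is selected.

    Returns ``(t1, t2)`` arrays (NaN where a vector has no energy).
    """
    meas = np.atleast_2d(np.asarray(measured, dtype=float))
    sig = dictionary.signals
    if meas.shape[1] != sig.shape[1]:
        raise ValueError(
            f"measured length {meas.shape[1]} != dictionary length {sig.shape[1]}")
    if ti is None:
        ti = dictionary.header.get("ti")
    order = (np.argsort(np.asarray(ti, dtype=float), kind="stable")
             if ti is not None else np.arange(meas.shape[1]))
    ref = sig[:, -1]
    ref = np.where(np.abs(ref) > 0, ref / np.abs(np.where(np.abs(ref) > 0, ref, 1.0)), 1.0)
    signed_dict = np.real(sig * np.conj(ref)[:, None])
    dnorm = np.linalg.norm(signed_dict, axis=1)
    ok = dnorm > 0
    d_unit = np.zeros_like(signed_dict)
    d_unit[ok] = signed_dict[ok] / dnorm[ok, None]

    t1 = np.full(meas.shape[0], np.nan)
    t2 = np.full(meas.shape[0], np.nan)
    for p in range(meas.shape[0]):
        v = meas[p]
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        cand = _signed_candidates(v, order) / nv
        corr = np.abs(cand @ d_unit.T)          # (n_flips, n_entries)
        best = int(np.argmax(corr.max(axis=0)))
        t1[p] = dictionary.entry_t1[best]
        t2[p] = dictionary.entry_t2[best]
    return t1, t2
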