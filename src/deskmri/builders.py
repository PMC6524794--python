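"""Sequence builders: spoiled Cartesian GRE and inversion-recovery bSSFP
(MOLLI-style) with a programmatic block/group construction.

Timing conventions (all snapped to the 1 us base raster):

* GRE: each repetition holds the slice-selective RF block, a combined
  slice-rephase / readout-prephase / phase-encode interval played
  simultaneously at up to the maximum gradient, the readout with centered
  ADC, and a software crusher at the end of the TR.  The echo time follows
  the minimum-TE rule ``TE = RF/2 + prephaser + readout/2`` with the
  prephaser sized by ``(readout area / 2) / g_max``.
* MOLLI ``a(bp)c``: one adiabatic inversion before image 1 and (if c > 0)
  one before image a+b+1; a single-shot balanced SSFP readout per simulated
  heartbeat with a linear flip-angle ramp-up, alternating RF/receiver phase
  and fully balanced gradients per TR; per-image effective inversion times
  (to the k-space-center echo) recorded in the header.
"""

from __future__ import annotations

import re
from typing import Optional

import numpy as np

from .expressions import Expression, eval_expression
from .rf import make_adiabatic_rf, make_sinc_rf
from .sequence import (
    AcquisitionWindow,
    Block,
    BlockGroup,
    GlobalParams,
    GradientPulse,
    RFPulse,
    Sequence,
    SinglePointRecorder,
    SoftwareCrusher,
)

__all__ = ["build_gre", "build_molli", "parse_molli_scheme"]

_US = 1e-6


def _ceil_us(t: float) -> float:
    """Round a duration up to the next microsecond."""
    return np.ceil(t / _US - 1e-9) * _US


def _ky_indices(n_pe: int) -> np.ndarray:
    """Linear phase-encode ordering -k_max..+k_max.

    Even matrix sizes use the FFT-standard indices -N/2..N/2-1; odd sizes
    are symmetric about zero.
    """
    return np.arange(n_pe) - n_pe // 2


def build_gre(params: GlobalParams, flip_deg: float = 15.0, tr: float = 10e-3,
              rf_duration: float = 3e-3, n_lobes: int = 3,
              rf_raster: float = 10e-6) -> Sequence:
    """Spoiled Cartesian gradient-recalled-echo sequence.

    One repetition (block group) per phase-encode line; the phase-encode
    amplitude of repetition ``ID`` is a functional attribute evaluated over
    the global parameters.
    """
    g = params
    n_fe, n_pe = g.n_fe, g.n_pe
    dwell = g.dwell
    readout_dur = n_fe * dwell
    g_read = g.receiver_bw / (g.gamma * g.fov_fe)
    if g_read > g.g_max:
        raise ValueError("required readout gradient exceeds g_max")
    rf_bw = (n_lobes + 1) / rf_duration
    g_ss = rf_bw / (g.gamma * g.slice_thickness)
    if g_ss > g.g_max:
        raise ValueError("required slice-select gradient exceeds g_max")

    area_read_pre = g_read * readout_dur / 2.0
    area_ss_reph = g_ss * rf_duration / 2.0
    area_pe_max = n_pe / (2.0 * g.fov_pe * g.gamma)
    # min-TE rule: the interval is sized by the simultaneous readout-prephase
    # and phase-encode demand at g_max; the slice rephaser shares the interval
    # (idealized amplitude, steep-step gradients)
    pre_dur = _ceil_us(max(area_read_pre, area_pe_max) / g.g_max)
    te = rf_duration / 2.0 + pre_dur + readout_dur / 2.0
    used = rf_duration + pre_dur + readout_dur
    if tr < used + 2 * g.base_dt:
        raise ValueError(f"TR {tr} shorter than minimum block content {used}")

    pe_amp_expr = Expression("((ID - 1) - N_pe/2) / (gamma * fov_pe * pre_dur)")
    seq = Sequence(globals=g)
    block_id = 0
    for rep in range(1, n_pe + 1):
        ctx = dict(g.as_context(), ID=rep, pre_dur=pre_dur)
        pe_amp = eval_expression(pe_amp_expr, ctx)
        rf = make_sinc_rf(flip_deg, rf_duration, n_lobes, rf_raster, g.gamma)
        blocks = []
        blocks.append(Block(
            id=(block_id := block_id + 1), duration=rf_duration, rf=rf,
            gz=GradientPulse("z", 0.0, rf_duration, g_ss)))
        b2 = Block(id=(block_id := block_id + 1), duration=pre_dur,
                   gz=GradientPulse("z", 0.0, pre_dur, -area_ss_reph / pre_dur),
                   gx=GradientPulse("x", 0.0, pre_dur, -area_read_pre / pre_dur))
        if pe_amp != 0.0:
            b2.add(GradientPulse("y", 0.0, pre_dur, pe_amp))
        blocks.append(b2)
        blocks.append(Block(
            id=(block_id := block_id + 1), duration=readout_dur,
            gx=GradientPulse("x", 0.0, readout_dur, g_read),
            adc=AcquisitionWindow(0.0, n_fe, dwell)))
        tail = tr - used
        blocks.append(Block(
            id=(block_id := block_id + 1), duration=tail,
            crushers=[SoftwareCrusher(tail - g.base_dt)]))
        seq.groups.append(BlockGroup(id=rep, blocks=blocks))

    seq.header.update({
        "sequence": "gre", "te": te, "tr": tr, "flip_deg": flip_deg,
        "n_images": 1, "n_pe": n_pe, "n_fe": n_fe, "dwell": dwell,
        "fov_fe": g.fov_fe, "fov_pe": g.fov_pe, "trajectory": "cartesian",
        "ky_indices": _ky_indices(n_pe).tolist(),
        "duration": n_pe * tr,
    })
    seq.validate()
    return seq


def parse_molli_scheme(scheme: str):
    """Parse an ``a(bp)c`` acquisition scheme into (a, pause_beats, c)."""
    m = re.fullmatch(r"\s*(\d+)\(\s*(\d+)\s*p?\s*\)(\d+)\s*", scheme)
    if not m:
        raise ValueError(f"malformed MOLLI scheme {scheme!r}")
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


def build_molli(params: GlobalParams, scheme: str = "5(3p)3",
                heart_rate_bpm: float = 60.0,
                tr: float = 2.06e-3, te: float = 1.03e-3,
                flip_deg: float = 35.0, rf_duration: float = 490e-6,
                rf_raster: float = 10e-6, n_ramp: int = 10,
                ti1: float = 0.100, ti2: float = 0.180,
                ir_kind: str = "hyperbolic_secant", ir_duration: float = 4.74e-3,
                ir_peak_b1: Optional[float] = None, ir_shape: Optional[dict] = None,
                add_recorders: bool = False) -> Sequence:
    """Inversion-recovery single-shot bSSFP T1-mapping sequence.

    ``params.matrix_size`` is (frequency-encode, phase-encode); one image is
    acquired per simulated heartbeat (interval ``60 / heart_rate_bpm`` s).
    With ``add_recorders`` a single-point recorder is placed at the
    k-space-center echo of every image (dictionary mode).
    """
    from .rf import ADIABATIC_PEAK_B1

    if ir_peak_b1 is None:
        ir_peak_b1 = ADIABATIC_PEAK_B1[ir_kind]
    g = params
    n_fe, n_pe = g.n_fe, g.n_pe
    dwell = g.dwell
    rr = 60.0 / heart_rate_bpm
    n1, pause, n2 = parse_molli_scheme(scheme)
    if n1 < 1:
        raise ValueError("scheme must contain at least one image")
    n_images = n1 + n2
    n_beats = n1 + pause + n2 if n2 > 0 else n1

    # ---- per-TR geometry -------------------------------------------------
    readout_dur = n_fe * dwell
    rf_center = rf_duration / 2.0
    echo_t = rf_center + te
    adc_start = echo_t - readout_dur / 2.0
    adc_end = adc_start + readout_dur
    if adc_start < rf_duration or adc_end > tr:
        raise ValueError("readout does not fit between the RF pulse and TR end")
    gap1 = adc_start - rf_duration
    gap2 = tr - adc_end
    g_read = g.receiver_bw / (g.gamma * g.fov_fe)
    n_lobes = 3
    rf_bw = (n_lobes + 1) / rf_duration
    g_ss = rf_bw / (g.gamma * g.slice_thickness)
    area_ss_half = g_ss * rf_duration / 2.0
    area_read_half = g_read * readout_dur / 2.0
    dky = 1.0 / g.fov_pe
    ky = _ky_indices(n_pe)
    kc_line = int(np.flatnonzero(ky == 0)[0])
    for area, dur in ((area_ss_half, gap1), (area_read_half, gap1),
                      (np.abs(ky).max() * dky / g.gamma, gap1)):
        if dur <= 0 or area / dur > g.g_max:
            raise ValueError("balanced gradient demand exceeds g_max")

    # time from image start to the k-space-center echo
    t_kcenter = (n_ramp + kc_line) * tr + echo_t
    half_ir = ir_duration / 2.0
    for ti in (ti1,) + ((ti2,) if n2 else ()):
        if ti < t_kcenter + half_ir + 1e-3:
            raise ValueError(
                f"TI {ti * 1e3:.0f} ms unreachable: k-space center is "
                f"{t_kcenter * 1e3:.1f} ms into the readout; shorten the "
                "phase-encode train or increase TI")
    # image start offset within each beat so the first inversion fits
    offs = _ceil_us(max(0.0, ti1 - t_kcenter + half_ir + 1e-3))

    # ---- event schedule (absolute start times) ---------------------------
    image_beats = list(range(n1)) + [n1 + pause + j for j in range(n2)]
    image_tis = [ti1 + b * rr for b in range(n1)] + [ti2 + j * rr for j in range(n2)]
    events = []  # (start_time, kind, payload)
    for idx, (beat, ti) in enumerate(zip(image_beats, image_tis)):
        events.append((beat * rr + offs, "image", idx))
    # effective TI runs from the inversion-pulse center to the k-center echo
    ir_starts = [image_beats[0] * rr + offs + t_kcenter - ti1 - half_ir]
    if n2:
        ir_starts.append(image_beats[n1] * rr + offs + t_kcenter - ti2 - half_ir)
    # the inversion block includes the pulse plus a trailing spoiler step
    ir_block_dur = _ceil_us(ir_duration) + 2 * g.base_dt
    for t_ir in ir_starts:
        if t_ir < 0:
            raise ValueError("inversion pulse would start before t = 0")
        events.append((t_ir, "ir", None))
    events.sort(key=lambda e: e[0])

    # ---- build groups ----------------------------------------------------
    seq = Sequence(globals=g)
    block_id = 0
    group_id = 0
    cursor = 0.0

    def idle(duration):
        nonlocal block_id, group_id
        if duration <= 1e-12:
            return
        group_id += 1
        block_id += 1
        seq.groups.append(BlockGroup(id=group_id, blocks=[
            Block(id=block_id, duration=round(duration / _US) * _US)]))

    def bssfp_tr(flip, phase, with_adc, ky_area, with_recorder=False):
        nonlocal block_id
        rf = make_sinc_rf(flip, rf_duration, n_lobes, rf_raster, g.gamma,
                          phase_offset=phase)
        blocks = [Block(id=(block_id := block_id + 1), duration=rf_duration,
                        rf=rf, gz=GradientPulse("z", 0.0, rf_duration, g_ss))]
        b = Block(id=(block_id := block_id + 1), duration=gap1,
                  gz=GradientPulse("z", 0.0, gap1, -area_ss_half / gap1),
                  gx=GradientPulse("x", 0.0, gap1, -area_read_half / gap1))
        if ky_area != 0.0:
            b.add(GradientPulse("y", 0.0, gap1, ky_area / gap1))
        blocks.append(b)
        ro = Block(id=(block_id := block_id + 1), duration=readout_dur,
                   gx=GradientPulse("x", 0.0, readout_dur, g_read))
        if with_adc:
            ro.add(AcquisitionWindow(0.0, n_fe, dwell, phase=phase))
        if with_recorder:
            ro.add(SinglePointRecorder(readout_dur / 2.0, index=0, phase=phase))
        blocks.append(ro)
        b = Block(id=(block_id := block_id + 1), duration=gap2,
                  gz=GradientPulse("z", 0.0, gap2, -area_ss_half / gap2),
                  gx=GradientPulse("x", 0.0, gap2, -area_read_half / gap2))
        if ky_area != 0.0:
            b.add(GradientPulse("y", 0.0, gap2, -ky_area / gap2))
        blocks.append(b)
        return blocks

    for start, kind, payload in events:
        idle(start - cursor)
        cursor = start
        group_id += 1
        if kind == "ir":
            ir = make_adiabatic_rf(ir_kind, ir_duration, ir_peak_b1, ir_shape,
                                   raster=2e-6)
            block_id += 1
            blk = Block(id=block_id, duration=ir_block_dur, rf=ir,
                        crushers=[SoftwareCrusher(_ceil_us(ir_duration) + g.base_dt)])
            seq.groups.append(BlockGroup(id=group_id, blocks=[blk]))
            cursor += ir_block_dur
        else:
            blocks = []
            for j in range(n_ramp):
                flip = flip_deg * (j + 0.5) / n_ramp
                blocks += bssfp_tr(flip, np.pi * (j % 2), False, 0.0)
            for line in range(n_pe):
                phase = np.pi * ((n_ramp + line) % 2)
                blocks += bssfp_tr(flip_deg, phase, True, ky[line] * dky / g.gamma,
                                   with_recorder=(add_recorders and line == kc_line))
            seq.groups.append(BlockGroup(id=group_id, blocks=blocks))
            cursor += (n_ramp + n_pe) * tr
    idle(n_beats * rr - cursor)

    # recorder ordinals must increase along the timeline
    n_rec = 0
    for _, blk in seq.iter_blocks():
        for r in blk.recorders:
            r.index = n_rec
            n_rec += 1

    seq.header.update({
        "sequence": "molli", "scheme": scheme, "heart_rate_bpm": heart_rate_bpm,
        "te": te, "tr": tr, "flip_deg": flip_deg, "n_images": n_images,
        "n_pe": n_pe, "n_fe": n_fe, "dwell": dwell,
        "fov_fe": g.fov_fe, "fov_pe": g.fov_pe, "trajectory": "cartesian",
        "ky_indices": ky.tolist(), "ti": image_tis,
        "ir_kind": ir_kind, "ir_duration": ir_duration,
        "n_ramp": n_ramp, "duration": n_beats * rr,
        "n_recorders": n_rec,
    })
    seq.validate()
    return seq
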