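"""pulseq-style .seq text I/O (v1.4 dialect, rectangular-gradient subset).

Supported constructs: [VERSION], [DEFINITIONS], [BLOCKS], [RF] (sampled
magnitude/phase/time shapes), [TRAP] with zero ramp times (steep-step
gradients), [ADC], [SHAPES] (uncompressed), and an [EXTENSIONS] section
carrying the simulation-only events of this package (software crushers and
single-point recorders) under declared extension type names.  Units follow
pulseq: RF amplitude Hz (gamma*B1), gradient amplitude Hz/m, delays and
durations us, ADC dwell ns.

``read_pulseq(write_pulseq(seq))`` reproduces every object timing and
amplitude (to 1e-9 relative) and hence an identical discretized timeline;
the block-group structure is flattened to one group per block and nominal
flip-angle metadata is not preserved.  Files using constructs outside the
subset (shaped/ramped gradients, compressed shapes, unknown sections) raise
an explicit unsupported-feature error naming the construct.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .sequence import (AcquisitionWindow, Block, BlockGroup, GlobalParams,
                       GradientPulse, RFPulse, Sequence, SinglePointRecorder,
                       SoftwareCrusher)

__all__ = ["write_pulseq", "read_pulseq", "UnsupportedPulseqFeature"]

_CRUSHER_TYPE = "DESKMRI_CRUSHERS"
_RECORDER_TYPE = "DESKMRI_RECORDERS"


class UnsupportedPulseqFeature(ValueError):
    """A .seq construct outside the supported subset."""


def _fmt(x: float) -> str:
    # 17 significant digits: exact decimal round trip for float64
    return f"{x:.17g}"


class _ShapeTable:
    def __init__(self):
        self.shapes: List[np.ndarray] = []

    def add(self, values: np.ndarray) -> int:
        arr = np.asarray(values, dtype=float)
        for i, s in enumerate(self.shapes):
            if s.shape == arr.shape and np.array_equal(s, arr):
                return i + 1
        self.shapes.append(arr)
        return len(self.shapes)


def write_pulseq(seq: Sequence, path) -> None:
    """Write a sequence as a .seq text file (supported subset)."""
    g = seq.globals
    shapes = _ShapeTable()
    rf_events: List[str] = []
    trap_events: List[str] = []
    adc_events: List[str] = []
    ext_specs: List[str] = []       # extension-list chain lines
    crusher_entries: List[str] = []
    recorder_entries: List[str] = []
    block_lines: List[str] = []

    def rf_id(rf: RFPulse) -> int:
        mag = np.abs(rf.amplitude_samples)
        peak = mag.max()
        pha = np.angle(rf.amplitude_samples)
        mag_id = shapes.add(mag / peak if peak > 0 else mag)
        phase_id = shapes.add(np.mod(pha / (2 * np.pi), 1.0))
        n = len(mag)
        time_id = shapes.add(np.arange(n) * (rf.raster / 1e-6))
        amp_hz = g.gamma * peak
        rf_events.append(
            f"{len(rf_events) + 1} {_fmt(amp_hz)} {mag_id} {phase_id} {time_id} "
            f"{_fmt(rf.start / 1e-6)} {_fmt(rf.freq_offset)} {_fmt(rf.phase_offset)}")
        return len(rf_events)

    def trap_id(grad: GradientPulse) -> int:
        amp_hz_m = g.gamma * grad.amplitude
        trap_events.append(
            f"{len(trap_events) + 1} {_fmt(amp_hz_m)} 0 {_fmt(grad.duration / 1e-6)} 0 "
            f"{_fmt(grad.start / 1e-6)}")
        return len(trap_events)

    def adc_id(adc: AcquisitionWindow) -> int:
        adc_events.append(
            f"{len(adc_events) + 1} {adc.n_samples} {_fmt(adc.dwell / 1e-9)} "
            f"{_fmt(adc.start / 1e-6)} 0 {_fmt(adc.phase)}")
        return len(adc_events)

    def ext_id(blk: Block) -> int:
        if not blk.crushers and not blk.recorders:
            return 0
        first = 0
        # chain entries in reverse so `first` points at the head
        for rec in reversed(blk.recorders):
            recorder_entries.append(
                f"{len(recorder_entries) + 1} {_fmt(rec.time_point / 1e-6)} "
                f"{_fmt(rec.phase)}")
            ext_specs.append(f"{len(ext_specs) + 1} 2 {len(recorder_entries)} {first}")
            first = len(ext_specs)
        for cr in reversed(blk.crushers):
            crusher_entries.append(
                f"{len(crusher_entries) + 1} {_fmt(cr.time_point / 1e-6)}")
            ext_specs.append(f"{len(ext_specs) + 1} 1 {len(crusher_entries)} {first}")
            first = len(ext_specs)
        return first

    for num, (_, blk) in enumerate(seq.iter_blocks(), start=1):
        rid = rf_id(blk.rf) if blk.rf is not None else 0
        gids = [trap_id(getattr(blk, ax)) if getattr(blk, ax) is not None else 0
                for ax in ("gx", "gy", "gz")]
        aid = adc_id(blk.adc) if blk.adc is not None else 0
        eid = ext_id(blk)
        dur = int(round(blk.duration / 1e-6))
        block_lines.append(
            f"{num} {dur} {rid} {gids[0]} {gids[1]} {gids[2]} {aid} {eid}")

    lines = ["# Pulseq sequence file (deskmri subset)", "", "[VERSION]",
             "major 1", "minor 4", "revision 0", "", "[DEFINITIONS]",
             f"FOV {_fmt(g.fov_fe)} {_fmt(g.fov_pe)} {_fmt(g.slice_thickness)}",
             "BlockDurationRaster 1e-06",
             "RadiofrequencyRasterTime 1e-06",
             "GradientRasterTime 1e-06",
             f"AdcRasterTime {_fmt(g.base_dt)}",
             f"deskmri_MatrixFE {g.n_fe}",
             f"deskmri_MatrixPE {g.n_pe}",
             f"deskmri_ReceiverBW {_fmt(g.receiver_bw)}",
             f"deskmri_Gamma {_fmt(g.gamma)}",
             f"deskmri_B0 {_fmt(g.b0)}",
             f"deskmri_GMax {_fmt(g.g_max)}",
             f"deskmri_BaseDt {_fmt(g.base_dt)}", ""]
    lines += ["[BLOCKS]", "# NUM DUR RF GX GY GZ ADC EXT"] + block_lines + [""]
    if rf_events:
        lines += ["[RF]", "# id amp mag_id phase_id time_id delay freq phase"]
        lines += rf_events + [""]
    if trap_events:
        lines += ["[TRAP]", "# id amp rise flat fall delay"] + trap_events + [""]
    if adc_events:
        lines += ["[ADC]", "# id num dwell delay freq phase"] + adc_events + [""]
    if ext_specs:
        lines += ["[EXTENSIONS]", f"extension {_CRUSHER_TYPE} 1",
                  f"extension {_RECORDER_TYPE} 2",
                  "# id type ref next"] + ext_specs + [""]
        lines += [f"[{_CRUSHER_TYPE}]", "# id time_us"] + crusher_entries + [""]
        lines += [f"[{_RECORDER_TYPE}]", "# id time_us phase"] + recorder_entries + [""]
    if shapes.shapes:
        lines += ["[SHAPES]", ""]
        for i, s in enumerate(shapes.shapes, start=1):
            lines += [f"shape_id {i}", f"num_samples {len(s)}"]
            lines += [_fmt(v) for v in s] + [""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_sections(path) -> Dict[str, List[str]]:
    sections: Dict[str, List[str]] = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                sections[current] = []
            elif current is not None:
                sections[current].append(line)
    return sections


def read_pulseq(path) -> Sequence:
    """Read a .seq file of the supported subset into a Sequence."""
    sections = _parse_sections(path)
    known = {"VERSION", "DEFINITIONS", "BLOCKS", "RF", "TRAP", "ADC",
             "EXTENSIONS", "SHAPES", _CRUSHER_TYPE, _RECORDER_TYPE}
    for sec in sections:
        if sec not in known:
            if sec in ("GRADIENTS", "GRAD"):
                raise UnsupportedPulseqFeature(
                    f"arbitrary-shape gradients ([{sec}]) are not supported; "
                    "only zero-ramp [TRAP] gradients are")
            raise UnsupportedPulseqFeature(f"section [{sec}] is not supported")
    if "BLOCKS" not in sections:
        raise UnsupportedPulseqFeature("file has no [BLOCKS] section")

    defs: Dict[str, List[str]] = {}
    for line in sections.get("DEFINITIONS", []):
        parts = line.split()
        defs[parts[0]] = parts[1:]

    def d(key, default):
        return float(defs[key][0]) if key in defs else default

    gamma = d("deskmri_Gamma", 42.577478518e6)
    fov = defs.get("FOV", ["0.4", "0.4", "0.01"])
    g = GlobalParams(
        matrix_size=(int(d("deskmri_MatrixFE", 128)), int(d("deskmri_MatrixPE", 128))),
        fov=(float(fov[0]), float(fov[1])), slice_thickness=float(fov[2]),
        receiver_bw=d("deskmri_ReceiverBW", 1e5), gamma=gamma,
        b0=d("deskmri_B0", 1.5), g_max=d("deskmri_GMax", 0.04),
        base_dt=d("deskmri_BaseDt", 1e-6),
    )

    # shapes
    shapes: Dict[int, np.ndarray] = {}
    tokens = sections.get("SHAPES", [])
    i = 0
    while i < len(tokens):
        if not tokens[i].startswith("shape_id"):
            raise UnsupportedPulseqFeature(f"malformed [SHAPES] near {tokens[i]!r}")
        sid = int(tokens[i].split()[1])
        n = int(tokens[i + 1].split()[1])
        vals = np.array([float(v) for v in tokens[i + 2:i + 2 + n]])
        if len(vals) != n:
            raise UnsupportedPulseqFeature(
                "compressed shapes are not supported (sample count mismatch)")
        shapes[sid] = vals
        i += 2 + n

    rf_events: Dict[int, RFPulse] = {}
    for line in sections.get("RF", []):
        p = line.split()
        rid, amp, mag_id, phase_id, time_id = (int(p[0]), float(p[1]), int(p[2]),
                                               int(p[3]), int(p[4]))
        delay_us, freq, phase = float(p[5]), float(p[6]), float(p[7])
        mag = shapes[mag_id]
        pha = shapes[phase_id] * 2 * np.pi
        tshape = shapes[time_id]
        steps = np.diff(tshape)
        if len(steps) and not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise UnsupportedPulseqFeature("non-uniform RF time shapes")
        raster = (steps[0] if len(steps) else 1.0) * 1e-6
        b1 = (amp / g.gamma) * mag * np.exp(1j * pha)
        rf_events[rid] = RFPulse(start=delay_us * 1e-6, duration=len(mag) * raster,
                                 amplitude_samples=b1, raster=raster,
                                 freq_offset=freq, phase_offset=phase)

    trap_events: Dict[int, tuple] = {}
    for line in sections.get("TRAP", []):
        p = line.split()
        tid, amp, rise, flat, fall, delay = (int(p[0]), float(p[1]), float(p[2]),
                                             float(p[3]), float(p[4]), float(p[5]))
        if rise != 0 or fall != 0:
            raise UnsupportedPulseqFeature(
                "trapezoids with nonzero ramp times are not supported "
                "(steep-step gradients only)")
        trap_events[tid] = (delay * 1e-6, flat * 1e-6, amp / g.gamma)

    adc_events: Dict[int, AcquisitionWindow] = {}
    for line in sections.get("ADC", []):
        p = line.split()
        aid, num, dwell_ns, delay_us = int(p[0]), int(p[1]), float(p[2]), float(p[3])
        phase = float(p[5]) if len(p) > 5 else 0.0
        adc_events[aid] = AcquisitionWindow(start=delay_us * 1e-6, n_samples=num,
                                            dwell=dwell_ns * 1e-9, phase=phase)

    ext_types: Dict[int, str] = {}
    ext_chain: Dict[int, tuple] = {}
    for line in sections.get("EXTENSIONS", []):
        p = line.split()
        if p[0] == "extension":
            ext_types[int(p[2])] = p[1]
        else:
            ext_chain[int(p[0])] = (int(p[1]), int(p[2]), int(p[3]))
    crushers = {int(l.split()[0]): float(l.split()[1]) * 1e-6
                for l in sections.get(_CRUSHER_TYPE, [])}
    recorders = {int(l.split()[0]): (float(l.split()[1]) * 1e-6, float(l.split()[2]))
                 for l in sections.get(_RECORDER_TYPE, [])}

    seq = Sequence(globals=g)
    n_rec = 0
    for line in sections["BLOCKS"]:
        p = [int(float(v)) for v in line.split()]
        num, dur, rid, gxid, gyid, gzid, aid = p[:7]
        eid = p[7] if len(p) > 7 else 0
        blk = Block(id=num, duration=dur * 1e-6)
        if rid:
            blk.add(rf_events[rid])
        for ax, gid in zip("xyz", (gxid, gyid, gzid)):
            if gid:
                delay, flat, amp = trap_events[gid]
                blk.add(GradientPulse(ax, delay, flat, amp))
        if aid:
            blk.add(adc_events[aid])
        while eid:
            etype, ref, nxt = ext_chain[eid]
            name = ext_types.get(etype, "")
            if name == _CRUSHER_TYPE:
                blk.add(SoftwareCrusher(crushers[ref]))
            elif name == _RECORDER_TYPE:
                t, ph = recorders[ref]
                blk.add(SinglePointRecorder(t, index=n_rec, phase=ph))
                n_rec += 1
            else:
                raise UnsupportedPulseqFeature(
                    f"extension type {name or etype!r} is not supported")
            eid = nxt
        seq.groups.append(BlockGroup(id=num, blocks=[blk]))
    return seq
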