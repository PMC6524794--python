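import numpy as np
import pytest

import deskmri as dm
from deskmri.builders import parse_molli_scheme


@pytest.mark.parametrize("matrix, te_ms, duration_s", [
    (128, 2.23, 1.28),
    (256, 2.94, 2.56),
    (512, 4.43, 5.12),
])
def test_gre_min_te_rule_reproduces_printed_values(matrix, te_ms, duration_s):
    """The three published (TE, duration) pairs of the 40 cm / 100 kHz /
    40 mT/m spoiled GRE family, reproduced by the min-TE rule."""
    g = dm.GlobalParams(matrix_size=matrix, fov=0.4, receiver_bw=1e5,
                        g_max=0.04, slice_thickness=0.01)
    seq = dm.build_gre(g, flip_deg=15.0, tr=10e-3)
    assert seq.header["te"] * 1e3 == pytest.approx(te_ms, abs=0.03)
    assert seq.header["duration"] == pytest.approx(duration_s, abs=1e-9)


def test_gre_pe_amplitudes_follow_linear_ordering():
    g = dm.GlobalParams(matrix_size=8, fov=0.2)
    seq = dm.build_gre(g, tr=5e-3)
    amps = []
    for grp in seq.groups:
        gy = grp.blocks[1].gy
        amps.append(0.0 if gy is None else gy.amplitude)
    areas = np.array(amps) * seq.groups[0].blocks[1].duration
    ky = areas * g.gamma * g.fov_pe
    assert np.allclose(ky, np.arange(8) - 4, atol=1e-6)


def test_gre_infeasible_gradient_demand():
    g = dm.GlobalParams(matrix_size=64, fov=0.02, receiver_bw=1e5, g_max=0.04)
    with pytest.raises(ValueError, match="g_max"):
        dm.build_gre(g)


def test_gre_has_crusher_every_tr(small_gre):
    seq = small_gre["seq"]
    n_crush = sum(len(b.crushers) for _, b in seq.iter_blocks())
    assert n_crush == seq.globals.n_pe


@pytest.mark.parametrize("scheme, expected", [
    ("5(3p)3", (5, 3, 3)),
    ("3(3)5", (3, 3, 5)),
    ("1(0p)0", (1, 0, 0)),
])
def test_scheme_parsing(scheme, expected):
    assert parse_molli_scheme(scheme) == expected


def test_malformed_scheme_raises():
    for bad in ("5-3-3", "(3p)3", "5(3p", "abc"):
        with pytest.raises(ValueError, match="malformed"):
            parse_molli_scheme(bad)


@pytest.fixture(scope="module")
def molli_seq():
    g = dm.GlobalParams(matrix_size=(32, 24), fov=(0.36, 0.27),
                        slice_thickness=6e-3, receiver_bw=2e5)
    return dm.build_molli(g, scheme="5(3p)3", heart_rate_bpm=60.0,
                          add_recorders=True)


def test_molli_image_and_beat_count(molli_seq):
    hdr = molli_seq.header
    assert hdr["n_images"] == 8
    assert hdr["duration"] >= 11.0            # spans 11 heartbeats at 60 bpm
    assert len(hdr["ti"]) == 8


def test_molli_recorder_count_equals_images(molli_seq):
    assert molli_seq.header["n_recorders"] == 8


def test_molli_effective_ti_spacing(molli_seq):
    ti = np.array(molli_seq.header["ti"])
    # five readouts after IR1 separated by one heartbeat, then three after IR2
    assert np.allclose(np.diff(ti[:5]), 1.0, atol=1e-9)
    assert np.allclose(np.diff(ti[5:]), 1.0, atol=1e-9)
    assert ti[0] == pytest.approx(0.100)
    assert ti[5] == pytest.approx(0.180)


def test_molli_single_image_scheme():
    g = dm.GlobalParams(matrix_size=(32, 24), fov=(0.36, 0.27),
                        slice_thickness=6e-3, receiver_bw=2e5)
    seq = dm.build_molli(g, scheme="1(0p)0")
    assert seq.header["n_images"] == 1
    n_rf = sum(1 for _, b in seq.iter_blocks() if b.rf is not None)
    # one inversion + ramp-up + one line per phase-encode
    assert n_rf == 1 + 10 + 24


def test_molli_rf_phase_alternates(molli_seq):
    phases = [b.rf.phase_offset for _, b in molli_seq.iter_blocks()
              if b.rf is not None and b.rf.flip_angle != 180.0]
    signs = np.cos(phases[:34])               # first image: ramp + lines
    assert np.allclose(signs[::2], 1.0) and np.allclose(signs[1::2], -1.0)


def test_molli_unreachable_ti_raises():
    g = dm.GlobalParams(matrix_size=(64, 120), fov=(0.36, 0.27),
                        slice_thickness=6e-3, receiver_bw=2e5)
    with pytest.raises(ValueError, match="unreachable"):
        dm.build_molli(g, scheme="5(3p)3", ti1=0.050)
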