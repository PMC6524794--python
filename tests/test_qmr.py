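import numpy as np
import pytest

import deskmri as dm
from deskmri.engine import SignalDictionary
from deskmri.qmr import molli_fit, segment_annulus, squaremr_match

MOLLI_TIS = np.array([0.1, 1.1, 2.1, 3.1, 4.1, 0.18, 1.18, 2.18])


def ir_signal(a, b, t1_star, ti):
    return a - b * np.exp(-np.asarray(ti) / t1_star)


def test_exact_model_recovery_reference_case():
    """Noiseless magnitude samples from A=2, B=4, T1*=0.5 at the 8 MOLLI TIs
    recover all parameters and T1 = T1*(B/A - 1) = 0.5 s."""
    s = np.abs(ir_signal(2.0, 4.0, 0.5, MOLLI_TIS))
    fit = molli_fit(s, MOLLI_TIS)
    assert fit.a == pytest.approx(2.0, rel=1e-6)
    assert fit.b == pytest.approx(4.0, rel=1e-6)
    assert fit.t1_star == pytest.approx(0.5, rel=1e-6)
    assert fit.t1 == pytest.approx(0.5, rel=1e-6)


def test_exact_model_recovery_random_draws(rng):
    """Parameter recovery to <= 1e-6 relative across 100 random draws."""
    for _ in range(100):
        a = rng.uniform(0.5, 3.0)
        b = a * rng.uniform(1.6, 2.0)
        tau = rng.uniform(0.2, 2.5)
        s = np.abs(ir_signal(a, b, tau, MOLLI_TIS))
        fit = molli_fit(s, MOLLI_TIS)
        assert fit.t1_star == pytest.approx(tau, rel=1e-6)
        assert fit.t1 == pytest.approx(tau * (b / a - 1), rel=1e-6)


def test_no_inversion_component_gives_zero_t1():
    s = np.abs(ir_signal(2.0, 2.0, 0.5, MOLLI_TIS))
    fit = molli_fit(s, MOLLI_TIS)
    assert fit.t1 == pytest.approx(0.0, abs=1e-6)


def test_too_few_points_raises():
    with pytest.raises(ValueError):
        molli_fit([1.0, 2.0], [0.1, 0.2])


def test_make_t1_map_uniform_stack():
    ti = MOLLI_TIS
    sig = np.abs(ir_signal(2.0, 4.0, 0.5, ti))
    stack = np.tile(sig[:, None, None], (1, 6, 6))
    rois = dm.ROISpec(masks=[np.ones((6, 6), dtype=bool)], labels=["all"])
    t1_map, stats = dm.make_t1_map(stack, ti, rois=rois)
    assert np.allclose(t1_map, 0.5, atol=1e-6)
    mean, sd, n = stats["all"]
    assert mean == pytest.approx(0.5, abs=1e-6)
    assert sd == pytest.approx(0.0, abs=1e-9)
    assert n == 36


def test_empty_roi_raises():
    stack = np.ones((8, 4, 4))
    rois = dm.ROISpec(masks=[np.zeros((4, 4), dtype=bool)])
    with pytest.raises(ValueError, match="empty"):
        dm.make_t1_map(stack, MOLLI_TIS, rois=rois)


@pytest.fixture
def annulus_rois():
    return segment_annulus((48, 48), (0.003, 0.003), (0.0, 0.0),
                           r_in=0.020, r_out=0.028)


def test_segments_are_disjoint(annulus_rois):
    total = np.zeros((48, 48), dtype=int)
    for m in annulus_rois.masks:
        total += m
    assert total.max() == 1


def test_segments_cover_central_wall(annulus_rois):
    """The union covers at least 90% of the radially central wall region
    minus the sector borders."""
    yy = (np.arange(48) - 24)[:, None] * 0.003
    xx = (np.arange(48) - 24)[None, :] * 0.003
    r = np.hypot(xx, yy)
    central = (r >= 0.022) & (r <= 0.026)
    union = np.any(annulus_rois.masks, axis=0)
    # angular ROI fraction is 50%, so expect about half the central band
    assert union[central].sum() >= 0.9 * 0.5 * central.sum()
    assert not union[~((r >= 0.020) & (r <= 0.028))].any()


def test_rotating_by_sixty_degrees_permutes_segments():
    rois = segment_annulus((96, 96), (0.0015, 0.0015), (0.0, 0.0),
                           0.020, 0.028)
    yy = (np.arange(96) - 48)[:, None] * 0.0015
    xx = (np.arange(96) - 48)[None, :] * 0.0015
    ang = np.arctan2(xx, yy) - np.pi / 3.0     # rotate by one sector
    r = np.hypot(xx, yy)
    rot_mask_1 = segment_annulus((96, 96), (0.0015, 0.0015), (0.0, 0.0),
                                 0.020, 0.028).masks[1]
    # segment 2's pixels, rotated by 60 degrees, fall into segment 1's sector
    d = np.angle(np.exp(1j * ang))
    sector = 2 * np.pi / 6
    in_seg1_after_rot = np.abs(d) <= 0.5 * sector / 2
    assert (rot_mask_1 & ~((r >= 0.020) & (r <= 0.028))).sum() == 0
    overlap = (rot_mask_1 & in_seg1_after_rot).sum() / rot_mask_1.sum()
    assert overlap > 0.95


def _toy_dictionary():
    t1s = np.array([0.7, 0.9, 1.1, 1.3])
    t2s = np.array([0.04, 0.05])
    ti = MOLLI_TIS
    entries = []
    et1, et2 = [], []
    for t1 in t1s:
        for t2 in t2s:
            tau = t1 * (1 - 1.5 * t2)           # distinct synthetic curves
            entries.append(ir_signal(1.0, 1.9, tau, np.sort(ti))[
                np.argsort(np.argsort(ti))])
            et1.append(t1)
            et2.append(t2)
    return SignalDictionary(
        t1_values=t1s, t2_values=t2s, b0_values=np.array([0.0]),
        slice_positions=np.array([0.0]),
        signals=np.array(entries, dtype=complex),
        entry_t1=np.array(et1), entry_t2=np.array(et2),
        header={"ti": ti.tolist()})


def test_dictionary_self_match_is_exact():
    d = _toy_dictionary()
    t1, t2 = squaremr_match(np.abs(d.signals.real), d)
    assert np.array_equal(t1, d.entry_t1)
    assert np.array_equal(t2, d.entry_t2)


def test_small_perturbation_matches_same_or_adjacent(rng):
    d = _toy_dictionary()
    base = np.abs(d.signals.real)
    noise = rng.normal(size=base.shape)
    noise *= 0.01 * np.linalg.norm(base, axis=1, keepdims=True) / \
        np.linalg.norm(noise, axis=1, keepdims=True)
    t1, t2 = squaremr_match(base + noise, d)
    assert np.all(np.abs(t1 - d.entry_t1) <= 0.21)
    assert np.all(np.abs(t2 - d.entry_t2) <= 0.011)


def test_zero_signal_is_flagged_not_matched():
    d = _toy_dictionary()
    t1, t2 = squaremr_match(np.zeros((1, d.n_points)), d)
    assert np.isnan(t1[0]) and np.isnan(t2[0])


def test_length_mismatch_raises():
    d = _toy_dictionary()
    with pytest.raises(ValueError, match="length"):
        squaremr_match(np.ones((1, 5)), d)
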