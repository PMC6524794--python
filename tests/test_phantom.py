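import numpy as np
import pytest

import deskmri as dm
from deskmri.phantom import BRAIN_TISSUES_1P5T


def brute_force_cylinder_count(radius, height, spacing):
    """Independent point-in-cylinder rasterization."""

    def centers(extent):
        n = max(int(np.floor(2 * extent / spacing)), 1)
        return (np.arange(n) - (n - 1) / 2.0) * spacing

    count = 0
    for x in centers(radius):
        for y in centers(radius):
            if x * x + y * y <= radius ** 2:
                count += len(centers(height / 2))
    return count


def test_cylinder_count_matches_brute_force(rng):
    for _ in range(10):
        r = rng.uniform(0.01, 0.06)
        h = rng.uniform(0.002, 0.02)
        s = rng.uniform(0.001, 0.005)
        ph = dm.make_cylinder_phantom(r, h, s, 0.9, 0.05)
        assert ph.n == brute_force_cylinder_count(r, h, s)
        assert np.all(ph.positions[:, 0] ** 2 + ph.positions[:, 1] ** 2
                      <= r ** 2 + 1e-12)


def test_annulus_count_matches_brute_force(rng):
    for _ in range(10):
        outer = rng.uniform(0.03, 0.08)
        wall = rng.uniform(0.004, outer / 2)
        s = rng.uniform(0.0008, 0.003)
        ph = dm.make_annulus_phantom(outer, wall, 0.002, s, 0.9, 0.05)
        r = np.hypot(ph.positions[:, 0], ph.positions[:, 1])
        r_out, r_in = outer / 2, outer / 2 - wall
        assert np.all((r <= r_out + 1e-12) & (r > r_in - 1e-12))
        full = dm.make_cylinder_phantom(r_out, 0.002, s, 0.9, 0.05)
        inner = np.hypot(full.positions[:, 0], full.positions[:, 1]) <= r_in
        assert ph.n == full.n - inner.sum()


def test_annulus_keeps_lumen_empty():
    ph = dm.make_annulus_phantom(0.056, 0.008, 0.002, 0.001, 0.9, 0.05)
    assert np.hypot(ph.positions[:, 0], ph.positions[:, 1]).min() > 0.020


def test_full_wall_annulus_is_solid():
    a = dm.make_annulus_phantom(0.04, 0.02, 0.002, 0.001, 0.9, 0.05)
    c = dm.make_cylinder_phantom(0.02, 0.002, 0.001, 0.9, 0.05)
    assert a.n == c.n


def test_spacing_larger_than_geometry_raises():
    with pytest.raises(ValueError, match="empty"):
        dm.make_cylinder_phantom(0.005, 0.002, 0.02, 0.9, 0.05)


def test_two_cylinders_have_exactly_two_property_pairs():
    ph = dm.concat_phantoms([
        dm.make_cylinder_phantom(0.05, 0.002, 0.002, 0.9, 0.05, center=(-0.06, 0, 0)),
        dm.make_cylinder_phantom(0.05, 0.002, 0.002, 1.5, 0.25, center=(+0.06, 0, 0)),
    ])
    pairs = set(zip(ph.t1.tolist(), ph.t2.tolist()))
    assert pairs == {(0.9, 0.05), (1.5, 0.25)}


def test_brainlike_phantom_has_seven_tissues():
    ph = dm.make_brainlike_phantom(spacing=3e-3)
    pairs = set(zip(ph.t1.tolist(), ph.t2.tolist()))
    assert len(pairs) == 7
    assert len(ph.meta["labels"]) == 7


def test_brainlike_uniform_table_is_single_tissue_ellipsoid():
    table = {lab: (1.0, 0.1, 1.0) for lab in BRAIN_TISSUES_1P5T}
    ph = dm.make_brainlike_phantom(spacing=3e-3, tissue_table=table)
    assert set(ph.t1.tolist()) == {1.0}
    assert set(ph.t2.tolist()) == {0.1}


def test_brainlike_reproducible_under_seed():
    a = dm.make_brainlike_phantom(spacing=3e-3, seed=4)
    b = dm.make_brainlike_phantom(spacing=3e-3, seed=4)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.meta["label_index"], b.meta["label_index"])


def test_brainlike_missing_label_raises():
    bad = dict(BRAIN_TISSUES_1P5T)
    bad.pop("white")
    with pytest.raises(ValueError, match="7 labels"):
        dm.make_brainlike_phantom(tissue_table=bad)


def test_linear_b0_map_extremes_and_center():
    ph = dm.make_annulus_phantom(0.056, 0.008, 0.002, 0.001, 0.9, 0.05)
    ph = dm.make_linear_b0_map(ph, 150.0, axis=1)
    y = ph.positions[:, 1]
    assert ph.b0_offset_hz[np.argmax(y)] == pytest.approx(150.0, abs=150 * 0.05)
    assert ph.b0_offset_hz[np.argmin(y)] == pytest.approx(-150.0, abs=150 * 0.05)
    assert abs(ph.b0_offset_hz.mean()) < 1.0        # symmetric phantom
    zero = dm.make_linear_b0_map(ph, 0.0, axis=1)
    assert np.all(zero.b0_offset_hz == 0)


def test_linear_b0_map_degenerate_extent():
    ph = dm.make_cylinder_phantom(0.05, 0.002, 0.002, 0.9, 0.05)
    with pytest.raises(ValueError, match="extent"):
        dm.make_linear_b0_map(ph, 150.0, axis=2)    # single z layer


def test_displace_identity_at_t0():
    pos = np.array([[0.01, 0.02, 0.0], [-0.03, 0.0, 0.01]])
    for mo in (dm.MotionSpec("translation", amplitude_d=0.05, frequency=1.0),
               dm.MotionSpec("rotation", theta_max_deg=20.0, frequency=1.0)):
        assert np.allclose(dm.displace(pos, 0.0, mo), pos)


def test_rotation_is_an_isometry(rng):
    pos = rng.uniform(-0.05, 0.05, (30, 3))
    mo = dm.MotionSpec("rotation", theta_max_deg=17.0, center=(0.01, -0.02),
                       frequency=2.0)
    for t in rng.uniform(0, 1, 5):
        moved = dm.displace(pos, t, mo)
        d0 = np.hypot(pos[:, 0] - 0.01, pos[:, 1] + 0.02)
        d1 = np.hypot(moved[:, 0] - 0.01, moved[:, 1] + 0.02)
        assert np.allclose(d0, d1, atol=1e-15)
        assert np.array_equal(moved[:, 2], pos[:, 2])


def test_rotation_quarter_turn_closed_form():
    mo = dm.MotionSpec("rotation", theta_max_deg=90.0, center=(0.0, 0.0),
                       frequency=0.25)           # sin(2 pi f t) = 1 at t = 1
    out = dm.displace(np.array([[1.0, 0.0, 0.0]]), 1.0, mo)
    assert np.allclose(out[0], [0.0, 1.0, 0.0], atol=1e-12)


def test_motion_is_periodic(rng):
    pos = rng.uniform(-0.05, 0.05, (10, 3))
    for mo in (dm.MotionSpec("translation", axis=(0, 1, 0), amplitude_d=0.02,
                             frequency=3.0),
               dm.MotionSpec("rotation", theta_max_deg=10.0, frequency=3.0)):
        a = dm.displace(pos, 0.123, mo)
        b = dm.displace(pos, 0.123 + 1 / 3.0, mo)
        assert np.allclose(a, b, atol=1e-12)


def test_translation_displaces_all_points_identically(rng):
    pos = rng.uniform(-0.05, 0.05, (20, 3))
    mo = dm.MotionSpec("translation", axis=(1, 0, 0), amplitude_d=0.05,
                       frequency=1.0)
    moved = dm.displace(pos, 0.2, mo)
    delta = moved - pos
    assert np.allclose(delta, delta[0], atol=1e-15)
    assert delta[0, 0] == pytest.approx(0.05 * np.sin(2 * np.pi * 0.2))


def test_optional_fields_default_to_noop(small_gre):
    """Explicit zero chemical shift / B0 map and disabled MT leave the
    simulation bitwise identical to the bare phantom."""
    tl = small_gre["compressed"]
    base = dm.make_cylinder_phantom(0.05, 0.004, 0.02, 0.9, 0.05)
    n = base.n
    decorated = dm.IsochromatSet(
        positions=base.positions, t1=base.t1, t2=base.t2, pd=base.pd,
        chem_shift_hz=np.zeros(n), b0_offset_hz=np.zeros(n))
    decorated = decorated.with_mt(dm.MTParams(bound_fraction=0.0))
    a = dm.simulate(tl, base, dm.SimConfig())
    b = dm.simulate(tl, decorated, dm.SimConfig())
    assert np.array_equal(a.samples, b.samples)
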