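import json

import numpy as np
import pytest

import deskmri as dm
from deskmri import recipes


def test_unknown_recipe_raises():
    with pytest.raises(ValueError, match="unknown recipe"):
        recipes.run_experiment("not-a-recipe")


def test_validate_inputs_well_formed(small_gre, small_disk_phantom):
    issues = recipes.validate_inputs(phantom=small_disk_phantom,
                                     sequence=small_gre["seq"],
                                     config=dm.SimConfig())
    assert issues == []


def test_validate_inputs_t2_exceeds_t1():
    ph = dm.IsochromatSet(positions=np.zeros((2, 3)), t1=[0.5, 1.0],
                          t2=[0.6, 0.05], pd=[1.0, 1.0])
    issues = recipes.validate_inputs(phantom=ph)
    assert any(i["code"] == "t2_exceeds_t1" for i in issues)


def test_validate_inputs_raster_mismatch():
    g = dm.GlobalParams.__new__(dm.GlobalParams)   # bypass checked init
    g.matrix_size, g.fov = 16, 0.2
    g.slice_thickness, g.receiver_bw = 0.01, 3e6   # 1/3 us dwell
    g.gamma, g.b0, g.g_max, g.base_dt = dm.GAMMA_1H, 1.5, 0.04, 1e-6
    seq = dm.Sequence(globals=g)
    issues = recipes.validate_inputs(sequence=seq)
    assert any(i["code"] == "raster_mismatch" for i in issues)


def test_squaremr_recipe_deterministic_under_seed():
    a = recipes.run_experiment("squaremr-dict", seed=3,
                               overrides={"t1_axis_ms": (800, 1200, 200),
                                          "t2_axis_ms": (40, 80, 40),
                                          "n_slice": 2})
    b = recipes.run_experiment("squaremr-dict", seed=3,
                               overrides={"t1_axis_ms": (800, 1200, 200),
                                          "t2_axis_ms": (40, 80, 40),
                                          "n_slice": 2})
    pa = {k: v for k, v in a.items() if not k.startswith("_")}
    pb = {k: v for k, v in b.items() if not k.startswith("_")}
    assert json.dumps(pa, sort_keys=True, default=float) == \
        json.dumps(pb, sort_keys=True, default=float)
    assert np.array_equal(a["_dictionary"].signals, b["_dictionary"].signals)


def test_motion_theta_zero_reproduces_static_image_bitwise():
    moving = recipes.gre_motion(seed=0, matrix=16, theta_max_deg=0.0,
                                spacing=8e-3)
    g = dm.GlobalParams(matrix_size=16, fov=0.24, slice_thickness=0.01,
                        receiver_bw=1e5, b0=1.5)
    seq = dm.build_gre(g, tr=8e-3)
    ph = dm.make_brainlike_phantom(shape=(0.14, 0.17), spacing=8e-3, seed=0)
    ks = dm.simulate(dm.compress(dm.discretize(seq)), ph, dm.SimConfig(),
                     header=seq.header)
    static = dm.reconstruct(ks).pixels[0]
    assert np.array_equal(moving["_image"], static)


def test_motion_produces_ghosting():
    """Rotational motion spreads energy outside the static support."""
    static = recipes.gre_motion(seed=0, matrix=16, theta_max_deg=0.0,
                                spacing=8e-3)
    moving = recipes.gre_motion(seed=0, matrix=16, theta_max_deg=20.0,
                                frequency=7.0, spacing=8e-3)
    diff = np.abs(moving["_image"] - static["_image"])
    assert diff.max() > 0.01 * static["_image"].max()


def test_coil_recipe_rss_consistency():
    out = recipes.gre_coils(seed=0, matrix=16, n_coils=4, spacing=8e-3)
    rss = np.sqrt((out["_per_coil"] ** 2).sum(axis=0))
    assert np.allclose(rss, out["_rss"], rtol=1e-9)
    assert out["_per_coil"].shape[0] == 4


def test_brainlike_recipe_summary(tmp_path):
    out = recipes.run_experiment("gre-brainlike", seed=0,
                                 overrides={"matrix": 16, "spacing": 6e-3},
                                 outdir=tmp_path)
    assert out["n_tissues"] == 7
    assert out["image_energy"] > 0
    summary = json.loads((tmp_path / "gre-brainlike-summary.json").read_text())
    assert summary["experiment"] == "gre-brainlike"
    assert "image_energy" in summary


def test_cli_build_and_validate(tmp_path):
    from click.testing import CliRunner
    from deskmri.cli import main

    runner = CliRunner()
    seq_path = tmp_path / "gre.seq"
    res = runner.invoke(main, ["build-seq", "gre", "--matrix", "16",
                               "--fov", "0.2", "--out", str(seq_path)])
    assert res.exit_code == 0, res.output
    assert seq_path.exists()
    ph_path = tmp_path / "ph.h5"
    res = runner.invoke(main, ["make-phantom", "cylinder", "--spacing", "0.01",
                               "--out", str(ph_path)])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, ["validate", "--phantom", str(ph_path),
                               "--seq", str(seq_path)])
    assert res.exit_code == 0, res.output
    assert json.loads(res.output) == []
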