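"""HDF5 containers for phantoms, k-space data and signal dictionaries.

All quantities are SI; units are recorded as dataset attributes and headers
are stored as JSON strings, so containers are self-describing.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .engine import KSpaceData, SignalDictionary
from .phantom import IsochromatSet, MotionSpec

__all__ = ["save_phantom", "load_phantom", "save_kspace", "load_kspace",
           "save_dictionary", "load_dictionary", "save_nifti"]


def save_phantom(phantom: IsochromatSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=phantom.positions).attrs["units"] = "m"
        f.create_dataset("t1", data=phantom.t1).attrs["units"] = "s"
        f.create_dataset("t2", data=phantom.t2).attrs["units"] = "s"
        f.create_dataset("pd", data=phantom.pd).attrs["units"] = "a.u."
        if phantom.chem_shift_hz is not None:
            f.create_dataset("chem_shift", data=phantom.chem_shift_hz).attrs["units"] = "Hz"
        if phantom.b0_offset_hz is not None:
            f.create_dataset("b0_offset_hz", data=phantom.b0_offset_hz).attrs["units"] = "Hz"
        if phantom.mt is not None:
            grp = f.create_group("mt")
            grp.create_dataset("f", data=phantom.mt["bound_fraction"])
            grp.create_dataset("k", data=phantom.mt["k_exchange"]).attrs["units"] = "1/s"
            grp.create_dataset("t1s", data=phantom.mt["t1_semisolid"]).attrs["units"] = "s"
            grp.create_dataset("t2s", data=phantom.mt["t2_semisolid"]).attrs["units"] = "s"
        if phantom.sens is not None:
            f.create_dataset("sens", data=phantom.sens)
        if phantom.motion is not None:
            mo = phantom.motion
            f.attrs["motion"] = json.dumps({
                "kind": mo.kind, "axis": list(mo.axis), "amplitude_d": mo.amplitude_d,
                "theta_max_deg": mo.theta_max_deg, "center": list(mo.center),
                "frequency": mo.frequency})
        f.attrs["meta"] = json.dumps(phantom.meta, default=str)


def load_phantom(path) -> IsochromatSet:
    with h5py.File(path, "r") as f:
        kw = dict(
            positions=f["positions"][()], t1=f["t1"][()], t2=f["t2"][()],
            pd=f["pd"][()],
        )
        if "chem_shift" in f:
            kw["chem_shift_hz"] = f["chem_shift"][()]
        if "b0_offset_hz" in f:
            kw["b0_offset_hz"] = f["b0_offset_hz"][()]
        if "mt" in f:
            kw["mt"] = {"bound_fraction": f["mt/f"][()], "k_exchange": f["mt/k"][()],
                        "t1_semisolid": f["mt/t1s"][()], "t2_semisolid": f["mt/t2s"][()]}
        if "sens" in f:
            kw["sens"] = f["sens"][()]
        if "motion" in f.attrs:
            kw["motion"] = MotionSpec(**json.loads(f.attrs["motion"]))
        kw["meta"] = json.loads(f.attrs.get("meta", "{}"))
    return IsochromatSet(**kw)


def save_kspace(kspace: KSpaceData, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=kspace.samples)
        f.attrs["header"] = json.dumps(kspace.header, default=float)


def load_kspace(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        return KSpaceData(samples=f["samples"][()],
                          header=json.loads(f.attrs["header"]))


def save_dictionary(d: SignalDictionary, path) -> None:
    with h5py.File(path, "w") as f:
        ax = f.create_group("axes")
        ax.create_dataset("t1", data=d.t1_values).attrs["units"] = "s"
        ax.create_dataset("t2", data=d.t2_values).attrs["units"] = "s"
        ax.create_dataset("b0", data=d.b0_values).attrs["units"] = "Hz"
        ax.create_dataset("slice", data=d.slice_positions).attrs["units"] = "m"
        f.create_dataset("signals", data=d.signals)
        f.create_dataset("entry_t1", data=d.entry_t1)
        f.create_dataset("entry_t2", data=d.entry_t2)
        f.attrs["header"] = json.dumps(d.header, default=float)


def load_dictionary(path) -> SignalDictionary:
    with h5py.File(path, "r") as f:
        return SignalDictionary(
            t1_values=f["axes/t1"][()], t2_values=f["axes/t2"][()],
            b0_values=f["axes/b0"][()], slice_positions=f["axes/slice"][()],
            signals=f["signals"][()], entry_t1=f["entry_t1"][()],
            entry_t2=f["entry_t2"][()], header=json.loads(f.attrs["header"]))


def save_nifti(image: np.ndarray, path, pixel_spacing=(1e-3, 1e-3)) -> None:
    """Write a magnitude image (or stack) as NIfTI with mm pixel spacing."""
    import nibabel as nib

    img = np.asarray(image, dtype=np.float32)
    affine = np.diag([pixel_spacing[-1] * 1e3, pixel_spacing[0] * 1e3, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.atleast_3d(img.T), affine), str(path))
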