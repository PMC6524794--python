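"""Export a sequence to the pulseq-style .seq text format and read it back.

The file carries the rectangular-gradient subset plus an extensions section
for the simulation-only events (software crushers, single-point recorders);
re-reading reproduces an identical discretized timeline.
"""

import tempfile
from pathlib import Path

import numpy as np

import deskmri as dm
from deskmri.pulseq import read_pulseq, write_pulseq

g = dm.GlobalParams(matrix_size=32, fov=0.24)
seq = dm.build_gre(g, tr=6e-3)
with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "gre32.seq"
    write_pulseq(seq, path)
    back = read_pulseq(path)
    a = dm.discretize(seq)
    b = dm.discretize(back)
    same = all(np.allclose(getattr(a, f), getattr(b, f), rtol=1e-9, atol=0)
               for f in ("gx", "gy", "gz", "b1_mag"))
    print(f"wrote {path.name}: {path.stat().st_size:,} bytes, "
          f"{sum(1 for _ in seq.iter_blocks())} blocks")
    print(f"round-trip timeline identical: {same} "
          f"({a.n_steps:,} steps, {a.n_adc} ADC samples)")
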