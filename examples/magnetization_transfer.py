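"""Two-pool magnetization transfer shortens the apparent MOLLI T1.

An agar-like cylinder is simulated with and without the Bloch-McConnell
semisolid pool.  RF saturation of the bound pool plus exchange drains
longitudinal magnetization from the free water pool, so the with-MT
apparent T1 is lower — the ordering reported for agar phantoms of
increasing macromolecular content.
"""

from deskmri.recipes import molli_agar

for conc in ("2%", "8%"):
    kw = dict(seed=0, concentration=conc, matrix=(64, 48), spacing=2.5e-3)
    off = molli_agar(with_mt=False, **kw)
    on = molli_agar(with_mt=True, **kw)
    print(f"agar {conc}: true T1 {off['true_t1_ms']:.0f} ms | apparent "
          f"{off['roi_t1_ms']:.0f} ms (MT off) -> {on['roi_t1_ms']:.0f} ms "
          f"(MT on), reduction {off['roi_t1_ms'] - on['roi_t1_ms']:.0f} ms")
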