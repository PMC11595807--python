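"""Annotate one MS1 feature with its MS2 spectrum against the library.

The feature below is the extract's most abundant ion: a doubly charged
precursor at m/z 225.1835 whose fragments read out both side chains — the
CH2N2 (methylenediamine) loss and subsequent alkyl-chain loss as dications,
and the guanidinoalkyl chain as a singly charged ion.
"""

import numpy as np

from crambederep import Feature, Ms2Spectrum, annotate_feature

spectrum = Ms2Spectrum(
    precursor_mz=225.1835,
    rt=11.70,
    mz=np.array([127.0863, 132.1130, 204.1721, 276.2321]),
    intensity=np.array([60.0, 90.0, 80.0, 25.0]),
    precursor_z=2,
)
feature = Feature(mz=225.1835, rt=11.70, z=2, intensity=1e6, ms2=spectrum)

for ann in annotate_feature(feature)[:4]:
    frags = ", ".join(f"{m.mz_obs:.4f}->{m.role}" for m in ann.matched)
    print(
        f"rank {ann.rank}: {ann.name:45s} score={ann.score:.2f} "
        f"ppm={ann.delta_ppm:+.2f}  [{frags}]"
    )
print(
    "\nThe top candidate matches all four diagnostic ions; same-formula"
    "\nhomologues (other m + n splits of C24H44N6O2) keep only the shared"
    "\nCH2N2-loss ion and rank below it."
)
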