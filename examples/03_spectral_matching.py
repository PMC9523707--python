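"""Direct and reverse match factors between stick spectra.

DMF compares two spectra over the union of their m/z channels; RMF restricts
the comparison to the reference's channels, forgiving extra signal in the
analyzed spectrum (co-elution, column bleed).  Both live on the NIST 0-999
scale used by the matching gates (750 for alignment, 900/950 for targeting).
"""
import numpy as np

import gcxfp as g

ref = g.simulate_spectrum("79-09-4")        # propionic acid reference
same = g.simulate_spectrum("79-09-4")
other = g.simulate_spectrum("71-23-8")      # 1-propanol reference

print("self match      : DMF", g.dmf(same, ref), " RMF", g.rmf(same, ref))
print("different CAS   : DMF", g.dmf(other, ref), " RMF", g.rmf(other, ref))

# contaminate the analyzed spectrum with extra channels: DMF drops, RMF holds
dense = ref.to_dense()
rng = np.random.default_rng(0)
extra = rng.choice(np.flatnonzero(dense == 0), size=12, replace=False)
dense[extra] = 300.0
dirty = g.MassSpectrum.from_dense(dense)
print("contaminated    : DMF", g.dmf(dirty, ref), " RMF", g.rmf(dirty, ref))
# the reverse factor ignores the added channels, which is why targeting
# demands RMF >= 950 while tolerating a lower direct factor threshold
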