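"""Mathieu parameters and RF calibration for the miniature linear ion trap.

Shows how the RF amplitude places a chosen m/z at the target stability
parameter q = 0.65, what secular frequency that ion oscillates at, and which
m/z the resonance-ejection AC removes at that amplitude.
"""

import segscan as ss

cfg = ss.TrapConfig()  # RF 1033 kHz, ejection AC 376 kHz, r0 = 4 mm

mz_center = 200.0
v = ss.rf_voltage_for_center(mz_center, cfg)
q = ss.mathieu_q(mz_center, v, cfg)
f_sec = ss.secular_frequency(mz_center, v, cfg)
mz_ej = ss.ejection_mz(v, cfg)

print(f"RF amplitude for m/z {mz_center:.0f} at q=0.65 : {v:8.1f} V (0-peak)")
print(f"Mathieu q of the centre ion                 : {q:8.4f}")
print(f"beta(q=0.65)                                : {ss.beta_from_q(q):8.4f}")
print(f"secular frequency of the centre ion         : {f_sec/1e3:8.1f} kHz")
print(f"m/z resonantly ejected at this RF amplitude : {mz_ej:8.1f}")

# The secular frequency falls with m/z: heavier ions sit at lower q.
# (m/z below ~143 is unstable at this amplitude: q would exceed 0.908.)
for mz in (150.0, 200.0, 400.0):
    f = ss.secular_frequency(mz, v, cfg)
    print(f"  m/z {mz:5.0f} -> q {ss.mathieu_q(mz, v, cfg):5.3f}, "
          f"f_secular {f/1e3:6.1f} kHz")

# The numbers above tie the mass axis to trap electronics: the ejected m/z
# scales linearly with RF amplitude, which is the mass calibration of a
# resonance-ejection scan; the secular frequencies feed the SWIFT design.
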