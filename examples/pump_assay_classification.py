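"""Classify transport mode from pH-electrode traces, with a CCCP pair.

A Na+-exporting pump alkalinizes the medium during illumination and the
protonophore CCCP *enhances* the signal (it would suppress a pure H+ pump).
"""

from narkit import pump_metrics, simulate_pump_trace

plain = simulate_pump_trace("na_export", cccp_present=False, noise_sd=0.001, seed=1)
with_cccp = simulate_pump_trace("na_export", cccp_present=True, noise_sd=0.001, seed=2)
m = pump_metrics(plain, paired_cccp_trace=with_cccp)

print(f"initial slope  = {m.initial_slope:+.5f} pH/s (drift-corrected)")
print(f"net delta-pH   = {m.net_delta_pH:+.3f} over the 150-s illumination")
print(f"classification = {m.classification}")
print(f"CCCP ratio     = {m.cccp_ratio:.2f}  (>1 confirms Na+ export, not H+)")
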