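"""How many exponentials does a surface need?  BIC-based selection.

The slow biexponential (SrNaR-like) surface with realistic measurement
noise is fitted with 0..4 components; the BIC table shows 2 is optimal.
"""

from narkit import SRNAR_MODEL, select_components, simulate_photocycle

surface = simulate_photocycle(SRNAR_MODEL, noise_sd=1e-4, seed=0)
chosen, table = select_components(surface, max_n=4)

print("n_components   BIC")
for n, bic in table.items():
    marker = "  <- chosen" if n == chosen else ""
    print(f"{n:12d}   {bic:12.1f}{marker}")
# Lower BIC is better; adding a third component no longer pays for its
# 37 extra parameters once the two true decays are modelled.
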