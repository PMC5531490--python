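# narkit

Analysis toolkit for **sodium-pumping rhodopsins (NaRs)** — light-driven
outward Na⁺ pumps such as KR2 and its relatives.  Functional
characterization of these pigments rests on three computational workflows,
all implemented here as a tested, reusable library:

1. **Flash-photolysis kinetics.**  A laser flash drives the pigment through
   a sequence of spectrally distinct intermediates (K → L/M → O → dark).
   The measured surface ΔA(λ, t) is analysed by *global multi-exponential
   fitting*: ΔA(λ, t) ≈ Σᵢ DASᵢ(λ)·e^(−t/τᵢ) + offset(λ), with the
   lifetimes τᵢ shared across all wavelengths and the per-wavelength
   amplitudes forming the decay-associated spectra (DAS).  Amplitudes are
   solved exactly inside the τ search (variable projection / separable
   least squares); model order is chosen by BIC.  Intermediates are then
   labelled from DAS signatures and the cycle time Σᵢτᵢ converted into a
   maximal turnover of 60/Σᵢτᵢ pumped ions per minute.
2. **Electrophysiology and pump assays.**  Whole-cell photocurrent metrics
   (peak, steady state, inactivation ratio, light-off relaxation τ_off),
   I–V slope, action-spectrum peak, light-saturation hyperbola
   I = I_max·P/(P + P½), pulse-train adaptation, spike detection for
   optogenetic silencing, and pH-electrode pump-assay classification
   (H⁺ export acidifies the medium, Na⁺ export alkalinizes it; the
   protonophore CCCP suppresses the former and enhances the latter).
3. **Phylogenetics.**  Protein p-distances (pairwise gap deletion), the
   Poisson correction d = −ln(1 − p), Saitou–Nei neighbor-joining with
   deterministic tie-breaking, and column-resampling bootstrap supports
   (1000 replicates by default) mapped onto the full-data tree, with
   Newick and PHYLIP output.

A `synth` module generates every input with known ground truth —
transient-absorption surfaces from sequential photocycle models (exact
Bateman kinetics), photocurrent and pH traces, and amino-acid alignments
evolved on a known tree under an equal-rates Poisson process — so the whole
pipeline is testable end to end without any downloads.

## Worked example

```python
from narkit import DARK_LAMBDA_MAX, KR2_MODEL, assign_intermediates, fit_global, simulate_photocycle

surface = simulate_photocycle(KR2_MODEL)      # noiseless 36×200 ΔA surface
fit = fit_global(surface, n_components=4)     # variable-projection global fit
assign = assign_intermediates(fit, DARK_LAMBDA_MAX["KR2"])
print(assign.scheme_string)
```

prints

```
K(2.6e-05s) -> L/M(0.001s) -> O(0.0079s) -> O(0.112s) -> dark
```

i.e. the fit recovers the four generating lifetimes (26 µs, 1 ms, 7.9 ms,
112 ms) exactly and labels them from their DAS: the early red-shifted K,
the strongly blue-shifted L/M, and the two slow red-shifted O decay
components.  The cycle time is their 0.121-s sum, an upper bound of ~496
transported Na⁺ per minute.  More narrative scripts live in `examples/`
(model-order selection, photocurrent metrics, pump-assay classification,
NJ + bootstrap), and a thin CLI (`narkit simulate|globalfit|photocycle|
ephys|pump|phylo`) wraps the same functions for file-based pipelines.

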