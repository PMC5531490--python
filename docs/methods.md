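# Methods

## Photocycle model and the synthetic surface generator

The generator implements a **sequential, irreversible photocycle**: a flash
promotes a fraction *f* (`excited_fraction`, default 0.1, dimensionless) of
the dark state into the first intermediate, and each intermediate relaxes
into the next with a first-order rate kᵢ (s⁻¹), the last step returning to
the dark state.  Branched or reversible schemes are deliberately out of
scope: the linear chain keeps the concentration profiles exactly solvable
by the Bateman closed form, which is what makes the generator a trustworthy
oracle for the fitting layer.  The closed form is singular for repeated
rates, so duplicate rate constants are rejected with instructions to
perturb one by ~0.1% rather than silently switching to the confluent form.

Each intermediate and the dark state carries a Gaussian absorption band
(centre nm, SD nm, relative amplitude); the surface is
ΔA(λ, t) = Σᵢ cᵢ(t)·[εᵢ(λ) − ε_dark(λ)], which automatically contains the
ground-state bleach through the depleted dark population.  Measurement
noise is i.i.d. Gaussian and homoscedastic across wavelengths — the
simplest model consistent with photomultiplier-limited detection, and the
assumption under which the unweighted global fit is maximum-likelihood.

Default grids: wavelengths 360–710 nm in 10-nm steps (36 points), times 200
log-spaced points from 1 µs to 10 s (≥ 25 points/decade over seven decades,
bracketing lifetimes from tens of microseconds to seconds).

The preset models (`presets.py`) place the dark band at 525/520/550 nm for
the KR2-, FdNaR- and SrNaR-like pigments, K and O near 600 nm and L/M near
400 nm, with the published lifetimes as the reciprocal rates.  The SrNaR
preset emulates the biexponential L/M decay as two spectrally similar
blue-shifted states with no red-shifted O.  The photolyzed fraction under
the flash energies used in practice is not known; 0.1 is a documented
default, and none of the fitting results depend on it (it scales amplitudes
only).

What the generator does **not** emulate: instrument response (laser pulse
width, monochromator bandwidth), spectrotemporal artifacts, wavelength-
dependent noise, and photo-selection/anisotropy.  Passing recovery tests
therefore demonstrate correctness of the analysis chain, not robustness to
every artifact of real spectrometers.

## Global fitting (variable projection)

For trial lifetimes {τᵢ} the amplitudes are the exact linear least-squares
solution over all wavelength channels simultaneously; the nonlinear search
therefore runs only over log₁₀ τ (n parameters instead of n·(1+n_λ)).
Optimization uses a bounded trust-region least-squares solver on the full
residual matrix with multistart: a pool of candidate log-τ values is laid
out at 8 per decade of the time grid, and starting sets of n points are
strided across sliding sub-windows of the pool (16 windows), so starts
cover both tight and wide lifetime spreads in every region of the grid.
Best RSS wins; the procedure is deterministic for a given surface.
Components are reported sorted by ascending τ.  A non-decaying offset
spectrum is included by default to absorb long-lived photoproducts and can
be disabled.

Model order is chosen by the Gaussian-likelihood BIC,
N·ln(RSS/N) + k·ln N with k = n·(1+n_λ) + n_λ, compared from the
offset-only model (n = 0) upward.  The traditional workflow fixes n per
pigment by inspection; BIC makes that choice explicit and testable.

Numerical choices: τ bounds one decade beyond the time grid on either
side; solver tolerances 1e−14 (noiseless surfaces are recovered to
~machine precision, well inside the 1% acceptance band); RSS clamped at
1e−300 inside the log for degenerate exact fits.  The single-trace fitter
(`fit_trace_multiexp`) reuses the same machinery on a 1-channel surface and
flags non-identifiable fits (all amplitudes negligible against the data
scale, or τ at a search bound).

## Intermediate assignment and turnover

Labels derive from the positive-lobe peak of each DAS relative to the dark
λmax: blue-shifted by > 60 nm → L/M (deprotonated Schiff base near 400 nm
against a 520–550 nm dark band, so the threshold has a wide margin);
red-shifted with τ < 1 ms → K; red-shifted with τ ≥ 1 ms → O.  Components
peaking inside the ambiguous band (within 60 nm blue or exactly at the dark
maximum) are left unassigned with a warning — in sequential schemes with
close rates, fast-component DAS mix dark-recovery and intermediate lobes,
and the rule does not pretend to resolve them.  The cycle time is defined
as Σᵢτᵢ over the fitted sequential components, and turnover = 60/Σᵢτᵢ
min⁻¹ (one transported ion per completed cycle, saturating light).  For the
SrNaR-like constants this gives 2.13 s and ~28 min⁻¹, which coexists in the
literature with a quoted ~15-s cycle (4 min⁻¹); both numbers are surfaced
and no reconciliation (e.g. photon-limited turnover) is encoded.

## Electrophysiology metrics

Baseline is the pre-light mean; the steady state is the mean over the last
20% of the light epoch (the epoch length is operator-chosen, so a fixed
fraction is the reproducible definition); τ_off comes from a
mono-exponential fit to the post-light segment.  I–V relations use ordinary
least squares with a voltage-insensitivity flag at |slope| < 0.02 pA/mV
(~5% of typical fitted pump slopes; configurable).  The action-spectrum
peak refines the grid maximum by a quadratic through three points — with a
10-nm grid and smooth band shapes this is accurate to well under half a
grid step; edge maxima are returned with a warning.  Light saturation fits
I = I_max·P/(P + P½) by nonlinear least squares from a deterministic start.
Spikes are upward threshold crossings (default −20 mV) with a 2-ms lockout.
Traces are assumed leak-subtracted and series-resistance compensated
upstream; no conductance-based neuron model is included.

## Pump assay

The initial slope is OLS over the first 30 s of illumination after
subtracting the pre-illumination OLS drift slope, so any linear dark drift
cancels by construction.  Classification uses a 3-standard-error rule on
the slope: significantly negative → H⁺ export, significantly positive →
Na⁺-export alkalinization, otherwise none.  The 30-s window and 3σ rule
replace the qualitative trace-shape judgement of the wet-lab workflow with
a testable criterion.  When a paired CCCP trace is supplied the ratio of
drift-corrected slopes is reported.  ΔpH is not converted to absolute ion
flux (buffer capacity and cell count are not modelled).

## Phylogenetics

p-distance uses pairwise gap deletion by default (complete deletion
available); the Poisson correction d = −ln(1 − p) assumes equal rates
across sites and residues — exactly the model the sequence simulator
implements, where events on a branch of length d occur as Poisson(20d/19)
and each event redraws the residue uniformly from 20, giving
E[p] = (19/20)(1 − e^(−20d/19)).  Neighbor-joining follows Saitou–Nei with
ties in the Q-criterion broken toward the lowest creation-order index pair
(reproducibility), negative branch-length estimates clamped to zero with
the raw value retained on the node, and the final three lineages joined at
a trifurcating root (unrooted convention).  Bootstrap supports are
percentages of column-resampled replicates containing each internal
bipartition of the **full-data** tree (not a replicate consensus); the
default is 1000 replicates.  Replicates whose resampled distances saturate
(p = 1) are dropped from the denominator.

## Problem sizes and determinism

Tests and the acceptance script run on the default 36×200 surface
(noiseless fits ~1 s each), traces of ≤ 6001 samples, alignments of
≤ 50 000 sites for the closed-form sequence check, and 20–200 bootstrap
replicates on 4–6 taxa — sizes chosen so the whole suite exercises every
code path in well under a coffee break while leaving the statistical checks
(3-SE bands, 100-replicate-calibrated tolerances) meaningful.  Every
stochastic step takes an explicit integer seed and reproduces
bit-identically; JSON outputs use sorted keys and 12-significant-digit
floats so pipeline reruns are byte-identical.
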