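"""Synthetic-data generators with known ground truth.

Every downstream stage of the toolkit (global kinetics, photocycle
assignment, electrophysiology metrics, pump-assay classification,
phylogenetics) is exercised on data produced here, so each generator has a
closed-form model that tests can invert.

Conventions used throughout the package:

* outward (pump) current is positive, depolarizing current negative;
* times are seconds for spectroscopy and pump assays, milliseconds for
  electrophysiology traces;
* all randomness flows through a caller-supplied integer seed and is
  bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhotocycleModel",
    "TransientAbsorptionSurface",
    "PhotocurrentTrace",
    "PumpTrace",
    "SyntheticAlignment",
    "GaussianBand",
    "default_time_grid",
    "default_wavelength_grid",
    "bateman_concentrations",
    "simulate_photocycle",
    "simulate_photocurrent",
    "simulate_pump_trace",
    "simulate_alignment",
    "AMINO_ACIDS",
]

#: Canonical 20 amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def default_wavelength_grid() -> np.ndarray:
    """Probe grid 360–710 nm in 10-nm steps (36 points)."""
    return np.arange(360.0, 711.0, 10.0)


def default_time_grid(n: int = 200, t_min: float = 1e-6, t_max: float = 10.0) -> np.ndarray:
    """Log-spaced delay grid, by default 200 points from 1 µs to 10 s.

    Seven decades at ~28 points/decade comfortably brackets photocycle
    constants from tens of microseconds to seconds.
    """
    return np.logspace(math.log10(t_min), math.log10(t_max), n)


@dataclass(frozen=True)
class GaussianBand:
    """Absorption band as a Gaussian in wavelength.

    Parameters are the band centre (nm), the Gaussian standard deviation
    (nm) and a relative peak amplitude (dimensionless; difference spectra
    are formed from these relative profiles).
    """

    center_nm: float
    width_nm: float
    amplitude: float = 1.0

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((lam - self.center_nm) / self.width_nm) ** 2)


@dataclass(frozen=True)
class PhotocycleModel:
    """Sequential (irreversible, unbranched) photocycle.

    A flash promotes a fraction ``excited_fraction`` of the dark state into
    the first intermediate; each step ``i`` relaxes with first-order rate
    ``rate_constants[i]`` (s⁻¹) into the next intermediate, the last step
    returning to the dark state.  Each intermediate, and the dark state,
    carries a Gaussian absorption band.

    Only the distinct-rate case is supported: the concentration profiles use
    the Bateman closed form, which is singular for repeated rates.  Callers
    with (near-)equal rates should perturb one of them by ~0.1%.
    """

    intermediate_names: tuple[str, ...]
    rate_constants: tuple[float, ...]
    intermediate_spectra: tuple[GaussianBand, ...]
    dark_spectrum: GaussianBand
    excited_fraction: float = 0.1

    def __post_init__(self) -> None:
        n = len(self.intermediate_names)
        if n == 0:
            raise ValueError("photocycle needs at least one intermediate")
        if len(self.rate_constants) != n or len(self.intermediate_spectra) != n:
            raise ValueError(
                "need one rate constant and one spectrum per intermediate "
                f"(got {len(self.rate_constants)} rates, {len(self.intermediate_spectra)} "
                f"spectra for {n} intermediates)"
            )
        if any(k <= 0 for k in self.rate_constants):
            raise ValueError("rate constants must be positive")
        ks = sorted(self.rate_constants)
        for a, b in zip(ks, ks[1:]):
            if b - a <= 1e-12 * b:
                raise ValueError(
                    "duplicate rate constants: the Bateman closed form is singular; "
                    "perturb one rate by ~0.1% and retry"
                )
        # f = 0 is allowed as the degenerate no-photolysis case (zero surface)
        if not 0.0 <= self.excited_fraction <= 1.0:
            raise ValueError("excited_fraction must lie in [0, 1]")
        for band in (*self.intermediate_spectra, self.dark_spectrum):
            if not 300.0 <= band.center_nm <= 800.0:
                raise ValueError(f"band centre {band.center_nm} nm outside 300–800 nm")

    @property
    def taus(self) -> tuple[float, ...]:
        """Lifetimes 1/k per step (s)."""
        return tuple(1.0 / k for k in self.rate_constants)


@dataclass(frozen=True)
class TransientAbsorptionSurface:
    """Flash-photolysis ΔA(λ, t) surface (wavelength × time)."""

    wavelengths: np.ndarray
    times: np.ndarray
    delta_A: np.ndarray
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.delta_A, dtype=float)
        if d.shape != (wl.size, t.size):
            raise ValueError(f"delta_A shape {d.shape} != (n_wavelengths={wl.size}, n_times={t.size})")
        if np.any(t <= 0):
            raise ValueError("delay times must be positive")
        if np.any(np.diff(t) <= 0):
            raise ValueError("delay times must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "delta_A", d)


@dataclass(frozen=True)
class PhotocurrentTrace:
    """Whole-cell photocurrent trace (ms, pA) with illumination epochs."""

    time: np.ndarray
    current: np.ndarray
    light_epochs: tuple[tuple[float, float], ...]
    holding_potential_mV: float = 0.0
    irradiance_mW_mm2: float = 0.8

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if t.shape != i.shape:
            raise ValueError("time and current must have equal length")
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("sampling must be uniform")
        for on, off in self.light_epochs:
            if not (t[0] <= on < off <= t[-1]):
                raise ValueError(f"light epoch ({on}, {off}) ms outside trace span")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "current", i)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class PumpTrace:
    """pH-electrode trace of an illuminated cell suspension (s, pH units)."""

    time: np.ndarray
    pH: np.ndarray
    illumination_window: tuple[float, float] = (0.0, 150.0)
    cccp_present: bool = False
    nacl_present: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.pH, dtype=float)
        if t.shape != p.shape:
            raise ValueError("time and pH must have equal length")
        if np.any(p < 0) or np.any(p > 14):
            raise ValueError("pH outside 0–14")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pH", p)


@dataclass(frozen=True)
class SyntheticAlignment:
    """Aligned amino-acid sequences with the generating tree attached."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    true_tree: str  # newick

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must be aligned (equal length)")

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


# ---------------------------------------------------------------------------
# flash photolysis


def bateman_concentrations(model: PhotocycleModel, times: np.ndarray) -> np.ndarray:
    """Intermediate concentrations of the sequential chain, shape (n, n_t).

    Closed-form solution of the first-order linear cascade
    I₁ → I₂ → … → dark with distinct rates (Bateman): with c₁(0) = f,

        cᵢ(t) = f · (Π_{j<i} k_j) · Σ_{j≤i} e^(−k_j t) / Π_{l≤i, l≠j} (k_l − k_j)

    Concentrations are fractions of the total pigment.
    """
    t = np.asarray(times, dtype=float)
    k = np.asarray(model.rate_constants, dtype=float)
    f = model.excited_fraction
    n = k.size
    conc = np.zeros((n, t.size))
    for i in range(n):
        ki = k[: i + 1]
        prefactor = f * np.prod(k[:i])
        for j in range(i + 1):
            denom = np.prod(np.delete(ki, j) - ki[j]) if i > 0 else 1.0
            conc[i] += np.exp(-ki[j] * t) / denom
        conc[i] *= prefactor
    return conc


def simulate_photocycle(
    model: PhotocycleModel,
    times: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TransientAbsorptionSurface:
    """Simulate a flash-photolysis ΔA(λ, t) surface from a photocycle model.

    The difference spectrum of each intermediate is its band minus the dark
    band, so ground-state bleach (the depleted dark population) is included
    automatically: ΔA(λ, t) = Σᵢ cᵢ(t)·[εᵢ(λ) − ε_dark(λ)].  Optional
    i.i.d. Gaussian noise (homoscedastic across wavelengths) is added last.
    """
    t = default_time_grid() if times is None else np.asarray(times, dtype=float)
    lam = default_wavelength_grid() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    if np.any(t <= 0):
        raise ValueError("delay times must be positive")

    conc = bateman_concentrations(model, t)  # (n, n_t)
    eps_dark = model.dark_spectrum(lam)
    diff = np.stack([band(lam) - eps_dark for band in model.intermediate_spectra])  # (n, n_wl)
    surface = diff.T @ conc  # (n_wl, n_t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        surface = surface + rng.normal(0.0, noise_sd, surface.shape)
    return TransientAbsorptionSurface(lam, t, surface, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# electrophysiology


def simulate_photocurrent(
    peak_pA: float,
    steady_pA: float,
    tau_inact_ms: float,
    tau_off_ms: float,
    light_epochs: list[tuple[float, float]] | None = None,
    duration_ms: float = 600.0,
    sampling_ms: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
    holding_potential_mV: float = 0.0,
    irradiance_mW_mm2: float = 0.8,
) -> PhotocurrentTrace:
    """Synthetic pump photocurrent: transient peak inactivating to a steady
    state during light, mono-exponential relaxation to baseline after
    light-off.

    During an epoch starting at t_on:
        I(t) = steady + (peak − steady)·e^(−(t−t_on)/τ_inact)
    After light-off at t_off the current relaxes as I(t_off)·e^(−(t−t_off)/τ_off).
    """
    if tau_inact_ms <= 0 or tau_off_ms <= 0:
        raise ValueError("time constants must be positive")
    if not peak_pA >= steady_pA >= 0:
        raise ValueError("pump convention requires peak ≥ steady ≥ 0")
    epochs = tuple(tuple(map(float, e)) for e in (light_epochs or []))
    t = np.arange(0.0, duration_ms + 0.5 * sampling_ms, sampling_ms)
    current = np.zeros_like(t)
    for on, off in epochs:
        lit = (t >= on) & (t < off)
        current[lit] = steady_pA + (peak_pA - steady_pA) * np.exp(-(t[lit] - on) / tau_inact_ms)
        i_off = steady_pA + (peak_pA - steady_pA) * math.exp(-(off - on) / tau_inact_ms)
        after = t >= off
        current[after] += i_off * np.exp(-(t[after] - off) / tau_off_ms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, current.shape)
    return PhotocurrentTrace(
        t,
        current,
        epochs,
        holding_potential_mV=holding_potential_mV,
        irradiance_mW_mm2=irradiance_mW_mm2,
    )


# ---------------------------------------------------------------------------
# pump assay


def simulate_pump_trace(
    mode: str = "na_export",
    rate_pH_per_s: float = 0.002,
    cccp_present: bool = False,
    cccp_factor: float = 2.0,
    window: tuple[float, float] = (0.0, 150.0),
    t_start: float = -60.0,
    t_end: float = 240.0,
    sampling_s: float = 1.0,
    noise_sd: float = 0.002,
    pH0: float = 7.0,
    seed: int | None = None,
    nacl_present: bool = True,
) -> PumpTrace:
    """Synthetic pH-electrode trace of an illuminated cell suspension.

    ``h_export``: medium acidifies during illumination (pH falls at
    ``rate_pH_per_s``); the protonophore CCCP short-circuits the proton
    gradient, suppressing the signal by ``cccp_factor``.  ``na_export``:
    medium alkalinizes (secondary proton uptake after Na⁺ extrusion); CCCP
    *enhances* it by ``cccp_factor``.  ``none``: flat.  The trace plateaus
    outside the window.
    """
    if mode not in ("h_export", "na_export", "none"):
        raise ValueError(f"unknown mode {mode!r}; expected h_export, na_export or none")
    if cccp_factor <= 0:
        raise ValueError("cccp_factor must be positive")
    t = np.arange(t_start, t_end + 0.5 * sampling_s, sampling_s)
    if mode == "none":
        rate = 0.0
    else:
        rate = -rate_pH_per_s if mode == "h_export" else rate_pH_per_s
        if cccp_present:
            rate = rate / cccp_factor if mode == "h_export" else rate * cccp_factor
    on, off = window
    elapsed_lit = np.clip(t, on, off) - on
    pH = pH0 + rate * elapsed_lit
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pH = pH + rng.normal(0.0, noise_sd, pH.shape)
    return PumpTrace(t, pH, illumination_window=window, cccp_present=cccp_present, nacl_present=nacl_present)


# ---------------------------------------------------------------------------
# sequence evolution


def simulate_alignment(true_tree: str | dendropy.Tree, n_sites: int, seed: int | None = None) -> SyntheticAlignment:
    """Evolve an amino-acid alignment on a known tree under an equal-rates
    Poisson substitution process.

    Each site evolves independently.  Along a branch of length ``d``
    (expected substitutions/site) events occur as a Poisson process with
    mean ``20·d/19``; at each event the residue is redrawn uniformly from
    the 20 amino acids (so the per-event replacement probability to each of
    the 19 alternatives is equal, and the expected number of *actual*
    substitutions per site is exactly ``d``).  The expected proportion of
    differing sites between two sequences at distance ``d`` is then
    p = (19/20)·(1 − e^(−20d/19)), the relation inverted by the Poisson
    distance correction.
    """
    if isinstance(true_tree, str):
        tree = dendropy.Tree.get(data=true_tree, schema="newick")
        newick = true_tree
    else:
        tree = true_tree
        newick = tree.as_string(schema="newick").strip()
    rng = np.random.default_rng(seed)
    root = tree.seed_node
    seqs: dict[int, np.ndarray] = {id(root): rng.integers(0, 20, size=n_sites)}
    taxa: list[str] = []
    leaf_seqs: list[str] = []
    for node in tree.preorder_node_iter():
        if node is root:
            parent_seq = seqs[id(root)]
        else:
            d = node.edge.length or 0.0
            parent_seq = seqs[id(node.parent_node)]
            seq = parent_seq.copy()
            if d > 0:
                n_events = rng.poisson(20.0 * d / 19.0, size=n_sites)
                hit = n_events > 0
                seq[hit] = rng.integers(0, 20, size=int(hit.sum()))
            seqs[id(node)] = seq
            parent_seq = seq
        if node.is_leaf():
            taxa.append(node.taxon.label)
            leaf_seqs.append("".join(AMINO_ACIDS[i] for i in parent_seq))
    return SyntheticAlignment(tuple(taxa), tuple(leaf_seqs), newick)
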