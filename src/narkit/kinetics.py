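"""Global multi-exponential analysis of transient-absorption surfaces.

The model fitted to a ΔA(λ, t) surface is

    ΔA(λ, t) ≈ Σᵢ DASᵢ(λ)·e^(−t/τᵢ) + offset(λ)

with the time constants τᵢ shared across all wavelength channels (global
fitting) and the per-wavelength pre-exponential amplitudes forming the
decay-associated spectra (DAS).  The fit uses separable (variable
projection) least squares: for any trial {τᵢ} the amplitudes and offset are
the exact solution of a linear least-squares problem, so the nonlinear
search runs only over log τ.  Multistart from a deterministic log-spaced
grid makes the optimiser reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .synth import TransientAbsorptionSurface

__all__ = [
    "DecayComponent",
    "GlobalFitResult",
    "TraceFitResult",
    "reconstruct_spectra",
    "fit_global",
    "select_components",
    "fit_trace_multiexp",
]


@dataclass(frozen=True)
class DecayComponent:
    """One exponential component: lifetime τ (s) and its DAS (amplitude per
    wavelength, absorbance units)."""

    tau: float
    das: np.ndarray

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        object.__setattr__(self, "das", np.asarray(self.das, dtype=float))


@dataclass(frozen=True)
class GlobalFitResult:
    """Result of a global multi-exponential fit.

    Components are sorted by ascending τ.  ``offset_spectrum`` is the
    non-decaying baseline per wavelength (zeros when the offset was
    disabled).  ``bic`` is the Gaussian-likelihood Bayesian information
    criterion used for model-order selection.
    """

    components: tuple[DecayComponent, ...]
    offset_spectrum: np.ndarray
    residual_matrix: np.ndarray
    rss: float
    n_parameters: int
    bic: float
    wavelengths: np.ndarray
    times: np.ndarray

    @property
    def taus(self) -> np.ndarray:
        return np.array([c.tau for c in self.components])

    @property
    def das_matrix(self) -> np.ndarray:
        """DAS stacked as (n_components, n_wavelengths)."""
        return np.stack([c.das for c in self.components]) if self.components else np.empty((0, self.wavelengths.size))

    def reconstruction(self) -> np.ndarray:
        """Model surface Σᵢ DASᵢ(λ)·e^(−t/τᵢ) + offset(λ)."""
        out = np.tile(self.offset_spectrum[:, None], (1, self.times.size))
        for c in self.components:
            out += np.outer(c.das, np.exp(-self.times / c.tau))
        return out


def reconstruct_spectra(surface: TransientAbsorptionSurface, delay_times) -> dict[float, np.ndarray]:
    """Transient spectra (ΔA vs λ) at the requested delays.

    Each spectrum is obtained by linear interpolation in log-time at every
    wavelength; delays must lie within the measured span.
    """
    t = surface.times
    delays = np.atleast_1d(np.asarray(delay_times, dtype=float))
    for d in delays:
        if not t[0] <= d <= t[-1]:
            raise ValueError(f"delay {d:g} s outside measured span [{t[0]:g}, {t[-1]:g}] s")
    log_t = np.log(t)
    out: dict[float, np.ndarray] = {}
    for d in delays:
        out[float(d)] = np.array(
            [np.interp(math.log(d), log_t, surface.delta_A[i]) for i in range(surface.wavelengths.size)]
        )
    return out


def _design_matrix(times: np.ndarray, taus: np.ndarray, fit_offset: bool) -> np.ndarray:
    cols = [np.exp(-times / tau) for tau in taus]
    if fit_offset:
        cols.append(np.ones_like(times))
    return np.column_stack(cols)


def _solve_linear(times: np.ndarray, data_T: np.ndarray, taus: np.ndarray, fit_offset: bool):
    """Exact linear solve of amplitudes for fixed τ.  data_T is (n_t, n_wl)."""
    E = _design_matrix(times, taus, fit_offset)
    amps, *_ = np.linalg.lstsq(E, data_T, rcond=None)
    resid = data_T - E @ amps
    return amps, resid


def _multistart_log_taus(times: np.ndarray, n: int, seeds_per_decade: int = 8) -> list[np.ndarray]:
    """Deterministic starting sets for the log-τ search.

    A pool of candidate log₁₀ τ values is laid out at ``seeds_per_decade``
    per decade of the time grid; starting sets are n points evenly strided
    across sliding sub-windows of the pool, so starts cover tight and wide
    τ spreads in every region of the grid.
    """
    lo, hi = math.log10(times[0]), math.log10(times[-1])
    n_pool = max(n + 1, int(round((hi - lo) * seeds_per_decade)) + 1)
    pool = np.linspace(lo, hi, n_pool)
    starts: list[np.ndarray] = []
    for frac_lo in (0.0, 0.15, 0.3, 0.45):
        for frac_hi in (0.55, 0.7, 0.85, 1.0):
            if frac_hi - frac_lo < 0.2:
                continue
            a = lo + frac_lo * (hi - lo)
            b = lo + frac_hi * (hi - lo)
            starts.append(np.linspace(a, b, n + 2)[1:-1] if n > 1 else np.array([(a + b) / 2]))
    # de-duplicate (single-component windows collapse to similar midpoints)
    uniq: list[np.ndarray] = []
    for s in starts:
        if not any(np.allclose(s, u, atol=1e-9) for u in uniq):
            uniq.append(s)
    return uniq


def fit_global(
    surface: TransientAbsorptionSurface,
    n_components: int,
    fit_offset: bool = True,
    seeds_per_decade: int = 8,
) -> GlobalFitResult:
    """Global fit of ``n_components`` shared exponentials to a surface.

    Separable least squares: amplitudes (DAS and offset) are solved exactly
    for each trial {τᵢ}; the τ search runs in log₁₀ τ with multistart from a
    fixed grid, best RSS wins.  Deterministic for a given surface.
    """
    if n_components < 1:
        raise ValueError("n_components must be ≥ 1 (use select_components for the offset-only model)")
    times, data = surface.times, surface.delta_A
    if times.size < 2 * n_components:
        raise ValueError(f"{times.size} time points cannot constrain {n_components} components (need ≥ {2 * n_components})")
    data_T = data.T  # (n_t, n_wl)
    lo, hi = math.log10(times[0]) - 1.0, math.log10(times[-1]) + 1.0

    def residual_vec(log_tau: np.ndarray) -> np.ndarray:
        _, resid = _solve_linear(times, data_T, 10.0 ** log_tau, fit_offset)
        return resid.ravel()

    best = None
    for start in _multistart_log_taus(times, n_components, seeds_per_decade):
        sol = least_squares(
            residual_vec,
            start,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=400 * n_components,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("global fit failed to converge from any start")

    taus = np.sort(10.0 ** best.x)
    amps, resid = _solve_linear(times, data_T, taus, fit_offset)
    n_wl = surface.wavelengths.size
    components = tuple(DecayComponent(float(taus[i]), amps[i]) for i in range(n_components))
    offset = amps[n_components] if fit_offset else np.zeros(n_wl)
    rss = float(np.sum(resid**2))
    n_params = n_components * (1 + n_wl) + (n_wl if fit_offset else 0)
    n_obs = data.size
    bic = n_obs * math.log(max(rss, 1e-300) / n_obs) + n_params * math.log(n_obs)
    return GlobalFitResult(
        components=components,
        offset_spectrum=offset,
        residual_matrix=resid.T,
        rss=rss,
        n_parameters=n_params,
        bic=bic,
        wavelengths=surface.wavelengths,
        times=times,
    )


def select_components(
    surface: TransientAbsorptionSurface,
    max_n: int,
    fit_offset: bool = True,
) -> tuple[int, dict[int, float]]:
    """Choose the number of exponentials by BIC.

    Fits n = 0 (offset-only, or the null model without offset) through
    ``max_n`` components and returns (argmin-BIC n, per-n BIC table).
    """
    if max_n < 1:
        raise ValueError("max_n must be ≥ 1")
    n_obs = surface.delta_A.size
    n_wl = surface.wavelengths.size
    table: dict[int, float] = {}
    if fit_offset:
        offset = surface.delta_A.mean(axis=1, keepdims=True)
        rss0 = float(np.sum((surface.delta_A - offset) ** 2))
        k0 = n_wl
    else:
        rss0 = float(np.sum(surface.delta_A**2))
        k0 = 0
    table[0] = n_obs * math.log(max(rss0, 1e-300) / n_obs) + k0 * math.log(n_obs)
    for n in range(1, max_n + 1):
        table[n] = fit_global(surface, n, fit_offset=fit_offset).bic
    chosen = min(table, key=table.get)
    return chosen, table


@dataclass(frozen=True)
class TraceFitResult:
    """Multi-exponential fit of a single trace y(t) = Σᵢ aᵢ·e^(−t/τᵢ) + c."""

    taus: np.ndarray
    amplitudes: np.ndarray
    offset: float
    rss: float
    identifiable: bool = True

    def __iter__(self):
        yield from zip(self.taus, self.amplitudes)


def fit_trace_multiexp(
    time: np.ndarray,
    value: np.ndarray,
    n: int,
    fit_offset: bool = True,
) -> TraceFitResult:
    """Scalar-amplitude analogue of :func:`fit_global` for one trace.

    Time must be positive and increasing (shift to start at the decay onset
    before calling).  Components are returned sorted by ascending τ.  A fit
    whose amplitudes are all negligible against the data scale, or whose τ
    sits at the search bound, is flagged non-identifiable.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(value, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("time and value must be 1-D and equal length")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    # the exponential basis needs strictly positive times; nudge an exact zero
    t = np.where(t == 0, max(t[t > 0].min() * 1e-3, 1e-12) if np.any(t > 0) else 1e-12, t)
    surface = TransientAbsorptionSurface(np.array([0.0]), t, y[None, :])
    fit = fit_global(surface, n, fit_offset=fit_offset)
    taus = fit.taus
    amps = np.array([c.das[0] for c in fit.components])
    scale = max(float(np.ptp(y)), abs(float(y[0])), 1e-30)
    lo, hi = math.log10(t[0]) - 1.0, math.log10(t[-1]) + 1.0
    at_bound = bool(np.any(np.log10(taus) < lo + 1e-6) or np.any(np.log10(taus) > hi - 1e-6))
    identifiable = bool(np.max(np.abs(amps)) > 1e-6 * scale) and not at_bound
    if not identifiable:
        warnings.warn("exponential fit is non-identifiable (negligible amplitude or tau at bound)", stacklevel=2)
    return TraceFitResult(
        taus=taus,
        amplitudes=amps,
        offset=float(fit.offset_spectrum[0]) if fit_offset else 0.0,
        rss=fit.rss,
        identifiable=identifiable,
    )
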