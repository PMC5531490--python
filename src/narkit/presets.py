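"""Reference photocycle models for the three characterized sodium pumps.

The decay constants are the published flash-photolysis lifetimes; band
positions follow classic microbial-rhodopsin spectroscopy: the dark state
absorbs in the green (λmax ≈ 520–550 nm), the early red-shifted K
intermediate near 600 nm, the deprotonated-Schiff-base L/M intermediate
near 400 nm, and the late red-shifted O intermediate near 600 nm.  SrNaR
shows only a biexponentially decaying L/M with no O accumulation.
"""

from __future__ import annotations

from .synth import GaussianBand, PhotocycleModel

__all__ = ["KR2_MODEL", "FDNAR_MODEL", "SRNAR_MODEL", "PROTEIN_MODELS", "DARK_LAMBDA_MAX"]

#: Dark-state absorption maxima (nm) used for intermediate assignment.
DARK_LAMBDA_MAX = {"KR2": 525.0, "FdNaR": 520.0, "SrNaR": 550.0}

_WIDTH = 40.0  # nm; typical retinal-band Gaussian SD

KR2_MODEL = PhotocycleModel(
    intermediate_names=("K", "L/M", "O1", "O2"),
    rate_constants=(1.0 / 26e-6, 1.0 / 1e-3, 1.0 / 7.9e-3, 1.0 / 112e-3),
    intermediate_spectra=(
        GaussianBand(600.0, _WIDTH, 1.0),
        GaussianBand(400.0, _WIDTH, 0.9),
        GaussianBand(605.0, _WIDTH, 1.1),
        GaussianBand(590.0, _WIDTH, 1.0),
    ),
    dark_spectrum=GaussianBand(DARK_LAMBDA_MAX["KR2"], _WIDTH, 1.0),
    excited_fraction=0.1,
)

FDNAR_MODEL = PhotocycleModel(
    intermediate_names=("K", "L/M", "O1", "O2"),
    rate_constants=(1.0 / 40e-6, 1.0 / 1.63e-3, 1.0 / 15e-3, 1.0 / 55e-3),
    intermediate_spectra=(
        GaussianBand(595.0, _WIDTH, 1.0),
        GaussianBand(400.0, _WIDTH, 0.9),
        GaussianBand(600.0, _WIDTH, 1.1),
        GaussianBand(585.0, _WIDTH, 1.0),
    ),
    dark_spectrum=GaussianBand(DARK_LAMBDA_MAX["FdNaR"], _WIDTH, 1.0),
    excited_fraction=0.1,
)

# Two spectrally similar blue-shifted states decaying with the two printed
# constants emulate the biexponential L/M decay; no red-shifted O.
SRNAR_MODEL = PhotocycleModel(
    intermediate_names=("L/M-1", "L/M-2"),
    rate_constants=(1.0 / 0.59, 1.0 / 1.54),
    intermediate_spectra=(
        GaussianBand(400.0, _WIDTH, 0.9),
        GaussianBand(410.0, _WIDTH, 0.85),
    ),
    dark_spectrum=GaussianBand(DARK_LAMBDA_MAX["SrNaR"], _WIDTH, 1.0),
    excited_fraction=0.1,
)

PROTEIN_MODELS = {"KR2": KR2_MODEL, "FdNaR": FDNAR_MODEL, "SrNaR": SRNAR_MODEL}
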